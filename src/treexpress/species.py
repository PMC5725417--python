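"""Species sets and canonical pair ordering.

Every "tree" in this package is a vector of pairwise inter-species
distances.  For that representation to be comparable across genes,
regions and tissues, the ordering of species pairs must be fixed once
per run; :class:`SpeciesSet` owns that ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Tuple


@dataclass(frozen=True)
class SpeciesSet:
    """An ordered collection of species labels.

    The pair order is the lexicographic order of index pairs under the
    label ordering, i.e. ``(0,1), (0,2), ..., (1,2), ...``.  Six species
    yield 15 unordered pairs.
    """

    labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 3:
            raise ValueError("a SpeciesSet needs at least three species")
        if len(set(labels)) != len(labels):
            raise ValueError("species labels must be unique")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_pairs(self) -> int:
        return self.n * (self.n - 1) // 2

    @property
    def pairs(self) -> Tuple[Tuple[str, str], ...]:
        return tuple(combinations(self.labels, 2))

    @property
    def pair_labels(self) -> Tuple[str, ...]:
        return tuple(f"{a}|{b}" for a, b in self.pairs)

    def pair_index(self, a: str, b: str) -> int:
        i, j = sorted((self.labels.index(a), self.labels.index(b)))
        if i == j:
            raise ValueError("a pair needs two distinct species")
        # index of pair (i, j) in combinations order
        n = self.n
        return i * n - i * (i + 1) // 2 + (j - i - 1)

    def index(self, label: str) -> int:
        return self.labels.index(label)


#: Canonical six-primate panel spanning the five major primate groups
#: (two Old World monkeys).
SIX_PRIMATES = SpeciesSet(
    ("human", "chimpanzee", "macaque", "baboon", "marmoset", "mouse_lemur")
)
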