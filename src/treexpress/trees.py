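"""Pairwise-distance vectors, the package's tree representation.

A phylogenetic tree whose only consumer is a pairwise Pearson
correlation is fully described by its vector of leaf-to-leaf distances;
no topology inference is ever needed.  Both genomic (Jukes-Cantor) and
expression (delta) trees share this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .species import SpeciesSet


@dataclass
class PairDistanceVector:
    """Distances over all unordered species pairs, in canonical order."""

    species: SpeciesSet
    values: np.ndarray
    label: object = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.species.n_pairs,):
            raise ValueError(
                f"expected {self.species.n_pairs} pair distances, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pair distances must be finite")
        if np.any(self.values < 0):
            raise ValueError("pair distances must be non-negative")

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self.species.pair_index(a, b)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.species.pair_labels),
                         name=self.label)

    def __len__(self) -> int:
        return len(self.values)


def squareform(vec: PairDistanceVector) -> pd.DataFrame:
    """Expand a pair vector into a symmetric species × species matrix."""
    n = vec.species.n
    mat = np.zeros((n, n))
    for k, (a, b) in enumerate(vec.species.pairs):
        i, j = vec.species.index(a), vec.species.index(b)
        mat[i, j] = mat[j, i] = vec.values[k]
    labels = list(vec.species.labels)
    return pd.DataFrame(mat, index=labels, columns=labels)
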