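"""Per-gene genomic distance trees.

For every gene and region, pairwise sequence divergence is the
proportion of differing sites p, corrected for multiple substitutions
with the Jukes-Cantor maximum-likelihood estimate

    d = -(3/4) ln(1 - (4/3) p)

and assembled into a :class:`~treexpress.trees.PairDistanceVector`.
Each gene tree is then normalized by the global inter-species tree so
that gene-specific deviations, not overall phylogenetic distance,
drive the downstream correlation.

Sequences are compared positionwise over the first min-length
positions (no alignment stage; regions come from coordinate-anchored
extraction).  p ≥ 3/4 saturates the JC formula; the default policy
drops the gene for that region, optionally capping at a finite value
instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .species import SpeciesSet
from .trees import PairDistanceVector
from .regions import RegionSequenceSet

JC_SATURATION = 0.75


class SaturationError(ValueError):
    """p ≥ 3/4: the JC estimate is undefined (infinite divergence)."""


class UndefinedDistanceError(ValueError):
    """No overlapping sequence to compare (comparison length 0)."""


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of mismatching positions over the first min-length sites."""
    L = min(len(seq_a), len(seq_b))
    if L == 0:
        raise UndefinedDistanceError("empty sequence comparison")
    a = np.frombuffer(seq_a[:L].encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq_b[:L].encode("ascii"), dtype=np.uint8)
    return float(np.count_nonzero(a != b)) / L


def jukes_cantor(p: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Jukes-Cantor ML substitution estimate d = -(3/4) ln(1 - 4p/3).

    Scalar input with p ≥ 3/4 raises :class:`SaturationError`; array
    input returns ``inf`` at saturated entries (callers apply their
    saturation policy).
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("p must lie in [0, 1]")
    if arr.ndim == 0:
        if arr >= JC_SATURATION:
            raise SaturationError(f"p = {float(arr)} >= 3/4 saturates the JC estimate")
        return float(-0.75 * np.log1p(-4.0 * float(arr) / 3.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = -0.75 * np.log1p(-4.0 * arr / 3.0)
    d[arr >= JC_SATURATION] = np.inf
    return d


def build_gene_tree(
    region_set: RegionSequenceSet,
    species_set: SpeciesSet,
    saturation: str = "drop",
    cap: float = 5.0,
) -> Optional[PairDistanceVector]:
    """JC distances over all species pairs for one gene × region.

    Returns ``None`` when a pair saturates under the ``drop`` policy
    (the gene is excluded from that region's analysis).
    """
    values = np.empty(species_set.n_pairs)
    for k, (a, b) in enumerate(species_set.pairs):
        p = p_distance(region_set.sequences[a], region_set.sequences[b])
        try:
            values[k] = jukes_cantor(p)
        except SaturationError:
            if saturation == "cap":
                values[k] = cap
            elif saturation == "drop":
                return None
            else:
                raise
    return PairDistanceVector(species_set, values,
                              label=(region_set.gene_id, region_set.region))


@dataclass
class DropRecord:
    gene_id: str
    region: str
    reason: str


def build_tree_table(
    region_sets: Sequence[RegionSequenceSet],
    species_set: SpeciesSet,
    saturation: str = "drop",
    cap: float = 5.0,
) -> Tuple[pd.DataFrame, List[DropRecord]]:
    """Gene × pair JC distance table for one region (vectorized).

    Rows are genes, columns the canonical species-pair labels.  Genes
    whose comparison length is zero or that saturate (under ``drop``)
    are omitted and logged.
    """
    drops: List[DropRecord] = []
    rows, index = [], []
    pairs = species_set.pairs
    for rs in region_sets:
        encoded = {
            sp: np.frombuffer(rs.sequences[sp].encode("ascii"), dtype=np.uint8)
            for sp in species_set.labels
        }
        p = np.empty(len(pairs))
        bad = None
        for k, (a, b) in enumerate(pairs):
            L = min(len(encoded[a]), len(encoded[b]))
            if L == 0:
                bad = "zero comparison length"
                break
            p[k] = np.count_nonzero(encoded[a][:L] != encoded[b][:L]) / L
        if bad is None and np.any(p >= JC_SATURATION):
            if saturation == "cap":
                pass
            else:
                bad = "JC saturation (p >= 3/4)"
        if bad is not None:
            drops.append(DropRecord(rs.gene_id, rs.region, bad))
            continue
        d = jukes_cantor(p)
        if saturation == "cap":
            d = np.where(np.isinf(d), cap, d)
        rows.append(d)
        index.append(rs.gene_id)
    df = pd.DataFrame(
        np.array(rows).reshape(len(rows), len(pairs)),
        index=index,
        columns=list(species_set.pair_labels),
    )
    return df, drops


# ---------------------------------------------------------------------------
# global tree normalization


def load_global_tree(source, species_set: SpeciesSet) -> PairDistanceVector:
    """Load the global normalizing tree from Newick or a pairwise TSV.

    Newick input yields patristic (branch-length path) distances; TSV
    input needs columns species_a, species_b, distance.  All pairwise
    distances must be strictly positive (they are denominators).
    """
    text = _read_text(source)
    if text.lstrip().startswith("("):
        vec = _patristic_from_newick(text, species_set)
    else:
        vec = _pairs_from_tsv(text, species_set)
    if np.any(vec.values <= 0):
        raise ValueError("global tree distances must be strictly positive")
    return vec


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    text = str(source)
    if "\n" in text or text.lstrip().startswith("("):
        return text
    with open(text) as fh:
        return fh.read()


def _patristic_from_newick(text: str, species_set: SpeciesSet) -> PairDistanceVector:
    import dendropy

    tree = dendropy.Tree.get(data=text, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label.replace(" ", "_"): t for t in tree.taxon_namespace}
    values = np.empty(species_set.n_pairs)
    for k, (a, b) in enumerate(species_set.pairs):
        try:
            values[k] = pdm.patristic_distance(taxa[a], taxa[b])
        except KeyError as exc:
            raise ValueError(f"species {exc} missing from global tree") from exc
    return PairDistanceVector(species_set, values, label="global")


def _pairs_from_tsv(text: str, species_set: SpeciesSet) -> PairDistanceVector:
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t")
    lut = {}
    for _, row in df.iterrows():
        a, b = sorted((str(row.iloc[0]), str(row.iloc[1])))
        lut[(a, b)] = float(row.iloc[2])
    values = np.empty(species_set.n_pairs)
    for k, pair in enumerate(species_set.pairs):
        key = tuple(sorted(pair))
        if key not in lut:
            raise ValueError(f"pair {key} missing from global tree table")
        values[k] = lut[key]
    return PairDistanceVector(species_set, values, label="global")


def normalize_by_global(
    gene_tree: Union[PairDistanceVector, pd.DataFrame],
    global_tree: PairDistanceVector,
) -> Union[PairDistanceVector, pd.DataFrame]:
    """Divide each pair distance by the global tree's distance.

    Pearson correlation is invariant under positive affine maps, so the
    ratio form g/G and the percent-difference form (g−G)/G yield
    identical downstream statistics; the ratio is used.
    Accepts a single vector or a gene × pair table.
    """
    if np.any(global_tree.values <= 0):
        raise ValueError("global tree distances must be strictly positive")
    if isinstance(gene_tree, pd.DataFrame):
        if list(gene_tree.columns) != list(global_tree.species.pair_labels):
            raise ValueError("pair columns do not match the global tree")
        return gene_tree / global_tree.values
    if gene_tree.species != global_tree.species:
        raise ValueError("species sets differ between gene and global tree")
    return PairDistanceVector(
        gene_tree.species, gene_tree.values / global_tree.values,
        label=gene_tree.label,
    )
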