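"""Expression tables, quantile normalization, enrichment and delta trees.

Expression arrives as a gene × (species, tissue) matrix of
already-quantified values (any unit; quantile normalization makes
columns comparable).  Per gene and tissue, the expression "tree" is the
vector of absolute differences of quantile-normalized expression over
species pairs; per tissue, the whole-transcriptome divergence tree is
the Euclidean distance over all genes.

A tissue-enriched gene is expressed in that tissue at least
``fold_threshold`` (default 5) times higher than its average across all
other tissues; a tissue enters the analysis only when it has strictly
more than ``size_threshold`` (default 100) enriched genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .species import SpeciesSet
from .trees import PairDistanceVector

FOLD_THRESHOLD = 5.0
SIZE_THRESHOLD = 100


@dataclass
class ExpressionTable:
    """Gene × (species, tissue) expression matrix.

    ``data`` has a two-level column MultiIndex (species, tissue); every
    (species, tissue) cell of the grid must be present.
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.data.columns, pd.MultiIndex):
            raise ValueError("columns must be a (species, tissue) MultiIndex")
        if self.data.isna().any().any():
            raise ValueError("expression table has missing cells")
        species = self.species
        tissues = self.tissues
        have = set(self.data.columns)
        missing = [(s, t) for s in species for t in tissues if (s, t) not in have]
        if missing:
            raise ValueError(f"incomplete (species, tissue) grid; missing {missing[:5]}")

    @property
    def species(self) -> List[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    @property
    def tissues(self) -> List[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(1)))

    @property
    def genes(self) -> List[str]:
        return list(self.data.index)

    @classmethod
    def read_tsv(cls, source, normalized: bool = False) -> "ExpressionTable":
        """Read a TSV whose first column is gene_id and remaining columns
        are named ``<species>.<tissue>``."""
        df = pd.read_csv(source, sep="\t", index_col=0,
                         float_precision="round_trip")
        cols = []
        for c in df.columns:
            if "." not in c:
                raise ValueError(f"column {c!r} is not of the form species.tissue")
            sp, tissue = c.split(".", 1)
            cols.append((sp, tissue))
        df.columns = pd.MultiIndex.from_tuples(cols, names=["species", "tissue"])
        return cls(df, normalized=normalized)

    def write_tsv(self, path) -> None:
        flat = self.data.copy()
        flat.columns = [f"{s}.{t}" for s, t in flat.columns]
        flat.to_csv(path, sep="\t", index_label="gene_id")


def quantile_normalize(table: ExpressionTable) -> ExpressionTable:
    """Force every column to share one value distribution, rank-preserving.

    The k-th smallest value in each column becomes the mean of the k-th
    smallest values across columns.  Tied values within a column receive
    the mean of the reference values of their tied ranks.
    """
    if table.normalized:
        raise ValueError("table is already quantile-normalized")
    vals = table.data.to_numpy(dtype=float)
    n, m = vals.shape
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(m):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = ref
        # average reference values across ties (groups of equal raw values)
        s = pd.Series(assigned)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    df = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    return ExpressionTable(df, normalized=True)


def cross_database_check(
    table_a: ExpressionTable,
    table_b: ExpressionTable,
    tissues: Sequence[str],
) -> pd.Series:
    """Per-tissue Pearson r between two sources, on log2 scale.

    Used to confirm that two expression databases are concordant for
    shared tissues.  Gene sets are intersected; values are
    log2(x + 1)-transformed before correlating.
    """
    if not (table_a.normalized and table_b.normalized):
        raise ValueError("both tables must be quantile-normalized first")
    shared = table_a.data.index.intersection(table_b.data.index)
    if shared.empty:
        raise ValueError("no shared genes between the two tables")
    out = {}
    for tissue in tissues:
        a = table_a.data.loc[shared].xs(tissue, axis=1, level=1).mean(axis=1)
        b = table_b.data.loc[shared].xs(tissue, axis=1, level=1).mean(axis=1)
        out[tissue] = float(np.corrcoef(np.log2(a + 1), np.log2(b + 1))[0, 1])
    return pd.Series(out, name="pearson_r")


@dataclass
class EnrichedGeneSet:
    tissue: str
    genes: Set[str]
    fold_threshold: float = FOLD_THRESHOLD
    size_threshold: int = SIZE_THRESHOLD

    @property
    def passed_size_filter(self) -> bool:
        return len(self.genes) > self.size_threshold


def tissue_enriched_genes(
    table: ExpressionTable,
    tissue: str,
    fold_threshold: float = FOLD_THRESHOLD,
    size_threshold: int = SIZE_THRESHOLD,
) -> EnrichedGeneSet:
    """Genes at least ``fold_threshold``-fold above their average over all
    other tissues (species-averaged expression; boundary inclusive).

    A gene with zero expression everywhere else but positive in the
    tissue counts as enriched (infinite fold); zero in both is excluded.
    """
    if not table.normalized:
        raise ValueError("enrichment is defined on quantile-normalized data")
    if tissue not in table.tissues:
        raise ValueError(f"tissue {tissue!r} not in table")
    by_tissue = table.data.T.groupby(level=1).mean().T  # gene × tissue, species-averaged
    target = by_tissue[tissue]
    others = by_tissue.drop(columns=[tissue]).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        enriched = (target >= fold_threshold * others) & ~((target == 0) & (others == 0))
    genes = set(by_tissue.index[enriched])
    return EnrichedGeneSet(tissue, genes, fold_threshold, size_threshold)


def build_expression_tree(
    table: ExpressionTable, gene: str, tissue: str, species_set: SpeciesSet
) -> PairDistanceVector:
    """Per-pair |delta| of quantile-normalized expression for one gene."""
    if not table.normalized:
        raise ValueError("expression trees use quantile-normalized data")
    x = np.array([table.data.loc[gene, (sp, tissue)] for sp in species_set.labels])
    values = np.array([abs(x[species_set.index(a)] - x[species_set.index(b)])
                       for a, b in species_set.pairs])
    return PairDistanceVector(species_set, values, label=(gene, tissue))


def expression_tree_table(
    table: ExpressionTable,
    genes: Sequence[str],
    tissue: str,
    species_set: SpeciesSet,
) -> pd.DataFrame:
    """Gene × pair |delta| table for one tissue (vectorized)."""
    if not table.normalized:
        raise ValueError("expression trees use quantile-normalized data")
    cols = [(sp, tissue) for sp in species_set.labels]
    X = table.data.loc[list(genes), cols].to_numpy(dtype=float)
    idx_a = [species_set.index(a) for a, _ in species_set.pairs]
    idx_b = [species_set.index(b) for _, b in species_set.pairs]
    deltas = np.abs(X[:, idx_a] - X[:, idx_b])
    return pd.DataFrame(deltas, index=list(genes),
                        columns=list(species_set.pair_labels))


def tissue_divergence(
    table: ExpressionTable, tissue: str, species_set: SpeciesSet
) -> PairDistanceVector:
    """Whole-transcriptome Euclidean distance per species pair, one tissue."""
    if not table.normalized:
        raise ValueError("tissue divergence uses quantile-normalized data")
    cols = [(sp, tissue) for sp in species_set.labels]
    X = table.data.loc[:, cols].to_numpy(dtype=float)
    idx_a = [species_set.index(a) for a, _ in species_set.pairs]
    idx_b = [species_set.index(b) for _, b in species_set.pairs]
    values = np.sqrt(((X[:, idx_a] - X[:, idx_b]) ** 2).sum(axis=0))
    return PairDistanceVector(species_set, values, label=("divergence", tissue))
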