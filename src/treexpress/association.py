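"""Tree-correlation distributions, permutation null, and shift tests.

Per gene, the genomic tree (normalized JC distances) and the expression
tree (|delta| of normalized expression) are compared with the Pearson
correlation over the 15 species pairs.  Per region × tissue cell, the
distribution of per-gene correlations (area-normalized density) is
compared against a gene-permutation null: the genomic tree of one gene
paired with the expression tree of another, repeated for 1000
iterations per tissue and averaged/pooled across tissues into one null
per region.  Distribution shifts are tested with two-sample
Kolmogorov-Smirnov and Kruskal-Wallis tests, Bonferroni-corrected over
all region × tissue cells (per test family).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_BINS = 40
DEFAULT_ITERATIONS = 1000


class ZeroVarianceError(ValueError):
    """A distance vector is constant; its Pearson correlation is undefined."""


def tree_correlation(g, e) -> float:
    """Pearson correlation between two pair-distance vectors."""
    gv = np.asarray(getattr(g, "values", g), dtype=float)
    ev = np.asarray(getattr(e, "values", e), dtype=float)
    if gv.shape != ev.shape:
        raise ValueError("pair vectors have different lengths")
    if np.ptp(gv) == 0 or np.ptp(ev) == 0:
        raise ZeroVarianceError("constant distance vector")
    return float(np.corrcoef(gv, ev)[0, 1])


def _standardize_rows(M: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Row-wise z-scores (population SD) and a valid (nonconstant) mask.

    Input is forced C-contiguous so reduction order (hence the last ulp)
    does not depend on the caller's memory layout; reruns must be
    byte-identical.
    """
    M = np.ascontiguousarray(M, dtype=float)
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    valid = np.ptp(M, axis=1) > 0
    sd = np.where(sd == 0, 1.0, sd)
    return (M - mu) / sd, valid


def pearson_rows(G: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Per-row Pearson correlation between two gene × pair matrices."""
    zG, vg = _standardize_rows(G)
    zE, ve = _standardize_rows(E)
    r = (zG * zE).mean(axis=1)
    r[~(vg & ve)] = np.nan
    return r


# ---------------------------------------------------------------------------
# samples, densities, null


@dataclass
class CorrelationSample:
    region: str
    tissue: str
    genes: List[str]
    values: np.ndarray
    dropped: List[Tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.genes) != len(self.values):
            raise ValueError("one correlation per gene required")


@dataclass
class Density:
    """Area-normalized histogram density over [−1, 1]."""

    edges: np.ndarray
    density: np.ndarray

    @classmethod
    def from_sample(cls, values: np.ndarray, bins: int = DEFAULT_BINS) -> "Density":
        edges = np.linspace(-1.0, 1.0, bins + 1)
        density, _ = np.histogram(values, bins=edges, density=True)
        return cls(edges, density)

    @property
    def area(self) -> float:
        return float(np.sum(self.density * np.diff(self.edges)))


@dataclass
class NullDistribution:
    region: str
    values: np.ndarray            # pooled permuted r, all tissues × iterations
    density: Density              # per-tissue densities averaged, then across tissues
    iterations: int
    seed: int
    n_per_tissue: Dict[str, int] = field(default_factory=dict)


def correlation_distribution(
    region: str,
    tissue: str,
    genes: Sequence[str],
    genomic: pd.DataFrame,
    expr: pd.DataFrame,
    bins: int = DEFAULT_BINS,
) -> Tuple[CorrelationSample, Density]:
    """Observed per-gene tree correlations for one region × tissue cell.

    ``genomic`` and ``expr`` are gene × pair tables; only genes present
    in both are used.  Genes with a constant vector on either side are
    dropped with a reason.  Fewer than 3 usable genes is an error.
    """
    usable = [g for g in genes if g in genomic.index and g in expr.index]
    dropped = [(g, "missing tree") for g in genes if g not in usable]
    G = genomic.loc[usable].to_numpy(dtype=float)
    E = expr.loc[usable].to_numpy(dtype=float)
    r = pearson_rows(G, E)
    ok = ~np.isnan(r)
    dropped += [(g, "zero variance") for g, good in zip(usable, ok) if not good]
    kept = [g for g, good in zip(usable, ok) if good]
    if len(kept) < 3:
        raise ValueError(
            f"cell {region}×{tissue}: only {len(kept)} usable genes; "
            "distribution is meaningless"
        )
    sample = CorrelationSample(region, tissue, kept, r[ok], dropped)
    return sample, Density.from_sample(sample.values, bins)


def _cell_rng(seed: int, region_idx: int, tissue_idx: int) -> np.random.Generator:
    """Deterministic per-(region, tissue) stream, order-independent."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(region_idx, tissue_idx))
    return np.random.default_rng(ss)


def bootstrap_null(
    region: str,
    cells: Mapping[str, Tuple[pd.DataFrame, pd.DataFrame]],
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    bins: int = DEFAULT_BINS,
    region_idx: int = 0,
    tissue_order: Optional[Sequence[str]] = None,
    permutations: Optional[np.ndarray] = None,
) -> NullDistribution:
    """Gene-permutation null for one region, pooled over tissues.

    ``cells`` maps tissue → (genomic table, expression table) restricted
    to that tissue's usable genes.  Per tissue and iteration a uniform
    random permutation re-pairs genomic and expression trees; r values
    are pooled across iterations and tissues, and per-tissue densities
    are averaged into one region-level density.

    ``permutations`` is a test hook: an (iterations × n) index array
    used for every tissue in place of random permutations.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    tissues = list(tissue_order) if tissue_order is not None else sorted(cells)
    pooled: List[np.ndarray] = []
    densities: List[Density] = []
    n_per_tissue: Dict[str, int] = {}
    for t_idx, tissue in enumerate(tissues):
        G, E = cells[tissue]
        zG, vg = _standardize_rows(G.to_numpy(dtype=float))
        zE, ve = _standardize_rows(E.to_numpy(dtype=float))
        valid = vg & ve
        zG, zE = zG[valid], zE[valid]
        n = zG.shape[0]
        if n < 3:
            raise ValueError(f"cell {region}×{tissue}: fewer than 3 usable genes")
        if permutations is not None:
            perms = np.asarray(permutations)
        else:
            rng = _cell_rng(seed, region_idx, t_idx)
            perms = rng.permuted(
                np.broadcast_to(np.arange(n), (iterations, n)), axis=1
            )
        # r for genomic tree of gene i vs expression tree of gene perm[i]
        R = np.einsum("ik,jik->ji", zG, zE[perms]) / zG.shape[1]
        pooled.append(R.ravel())
        n_per_tissue[tissue] = n
        densities.append(Density.from_sample(R.ravel(), bins))
    values = np.concatenate(pooled)
    avg_density = Density(densities[0].edges,
                          np.mean([d.density for d in densities], axis=0))
    return NullDistribution(region, values, avg_density, iterations, seed,
                            n_per_tissue)


# ---------------------------------------------------------------------------
# distribution tests


def ks_2samp_sorted(obs: np.ndarray, null_sorted: np.ndarray) -> Tuple[float, float]:
    """Two-sample KS against a pre-sorted (large) null sample.

    Statistic is the exact sup |ECDF difference|; the p-value follows
    the asymptotic two-sample distribution at the effective sample size
    (matching scipy's ``method='asymp'``).
    """
    obs = np.sort(np.asarray(obs, dtype=float))
    n1, n2 = len(obs), len(null_sorted)
    if n1 == 0 or n2 == 0:
        raise ValueError("empty sample")
    cdf2_at = np.searchsorted(null_sorted, obs, side="right") / n2
    cdf2_before = np.searchsorted(null_sorted, obs, side="left") / n2
    cdf1_at = np.arange(1, n1 + 1) / n1
    cdf1_before = np.arange(0, n1) / n1
    d = max(np.abs(cdf1_at - cdf2_at).max(),
            np.abs(cdf1_before - cdf2_before).max())
    en = n1 * n2 / (n1 + n2)
    p = float(np.clip(stats.kstwo.sf(d, int(np.round(en))), 0, 1))
    return float(d), p


def kruskal_2samp_sorted(obs: np.ndarray, null_sorted: np.ndarray
                         ) -> Tuple[float, float]:
    """Two-group Kruskal-Wallis against a pre-sorted null sample.

    Midranks across obs/null ties are exact; the tie-correction factor
    is omitted (for the pooled-null sizes used here it differs from 1
    by < 1e-10).  p-value from the chi-square distribution, df = 1.
    """
    obs = np.asarray(obs, dtype=float)
    n1, n2 = len(obs), len(null_sorted)
    if n1 == 0 or n2 == 0:
        raise ValueError("empty sample")
    left = np.searchsorted(null_sorted, obs, side="left")
    right = np.searchsorted(null_sorted, obs, side="right")
    ranks = (left + right) / 2.0 + stats.rankdata(obs, method="average")
    N = n1 + n2
    r1 = float(ranks.sum())
    r2 = N * (N + 1) / 2.0 - r1
    H = 12.0 / (N * (N + 1)) * (r1 ** 2 / n1 + r2 ** 2 / n2) - 3.0 * (N + 1)
    p = float(stats.chi2.sf(max(H, 0.0), df=1))
    return float(H), p


@dataclass
class AssociationResult:
    region: str
    tissue: str
    n_genes: int
    ks_stat: float
    ks_p: float
    kw_stat: float
    kw_p: float
    mean_r: float
    null_mean: float
    shift: str
    ks_p_bonf: float = np.nan
    kw_p_bonf: float = np.nan


def compare_distributions(
    observed: CorrelationSample, null: NullDistribution
) -> AssociationResult:
    """KS and KW between observed per-gene r and the pooled null."""
    if np.std(observed.values) == 0 or np.std(null.values) == 0:
        raise ValueError("degenerate (constant) sample")
    null_sorted = np.sort(null.values)
    ks_stat, ks_p = ks_2samp_sorted(observed.values, null_sorted)
    kw_stat, kw_p = kruskal_2samp_sorted(observed.values, null_sorted)
    mean_r = float(np.mean(observed.values))
    null_mean = float(np.mean(null.values))
    shift = "positive" if mean_r >= null_mean else "negative"
    return AssociationResult(
        observed.region, observed.tissue, len(observed.genes),
        ks_stat, ks_p, kw_stat, kw_p, mean_r, null_mean, shift,
    )


def bonferroni(results: Sequence[AssociationResult],
               family_size: Optional[int] = None) -> List[AssociationResult]:
    """Bonferroni-correct p-values over the region × tissue family.

    The family size defaults to the number of cells actually computed
    (48 = 6 regions × 8 tissues in the full design); KS and KW
    are corrected as separate families of the same size.
    """
    m = family_size if family_size is not None else len(results)
    for res in results:
        res.ks_p_bonf = min(1.0, res.ks_p * m)
        res.kw_p_bonf = min(1.0, res.kw_p * m)
    return list(results)


def rank_signature_genes(sample: CorrelationSample, k: int = 50) -> pd.DataFrame:
    """Top-k genes by tree correlation (descending; ties by gene id)."""
    if len(sample.genes) == 0:
        raise ValueError("empty correlation sample")
    df = pd.DataFrame({"gene_id": sample.genes, "r": sample.values})
    df = df.sort_values(["r", "gene_id"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    return df.head(k)


def results_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    rows = [
        {
            "region": r.region, "tissue": r.tissue, "n_genes": r.n_genes,
            "mean_r": r.mean_r, "null_mean": r.null_mean,
            "ks_stat": r.ks_stat, "ks_p_raw": r.ks_p, "ks_p_bonf": r.ks_p_bonf,
            "kw_stat": r.kw_stat, "kw_p_raw": r.kw_p, "kw_p_bonf": r.kw_p_bonf,
            "shift_direction": r.shift,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
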