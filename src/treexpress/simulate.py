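"""Synthetic six-primate worlds for end-to-end testing.

The generator emulates the real inputs — per-species genomes with
Ensembl-style annotation, a global species tree, and a gene ×
(species, tissue) expression table — entirely from a seed:

* Region sequences evolve from a random ancestor down a fixed 6-taxon
  primate tree under a Jukes-Cantor substitution process, with
  per-gene and per-(gene, region, branch) lognormal rate multipliers so
  gene trees deviate from the global tree in gene-specific ways (the
  signal channel the analysis actually reads).  The three promoter
  windows evolve as independent processes and are concatenated into the
  full promoter.
* A configured fraction of gene × region sequences receives a short
  run of 'N' in one species (undefined-nucleotide contamination).
* Expression is lognormal around a per-gene baseline with per-tissue
  noise (brain tissues less noisy, mirroring the constrained brain
  transcriptome); designated genes are fold-boosted in their tissue to
  create tissue-enriched sets.
* An optional planted cell couples one region's true genomic distances
  to one tissue's expression deltas: species are placed on a line by
  their true distance from the first species and the planted genes'
  expression follows that embedding plus Gaussian species-level noise,
  whose SD is solved by seeded bisection so the per-gene correlation
  between planted deltas and true distances hits a target (0.6 by
  default).  A 1-D embedding cannot reproduce an arbitrary tree metric
  exactly, so the target correlation already absorbs embedding error.

Equal seeds produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .species import SpeciesSet, SIX_PRIMATES
from .trees import PairDistanceVector
from .regions import RegionSequenceSet

_ALPHABET = np.frombuffer(b"ACGTN", dtype=np.uint8)

#: Fixed 6-taxon topology covering the five major primate groups, branch
#: lengths in expected substitutions/site (pair distances ~0.013 for
#: human-chimp up to ~0.18 for human-mouse lemur).
DEFAULT_SPECIES_TREE = (
    "((((human:0.0065,chimpanzee:0.0065):0.022,"
    "(macaque:0.0055,baboon:0.0055):0.023):0.012,"
    "marmoset:0.043):0.04,mouse_lemur:0.095);"
)

PASSING_TISSUES = (
    "cerebellum", "frontal_cortex", "liver", "kidney",
    "heart", "lung", "skeletal_muscle", "testis",
)
MINOR_TISSUES = (
    "spleen", "pancreas", "stomach", "skin", "thymus", "adrenal_gland", "colon",
)

SIMULATED_REGIONS = (
    "upstream_far", "promoter_w1", "promoter_w2", "promoter_w3",
    "utr5", "cds", "utr3",
)


@dataclass(frozen=True)
class PlantedCell:
    region: str
    tissue: str
    beta: float = 1.0
    noise_sd: Optional[float] = None   # None: solve from target_r
    target_r: float = 0.6


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    species_tree: str = DEFAULT_SPECIES_TREE
    tissues: Tuple[str, ...] = PASSING_TISSUES + MINOR_TISSUES
    enriched_per_tissue: Mapping[str, int] = field(
        default_factory=lambda: {
            **{t: 300 for t in PASSING_TISSUES},
            **{t: 40 for t in MINOR_TISSUES},
        }
    )
    n_background_genes: int = 400
    fold_boost: float = 10.0
    region_length_means: Mapping[str, int] = field(
        default_factory=lambda: {"utr5": 250, "cds": 1200, "utr3": 600}
    )
    region_length_mins: Mapping[str, int] = field(
        default_factory=lambda: {"utr5": 100, "cds": 300, "utr3": 150}
    )
    human_utr3_factor: float = 2.0
    n_contamination_rate: float = 0.05
    gene_rate_sigma: float = 0.3
    branch_rate_sigma: float = 0.5
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    tissue_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            **{t: 0.25 for t in PASSING_TISSUES + MINOR_TISSUES},
            "cerebellum": 0.125,
            "frontal_cortex": 0.125,
        }
    )
    planted_coupling_scale: float = 0.15   # relative amplitude of planted signal
    #: fraction of expression noise variance following a Brownian-motion
    #: covariance on the species tree (phylogenetic signal).  None derives
    #: it from the planted calibration so that every tissue's permutation
    #: null matches the planted tissue's (the tissue-averaged null is only
    #: valid when per-tissue nulls are near-identical); 0 when nothing is
    #: planted.
    phylo_noise_share: Optional[float] = None
    planted_cells: Tuple[PlantedCell, ...] = ()

    @property
    def n_genes(self) -> int:
        return sum(self.enriched_per_tissue.get(t, 0) for t in self.tissues) \
            + self.n_background_genes

    def validate(self) -> None:
        window = 500
        for cell in self.planted_cells:
            if cell.region not in SIMULATED_REGIONS:
                raise ValueError(f"planted cell region {cell.region!r} unknown")
            if cell.tissue not in self.tissues:
                raise ValueError(f"planted cell tissue {cell.tissue!r} unknown")
            if cell.beta < 0:
                raise ValueError("planted beta must be >= 0")
        for r, m in self.region_length_mins.items():
            if m < 1:
                raise ValueError(f"region {r} minimum length must be positive")
        if any(v < 0 for v in self.enriched_per_tissue.values()):
            raise ValueError("enriched gene counts must be >= 0")
        if window <= 0:  # pragma: no cover - window is fixed
            raise ValueError("window must be positive")


def null_world(seed: int = 0) -> SyntheticConfig:
    """The default world with no planted association (type-I fixture)."""
    return SyntheticConfig(seed=seed)


def planted_world(seed: int = 0, region: str = "promoter_w2",
                  tissue: str = "cerebellum", beta: float = 1.0,
                  target_r: float = 0.6) -> SyntheticConfig:
    """One region × tissue cell carries a genuine sequence-expression
    coupling; everything else is null."""
    return SyntheticConfig(
        seed=seed,
        planted_cells=(PlantedCell(region, tissue, beta, None, target_r),),
    )


# ---------------------------------------------------------------------------
# species tree model


class TreeModel:
    """Parsed species tree: branch list and per-pair branch paths."""

    def __init__(self, newick: str, species_set: SpeciesSet) -> None:
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.species_set = species_set
        self.branches: List[Tuple[int, int, float]] = [
            (index[id(nd.parent_node)], index[id(nd)],
             float(nd.edge.length or 0.0))
            for nd in nodes[1:]
        ]
        self.lengths = np.array([b[2] for b in self.branches])
        leaf_nodes = {
            nd.taxon.label.replace(" ", "_"): index[id(nd)]
            for nd in tree.leaf_node_iter()
        }
        missing = set(species_set.labels) - set(leaf_nodes)
        if missing:
            raise ValueError(f"species {sorted(missing)} missing from tree")
        self.leaf_index = {sp: leaf_nodes[sp] for sp in species_set.labels}
        # branch sets from root, then symmetric difference per pair
        to_root: Dict[int, set] = {0: set()}
        for b_idx, (parent, child, _t) in enumerate(self.branches):
            to_root[child] = to_root[parent] | {b_idx}
        n_b = len(self.branches)
        self.pair_paths = np.zeros((species_set.n_pairs, n_b), dtype=bool)
        for k, (a, b) in enumerate(species_set.pairs):
            path = to_root[self.leaf_index[a]] ^ to_root[self.leaf_index[b]]
            for b_idx in path:
                self.pair_paths[k, b_idx] = True

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def global_tree(self) -> PairDistanceVector:
        values = self.pair_paths @ self.lengths
        return PairDistanceVector(self.species_set, values, label="global")

    def bm_correlation(self) -> np.ndarray:
        """Brownian-motion-on-the-tree correlation between species.

        cov(i, j) is the root-to-MRCA path length; the matrix is scaled
        to unit diagonal.  Used for the phylogenetic component of
        expression noise.
        """
        n = self.species_set.n
        d = np.zeros((n, n))
        pair_d = self.pair_paths @ self.lengths
        for k, (a, b) in enumerate(self.species_set.pairs):
            i, j = self.species_set.index(a), self.species_set.index(b)
            d[i, j] = d[j, i] = pair_d[k]
        depth = np.zeros(n)
        to_root_len = {0: 0.0}
        for parent, child, t in self.branches:
            to_root_len[child] = to_root_len[parent] + t
        for sp, node in self.leaf_index.items():
            depth[self.species_set.index(sp)] = to_root_len[node]
        cov = 0.5 * (depth[:, None] + depth[None, :] - d)
        sd = np.sqrt(np.diag(cov))
        return cov / np.outer(sd, sd)

    def pair_distances(self, branch_rates: np.ndarray) -> np.ndarray:
        """True per-gene pair distances given (n, n_branches) rates."""
        scaled = branch_rates * self.lengths  # (n, B)
        return scaled @ self.pair_paths.T     # (n, n_pairs)


def _detect_species(newick: str) -> SpeciesSet:
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    labels = tuple(t.label.replace(" ", "_") for t in tree.taxon_namespace)
    if set(labels) == set(SIX_PRIMATES.labels):
        return SIX_PRIMATES
    return SpeciesSet(labels)


# ---------------------------------------------------------------------------
# sequence simulation


def _evolve_matrix(parent: np.ndarray, p_row: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """One branch of JC evolution; ``p_row`` is per-gene mismatch probability
    of a single substitution event class (p_change = 3/4(1−e^{−4t/3}))."""
    mask = rng.random(parent.shape) < p_row[:, None]
    child = parent.copy()
    n_mut = int(mask.sum())
    if n_mut:
        child[mask] = (parent[mask]
                       + rng.integers(1, 4, n_mut, dtype=np.uint8)) % 4
    return child


def _simulate_region_matrix(
    tree: TreeModel,
    lengths: np.ndarray,
    branch_rates: np.ndarray,
    rng: np.random.Generator,
) -> Dict[str, np.ndarray]:
    """Evolve (n_genes, max_length) sequences down the tree; returns
    per-species uint8 matrices (0..3 coding; per-gene valid length in
    ``lengths``)."""
    n = len(lengths)
    L = int(lengths.max())
    node_seqs: Dict[int, np.ndarray] = {
        0: rng.integers(0, 4, (n, L), dtype=np.uint8)
    }
    for b_idx, (parent, child, t) in enumerate(tree.branches):
        d = t * branch_rates[:, b_idx]
        p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
        node_seqs[child] = _evolve_matrix(node_seqs[parent], p_change, rng)
    return {
        sp: node_seqs[tree.leaf_index[sp]]
        for sp in tree.species_set.labels
    }


def matrix_row_to_seq(row: np.ndarray, length: int) -> str:
    return _ALPHABET[row[:length]].tobytes().decode("ascii")


def simulate_jc_pair(t: float, length: int, seed: int = 0) -> Tuple[str, str]:
    """Two sequences separated by a JC process of expected divergence t."""
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 4, length, dtype=np.uint8)
    p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    mask = rng.random(length) < p_change
    b = a.copy()
    n_mut = int(mask.sum())
    if n_mut:
        b[mask] = (a[mask] + rng.integers(1, 4, n_mut, dtype=np.uint8)) % 4
    return (_ALPHABET[a].tobytes().decode("ascii"),
            _ALPHABET[b].tobytes().decode("ascii"))


@dataclass
class SimulatedRegions:
    """In-memory product of the sequence stage."""

    config: SyntheticConfig
    species_set: SpeciesSet
    tree: TreeModel
    gene_ids: List[str]
    sequences: Dict[str, Dict[str, np.ndarray]]   # region -> species -> (n, L)
    lengths: Dict[str, Dict[str, np.ndarray]]     # region -> species -> (n,)
    true_distances: Dict[str, np.ndarray]         # region -> (n, n_pairs)
    contamination: List[Tuple[str, str, str]]     # (gene, region, species)

    def global_tree(self) -> PairDistanceVector:
        return self.tree.global_tree()

    def contaminated_genes(self, region: str) -> set:
        if region == "promoter_full":
            return set().union(*(self.contaminated_genes(w)
                                 for w in ("promoter_w1", "promoter_w2",
                                           "promoter_w3")))
        return {g for g, r, _sp in self.contamination if r == region}

    def surviving_genes(self, region: str) -> List[str]:
        bad = self.contaminated_genes(region)
        return [g for g in self.gene_ids if g not in bad]

    def region_sets(self, regions: Sequence[str] = SIMULATED_REGIONS
                    ) -> Dict[str, List[RegionSequenceSet]]:
        """Materialize RegionSequenceSets (strings) per region.

        ``promoter_full`` is derived by concatenating the three windows
        in transcription order (w1 + w2 + w3).
        """
        out: Dict[str, List[RegionSequenceSet]] = {}
        for region in regions:
            sets = []
            for i, gid in enumerate(self.gene_ids):
                seqs = {}
                for sp in self.species_set.labels:
                    if region == "promoter_full":
                        seqs[sp] = "".join(
                            matrix_row_to_seq(
                                self.sequences[w][sp][i],
                                int(self.lengths[w][sp][i]),
                            )
                            for w in ("promoter_w1", "promoter_w2",
                                      "promoter_w3")
                        )
                    else:
                        seqs[sp] = matrix_row_to_seq(
                            self.sequences[region][sp][i],
                            int(self.lengths[region][sp][i]),
                        )
                sets.append(RegionSequenceSet(gid, region, seqs))
            out[region] = sets
        return out


def _gene_ids(n: int) -> List[str]:
    return [f"g{i:05d}" for i in range(n)]


def simulate_regions(config: SyntheticConfig) -> SimulatedRegions:
    """Simulate all region sequences, true distances and contamination."""
    config.validate()
    species_set = _detect_species(config.species_tree)
    tree = TreeModel(config.species_tree, species_set)
    n = config.n_genes
    ids = _gene_ids(n)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0,))
    )
    gene_rate = np.exp(rng.normal(0.0, config.gene_rate_sigma, n))

    sequences: Dict[str, Dict[str, np.ndarray]] = {}
    lengths: Dict[str, Dict[str, np.ndarray]] = {}
    true_d: Dict[str, np.ndarray] = {}
    for region in SIMULATED_REGIONS:
        if region in ("upstream_far",):
            base_len = np.full(n, 1500, dtype=int)
        elif region.startswith("promoter_w"):
            base_len = np.full(n, 500, dtype=int)
        else:
            mean = config.region_length_means[region]
            lo = config.region_length_mins[region]
            base_len = np.maximum(
                lo, rng.normal(mean, mean / 4.0, n).astype(int)
            )
        rates = gene_rate[:, None] * np.exp(
            rng.normal(0.0, config.branch_rate_sigma, (n, tree.n_branches))
        )
        true_d[region] = tree.pair_distances(rates)
        per_species_len = {sp: base_len.copy() for sp in species_set.labels}
        if region == "utr3" and "human" in species_set.labels \
                and config.human_utr3_factor != 1.0:
            per_species_len["human"] = (
                base_len * config.human_utr3_factor
            ).astype(int)
        max_len = max(int(v.max()) for v in per_species_len.values())
        seqs = _simulate_region_matrix(
            tree, np.full(n, max_len), rates, rng
        )
        # human 3'UTR extension beyond the shared part is fresh sequence,
        # not shared ancestry; distances only ever use the shared prefix.
        sequences[region] = seqs
        lengths[region] = per_species_len

    contamination: List[Tuple[str, str, str]] = []
    crng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    )
    for region in SIMULATED_REGIONS:
        hit = crng.random(n) < config.n_contamination_rate
        for i in np.nonzero(hit)[0]:
            sp = species_set.labels[crng.integers(0, species_set.n)]
            L = int(lengths[region][sp][i])
            run = int(crng.integers(1, 4))
            pos = int(crng.integers(0, max(1, L - run)))
            sequences[region][sp][i, pos:pos + run] = 4  # 'N'
            contamination.append((ids[i], region, sp))

    return SimulatedRegions(config, species_set, tree, ids, sequences,
                            lengths, true_d, contamination)


# ---------------------------------------------------------------------------
# expression simulation


def _embed_pairs_1d(y: np.ndarray, n_species: int, idx_a: np.ndarray,
                    idx_b: np.ndarray, n_iter: int = 300) -> np.ndarray:
    """Batched 1-D metric MDS: per-gene species positions whose absolute
    differences best fit the target pair vectors ``y`` (n_genes, n_pairs).

    Classical-MDS first coordinate as the start, then SMACOF (stress
    majorization) iterations.  Deterministic: no random restarts.
    """
    n, m = y.shape[0], n_species
    D = np.zeros((n, m, m))
    D[:, idx_a, idx_b] = y
    D[:, idx_b, idx_a] = y
    centering = np.eye(m) - np.ones((m, m)) / m
    gram = -0.5 * centering @ (D ** 2) @ centering
    w, v = np.linalg.eigh(gram)
    u = v[:, :, -1] * np.sqrt(np.maximum(w[:, -1:], 0.0))
    eye = np.eye(m, dtype=bool)
    for _ in range(n_iter):
        diff = u[:, :, None] - u[:, None, :]
        dist = np.abs(diff)
        dist[:, eye] = 1.0
        ratio = np.where(dist > 1e-12, D / dist, 0.0)
        ratio[:, eye] = 0.0
        B = -ratio
        B[:, eye] = ratio.sum(axis=2)
        u = np.einsum("nij,nj->ni", B, u) / m
    return u


def _enrichment_blocks(config: SyntheticConfig) -> Dict[str, List[int]]:
    """Deterministic assignment of gene indices to tissue-enriched blocks."""
    blocks: Dict[str, List[int]] = {}
    cursor = 0
    for tissue in config.tissues:
        k = config.enriched_per_tissue.get(tissue, 0)
        blocks[tissue] = list(range(cursor, cursor + k))
        cursor += k
    return blocks


def solve_planted_noise_sd(
    z: np.ndarray,
    d: np.ndarray,
    beta: float,
    target_r: float,
    rng: np.random.Generator,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    reps: int = 12,
    tol: float = 5e-3,
) -> float:
    """Solve the species-noise SD so mean corr(planted deltas, d) hits
    target_r, by bisection on a fixed set of noise draws."""
    if beta <= 0:
        return 1.0
    n, n_sp = z.shape
    dz = beta * (z[:, idx_a] - z[:, idx_b])          # (n, n_pairs)
    eta = rng.standard_normal((reps, n, n_sp))

    dc = d - d.mean(axis=1, keepdims=True)
    d_sd = d.std(axis=1, keepdims=True)

    def mean_corr(sigma: float) -> float:
        deltas = np.abs(dz[None] + sigma * (eta[:, :, idx_a] - eta[:, :, idx_b]))
        x = deltas - deltas.mean(axis=2, keepdims=True)
        sd = x.std(axis=2)
        sd[sd == 0] = np.inf
        r = (x * dc[None]).mean(axis=2) / (sd * d_sd[None, :, 0])
        return float(r.mean())

    lo, hi = 1e-4, 30.0
    if mean_corr(lo) <= target_r:
        return lo
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if mean_corr(mid) > target_r:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * lo:
            break
    return 0.5 * (lo + hi)


def simulate_expression(
    config: SyntheticConfig,
    sim: Optional[SimulatedRegions] = None,
):
    """Raw (un-normalized) expression table plus ground truth.

    Planted cells require ``sim`` (the true genomic distances).
    Returns (ExpressionTable, ground_truth dict).
    """
    from .expression import ExpressionTable
    import pandas as pd

    config.validate()
    if config.planted_cells and any(c.beta > 0 for c in config.planted_cells) \
            and sim is None:
        raise ValueError("planted cells need simulated sequences first")
    species_set = sim.species_set if sim is not None \
        else _detect_species(config.species_tree)
    n = config.n_genes
    ids = _gene_ids(n)
    tissues = list(config.tissues)
    labels = list(species_set.labels)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(2,))
    )

    blocks = _enrichment_blocks(config)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    boost = np.zeros((n, len(tissues)))
    log2_fold = np.log2(config.fold_boost)
    for t_idx, tissue in enumerate(tissues):
        boost[blocks[tissue], t_idx] = log2_fold

    # ---- planted cells first: their calibration fixes the phylogenetic
    # share of everyone's noise
    idx_a = np.array([species_set.index(a) for a, _ in species_set.pairs])
    idx_b = np.array([species_set.index(b) for _, b in species_set.pairs])
    planted_truth = []
    planted_signals: List[Tuple[np.ndarray, int, np.ndarray]] = []
    shares: List[float] = []
    prng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(3,))
    )
    for cell in config.planted_cells:
        g_idx = np.array(blocks[cell.tissue], dtype=int)
        t_idx = tissues.index(cell.tissue)
        if cell.beta > 0:
            # the analysed genomic quantity is the globally-normalized
            # distance, so the planted linear relation targets d/G
            d = sim.true_distances[cell.region][g_idx] \
                / sim.global_tree().values                  # (k, n_pairs)
            # embed the per-gene deviation (d minus its smallest pair):
            # Pearson is offset-invariant, the 1-D fit is better, and the
            # embedded configurations stay idiosyncratic per gene instead
            # of collapsing onto one shared even-spread pattern
            u = _embed_pairs_1d(d - d.min(axis=1, keepdims=True),
                                species_set.n, idx_a, idx_b)
            z = (u - u.mean(axis=1, keepdims=True)) / u.std(axis=1, keepdims=True)
            sigma = cell.noise_sd if cell.noise_sd is not None else \
                solve_planted_noise_sd(z, d, cell.beta, cell.target_r,
                                       prng, idx_a, idx_b)
            eta = prng.standard_normal((len(g_idx), species_set.n)) * sigma
            signal = cell.beta * z + eta
            shares.append(cell.beta ** 2 / (cell.beta ** 2 + sigma ** 2))
        else:
            sigma = cell.noise_sd if cell.noise_sd is not None else 1.0
            signal = prng.standard_normal((len(g_idx), species_set.n)) * sigma
        planted_signals.append((g_idx, t_idx, signal))
        planted_truth.append({
            "region": cell.region, "tissue": cell.tissue,
            "beta": cell.beta, "target_r": cell.target_r,
            "noise_sd": float(sigma),
            "genes": [ids[i] for i in g_idx],
        })

    # ---- phylogenetic share of expression noise: tissue nulls are only
    # exchangeable (and the tissue-averaged permutation null valid) when
    # every tissue carries the tree-structured variance fraction the
    # planted construction imposes on its tissue
    if config.phylo_noise_share is not None:
        phylo_share = float(config.phylo_noise_share)
    else:
        phylo_share = max(shares) if shares else 0.0
    if not 0.0 <= phylo_share <= 1.0:
        raise ValueError("phylo_noise_share must lie in [0, 1]")

    noise_sd = np.array([config.tissue_noise_sd.get(t, 0.25) for t in tissues])
    white = rng.standard_normal((n, species_set.n, len(tissues)))
    if phylo_share > 0:
        tree_model = sim.tree if sim is not None \
            else TreeModel(config.species_tree, species_set)
        L = np.linalg.cholesky(tree_model.bm_correlation())
        phylo = np.einsum("sk,nkt->nst",
                          L, rng.standard_normal((n, species_set.n, len(tissues))))
        eps = (np.sqrt(1 - phylo_share) * white
               + np.sqrt(phylo_share) * phylo) * noise_sd
    else:
        eps = white * noise_sd
    log2x = baseline[:, None, None] + boost[:, None, :] + eps
    values = np.power(2.0, log2x)   # (genes, species, tissues)

    for (g_idx, t_idx, signal), truth in zip(planted_signals, planted_truth):
        amp = config.planted_coupling_scale / max(1.0, np.abs(signal).max())
        base = np.power(2.0, baseline[g_idx] + log2_fold)
        planted_vals = base[:, None] * (1.0 + amp * signal)
        values[g_idx, :, t_idx] = np.maximum(planted_vals, base[:, None] * 1e-3)

    cols = pd.MultiIndex.from_product([labels, tissues],
                                      names=["species", "tissue"])
    flat = values.reshape(n, species_set.n * len(tissues))
    table = ExpressionTable(pd.DataFrame(flat, index=ids, columns=cols))

    ground_truth = {
        "seed": config.seed,
        "species": labels,
        "tissues": tissues,
        "enriched": {t: [ids[i] for i in blocks[t]] for t in tissues},
        "passing_tissues": [
            t for t in tissues
            if config.enriched_per_tissue.get(t, 0) > 100
        ],
        "planted": planted_truth,
    }
    if sim is not None:
        ground_truth["surviving"] = {
            region: sim.surviving_genes(region)
            for region in SIMULATED_REGIONS + ("promoter_full",)
        }
        ground_truth["contamination"] = [list(c) for c in sim.contamination]
    return table, ground_truth
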