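# Methods

## The model and procedure

The analysis asks whether, for a given functional genomic region and a
given tissue, genes whose sequences diverged more between species also
show larger expression differences between those species.  It never
infers tree topologies: a "tree" here is the vector of pairwise
leaf-to-leaf distances (15 entries for six species, in a fixed
canonical pair order), which is exactly the object a pairwise Pearson
comparison consumes.

**Genomic trees.**  Per gene × region, pairwise divergence is the
p-distance (proportion of differing sites) transformed to the
Jukes-Cantor ML substitution estimate d = −(3/4)·ln(1 − 4p/3), natural
log.  Sequences are compared positionwise over the first
min(len(a), len(b)) positions, anchored at the region's 5' end; no
alignment stage exists anywhere in the procedure, so unequal-length
regions (UTRs, CDS) are compared over their shared prefix.  Each gene
tree is divided pair-by-pair by the global inter-species tree (loaded
from Newick patristic distances or a pairwise TSV).  Because Pearson
correlation is invariant under positive affine maps, the ratio g/G and
the percent-difference (g−G)/G provably give identical downstream
statistics (a unit test verifies this to 1e−12).

**Expression trees.**  All (species × tissue) columns are
quantile-normalized jointly (k-th smallest value in every column ←
mean of the k-th smallest values across columns; ties within a column
receive the mean of the reference values of their tied ranks).  Per
gene × tissue the expression tree is |Δ| of normalized expression per
species pair.  Tissue-enriched sets are computed on species-averaged
normalized expression: a gene is enriched when its tissue value is at
least `fold_threshold` (5) times its mean over all other tissues
(boundary inclusive; x/0 counts as enriched, 0/0 does not).  A tissue
enters the analysis only with strictly more than `size_threshold`
(100) enriched genes.

**Association testing.**  Per region × tissue cell, the per-gene
Pearson r over the 15 pairs forms the observed sample (genes with a
constant vector on either side are dropped from observed *and*
permuted computations, keeping sizes matched).  The null re-pairs the
genomic tree of gene i with the expression tree of gene π(i) under
uniform random permutations (fixed points allowed), `iterations`
(1000) times per tissue; per-tissue densities are averaged and the
permuted r values pooled across tissues into one null per region.
Observed vs pooled null is tested with two-sample KS and
Kruskal-Wallis; p-values are Bonferroni-corrected over all cells
actually computed (48 in the full design), per test family.
Densities use 40 equal bins on [−1, 1] and integrate to 1.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| promoter length / window | 1500 / 500 bp | promoter span upstream of the TSS and its three windows |
| far-upstream span | [−3000, −1500) | negative-control region |
| fold_threshold | 5 | tissue-enrichment fold rule (inclusive) |
| size_threshold | 100 | strict minimum enriched-set size (>100) |
| iterations | 1000 | gene permutations per tissue per region |
| bins | 40 | density bins on [−1, 1] |
| saturation | drop (cap = 5.0 optional) | policy for p ≥ 3/4, where the JC estimate diverges |
| family_size | n cells computed | Bonferroni family (override available) |

All defaults are the published values of the procedure; every run
records them in a manifest together with input checksums and
per-region surviving-gene counts.

## The synthetic world

The generator emulates the real inputs end to end from one seed.
Region sequences evolve from random ancestors down a fixed six-taxon
primate tree (pair distances from ~0.013 human–chimpanzee to ~0.18 to
mouse lemur, in substitutions/site) under a Jukes-Cantor process, with
per-gene (lognormal σ=0.3) and per-(gene, region, branch) (σ=0.5) rate
multipliers — the latter give each gene's tree a gene-specific shape,
which is the only signal that survives global-tree normalization.  The
three promoter windows evolve as independent processes (concatenated
into the full promoter), so a planted effect in one window cannot leak
into its neighbors.  Region lengths: windows fixed at 500 bp, 5'UTR ≈
250 bp, CDS ≈ 1200 bp, 3'UTR ≈ 600 bp (human 2×, mirroring the longer
human 3'UTRs seen in real annotation).  ~5% of gene × region
sequences receive a short 'N' run in one random species.  Genome FASTA
and Ensembl-dialect GTF writers embed the regions at known coordinates
with minus-strand genes, split-CDS genes and duplicate transcript
variants, so extraction is exercised on realistic layouts; a round-trip
test confirms extraction returns the simulated sequences byte-exactly.

Expression is lognormal around per-gene baselines (log2 mean 5, SD 2)
with per-tissue noise SD 0.25 (0.125 for the two brain tissues — the
constrained brain transcriptome, which makes the whole-transcriptome
divergence recapitulation hold by construction).  Eight of fifteen
tissues carry 300 enriched genes (10-fold boost), the rest 40.

**Planted association.**  A planted cell couples one region's genomic
distances to one tissue's expression deltas.  Because the analyzed
genomic quantity is the *normalized* distance d/G, the planted linear
relation targets d/G: per gene, species are placed on a line by
batched 1-D metric MDS (classical-MDS start, SMACOF iterations) fitted
to the gene's normalized-distance deviations (d/G minus its smallest
pair — Pearson is offset-invariant and the offset-free target embeds
better and more idiosyncratically per gene).  Species-level Gaussian
noise is then added, its SD solved by seeded Monte-Carlo bisection so
the per-gene correlation between planted deltas and d/G hits the
target (0.6).  A 1-D embedding cannot represent an arbitrary pair
vector exactly, so the target already absorbs embedding error; quantile
normalization and JC estimation noise further attenuate the *realized*
pipeline correlation to ≈0.4.

**Phylogenetic noise share.**  The tissue-averaged permutation null is
valid only when per-tissue nulls are near-identical.  A planted tissue
necessarily has tree-structured expression vectors, which widen its
own permutation null relative to tissues with white species noise —
and that asymmetry makes *every* cell of the planted tissue
anticonservative against the pooled null.  Real cross-species
expression carries phylogenetic covariance in all tissues, so the
generator gives every tissue's noise the same tree-structured
(Brownian-motion-on-the-tree) variance fraction that the planted
calibration imposes on its tissue (β²/(β²+σ²), derived — not tuned —
from the solved noise SD; zero when nothing is planted).  This restores
exchangeability across tissues and, with it, the pooled null's
calibration.

**What a green test does and does not establish.**  The calibration
experiments show the pipeline controls type-I error and recovers a
single planted cell with high specificity *in this world*: independent
genes, clock-like contamination, no indels, no alignment error, no
batch structure beyond what quantile normalization removes, and
tissue-exchangeable nulls.  They do not establish calibration under
cross-gene correlation (co-expression, linked loci), and at small gene
counts (≲100/tissue) quantile normalization's rank granularity
compresses fold changes enough to erode both enrichment recovery and
planted-signal strength — the generator's stated scales avoid that
regime, real data at similar scales may not.

## Numerical choices

- 0-based half-open coordinates internally; GTF converted on read.
  "Upstream" always means 5' of the TSS on the coding strand;
  minus-strand output is reverse-complemented to read 5'→3'.
- Chromosome-edge truncated regions are kept and flagged; distances
  use the shared-prefix comparison either way.
- Soft-masked (lowercase) bases are uppercased; only 'N' triggers the
  contamination filter.
- JC saturation (p ≥ 3/4): the gene is dropped for that region by
  default (capping at d_max = 5.0 available); log1p is used for
  accuracy at small p.
- KS and KW against the pooled null run on a pre-sorted null via
  searchsorted (the pooled null has ~2.4 M values; re-sorting it for
  every cell would dominate runtime).  Midranks across observed/null
  ties are exact; the KW tie-correction divisor is omitted (< 1e−10
  relative at these null sizes); the KS p-value follows the asymptotic
  two-sample distribution at the effective sample size, matching
  scipy's `method="asymp"`.  Both are unit-tested against scipy and a
  brute-force ECDF oracle on small samples.
- Randomness: one run-level seed; per-(region, tissue) generator
  streams are spawned deterministically, so results do not depend on
  evaluation order, and shuffling gene-table row order changes no
  statistic (genes are canonically sorted before permuting).
- Reductions are forced onto C-contiguous arrays so the last ulp does
  not depend on the caller's memory layout; cached tables are read
  back with round-trip float parsing.  Reruns are byte-identical.
- Signature-gene ranking breaks ties by gene id, descending r.

## Known limitations

- No alignment and no indel model: distances compare positions, not
  homologous columns; for real data with indels an upstream alignment
  (or the shared-prefix convention) is a modeling choice the user must
  own.
- Orthology is an input (shared gene ids or an explicit table); no
  ortholog inference.
- Expression units are whatever the table carries; quantile
  normalization makes columns comparable but cannot remove gene-level
  biases shared across all columns.
- The permutation null assumes genes are exchangeable within a tissue;
  strong co-expression would inflate the observed distribution's
  spread relative to it.
- One-sample KS against the averaged null density (rather than
  two-sample against pooled values) is not implemented; pooled
  two-sample is the default and only route.
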