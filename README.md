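# treexpress

Which tissues' expression changes are coupled to genomic sequence change
across primates?  `treexpress` implements, as a tested and reusable
pipeline, an analysis that answers this by comparing *per-gene genomic
distance trees* against *per-gene tissue expression trees* for a panel
of species (the canonical setting: human, chimpanzee, macaque, baboon,
marmoset and mouse lemur), and asking — per functional genomic region
and per tissue — whether the two kinds of trees agree more often than a
gene-permutation null allows.

It is aimed at comparative genomics / molecular evolution researchers
who want to run this congruence analysis on their own genome +
expression panels, or to probe its statistical behavior on fully
synthetic data.

## The method

For each gene and each functional region — the three consecutive 500 bp
promoter windows upstream of the TSS, a far-upstream control
(−3000..−1500), 5'UTR, CDS, and 3'UTR, all strand-aware and unified
across transcript variants — pairwise sequence divergence between
species is the proportion of differing sites *p*, corrected for
multiple substitutions with the Jukes-Cantor maximum-likelihood
estimate

    d = −(3/4) · ln(1 − (4/3) p)

A gene's "tree" is simply its vector of the 15 pairwise distances,
divided pair-by-pair by the global inter-species tree so that
gene-specific deviation, not overall phylogeny, carries the signal.
Expression tables are quantile-normalized across all
(species × tissue) columns; per gene and tissue the expression tree is
the vector of absolute expression differences per species pair.
Tissue-enriched gene sets (≥5-fold above the mean of all other
tissues, strictly >100 genes required) define which genes enter each
tissue's comparison.

Per region × tissue cell, the per-gene Pearson correlations between
genomic and expression trees form an area-normalized distribution,
which is tested against a permutation null — the genomic tree of one
gene paired with the expression tree of another, 1000 iterations per
tissue, pooled/averaged across tissues per region — using two-sample
Kolmogorov–Smirnov and Kruskal–Wallis tests with Bonferroni correction
over all cells.

Every stage is driven by a synthetic-world generator (regions evolved
under a Jukes-Cantor process along a primate tree, Ensembl-style GTF +
FASTA output, expression with tissue-enriched genes and an optional
*planted* promoter–expression association), so the full pipeline is
testable without any downloads.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
default synthetic world (3080 genes, 15 tissues of which 8 pass the
enriched-set filter at 300 genes each, ~5% N-contamination, one planted
cell coupling promoter window 2 to cerebellum expression):

```bash
python analysis/01_simulate_world.py --seed 1
python analysis/02_extract_regions.py
python analysis/03_build_trees.py
python analysis/04_expression.py
python analysis/05_association.py --seed 1
python analysis/06_report.py --seed 1
```

Script 02 prints the undefined-nucleotide filter accounting (and checks
it against generator ground truth):

```
       region  extracted  after_n_filter  ground_truth_surviving
 upstream_far       3080            2937                    2937
  promoter_w2       3080            2930                    2930
         utr3       3080            2919                    2919
...
mean 3'UTR length: human 1189 bp vs macaque 595 bp
N-filter accounting matches ground truth exactly: True
```

Script 04 recapitulates the constrained brain transcriptome — the two
brain tissues show the smallest total inter-species expression
divergence:

```
total expression divergence by tissue (smallest first):
frontal_cortex     32466.2
cerebellum         34552.5
thymus             55781.6
...
```

and script 05 recovers exactly the planted cell out of the 48 tested:

```
48 cells tested, Bonferroni family m = 48
  significant shift: promoter_w2 × cerebellum  KS p = 1.40e-63  KW p = 1.01e-69  mean r = 0.409 (positive)
```

i.e. only the promoter window that was coupled to cerebellum expression
shows a correlation distribution shifted towards positive values; the
other 47 region × tissue cells stay at the null.  The same analysis is
available as a CLI (`treexpress simulate | run | report -c config.yaml`)
over a YAML run configuration.

## Acceptance script

`scripts/acceptance.py` re-runs the complete computation from scratch:
it simulates the default planted world at the given seed, executes the
full pipeline (region trees → quantile normalization → enrichment →
correlation distributions → 1000-iteration permutation null → KS/KW
with Bonferroni), prints the significant cells, and writes its JSON
result object to `--out`:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/treexpress/` — the library: `regions`, `genomic_trees`,
  `expression`, `association`, `simulate`/`worldio`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers writing tables to `results/`.
- `tests/` — pytest suite, including the seeded calibration experiments.
- `docs/methods.md` — the methods note (model, parameters, numerical
  choices, limitations).
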