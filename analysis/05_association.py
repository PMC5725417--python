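"""Correlate genomic and expression trees; test every region × tissue cell.

For each of the six analysis regions and each tissue passing the
enriched-set size filter, computes the per-gene Pearson correlation
between the normalized genomic tree and the tissue expression tree,
builds the 1000-iteration gene-permutation null (pooled across
tissues per region), and tests the observed distribution against it
with two-sample KS and Kruskal-Wallis, Bonferroni-corrected over all
cells.  Writes the results table, the per-region null densities, and
the top-50 genomic-signature genes for any significant cell.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, __file__.rsplit("/", 1)[0])
from _common import RESULTS_DIR, TREES_DIR, WORLD_DIR, ensure_dirs, parser


def main() -> None:
    args = parser(__doc__).parse_args()
    ensure_dirs()
    from treexpress.association import rank_signature_genes
    from treexpress.expression import ExpressionTable
    from treexpress.pipeline import (DEFAULT_ANALYSIS_REGIONS, StudyParams,
                                     run_association_study)
    from treexpress.species import SIX_PRIMATES

    tables = {
        region: pd.read_csv(os.path.join(TREES_DIR, f"{region}.tsv"),
                            sep="\t", index_col=0,
                            float_precision="round_trip")
        for region in DEFAULT_ANALYSIS_REGIONS
    }
    expr = ExpressionTable.read_tsv(
        os.path.join(WORLD_DIR, "expression_qn.tsv"), normalized=True
    )
    study = run_association_study(tables, expr, SIX_PRIMATES,
                                  StudyParams(seed=args.seed))
    study.table.to_csv(os.path.join(RESULTS_DIR, "association_results.tsv"),
                       sep="\t", index=False)

    dens_rows = []
    for region, null in study.nulls.items():
        mids = 0.5 * (null.density.edges[:-1] + null.density.edges[1:])
        for m, d in zip(mids, null.density.density):
            dens_rows.append((region, m, d))
    pd.DataFrame(dens_rows, columns=["region", "bin_mid", "null_density"]) \
        .to_csv(os.path.join(RESULTS_DIR, "null_densities.tsv"),
                sep="\t", index=False)

    print(f"{len(study.results)} cells tested, Bonferroni family "
          f"m = {study.family_size}")
    hits = study.significant()
    for region, tissue in hits:
        row = study.table[(study.table.region == region)
                          & (study.table.tissue == tissue)].iloc[0]
        print(f"  significant shift: {region} × {tissue}  "
              f"KS p = {row.ks_p_bonf:.2e}  KW p = {row.kw_p_bonf:.2e}  "
              f"mean r = {row.mean_r:.3f} ({row.shift_direction})")
        top = rank_signature_genes(study.samples[(region, tissue)], 50)
        top.to_csv(os.path.join(
            RESULTS_DIR, f"signature_genes_{region}_{tissue}.tsv"),
            sep="\t", index=False)
    if not hits:
        print("  no significant shifts")


if __name__ == "__main__":
    main()
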