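"""Plot observed vs null correlation densities per region × tissue.

Produces one panel per analysis region: the pooled permutation-null
density plus the observed per-gene correlation density for each
tissue, highlighting any Bonferroni-significant cell.
"""

import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, __file__.rsplit("/", 1)[0])
from _common import RESULTS_DIR, TREES_DIR, WORLD_DIR, ensure_dirs, parser


def main() -> None:
    args = parser(__doc__).parse_args()
    ensure_dirs()
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from treexpress.expression import ExpressionTable
    from treexpress.pipeline import (DEFAULT_ANALYSIS_REGIONS, StudyParams,
                                     run_association_study)
    from treexpress.association import Density
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
    sig = set(study.significant())

    figdir = os.path.join(RESULTS_DIR, "figures")
    os.makedirs(figdir, exist_ok=True)
    fig, axes = plt.subplots(2, 3, figsize=(14, 8), sharex=True, sharey=True)
    for ax, region in zip(axes.ravel(), DEFAULT_ANALYSIS_REGIONS):
        null = study.nulls[region]
        mids = 0.5 * (null.density.edges[:-1] + null.density.edges[1:])
        ax.fill_between(mids, null.density.density, color="0.8",
                        label="permutation null")
        for (r, tissue), sample in study.samples.items():
            if r != region:
                continue
            dens = Density.from_sample(sample.values)
            hot = (r, tissue) in sig
            ax.plot(mids, dens.density, lw=2.2 if hot else 0.8,
                    color="crimson" if hot else "steelblue",
                    alpha=1.0 if hot else 0.5,
                    label=tissue if hot else None)
        ax.set_title(region)
        ax.legend(fontsize=8)
    fig.supxlabel("per-gene tree correlation r")
    fig.supylabel("density")
    out = os.path.join(figdir, "correlation_densities.png")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    print(f"wrote {out}")
    print(f"significant cells: {sorted(sig) if sig else 'none'}")


if __name__ == "__main__":
    main()
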