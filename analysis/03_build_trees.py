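"""Build per-gene Jukes-Cantor trees and normalize by the global tree.

For every region that survived the N-filter, computes the 15 pairwise
JC distances per gene, divides by the global inter-species tree, and
writes one gene × pair table per region under scratch/trees/.
"""

import os
import pickle
import sys

import pandas as pd

sys.path.insert(0, __file__.rsplit("/", 1)[0])
from _common import RESULTS_DIR, TREES_DIR, WORLD_DIR, ensure_dirs, parser


def main() -> None:
    parser(__doc__).parse_args()
    ensure_dirs()
    from treexpress.genomic_trees import (build_tree_table, load_global_tree,
                                          normalize_by_global)
    from treexpress.species import SIX_PRIMATES

    with open(os.path.join(WORLD_DIR, "filtered_region_sets.pkl"), "rb") as fh:
        filtered = pickle.load(fh)
    global_tree = load_global_tree(
        os.path.join(WORLD_DIR, "global_tree.nwk"), SIX_PRIMATES
    )
    rows = []
    for region, sets in filtered.items():
        table, drops = build_tree_table(sets, SIX_PRIMATES)
        norm = normalize_by_global(table, global_tree)
        norm.to_csv(os.path.join(TREES_DIR, f"{region}.tsv"), sep="\t")
        rows.append({"region": region, "genes_with_tree": len(norm),
                     "dropped": len(drops),
                     "median_normalized_distance": float(
                         norm.to_numpy().ravel().mean())})
    summary = pd.DataFrame(rows)
    summary.to_csv(os.path.join(RESULTS_DIR, "tree_summary.tsv"),
                   sep="\t", index=False)
    print(summary.to_string(index=False))
    print("\nglobal tree pair distances (substitutions/site):")
    print(global_tree.as_series().round(4).to_string())


if __name__ == "__main__":
    main()
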