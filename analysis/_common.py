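"""Shared paths and argument handling for the analysis scripts."""

import argparse
import os

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
WORLD_DIR = os.path.join(ROOT, "scratch", "world")
TREES_DIR = os.path.join(ROOT, "scratch", "trees")
RESULTS_DIR = os.path.join(ROOT, "results")

SPECIES = ["human", "chimpanzee", "macaque", "baboon", "marmoset", "mouse_lemur"]


def parser(description: str) -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(description=description)
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--small", action="store_true",
                   help="run a reduced world (quick smoke run)")
    return p


def world_config(seed: int, small: bool = False):
    from treexpress.simulate import (SyntheticConfig, PlantedCell,
                                     PASSING_TISSUES, MINOR_TISSUES)

    if small:
        return SyntheticConfig(
            seed=seed,
            enriched_per_tissue={**{t: 110 for t in PASSING_TISSUES},
                                 **{t: 20 for t in MINOR_TISSUES}},
            n_background_genes=150,
            planted_cells=(PlantedCell("promoter_w2", "cerebellum"),),
        )
    from treexpress.simulate import planted_world

    return planted_world(seed)


def ensure_dirs() -> None:
    for d in (WORLD_DIR, TREES_DIR, RESULTS_DIR):
        os.makedirs(d, exist_ok=True)
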