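import numpy as np
import pytest

from treexpress.species import SpeciesSet, SIX_PRIMATES
from treexpress.simulate import (SyntheticConfig, PASSING_TISSUES,
                                 MINOR_TISSUES, PlantedCell)


@pytest.fixture(scope="session")
def six():
    return SIX_PRIMATES


@pytest.fixture(scope="session")
def trio():
    return SpeciesSet(("s1", "s2", "s3"))


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down world: fast to simulate, same structure as the default."""
    return SyntheticConfig(
        seed=11,
        enriched_per_tissue={**{t: 20 for t in PASSING_TISSUES},
                             **{t: 5 for t in MINOR_TISSUES}},
        n_background_genes=30,
    )


@pytest.fixture(scope="session")
def e2e_world_config():
    """Small file-pipeline world: three tissues pass the >100 filter and
    cerebellum carries a planted promoter_w2 association."""
    tissues = ("cerebellum", "frontal_cortex", "liver", "kidney")
    return SyntheticConfig(
        seed=3,
        tissues=tissues,
        enriched_per_tissue={"cerebellum": 130, "frontal_cortex": 130,
                             "liver": 130, "kidney": 40},
        n_background_genes=60,
        tissue_noise_sd={**{t: 0.25 for t in tissues},
                         "cerebellum": 0.125, "frontal_cortex": 0.125},
        planted_cells=(PlantedCell("promoter_w2", "cerebellum"),),
    )


@pytest.fixture(scope="session")
def e2e_world(e2e_world_config, tmp_path_factory):
    from treexpress.worldio import write_world

    outdir = tmp_path_factory.mktemp("world")
    paths = write_world(e2e_world_config, str(outdir))
    return e2e_world_config, paths
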