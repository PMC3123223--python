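import numpy as np
import pytest

from homeosort.alignment_io import MultipleAlignment, Region, RegionMap
from homeosort.synthetic_data import (SimConfig, study_panel_config,
                                      simulate_clone_library,
                                      simulate_progenitors)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def toy_alignment():
    return MultipleAlignment(
        ["s1", "s2", "s3", "s4"],
        ["ACGTACGTAC", "ACGTACGTAC", "ACCTACGAAC", "ACCTACGTAC"],
    )


@pytest.fixture
def gbssi_region_map():
    return RegionMap(
        [
            Region("exon9", 1, 81, "exon"),
            Region("intron9", 82, 189, "intron"),
            Region("exon10", 190, 369, "exon"),
            Region("intron10", 370, 582, "intron"),
            Region("exon11", 583, 718, "exon"),
        ],
        frame_offset=1,
    )


@pytest.fixture(scope="session")
def default_sim():
    cfg = SimConfig(seed=1)
    rng = np.random.default_rng(cfg.seed)
    panel, newick, rm = simulate_progenitors(cfg, rng)
    clones, truth = simulate_clone_library(panel, cfg, rng,
                                           tree_newick=newick)
    return cfg, panel, newick, rm, clones, truth


@pytest.fixture(scope="session")
def study_panel():
    cfg = study_panel_config(seed=1)
    rng = np.random.default_rng(cfg.seed)
    panel, newick, rm = simulate_progenitors(cfg, rng)
    return cfg, panel, newick, rm
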