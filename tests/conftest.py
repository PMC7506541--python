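import numpy as np
import pytest

from msiedit import (
    CmsLocus,
    SimulationConfig,
    StutterModel,
    build_contribution_matrix,
    simulate_loci,
    true_stutter_model,
)


@pytest.fixture
def toy_locus():
    return CmsLocus("TGFBR2", "TGFBR2", "A", 10, 120)


@pytest.fixture
def toy_model(toy_locus):
    """Stutter model with a hand-checkable reference shape {0:0.7, -1:0.2, -2:0.1}."""
    ref = np.zeros(9)
    ref[4], ref[3], ref[2] = 0.7, 0.2, 0.1
    return StutterModel(slope=0.35, midpoint=18.0, reference_stutter={"TGFBR2": ref})


@pytest.fixture
def toy_matrix(toy_locus, toy_model):
    return build_contribution_matrix(toy_locus, toy_model)


@pytest.fixture(scope="session")
def sim_panel():
    """A seeded synthetic cMS panel with its generating stutter model."""
    config = SimulationConfig(seed=11, n_loci=20, noise_cv=0.02)
    loci = simulate_loci(config)
    model = true_stutter_model(loci, config)
    matrices = {l.locus_id: build_contribution_matrix(l, model) for l in loci}
    return config, loci, model, matrices
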