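import numpy as np
import pytest

import rankvec as rv


@pytest.fixture(scope="session")
def fast_config():
    """Reduced permutation counts for unit tests; thresholds at defaults."""
    return rv.RunConfig(n_permutations_rp=150, n_permutations_vector=199)


@pytest.fixture(scope="session")
def small_sim():
    """One-tissue planted simulation small enough for per-module tests."""
    params = rv.SimulationParams(
        n_genes=400,
        n_per_category={"I": 10, "II": 10, "III": 10, "IV": 10},
        effect_size=2.5,
        seed=7,
    )
    cm, ss, truth = rv.simulate_counts(params, tissues=("hippocampus",))
    return cm, ss, truth


@pytest.fixture(scope="session")
def small_em(small_sim):
    cm, ss, _ = small_sim
    return rv.expression_matrix(cm)


@pytest.fixture(scope="session")
def small_six(small_sim, small_em, fast_config):
    cm, ss, _ = small_sim
    return rv.six_contrasts(
        small_em, ss, "hippocampus", fast_config, rng=np.random.default_rng(5)
    )
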