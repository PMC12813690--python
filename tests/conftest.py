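import numpy as np
import pytest

from connectoscope.synthetic_cohort import GroundTruthSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny 6-subject cohort reused by IO-free unit tests."""
    spec = GroundTruthSpec(n_per_group=(3, 3), grid_dims=(8, 8, 8), n_rois=12,
                           n_volumes=40, seed=42)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def subject_matrix():
    """One realistic 90-node correlation matrix (band-limited signals)."""
    from connectoscope.connectome import pearson_matrix
    from connectoscope.synthetic_cohort import (default_base_corr,
                                                simulate_roi_signals)
    C = default_base_corr(90, seed=1)
    S = simulate_roi_signals(C, 230, 2.0, seed=3)
    return pearson_matrix(S.T)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
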