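import numpy as np
import pytest

from curiosync import synthetic


@pytest.fixture(scope="session")
def behav_table():
    """Moderate trial table with non-trivial effects (30 subjects x 36 stimuli)."""
    cfg = synthetic.BehaviourSimConfig(
        n_subjects=30, beta_curiosity=0.15, beta_incentive=0.1, seed=7
    )
    return synthetic.generate_behaviour(cfg)


@pytest.fixture(scope="session")
def fmri_set():
    """Eight subjects, 5^3 grid, default layout (lag 4, T=594)."""
    cfg = synthetic.FmriSimConfig(n_subjects=8, voxel_grid=(5, 5, 5), seed=1)
    return synthetic.generate_fmri(cfg)


@pytest.fixture(scope="session")
def fmri_mask(fmri_set):
    return np.ones(fmri_set[0].data.shape[:3], dtype=bool)
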