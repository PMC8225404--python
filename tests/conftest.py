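import numpy as np
import pytest

from naturalreach.hsmm import HSMMParams
from naturalreach.synthetic import SyntheticConfig, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_hsmm_params(rng: np.random.Generator, max_dwell: int = 12) -> HSMMParams:
    covs = []
    for _ in range(2):
        L = rng.normal(0, 1, (2, 2))
        covs.append(L @ L.T + 0.3 * np.eye(2))
    return HSMMParams(
        ar=np.stack([rng.normal(0, 0.3, (2, 2)) for _ in range(2)]),
        innovation_cov=np.stack(covs),
        dwell_r=rng.uniform(0.5, 5.0, 2),
        dwell_p=rng.uniform(0.2, 0.8, 2),
        init_prob=np.array([0.5, 0.5]),
        max_dwell=max_dwell,
    )


@pytest.fixture(scope="session")
def small_study():
    cfg = SyntheticConfig(
        n_subjects=2, days=(1, 2), events_per_day=12, n_channels=8,
        true_betas={"angle": (-0.5, 0.5)}, seed=7,
    )
    return generate_study(cfg)
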