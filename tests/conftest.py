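import numpy as np
import pytest

from dynconn.synthetic import SyntheticSpec


def block_covariance(n: int, blocks: list[tuple[int, int]], r: float = 0.8) -> np.ndarray:
    """Covariance with correlation r inside each (start, end) block, else 0."""
    C = np.eye(n)
    for start, end in blocks:
        for i in range(start, end):
            for j in range(start, end):
                if i != j:
                    C[i, j] = r
    return C


@pytest.fixture
def three_state_covs():
    """Three clearly distinct covariance regimes over 10 networks."""
    return [
        block_covariance(10, [(0, 5)]),
        block_covariance(10, [(5, 10)]),
        block_covariance(10, [(2, 8)]),
    ]


@pytest.fixture
def three_state_spec(three_state_covs):
    P = np.full((3, 3), 0.025)
    np.fill_diagonal(P, 0.95)
    return SyntheticSpec(
        n_subjects_per_group=2,
        state_covariances=three_state_covs,
        transition_matrix=P,
        groups=("HC", "MCI"),
        n_volumes=290,
        observation_noise_sd=0.1,
        seed=7,
    )
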