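import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def monolayer40():
    """One 512x512 monolayer field with 40% planted disruption (seed 7)."""
    from epiquant.synthetic import MonolayerSpec, generate_monolayer

    spec = MonolayerSpec(disrupted_fraction_target=0.40, seed=7)
    stack, truth = generate_monolayer(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def large_monolayer():
    """A 1024x1024 field giving >=200 cells per distance ring."""
    from epiquant.synthetic import MonolayerSpec, generate_monolayer

    spec = MonolayerSpec(
        field_size_px=(1024, 1024),
        disrupted_fraction_target=0.3,
        n_patches=5,
        marker_prob_by_ring=(0.9, 0.7, 0.5, 0.3),
        seed=11,
    )
    stack, truth = generate_monolayer(spec)
    return spec, stack, truth


def brute_force_nearest_distance(mask: np.ndarray) -> np.ndarray:
    """O(N*M) nearest-true-pixel Euclidean distance, for small images only."""
    from scipy.spatial.distance import cdist

    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    src = np.column_stack(np.nonzero(mask)).astype(float)
    return cdist(pix, src).min(axis=1).reshape(h, w)
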