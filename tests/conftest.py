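import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from gratiomap import CohortSpec, build_phantom, simulate_subject  # noqa: E402

SMALL_GRID = (32, 32, 16)


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(grid_shape=SMALL_GRID, noise_sigma=0.0,
                      lesion_count_per_patient=2, lesion_radius_range=(2.0, 3.0))


@pytest.fixture(scope="session")
def healthy_phantom(small_spec):
    return build_phantom(small_spec, "healthy", seed=11)


@pytest.fixture(scope="session")
def patient_phantom(small_spec):
    return build_phantom(small_spec, "patient", seed=13)


@pytest.fixture(scope="session")
def noiseless_subject(small_spec):
    """Fully simulated noiseless patient (all contrasts)."""
    return simulate_subject(small_spec, "patient", seed=13)


def subsample_mask(mask: np.ndarray, step: int) -> np.ndarray:
    """Every step-th voxel of a mask (keeps tests fast)."""
    idx = np.argwhere(mask)[::step]
    out = np.zeros_like(mask)
    out[tuple(idx.T)] = True
    return out
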