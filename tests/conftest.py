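import numpy as np
import pytest

import punctakit as pk


@pytest.fixture
def clean_frap_truth() -> pk.FrapGroundTruth:
    """Noiseless default-geometry FRAP ground truth."""
    return pk.FrapGroundTruth(mobile_fraction=0.7, half_time=60.0, noise_sd=0.0)


@pytest.fixture
def clean_stack(clean_frap_truth):
    stack, truth = pk.simulate_frap_stack(clean_frap_truth)
    return stack, truth


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
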