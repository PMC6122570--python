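import numpy as np
import pytest

from ki67area import ROISpec, generate_roi, load_default_precomputed


@pytest.fixture(scope="session")
def precomputed():
    return load_default_precomputed()


@pytest.fixture(scope="session")
def noiseless_roi():
    """Noiseless 20+20 ROI: the canonical segmentation test substrate."""
    spec = ROISpec(n_positive=20, n_negative=20, width=360, height=240,
                   noise_sd=0.0, seed=7)
    return generate_roi(spec)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0


@pytest.fixture(scope="session")
def dice_fn():
    return dice
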