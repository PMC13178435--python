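import numpy as np
import pytest

from orgaprint import synthetic


@pytest.fixture(scope="session")
def default_readouts():
    """One draw of the calibrated printed/manual assay populations."""
    spec = synthetic.default_assay_spec(n_per_condition=200, seed=123)
    return synthetic.gen_assay_readouts(spec)


@pytest.fixture(scope="session")
def printed_array_image():
    """3x3 printed array with mild noise, plus its ground-truth table."""
    spec = synthetic.ImageSimSpec(
        shape_px=(900, 900),
        um_per_px=2.0,
        mode="printed",
        n_organoids=9,
        radius_mean_um=100.0,
        radius_cv=0.05,
        pitch_um=500.0,
        noise_sd=0.02,
        blur_sigma_um=4.0,
        seed=1,
    )
    return synthetic.gen_organoid_image(spec)


def disk_mask(shape, center, radius, lobes=0, lobe_amp=0.0):
    return synthetic._lobed_disk_mask(shape, center, radius, lobes, lobe_amp)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
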