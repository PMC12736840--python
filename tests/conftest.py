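import numpy as np
import pytest

import peelscan as ps


@pytest.fixture
def tiny_cube():
    """2x2x3 raw cube with hand-enumerated values 0..11 (row-major, band last)."""
    data = np.arange(12, dtype=np.float32).reshape(2, 2, 3)
    return ps.HyperspectralCube(data=data, wavelengths_nm=np.array([400.0, 500.0, 600.0]))


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Calibrated noiseless phantom scene with its ground truth and key window."""
    spec = ps.PhantomSpec(seed=3, flesh_fraction=0.7, gaussian_sd=0.0, salt_pepper_density=0.0)
    raw, refs, truth = ps.generate_phantom(spec)
    cal = ps.calibrate_reflectance(raw, refs)
    window = ps.resolve_band_window(cal.wavelengths_nm, 592.0, 20.0)
    return cal, truth, window


@pytest.fixture(scope="session")
def phantom_factory():
    def make(seed, flesh_fraction, **kw):
        spec = ps.PhantomSpec(seed=seed, flesh_fraction=flesh_fraction, **kw)
        raw, refs, truth = ps.generate_phantom(spec)
        return ps.calibrate_reflectance(raw, refs), truth

    return make
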