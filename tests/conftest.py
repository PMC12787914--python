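import numpy as np
import pytest

import stemscan as ss


@pytest.fixture(scope="session")
def lab_diameters():
    return ss.lab_reference_diameters()


@pytest.fixture(scope="session")
def lab_heights():
    return ss.lab_reference_heights()


@pytest.fixture(scope="session")
def lab_scene():
    return ss.make_lab_scene()


@pytest.fixture(scope="session")
def tls_noiseless():
    """A survey-TLS-like profile with ranging noise switched off."""
    return ss.DeviceProfile(
        "riegl", 122_000, 360.0, 100.0, 0.0, 1400.0,
        pattern="raster_lines", fov_v_offset=10.0,
    )


@pytest.fixture(scope="session")
def lab_cloud_noiseless(lab_scene, tls_noiseless):
    """One multi-scan noiseless survey of the 12-tube lab (shared: slow)."""
    return ss.scan_scene(lab_scene, tls_noiseless, seed=2, total_points=3_000_000)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
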