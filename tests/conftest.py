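import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import octscreen as oc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_volume_spec():
    """Reduced-geometry OCT phantom: fast to render, default artifact levels."""
    return oc.PhantomSpec(
        n_alines=160, n_bscans=24, axial_px=256, dz_um=2.0,
        tissue_radii_mm=(2.0, 2.0),
    )


@pytest.fixture
def noise_free_spec():
    """Artifact-free reduced phantom: two-level intensities by construction."""
    return oc.PhantomSpec(
        n_alines=160, n_bscans=8, axial_px=256, dz_um=2.0,
        tissue_radii_mm=(2.0, 2.0),
        speckle_sd=0.0, reflectance_drift=0.0, specular_column_rate=0.0,
    )


@pytest.fixture
def uniform_map():
    values = np.zeros((40, 40))
    values[10:30, 10:30] = 180.0
    return oc.ThicknessMap(values, dx_um=12.0, dy_um=12.0)
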