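import numpy as np
import pytest
from hypothesis import settings

import onhmetry as om

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cirrus_spec():
    """Default device-like phantom: 200 x 200 A-scans over 6 x 6 mm."""
    return om.PhantomSpec()


@pytest.fixture(scope="session")
def cirrus_phantom(cirrus_spec):
    return om.make_phantom(cirrus_spec)


@pytest.fixture(scope="session")
def cirrus_report(cirrus_phantom):
    vol, _truth = cirrus_phantom
    return om.extract_biomarkers(vol, om.RunConfig())


@pytest.fixture(scope="session")
def cirrus_radial_set(cirrus_spec):
    return om.derive_radial_set(cirrus_spec, diameters_mm=(3.4, 3.5, 4.1, 4.7))


@pytest.fixture(scope="session")
def small_spec():
    """Coarse phantom for fast unit tests (96 x 96 x 320, 62.5 um pixels)."""
    return om.PhantomSpec(
        n_bscans=96, n_ascans=96, n_axial=320,
        spacing_bscan_um=62.5, spacing_ascan_um=62.5, spacing_axial_um=6.25,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return om.make_phantom(small_spec)


@pytest.fixture(scope="session")
def flat_bm_volume():
    """Thin volume containing only the membrane plane with an elliptic hole."""
    spec = om.PhantomSpec(
        n_axial=16, spacing_axial_um=3.125, ilm_depth_um=1.0, rnfl_t0_um=2.0,
        rnfl_amp_um=0.0, bm_depth_um=15.0, bm_thickness_um=18.0,
        cup_depth_um=4.0, rim_height_um=2.0, prelaminar_base_um=45.0,
        n_vessels=0,
    )
    vol, truth = om.make_phantom(spec)
    return vol, truth


def label_volume_from(labels, **kw):
    defaults = dict(spacing_bscan_um=30.0, spacing_ascan_um=30.0,
                    spacing_axial_um=3.0)
    defaults.update(kw)
    return om.LabelVolume(labels=np.asarray(labels, dtype=np.uint8),
                          **defaults)
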