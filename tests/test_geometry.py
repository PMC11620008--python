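"""En-face projection, circle sampling and the TSNIT angle convention."""

import numpy as np
import pytest
from scipy import integrate

import onhmetry as om
from onhmetry.exceptions import ConfigurationError, OutOfBoundsError
from onhmetry.geometry import (
    EnFaceMap,
    TSNIT_SECTORS,
    TSNIT_SECTOR_WIDTHS,
    clock_hour_of,
    sample_circle,
    sector_of,
    synthesize_radials,
    tsnit_angle_transform,
)

from conftest import label_volume_from


class TestEnfacePresence:
    def test_single_voxel_marks_single_pixel(self):
        labels = np.zeros((5, 6, 7), dtype=np.uint8)
        labels[2, 3, 4] = om.DEFAULT_SCHEME["rpe_bm"]
        m = om.enface_presence(label_volume_from(labels), ["rpe_bm"])
        expected = np.zeros((5, 6), dtype=bool)
        expected[2, 3] = True
        assert np.array_equal(m.values, expected)

    def test_all_background_is_all_false(self):
        m = om.enface_presence(
            label_volume_from(np.zeros((4, 4, 4), dtype=np.uint8)), ["rnfl"])
        assert not m.values.any()

    def test_unknown_label_rejected(self):
        vol = label_volume_from(np.zeros((4, 4, 4), dtype=np.uint8))
        with pytest.raises(KeyError):
            om.enface_presence(vol, ["sclera"])


def affine_map(n=160, pitch=25.0, a=5.0, b=0.012, c=0.034):
    xx, yy = np.meshgrid(np.arange(n) * pitch, np.arange(n) * pitch)
    return EnFaceMap(a + b * xx + c * yy, pitch, pitch), (a, b, c)


class TestSampleCircle:
    def test_constant_map_gives_constant_profile(self):
        m = EnFaceMap(np.full((64, 64), 100.0), 50.0, 50.0)
        p = sample_circle(m, (1600, 1600), 2.0, 64)
        assert np.allclose(p.values, 100.0, atol=1e-12)

    def test_affine_map_sampled_exactly(self):
        m, (a, b, c) = affine_map()
        center = (2000.0, 2000.0)
        tr = tsnit_angle_transform("OD", center)
        p = sample_circle(m, center, 3.0, 360, tr)
        dirs = tr.direction(p.angles_deg)
        x = center[0] + 1500.0 * dirs[:, 0]
        y = center[1] + 1500.0 * dirs[:, 1]
        assert np.allclose(p.values, a + b * x + c * y, atol=1e-9)
        # linearity + symmetry: full-circle mean equals the centre value
        assert p.values.mean() == pytest.approx(a + b * 2000 + c * 2000,
                                                abs=1e-9)

    def test_sinusoidal_field_recovered_with_sector_oracle(self):
        # t(theta) = 100 + 30 sin(2 theta) painted on a fine grid
        n, pitch = 600, 10.0
        center = (2995.0, 2995.0)
        tr = tsnit_angle_transform("OD", center)
        xx, yy = np.meshgrid(np.arange(n) * pitch, np.arange(n) * pitch)
        theta = np.radians(tr.angle_of(np.stack(
            [xx - center[0], yy - center[1]], axis=-1)))
        m = EnFaceMap(100.0 + 30.0 * np.sin(2 * theta), pitch, pitch)
        p = sample_circle(m, center, 3.5, 720, tr)
        expected = 100.0 + 30.0 * np.sin(2 * np.radians(p.angles_deg))
        assert np.abs(p.values - expected).max() < 1.0
        # sector means against a numeric integration oracle
        from onhmetry.rnfl import summarize_profile

        summary = summarize_profile(p)
        for name, (start, _) in TSNIT_SECTORS.items():
            width = TSNIT_SECTOR_WIDTHS[name]
            oracle, _err = integrate.quad(
                lambda t: 100.0 + 30.0 * np.sin(2 * np.radians(t)),
                start, start + width)
            assert summary.tsnit[name] == pytest.approx(oracle / width,
                                                        abs=1.0)

    def test_out_of_bounds_names_diameter(self):
        m = EnFaceMap(np.zeros((32, 32)), 50.0, 50.0)
        with pytest.raises(OutOfBoundsError, match="4.7"):
            sample_circle(m, (800, 800), 4.7, 64)

    def test_undefined_pixels_flag_touching_samples(self):
        vals = np.full((64, 64), 10.0)
        und = np.zeros((64, 64), dtype=bool)
        und[:, 40:] = True
        m = EnFaceMap(vals, 50.0, 50.0, undefined=und)
        p = sample_circle(m, (1600, 1600), 1.6, 360)
        assert p.undefined.any() and not p.undefined.all()


class TestTsnitTransform:
    def test_od_cardinal_directions(self):
        tr = tsnit_angle_transform("OD", (0, 0))
        assert np.allclose(tr.direction(0.0), [1, 0], atol=1e-12)   # temporal
        assert np.allclose(tr.direction(90.0), [0, -1], atol=1e-12)  # superior
        assert np.allclose(tr.direction(180.0), [-1, 0], atol=1e-12)
        assert np.allclose(tr.direction(270.0), [0, 1], atol=1e-12)

    def test_os_mirrors_temporal_axis(self):
        tr = tsnit_angle_transform("OS", (0, 0))
        assert np.allclose(tr.direction(0.0), [-1, 0], atol=1e-12)
        assert np.allclose(tr.direction(90.0), [0, -1], atol=1e-12)

    def test_temporal_horizontal_fovea_is_identity(self):
        base = tsnit_angle_transform("OD", (1000.0, 1000.0))
        tilted = tsnit_angle_transform("OD", (1000.0, 1000.0),
                                       fovea_um=(3000.0, 1000.0))
        angles = np.arange(0, 360, 15.0)
        assert np.allclose(base.direction(angles), tilted.direction(angles),
                           atol=1e-12)
        assert tilted.tilt_applied and tilted.tilt_deg == pytest.approx(0.0)

    def test_fovea_below_horizontal_rotates_all_boundaries(self):
        # fovea 10 deg below the temporal horizontal: every boundary
        # direction rotates rigidly by 10 deg
        c = (1000.0, 1000.0)
        dy = 2000.0 * np.tan(np.radians(10.0))
        tr = tsnit_angle_transform("OD", c, fovea_um=(3000.0, 1000.0 + dy))
        assert tr.tilt_deg == pytest.approx(-10.0, abs=1e-9)
        base = tsnit_angle_transform("OD", c)
        for a in (0.0, 45.0, 90.0, 200.0):
            v = tr.direction(a)
            # same vector re-expressed: its TSNIT angle under the
            # untilted frame differs by exactly the tilt
            back = base.angle_of(v * 100.0)
            assert (back - a) % 360 == pytest.approx(350.0, abs=1e-9)

    def test_degenerate_fovea_rejected(self):
        with pytest.raises(ConfigurationError):
            tsnit_angle_transform("OD", (1000, 1000), fovea_um=(1000, 1000))

    def test_missing_fovea_records_warning(self):
        tr = tsnit_angle_transform("OD", (0, 0))
        assert not tr.tilt_applied
        assert "no fovea" in tr.warning

    def test_angle_of_inverts_direction(self):
        for lat in ("OD", "OS"):
            tr = tsnit_angle_transform(lat, (500.0, 500.0),
                                       fovea_um=(2600.0, 800.0))
            angles = np.arange(0, 360, 7.5)
            d = tr.direction(angles)
            assert np.allclose(tr.angle_of(d * 321.0), angles, atol=1e-9)


class TestSectors:
    def test_sector_widths_are_protocol_exact(self):
        assert TSNIT_SECTOR_WIDTHS == {"T": 90.0, "TS": 40.0, "NS": 40.0,
                                       "N": 110.0, "NI": 40.0, "TI": 40.0}
        assert sum(TSNIT_SECTOR_WIDTHS.values()) == 360.0
        widths = {
            name: (np.mod(np.arange(0, 360, 0.25), 360)[
                sector_of(np.arange(0, 360, 0.25)) == name].size * 0.25)
            for name in TSNIT_SECTORS
        }
        assert widths == TSNIT_SECTOR_WIDTHS

    def test_clock_hours_cover_circle_in_30_deg_bins(self):
        angles = np.arange(0, 360, 0.5)
        hours = clock_hour_of(angles)
        counts = {h: int((hours == h).sum()) for h in range(1, 13)}
        assert all(c == 60 for c in counts.values())
        assert clock_hour_of(np.array([90.0]))[0] == 12  # superior
        assert clock_hour_of(np.array([180.0]))[0] == 3  # nasal


class TestSynthesizeRadials:
    def test_horizontal_radial_equals_bscan_row(self, small_phantom,
                                                small_spec):
        vol, _ = small_phantom
        center = small_spec.bmo_center_um
        sl = synthesize_radials(vol, center, 24)[0]
        assert sl.angle_deg == 0.0
        b_c = int(round(center[1] / vol.spacing_bscan_um))
        a_c = int(round(center[0] / vol.spacing_ascan_um))
        row = vol.labels[b_c]
        n_pos = sl.labels.shape[0] - sl.center_offset
        assert np.array_equal(sl.labels[sl.center_offset:],
                              row[a_c:a_c + n_pos])

    def test_24_radials_at_7p5_deg_increments(self, small_phantom,
                                              small_spec):
        vol, _ = small_phantom
        slices = synthesize_radials(vol, small_spec.bmo_center_um, 24)
        assert len(slices) == 24
        assert [s.angle_deg for s in slices] == [k * 7.5 for k in range(24)]
        assert all(s.lateral_step_um == 62.5 for s in slices)

    def test_symmetric_phantom_slices_agree(self):
        spec = om.PhantomSpec(
            n_bscans=96, n_ascans=96, n_axial=160, spacing_bscan_um=62.5,
            spacing_ascan_um=62.5, spacing_axial_um=12.5,
            bmo_semi_major_um=800.0, bmo_semi_minor_um=800.0,
            rnfl_amp_um=0.0, n_vessels=0)
        vol, _ = om.make_phantom(spec)
        slices = synthesize_radials(vol, spec.bmo_center_um, 24)
        # label multisets on a rotationally symmetric phantom differ
        # between slices only by nearest-neighbour quantisation (< 2%)
        n_lat = min(s.labels.shape[0] for s in slices)
        fracs = []
        for s in slices:
            j0 = s.center_offset - n_lat // 2
            crop = s.labels[max(j0, 0):max(j0, 0) + n_lat]
            fracs.append([np.mean(crop == c) for c in (0, 1, 3, 4)])
        fracs = np.asarray(fracs)
        assert np.ptp(fracs, axis=0).max() < 0.02

    def test_center_outside_rejected(self, small_phantom):
        vol, _ = small_phantom
        with pytest.raises(OutOfBoundsError):
            synthesize_radials(vol, (-50.0, 100.0), 8)
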