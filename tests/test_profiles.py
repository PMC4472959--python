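import numpy as np
import pytest

from gliaquant.io_formats import ChannelStack
from gliaquant.profiles import (
    IntensityProfile,
    ProfileBox,
    box_profile,
    estimate_core_radius,
    peak_report,
    radial_profile,
)
from gliaquant.synthetic import generate_if_phantom, plaque_default

from conftest import make_stack


def disk_stack(radius_um=7.0, ppum=4.0, size=96, amplitude=100.0):
    yy, xx = np.mgrid[0:size, 0:size]
    d = np.hypot(xx + 0.5 - size / 2, yy + 0.5 - size / 2) / ppum
    return make_stack({"CB2": np.where(d < radius_um, amplitude, 0.0)}, ppum)


class TestRadialProfile:
    def test_step_disk(self):
        stack = disk_stack()
        prof = radial_profile(stack, (48, 48), max_radius_um=11, bin_width_um=1)
        vals = prof.channel("CB2")
        assert np.all(vals[prof.positions_um < 6.5] == pytest.approx(100.0))
        assert np.all(vals[prof.positions_um > 8.5] == pytest.approx(0.0))

    def test_gaussian_matches_generating_function(self):
        ppum, size, sigma = 8.0, 160, 3.0
        yy, xx = np.mgrid[0:size, 0:size]
        d = np.hypot(xx + 0.5 - size / 2, yy + 0.5 - size / 2) / ppum
        stack = make_stack({"g": 100 * np.exp(-d**2 / (2 * sigma**2))}, ppum)
        prof = radial_profile(stack, (size / 2, size / 2), 8, bin_width_um=0.5)
        expected = 100 * np.exp(-prof.positions_um**2 / (2 * sigma**2))
        expected *= 100 / expected.max()
        np.testing.assert_allclose(prof.channel("g"), expected, atol=2.0)

    def test_plaque_phantom_minimum_inside_core(self):
        spec = plaque_default()
        spec.poisson_scale, spec.gaussian_sd = 0, 0
        stack, gt = generate_if_phantom(spec, 0)
        prof = radial_profile(stack, gt.plaque_centers_px[0], 15, channels=["CB2"])
        r_min = prof.positions_um[np.argmin(prof.channel("CB2"))]
        assert r_min < gt.plaque_core_radii_um[0]

    def test_scaling_invariance(self, rng):
        arr = rng.uniform(1, 50, (32, 32))
        p1 = radial_profile(make_stack({"c": arr}), (16, 16), 1.2)
        p2 = radial_profile(make_stack({"c": arr * 7.3}), (16, 16), 1.2)
        np.testing.assert_allclose(p1.channel("c"), p2.channel("c"), rtol=1e-9)

    def test_rotation_invariance(self):
        spec = plaque_default()
        spec.poisson_scale, spec.gaussian_sd = 0, 0
        stack, gt = generate_if_phantom(spec, 0)
        rot = ChannelStack(np.rot90(stack.intensities, axes=(2, 3)).copy(),
                           stack.channel_names, stack.pixels_per_um,
                           stack.z_step_um)
        cx, cy = gt.plaque_centers_px[0]
        ny = stack.intensities.shape[2]
        p1 = radial_profile(stack, (cx, cy), 12, channels=["CB2"])
        p2 = radial_profile(rot, (cy, ny - cx), 12, channels=["CB2"])
        np.testing.assert_allclose(p1.channel("CB2"), p2.channel("CB2"), atol=0.5)

    def test_center_outside_rejected(self):
        with pytest.raises(ValueError):
            radial_profile(disk_stack(), (-5, 10), 5)


class TestEstimateCoreRadius:
    def _step_profile(self, radius=7.0):
        pos = np.arange(0.5, 15, 1.0)
        vals = np.where(pos < radius, 0.0, 100.0)
        return IntensityProfile("radial", pos, {"CB2": vals}, 1.0, 11.1)

    def test_step_profile(self):
        r = estimate_core_radius(self._step_profile(7.0))
        assert r == pytest.approx(7.0, abs=1.0)

    def test_noiseless_phantom_radius_10(self):
        spec = plaque_default(core_radius_um=10.0)
        spec.poisson_scale, spec.gaussian_sd = 0, 0
        stack, gt = generate_if_phantom(spec, 0)
        prof = radial_profile(stack, gt.plaque_centers_px[0], 15, channels=["CB2"])
        assert estimate_core_radius(prof) == pytest.approx(10.0, abs=1.0)

    def test_monotone_decreasing_rejected(self):
        pos = np.arange(0.5, 15, 1.0)
        prof = IntensityProfile("radial", pos,
                                {"CB2": np.linspace(100, 1, pos.size)}, 1.0, 11.1)
        with pytest.raises(ValueError, match="no core rise"):
            estimate_core_radius(prof)


class TestBoxProfile:
    def test_constant_image_flat_at_100(self):
        stack = make_stack({"c": np.full((32, 32), 9.0)})
        prof = box_profile(stack, ProfileBox((2, 16), (30, 16), 8))
        np.testing.assert_allclose(prof.channel("c"), 100.0)

    def test_bright_column_peak_position(self):
        arr = np.ones((40, 40))
        arr[:, 25] = 50.0
        stack = make_stack({"c": arr}, pixels_per_um=1.0)
        prof = box_profile(stack, ProfileBox((0, 20), (39, 20), 6))
        rep = peak_report(prof)
        assert rep.peaks_um["c"] == pytest.approx(25.5, abs=1.0)

    def test_rotated_box_transposes_profile(self, rng):
        arr = rng.uniform(1, 20, (40, 40))
        stack = make_stack({"c": arr})
        stack_t = make_stack({"c": arr.T})
        p1 = box_profile(stack, ProfileBox((5, 13), (35, 13), 7))
        p2 = box_profile(stack_t, ProfileBox((13, 5), (13, 35), 7))
        np.testing.assert_allclose(p1.channel("c"), p2.channel("c"), atol=1e-6)

    def test_short_axis_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            box_profile(make_stack({"c": np.ones((16, 16))}),
                        ProfileBox((2, 2), (6, 2), 4))

    def test_degenerate_width_rejected(self):
        with pytest.raises(ValueError, match="width"):
            box_profile(make_stack({"c": np.ones((16, 16))}),
                        ProfileBox((2, 2), (14, 2), 0))


class TestPeakReport:
    @staticmethod
    def _bump(pos, center, width=0.8):
        return 100 * np.exp(-(pos - center) ** 2 / (2 * width**2))

    def test_three_shifted_bumps(self):
        pos = np.arange(0, 12, 0.1)
        prof = IntensityProfile("box", pos, {
            "DAPI": self._bump(pos, 4.0),
            "CB2": self._bump(pos, 5.5),
            "CD68": self._bump(pos, 7.0),
        }, 0.1, 11.1)
        rep = peak_report(prof)
        assert rep.offset("CB2", "DAPI") == pytest.approx(1.5, abs=0.05)
        assert rep.offset("CD68", "CB2") == pytest.approx(1.5, abs=0.05)
        assert rep.ordering_dapi_cb2_cd68 is True

    def test_identical_channels_zero_offset(self):
        pos = np.arange(0, 10, 0.1)
        b = self._bump(pos, 5.0)
        prof = IntensityProfile("box", pos, {"CB2": b, "CD68": b.copy()}, 0.1, 11.1)
        assert peak_report(prof).offset("CB2", "CD68") == 0.0

    def test_flat_channel_dropped(self):
        pos = np.arange(0, 10, 0.1)
        prof = IntensityProfile("box", pos, {
            "CB2": self._bump(pos, 5.0),
            "CD68": np.full(pos.size, 100.0),
        }, 0.1, 11.1)
        rep = peak_report(prof)
        assert "CD68" not in rep.peaks_um and "CB2" in rep.peaks_um
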