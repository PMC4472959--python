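import numpy as np
import pytest

from gliaquant.pet import (
    FrameSchedule,
    TimeActivityCurve,
    blockade_comparison,
    parse_schedule,
    peak_suv,
    suv,
    value_at,
    windowed_mean_suv,
)
from gliaquant.synthetic import TacSpec, generate_tac

PAPER_SCHEDULE = "20 sec x 3, 30 sec x 2, 1 min x 2, 2 min x 3, 5 min x 4"


class TestParseSchedule:
    def test_dynamic_acquisition_is_30_minutes(self):
        sched = parse_schedule(PAPER_SCHEDULE)
        assert sched.n_frames == 14
        assert sched.total_duration_s == 1800.0

    def test_compact_form_equivalent(self):
        assert parse_schedule("20x3,30x2,60x2,120x3,300x4") == \
            parse_schedule(PAPER_SCHEDULE)

    def test_single_frame(self):
        sched = parse_schedule("60x1")
        assert sched.frames == ((0.0, 60.0),)

    @pytest.mark.parametrize("bad", ["20x0", "0x3", "x2", "20*3"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_schedule(bad)

    def test_gap_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            FrameSchedule([(0, 20), (30, 20)])


class TestSuv:
    def test_formula(self):
        assert suv(10, 100, 25) == pytest.approx(2.5)
        assert suv(4.0 / 25.0, 4.0, 25.0) == pytest.approx(1.0)

    def test_dose_scaling(self):
        assert suv(10, 200, 25) == pytest.approx(suv(10, 100, 25) / 2)

    def test_simultaneous_rescale_invariant(self):
        assert suv(10, 100, 25) == pytest.approx(suv(10 * 3.7, 100 * 3.7, 25))

    def test_unit_mismatch_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            suv(10, 100, 25, concentration_unit="kBq/mL", dose_unit="MBq")


@pytest.fixture
def tac(schedule):
    vals = np.array([1, 3, 2] + [1.0] * (schedule.n_frames - 3))
    return TimeActivityCurve(schedule, vals)


class TestWindowedMean:
    def test_constant(self, schedule):
        tac = TimeActivityCurve(schedule, np.full(schedule.n_frames, 2.0))
        assert windowed_mean_suv(tac, 37, 1500) == pytest.approx(2.0)

    def test_two_frames_weighted(self):
        sched = FrameSchedule([(0, 60), (60, 180)])
        tac = TimeActivityCurve(sched, [1.0, 3.0])
        assert windowed_mean_suv(tac, 0, 240) == pytest.approx(2.5)

    def test_exact_frame_window(self, tac, schedule):
        start, dur = schedule.frames[5]
        assert windowed_mean_suv(tac, start, start + dur) == \
            pytest.approx(tac.frame_values[5])

    def test_full_span_equals_duration_weighted_mean(self, tac, schedule):
        full = windowed_mean_suv(tac, 0, schedule.total_duration_s)
        expected = np.average(tac.frame_values, weights=schedule.durations_s)
        assert full == pytest.approx(expected)

    def test_inverted_window_rejected(self, tac):
        with pytest.raises(ValueError):
            windowed_mean_suv(tac, 100, 100)


class TestPeakAndValueAt:
    def test_peak(self, tac):
        value, interval = peak_suv(tac)
        assert value == 3.0
        assert interval == (20.0, 40.0)

    def test_boundary_belongs_to_earlier_frame(self, tac):
        # t = 40 s is the boundary of frames 2 and 3
        assert value_at(tac, 40 / 60) == tac.frame_values[1]

    def test_outside_span_rejected(self, tac):
        with pytest.raises(ValueError):
            value_at(tac, 31.0)


class TestBlockadeComparison:
    def test_half_gives_fold_two(self, schedule):
        vals = np.linspace(2, 0.2, schedule.n_frames)
        base = TimeActivityCurve(schedule, vals)
        blk = TimeActivityCurve(schedule, vals * 0.5)
        b, k, fold = blockade_comparison(base, blk)
        assert fold == pytest.approx(2.0)
        assert k == pytest.approx(b / 2)

    def test_identical_fold_one(self, schedule):
        vals = np.linspace(2, 0.2, schedule.n_frames)
        t = TimeActivityCurve(schedule, vals)
        assert blockade_comparison(t, t)[2] == pytest.approx(1.0)


class TestGenerateTac:
    def test_constant_curve_samples_to_constant(self, schedule):
        spec = TacSpec([(0.0, 1.0), (30.0, 1.0)], noise_sd=0.0)
        tac = generate_tac(spec, schedule, 0)[0]
        np.testing.assert_allclose(tac.frame_values, 1.0, atol=1e-9)

    def test_four_anchor_curve_peak_frame(self, schedule):
        # piecewise-linear rise to 2.30 at 45 s: the 40-60 s frame mean
        # sits within 0.20 of the anchor value
        spec = TacSpec([(0, 0), (0.75, 2.30), (10, 0.67), (20, 0.22)],
                       noise_sd=0.0)
        tac = generate_tac(spec, schedule, 0)[0]
        assert tac.frame_values[2] == pytest.approx(2.30, abs=0.20)

    def test_blockade_exactly_scales_baseline(self, schedule):
        spec = TacSpec([(0, 0), (1, 2.0), (30, 0.5)], noise_sd=0.0,
                       blockade_scale=0.5)
        base = generate_tac(spec, schedule, 0)[0]
        blk = generate_tac(spec, schedule, 0, condition="blockade")[0]
        np.testing.assert_allclose(blk.frame_values, base.frame_values * 0.5)

    def test_terminal_extrapolation_positive_and_decaying(self, schedule):
        spec = TacSpec([(0, 0), (1, 2.0), (10, 1.0), (20, 0.5)], noise_sd=0.0)
        tac = generate_tac(spec, schedule, 0)[0]
        tail = tac.frame_values[-2:]    # frames beyond the last control point
        assert np.all(tail > 0)
        assert tail[1] < tail[0]

    def test_seed_determinism_and_noise_variation(self, schedule):
        spec = TacSpec([(0, 0), (1, 2.0), (30, 0.2)], noise_sd=0.1)
        a = generate_tac(spec, schedule, 7)[0].frame_values
        b = generate_tac(spec, schedule, 7)[0].frame_values
        c = generate_tac(spec, schedule, 8)[0].frame_values
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            TacSpec([(0, 0), (5, 1.0), (5, 0.5)])      # non-increasing times
        with pytest.raises(ValueError):
            TacSpec([(0, 0), (5, -1.0)])               # negative SUV
        with pytest.raises(ValueError):
            TacSpec([(0, 0), (5, 1.0)], blockade_scale=1.5)
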