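import math

import numpy as np
import pytest

import audiosim as asim
from audiosim.core import ABOVE_MAX, BELOW_MIN, DEFAULT_GRID, IN_RANGE
from audiosim.cohort import ListenerParams
from audiosim.procedures import (ProcedureConfig, UncalibratedModelError,
                                 bekesy_track, effective_level,
                                 hughson_westlake, run_full_exam,
                                 self_adjust_test)

from conftest import flat_listener, perfect_device

STOCHASTIC = ListenerParams(slope=3.0, guess_rate=0.02, lapse_rate=0.02,
                            session_sd=0.0)


def smallest_grid_at_or_above(t, step=5):
    return step * math.ceil(t / step)


class TestEffectiveLevel:
    def test_cross_hearing_attenuation(self):
        assert effective_level(60, False, 40) == (60, 20)
        assert effective_level(30, False, 40) == (30, -10)

    def test_masking_removes_cross_path(self):
        test, contra = effective_level(60, True, 40)
        assert test == 60 and contra == -math.inf


class TestHughsonWestlake:
    def test_hand_run_staircase_t_32_5(self):
        res = hughson_westlake(flat_listener(32.5), "left", 1000,
                               rng=np.random.default_rng(0))
        assert res.level == 35 and res.flag == IN_RANGE

    @pytest.mark.parametrize("t", [-7.3, -2.1, 2.1, 17.5 + 1e-6, 32.5, 47.2,
                                   63.9, 88.1, 101.2])
    def test_deterministic_exact_recovery(self, t):
        """For step-function listeners the staircase returns the smallest
        grid level at or above the true threshold."""
        res = hughson_westlake(flat_listener(t), "left", 2000,
                               rng=np.random.default_rng(1))
        assert res.level == smallest_grid_at_or_above(t)

    def test_below_floor_flagged(self):
        res = hughson_westlake(flat_listener(-100), "left", 1000,
                               rng=np.random.default_rng(2))
        assert res.flag == BELOW_MIN and res.level == -10

    def test_above_ceiling_flagged(self):
        res = hughson_westlake(flat_listener(118), "left", 1000,
                               rng=np.random.default_rng(3))
        assert res.flag == ABOVE_MAX and res.level == 110

    def test_stochastic_mean_near_threshold(self):
        """Monte-Carlo: the staircase's mean estimate sits within the small
        upward bias inherent to the ascending-response rule."""
        rng = np.random.default_rng(4)
        t = 30.0
        est = [hughson_westlake(flat_listener(t, STOCHASTIC), "left", 1000,
                                rng=rng).level for _ in range(500)]
        assert abs(np.mean(est) - t) < 3.5

    def test_threshold_appears_in_trace(self):
        for t in (12.3, 41.7):
            res = hughson_westlake(flat_listener(t, STOCHASTIC), "left", 500,
                                   rng=np.random.default_rng(5))
            if res.flag == IN_RANGE:
                assert res.level in res.trace.levels

    def test_trace_steps_follow_config(self):
        cfg = ProcedureConfig()
        res = hughson_westlake(flat_listener(37.2, STOCHASTIC), "left", 500,
                               rng=np.random.default_rng(6), config=cfg)
        levels = res.trace.levels
        for a, b in zip(levels, levels[1:]):
            assert (b - a == cfg.step_up or a - b == cfg.step_down
                    or (b - a) == 0  # clamped at an output limit
                    or abs(b - a) in (cfg.step_up, cfg.step_down))


class TestSelfAdjust:
    def test_noise_free_recovery_with_perfect_calibration(self):
        _, inst, ref = perfect_device()
        res = self_adjust_test(flat_listener(19.9), "left", 1000, inst,
                               ref, rng=np.random.default_rng(0))
        assert res.level == 20 and res.flag == IN_RANGE

    @pytest.mark.parametrize("t", [-4.9, 3.2, 22.5, 38.1, 61.4])
    def test_deterministic_exact_recovery(self, t):
        _, inst, ref = perfect_device()
        res = self_adjust_test(flat_listener(t), "left", 4000, inst, ref,
                               rng=np.random.default_rng(1))
        assert res.level == smallest_grid_at_or_above(t)

    def test_reference_error_shifts_thresholds_linearly(self):
        """Overestimating the reference by +5 dB lowers every reading by 5."""
        _, inst, ref0 = perfect_device()
        ref5 = asim.ReferenceLevel("M", {f: 5.0 for f in DEFAULT_GRID}, 15, 15, True)
        for t in (12.4, 33.3, 47.9):
            r0 = self_adjust_test(flat_listener(t), "left", 1000, inst, ref0,
                                  rng=np.random.default_rng(2))
            r5 = self_adjust_test(flat_listener(t), "left", 1000, inst, ref5,
                                  rng=np.random.default_rng(2))
            assert r5.level == r0.level - 5

    def test_threshold_above_device_limit_flagged(self):
        _, inst, ref = perfect_device()
        res = self_adjust_test(flat_listener(95), "left", 1000, inst, ref,
                               rng=np.random.default_rng(3))
        assert res.flag == ABOVE_MAX

    def test_uncalibrated_model_rejected(self):
        _, inst, _ = perfect_device()
        invalid = asim.ReferenceLevel("M", {f: 0.0 for f in DEFAULT_GRID},
                                      10, 10, False)
        with pytest.raises(UncalibratedModelError):
            self_adjust_test(flat_listener(20), "left", 1000, inst, invalid,
                             rng=np.random.default_rng(4))


class TestMasking:
    def test_masking_never_improves_threshold(self):
        """Cross-hearing can only help detection: with the contralateral ear
        far more sensitive, removing the cross path (masking always on)
        yields an equal or worse measured threshold."""
        thresholds = {("left", f): 60.0 + 0.1 for f in DEFAULT_GRID}
        thresholds.update({("right", f): -5.0 for f in DEFAULT_GRID})
        listener = asim.ListenerProfile("A", 30, thresholds, slope=1e-6,
                                        lapse_rate=0, guess_rate=0, session_sd=0)
        unmasked = hughson_westlake(listener, "left", 1000,
                                    ProcedureConfig(masking_trigger=1e9),
                                    np.random.default_rng(5))
        masked = hughson_westlake(listener, "left", 1000,
                                  ProcedureConfig(masking_trigger=-1e9),
                                  np.random.default_rng(5))
        assert masked.level >= unmasked.level
        # cross-hearing caps the unmasked threshold near IA + contra threshold
        assert unmasked.level < 60 <= masked.level

    def test_masking_flag_recorded_in_trace(self):
        res = hughson_westlake(flat_listener(55), "left", 1000,
                               rng=np.random.default_rng(6))
        masked_levels = [lvl for lvl, _, m in res.trace.presentations if m]
        assert all(lvl > 40 for lvl in masked_levels)
        assert masked_levels  # levels above the trigger were presented


class TestBekesy:
    def test_deterministic_track_oscillates_at_threshold(self):
        _, inst, _ = perfect_device()
        est, ok = bekesy_track(flat_listener(30.2), "left", 1000, inst,
                               rng=np.random.default_rng(0))
        assert ok and abs(est - 30.2) <= 0.5 + 1e-9

    def test_stochastic_bias_below_one_db(self):
        _, inst, _ = perfect_device()
        rng = np.random.default_rng(1)
        ests = []
        for _ in range(500):
            est, ok = bekesy_track(flat_listener(25.0, STOCHASTIC), "left",
                                   1000, inst, rng=rng)
            if ok:
                ests.append(est)
        assert len(ests) > 450
        assert abs(np.mean(ests) - 25.0) < 1.0

    def test_inattentive_listener_yields_more_invalid_tracks(self):
        """A listener whose responses barely depend on level (the degenerate
        inattentive case) fails the settle check far more often."""
        _, inst, _ = perfect_device()
        rng = np.random.default_rng(2)
        sloppy = ListenerParams(slope=25.0, guess_rate=0.1, lapse_rate=0.1,
                                session_sd=0.0)
        good = ListenerParams(slope=3.0, guess_rate=0.02, lapse_rate=0.02,
                              session_sd=0.0)
        def invalid_rate(params):
            return sum(not bekesy_track(flat_listener(30, params), "left",
                                        1000, inst, rng=rng)[1]
                       for _ in range(100))
        assert invalid_rate(sloppy) > invalid_rate(good) + 10


class TestFullExam:
    def test_output_shape_two_ears_full_grid(self):
        ags, _ = run_full_exam(flat_listener(15), procedure="pta",
                               rng=np.random.default_rng(0))
        assert set(ags) == {"left", "right"}
        for ear, ag in ags.items():
            assert len(ag.thresholds) + len(ag.oor_flags) == 7

    def test_deterministic_exams_are_identical(self):
        l = flat_listener(27.3)  # session_sd = 0
        a1, _ = run_full_exam(l, procedure="pta", rng=np.random.default_rng(1))
        a2, _ = run_full_exam(l, procedure="pta", rng=np.random.default_rng(2))
        assert a1 == a2

    def test_mobile_exam_uses_mhl_scale(self):
        _, inst, ref = perfect_device()
        ags, _ = run_full_exam(flat_listener(20), inst, ref, "mobile",
                               rng=np.random.default_rng(3))
        assert all(ag.scale == "mHL" for ag in ags.values())
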