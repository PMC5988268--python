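import numpy as np
import pandas as pd
import pytest

from contextsacc import BehaviorParams, simulate_eye_trace, simulate_later_rt
from contextsacc.behavior import (Excluded, InsufficientDataError,
                                  choice_probability, detect_saccades,
                                  first_saccade_rt, fit_reciprobit,
                                  radial_velocity, reciprobit_points,
                                  reciprobit_slope, sacrt_anova, success_rate)
from contextsacc.model import EyeTrace, Trial

EVENTS = {"scene_onset": 0.0, "fix_start": 1080.0, "object_onset": 1860.0,
          "outcome_time": 2400.0}


def _trial(**kw):
    defaults = dict(trial_id="t0", scene_id="s0", monkey_id="PA",
                    events=EVENTS, first_object_value="good",
                    target_angle_deg=0.0)
    defaults.update(kw)
    return Trial(**defaults)


def _trace(x, y, trial_id="t0", t0=0.0):
    x = np.asarray(x, dtype=float)
    return EyeTrace(trial_id=trial_id, sample_rate=1000.0, t0_ms=t0,
                    x=x, y=np.asarray(y, dtype=float),
                    pupil=np.full(len(x), 3.0))


class TestRadialVelocity:
    def test_stationary_trace_near_zero(self):
        v = radial_velocity(_trace(np.ones(100), np.ones(100)))
        assert np.max(np.abs(v)) < 1e-9

    def test_horizontal_ramp_closed_form(self):
        t = np.arange(200)
        v = radial_velocity(_trace(0.1 * t, np.zeros(200)))  # 100 deg/s
        np.testing.assert_allclose(v[5:-5], 100.0, rtol=1e-6)

    def test_peak_matches_analytic_profile(self):
        """Numeric peak vs the minimum-jerk analytic maximum (1.875 A/d)."""
        tr, _ = simulate_eye_trace(EVENTS, 100.0, 0.0, "t", seed=0,
                                   fixation_sd=0.0, saccade_duration=40.0)
        analytic = 1.875 * 15.0 / 0.040
        assert radial_velocity(tr).max() == pytest.approx(analytic, rel=0.05)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            radial_velocity(_trace([0.0, 1.0], [0.0, 0.0]))


class TestDetectSaccades:
    def test_fixation_noise_yields_none(self):
        rng = np.random.default_rng(0)
        # slow drifting jitter, never near the 300 deg/s threshold
        t = np.arange(2000)
        x = 0.05 * np.sin(2 * np.pi * t / 500.0)
        assert detect_saccades(_trace(x, np.zeros(2000))) == []

    def test_smooth_drift_below_threshold(self):
        t = np.arange(1000)
        x = 0.02 * t  # 20 deg/s
        assert detect_saccades(_trace(x, np.zeros(1000))) == []

    def test_generator_ground_truth_onset(self):
        errs = []
        for seed in range(10):
            tr, onset = simulate_eye_trace(EVENTS, 100.0 + seed, 45.0, "t",
                                           seed=seed, fixation_sd=0.0)
            sacs = detect_saccades(tr)
            assert len(sacs) == 1
            errs.append(abs(sacs[0].onset_ms - onset))
        assert max(errs) <= 3.0

    def test_translation_and_rotation_equivariance(self):
        tr1, _ = simulate_eye_trace(EVENTS, 100.0, 0.0, "t", seed=5,
                                    fixation_sd=0.0)
        s1 = detect_saccades(tr1)[0]
        # same trace shifted in time
        tr2 = EyeTrace(trial_id="t", sample_rate=1000.0,
                       t0_ms=tr1.t0_ms + 250.0, x=tr1.x, y=tr1.y,
                       pupil=tr1.pupil)
        s2 = detect_saccades(tr2)[0]
        assert s2.onset_ms - s1.onset_ms == pytest.approx(250.0)
        # rotated by 90 deg: (x, y) -> (-y, x)
        tr3 = EyeTrace(trial_id="t", sample_rate=1000.0, t0_ms=tr1.t0_ms,
                       x=-tr1.y, y=tr1.x, pupil=tr1.pupil)
        s3 = detect_saccades(tr3)[0]
        assert (s3.direction - s1.direction) % 360.0 == pytest.approx(
            90.0, abs=1.0)
        assert s3.onset_ms == pytest.approx(s1.onset_ms)


class TestFirstSaccadeRT:
    def _sac(self, onset, direction=0.0):
        from contextsacc.behavior import SaccadeEvent
        return SaccadeEvent(onset_ms=onset, peak_velocity=500.0,
                            peak_time_ms=onset + 20, amplitude=15.0,
                            direction=direction)

    def test_basic_rt(self):
        rt = first_saccade_rt(_trial(), [self._sac(1960.0)])
        assert rt == pytest.approx(100.0)

    def test_repeat_excluded(self):
        res = first_saccade_rt(_trial(is_repeat=True), [self._sac(1960.0)])
        assert isinstance(res, Excluded) and res.reason == "repeat"

    def test_failure_excluded(self):
        for outcome in ("fixation_break", "robbed"):
            res = first_saccade_rt(_trial(outcome=outcome),
                                   [self._sac(1960.0)])
            assert isinstance(res, Excluded) and res.reason == "failure"

    def test_wrong_direction_excluded(self):
        res = first_saccade_rt(_trial(), [self._sac(1960.0, direction=180.0)])
        assert isinstance(res, Excluded) and res.reason == "wrong_direction"

    def test_pre_object_saccades_ignored(self):
        res = first_saccade_rt(_trial(), [self._sac(500.0),
                                          self._sac(1940.0)])
        assert res == pytest.approx(80.0)

    def test_no_saccade(self):
        res = first_saccade_rt(_trial(), [])
        assert isinstance(res, Excluded) and res.reason == "none_found"


class TestChoiceAndSuccess:
    def _trials(self, outcomes):
        return [_trial(trial_id=f"t{i}", outcome=o)
                for i, o in enumerate(outcomes)]

    def test_choice_probability(self):
        trials = self._trials(["rewarded"] * 9 + ["no_reward"])
        assert choice_probability(trials) == pytest.approx(0.9)
        assert choice_probability(self._trials(["no_reward"] * 5)) == 0.0
        assert choice_probability(
            self._trials(["fixation_break"] * 3)) is None

    def test_success_rate_counts_robbed_against(self):
        trials = self._trials(["rewarded"] * 8 + ["robbed"] * 2)
        assert success_rate(trials) == pytest.approx(0.8)
        assert success_rate(self._trials(["rewarded"] * 4)) == 1.0
        assert success_rate(self._trials(["fixation_break"])) is None

    def test_planted_robber_loss_recovered(self):
        rng = np.random.default_rng(2)
        outcomes = np.where(rng.random(400) < 0.25, "robbed", "rewarded")
        s = success_rate(self._trials(outcomes))
        assert s == pytest.approx(0.75, abs=3 * np.sqrt(0.25 * 0.75 / 400))


class TestReciprobit:
    def _later(self, mu, n=5000, seed=1, sigma=1.2):
        p = BehaviorParams(later_mu={"S/R": mu}, later_sigma=sigma,
                           express_fraction=0.0, object_penalty=0.0)
        return simulate_later_rt(p, "S/R", "good", n, seed=seed)

    def test_points_monotone(self):
        x, y = reciprobit_points(self._later(9.0, n=500))
        assert np.all(np.diff(x) >= 0)
        assert np.all(np.diff(y) > 0)

    def test_identical_latencies_degenerate(self):
        with pytest.raises(ValueError):
            fit_reciprobit(np.full(50, 100.0))

    def test_nonpositive_rt_rejected(self):
        with pytest.raises(ValueError):
            fit_reciprobit(np.concatenate([np.full(30, 100.0), [-1.0]]))

    def test_insufficient_n(self):
        with pytest.raises(InsufficientDataError):
            fit_reciprobit(np.linspace(90, 110, 10))

    def test_mu_recovery_against_bruteforce(self):
        """Fitted location vs the mean of 10^6 brute-force reciprocals."""
        fit = fit_reciprobit(self._later(8.0))
        rng = np.random.default_rng(77)
        r = rng.normal(8.0, 1.2, 1_200_000)
        oracle = np.mean(r[r > 0][:1_000_000])
        assert fit.mu_recip == pytest.approx(oracle, rel=0.02)
        assert fit.median_latency_ms == pytest.approx(1000.0 / oracle,
                                                      rel=0.02)

    def test_rate_shift_moves_line_parallel(self):
        f1 = fit_reciprobit(self._later(8.0, seed=3))
        f2 = fit_reciprobit(self._later(10.0, seed=4))
        ratio = reciprobit_slope(f1) / reciprobit_slope(f2)
        assert 0.9 < ratio < 1.1

    def test_express_mixture_degrades_linearity(self):
        """A context-only express component curves the reciprobit line."""
        pure = fit_reciprobit(self._later(9.0, seed=5))
        p = BehaviorParams(later_mu={"D/R": 9.0}, later_sigma=1.2,
                           express_fraction=0.35, object_penalty=3.0)
        mixed = fit_reciprobit(
            simulate_later_rt(p, "D/R", "bad", 5000, seed=5))
        assert mixed.r_squared < pure.r_squared


class TestSacrtAnova:
    def _df(self, mus, n, seed, object_effect=1.0):
        rng = np.random.default_rng(seed)
        rows = []
        for ctx, mu in mus.items():
            for obj, pen in (("good", 0.0), ("bad", object_effect)):
                r = rng.normal(mu - pen, 1.2, n)
                r = np.maximum(r, 0.5)
                rows.append(pd.DataFrame({
                    "rt": 1000.0 / r, "context": ctx, "object_value": obj}))
        return pd.concat(rows, ignore_index=True)

    def test_planted_ordering_significant(self):
        df = self._df({"D/R": 10.5, "S/R": 9.5, "S/P": 8.8}, 500, 11)
        res = sacrt_anova(df)
        assert res["p_scene"] < 0.05 and res["p_object"] < 0.05
        tk = res["tukey"].set_index(["group1", "group2"])
        assert bool(tk.loc[("D/R", "S/R"), "reject"])
        assert bool(tk.loc[("S/P", "S/R"), "reject"])
        means = res["cell_means"].groupby("scene", observed=True).mean()
        assert means["D/R"] < means["S/R"] < means["S/P"]

    def test_single_observation_cell_rejected(self):
        df = self._df({"D/R": 10.0, "S/R": 9.0, "S/P": 8.0}, 5, 1)
        df = df.drop(df[(df.context == "D/R")
                        & (df.object_value == "bad")].index[1:])
        with pytest.raises(InsufficientDataError, match="D/R"):
            sacrt_anova(df)
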