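import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contextsacc.spikes import (DeltaFRSeries, InsufficientDataError,
                                classify_unit, delta_fr_series,
                                discrimination_latency, population_average,
                                population_si, response_latency,
                                scene_response_latency, scene_zscores,
                                selectivity_index, spike_density, window_rate)
from contextsacc.synth import RateProfile, simulate_spike_train

from conftest import make_trials


def _spike_maps(trials, profile, rng):
    return {t.trial_id: simulate_spike_train(profile, (-500.0, 1860.0),
                                             rng=rng)
            for t in trials}


FLAT10 = RateProfile([-500.0, 1860.0], [10.0, 10.0])


class TestSpikeDensity:
    def test_no_spikes_zero(self):
        grid = np.arange(0.0, 100.0)
        assert np.all(spike_density([], grid) == 0.0)

    def test_single_spike_peak_closed_form(self):
        grid = np.arange(-50.0, 50.0, 1.0)
        sdf = spike_density([0.0], grid, sigma=10.0)
        assert sdf.max() == pytest.approx(1000.0 / (10.0 * np.sqrt(2 * np.pi)),
                                          rel=1e-9)
        assert grid[np.argmax(sdf)] == 0.0

    def test_integral_conserves_spike_count(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0, 1000, 100))
        grid = np.arange(-100.0, 1100.0, 0.5)
        sdf = spike_density(spikes, grid)
        integral = np.trapezoid(sdf, grid) / 1000.0
        assert integral == pytest.approx(100.0, rel=1e-3)


class TestWindowRate:
    def test_rate(self):
        assert window_rate([10, 20, 30, 40, 450], (0, 500)) == 10.0

    def test_empty(self):
        assert window_rate([], (0, 500)) == 0.0

    def test_half_open_boundary(self):
        assert window_rate([0.0, 500.0], (0, 500)) == 2.0  # 0 in, 500 out
        assert window_rate([500.0], (0, 500)) == 0.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            window_rate([1.0], (5, 5))


class TestClassifyUnit:
    def test_planted_excitation(self, context_trials):
        rng = np.random.default_rng(1)
        prof = RateProfile([-500.0, 0.0, 0.0, 1860.0],
                           [10.0, 10.0, 30.0, 30.0])
        sm = {t.trial_id: simulate_spike_train(prof, (-500, 1860), rng=rng)
              for ts in context_trials.values() for t in ts}
        assert classify_unit("u", context_trials, sm) == "excited"

    def test_planted_inhibition(self, context_trials):
        rng = np.random.default_rng(2)
        prof = RateProfile([-500.0, 1080.0, 1080.0, 1860.0],
                           [20.0, 20.0, 2.0, 2.0])
        sm = {t.trial_id: simulate_spike_train(prof, (-500, 1860), rng=rng)
              for ts in context_trials.values() for t in ts}
        assert classify_unit("u", context_trials, sm) == "inhibited"

    def test_insufficient_trials_unclassified(self):
        trials = {c: make_trials(3, c.replace("/", ""))
                  for c in ("D/R", "S/R", "S/P")}
        assert classify_unit("u", trials, {}) == "unclassified"

    def test_null_other_rate_matches_selection_inflation(self, context_trials):
        """Picking the strongest of three groups before testing inflates the
        family-wise rejection to ~1-(1-alpha)^3, not alpha itself."""
        rng = np.random.default_rng(3)
        n_other = 0
        n_sims = 300
        for _ in range(n_sims):
            sm = {t.trial_id: simulate_spike_train(FLAT10, (-500, 1860),
                                                   rng=rng)
                  for ts in context_trials.values() for t in ts}
            if classify_unit("u", context_trials, sm) == "other":
                n_other += 1
        expected = (1 - 0.05) ** 3
        assert n_other / n_sims == pytest.approx(expected, abs=0.05)


class TestZScoresAndSelectivity:
    def test_zscores_hand_arithmetic(self):
        z = scene_zscores({"a": 2.0, "b": 4.0, "c": 6.0}, 2.0)
        assert z == {"a": 0.0, "b": 1.0, "c": 2.0}

    def test_zscores_flat_undefined(self):
        assert scene_zscores({"a": 3.0, "b": 3.0}, 1.0) is None

    def test_selectivity_closed_forms(self):
        assert selectivity_index([5.0] * 6) == pytest.approx(0.0)
        one_hot = [1.0] + [0.0] * 7
        assert selectivity_index(one_hot) == pytest.approx(1 - 1 / 8)
        assert selectivity_index([10.0, 5.0, 5.0, 5.0]) == pytest.approx(0.375)

    def test_selectivity_all_zero_undefined(self):
        assert selectivity_index([0.0, 0.0, 0.0]) is None

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.1, 100.0), min_size=3, max_size=12),
           st.floats(0.1, 10.0))
    def test_si_scale_invariant_and_bounded(self, frs, c):
        si = selectivity_index(frs)
        si_scaled = selectivity_index([c * f for f in frs])
        assert si_scaled == pytest.approx(si, abs=1e-9)
        assert -1e-12 <= si <= 1 - 1 / len(frs) + 1e-12

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.0, 50.0), min_size=3, max_size=10,
                    unique=True), st.floats(0.0, 20.0))
    def test_zscores_have_unit_sample_sd(self, frs, base):
        z = scene_zscores({f"s{i}": f for i, f in enumerate(frs)}, base)
        assert np.std(list(z.values()), ddof=1) == pytest.approx(1.0)


class TestResponseLatency:
    def test_zero_spikes_no_latency(self):
        trials = make_trials(20)
        lat = response_latency("u", trials, {t.trial_id: np.empty(0)
                                             for t in trials})
        assert lat.latency_ms is None

    def test_planted_step_detected_with_bounded_bias(self):
        """5 -> 40 spikes/s step at 150 ms: detected latency lags by at most
        the 35-ms window plus the run criterion."""
        rng = np.random.default_rng(4)
        trials = make_trials(30)
        prof = RateProfile([-500.0, 150.0, 150.0, 1860.0],
                           [5.0, 5.0, 40.0, 40.0])
        lats = []
        for _ in range(30):
            sm = _spike_maps(trials, prof, rng)
            lat = scene_response_latency("u", {"D/R": trials}, sm)
            assert lat.latency_ms is not None
            lats.append(lat.latency_ms)
        assert 150.0 <= np.median(lats) <= 190.0

    def test_latency_never_below_window_a(self):
        rng = np.random.default_rng(5)
        trials = make_trials(20)
        prof = RateProfile([-500.0, 0.0, 0.0, 1860.0],
                           [2.0, 2.0, 60.0, 60.0])
        sm = _spike_maps(trials, prof, rng)
        lat = response_latency("u", trials, sm)
        assert lat.latency_ms is not None and lat.latency_ms >= 35.0

    def test_null_rarely_fires_through_full_procedure(self, context_trials):
        rng = np.random.default_rng(6)
        n_fp = 0
        for _ in range(100):
            sm = {t.trial_id: simulate_spike_train(FLAT10, (-500, 1860),
                                                   rng=rng)
                  for ts in context_trials.values() for t in ts}
            if scene_response_latency("u", context_trials,
                                      sm).latency_ms is not None:
                n_fp += 1
        assert n_fp <= 5

    def test_insufficient_trials(self):
        lat = response_latency("u", make_trials(5), {})
        assert lat.latency_ms is None and lat.reason == "insufficient_trials"


class TestDiscriminationLatency:
    def test_requires_scene_response(self, context_trials):
        res = discrimination_latency("u", context_trials, {},
                                     "dangerous-safe", None)
        assert res.latency_ms is None and res.reason == "no_scene_response"

    def test_planted_context_gain_detected(self):
        """D/R rate x3 from 200 ms: discrimination onset near 200-250 ms."""
        rng = np.random.default_rng(7)
        groups = {c: make_trials(30, c.replace("/", ""))
                  for c in ("D/R", "S/R", "S/P")}
        prof_dr = RateProfile([-500.0, 200.0, 200.0, 1860.0],
                              [10.0, 10.0, 30.0, 30.0])
        lats = []
        for _ in range(20):
            sm = {}
            for c, ts in groups.items():
                prof = prof_dr if c == "D/R" else FLAT10
                for t in ts:
                    sm[t.trial_id] = simulate_spike_train(prof, (-500, 1860),
                                                          rng=rng)
            g = scene_response_latency("u", groups, sm)
            d = discrimination_latency("u", groups, sm, "dangerous-safe",
                                       g.latency_ms)
            if d.latency_ms is not None:
                lats.append(d.latency_ms)
        assert len(lats) >= 18
        assert 200.0 <= np.median(lats) <= 260.0

    def test_missing_context_errors(self, context_trials):
        trials = dict(context_trials)
        trials.pop("S/R")
        with pytest.raises(InsufficientDataError):
            discrimination_latency("u", trials, {}, "rich-poor", 100.0)


class TestDeltaFR:
    def test_identical_groups_all_zero(self, context_trials):
        rng = np.random.default_rng(8)
        sm = {t.trial_id: simulate_spike_train(FLAT10, (-500, 1860), rng=rng)
              for ts in context_trials.values() for t in ts}
        series = delta_fr_series("u", context_trials, sm, "dangerous-safe")
        # significance gate zeroes (almost) everything under the null;
        # if anything survives, normalization pins max |score| to 1
        assert np.mean(series.score != 0) < 0.3

    def test_planted_excess_sign_and_normalization(self, context_trials):
        rng = np.random.default_rng(9)
        prof_dr = RateProfile([-500.0, 200.0, 200.0, 1860.0],
                              [10.0, 10.0, 40.0, 40.0])
        sm = {}
        for c, ts in context_trials.items():
            prof = prof_dr if c == "D/R" else FLAT10
            for t in ts:
                sm[t.trial_id] = simulate_spike_train(prof, (-500, 1860),
                                                      rng=rng)
        series = delta_fr_series("u", context_trials, sm, "dangerous-safe")
        assert np.abs(series.score).max() == pytest.approx(1.0)
        # windows entirely before the 200-ms onset stay zero
        assert np.all(series.score[series.times < 150.0] == 0.0)
        # dangerous > safe: positive sign convention
        assert series.score[series.times > 600.0].min() >= 0.0

    def test_rich_poor_sign_convention(self, context_trials):
        """S/P above S/R gives negative rich-poor scores."""
        rng = np.random.default_rng(10)
        prof_sp = RateProfile([-500.0, 0.0, 0.0, 1860.0],
                              [10.0, 10.0, 40.0, 40.0])
        sm = {}
        for c, ts in context_trials.items():
            prof = prof_sp if c == "S/P" else FLAT10
            for t in ts:
                sm[t.trial_id] = simulate_spike_train(prof, (-500, 1860),
                                                      rng=rng)
        series = delta_fr_series("u", context_trials, sm, "rich-poor")
        assert np.all(series.score <= 0.0)
        assert series.score.min() == -1.0

    def test_sliding_gate_matches_statsmodels_oracle(self, context_trials):
        """The hand-vectorized ANOVA + Tukey gate agrees with
        scipy/statsmodels on a sampled window."""
        from scipy.stats import f_oneway
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        from contextsacc.spikes import (_anova_oneway, _counts_matrix,
                                        _tukey_pair_p)
        rng = np.random.default_rng(11)
        groups = []
        for i, (c, ts) in enumerate(context_trials.items()):
            groups.append(rng.poisson(3.0 + i, len(ts)) * (1000.0 / 300.0))
        p_omni, means, ns, mse, df_w = _anova_oneway(groups)
        assert p_omni == pytest.approx(f_oneway(*groups).pvalue, rel=1e-9)
        data = np.concatenate(groups)
        labels = np.repeat(["a", "b", "c"], [len(g) for g in groups])
        tk = pairwise_tukeyhsd(data, labels, alpha=0.05)
        p_ab = _tukey_pair_p(means, ns, mse, df_w, 0, 1, 3)
        assert p_ab == pytest.approx(tk.pvalues[0], abs=1e-6)

    def test_missing_group_errors(self, context_trials):
        trials = dict(context_trials)
        trials["S/P"] = []
        with pytest.raises(InsufficientDataError):
            delta_fr_series("u", trials, {}, "rich-poor")


class TestPopulation:
    def test_two_unit_average(self):
        z = {"a": {"D/R": 1.0}, "b": {"D/R": -1.0}}
        res = population_average(z)
        assert res["D/R"][0] == pytest.approx(0.0)

    def test_identical_units_population_si_equals_individual(self):
        profile = {"s1": 3.0, "s2": 0.5, "s3": 0.5, "s4": 0.5}
        res = population_si({"a": profile, "b": profile})
        per_unit = list(res["per_unit_si"].values())
        assert res["population_si"] == pytest.approx(per_unit[0])

    def test_disjoint_preferences_flatten_population(self):
        n = 4
        units = {}
        for i in range(n):
            units[f"u{i}"] = {f"s{j}": (3.0 if i == j else 0.0)
                              for j in range(n)}
        res = population_si(units)
        assert res["population_si"] == pytest.approx(0.0, abs=1e-12)
        assert all(si == pytest.approx(1 - 1 / n)
                   for si in res["per_unit_si"].values())

    def test_independent_scene_gains_lower_population_si(self):
        """With per-unit idiosyncratic scene preferences, averaging across
        units flattens the profile: population SI < mean individual SI."""
        rng = np.random.default_rng(12)
        units = {f"u{i}": {f"s{j}": float(rng.lognormal(0.0, 0.8))
                           for j in range(8)} for i in range(12)}
        res = population_si(units)
        mean_individual = np.mean(list(res["per_unit_si"].values()))
        assert res["population_si"] < mean_individual
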