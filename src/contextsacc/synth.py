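"""Synthetic foraging-session generator.

Emulates the statistical structure the analysis stages assume: three scene
contexts (D/R, S/R, S/P) x many scenes; trial timing (scene onset -> 1,080 ms
free viewing -> 780 ms fixation -> object onset -> saccade); LATER-distributed
saccade reaction times with context-dependent rate means and a late-only
object-value effect; excited/inhibited inhomogeneous-Poisson units with
context gains and per-scene gain variability; context-modulated pupil and
cardiac pulse signals; and depth-dependent background-rate variance.

The LATER latency model: on each trial a decision signal rises linearly to a
threshold (normalized to 1) at rate ``r ~ Normal(mu, sigma)`` (units 1/s), so
RT = 1000/r ms and reciprocal latency is Gaussian -- a straight line on a
reciprobit plot.  A configurable "express" component draws its rate without
the object-value penalty, reproducing the observation that object value
separates latency distributions only in the late (> ~100 ms) tail while the
scene context shifts the whole distribution.

All randomness flows from a single seed through ``numpy.random.Generator``
streams; the same seed reproduces a byte-identical session on disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np

from .model import (CONTEXTS, REWARD_POOR, REWARD_RICH, EyeTrace, SceneDef,
                    Session, SpikeTrain, Trial, UnitRecord)

# Canonical task timing (ms).
FV_DURATION = 1080.0
FX_DURATION = 780.0
#: Per-monkey robber race thresholds: RT above a uniform draw in this range
#: loses the reward to the robber.
ROBBER_THRESHOLDS = {"PA": (90.0, 120.0), "PI": (100.0, 180.0),
                     "SO": (95.0, 125.0)}
SACCADE_AMPLITUDE_DEG = 15.0
TARGET_ANGLES = tuple(float(a) for a in range(0, 360, 45))


class ParameterError(ValueError):
    """A generator parameter is outside its valid range."""


@dataclass
class BehaviorParams:
    """LATER parameters per context plus the object-value mixture.

    ``later_mu`` / ``later_sigma``: mean and SD of the threshold-normalized
    rate of rise (1/s).  ``express_fraction``: proportion of context-only
    (object-blind) saccades.  ``object_penalty``: additive decrease of the
    rate of rise for bad objects, applied only to the non-express component.
    """

    later_mu: dict = field(default_factory=lambda: {
        "D/R": 10.5, "S/R": 9.5, "S/P": 8.8})
    later_sigma: float = 1.2
    express_fraction: float = 0.1
    object_penalty: float = 1.0
    rt_floor: float = 0.0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.later_mu.values()):
            raise ParameterError("later_mu must be > 0")
        if not 0.0 <= self.express_fraction <= 1.0:
            raise ParameterError("express_fraction must lie in [0, 1]")


@dataclass
class UnitParams:
    """Rate model of one simulated unit.

    ``context_gain`` multiplies the baseline from the response latency on;
    for inhibited units the gain (< 1) applies during FX only.
    ``scene_gain_sd`` is the lognormal sigma of a per-unit x scene gain drawn
    once (stable across trials, so the selectivity index measures stable
    scene selectivity).  ``ramp_to_object`` (spikes/s per s) tilts the FX
    rate upward toward object onset.
    """

    baseline_rate: float = 10.0
    unit_type: str = "excited"
    response_latency_true: float = 120.0
    context_gain: dict = field(default_factory=lambda: {
        "D/R": 2.5, "S/R": 1.8, "S/P": 1.3})
    scene_gain_sd: float = 0.3
    ramp_to_object: float = 5.0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ParameterError("baseline_rate must be >= 0")
        if self.unit_type not in ("excited", "inhibited"):
            raise ParameterError("unit_type must be excited or inhibited")
        if any(g <= 0 for g in self.context_gain.values()):
            raise ParameterError("context gains must be > 0")


@dataclass
class SuccessModel:
    """Per-context probability that a trial ends rewarded, before the robber
    race; D/R losses to the robber further lower its realized rate."""

    success_rate: dict = field(default_factory=lambda: {
        "D/R": 0.97, "S/R": 0.95, "S/P": 0.95})

    def __post_init__(self) -> None:
        if any(not 0.0 < s <= 1.0 for s in self.success_rate.values()):
            raise ParameterError("success rates must lie in (0, 1]")


@dataclass
class SessionConfig:
    """Full parameter set for :func:`generate_session`."""

    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    success: SuccessModel = field(default_factory=SuccessModel)
    n_per_context: int = 10
    n_trials_per_scene: int = 15
    n_units: int = 20
    excited_fraction: float = 0.75
    monkey_id: str = "PA"
    # Per-scene arousal couples unit gains and the LATER rate so population
    # activity and SacRT co-vary across scenes (negatively for RT).
    arousal_sd: float = 0.2
    arousal_rt_coupling: float = 0.3
    # Excited / inhibited context gains.
    excited_gain: dict = field(default_factory=lambda: {
        "D/R": 2.5, "S/R": 1.8, "S/P": 1.3})
    inhibited_gain: dict = field(default_factory=lambda: {
        "D/R": 0.45, "S/R": 0.55, "S/P": 0.65})
    scene_gain_sd: float = 0.3
    # Physiology: pupil (arbitrary units) and heart rate (bpm) per context.
    pupil_mean: dict = field(default_factory=lambda: {
        "D/R": 3.6, "S/R": 3.3, "S/P": 3.0})
    heart_rate_bpm: dict = field(default_factory=lambda: {
        "D/R": 128.0, "S/R": 120.0, "S/P": 112.0})
    # Anatomy: dorsoventral border in background-FR variance.
    depth_range_mm: tuple = (4.0, 12.0)
    fr_border_mm: float = 8.0
    background_fr_mean: float = 14.0
    background_fr_sd_dorsal: float = 19.0
    background_fr_sd_ventral: float = 10.0
    # Behavioral nuisance rates.
    fixation_break_prob: float = 0.02
    wrong_direction_prob: float = 0.02
    object_context_prob: float = 0.4
    robber_rt_boost: float = 1.0


def make_scene_set(n_per_context: int, seed: int = 0) -> list:
    """Create ``n_per_context`` scenes per context with correct flags.

    D/R scenes carry the robber and the big (0.3 mL) reward; some safe
    scenes carry a lingering distractor; a subset of D/R scenes adds an
    air puff on robber wins.
    """
    if n_per_context < 1:
        raise ParameterError("n_per_context must be >= 1")
    rng = np.random.default_rng(seed)
    scenes = []
    for context in CONTEXTS:
        rich = context != "S/P"
        for i in range(n_per_context):
            dangerous = context == "D/R"
            scenes.append(SceneDef(
                scene_id=f"{context.replace('/', '')}-{i:03d}",
                context=context,
                reward_volume=REWARD_RICH if rich else REWARD_POOR,
                has_robber=dangerous,
                has_distractor=bool(not dangerous and rng.random() < 0.5),
                airpuff_on_fail=bool(dangerous and i % 4 == 0)))
    return scenes


def simulate_later_rt(params: BehaviorParams, context: str,
                      object_value: str, n: int,
                      seed=None, rng: Optional[np.random.Generator] = None,
                      ) -> np.ndarray:
    """Draw ``n`` LATER saccade latencies (ms) for one context/object cell.

    Rate of rise ``r ~ Normal(mu_context - penalty*[bad and non-express],
    sigma)``; non-positive draws are redrawn; RT = 1000/r + rt_floor.
    The express component ignores the object value.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    mu = params.later_mu.get(context)
    if mu is None:
        raise ParameterError(f"no later_mu for context {context!r}")
    if mu <= 0:
        raise ParameterError("later_mu must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    express = rng.random(n) < params.express_fraction
    penalty = params.object_penalty if object_value == "bad" else 0.0
    means = np.where(express, mu, mu - penalty)
    if np.any(means <= 0):
        raise ParameterError("penalty drives the mean rate non-positive")
    r = rng.normal(means, params.later_sigma)
    while np.any(r <= 0):
        bad = r <= 0
        r[bad] = rng.normal(means[bad], params.later_sigma)
    return 1000.0 / r + params.rt_floor


class RateProfile:
    """Piecewise-linear firing-rate profile (ms -> spikes/s)."""

    def __init__(self, breakpoints, rates):
        self.t = np.asarray(breakpoints, dtype=float)
        self.r = np.asarray(rates, dtype=float)
        if np.any(self.r < 0):
            raise ParameterError("rates must be >= 0")
        if not np.all(np.isfinite(self.r)):
            raise ParameterError("rates must be bounded")

    def __call__(self, t) -> np.ndarray:
        return np.interp(t, self.t, self.r)

    @property
    def max_rate(self) -> float:
        return float(self.r.max()) if len(self.r) else 0.0

    def integral(self, a: float, b: float) -> float:
        """Expected spike count in [a, b) (rate in spikes/s, t in ms).

        Segments are integrated from interior evaluations so step
        discontinuities at duplicated breakpoints are handled exactly.
        """
        grid = np.unique(np.concatenate([[a, b],
                                         self.t[(self.t > a) & (self.t < b)]]))
        total = 0.0
        for g0, g1 in zip(grid[:-1], grid[1:]):
            eps = 1e-9 * max(g1 - g0, 1.0)
            total += 0.5 * (self(g0 + eps) + self(g1 - eps)) * (g1 - g0)
        return float(total / 1000.0)


def simulate_spike_train(rate_profile, t_range, seed=None,
                         rng: Optional[np.random.Generator] = None,
                         ) -> np.ndarray:
    """Inhomogeneous Poisson spike times by thinning.

    ``rate_profile`` is a callable ms -> spikes/s with a ``max_rate``
    attribute (or a :class:`RateProfile`); counts in any window are Poisson
    with mean equal to the integrated rate.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    t0, t1 = float(t_range[0]), float(t_range[1])
    rmax = getattr(rate_profile, "max_rate", None)
    if rmax is None:
        rmax = float(np.max(rate_profile(np.linspace(t0, t1, 2001))))
    if not np.isfinite(rmax):
        raise ParameterError("rate profile must be bounded")
    if rmax <= 0:
        return np.empty(0)
    expected = rmax * (t1 - t0) / 1000.0
    n = rng.poisson(expected)
    times = np.sort(rng.uniform(t0, t1, n))
    keep = rng.random(n) < np.asarray(rate_profile(times)) / rmax
    out = times[keep]
    # strictly increasing: drop exact duplicates (measure-zero in theory,
    # possible in floating point)
    if len(out) > 1:
        out = out[np.concatenate([[True], np.diff(out) > 0])]
    return out


def build_rate_profile(unit: UnitParams, scene: SceneDef, events: dict,
                       scene_gain: float = 1.0) -> RateProfile:
    """Rate profile for one unit on one trial of one scene.

    Excited units sit at baseline until their true response latency, then
    step to ``baseline * context_gain * scene_gain`` and ramp linearly over
    the FX period (activity grows toward object onset).  Inhibited units stay
    near baseline through FV and are suppressed during FX only.
    """
    base = unit.baseline_rate
    gain = unit.context_gain[scene.context] * scene_gain
    fix_start = float(events["fix_start"])
    object_onset = float(events["object_onset"])
    lat = float(unit.response_latency_true)
    t_end = float(events.get("outcome_time", object_onset + 600.0))
    fx_s = (object_onset - fix_start) / 1000.0
    if unit.unit_type == "excited":
        level = base * gain
        ramp_end = max(level + unit.ramp_to_object * fx_s, 0.0)
        bp = [-600.0, lat, lat, fix_start, object_onset, t_end]
        rr = [base, base, level, level, ramp_end, ramp_end]
    else:
        suppressed = base * gain
        bp = [-600.0, fix_start, fix_start, object_onset, object_onset, t_end]
        rr = [base, base, suppressed, suppressed, base, base]
    # merge any non-monotone breakpoints from degenerate event timing
    bp = np.maximum.accumulate(np.asarray(bp, dtype=float))
    return RateProfile(bp, rr)


def _minimum_jerk(s: np.ndarray) -> np.ndarray:
    return 10 * s**3 - 15 * s**4 + 6 * s**5


def simulate_eye_trace(trial_events: dict, rt: Optional[float],
                       target_angle: float, trial_id: str,
                       pupil_mean: float = 3.2,
                       seed=None, rng: Optional[np.random.Generator] = None,
                       fixation_sd: float = 0.1,
                       saccade_duration: float = 40.0,
                       blink_prob: float = 0.1) -> tuple:
    """Generate a 1 kHz eye trace; returns ``(EyeTrace, true_onset_ms)``.

    Gaussian fixation jitter (sd ~0.1 deg) holds until ``object_onset + rt``,
    then a 15-deg saccade with a minimum-jerk position profile (peak radial
    velocity > 300 deg/s, duration ~40 ms).  The pupil channel is a context
    mean plus AR(1) noise with occasional blink gaps (NaN).  ``rt=None``
    schedules no saccade.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if rt is not None and rt <= 0:
        raise ParameterError("rt must be > 0")
    object_onset = float(trial_events["object_onset"])
    t_end = float(trial_events.get("outcome_time", object_onset + 600.0))
    from scipy.signal import lfilter

    t0 = -500.0
    n = int(round(t_end - t0)) + 1
    times = t0 + np.arange(n)
    # Fixational jitter is slow drift/tremor, not white noise at 1 kHz: an
    # AR(1) with ~200-ms correlation time and stationary sd `fixation_sd`.
    phi = 0.995
    innov_sd = fixation_sd * np.sqrt(1.0 - phi * phi)

    def _jitter():
        w = rng.normal(0.0, innov_sd, n)
        z0 = rng.normal(0.0, fixation_sd)
        return lfilter([1.0], [1.0, -phi], w, zi=np.array([phi * z0]))[0]

    x = _jitter()
    y = _jitter()
    true_onset = None
    if rt is not None:
        true_onset = object_onset + rt
        s = np.clip((times - true_onset) / saccade_duration, 0.0, 1.0)
        prof = SACCADE_AMPLITUDE_DEG * _minimum_jerk(s)
        ang = math.radians(target_angle)
        x = x + prof * math.cos(ang)
        y = y + prof * math.sin(ang)
    # pupil: slow AR(1) around the context mean
    from scipy.signal import lfilter
    noise = rng.normal(0.0, 0.004, n)
    phi = 0.998
    dev0 = rng.normal(0.0, 0.05)
    dev = lfilter([1.0], [1.0, -phi], noise, zi=np.array([phi * dev0]))[0]
    pupil = pupil_mean + dev
    if rng.random() < blink_prob:
        start = rng.integers(0, max(n - 200, 1))
        pupil[start:start + int(rng.integers(80, 200))] = np.nan
    trace = EyeTrace(trial_id=trial_id, sample_rate=1000.0, t0_ms=t0,
                     x=x, y=y, pupil=pupil)
    return trace, true_onset


def _draw_units(cfg: SessionConfig, rng: np.random.Generator):
    """Unit records + rate-model parameters with a planted dorsoventral
    background-FR variance border."""
    units, params = [], {}
    n_excited = int(round(cfg.n_units * cfg.excited_fraction))
    for i in range(cfg.n_units):
        uid = f"u{i:03d}"
        excited = i < n_excited
        depth = rng.uniform(*cfg.depth_range_mm)
        sd = (cfg.background_fr_sd_dorsal if depth < cfg.fr_border_mm
              else cfg.background_fr_sd_ventral)
        background = max(float(rng.normal(cfg.background_fr_mean, sd)), 0.5)
        baseline = max(float(rng.normal(10.0, 3.0)), 1.0)
        gains = dict(cfg.excited_gain if excited else cfg.inhibited_gain)
        params[uid] = UnitParams(
            baseline_rate=baseline,
            unit_type="excited" if excited else "inhibited",
            response_latency_true=float(np.clip(rng.normal(120.0, 30.0),
                                                60.0, 400.0)),
            context_gain=gains,
            scene_gain_sd=cfg.scene_gain_sd,
            ramp_to_object=5.0 if excited else 0.0)
        units.append(UnitRecord(
            unit_id=uid, monkey_id=cfg.monkey_id,
            coords=(float(rng.uniform(0.0, 4.0)),
                    float(rng.uniform(20.0, 26.0)), float(depth)),
            background_fr=background))
    return units, params


def generate_session(config: Optional[SessionConfig] = None, *,
                     seed: int = 0, n_units: Optional[int] = None,
                     n_trials_per_scene: Optional[int] = None,
                     with_eye_traces: bool = True) -> Session:
    """Generate a full synthetic session; deterministic under ``seed``.

    Trials are randomized over scenes; outcomes follow the success model
    with the robber race deciding D/R losses; every unit gets a spike train
    on every trial; pulse times carry context-modulated heart rate.  Ground
    truth (true unit latencies/gains, per-scene arousal, true saccade onsets)
    is stored in ``session.provenance``.
    """
    cfg = config or SessionConfig()
    if n_units is not None:
        cfg.n_units = n_units
    if n_trials_per_scene is not None:
        cfg.n_trials_per_scene = n_trials_per_scene
    rng = np.random.default_rng(seed)
    scenes = make_scene_set(cfg.n_per_context,
                            seed=rng.integers(0, 2**31 - 1))
    units, unit_params = _draw_units(cfg, rng)

    # Per-scene arousal couples neuronal gain (x a) and LATER rate (x a^k).
    arousal = {s.scene_id: float(rng.lognormal(0.0, cfg.arousal_sd))
               for s in scenes}
    # Per-unit x scene idiosyncratic gain, drawn once (stable selectivity).
    scene_gain = {(u.unit_id, s.scene_id):
                  float(rng.lognormal(0.0, unit_params[u.unit_id].scene_gain_sd))
                  for u in units for s in scenes}

    scene_order = np.repeat([s.scene_id for s in scenes],
                            cfg.n_trials_per_scene)
    rng.shuffle(scene_order)
    scene_by_id = {s.scene_id: s for s in scenes}
    beh = cfg.behavior

    trials, traces, spikes, pulses = [], [], [], []
    truth_trials = {}
    counter = 0
    queue = list(scene_order)
    idx = 0
    while idx < len(queue):
        scene_id = queue[idx]
        idx += 1
        scene = scene_by_id[scene_id]
        ctx = scene.context
        trial_id = f"t{counter:05d}"
        counter += 1
        fix_start = FV_DURATION
        object_onset = fix_start + FX_DURATION
        first_value = "good" if rng.random() < 0.5 else "bad"
        object_context = "absent"
        mu_scale = arousal[scene_id] ** cfg.arousal_rt_coupling
        mu_eff = beh.later_mu[ctx] * mu_scale
        if scene.has_robber and rng.random() < cfg.object_context_prob:
            object_context = "robber_present"
            mu_eff += cfg.robber_rt_boost
        elif scene.has_distractor and rng.random() < cfg.object_context_prob:
            object_context = "distractor_present"
            mu_eff += 0.5 * cfg.robber_rt_boost
        params_eff = BehaviorParams(
            later_mu={ctx: mu_eff}, later_sigma=beh.later_sigma,
            express_fraction=beh.express_fraction,
            object_penalty=beh.object_penalty, rt_floor=beh.rt_floor)
        rt = float(simulate_later_rt(params_eff, ctx, first_value, 1,
                                     rng=rng)[0])

        outcome = "rewarded"
        if rng.random() < cfg.fixation_break_prob:
            outcome = "fixation_break"
        elif rng.random() > cfg.success.success_rate[ctx]:
            outcome = "no_reward"
        elif scene.has_robber:
            lo, hi = ROBBER_THRESHOLDS.get(cfg.monkey_id, (90.0, 120.0))
            if rt > rng.uniform(lo, hi):
                outcome = "robbed"
        wrong = rng.random() < cfg.wrong_direction_prob
        target_angle = float(rng.choice(TARGET_ANGLES))
        saccade_angle = (target_angle + 180.0) % 360.0 if wrong else target_angle

        events = {"scene_onset": 0.0, "fix_start": fix_start,
                  "object_onset": object_onset}
        if outcome != "fixation_break":
            events["saccade_onset"] = object_onset + rt
            events["outcome_time"] = object_onset + rt + 500.0
        else:
            events["outcome_time"] = object_onset + 200.0

        trial = Trial(trial_id=trial_id, scene_id=scene_id,
                      monkey_id=cfg.monkey_id, events=events,
                      first_object_value=first_value,
                      object_context=object_context, outcome=outcome,
                      is_repeat=False, target_angle_deg=target_angle)
        trials.append(trial)
        truth_trials[trial_id] = {
            "rt_ms": rt if outcome != "fixation_break" else None,
            "saccade_onset_ms": events.get("saccade_onset"),
            "wrong_direction": wrong,
        }

        if with_eye_traces:
            trace, true_onset = simulate_eye_trace(
                events, None if outcome == "fixation_break" else rt,
                saccade_angle, trial_id, pupil_mean=cfg.pupil_mean[ctx],
                rng=rng)
            traces.append(trace)
            truth_trials[trial_id]["true_saccade_onset_ms"] = true_onset

        for u in units:
            prof = build_rate_profile(
                unit_params[u.unit_id], scene, events,
                scene_gain=scene_gain[(u.unit_id, scene_id)] * arousal[scene_id]
                if unit_params[u.unit_id].unit_type == "excited" else 1.0)
            st = simulate_spike_train(prof, (-500.0, events["outcome_time"]),
                                      rng=rng)
            spikes.append(SpikeTrain(unit_id=u.unit_id, trial_id=trial_id,
                                     spike_times=st))

        bpm = cfg.heart_rate_bpm[ctx] + rng.normal(0.0, 2.0)
        ipi = 60000.0 / bpm
        pulse = [-500.0 + rng.uniform(0.0, ipi)]
        while pulse[-1] < events["outcome_time"]:
            pulse.append(pulse[-1] + ipi * (1.0 + rng.normal(0.0, 0.03)))
        pulses.append((trial_id, np.asarray(pulse)))

        # Failed robber races repeat the same scene once (marked, excluded
        # from analysis by the exclusion rules).
        if outcome == "robbed":
            repeat_id = f"t{counter:05d}"
            counter += 1
            rt2 = float(simulate_later_rt(params_eff, ctx, first_value, 1,
                                          rng=rng)[0])
            ev2 = {"scene_onset": 0.0, "fix_start": fix_start,
                   "object_onset": object_onset,
                   "saccade_onset": object_onset + rt2,
                   "outcome_time": object_onset + rt2 + 500.0}
            trials.append(Trial(
                trial_id=repeat_id, scene_id=scene_id,
                monkey_id=cfg.monkey_id, events=ev2,
                first_object_value=first_value, object_context=object_context,
                outcome="rewarded", is_repeat=True,
                target_angle_deg=target_angle))
            truth_trials[repeat_id] = {"rt_ms": rt2,
                                       "saccade_onset_ms": ev2["saccade_onset"],
                                       "wrong_direction": False}
            if with_eye_traces:
                trace, true_onset = simulate_eye_trace(
                    ev2, rt2, target_angle, repeat_id,
                    pupil_mean=cfg.pupil_mean[ctx], rng=rng)
                traces.append(trace)
                truth_trials[repeat_id]["true_saccade_onset_ms"] = true_onset
            for u in units:
                prof = build_rate_profile(
                    unit_params[u.unit_id], scene, ev2,
                    scene_gain=scene_gain[(u.unit_id, scene_id)]
                    * arousal[scene_id]
                    if unit_params[u.unit_id].unit_type == "excited" else 1.0)
                st = simulate_spike_train(prof, (-500.0, ev2["outcome_time"]),
                                          rng=rng)
                spikes.append(SpikeTrain(unit_id=u.unit_id,
                                         trial_id=repeat_id, spike_times=st))
            pulses.append((repeat_id, pulses[-1][1].copy()))

    provenance = {
        "generator": "contextsacc.synth.generate_session",
        "seed": int(seed),
        "config": _config_dict(cfg),
        "ground_truth": {
            "unit_params": {uid: asdict(p) for uid, p in unit_params.items()},
            "scene_arousal": arousal,
            "trials": truth_trials,
        },
    }
    session = Session(scenes=scenes, trials=trials, eye_traces=traces,
                      spike_trains=spikes, units=units,
                      pulse_times=dict(pulses), provenance=provenance)
    session.validate()
    return session


def _config_dict(cfg: SessionConfig) -> dict:
    d = asdict(cfg)
    d["depth_range_mm"] = list(cfg.depth_range_mm)
    return d
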