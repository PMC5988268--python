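"""Saccade detection, reaction-time extraction, and latency-distribution
analysis.

Saccades are detected where the radial eye velocity (norm of the smoothed
2-D derivative) exceeds 300 deg/s; the onset is the time the velocity last
rose above 30 deg/s before the peak.  SacRT is the interval from object
onset (= fixation-point offset) to the onset of the first saccade toward
the object; repeat trials, failures and wrong-direction saccades are
excluded.

Latency distributions are summarized with the LATER model: reciprocal
latency is Gaussian, so the empirical CDF plotted on a probit axis against
-1/RT (a reciprobit plot) is a straight line.  A change in the mean rate of
rise translates the line parallel to itself; a change in its SD swivels it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import EyeTrace, Trial

PEAK_VELOCITY_THRESHOLD = 300.0   # deg/s, saccade detection
ONSET_VELOCITY_THRESHOLD = 30.0   # deg/s, onset definition
DIRECTION_TOLERANCE_DEG = 45.0    # wrong-direction exclusion window


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class SaccadeEvent:
    onset_ms: float
    peak_velocity: float
    peak_time_ms: float
    amplitude: float
    direction: float  # deg, of the displacement vector


@dataclass(frozen=True)
class Excluded:
    """SacRT exclusion with its reason."""
    reason: str  # repeat | failure | wrong_direction | none_found


@dataclass(frozen=True)
class ReciprobitFit:
    mu_recip: float      # mean reciprocal latency, 1/s
    sigma_recip: float   # SD of reciprocal latency, 1/s
    r_squared: float     # of the probit-vs-(-1/RT) line
    n: int

    @property
    def median_latency_ms(self) -> float:
        return 1000.0 / self.mu_recip


def radial_velocity(trace: EyeTrace) -> np.ndarray:
    """Radial (polar) eye speed in deg/s, same length as the trace.

    Central-difference derivative of x and y, then the Euclidean norm,
    smoothed with a 5-sample moving average (raw 1 kHz differentiation is
    noise-dominated).
    """
    if len(trace.x) < 3:
        raise InsufficientDataError("need at least 3 samples")
    dt = 1.0 / trace.sample_rate  # s per sample
    vx = np.gradient(trace.x, dt)
    vy = np.gradient(trace.y, dt)
    v = np.hypot(vx, vy)
    kernel = np.ones(5) / 5.0
    return np.convolve(v, kernel, mode="same")


def detect_saccades(trace: EyeTrace,
                    velocity: Optional[np.ndarray] = None) -> list:
    """Detect saccades as suprathreshold (> 300 deg/s) velocity excursions.

    Each contiguous excursion yields one event.  Onset: walk back from the
    peak to the first sample at or below 30 deg/s; onset is the next sample.
    """
    v = radial_velocity(trace) if velocity is None else velocity
    times = trace.times
    above = v > PEAK_VELOCITY_THRESHOLD
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(edges[np.diff(above.astype(int))[edges] == 1] + 1)
    ends = list(edges[np.diff(above.astype(int))[edges] == -1] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(v))
    events = []
    for s, e in zip(starts, ends):
        peak_idx = s + int(np.argmax(v[s:e]))
        i = peak_idx
        while i > 0 and v[i - 1] > ONSET_VELOCITY_THRESHOLD:
            i -= 1
        onset_idx = i
        # end of saccade: forward to first sample <= onset threshold
        j = peak_idx
        while j < len(v) - 1 and v[j + 1] > ONSET_VELOCITY_THRESHOLD:
            j += 1
        dx = trace.x[j] - trace.x[onset_idx]
        dy = trace.y[j] - trace.y[onset_idx]
        events.append(SaccadeEvent(
            onset_ms=float(times[onset_idx]),
            peak_velocity=float(v[peak_idx]),
            peak_time_ms=float(times[peak_idx]),
            amplitude=float(np.hypot(dx, dy)),
            direction=float(np.degrees(np.arctan2(dy, dx)) % 360.0)))
    return events


def _angle_diff(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def first_saccade_rt(trial: Trial, saccades: Sequence[SaccadeEvent]):
    """SacRT (ms) of the first saccade after object onset toward the target,
    or :class:`Excluded` with a reason.

    Exclusions follow the task's rules: repeat trials (same scene replayed
    after a failure), failure trials (fixation breaks and robber wins), and
    saccades more than +/-45 deg off the target direction.
    """
    if trial.is_repeat:
        return Excluded("repeat")
    if trial.outcome in ("fixation_break", "robbed"):
        return Excluded("failure")
    onset = trial.object_onset
    for sac in saccades:
        if sac.onset_ms <= onset:
            continue
        if _angle_diff(sac.direction,
                       trial.target_angle_deg) > DIRECTION_TOLERANCE_DEG:
            return Excluded("wrong_direction")
        return float(sac.onset_ms - onset)
    return Excluded("none_found")


def choice_probability(trials: Sequence[Trial]) -> Optional[float]:
    """N_good / (N_good + N_bad) over completed choices.

    Rewarded and robbed trials chose the good object; no-reward trials chose
    the bad one; fixation breaks never completed a choice and are excluded.
    Returns None (undefined) on an empty denominator.
    """
    n_good = sum(t.outcome in ("rewarded", "robbed") for t in trials)
    n_bad = sum(t.outcome == "no_reward" for t in trials)
    if n_good + n_bad == 0:
        return None
    return n_good / (n_good + n_bad)


def success_rate(trials: Sequence[Trial]) -> Optional[float]:
    """Proportion of rewarded trials among completed ones; robbed trials
    count against success.  None when no eligible trial exists."""
    counts = {"rewarded": 0, "robbed": 0, "no_reward": 0}
    for t in trials:
        if t.outcome in counts:
            counts[t.outcome] += 1
    total = sum(counts.values())
    if total == 0:
        return None
    return counts["rewarded"] / total


def reciprobit_points(latencies) -> tuple:
    """(-1/RT, probit(ECDF)) coordinate pairs for a reciprobit plot.

    RT in ms, x-axis in -1/s (so more negative = slower); ECDF evaluated at
    plotting positions (i - 0.5)/n to keep the probit finite.
    """
    rt = np.sort(np.asarray(latencies, dtype=float))
    if np.any(rt <= 0):
        raise ValueError("latencies must be > 0")
    n = len(rt)
    p = (np.arange(1, n + 1) - 0.5) / n
    return -1000.0 / rt, stats.norm.ppf(p)


def fit_reciprobit(latencies) -> ReciprobitFit:
    """Fit the LATER (Gaussian reciprocal-latency) model.

    The location/scale are Gaussian maximum-likelihood estimates on the
    reciprocal latencies (seed-free and well defined); the straight-line R^2
    of probit(ECDF) against -1/RT is reported as the linearity diagnostic.
    """
    rt = np.asarray(latencies, dtype=float)
    if np.any(rt <= 0):
        raise ValueError("latencies must be > 0")
    if len(rt) < 20:
        raise InsufficientDataError("need at least 20 latencies")
    recip = 1000.0 / rt  # 1/s
    mu = float(np.mean(recip))
    sigma = float(np.std(recip))  # MLE (ddof=0)
    if sigma == 0:
        raise ValueError("degenerate sample: all latencies identical")
    x, y = reciprobit_points(rt)
    r = np.corrcoef(x, y)[0, 1]
    return ReciprobitFit(mu_recip=mu, sigma_recip=sigma,
                         r_squared=float(r**2), n=len(rt))


def reciprobit_slope(fit: ReciprobitFit) -> float:
    """Slope of the reciprobit line in probit units per (1/s).

    probit(P(RT <= t)) = (mu - 1000/t)/sigma, linear in -1000/t with slope
    1/sigma; parallel lines (equal sigma) indicate a pure rate-mean shift.
    """
    return 1.0 / fit.sigma_recip


def sacrt_anova(df: pd.DataFrame, rt_col: str = "rt",
                scene_col: str = "context",
                object_col: str = "object_value") -> dict:
    """Two-way ANOVA of SacRT on scene group x object value, with
    Tukey-Kramer pairwise contrasts among the three scene groups.

    ``df`` holds one analyzed (non-excluded) saccade per row.  Returns a dict
    with the ANOVA table, the Tukey results, and per-cell means.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    data = df[[rt_col, scene_col, object_col]].dropna()
    cells = data.groupby([scene_col, object_col], observed=True)[rt_col].count()
    if (cells < 2).any():
        bad = cells[cells < 2].index.tolist()
        raise InsufficientDataError(f"cell(s) with < 2 observations: {bad}")
    if data[scene_col].nunique() < 2 or data[object_col].nunique() < 2:
        raise InsufficientDataError("need >= 2 levels per factor")
    d = data.rename(columns={rt_col: "rt", scene_col: "scene",
                             object_col: "obj"})
    model = ols("rt ~ C(scene) * C(obj)", data=d).fit()
    table = sm.stats.anova_lm(model, typ=2)
    tukey = pairwise_tukeyhsd(d["rt"], d["scene"], alpha=0.05)
    tukey_df = pd.DataFrame(tukey.summary().data[1:],
                            columns=tukey.summary().data[0])
    means = d.groupby(["scene", "obj"], observed=True)["rt"].mean()
    return {
        "anova": table,
        "p_scene": float(table.loc["C(scene)", "PR(>F)"]),
        "p_object": float(table.loc["C(obj)", "PR(>F)"]),
        "p_interaction": float(table.loc["C(scene):C(obj)", "PR(>F)"]),
        "tukey": tukey_df,
        "cell_means": means,
    }


def extract_sacrt_table(session, use_ground_truth: bool = False
                        ) -> pd.DataFrame:
    """Run saccade detection + RT extraction over a whole session.

    Returns one row per trial with columns trial_id, scene_id, context,
    object_value, object_context, rt (NaN when excluded) and exclusion
    reason.  With ``use_ground_truth`` the generator's stored saccade onsets
    are used instead of trace detection (fast path for statistical tests
    that do not probe the detector itself).
    """
    traces = {tr.trial_id: tr for tr in session.eye_traces}
    truth = (session.provenance.get("ground_truth", {}).get("trials", {})
             if use_ground_truth else {})
    rows = []
    for t in session.trials:
        ctx = session.context_of_trial(t)
        if use_ground_truth:
            info = truth.get(t.trial_id, {})
            if t.is_repeat:
                res = Excluded("repeat")
            elif t.outcome in ("fixation_break", "robbed"):
                res = Excluded("failure")
            elif info.get("wrong_direction"):
                res = Excluded("wrong_direction")
            elif info.get("rt_ms") is None:
                res = Excluded("none_found")
            else:
                res = float(info["rt_ms"])
        else:
            trace = traces.get(t.trial_id)
            sacs = detect_saccades(trace) if trace is not None else []
            res = first_saccade_rt(t, sacs)
        rows.append({
            "trial_id": t.trial_id, "scene_id": t.scene_id, "context": ctx,
            "object_value": t.first_object_value,
            "object_context": t.object_context, "outcome": t.outcome,
            "rt": res if isinstance(res, float) else np.nan,
            "exclusion": res.reason if isinstance(res, Excluded) else "",
        })
    return pd.DataFrame(rows)
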