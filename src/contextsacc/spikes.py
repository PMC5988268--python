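"""Spike-train characterization.

Spike density functions (Gaussian kernel, sigma = 10 ms), half-open window
rates, excited/inhibited unit classification, per-scene z-scores, a scene
selectivity index, response and context-discrimination latencies with a
run-length significance criterion, significance-gated normalized firing-rate
difference (dFR) time courses, and population averages.

Latency detection scans 1-ms steps: at step ``t`` the mean rate in period A
``[t-35, t)`` is compared with period B ``[t-235, t-35)`` by a paired t-test
across trials (alpha = 0.05, two-sided).  The latency is the first step of a
30-step run whose first step is significant and at least 26 of the following
29 are.  If nothing is found before object onset, the scan repeats with B
fixed to the pre-scene baseline ``[-200, 0)``.  Windows are attributed to
their end time, so reported latencies inherit up to the 35-ms window length
as lag; this is documented, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .model import Session, Trial, trial_windows

ALPHA = 0.05
RUN_LENGTH = 30       # consecutive 1-ms steps considered
RUN_REQUIRED = 27     # the first step plus at least 26 of the following 29
PERIOD_A_MS = 35.0
PERIOD_B_MS = 200.0
DISCRIM_WINDOW_MS = 30.0

DIMENSIONS = {"dangerous-safe": ("D/R", "S/R"),
              "rich-poor": ("S/R", "S/P")}


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class LatencyResult:
    unit_id: str
    kind: str                    # "general" or "discrimination"
    latency_ms: Optional[float]
    dimension: Optional[str] = None
    reason: Optional[str] = None


@dataclass(frozen=True)
class DeltaFRSeries:
    unit_id: str
    dimension: str
    times: np.ndarray   # window centers, ms
    score: np.ndarray   # normalized signed difference in [-1, 1]


def spike_density(spike_times, grid, sigma: float = 10.0) -> np.ndarray:
    """Spike density function in spikes/s on ``grid`` (ms).

    Each spike is replaced by a Gaussian of width ``sigma`` ms, scaled so
    the SDF integrates (over an unbounded grid) to the spike count.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    grid = np.asarray(grid, dtype=float)
    t = np.asarray(spike_times, dtype=float)
    if len(t) == 0:
        return np.zeros_like(grid)
    z = (grid[:, None] - t[None, :]) / sigma
    return 1000.0 * np.exp(-0.5 * z * z).sum(axis=1) / (
        sigma * np.sqrt(2.0 * np.pi))


def window_rate(spike_times, window) -> float:
    """Firing rate (spikes/s) in the half-open window ``[a, b)``."""
    a, b = float(window[0]), float(window[1])
    if b <= a:
        raise ValueError("window length must be > 0")
    t = np.asarray(spike_times, dtype=float)
    count = int(np.count_nonzero((t >= a) & (t < b)))
    return count * 1000.0 / (b - a)


def _rates_by_trial(spike_map: dict, trials: Sequence[Trial], window_of):
    """Per-trial rates for a window function trial -> (a, b)."""
    out = []
    for t in trials:
        st = spike_map.get(t.trial_id)
        out.append(window_rate(st, window_of(t)) if st is not None else 0.0)
    return np.asarray(out)


def spike_map_for_unit(session: Session, unit_id: str) -> dict:
    return {st.trial_id: st.spike_times for st in session.spike_trains
            if st.unit_id == unit_id}


def classify_unit(unit_id: str, trials_by_context: dict,
                  spike_map: dict, min_trials: int = 5) -> str:
    """Classify a unit as excited / inhibited / other.

    The strongest context is the one maximizing |mean FX rate - mean
    baseline rate|; a two-sided Wilcoxon rank-sum test of per-trial FX vs
    baseline rates in that context decides significance (p < 0.05), and the
    sign of the difference sets the class.  Returns "unclassified" when any
    context has fewer than ``min_trials`` analyzable trials.
    """
    per_context = {}
    for ctx, trials in trials_by_context.items():
        if len(trials) < min_trials:
            return "unclassified"
        fx = _rates_by_trial(spike_map, trials,
                             lambda t: trial_windows(t).fx)
        base = _rates_by_trial(spike_map, trials,
                               lambda t: trial_windows(t).baseline)
        per_context[ctx] = (fx, base)
    strongest = max(per_context,
                    key=lambda c: abs(per_context[c][0].mean()
                                      - per_context[c][1].mean()))
    fx, base = per_context[strongest]
    if np.all(fx == base):
        return "other"
    stat, p = stats.ranksums(fx, base)
    if p >= ALPHA:
        return "other"
    return "excited" if fx.mean() > base.mean() else "inhibited"


def scene_zscores(per_scene_fr: dict, baseline_fr: float):
    """Normalized z-scores (FR_i - FR_b) / SD per scene.

    SD is the sample standard deviation (n-1 denominator) of the per-scene
    mean firing rates.  Returns None when SD = 0 (undefined, flagged).
    """
    ids = list(per_scene_fr)
    if len(ids) < 2:
        raise InsufficientDataError("need >= 2 scenes")
    fr = np.asarray([per_scene_fr[k] for k in ids], dtype=float)
    sd = fr.std(ddof=1)
    if sd == 0:
        return None
    return {k: float((v - baseline_fr) / sd)
            for k, v in zip(ids, fr)}


def selectivity_index(per_scene_fr) -> Optional[float]:
    """SI = 1 - FRall / (FRm * NS) over the scenes of one context.

    0 for uniform responses, approaching 1 - 1/NS for a single-scene
    responder.  Returns None for all-zero responses (undefined).
    """
    fr = np.asarray(list(per_scene_fr.values())
                    if isinstance(per_scene_fr, dict) else per_scene_fr,
                    dtype=float)
    if len(fr) < 2:
        raise InsufficientDataError("need >= 2 scenes")
    if np.any(fr < 0):
        raise ValueError("firing rates must be >= 0")
    frm = fr.max()
    if frm == 0:
        return None
    return float(1.0 - fr.sum() / (frm * len(fr)))


def _counts_matrix(spike_map: dict, trials, starts, ends):
    """counts[i, j] = spikes of trial i in [starts[j], ends[j])."""
    starts = np.asarray(starts, dtype=float)
    ends = np.asarray(ends, dtype=float)
    counts = np.empty((len(trials), len(starts)))
    for i, t in enumerate(trials):
        st = spike_map.get(t.trial_id)
        if st is None or len(st) == 0:
            counts[i] = 0.0
            continue
        counts[i] = (np.searchsorted(st, ends, side="left")
                     - np.searchsorted(st, starts, side="left"))
    return counts


def _paired_t_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided paired t-test p-values per column."""
    d = a - b
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    p = np.ones(d.shape[1])
    ok = sd > 0
    tval = np.zeros(d.shape[1])
    tval[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(tval[ok]), n - 1)
    return p


def _two_sample_t_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided pooled-variance t-test p-values per column."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = np.ones(a.shape[1])
    ok = se > 0
    tval = np.zeros(a.shape[1])
    tval[ok] = (ma[ok] - mb[ok]) / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(tval[ok]), na + nb - 2)
    return p


def _first_run(sig: np.ndarray,
               direction: Optional[np.ndarray] = None) -> Optional[int]:
    """Index of the first step opening a qualifying significance run.

    ``direction``, when given, is a boolean mask marking steps whose mean
    difference has the expected response sign; only sign-consistent
    significant steps count toward the run.  Without it, chance deficits
    and excesses both qualify and the false-alarm rate of the scan rises
    steeply (the run criterion alone does not control it, because
    overlapping windows make neighboring steps strongly dependent).
    """
    eff = sig if direction is None else (sig & direction)
    n = len(eff)
    if n < RUN_LENGTH:
        return None
    window = np.convolve(eff.astype(int), np.ones(RUN_LENGTH, dtype=int),
                         mode="valid")
    cand = np.flatnonzero(eff[:n - RUN_LENGTH + 1]
                          & (window >= RUN_REQUIRED))
    return int(cand[0]) if len(cand) else None


def _direction_mask(diff: np.ndarray, direction: str) -> Optional[np.ndarray]:
    if direction == "increase":
        return diff > 0
    if direction == "decrease":
        return diff < 0
    if direction == "any":
        return None
    raise ValueError(f"direction must be increase/decrease/any, "
                     f"got {direction!r}")


def response_latency(unit_id: str, trials: Sequence[Trial],
                     spike_map: dict, min_trials: int = 10,
                     paired: bool = True,
                     direction: str = "increase") -> LatencyResult:
    """Latency of the scene response for one unit.

    Scans 1-ms steps after scene onset comparing period A ``[t-35, t)``
    against the moving period B ``[t-235, t-35)`` with a paired (default) or
    two-sample t-test across trials, applying the 30-step run criterion.
    Falls back to B fixed at the pre-scene baseline ``[-200, 0)`` if nothing
    is found before object onset; reports no latency otherwise.

    ``direction`` gives the expected sign of the response (``increase`` for
    excited units -- the default, since the procedure is defined for them --
    ``decrease`` for inhibited, ``any`` to accept either): only steps whose
    A-B difference has that sign count toward the run, so chance deficits
    do not masquerade as response onsets.  See
    :func:`scene_response_latency` for the full procedure including the
    responsiveness prerequisite.
    """
    if len(trials) < min_trials:
        return LatencyResult(unit_id, "general", None,
                             reason="insufficient_trials")
    t_stop = float(min(t.object_onset for t in trials))
    # moving-B scan: A must fit after scene onset, so t starts at 35 ms
    steps = np.arange(PERIOD_A_MS, t_stop, 1.0)
    if len(steps) >= RUN_LENGTH:
        a = _counts_matrix(spike_map, trials, steps - PERIOD_A_MS, steps)
        b = _counts_matrix(spike_map, trials,
                           steps - PERIOD_A_MS - PERIOD_B_MS,
                           steps - PERIOD_A_MS)
        rate_a = a * (1000.0 / PERIOD_A_MS)
        rate_b = b * (1000.0 / PERIOD_B_MS)
        p = (_paired_t_p(rate_a, rate_b) if paired
             else _two_sample_t_p(rate_a, rate_b))
        diff = rate_a.mean(axis=0) - rate_b.mean(axis=0)
        idx = _first_run(p < ALPHA, _direction_mask(diff, direction))
        if idx is not None:
            return LatencyResult(unit_id, "general", float(steps[idx]))
    # fallback: B fixed to the 200-ms pre-scene window, scan from 1 ms on
    steps = np.arange(1.0, t_stop, 1.0)
    if len(steps) < RUN_LENGTH:
        return LatencyResult(unit_id, "general", None, reason="not_detected")
    a_start = np.maximum(steps - PERIOD_A_MS, 0.0)
    a = _counts_matrix(spike_map, trials, a_start, steps)
    rate_a = a * 1000.0 / np.maximum(steps - a_start, 1.0)
    b = _counts_matrix(spike_map, trials,
                       np.full_like(steps, -PERIOD_B_MS),
                       np.zeros_like(steps))
    rate_b = b * (1000.0 / PERIOD_B_MS)
    p = (_paired_t_p(rate_a, rate_b) if paired
         else _two_sample_t_p(rate_a, rate_b))
    diff = rate_a.mean(axis=0) - rate_b.mean(axis=0)
    idx = _first_run(p < ALPHA, _direction_mask(diff, direction))
    if idx is None:
        return LatencyResult(unit_id, "general", None, reason="not_detected")
    return LatencyResult(unit_id, "general", float(steps[idx]))


def scene_response_latency(unit_id: str, trials_by_context: dict,
                           spike_map: dict, min_trials: int = 10,
                           allow_inhibited: bool = False) -> LatencyResult:
    """Scene-response latency with the responsiveness prerequisite.

    The latency scan is only meaningful for units that respond to scenes:
    the unit is first classified (excited / inhibited / other) and the scan
    runs in the class's response direction.  By default only excited units
    get a latency (the procedure is defined for them); non-responsive units
    return no latency with reason ``not_responsive``.  This prerequisite is
    what controls the procedure's false-detection rate on non-responsive
    units -- the scan alone, over ~1,800 strongly overlapping windows,
    cannot.
    """
    cls = classify_unit(unit_id, trials_by_context, spike_map,
                        min_trials=min(5, min_trials))
    all_trials = [t for ts in trials_by_context.values() for t in ts]
    if cls == "excited":
        return response_latency(unit_id, all_trials, spike_map,
                                min_trials=min_trials, direction="increase")
    if cls == "inhibited" and allow_inhibited:
        return response_latency(unit_id, all_trials, spike_map,
                                min_trials=min_trials, direction="decrease")
    return LatencyResult(unit_id, "general", None, reason="not_responsive")


def discrimination_latency(unit_id: str, trials_by_context: dict,
                           spike_map: dict, dimension: str,
                           general_latency_ms: Optional[float],
                           min_trials: int = 10) -> LatencyResult:
    """Latency at which the two contexts of ``dimension`` separate.

    At each 1-ms step after the general response latency the per-trial mean
    rates in the preceding 30 ms are compared between contexts with a
    two-sample t-test; the same 30-step run criterion applies.  The scan
    ends at object onset.
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}")
    if general_latency_ms is None:
        return LatencyResult(unit_id, "discrimination", None,
                             dimension=dimension, reason="no_scene_response")
    c1, c2 = DIMENSIONS[dimension]
    for c in (c1, c2):
        if c not in trials_by_context or len(trials_by_context[c]) == 0:
            raise InsufficientDataError(
                f"dimension {dimension}: no trials for context {c}")
    t1, t2 = trials_by_context[c1], trials_by_context[c2]
    if len(t1) < min_trials or len(t2) < min_trials:
        return LatencyResult(unit_id, "discrimination", None,
                             dimension=dimension,
                             reason="insufficient_trials")
    t_stop = float(min(t.object_onset for t in (*t1, *t2)))
    t_start = max(float(general_latency_ms), DISCRIM_WINDOW_MS)
    steps = np.arange(t_start, t_stop, 1.0)
    if len(steps) < RUN_LENGTH:
        return LatencyResult(unit_id, "discrimination", None,
                             dimension=dimension, reason="not_detected")
    r1 = _counts_matrix(spike_map, t1, steps - DISCRIM_WINDOW_MS,
                        steps) * (1000.0 / DISCRIM_WINDOW_MS)
    r2 = _counts_matrix(spike_map, t2, steps - DISCRIM_WINDOW_MS,
                        steps) * (1000.0 / DISCRIM_WINDOW_MS)
    p = _two_sample_t_p(r1, r2)
    sig = p < ALPHA
    # a discrimination onset has a direction: the run's significant steps
    # must agree in sign; either direction qualifies, earliest onset wins
    diff = r1.mean(axis=0) - r2.mean(axis=0)
    cands = [i for i in (_first_run(sig, diff > 0), _first_run(sig, diff < 0))
             if i is not None]
    idx = min(cands) if cands else None
    if idx is None:
        return LatencyResult(unit_id, "discrimination", None,
                             dimension=dimension, reason="not_detected")
    return LatencyResult(unit_id, "discrimination", float(steps[idx]),
                         dimension=dimension)


def _tukey_pair_p(means, ns, mse, df_w, i, j, k):
    """Tukey-Kramer p for the (i, j) pairwise contrast among k groups."""
    se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
    if se == 0:
        return 1.0
    q = abs(means[i] - means[j]) / se
    return float(stats.studentized_range.sf(q, k, df_w))


def _anova_oneway(groups):
    """One-way ANOVA returning (p_omnibus, means, ns, mse, df_within)."""
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ss_b = float(np.sum(ns * (means - grand) ** 2))
    ss_w = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_b, df_w = k - 1, int(ns.sum()) - k
    if df_w <= 0 or ss_w == 0:
        return 1.0, means, ns, 0.0, df_w
    ms_b, ms_w = ss_b / df_b, ss_w / df_w
    f = ms_b / ms_w
    p = float(stats.f.sf(f, df_b, df_w))
    return p, means, ns, ms_w, df_w


def delta_fr_series(unit_id: str, trials_by_context: dict, spike_map: dict,
                    dimension: str, window_ms: float = 300.0,
                    step_ms: float = 10.0, min_trials: int = 5
                    ) -> DeltaFRSeries:
    """Significance-gated, max-normalized firing-rate difference time course.

    A 300-ms window slides in 10-ms steps over [0, object onset).  The score
    is the mean-rate difference of the dimension's context pair when both
    the three-group one-way ANOVA omnibus and the pair's Tukey-Kramer post
    hoc are significant (p < 0.05), else 0.  Scores are finally divided by
    max|score| over the free-viewing + fixation periods (all zeros when no
    window is significant).  Positive = dangerous > safe, or rich > poor.
    """
    for ctx in ("D/R", "S/R", "S/P"):
        if ctx not in trials_by_context or \
                len(trials_by_context[ctx]) < min_trials:
            raise InsufficientDataError(
                f"context {ctx}: need >= {min_trials} trials")
    c1, c2 = DIMENSIONS[dimension]
    contexts = ("D/R", "S/R", "S/P")
    all_trials = [t for ctx in contexts for t in trials_by_context[ctx]]
    t_stop = float(min(t.object_onset for t in all_trials))
    starts = np.arange(0.0, t_stop - window_ms + 1e-9, step_ms)
    ends = starts + window_ms
    rates = {ctx: _counts_matrix(spike_map, trials_by_context[ctx],
                                 starts, ends) * (1000.0 / window_ms)
             for ctx in contexts}
    k = len(contexts)
    i1, i2 = contexts.index(c1), contexts.index(c2)
    scores = np.zeros(len(starts))
    for w in range(len(starts)):
        groups = [rates[ctx][:, w] for ctx in contexts]
        p_omni, means, ns, mse, df_w = _anova_oneway(groups)
        if p_omni >= ALPHA or df_w <= 0:
            continue
        p_pair = _tukey_pair_p(means, ns, mse, df_w, i1, i2, k)
        if p_pair < ALPHA:
            scores[w] = means[i1] - means[i2]
    max_abs = np.abs(scores).max()
    if max_abs > 0:
        scores = scores / max_abs
    return DeltaFRSeries(unit_id=unit_id, dimension=dimension,
                         times=starts + window_ms / 2.0, score=scores)


def population_average(per_unit_z: dict) -> dict:
    """Unweighted population mean +/- SE of per-unit z per context.

    ``per_unit_z`` maps unit_id -> {context: z}.  Returns
    {context: (mean, se)}; SE over units.
    """
    if len(per_unit_z) < 2:
        raise InsufficientDataError("need >= 2 units")
    contexts = sorted({c for z in per_unit_z.values() for c in z})
    out = {}
    for c in contexts:
        vals = np.asarray([z[c] for z in per_unit_z.values() if c in z])
        if len(vals) == 0:
            raise InsufficientDataError(f"no units for context {c}")
        se = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        out[c] = (float(vals.mean()), float(se))
    return out


def population_si(per_unit_scene_z: dict) -> dict:
    """Scene selectivity of the population activity within one context.

    Per-scene z-scores are averaged across units; the population profile is
    shifted to be nonnegative (subtracting its minimum when negative) and
    the selectivity index applied.  Also returns the per-unit SI
    distribution computed from each unit's shifted z profile, for the
    individual-vs-population comparison.
    """
    units = list(per_unit_scene_z)
    if len(units) < 2:
        raise InsufficientDataError("need >= 2 units")
    scene_ids = sorted(per_unit_scene_z[units[0]])
    if len(scene_ids) < 2:
        raise InsufficientDataError("need >= 2 scenes")
    mat = np.asarray([[per_unit_scene_z[u][s] for s in scene_ids]
                      for u in units], dtype=float)
    pop = mat.mean(axis=0)

    def _si_of(profile):
        prof = profile - profile.min() if profile.min() < 0 else profile
        return selectivity_index(prof)

    return {
        "population_si": _si_of(pop),
        "per_unit_si": {u: _si_of(mat[i]) for i, u in enumerate(units)},
    }


def trials_by_context(session: Session, include_repeats: bool = False,
                      include_failures: bool = True) -> dict:
    """Group analyzable trials by scene context."""
    out = {c: [] for c in ("D/R", "S/R", "S/P")}
    for t in session.trials:
        if t.is_repeat and not include_repeats:
            continue
        if t.outcome == "fixation_break" and not include_failures:
            continue
        out[session.context_of_trial(t)].append(t)
    return out


def unit_scene_rates(session: Session, unit_id: str, window: str = "fx",
                     include_repeats: bool = False) -> dict:
    """Mean firing rate per scene for one unit in one window (fv/fx/baseline).

    Returns {scene_id: mean spikes/s} over analyzable trials.
    """
    spike_map = spike_map_for_unit(session, unit_id)
    per_scene = {}
    for t in session.trials:
        if t.is_repeat and not include_repeats:
            continue
        w = getattr(trial_windows(t), window)
        if w[1] <= w[0]:
            continue
        st = spike_map.get(t.trial_id)
        if st is None:
            continue
        per_scene.setdefault(t.scene_id, []).append(window_rate(st, w))
    return {s: float(np.mean(v)) for s, v in per_scene.items()}
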