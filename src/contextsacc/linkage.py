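"""Value-prediction linkage: predicted reward value, predicted activity,
neuron-behavior correlation, pupil/heart trial metrics, and object-context
contrasts.

The predicted reward value of a context is ``PV = R * S * 10`` (R: reward
volume in mL, S: success rate).  Because the robber sometimes steals the
reward, the dangerous context has a lower PV than the safe-rich context at
the same reward volume; any measure (activity z, SacRT, pupil, heart rate)
can then be compared against the value ``PN`` predicted for the dangerous
PV by linear interpolation between the poor and rich anchor points:

    PN = FRp + (FRr - FRp) * (PVd - PVp) / (PVr - PVp)

An actual dangerous-context value above (or SacRT below) its PN indicates a
danger effect over and above reward value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class ValuePoint:
    context: str
    pv: float
    mean_activity_z: Optional[float] = None
    mean_sacrt_ms: Optional[float] = None
    pupil_z: Optional[float] = None
    heart_rate_bpm: Optional[float] = None


def predicted_value(reward_ml: float, success: float) -> float:
    """PV = R * S * 10 (dimensionless predicted reward value)."""
    if not 0.0 <= success <= 1.0:
        raise ValueError("success rate must lie in [0, 1]")
    return reward_ml * success * 10.0


def predicted_activity(fr_poor: float, fr_rich: float,
                       pv_dangerous: float, pv_rich: float,
                       pv_poor: float) -> float:
    """PN: linear interpolation of a measure at the dangerous PV between the
    (PV_poor, value_poor) and (PV_rich, value_rich) anchor points.

    Applies identically to firing-rate z, SacRT, pupil z, and heart rate.
    """
    if pv_rich == pv_poor:
        raise ValueError("pv_rich must differ from pv_poor")
    return fr_poor + (fr_rich - fr_poor) * (pv_dangerous - pv_poor) / (
        pv_rich - pv_poor)


def actual_vs_predicted(actual: Sequence[float],
                        predicted: Sequence[float]) -> dict:
    """One-sample two-sided t-test on (actual - predicted) differences.

    Used per unit (or per trial for behavior/physiology) to ask whether the
    dangerous context deviates from its reward-value prediction.  A
    zero-variance difference is flagged degenerate (p = 1 by convention).
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if len(a) != len(p):
        raise ValueError("actual and predicted must pair up")
    if len(a) < 3:
        raise InsufficientDataError("need >= 3 paired values")
    d = a - p
    if np.allclose(d.std(ddof=1), 0.0):
        return {"t": 0.0, "p": 1.0, "mean_diff": float(d.mean()),
                "n": len(d), "degenerate": True}
    t, pval = stats.ttest_1samp(d, 0.0)
    return {"t": float(t), "p": float(pval), "mean_diff": float(d.mean()),
            "n": len(d), "degenerate": False}


def neuron_behavior_correlation(per_scene_activity: dict,
                                per_scene_sacrt: dict) -> dict:
    """Pearson correlation across scenes between population activity (z)
    and mean SacRT; based on excited-type units.

    Returns r, two-sided p and n; raises on constant input (undefined).
    """
    scenes = sorted(set(per_scene_activity) & set(per_scene_sacrt))
    if len(scenes) < 4:
        raise InsufficientDataError("need >= 4 scenes present in both")
    x = np.asarray([per_scene_activity[s] for s in scenes])
    y = np.asarray([per_scene_sacrt[s] for s in scenes])
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": len(scenes)}


def pupil_trial_mean(trace, object_onset: float,
                     window_ms: float = 500.0,
                     robust_sd_limit: float = 4.0) -> Optional[float]:
    """Mean pupil diameter in the 500 ms before object onset (FX period).

    Missing (NaN) samples and samples more than ``robust_sd_limit`` robust
    SDs (1.4826 * MAD) from the trial median are removed as eyelid-closure /
    tracking-loss outliers.  Returns None (trial excluded) when fewer than
    50% of the window's samples are valid.
    """
    times = trace.times
    mask = (times >= object_onset - window_ms) & (times < object_onset)
    seg = np.asarray(trace.pupil)[mask]
    if len(seg) == 0:
        return None
    valid = seg[~np.isnan(seg)]
    if len(valid) < 0.5 * len(seg):
        return None
    med = np.median(valid)
    mad = np.median(np.abs(valid - med))
    if mad > 0:
        robust_sd = 1.4826 * mad
        valid = valid[np.abs(valid - med) <= robust_sd_limit * robust_sd]
    if len(valid) == 0:
        return None
    return float(valid.mean())


def zscore_across_trials(values: Sequence[Optional[float]]) -> np.ndarray:
    """Session-level z-scoring across trials; None/NaN entries stay NaN."""
    arr = np.asarray([np.nan if v is None else v for v in values],
                     dtype=float)
    ok = ~np.isnan(arr)
    m, s = arr[ok].mean(), arr[ok].std(ddof=1)
    out = np.full_like(arr, np.nan)
    if s > 0:
        out[ok] = (arr[ok] - m) / s
    return out


def heart_rate_trial(pulse_times, object_onset: float,
                     n_intervals: int = 1) -> Optional[float]:
    """Heart rate (bpm) from the most recent interpulse interval(s) ending
    before object onset; ``n_intervals`` > 1 averages the last few.

    Returns None (trial excluded) with fewer than 2 usable pulses.
    """
    t = np.asarray(pulse_times, dtype=float)
    t = t[t <= object_onset]
    if len(t) < 2:
        return None
    ipis = np.diff(t)[-n_intervals:]
    return float(60000.0 / ipis.mean())


def object_context_table(df: pd.DataFrame, value_col: str = "rt",
                         group_col: str = "context",
                         presence_col: str = "present",
                         outcome_col: str = "outcome") -> dict:
    """Object-context contrasts: split a measure by robber/distractor
    presence within each scene group.

    ``df`` has one analyzed trial per row with the scene group, a boolean
    presence flag, the measure, and the outcome.  Returns per-group means by
    presence, a two-way ANOVA (group x presence) with Tukey-Kramer post hoc
    on the presence factor, and per-group chi-squared tests of success rate
    by presence.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    data = df[[value_col, group_col, presence_col, outcome_col]].dropna(
        subset=[value_col])
    counts = data.groupby([group_col, presence_col],
                          observed=True)[value_col].count()
    table = counts.unstack(presence_col)
    if (table.shape[1] < 2 or table.isna().any().any()
            or (table < 2).any().any()):
        raise InsufficientDataError(
            "each scene group needs both presence states with >= 2 trials")
    d = data.rename(columns={value_col: "y", group_col: "grp",
                             presence_col: "pres"})
    d["pres"] = d["pres"].astype(bool)
    model = ols("y ~ C(grp) * C(pres)", data=d).fit()
    table = sm.stats.anova_lm(model, typ=2)
    means = d.groupby(["grp", "pres"], observed=True)["y"].mean()

    chi2 = {}
    for grp, sub in data.groupby(group_col, observed=True):
        tab = pd.crosstab(sub[presence_col],
                          sub[outcome_col].eq("rewarded"))
        if tab.shape == (2, 2):
            stat, p, _, _ = stats.chi2_contingency(tab, correction=False)
            chi2[grp] = {"chi2": float(stat), "p": float(p)}
        else:
            chi2[grp] = {"chi2": np.nan, "p": np.nan}
    return {
        "means": means,
        "anova": table,
        "p_group": float(table.loc["C(grp)", "PR(>F)"]),
        "p_presence": float(table.loc["C(pres)", "PR(>F)"]),
        "p_interaction": float(table.loc["C(grp):C(pres)", "PR(>F)"]),
        "success_chi2": chi2,
    }


def value_table(contexts: dict) -> pd.DataFrame:
    """Assemble the per-context summary (PV, activity z, SacRT, pupil, HR).

    ``contexts`` maps context -> dict with keys reward_ml, success and any
    of mean_activity_z, mean_sacrt_ms, pupil_z, heart_rate_bpm.
    """
    rows = []
    for ctx, d in contexts.items():
        rows.append({
            "context": ctx,
            "pv": predicted_value(d["reward_ml"], d["success"]),
            "mean_activity_z": d.get("mean_activity_z"),
            "mean_sacrt_ms": d.get("mean_sacrt_ms"),
            "pupil_z": d.get("pupil_z"),
            "heart_rate_bpm": d.get("heart_rate_bpm"),
        })
    return pd.DataFrame(rows).set_index("context")
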