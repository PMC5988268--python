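"""End-to-end session analysis: runs the behavior, spikes, linkage and
anatomy stages over one session and assembles the summary tables.

This is the programmatic equivalent of running the full analysis of a
recording day: extract SacRTs, classify units, z-score their context
responses, average the excited population, build the value table (PV vs
activity/SacRT/pupil/heart rate), correlate population activity with SacRT
across scenes, and locate the dorsoventral background-rate border.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import anatomy, behavior, linkage, spikes
from .model import REWARD_POOR, REWARD_RICH, Session, trial_windows


def analyze_behavior(session: Session,
                     use_ground_truth: bool = False) -> dict:
    """SacRT table, per-context stats, reciprobit fits, two-way ANOVA."""
    table = behavior.extract_sacrt_table(session,
                                         use_ground_truth=use_ground_truth)
    analyzed = table[table["exclusion"] == ""]
    by_context = {}
    for ctx, sub in analyzed.groupby("context", observed=True):
        entry = {"n": len(sub), "mean_rt": float(sub["rt"].mean()),
                 "median_rt": float(sub["rt"].median())}
        if len(sub) >= 20:
            entry["reciprobit"] = behavior.fit_reciprobit(sub["rt"].to_numpy())
        by_context[ctx] = entry
    anova = None
    try:
        anova = behavior.sacrt_anova(analyzed)
    except behavior.InsufficientDataError:
        pass
    non_repeat = [t for t in session.trials if not t.is_repeat]
    ctx_trials = {}
    for t in non_repeat:
        ctx_trials.setdefault(session.context_of_trial(t), []).append(t)
    success = {c: behavior.success_rate(ts) for c, ts in ctx_trials.items()}
    return {"table": table, "by_context": by_context, "anova": anova,
            "success_rate": success,
            "choice_probability": behavior.choice_probability(non_repeat)}


def analyze_units(session: Session) -> pd.DataFrame:
    """Classify every unit and compute z-scores, SI and latencies.

    Returns one row per unit: class, FV/FX context z, per-context SI, and
    general + discrimination latencies (for excited units).
    """
    by_ctx = spikes.trials_by_context(session, include_failures=False)
    scene_ctx = {s.scene_id: s.context for s in session.scenes}
    rows = []
    for u in session.units:
        spike_map = spikes.spike_map_for_unit(session, u.unit_id)
        cls = spikes.classify_unit(u.unit_id, by_ctx, spike_map)
        row = {"unit_id": u.unit_id, "unit_class": cls,
               "background_fr": u.background_fr, "depth_mm": u.depth}
        for window in ("fv", "fx"):
            per_scene = spikes.unit_scene_rates(session, u.unit_id, window)
            base = np.mean([spikes.window_rate(st, trial_windows(
                session.trial(tid)).baseline)
                for tid, st in spike_map.items()
                if not session.trial(tid).is_repeat]) if spike_map else 0.0
            z = spikes.scene_zscores(per_scene, float(base)) \
                if len(per_scene) >= 2 else None
            for ctx in ("D/R", "S/R", "S/P"):
                scene_frs = {s: r for s, r in per_scene.items()
                             if scene_ctx[s] == ctx}
                row[f"z_{window}_{ctx}"] = (
                    float(np.mean([z[s] for s in scene_frs]))
                    if z and scene_frs else np.nan)
                si = (spikes.selectivity_index(scene_frs)
                      if len(scene_frs) >= 2 else None)
                row[f"si_{window}_{ctx}"] = np.nan if si is None else si
        lat = spikes.scene_response_latency(u.unit_id, by_ctx, spike_map,
                                            allow_inhibited=True)
        row["latency_ms"] = lat.latency_ms
        for dim in spikes.DIMENSIONS:
            try:
                d = spikes.discrimination_latency(
                    u.unit_id, by_ctx, spike_map, dim, lat.latency_ms)
                row[f"discrim_{dim}"] = d.latency_ms
            except spikes.InsufficientDataError:
                row[f"discrim_{dim}"] = None
        rows.append(row)
    return pd.DataFrame(rows).set_index("unit_id")


def analyze_session(session: Session,
                    use_ground_truth_rt: bool = False) -> dict:
    """Full pipeline over one session; returns the assembled results."""
    beh = analyze_behavior(session, use_ground_truth=use_ground_truth_rt)
    units_df = analyze_units(session)

    excited = units_df[units_df["unit_class"] == "excited"]
    per_unit_z = {uid: {c: r[f"z_fx_{c}"] for c in ("D/R", "S/R", "S/P")
                        if np.isfinite(r[f"z_fx_{c}"])}
                  for uid, r in excited.iterrows()}
    pop = (spikes.population_average(per_unit_z)
           if len(per_unit_z) >= 2 else None)

    # per-scene population z (excited units, FX) vs per-scene mean SacRT
    scene_z = {}
    for uid in excited.index:
        per_scene = spikes.unit_scene_rates(session, uid, "fx")
        spike_map = spikes.spike_map_for_unit(session, uid)
        base = np.mean([spikes.window_rate(st, trial_windows(
            session.trial(tid)).baseline) for tid, st in spike_map.items()])
        z = spikes.scene_zscores(per_scene, float(base))
        if z:
            for s, v in z.items():
                scene_z.setdefault(s, []).append(v)
    per_scene_z = {s: float(np.mean(v)) for s, v in scene_z.items()}
    analyzed = beh["table"][beh["table"]["exclusion"] == ""]
    per_scene_rt = {s: float(g["rt"].mean())
                    for s, g in analyzed.groupby("scene_id", observed=True)}
    corr = None
    if len(set(per_scene_z) & set(per_scene_rt)) >= 4:
        try:
            corr = linkage.neuron_behavior_correlation(per_scene_z,
                                                       per_scene_rt)
        except (linkage.InsufficientDataError, ValueError):
            pass

    physio = physiology_by_context(session)

    ctx_info = {}
    for ctx in ("D/R", "S/R", "S/P"):
        reward = REWARD_RICH if ctx != "S/P" else REWARD_POOR
        success = beh["success_rate"].get(ctx)
        sub = analyzed[analyzed["context"] == ctx]
        ctx_info[ctx] = {
            "reward_ml": reward, "success": success if success else 0.0,
            "mean_activity_z": pop[ctx][0] if pop and ctx in pop else None,
            "mean_sacrt_ms": float(sub["rt"].mean()) if len(sub) else None,
            "pupil_z": physio["pupil_z"].get(ctx),
            "heart_rate_bpm": physio["heart_rate_bpm"].get(ctx),
        }
    vtab = linkage.value_table(ctx_info)

    # danger effect over reward value: actual D/R vs PN interpolation
    pv = vtab["pv"]
    danger = {}
    if {"D/R", "S/R", "S/P"} <= set(vtab.index):
        for col in ("mean_activity_z", "mean_sacrt_ms", "pupil_z",
                    "heart_rate_bpm"):
            vals = vtab[col]
            if vals.isna().any():
                continue
            pn = linkage.predicted_activity(
                vals["S/P"], vals["S/R"], pv["D/R"], pv["S/R"], pv["S/P"])
            danger[col] = {"actual": float(vals["D/R"]),
                           "predicted": float(pn),
                           "excess": float(vals["D/R"] - pn)}

    border = None
    try:
        border = anatomy.dorsoventral_border(session.units)
    except anatomy.InsufficientDataError:
        pass

    return {"behavior": beh, "units": units_df, "population": pop,
            "per_scene_z": per_scene_z, "per_scene_rt": per_scene_rt,
            "correlation": corr, "value_table": vtab,
            "danger_effect": danger, "border": border}


def physiology_by_context(session: Session) -> dict:
    """Per-context mean pupil z and heart rate over analyzable trials."""
    traces = {tr.trial_id: tr for tr in session.eye_traces}
    ids, pupil_raw, hr, ctxs = [], [], [], []
    for t in session.trials:
        if t.is_repeat or t.outcome == "fixation_break":
            continue
        ctx = session.context_of_trial(t)
        tr = traces.get(t.trial_id)
        p = (linkage.pupil_trial_mean(tr, t.object_onset)
             if tr is not None else None)
        h = (linkage.heart_rate_trial(session.pulse_times.get(t.trial_id, []),
                                      t.object_onset))
        ids.append(t.trial_id)
        pupil_raw.append(p)
        hr.append(h)
        ctxs.append(ctx)
    pupil_z = linkage.zscore_across_trials(pupil_raw)
    df = pd.DataFrame({"context": ctxs, "pupil_z": pupil_z,
                       "hr": [np.nan if h is None else h for h in hr]})
    by = df.groupby("context", observed=True)
    return {"pupil_z": {c: float(v) for c, v in
                        by["pupil_z"].mean().dropna().items()},
            "heart_rate_bpm": {c: float(v) for c, v in
                               by["hr"].mean().dropna().items()},
            "trial_table": df.assign(trial_id=ids)}
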