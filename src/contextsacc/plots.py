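"""Plotting helpers: reciprobit latency plots and population SDF panels."""

from __future__ import annotations

import numpy as np

from . import behavior, spikes


def reciprobit_plot(latencies_by_group: dict, ax=None, colors=None):
    """Cumulative SacRT distributions on a probit axis vs reciprocal time.

    Straight lines indicate Gaussian reciprocal latency (LATER); parallel
    horizontal shifts indicate a change in the mean rate of rise.
    """
    import matplotlib.pyplot as plt
    from scipy import stats

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for i, (label, lat) in enumerate(latencies_by_group.items()):
        x, y = behavior.reciprobit_points(lat)
        color = None if colors is None else colors.get(label)
        ax.plot(x, y, ".", ms=2, label=f"{label} (n={len(lat)})",
                color=color)
        fit = behavior.fit_reciprobit(lat)
        xs = np.linspace(x.min(), x.max(), 50)
        # probit(P) = (mu + x)/sigma with x = -1000/RT in 1/s
        ax.plot(xs, (fit.mu_recip + xs) / fit.sigma_recip, "-", lw=1,
                color=color, alpha=0.6)
    probs = np.array([0.01, 0.1, 0.5, 0.9, 0.99])
    ax.set_yticks(stats.norm.ppf(probs))
    ax.set_yticklabels([f"{p:g}" for p in probs])
    rts = np.array([80, 100, 150, 300])
    ax.set_xticks(-1000.0 / rts)
    ax.set_xticklabels([str(r) for r in rts])
    ax.set_xlabel("SacRT (ms, reciprocal axis)")
    ax.set_ylabel("cumulative probability (probit)")
    ax.legend(fontsize=8)
    return ax


def population_sdf_plot(session, unit_ids, grid=None, ax=None):
    """Mean spike density function per context across the given units."""
    import matplotlib.pyplot as plt

    if grid is None:
        grid = np.arange(-500.0, 1860.0, 5.0)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    ctx_of = {s.scene_id: s.context for s in session.scenes}
    trials = {t.trial_id: t for t in session.trials if not t.is_repeat}
    for ctx, color in (("D/R", "k"), ("S/R", "r"), ("S/P", "b")):
        sdfs = []
        for uid in unit_ids:
            sm = spikes.spike_map_for_unit(session, uid)
            per_trial = [spikes.spike_density(st, grid)
                         for tid, st in sm.items()
                         if tid in trials and ctx_of[trials[tid].scene_id] == ctx]
            if per_trial:
                sdfs.append(np.mean(per_trial, axis=0))
        if sdfs:
            ax.plot(grid, np.mean(sdfs, axis=0), color=color, label=ctx)
    ax.axvspan(0, 1080, color="0.9", zorder=0)
    ax.axvspan(1080, 1860, color="0.8", zorder=0)
    ax.set_xlabel("time from scene onset (ms)")
    ax.set_ylabel("firing rate (spikes/s)")
    ax.legend()
    return ax
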