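# contextsacc

Analysis pipeline for context-dependent saccade behavior and spike-train
data from a visual-scene foraging task, with a synthetic-session generator
that stands in for the recordings.

## The scientific problem

In the foraging task a large visual scene (the "environment") appears
suddenly, the subject views it freely for ~1,080 ms (FV period), fixates a
central point for ~780 ms (FX period), and then makes a saccade to a
peripheral object to earn a reward. Scenes fall into three context groups:

* **D/R** — dangerous (a "robber" object may race the saccade and steal the
  reward) and rich (0.3 mL reward),
* **S/R** — safe and rich,
* **S/P** — safe and poor (0.1 mL).

The analyses this package implements ask how the context, established
*before* the target appears, modulates (i) saccade reaction time (SacRT),
(ii) pre-target neuronal firing, (iii) pupil diameter and heart rate, and
how tightly neuronal activity and behavior are coupled across scenes.

The core quantitative tools, in the field's standard notation:

* **LATER / reciprobit analysis.** A decision signal rises to threshold at
  rate *r* ~ N(μ, σ²) per trial, so RT = 1/*r* and the cumulative RT
  distribution is a straight line on a probit axis against −1/RT. A context
  that changes μ translates the line parallel to itself. `fit_reciprobit`
  estimates (μ, σ) by Gaussian ML on reciprocal latencies and reports the
  line's R².
* **Saccade detection.** Radial eye velocity > 300 deg/s marks a saccade;
  onset is the preceding crossing of 30 deg/s. SacRT = onset − object onset,
  with repeat / failure / wrong-direction exclusions.
* **Spike-train characterization.** SDF with a σ = 10 ms Gaussian kernel;
  excited/inhibited classification (FX vs baseline rank-sum, strongest
  context); response latency by a sliding 35-ms test window against a
  moving 200-ms reference (paired *t*, α = 0.05, a 30-step run criterion
  with ≥ 27 significant steps); context-discrimination latency with 30-ms
  windows; selectivity index SI = 1 − FR_all/(FR_max · N_S); significance-
  gated, max-normalized ΔFR time courses; population averages of per-scene
  z-scores (FR_i − FR_b)/SD.
* **Value linkage.** Predicted reward value PV = R · S · 10 (reward volume ×
  success rate); predicted activity PN interpolates the measure at the
  dangerous PV between the safe-poor and safe-rich anchors; one-sample *t*
  on actual − PN gives the danger effect beyond value; Pearson correlation
  couples per-scene population activity with per-scene mean SacRT.
* **Recording-site statistics.** A dorsoventral border in background-rate
  variance located by the minimum two-sample F-test p over a 0.2-mm depth
  grid, separating central-nucleus-like (dorsal, variable) from
  basolateral/lateral-like (ventral) units.

The synthetic generator (`contextsacc.synth`) plants all of these
structures — context-ordered LATER rates with an express (context-only)
mixture component and a late-only object-value penalty, excited/inhibited
inhomogeneous-Poisson units with context and per-scene gains, a robber race
with the task's per-monkey thresholds, pupil/heart context modulation, and
a depth-dependent background-rate variance border — so every stage can be
tested by parameter recovery.

## Worked example

```python
from contextsacc import generate_session
from contextsacc import pipeline

session = generate_session(seed=42)      # 30 scenes, 20 units, 450 trials
res = pipeline.analyze_session(session)
print(res["value_table"].round(3))
corr = res["correlation"]
print(f"r = {corr['r']:.3f} (p = {corr['p']:.2e}, {corr['n']} scenes)")
```

prints

```
            pv  mean_activity_z  mean_sacrt_ms  pupil_z  heart_rate_bpm
context
D/R      2.062            2.038         92.701    1.208         128.039
S/R      2.960            1.131        114.701    0.017         120.068
S/P      0.966            0.581        126.890   -1.193         112.636
r = -0.914 (p = 1.71e-12, 30 scenes)
```

Reading the table: the dangerous context has a *lower* predicted reward
value than safe-rich (PV 2.06 vs 2.96 — the robber steals ~30% of its
rewards) yet the *highest* population activity (z = 2.04), the *fastest*
saccades (92.7 ms), the largest pupil and the highest heart rate. Across
the 30 individual scenes, population FX activity and mean SacRT are
strongly negatively correlated: scenes that drive more pre-target activity
get faster saccades. Those are exactly the planted relationships, recovered
end-to-end from simulated spike trains and eye traces.

The `examples/` directory has one short script per capability (simulation
and serialization, reciprobit analysis, unit characterization, value
linkage, recording-site statistics). A thin CLI wraps the same functions:

```
contextsacc simulate --seed 7 --out scratch/session
contextsacc validate scratch/session
contextsacc analyze all scratch/session --out scratch/tables
```

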