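# Methods

This note documents the models and procedures the package implements, the
defaults and why, what the synthetic generator does and does not emulate,
and the numerical/design choices made where the procedure left room.

## Task model and windows

All times are milliseconds relative to scene onset; windows are half-open
[a, b) so boundary spikes count once. The canonical trial is: baseline
[−500, 0), free viewing FV [0, 1080), fixation FX [1080, 1860), object
onset at 1860 ms, saccade, outcome. FV/FX bounds are stored per trial (the
schema permits behaviorally varying fixation acquisition); the generator
uses the canonical values.

Contexts: D/R (dangerous + rich, 0.3 mL, robber present), S/R (safe +
rich), S/P (safe + poor, 0.1 mL). The dangerous+poor cell does not exist.
The two context dimensions are assessed by the pairs D/R vs S/R
(dangerous–safe) and S/R vs S/P (rich–poor).

## Behavior

**Saccade detection.** Velocity is the Euclidean norm of the
central-difference derivative of (x, y), smoothed with a 5-sample moving
average — raw 1 kHz differentiation is noise-dominated, and "polar
component" is read as this radial speed. Detection threshold 300 deg/s;
onset = the sample after the last sub-30 deg/s sample before the peak. On
noiseless minimum-jerk saccades the detected onset lags the true movement
start by ~2 ms (the profile needs ~2 ms to reach 30 deg/s).

**SacRT.** Time from object onset (= fixation-point offset) to the onset of
the first saccade toward the object. Exclusions: repeat trials (a scene
replayed after a robber win), failures (fixation breaks and robbed trials),
and saccades more than ±45° off the target direction (the tolerance is this
package's choice; no angular window is prescribed). Only the first saccade
per trial enters the context analyses; object-context (robber/distractor
presence) contrasts use the per-trial presence labels.

**LATER / reciprobit.** Location and scale of the reciprocal-latency
Gaussian are maximum-likelihood estimates (mean and ML SD of 1000/RT,
in 1/s) — well-defined and seed-free; the straight-line R² of
probit(ECDF at (i−½)/n) against −1000/RT is reported as the linearity
diagnostic rather than being used for fitting. Degenerate samples (zero
variance) and n < 20 raise errors.

**Two-way ANOVA.** SacRT ~ scene group × object value via OLS with a
type-II table (statsmodels), Tukey–Kramer contrasts among the three scene
groups. Cells with fewer than two observations are rejected by name.

## Spike-train analysis

**SDF.** Each spike becomes a Gaussian (σ = 10 ms) scaled to spikes/s; the
single-spike peak is 1000/(σ√2π) ≈ 39.894 spikes/s and the SDF integrates
to the spike count.

**Classification.** For the context with the largest |mean FX − mean
baseline| rate difference, per-trial FX rates are compared with per-trial
baseline rates by a two-sided Wilcoxon rank-sum at α = 0.05; the sign sets
excited/inhibited, non-significance gives "other". Because the strongest of
three contexts is selected before testing, the family-wise null rejection
is ≈ 1 − (1 − α)³ ≈ 14%, not α — an inherent property of the
select-then-test procedure, verified by simulation in the test suite.

**Response latency.** At each 1-ms step t, period A = [t−35, t) is compared
with the moving period B = [t−235, t−35) by a paired t-test across trials
(paired controls trial-to-trial rate variability; an unpaired variant is
available). The latency is the first step of a 30-step run whose first step
is significant and at least 26 of the following 29 are. If nothing is found
before object onset the scan repeats with B fixed to the pre-scene
[−200, 0) baseline (the moving B tracks slow ramps; the fixed B catches
them). Windows are attributed to their end time, so latencies inherit up to
the 35-ms window length as lag — documented, not corrected. Under the
moving-B scan the earliest reportable latency is 35 ms; the fallback can
report from 1 ms.

Two elements control the scan's false alarms, and both are part of the
procedure's logic rather than add-ons. First, runs are *sign-gated*: a
response onset for an excited unit is a rate increase, so only significant
steps with A > B count (decrease for inhibited units). Without the gate,
chance spike "deserts" — 35-ms stretches with few spikes across trials —
produce strongly significant deficits, and because the 1-ms-step windows
overlap by 34/35 samples, any chance excursion persists through the run
criterion: the bare two-sided scan false-fires on most homogeneous-Poisson
simulations. Second, the latency is only computed for units that pass the
responsiveness classification (`scene_response_latency`); on
non-responsive units the full procedure reports a latency in ~2% of null
simulations (10 spikes/s, 20 trials), while a planted 5→40 spikes/s step at
150 ms is localized with median ≈ 158 ms.

**Discrimination latency.** From the scene-response latency onward, 30-ms
windows are compared between the dimension's two contexts by a two-sample
pooled t-test with the same run criterion; the run must be sign-consistent
and either direction qualifies (earliest wins). The scene-response
prerequisite again controls the null rate: with identical context rates the
procedure reported no latency in 200/200 null simulations. Conditional on a
real scene response, chance context runs within the scan are more frequent
(the same overlap autocorrelation); the per-window test itself is
calibrated at α.

**ΔFR time course.** A 300-ms window slides in 10-ms steps over
[0, object onset). The score is the mean-rate difference of the dimension's
pair (D/R − S/R, or S/R − S/P; positive = dangerous > safe / rich > poor)
when both the three-group one-way ANOVA omnibus and the pair's
Tukey–Kramer post hoc are significant at 0.05, else 0; scores are finally
divided by max|score| over the scan (all-zero if nothing is significant).
The ANOVA/Tukey gate is computed closed-form (studentized-range p) for
speed and is cross-checked against scipy/statsmodels in the tests.
Normalization uses the max of |difference| (signed-max is not prescribed).

**z-scores, SI, population.** Per-scene z = (FR_i − FR_b)/SD with SD the
sample (n−1) SD of per-scene mean rates, so the z profile has unit sample
SD by construction. SI = 1 − FR_all/(FR_max · N_S) ranges from 0 (uniform)
to 1 − 1/N_S (single-scene responder) and is scale-invariant. Population
averages are unweighted means of per-unit z (excited units) with SE across
units. Population SI averages per-scene z across units and, if the profile
dips below zero, shifts it by its minimum before applying SI; per-unit SIs
from the same shifted-z construction are returned for the
individual-vs-population comparison (averaging units with idiosyncratic
scene preferences flattens the population profile, lowering its SI).

## Value linkage and physiology

PV = R · S · 10 with R the reward volume (mL) and S the realized success
rate (rewarded / (rewarded + robbed + no-reward); robbed counts against).
PN interpolates any per-context measure at the dangerous PV between the
(PV_SP, value_SP) and (PV_SR, value_SR) anchors; it is exact at the anchors
and affine in PV. The danger effect is a one-sample two-sided t-test on
actual − PN (zero-variance differences are flagged degenerate). The
neuron–behavior coupling is the Pearson correlation across scenes between
per-scene mean population FX z (excited units) and per-scene mean SacRT.

Pupil: mean over the 500 ms before object onset after removing NaN
(blink/tracking-loss) samples and samples > 4 robust SDs (1.4826·MAD) from
the trial median — the outlier rule is this package's choice; trials with
< 50% valid samples are excluded; means are z-scored across trials per
session. Heart rate: 60000 / (most recent inter-pulse interval ending
before object onset); an option averages the last k intervals.

## Recording-site statistics

The dorsoventral border is the candidate depth (0.2-mm grid, ≥ 5 units per
side — the guard is this package's addition) minimizing the two-sided
two-sample F-test p for background-rate variance dorsal vs ventral; ties go
to the shallowest candidate and the search is order-invariant and
deterministic. The reported p is the minimum over candidates and is *not*
corrected for that selection (matching the procedure; the caveat is
reported). The estimator's localization is limited by the flatness of the p
landscape: at variance ratio (19/10)² with 150 units spread over 8 mm,
moving the candidate 0.4 mm exchanges only ~7 units, changing the log
variance ratio by much less than its sampling noise, so the recovered
border scatters with ≈ 0.45 mm SD around the true depth (~70–80% of runs
land within ±0.4 mm). Region assignment: depth ≤ border → dorsal
(CE-like), else ventral (BL/L-like). The same F-test compares selectivity
variance across the border.

## Synthetic generator

Defaults (the study conditions the tests assume): 10 scenes per context,
15 trials per scene, 20 units (75% excited), monkey "PA".

* **SacRT.** LATER rates μ = 10.5 / 9.5 / 8.8 s⁻¹ for D/R / S/R / S/P
  (medians ≈ 95/105/114 ms — post-learning SacRTs sit near 100 ms),
  σ = 1.2 s⁻¹, threshold normalized to 1 so RT = 1000/r ms. A 10% express
  component draws its rate without the object penalty, so the bad-object
  penalty (1 s⁻¹) separates the distributions only in the late tail while
  context shifts the whole distribution — the dissociation the analysis is
  designed to detect. The robber race: a D/R trial is "robbed" when its RT
  exceeds a per-trial uniform threshold from the task's per-monkey range
  (PA 90–120, PI 100–180, SO 95–125 ms); robbed trials are replayed once as
  excluded repeats.
* **Units.** Baseline ~10 spikes/s; excited context gains 2.5/1.8/1.3
  applied from a true response latency ~N(120, 30²) ms, with a linear FX
  ramp (5 spikes/s per s) toward object onset; inhibited units are
  suppressed (gains 0.45/0.55/0.65) during FX only. A per-unit×scene
  lognormal gain (σ = 0.3), drawn once, gives stable scene selectivity; a
  per-scene lognormal "arousal" factor (σ = 0.2) multiplies every excited
  unit's gain and raises the scene's LATER rate (exponent 0.3), creating
  the negative activity–SacRT coupling across scenes.
* **Physiology.** Pupil means 3.6/3.3/3.0 a.u. by context with slow AR(1)
  noise and occasional NaN blink gaps; pulse trains at 128/120/112 bpm with
  3% IPI jitter.
* **Anatomy.** Depths uniform in 4–12 mm; background rates N(14, 19²)
  above 8 mm and N(14, 10²) below (clipped at 0.5), planting the variance
  border.
* **Eye traces.** Fixational jitter is a slow AR(1) (φ = 0.995, stationary
  SD 0.1°, ~200-ms correlation time) — white noise at 1 kHz would imply
  absurd velocities; saccades are 15° minimum-jerk profiles (40 ms, peak
  ≈ 560 deg/s). Free viewing is idealized as fixation-like jitter: the
  generator does not emulate scene-exploration saccades, pursuit, or
  microsaccades, so detector tests exercise threshold logic, not clutter
  rejection.

All randomness flows from one `numpy.random.Generator` seeded once; the
same seed yields a byte-identical session on disk. Sessions are
post-learning steady state: no acquisition dynamics.

What passing tests show — and do not. Recovery tests demonstrate that the
analysis chain detects the planted statistical structure at realistic
sizes; they do not validate any claim about real amygdala biology, and the
generator's idealizations (independent Poisson spiking, no slow
nonstationarities, no correlated noise between units, idealized eye
traces) mean real-data performance can differ, especially for the
latency detectors whose calibration depends on spike-count statistics.

Simulation sizes used by the tests and the acceptance script (chosen to
give stable Monte-Carlo estimates at desk scale): 200 null runs and 100
planted runs for detector calibration, 200–300 runs for α calibrations,
100 runs for border recovery, n = 5,000 latencies for reciprobit recovery,
and the default 30-scene/20-unit session for end-to-end recovery.

## Known limitations

* The latency-scan α = 0.05 is applied per step with no multiplicity
  correction beyond the run criterion and the structural prerequisites;
  reported latencies carry the documented window lag.
* The classifier's select-then-test structure inflates its family-wise
  null rejection to ≈ 14% (see above); consumers wanting α-level control
  should Bonferroni-correct across the three contexts.
* The border search reports an uncorrected minimum p and has ~0.45 mm
  localization scatter under the default planted contrast.
* Serialization stores eye traces at full precision as text; a 450-trial
  session directory is ~100 MB and is intended for scratch use, not
  archival compression.
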