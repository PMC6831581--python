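# Methods

`synreach` studies how myofascial trigger points (TPs) relate to the modular
control of center-out reaching. Because no raw recordings are publicly
deposited for this protocol, the package pairs a synthetic study generator
with the full analysis chain, so that every stage can be validated against a
known ground truth. The one piece of real data is the published palpation
table (subject × muscle TP statuses), shipped as a plain-text fixture.

## The model

Surface EMG envelopes from `m = 13` muscles over `t` time samples are
factorized as

```
X ≈ S · P,      S ∈ R^{m×k}_{≥0},  P ∈ R^{k×t}_{≥0}
```

where the columns of `S` are motor modules (muscle weighting coefficients)
and the rows of `P` their activation signals. Reconstruction quality is the
variance accounted for,

```
VAF = 1 − SSE / SST,
```

with `SSE = Σ (X − S·P)²` and `SST = Σ (X − mean(X))²`. The number of
modules is chosen at the inflexion point (change in slope) of the VAF-vs-k
curve, `k = 1..12`, averaged across subjects; per-subject selection uses the
same rule on individual curves.

A muscle is **dominant** in a module when its weighting reaches 0.3 of the
module's maximum weighting (boundary inclusive). Coupling dominance with the
per-muscle TP status (ACT / LAT / NO) yields the long observation table —
one row per subject × muscle × module — on which the association statistics
run.

## Synthetic data generator

The generator emulates the study design: 15 subjects × 13 muscles × 8 radial
targets (45° spacing) × 2 trials, EMG at 2048 Hz and inertial kinematics at
100 Hz, with the task paced in four periods (hold-center 4 s, transition-out
2 s, hold-target 4 s, transition-back 2 s, plus a 0.5 s tail).

* **Weightings.** A fixed canonical three-module structure: module A (reach
  initiation; anterior deltoid dominant with pectoralis major and
  brachioradialis), module B (arm elevation/extension; posterior and middle
  deltoid, triceps, biceps, anterior deltoid at a moderate weight) and
  module C (scapular/neck stabilisation; trapezius chain and SCOM). Columns
  are scaled to unit maximum. Every muscle is dominant in exactly one module
  and the dominant weights are spread over ≈ 0.35–1.0: this gives the
  injected TP effect (below) a realistic detectable magnitude while keeping
  the module columns weakly correlated, which in turn is what makes the
  VAF inflexion sit at the true rank. Per subject, weightings are jittered
  by a multiplicative log-normal factor (σ = 0.12).
* **Activations.** Each module emits one smooth unimodal burst per movement
  (Gaussian bump, σ = 0.11 of the movement, tapered to zero at the ends),
  with burst centers staggered across the movement so the three module
  terms are nearly orthogonal in time. Burst amplitude follows cosine
  directional tuning around module-specific preferred directions (120°
  apart), with a floor of 0.15 so every module participates in every
  direction. Module gains are calibrated by a short deterministic fixed
  point so that the three modules contribute equal variance to the
  normalized envelope matrix — without this the first factor absorbs the
  shared variance and no curve inflexion exists at k = 3.
* **EMG.** Amplitude-modulated Gaussian noise: a zero-mean broadband carrier
  multiplied by the noiseless envelope `S·P` plus a slowly drifting tonic
  (gravity) baseline, with additive white noise at a configurable SNR
  (default 20 dB). A motor-unit-level simulation would add nothing
  observable, since all downstream computation uses envelopes.
* **Kinematics.** Minimum-jerk speed bells in the transitions, direction
  given by the target angle, differentiated to accelerations with constant
  per-axis offsets (imperfect gravity removal) and white jitter; smooth
  roll/pitch/yaw excursions; four sensor positions with graded amplitude.
  The jitter guarantees a strictly positive rest-phase speed SD so the
  segmentation criterion is always defined.
* **TP labels.** Per (subject, muscle), ACT with probability 13/195 and LAT
  with probability 50/195 (the published prevalences); alternatively a
  fixed palpation grid — e.g. the shipped table — can be imposed, which
  anchors a synthetic study on the observed label frequencies and
  positions. With
  `tp_effect_delta > 0`, the weighting of every ACT muscle that is dominant
  in a module is increased by `delta` before synthesis — mirroring the
  effect the analysis is designed to detect, and only that effect. Labels
  and jitter are drawn from streams independent of `delta`, so paired runs
  differing only in `delta` are exact counterfactuals.

### What the generator does *not* emulate

Motor-unit recruitment and firing statistics, electrode placement and
cross-talk, innervation-zone artifacts, fatigue, inertial-sensor drift
models, palpation reliability, and between-subject differences in module
*structure* (subjects share one canonical structure up to jitter; the
published cross-subject similarity was far lower, NDP 0.73 ± 0.14, than the
synthetic one, ≈ 0.99). Passing recovery tests therefore show that the
pipeline is correct and well-calibrated, not that real reaching EMG has
exactly three modules.

## Preprocessing

Band-pass 10–450 Hz then high-pass 50 Hz (2nd-order Butterworth, both
zero-phase) — the unusual high-pass-after-band-pass order is applied exactly
as specified in the protocol. Movement segmentation thresholds a kinematic
speed proxy at rest-mean + 1.05 × rest-SD (an alternative reading,
1.05 × SD as an absolute threshold, is available via configuration). The
speed proxy integrates the forearm 3-axis acceleration once and
drift-corrects against the rest window; because single integration turns
sensor noise into a random walk and the threshold sits only 1.05 SD above
the rest mean, isolated crossings are frequent, so the movement is taken as
the **longest** suprathreshold run (≥ 0.1 s) rather than the literal
first-to-last crossing. Envelopes are full-wave rectified and low-passed at
5 Hz (4th order, zero-phase); the tonic baseline is the line between the
mean rectified values of two 300 ms windows flanking the movement,
subtracted samplewise with negative residuals padded to zero; each movement
is then resampled to exactly 200 samples (linear interpolation; polyphase
available).

**Normalization.** Each movement is divided by the average of the two
trials' global maxima. "Global" is read as *across muscles and time* (one
scalar per movement). The per-muscle reading is implemented and selectable,
but measurement on synthetic studies showed it flattens cross-target
directional tuning, inflates the effective rank of the concatenated matrix
and degrades module recovery (NDP to ground truth 0.84 vs 0.99), so the
scalar reading is the default. Trials are averaged after normalization and
the 8 per-target envelopes are concatenated into `X` (13 × 1600).

Per-muscle RMS of the normalized movement envelope quantifies muscle
activity; the kinematic coefficient of variation (COV = SD/|mean|) is
computed across the time samples of each movement per variable, sensor and
target (with two repetitions, a cross-repetition SD is ill-conditioned; a
flag switches to it).

### Envelope estimation variance

With a stochastic broadband carrier, the rectified-and-smoothed envelope
carries irreducible amplitude-estimation noise of order
`sqrt(2 f_lp / B)` relative to the local amplitude (`B` ≈ carrier
bandwidth): ≈ 7–9 % of the Frobenius norm of `X` after two-trial averaging.
The deterministic part of the chain (enveloping, tonic subtraction,
resampling, normalization applied to the noiseless amplitude) reproduces
the normalized `S·P` concatenation to ≈ 0.5 % relative error; tests assert
5 % for the deterministic chain and 15 % for the full stochastic run.

## Factorization and selection

NMF uses Lee–Seung multiplicative updates on the Frobenius objective from
random nonnegative initializations, 10 restarts (advanced in lock-step and
batched for speed), keeping the restart with the highest VAF. Convergence:
relative objective change < 1e-6 between checks (every 10 iterations) or an
iteration cap, default 500. The cap was chosen after measuring that
extending to 2000 iterations changes VAF by ≤ 7 × 10⁻⁴ at k = 12 and not at
all at k = 3 on study-sized matrices, at four times the cost; the cap is a
parameter. Restart streams are spawned from a master seed, so results are
bit-reproducible. Recovered weighting columns are normalized to unit
maximum (scale absorbed by `P`), making weighting coefficients comparable
across subjects.

The inflexion point is operationalized as the k maximizing the discrete
second difference of the VAF curve (the largest drop in marginal gain, with
the first gain measured from VAF = 0); ties break toward the smaller k and
are logged. An alternative rule — first k whose next marginal gain falls
below 0.05 — is available.

Modules are matched across subjects by maximizing total normalized dot
product (NDP, cosine similarity) under a one-to-one assignment (Hungarian
algorithm, verified against exhaustive permutation search for k ≤ 5); every
subject serves in turn as the reference, and the reference with the highest
average matched NDP is retained.

## Association statistics

**Weighting contrast.** The central model couples the weighting coefficient
with TP presence (ACT/LAT/NO) × muscle condition (dominant/non-dominant),
plus optionally module, as fixed effects, and crossed subject and muscle
variance components (ML). Fixed effects are screened with the variance
inflation factor; if the module term's VIF is ≥ 2 it is dropped and the
model re-run, with the full-vs-reduced comparison reported by likelihood
ratio and AIC. Pairwise TP-status contrasts within each condition are Wald
contrasts of cell means with normal-approximation 95 % CIs — a documented
approximation in place of Kenward–Roger degrees of freedom. Variance
components estimated at ≈ 0 are dropped and noted. Marginal/conditional R²
follow the fixed/total variance partition; the effect size is the key
contrast standardized by the total SD. A **permutation engine** provides
the assumption-free reference: the same cell-mean contrasts with p-values
from shuffling TP status across the subject-muscle units and CIs from the
centered permutation quantiles. Degenerate cells yield an explicitly
undefined contrast, never a fabricated one.

**RMS model.** TP × muscle × target fixed effects with a random subject
intercept (ML); the interaction structure is tested against the additive
model by likelihood ratio, with design columns pruned to full rank (empty
TP × muscle cells are structural). The permutation fallback uses the OLS
sum-of-squares reduction as its statistic.

**Kinematic model.** Subjects are dichotomized by the presence of any
active TP; per kinematic variable, a mixed model with the group fixed
effect and subject, target and sensor variance components is compared to
its null by χ²(1). A per-(variable, sensor) breakdown (Welch t) accompanies
the tests. Undefined COV cells are excluded and counted.

**Dimensionality regressions.** Pearson correlations of per-subject module
count with the total TP count and with an active-TP indicator; zero
variance in either variable is reported as undefined.

**Random-grid robustness.** The TP grid is regenerated many times (default
2000; the scaled acceptance run uses 200) preserving the observed ACT and
LAT totals exactly — uniformly over all cells by default, or within muscle
columns (`per_muscle`) since the protocol does not fix which margins are
held. A grid counts as "similar" when its ACT−NO dominant-condition mean
difference lies inside the original contrast's 95 % CI; the association is
considered robust to palpation misclassification when fewer than 5 % of
grids are similar. Dominance labels are reused across grids by default
(only TP status is randomized); recomputation is available via flag.
Degenerate grids are resampled and counted.

## Calibration checks and problem sizes

The acceptance layer re-derives everything at study scale: palpation-table
tallies; NMF oracle reconstruction (VAF ≥ 0.999 on exact products);
dimensionality and module recovery on the default 15-subject study
(selected k = 3; mean NDP to ground truth ≈ 0.99); detection of the
injected `delta = 0.5` effect over 20 seeded replicate studies (permutation
engine, 200 resamples); the permutation test's null rejection rate over 100
TP-grid redraws against a no-effect study (conditioning on one set of
recovered weightings is exact for a label-exchange null and avoids
re-synthesising EMG 100 times); and the random-grid fraction on 200 grids,
computed on an injected-effect study anchored on the shipped palpation grid
so that the randomized grids preserve the observed ACT/LAT totals — with
freshly drawn labels, an unlucky draw (few ACT cells) widens the reference
CI and the scaled-down grid count no longer bounds the similar fraction.
These sizes keep a full run in the tens of minutes on one CPU; all
randomness derives from a single command-line seed.

## Known limitations

* Kenward–Roger degrees of freedom and the published effect-size simulation
  are not reproduced; the permutation engine is the reference where exact
  small-sample inference matters.
* The crossed-random-effects fit uses variance components within a single
  trivial group, which is correct but can be slow or flat near zero
  variances; zero components are pruned rather than profiled.
* Movement crops inherit up to ~0.3 s of flanking hold when integrated
  sensor noise sits above the (deliberately tight) 5 % threshold; the
  tonic-subtracted envelope there is ≈ 0, so downstream results are
  insensitive, but crop edges are not sample-exact on noisy kinematics.
* The published EMG-derived values (VAF 0.77 ± 0.06, NDP 0.73 ± 0.14, the
  mixed-model MD/CI/AIC numbers, 7/2000 grids) cannot be reproduced without
  the undeposited recordings; the synthetic studies validate the machinery,
  not those numbers.
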