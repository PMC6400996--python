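# Methods

This note documents the models, conventions and numerical choices behind
`ucmgait`, in the order the pipeline runs. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Geometric model

The performance variable is the mediolateral (ML) position of the swing-foot
endpoint relative to the stance-foot contact, modeled as a 7-link planar
chain in the frontal (ML–vertical) plane: stance foot, stance shank, stance
thigh, pelvis, swing thigh, swing shank, swing foot. Every link — the pelvis
included — is parameterized the same way, by the angle `φᵢ` of its traversal
vector (the direction in which the chain is walked from stance foot to swing
foot) measured from the lab vertical, so that

    x(φ) = Σ lᵢ sin φᵢ,    Jᵢ = ∂x/∂φᵢ = lᵢ cos φᵢ.

This single-convention parameterization absorbs all segment-specific signs
into the angles themselves: stance-limb links sit near 0, the pelvis near
π/2, and swing-limb links (which point downward in traversal order) near −π.
It is a deliberate reconstruction — published chain models for this analysis
differ in bookkeeping details — chosen because it is the simplest
self-consistent instantiation with a uniform forward model and Jacobian.

Segment lengths default to anthropometric values for an adult of ~1.7 m
stature (feet 0.12 m, shanks 0.40 m, thighs 0.42 m, pelvis 0.28 m) and are
otherwise estimated per subject as the mean frontal-plane distance between
the segment's endpoint markers over the trial.

The null-space basis `E` (7×6) is computed by SVD, which is deterministic for
a given Jacobian; the mathematically meaningful object is the projector
`E Eᵀ = I − ĵĵᵀ`, which is unique. A zero Jacobian row (all links
horizontal) is a named degenerate-configuration error, not a silent result.

## Variance decomposition

At each percent of swing, `decompose` linearizes at the across-step mean
configuration — the standard linearization point for deviations measured
from that mean — and splits each step's deviation into the null-space
component and its orthogonal residual. The residual is computed vectorially
(`d − E Eᵀ d`) rather than as a difference of squared norms, which would
lose up to six digits when the orthogonal component is locally tiny.

Conventions, each with a config switch:

* **Divisor** — variance is normalized by N (steps), the common convention
  for this analysis; since the across-step mean is estimated, expectations
  carry an (N−1)/N factor, which the recovery tests account for. `"n-1"`
  selects the unbiased convention.
* **z-transform order** — the synergy index is z-transformed per percent and
  then averaged over swing (`transform-then-average`, the dominant
  convention), or averaged first (`average-then-transform`). The transform
  is the Fisher-type form `ΔV_Z = ½ ln((7 + ΔV)/(7/6 − ΔV))`, whose
  singularities sit exactly at the attainable bounds of the index.
* **Degenerate samples** — a percent with zero total variance aborts with a
  diagnostic; silently skipping samples would bias the swing average. A
  profile whose index sits at a bound (e.g. a constructed ensemble with no
  orthogonal variance) is representable; only accessing its `dvz` raises.

The partition identity `6·V_UCM + V_ORT = 7·V_TOT` is exact Pythagoras of an
orthogonal projection and is asserted at every percent of every run in the
test suite.

## Marker processing

* **Gap interpolation** — cubic spline through all valid samples of the
  affected coordinate, filling gaps up to `max_gap` = 12 frames (0.1 s at
  120 Hz, a conservative common practice); boundary gaps have no anchor and
  stay flagged.
* **Filtering** — zero-lag low-pass Butterworth, cutoff 6 Hz. "Fourth-order
  zero-lag" is read as a forward and a backward pass of a 2nd-order filter
  (4th-order effective response), the conventional reading; `mode="cascade"`
  instead runs both passes at the stated order (8th-order effective) for
  labs that report it that way.
* **Gait events** — no force plates are assumed. Heel-strikes are maxima and
  toe-offs minima of the foot marker's fore-aft position relative to the
  pelvis, signed by walking direction so back-and-forth trials work
  unchanged; a standard coordinate-based method. Events are detected on the
  unfiltered (gap-filled) series, where the relative-excursion extrema are
  sharpest.
* **Angles** — `atan2(ML, UP)` of each segment's traversal vector, unwrapped
  over time and re-anchored so the starting value lies in (−π, π]. Positive
  rotation tips the vector toward +ML.
* **Swing extraction** — the left limb is the analysis (swing) limb by
  default; each toe-off→heel-strike window is kept only if the swing-foot
  marker stays inside the declared capture volume (5 m), which discards the
  turns of back-and-forth protocols. Segments are cubic-resampled onto 101
  samples (0–100 %), endpoints preserved exactly.
* **Gait speed** — mean over complete passes of (volume length ÷ traversal
  time), with boundary-crossing times linearly interpolated.

## Inference layer

The analysis plan for a randomized 3-arm pre/post design with repeated
measures on session:

* Lilliefors-corrected Kolmogorov–Smirnov screen per group and variable
  (parameters estimated from the sample); parametric tests are retained
  unless a variable is non-normal in ≥ 2 groups. A switch gives the
  uncorrected plug-in KS variant.
* Split-plot ANOVA (between: group; within: session) via
  `pingouin.mixed_anova`; group is tested against subject-within-group
  error, session and session × group against the subject × session error. A
  hand-written balanced cell-means sums-of-squares oracle cross-checks it in
  the tests. If no subject changes at all, the within-stratum F ratios are
  0/0; they are defined as 0 (no evidence of change) by an explicit guard.
* ANOVA effects are reported on the d scale as `d = 2·√(F·df_num/df_den)`
  (the f → d conversion) — a reconstruction, flagged as such, since d-scale
  ANOVA effect sizes have no single standard definition.
* Post-hoc dependent t-tests within each group are computed unconditionally
  and stored; the gating rule (report them only when the interaction has
  p ≤ α) is applied at report level, so bundles remain reusable. The Holm
  family is the three within-group tests for one variable. The step-down
  Holm adjustment (with enforced monotonicity, capped at 1) is implemented
  directly; Ryan's sequential-rejective variant coincides with it in
  adjusted-p form for families like these. `statsmodels.multipletests` is
  the independent oracle in the tests (the in-package implementation also
  avoids a surprisingly expensive garbage-collection call inside
  statsmodels, which matters in 400-cohort calibration loops).
* Paired effect sizes use the SD of difference scores as standardizer:
  `d_z = t/√n`, Hedges-corrected by `1 − 3/(4·df − 1)`. The 95 % CI inverts
  the noncentral-t distribution of the observed statistic by bracketed root
  finding (with a NaN-safe CDF for deep-tail noncentralities), rescales by
  √n and applies the same correction.
* JZS Bayes factors integrate the noncentral-t likelihood against a
  Cauchy(0, r) prior on the standardized effect (r = 0.707 default) by
  adaptive quadrature, split at the prior mode and the likelihood peak so
  the adaptive rule cannot miss a narrow peak; relative tolerance 1e-6,
  verified against Monte-Carlo integration and `pingouin.bayesfactor_ttest`
  in the tests. The two-sample variant uses the effective sample size
  `n₁n₂/(n₁+n₂)`. Training-load comparisons use Welch t-tests by default
  (pooled-variance switch available).

## Synthetic cohort generator

The generator defines the study conditions the package is tested under:

* **Cohort structure** — 24/21/23 subjects in the three training arms
  (machine-based stable, instability free-weight, machine-based hip
  adductor/abductor), sessions pre/post, walking conditions even surface
  (ES), uneven surface (US), uneven surface with an imbalanced bag (US_ISB);
  20 analyzed steps per trial.
* **Angle ensembles** — each step is the condition's smooth template plus
  deviations injected in the null/orthogonal frame of the template:
  `θₖ(t) = θ̄(t) + E(t)aₖ(t) + ĵ(t)bₖ(t)`, with `aₖ, bₖ` order-4 random
  Fourier series whose coefficients are scaled so the pointwise variance is
  *exactly* the prescribed σ²_ucm (per null dimension) and σ²_ort at every
  percent. Order 4 keeps the curves well inside the 6 Hz passband, so the
  full marker path survives filtering untouched. Deviations are injected at
  the template mean while decomposition linearizes at the sample mean; the
  mismatch is O(deviation²) and covered by the stated recovery tolerances.
* **Variance magnitudes** — baseline σ_ucm ≈ 0.01 rad (1e-4 rad²), higher on
  uneven ground; order-of-magnitude physiologic, since absolute variance
  levels for this protocol are not published. Pre→post effects are
  multiplicative factors per group × condition mirroring the reported
  pattern: nothing changes on the even surface; "good" variance rises
  21–50 % on uneven ground in all arms; "bad" variance falls 25 % (US) /
  24 % (US_ISB) after instability free-weight training but rises > 35 %
  after both machine-based modalities.
* **Between-subject and session noise** — multiplicative log-normal factors
  on the variance components: subject level log-SD 0.35 (shared across
  sessions and conditions), session level log-SD 0.20. The session value is
  set so that a 25 % single-group change in one variance component is
  detected by the interaction test with ≈ 0.9 power at the cohort's sample
  sizes — the same power level such trials are planned for.
* **Fast vs full path** — the full path generates every ensemble and runs it
  through the decomposition (~5 s per cohort); the fast path draws the
  swing-averaged outcomes directly from the implied distributions:
  σ²·(N−1)/N times the log-normal factors times a χ²_df/df sampling factor
  with df = 2·(Fourier order)·d·(N−1), the count of independent Fourier
  coefficients per component surviving mean subtraction. The two paths agree
  in distribution (two-sample KS check in the suite).
* **Markers** — frontal-plane joint positions tip-to-tail from the chain;
  fore-aft progression is a straight pass at the chosen speed, each foot
  planted in stance and advancing linearly in swing, which places the
  extrema of foot-relative-to-pelvis position exactly at the true events.
  Gait speeds carry the prescribed paired pre→post standardized effects
  (0.45 ES / 0.41 US / 0.29 US_ISB). Secondary outcomes (timed-up-and-go,
  reach distances, sit-to-stand, strength, fear-of-falling score, training
  load) are Gaussian with physiologic means and change directions matching
  the study pattern; fear-of-falling uses the published group descriptives.

What the generator does **not** emulate: soft-tissue artifact, marker
mislabeling, non-stationary fatigue or learning drift within a session,
skewed or heavy-tailed outcome distributions, missing sessions, and any
dynamics (no ground-reaction forces, no uneven-surface geometry). Passing
tests therefore demonstrate correctness of the computations and calibration
of the statistics under clean, well-specified variability — not robustness
to every artifact of real recordings.

## Problem sizes

The suite and the acceptance script use desk-scale replicates chosen to keep
Monte-Carlo error well inside the asserted tolerances: 100 seeds × 200 steps
for variance recovery (SE of the mean ≈ 0.5 %, tolerance 5 %), 400 null
cohorts for the type-I rate (SE ≈ 0.6 points on the 5 % rate), 100 cohorts
for effect detection, 10⁶ draws for the Bayes-factor Monte-Carlo oracle
(≈ 0.3 % error against a 1 % tolerance), and 25 cohort replicates for the
recovered percent changes.

## Known limitations

* The event detector assumes reasonably clean foot and pelvis trajectories;
  it has no stumble or shuffle handling.
* The fast-path χ² degrees-of-freedom formula is a first-order count of
  independent coefficients; it ignores the small covariance introduced by
  projecting at the sample mean and by E(t) rotating along the swing. The
  KS agreement check bounds the practical effect.
* The split-plot ANOVA follows `pingouin`'s sums of squares for unbalanced
  groups; other packages' Type-III conventions can differ slightly in the
  group main effect.
* C3D reading requires the optional `ezc3d` dependency and is exercised only
  when it is installed; CSV is the canonical, fully tested path.
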