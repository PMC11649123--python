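# Methods

This note records the statistical model behind `steplock`, the decisions
taken where the design was genuinely open, and what the synthetic-data
studies do and do not establish.

## Outcome series and pre-processing

Trials are event-time tables: footfall times from ankle inertial sensors and
beat times of the auditory stimulus, both in seconds from trial start. The
package deliberately starts *after* gait-event detection; raw IMU traces are
out of scope.

- **Inter-step interval.** `δ_j = Step_{j+1} − Step_j`, stamped at
  `t_j = Step_j`, so J steps yield J−1 intervals and an interval straddling a
  window boundary belongs to the window of its initiating step.
- **Outlier rule.** One pass per trial: median and sample standard deviation
  (n−1 denominator) computed once on the raw δ values; observations outside
  median ± 3 sd removed. The rule is intentionally not iterated — re-applying
  it to its own output is a different (stricter) filter. With a degenerate sd
  (constant series) nothing is removed.
- **Truncation and windows.** Observations at t ≥ 180 s are dropped; windows
  are half-open `[(k−1)·20, k·20)` so nine windows tile the trial with no
  double counting and an observation at exactly 20.0 s belongs to window 2.
- **Relative phase angle.** For a step bracketed by beats,
  `raw = 360·(Step − Beat_j)/(Beat_{j+1} − Beat_j) ∈ [0°, 360°)`, re-expressed
  on (−180°, +180°] by subtracting 360 above 180 — the "closest beat"
  convention, so a step just before a beat has a small negative angle and
  `raw = 180` maps to +180. Steps before the first or at/after the last beat
  carry no defined phase and are dropped with a report.

## Window labelling

Two independent evaluations per window, combined conservatively (locked only
if both agree), classify coupling without any a-priori variability threshold.

### Circular uniformity test (fluctuation)

The circular range `w = 360° − max angular gap` between sorted rPA values is
small when observations concentrate on an arc. Under uniformity its exact
CDF is

    P(W ≤ w) = Σ_{k≥1} (−1)^{k−1} C(n,k) (1 − k t)_+^{n−1},  t = 1 − w/360,

a finite alternating sum (terms vanish for k > n or 1 − kt ≤ 0). Small p
rejects uniformity in favour of concentration *without a preferred mean
direction being estimated* — drifting phases that sweep the whole circle are
not concentrated and correctly fail to reject. α defaults to 0.05 and is
configurable; the implementation works in degrees throughout and is
vectorised for simulation studies. Monte-Carlo checks (20 000 null samples
for n ∈ {10, 20, 30}; CDF agreement within 0.01 at 100 000 reps) confirm
calibration.

### Window-specific slope test (trend)

Per trial, with `s` the time since each window's start,

    rPA = β₀ + β₁ s + b₀(k) + b₁(k) s + ε,   (b₀,b₁) ~ N(0, G) per window k,

is fitted by REML (statsmodels `MixedLM`; unstructured 2×2 G by default).
Each window's predicted slope deviation `b̂₁(k)` (BLUP) is tested against
zero with a standard-normal reference on `b̂₁(k)/SE`.

Numerical decisions:

- **Prediction SE.** The SE is the square root of the Henderson
  mixed-model-equations prediction variance
  `G − GZ'V⁻¹ZG + (GZ'V⁻¹X)(X'V⁻¹X)⁻¹(GZ'V⁻¹X)'` at the plugged-in REML
  components. The fixed-effects term matters: with only ~9 windows the
  overall slope is itself uncertain, and omitting the term overstates every
  window's deviation from it (in simulation it roughly doubled the
  false-unlock rate on locked windows in mixed trials). The normal reference
  is an approximation — no degrees-of-freedom correction is applied.
- **Boundary fits.** When the REML random-slope variance is at zero, no
  window can deviate from the common trend; all evaluable windows are
  labelled locked and a warning is emitted.
- **Optimisers.** Small REML surfaces often trip a single optimizer's
  convergence flag at a usable optimum; the fit retries lbfgs → powell → cg
  and accepts the best finite optimum, warning when no optimizer flags
  convergence. BLUPs and their prediction variances are computed directly
  from the variance components, which stays well-defined when G is singular.
- **No unwrapping, no multiplicity correction.** rPA enters on its raw
  (−180°, 180°] scale; drift that wraps produces sawtooth patterns the slope
  test can miss, which is precisely why it is paired with the uniformity
  test. The nine per-window tests are not corrected for multiplicity by
  default (Bonferroni is a config switch).
- **Unevaluable windows.** Windows with fewer than 8 observations are
  excluded from the model and labelled unevaluable rather than guessed; the
  circular-range p-value and the BLUP are unstable at very small n. At
  normal walking cadence windows hold 20–30 steps, so this margin only
  triggers on pathological data.

## Variability model

Each evaluable window contributes `S = √(Σ(δ−μ)²/J)` — the population-
denominator SD, a descriptive within-window statistic. `log S` (natural log;
the base only rescales coefficients) is modelled as

    log S = Tempi + Stimuli + Window/10 + Lock
            + Tempi×Stimuli + Tempi×Lock + u_subject + ε,

with reference levels tempo 0 %, stimulus metronome, lock locked, a
subject-level random intercept, and REML estimation. The window ordinal is
divided by 10 purely for conditioning. Fixed-effect p-values use the normal
approximation on estimate/SE. Coefficients are named in a compact dialect
(`Tempi: n12`, `Stimuli: music`, `Window_lab_resc`, `Lock_lab: unlocked`,
interactions with `*`) so fitted tables can be read at a glance.

`model_reduction` starts from all five two-way interaction blocks involving
tempo or lock and backward-eliminates blocks by likelihood-ratio tests
between ML refits (χ² with df = block size, threshold 0.05), never touching
main effects; the surviving model is refitted by REML. The elimination
order/test is one defensible reading of standard mixed-model practice; the
default (unreduced) mean structure is the two-interaction model above.

Records with S = 0 (constant intervals in a window) make log S undefined;
the fit refuses them with instructions to floor or exclude — at realistic
timing noise they do not occur.

## Synthetic data

`synth` emulates the event structure of the paradigm, not its biomechanics:

- **Beats** are isochronous at the trial tempo (baseline cadence default
  75 steps/min — IBI 0.8 s, ~25 steps per 20-s window — detuned ±4–12 % per
  condition).
- **Locked segments** place one step per beat at a mean offset (default
  −30°, slight anticipation, typical of sensorimotor synchronisation) with
  von Mises phase jitter (κ = 8 ⇒ angular sd ≈ 20°) plus 10 ms Gaussian
  timing noise — concentrated, trend-flat rPA.
- **Drift segments** emit isochronous steps detuned 4–8 % from the beat
  period: rPA advances ≈ 360·detuning/100 degrees per beat and wraps at
  least ~0.9 times per window even at the slowest tempo, so phases spread
  over the circle.
- **Uniform segments** draw an independent uniform phase per beat interval.

Segment boundaries in the default sampler sit on window boundaries (three
60-s segments, locked with probability 0.5), making the majority-occupancy
ground truth exact rather than a judgement call. Collisions after jitter are
resolved by a 1 ms minimal separation.

These regimes are deliberately well-separated: the validation study answers
"does the two-test pipeline recover unambiguous states?", not "how would
human raters judge borderline windows?". Real data adds phenomena the
generator omits — gradual tempo adaptation, missed steps, asymmetric gait,
sensor dropout — so the surrogate performance figures (~98 % accuracy,
~96 % precision, recall ≈ 1.0 at the default settings) bound behaviour under
idealised conditions only. The generator's parameters are the study
conditions of the simulation and are not adjusted per run.

`generate_variability_dataset` draws per-window SDs directly from the
log-linear model (default truth: effect magnitudes of realistic size on a
millisecond-like scale, subject-intercept sd 0.15, residual sd 0.2, 12
subjects × 14 conditions × 9 windows, Bernoulli(0.5) lock labels). A
600-replicate side study put per-coefficient 95 % CI coverage at 0.93–0.97
(mean 0.949), i.e. the REML + normal-approximation inference is calibrated
at this design size.

## Problem sizes used in validation

The shipped studies use 112 simulated trials (≈1000 windows) for the
classification surrogate, 20 000/100 000 replicates for circular-test
calibration, 500 trials for the slope-test null rate, and 200 replicates for
variability-model recovery — sizes at which every Monte-Carlo tolerance in
the test suite is a small multiple of its standard error.

## Known limitations

- Normal-reference tests for BLUPs and fixed effects ignore df corrections;
  at 9 windows or 12 subjects this is approximate (documented, standard).
- The slope test assumes homoscedastic residuals across windows; a window of
  uniform phases inflates the shared residual variance and makes the slope
  test conservative in mixed trials (the uniformity test carries those
  windows instead).
- Wrapped drift is invisible to the slope test by construction; detunings
  well below ~2.5 % produce partial-circle coverage that neither test may
  flag within a single 20-s window.
- The locked/unlocked dichotomy is binary; intermediate coupling (e.g.
  intermittent locking within one window) maps to whichever evidence
  dominates.
- Ground truth here is simulated; agreement statistics with human raters
  (Cohen's κ utilities in `evalmetrics`) are provided but no rater data
  ships with the package.
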