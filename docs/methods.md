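# Methods

This note documents the models implemented in `vplearn`, the parameter
choices that matter, the design decisions taken where the design was
genuinely open, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate and angle conventions

All geometry is in degrees of visual angle, origin at the annulus center,
y up. Orientations are measured **from the vertical axis** in radians on
the axial domain (−π/2, π/2] — a dipole axis has no polarity, so θ and
θ + π are the same orientation. Per-frame mRDK motion directions are
full-circle, but the signal *axis* is axial: each signal dot's up/down sign
is redrawn per frame, which is what makes the motion non-directional.
Gaussian external noise on orientations is **wrapped** onto the axial
domain rather than truncated; for σ_ext ≲ 0.5 rad the wrapping correction
is negligible, and wrapping avoids distorting the tails at high noise.
Axial sample statistics use angle doubling (for a wrapped normal, the
circular SD of doubled angles exactly recovers the generating σ).

## Stimulus generation

* **Glass patterns** — dipole *centers* are sampled uniformly by area over
  the 0.2°–5° annulus; each dipole is realised as two dots 0.18° apart
  along its orientation. Configurations whose dots would protrude beyond
  the annulus are resampled whole, which keeps dipole density uniform.
  Exactly `round(coherence · n)` dipoles (round half up) take the signal
  orientation; the rest are uniform on the axial domain. Frames are
  mutually independent (fresh positions, no dipole correspondence); only
  the signal orientation persists.
* **mRDKs** — dots step 0.18° per frame; signal dots along the signal axis
  with a per-dot random sign, noise dots in uniformly random directions.
  Dots live `dot_lifetime` frames (default 2: one step, then relocation);
  ages are staggered at initialisation so a constant fraction relocates per
  frame; dots stepping out of the annulus relocate immediately. Element
  overlap is permitted (no collision handling), as is standard for these
  textures.
* **Equivalent-noise variant** — every element is signal; orientations (or
  per-frame direction axes) are drawn from a wrapped Gaussian with mean
  vertical + `mean_offset` and SD `sigma_ext`.
* Rasterisation draws white squares of the element width on a gray field
  and is deterministic given a frame; it exists for visual checking and
  export, not for experimental presentation (no display timing or gamma
  handling).

A 2IFC presentation interval defaults to 5 frames (0.5 s at 10 Hz); the
interval duration is a free choice here, as nothing downstream depends on
it.

## Staircase

1-up/2-down with the step schedule 25, 20, 15, 10, 5, 2, 1 (coherence %),
initial level 50 %, bounds [1, 100] % with clamping (no reflection). The
step shrinks one schedule entry per reversal and stays at the final entry;
**the shrink takes effect from the move after the reversal** — the move
that reveals a reversal still uses the step that produced it. This ordering
matters: advancing the schedule before the recovery move slows the escape
from overshoots and measurably biases thresholds low. A reversal is
recorded at the pre-move level; no reversal exists before the first level
change establishes a direction.

Thresholds are the mean of the last 14 reversal levels, spread their
sample SD. Stand-alone runs stop at 21 total reversals (schedule length 7
plus 14 at the finest steps) or 300 trials, whichever comes first; inside
the simulated study every block runs its full fixed trial count, matching
a fixed-length experimental block, and the last 14 reversals are taken
from wherever they fell.

The 1-up/2-down fixed point satisfies p² = ½, i.e. 70.71 % correct. The
acceptance script measures the empirical convergence level: 500 staircases
against a Weibull observer (threshold 10 %, slope 3), then the observer's
true percent-correct at the mean estimated threshold.

## Simulated observers (the synthetic-data generator)

The generator reproduces the study design: 10 participants; a pre-test of
four 300-trial tasks (coherence × {GP, mRDK}, equivalent-noise × {GP,
mRDK}); eight training sessions of 2 × 300 coherence trials with GPs; a
post-test mirroring the pre-test — 7,200 trials per participant.

* **Coherence observer** — a Weibull psychometric function
  p(c) = 0.5 + (0.5 − λ)(1 − exp(−(c/α)^β)) with α set so that
  p(threshold) = √½. Slope β = 3 (a typical value for coherence tasks),
  lapse λ = 0 by default. The 2IFC trial is a single Bernoulli draw — the
  staircase only consumes correctness, so the two intervals need no
  explicit signal-detection model.
* **EN observer** — its tilt estimate is the true offset plus Gaussian
  error with SD √((σ_int² + σ_ext²)/η); it answers with the estimate's
  sign; a zero offset is credited at chance. This is the forward model the
  equivalent-noise formula inverts exactly.
* **Learning** — GP coherence thresholds follow a·x^(−b) over sessions
  x = 1…10 with a = 33.89, b = 0.20 (the reported group trajectory).
  mRDK thresholds start 1.5× higher; learning transfers to them with a
  configurable factor (default 1 = full transfer, the qualitative outcome
  reported for this stimulus pair).
* **EN parameters** — per (stimulus, phase) cell defaults emulate the
  reported group means: η = 2.26/2.62 (GP pre/post) and 3.38/1.1 (mRDK
  pre/post); σ_int cells (0.30/0.14 GP, 0.94/0.44 mRDK) solve the reported
  two-way margins (pre 0.62, post 0.29, GP 0.22, mRDK 0.70), since cell
  means are not reported.
* **Heterogeneity** — one log-normal multiplier per participant and
  parameter family (scale a, σ_int, η), SD 0.2. Invented and configurable.
* The EN task's 300 trials are split into two 150-trial sub-staircases
  (zero-noise tilt, then high-noise σ_ext); how the two-point measurements
  shared a block in the original design is not specified.

What the generator does **not** emulate: reaction times, session-to-session
fluctuations beyond the trajectory, task-order effects, non-learning
participants, and any perceptual nonlinearity beyond the Gaussian/Weibull
forward models. Passing recovery tests therefore shows the *analysis* is
correct and well-calibrated for observers obeying its assumptions — not
that real observers obey them.

## Equivalent-noise staircases and calibration

The zero-noise staircase adapts the tilt (start 0.35 rad, steps 0.12,
0.08, 0.05, 0.035, 0.025, 0.015, 0.01, bounds [0.001, π/2], smaller =
harder). The high-noise staircase fixes the tilt at ±π/4 and adapts
σ_ext (start 0.1 rad, steps 0.6, 0.5, 0.4, 0.3, 0.25, 0.2, 0.15, bounds
[0, 2π], larger = harder). Two properties of the noise task dictated this
design: its psychometric function is *shallow* in σ_ext, so terminal steps
must stay coarse or the track freezes before reaching its convergence
level; and for a Gaussian observer the 70.7 % noise level is
≈ 1.44·√η rad, so the upper bound must sit far above it or clamping
truncates the track's stationary distribution (both failure modes were
observed with a finer, tighter first design and are why the defaults look
asymmetric to the coherence schedule).

Staircase thresholds are 70.7 %-correct *tilt levels*, not standard
deviations. `threshold_to_sigma` bridges them: σ = threshold/k with
k = Φ⁻¹(√½) ≈ 0.5449 by default, since a Gaussian observer's 70.7 % tilt
threshold is exactly k·σ. The same conversion is applied to the fixed
high-noise tilt, giving σ_obs,H = (π/4)/k. The staircased external-noise
level is already a physical σ and is never rescaled. Consequences, both
asserted in tests: σ̂_int is algebraically independent of k, and η̂ scales
as k²; k = 1 reproduces the literal convention in which the 70.7 %
threshold is itself called σ_obs. With the default k the decomposition
recovers a simulated Gaussian observer's (σ_int, η) without systematic
calibration error.

Uncertainties: δη = (2σ_ext,H/σ_obs,H²)·δσ_ext,H (σ_obs,H is set by
design, not measured, so it carries none), and δσ_int propagates
σ_int = σ_obs,0√η to first order:
δσ_int = √(η·δσ_obs,0² + σ_obs,0²/(4η)·δη²), verified against a
Monte-Carlo resampling oracle. The `high_noise_regime_ok` diagnostic flags
estimates where σ_ext,H < 3·σ̂_int, i.e. where the high-noise
approximation σ_ext ≫ σ_int that underlies η̂ is doubtful (the mRDK
pre-test cell, with σ_int ≈ 0.94 rad, sits in this regime and its η̂ is
accordingly biased — visibly so in the simulated study).

## Learning-curve fitting

Fits are by least squares in the untransformed y-space (linear closed-form;
power/exponential via Levenberg–Marquardt with multi-start: a data-driven
start from the log-log / semi-log slope plus perturbations). Fitting
operates on session means across participants, matching how group learning
curves are usually summarised. Information criteria use the
Gaussian-likelihood convention AIC = n·ln(RSS/n) + 2k with k = 3 (two curve
parameters plus the error variance) — the only k consistent with
AICc − AIC = 4.0 and BIC − AIC ≈ 0.91 at n = 10. Selection minimises AICc
with ties broken by BIC then AIC. RSS = 0 yields −∞ sentinels with a
warning rather than an error, so noiseless series still select correctly.

## Screening

Double-MAD outlier detection: side-specific scales (left MAD over x ≤
median, right MAD over x ≥ median); a value is flagged when its deviation
exceeds 3× its own side's MAD (the conventional multiplier; the cutoff
used in the original analysis is not stated). A degenerate side MAD of 0
flags any nonzero deviation on that side. Flagged values are reported and
**retained** — screening informs the choice of robust statistics
downstream, it does not delete data. Descriptives: mean, SEM, adjusted
Fisher–Pearson skewness with SE = √(6n(n−1)/((n−2)(n+1)(n+3))).

## Problem sizes and reproducibility

Default analyses and tests run at the study's own scale (300-trial blocks,
500-run convergence checks, 200-replicate recovery grids) — a few seconds
to a few minutes on one CPU. All randomness flows through
`numpy.random.Generator` objects seeded from a single master seed; the
pipeline writes a manifest with the seed, package version and a hash of the
analysis-relevant configuration, and identical configurations reproduce
byte-identical tables.

## Known limitations

* The equivalent-noise decomposition is the two-point variant; it does not
  fit full threshold-versus-σ_ext curves and cannot detect departures from
  the equivalent-noise model itself.
* η̂ inherits the high-noise approximation's bias when σ_ext,H is not ≫
  σ_int (flagged, not corrected).
* The mean-of-reversals estimator retains a small bias (≲ 1 % of the
  threshold under the default conditions, measured in the convergence
  test); no correction is applied, matching standard practice.
* Rasterisation is diagnostic-quality; the package does not attempt
  display-hardware fidelity.
* The simulator's transfer and heterogeneity settings are knobs with
  plausible defaults, not estimates.
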