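# vplearn

Tools for studying **visual perceptual learning of non-directional motion**:
procedural generation of dynamic Glass patterns (GPs) and modified
random-dot kinematograms (mRDKs), 1-up/2-down adaptive staircases,
simulated observers, two-point **equivalent-noise decomposition** and
**learning-curve model selection**.

It is aimed at visual psychophysicists who want a tested, reproducible
implementation of this experimental pipeline — from stimulus geometry to
parameter estimates — with simulated observers standing in for human
participants, so that every analysis can be validated against known ground
truth.

## The science in brief

**Stimuli.** A dynamic GP is a field of 250 white dot pairs ("dipoles",
dots 0.18° apart) placed in a 0.2°–5° annulus; positions are resampled at
10 Hz while the shared dipole orientation stays constant, producing
illusory motion along an axis with no recoverable direction. An mRDK is a
field of 500 single dots whose signal fraction steps 0.18° per frame along
a fixed axis with the up/down sign redrawn every frame.

**Staircase.** Coherence and discrimination thresholds are measured with a
1-up/2-down (Levitt) staircase — two consecutive correct responses make the
task harder, one error makes it easier — which converges on the level where
p² = ½, i.e. **70.7 % correct**. Steps follow the schedule
25, 20, 15, 10, 5, 2, 1 (coherence %), shrinking one entry per reversal;
the threshold is the mean of the last 14 reversal levels.

**Equivalent noise.** An observer judging the mean orientation/direction of
n noisy elements has total uncertainty

    σ_obs = sqrt((σ_int² + σ_ext²) / η)

with internal noise σ_int, external (stimulus) noise σ_ext and sampling
efficiency η (effective number of elements pooled). Two measurements — one
at σ_ext = 0 and one at high σ_ext with the observed level fixed at
σ_obs,H = π/4 — give

    η = σ_ext,H² / σ_obs,H²,   σ_int = σ_obs,0 · √η

with first-order uncertainty propagation for δη and δσ_int.

**Learning curves.** Coherence thresholds across 10 sessions (pre-test,
8 training sessions, post-test) are fitted with linear (y = ax + b), power
(y = a·x⁻ᵇ) and exponential (y = a·eᵇˣ) models and compared by AIC, AICc
and BIC (Gaussian-likelihood convention, k = 3 parameters per model).

## Worked example

```python
import numpy as np
from vplearn import (CoherenceObserver, ENObserver, LearningCurveModel,
                     estimate_threshold, run_staircase)
from vplearn.observers import (coherence_observer_respond, coherence_protocol,
                               simulate_en_measurement)

# 1. staircase a Weibull observer whose true 70.7% point is 10% coherence
rng = np.random.default_rng(0)
obs = CoherenceObserver(threshold_c=10.0)
protocol = coherence_protocol(min_total_reversals=21)
state, log = run_staircase(protocol,
                           lambda c: coherence_observer_respond(obs, c, rng))
print(estimate_threshold(state, protocol))
# ThresholdEstimate(threshold=10.571428571428571, spread=1.5548..., n_reversals_used=14)

# 2. equivalent-noise decomposition of a known observer
results, *_ = simulate_en_measurement(ENObserver(sigma_int=0.2, eta=2.0),
                                      np.random.default_rng(1))
print(results.summary())
# Equivalent-noise decomposition (two-point)
# ============================================
# sampling efficiency  eta       =   2.1159 +/- 0.8449
# internal noise       sigma_int =   0.1781 +/- 0.0844 rad
# high-noise regime (sigma_extH >= 3 sigma_int): ok

# 3. learning-curve model selection on a power-law series
x = np.arange(1, 11)
fit = LearningCurveModel(33.89 * x**-0.20 * 1.02, x).fit()
print(fit.selected)             # 'power'
```

The staircase threshold (10.6 %) sits within one step of the observer's
true 10 % point; the decomposition recovers σ_int = 0.18 rad and η = 2.1
for a (0.2, 2.0) observer from 300 simulated trials; and the model
comparison identifies the power law that generated the learning series.

A full simulated study (10 participants, 7,200 trials each) with all
analyses:

```bash
vplearn pipeline --seed 1 --out results/run1
```

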