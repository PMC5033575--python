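# movewarp

Statistical decomposition of repeated movement signals into **timing** and
**amplitude** variation, with participant-level structure — and a
mixed-effects factor analysis of the aligned 3-D movement paths.

## The problem

Repeated human movements (e.g. transporting an object over an obstacle,
recorded by motion capture) produce functional data whose variation mixes
three sources: *when* things happen (timing), *how large* the signal is
(amplitude), and observation noise. Conventional pipelines align curves
first (percentual time, dynamic time warping) and analyze amplitude
afterwards, which biases both: an aligner that ignores amplitude noise
overfits the warps, and amplitude analysis on badly aligned curves smears
systematic structure. `movewarp` estimates both at once, by maximum
likelihood, in a hierarchical nonlinear mixed-effects model.

## The model

For participant i, repetition j, observed at times t on [0, 1]:

    y_ij(t) = (θ + φ_i) ∘ (ν_i + v_ij)(t) + x_ij(t) + ε_ij(t)

* θ = Φc — common template in a cubic B-spline basis Φ with K knots;
* φ_i = Φd_i — participant deviation (Σ_i d_i = 0, ridge weight
  η = λ/(1+τ²));
* ν_i — participant **fixed warp**: an increasing piecewise-linear
  homeomorphism of [0, 1] with n_w equidistant anchors;
* v_ij — repetition **random warp**: anchor deviations
  w_ij ~ N(0, σ²γ²·C_BB) with the Brownian-bridge covariance
  C_BB(t,t') = t(1−t') for t ≤ t' (warps pinned at onset and offset);
* x_ij — serially correlated amplitude variation: a stationary Gaussian
  process with Matérn covariance (smoothness μ, scale σ²τ², range 1/α);
* ε_ij — white noise, variance σ².

Estimation runs on three levels: generalized-least-squares updates of
(c, d_i) at fixed warps; joint estimation of ν_i and prediction of w_ij
from the negative log posterior

    p(ν_i, w_ij) = Σ_j ‖y_ij − (θ̂+φ̂_i)∘(ν_i+v_ij)(t)‖²_{I+S} + Σ_j ‖w_ij‖²_C ;

and variance estimation (σ², τ², α, γ²) by minimizing the linearized
(Laplace-approximate) marginal likelihood

    ℓ = m log σ² + log det V + σ⁻²‖y − ϑ̂ + Zw⁰‖²_V ,   V = S + Z(I⊗C)Z' + I.

A fitted model classifies single movements by participant ("timing and
motion separation"): a test curve goes to the participant whose template
(θ+φ̂_i)∘ν̂_i gives the least negative log posterior after re-predicting
only the test curve's random warp.

The companion factor model represents aligned 30×3 movement paths as

    y_ijh = θ + (X_h β + Σ_l Z_{i,g_l(j,h),l}) W' + ε_ij

with orthonormal loadings W (90×q), an obstacle-height covariate X_h
(2-parameter ANOVA or 1-parameter linear height scaling), and three nested
Gaussian random-effect levels (participant, participant×height reaction,
repetition). It is fitted by an ECM algorithm accelerated with SQUAREM,
identified like PCA (W orthonormal, total latent covariance diagonal), and
supports variance decomposition, likelihood-ratio tests of the height
design (χ² with q degrees of freedom), and 95% prediction ellipsoids.

## Worked example

```python
import movewarp as mw

samples, truth = mw.simulate_pavpop(mw.PavpopSimConfig(
    n_participants=5, n_repetitions=8, n_timepoints=50, seed=7))
fit = mw.fit_pavpop(samples, mw.PavpopConfig(n_knots=12, n_w=2, mu=1.0))
p = fit.params
print(p.sigma2, p.matern.tau2, 1 / p.matern.alpha, p.bridge.gamma2)
```

prints (estimates against generating values σ²=1e-4, τ²=1, 1/α=0.2,
γ²=0.25):

```
9.68e-05 0.914 0.190 0.341
```

i.e. the noise variance, amplitude variance, amplitude correlation range
and warp variance are recovered from 40 simulated curves, and `fit.nu`
holds each participant's timing trait (its fixed-warp anchors, e.g.
estimated `[0.367, 0.570]` against generating `[0.366, 0.567]` for
participant 1 — this participant reaches the first anchor event slightly
late and the second early relative to the average timeline).

The `examples/` directory has one short script per capability:
preprocessing raw tracks (`01`), fitting the warping model (`02`),
participant classification with chronological cross-validation (`03`),
the factor analysis of aligned paths (`04`), and the synthetic-data
generators with file round-trips (`05`).

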