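# vbglm

Variational Bayes (VB), variational maximum likelihood (VML, a.k.a.
expectation-maximization), restricted maximum likelihood (ReML) and maximum
likelihood (ML) estimation for the general linear model with linearly
decomposable, non-spherical error covariance — the workhorse model of
first-level fMRI time-series analysis:

```
y = X β + ε,   ε ~ N(0, V_λ),   V_λ = Σᵢ exp(λᵢ) Qᵢ
```

Here `X ∈ ℝ^{n×p}` is a design matrix (condition onsets convolved with the
canonical hemodynamic response), `β` are effect sizes, and the error
covariance is a positive combination of fixed symmetric basis matrices
`Q₁ = I_n` and `(Q₂)_{ij} = exp(−|i−j|/τ)` — white noise plus exponentially
decaying serial correlations (the common AR(1)+white-noise approximation,
`τ = 0.2` by default). The `exp(λᵢ)` parameterization keeps every component
scaling positive.

The four techniques form a nested family distinguished by which parameters
carry a posterior distribution. Each maximizes a free energy `F` — a lower
bound on (or degeneration of) the log marginal likelihood — by alternating a
closed-form update of the β block with a safeguarded Newton ascent on the λ
block:

| technique | q(β)           | q(λ)           | prior on β | prior on λ |
|-----------|----------------|----------------|------------|------------|
| VB        | N(m_β, S_β)    | N(m_λ, S_λ)    | Gaussian   | Gaussian   |
| VML       | N(m_β, S_β)    | point estimate | Gaussian   | flat       |
| ReML      | exact Gaussian | point estimate | flat       | flat       |
| ML        | point estimate | point estimate | flat       | flat       |

The converged `F` approximates the log model evidence (enabling model
comparison), and the Gaussian posteriors yield exceedance-probability maps
`p(β₁ > η) = 1 − Φ((η − m_β₁)/√S_β₁)` for mass-univariate inference.

The package is intended for methodologists and neuroimaging practitioners
who want a transparent, fully tested reference implementation of these
estimators, their mutual relationships (ReML = VML with a flat β prior and
exact β posterior; in the spherical case ML gives RSS/n and ReML the
unbiased RSS/(n−p)), and the simulation designs used to probe them. A
closed-form conjugate Gaussian-Gamma reference (`vbglm.conjugate`) serves as
an analytic oracle.

## Worked example

```python
import numpy as np
from vbglm import (fixture_spec, simulate_glm, TrueParams, PriorSpec,
                   vb_fit, exceedance_probability)

spec = fixture_spec(seed=2017)          # 400-scan, TR 2 s, two conditions
truth = TrueParams(beta=[2.0, -1.0], lam=[-0.5, -2.0])
y = simulate_glm(spec, truth, seed=1)

prior = PriorSpec.imprecise(p=2, k=2)   # N(0, 10 I) on beta and lambda
fit = vb_fit(y, spec, prior)

print(f"converged in {fit.n_iter} iterations: {fit.converged}")
print("posterior mean of beta:", np.round(fit.state.m_beta, 3))
print("posterior var of beta: ", np.round(np.diag(fit.state.S_beta), 4))
print("posterior mean of lambda:", np.round(fit.state.m_lam, 3))
print("free energy trace:", np.round(fit.free_energy_trace, 2))
p = exceedance_probability(fit.state.m_beta[0], fit.state.S_beta[0, 0], 1.0)
print(f"p(beta_1 > 1) = {p:.4f}")
```

prints

```
converged in 4 iterations: True
posterior mean of beta: [ 2.15  -1.249]
posterior var of beta:  [0.017  0.0175]
posterior mean of lambda: [-0.866 -1.645]
free energy trace: [-2444.38 -1042.35  -480.56  -480.54  -480.54]
p(beta_1 > 1) = 1.0000
```

The posterior mean of β lands close to the true (2, −1) with posterior
standard deviations ≈ 0.13; the free-energy trace increases monotonically
and converges in four sweeps. The λ posterior concentrates on the ridge
where `exp(λ₁) + exp(λ₂)` matches the realized noise variance — the two
basis matrices are nearly collinear under the default decay constant, so
the individual components are only weakly identified (see
`docs/methods.md`). `p(β₁ > 1) = 1.0` is the posterior exceedance
probability at threshold η = 1.

A command line mirrors the library. `vbglm fixtures --seed 7 --out demo/`
writes the demo design, basis, one simulated series and ready-made configs;
then `vbglm fit --config demo/config_vb.yaml --out demo/fit/` fits it, and
`vbglm maps`, `simulate`, `recover`, `model-recover`, `diverge` drive the
other operations. All matrices are headerless CSV (rows = scans, 17
significant digits, exact round-trip).

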