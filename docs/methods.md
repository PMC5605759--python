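# Methods

## Model

All estimators address the general linear model with linearly decomposable
error covariance,

    y = X β + ε,   ε ~ N(0, V_λ),   V_λ = Σ_{i=1}^k exp(λ_i) Q_i,

with `X ∈ ℝ^{n×p}` of full column rank and fixed symmetric covariance basis
matrices `Q_i`. The default basis is `Q₁ = I_n` and
`(Q₂)_{ij} = exp(−|i−j|/τ)` with decay constant τ = 0.2 (scan-index units),
the conventional approximation to AR(1)-plus-white-noise serial correlation
in fMRI time series. The `exp(λ)` parameterization enforces positive
component scalings; positive definiteness of `V_λ` is established by
factorization, never by silent jitter — failures surface to the caller.

## Free energies and algorithms

Four estimation techniques maximize nested variational free energies. With
Gaussian priors `p(β) = N(μ_β, Σ_β)`, `p(λ) = N(μ_λ, Σ_λ)` and Gaussian
variational factors `q(β) = N(m_β, S_β)`, `q(λ) = N(m_λ, S_λ)`:

* **VB.** `F^VB(m_β, S_β, m_λ, S_λ)` consists of an accuracy term
  `−½(y−Xm_β)ᵀV_{m_λ}^{-1}(y−Xm_β)` with the attendant `−(n/2)ln 2π −
  ½ln|V_{m_λ}| − ½tr(S_β XᵀV_{m_λ}^{-1}X)`, a curvature correction
  `−¼tr(B S_λ)` for posterior λ uncertainty, Gaussian prior complexity
  terms for β and λ, and the entropies of the two variational factors.
  `B(m_β, S_β, m_λ)` is the sum of the λ-Hessians of `ln|V_λ|`,
  `tr(V_λ^{-1}XS_βXᵀ)` and the residual quadratic form, derived in closed
  form from `∂V_λ/∂λ_j = exp(λ_j)Q_j` and
  `∂V_λ^{-1}/∂λ_j = −exp(λ_j)V_λ^{-1}Q_jV_λ^{-1}` and validated against
  finite differences in the test suite.
* **VML** drops all λ-uncertainty terms (point λ, flat λ prior).
* **ReML** additionally drops the β prior-deviation penalty (flat β prior);
  its β update is exactly GLS with covariance `(XᵀV^{-1}X)^{-1}`, and at
  that point `F^ReML` equals the restricted log likelihood
  `−½ln|V| − ½ln|XᵀV^{-1}X| − ½rᵀV^{-1}r` up to the constant
  `−(n/2)ln 2π + (p/2)ln 2π` (asserted to 1e-10 in the tests).
* **ML** reduces to the plain Gaussian log likelihood.

Entropy prefactors pair the dimension with its own block — `(p/2)ln(2πe) +
½ln|S_β|` and `(k/2)ln(2πe) + ½ln|S_λ|` — and every prior-complexity trace
carries the factor ½, as dictated by the KL divergence between Gaussians.

Each fit alternates (i) the closed-form β-block update
`S_β = (XᵀV^{-1}X + Σ_β^{-1})^{-1}`, `m_β = S_β(XᵀV^{-1}y + Σ_β^{-1}μ_β)`
(flat-prior limits for ReML/ML), (ii) for VB the covariance update
`S_λ = (½B + Σ_λ^{-1})^{-1}`, and (iii) a λ-block maximization. Convergence
is declared when the free-energy increment falls below δ (default 1e-3),
with a hard cap of 64 sweeps (`converged=False` beyond it, never an
exception).

Two practical safeguards:

* At an imprecise-prior initialization `B` is typically indefinite (the
  prior `S_β = Σ_β` term dominates the curvature far from the optimum), so
  `½B + Σ_λ^{-1}` may not be invertible as a covariance. The S_λ update is
  then skipped for that sweep (flagged in diagnostics) and resumes once the
  other blocks have moved; on the demo model this happens only in the first
  sweep.
* The block updates ignore the dependence of `B` on `(m_β, S_β, m_λ)`, so a
  sweep is not mathematically guaranteed to increase `F^VB`. The outer loop
  therefore evaluates `F` after every full sweep and rolls the final sweep
  back if it decreased the objective — the reported trace is monotone by
  construction. A rollback has not been observed on the demo model.

### λ solver

The λ block is maximized by damped Newton ascent: step `−H^{-1}g` from the
analytic gradient/Hessian, halved (≤16 times) until the objective does not
decrease, with a scaled gradient-ascent fallback when the Hessian is
singular/indefinite or the Newton direction is not an ascent direction.
Steps are capped at norm 25 so that a flat objective crest cannot launch λ
into overflow territory. Termination: gradient norm < 1e-9 (`newton_tol`) or
32 sweeps. The returned point never has a lower objective than the start.
For VB the solve maximizes the smooth λ-part (log-determinant, quadratic,
trace, prior penalty); the `−¼tr(B(λ)S_λ)` correction would require third
derivatives of `ln|V_λ|` and is excluded from the solve but included in
every free-energy evaluation — consistent with the alternating scheme's
treatment of `B` as fixed within a sweep.

### Numerical linear algebra

All covariance-role inverses are triangular solves from Cholesky
factorizations; log-determinants come from factor diagonals; matrices are
re-symmetrized (`(M+Mᵀ)/2`) after updates. When the basis matrices commute —
the default `[I, Toeplitz]` pair always does — the package computes a common
orthogonal eigenbasis once per model (verified by reconstruction to 1e-8,
with a dense fallback otherwise) and carries `A = XS_βXᵀ + rrᵀ` in factored
low-rank form, making every λ-objective evaluation O(nk²) instead of O(n³).
The fast and dense paths agree to rounding error (property-tested); a full
four-method fit of an n = 400 series takes ≈ 45 ms on one core.

## Parameters

| parameter | default | meaning |
|---|---|---|
| τ | 0.2 | decay constant of Q₂, scan-index units |
| δ (`delta`) | 1e-3 | free-energy increment convergence criterion |
| `max_iter` | 64 | outer-sweep cap |
| `newton_tol` | 1e-9 | λ gradient-norm tolerance |
| `newton_max_steps` / `step_halving_max` / `newton_max_step` | 32 / 16 / 25 | λ ascent safeguards |
| priors (demo) | N(0, 10·I) | imprecise priors on β and λ |
| Grubbs α | 0.05 | two-sided, applied iteratively per λ component |

## Synthetic data generator

The demo model emulates a single-session event-related fMRI acquisition:
n = 400 scans at TR = 2 s, two conditions with independent onset streams
whose inter-trial gaps are Gaussian (mean 6 s, sd 1 s, truncated below at
1 s), onsets quantized to a fixed TR/16 grid, stick functions convolved at
micro-time resolution (16 bins per TR by default) with a canonical
double-gamma hemodynamic response (response peak 6 s, undershoot peak 16 s,
unit dispersions, undershoot ratio 1/6, 32 s support), downsampled to the
scan grid. The kernel is normalized to unit peak so that β is in signal
units; with the demo β = (2, −1) and λ = (−0.5, −2) this yields a realistic
single-voxel SNR. Because onsets live on the fixed TR/16 grid, refining
`microtime_bins` beyond 16 leaves the design numerically invariant. The
generator deliberately omits signal offset/drift, motion, and physiological
noise; no constant column is included in the demo design. Noise is drawn
through the Cholesky factor of `V_λ`, one explicit seed per operation.

Consequently, passing tests demonstrate correctness of the estimators under
the stated Gaussian model with known basis — they do not certify behavior
under real-data violations (drift, spikes, non-Gaussian noise, basis
misspecification).

## Identifiability of the covariance components

Under the default decay constant the off-diagonal of Q₂ is tiny
(lag-1 entry e⁻⁵ ≈ 0.0067), so `exp(λ₁)Q₁` and `exp(λ₂)Q₂` are nearly
collinear: the data identify the total scale `exp(λ₁)+exp(λ₂)` sharply but
the split between components only very weakly. The λ free-energy surface is
a long flat crest; point-estimation methods (VML/ReML/ML) drift along it —
frequently railing λ₂ toward −∞ (a boundary maximum where that component's
gradient vanishes) — while VB's λ prior pins the solution to a
prior-dependent point on the crest. β estimation, model comparison, and the
total noise scale are unaffected. The parameter-recovery study reports the
λ estimates exactly as obtained; their dispersion across realizations is a
property of the model, not of the optimizer (verified against independent
Nelder-Mead maximization of the same objectives). For the same reason,
the VML/ReML/VB nesting checks under vague priors assert agreement of
`m_β`, λ₁ and the identifiable total `Σ exp(λ_j)` rather than of the
unidentified λ₂ split.

## Conjugate reference

For the spherical model with noise precision λ = 1/σ², the Gaussian-Gamma
prior `β|λ ~ N(μ_β, λ^{-1}V_β)`, `λ ~ Gamma(a, b)` (shape/rate) gives the
closed-form posterior with `μ_{β|y} = (XᵀX+V_β^{-1})^{-1}(Xᵀy+V_β^{-1}μ_β)`,
`a_{λ|y} = (2a+n)/2`, and the standard rate update. The marginal of y is a
multivariate Student-t; `conjugate_marginal` returns the parameterization
`ν_y = 2a+n−1`, scale `2b/(2a+n−1)(XV_βXᵀ+I)`. This degrees-of-freedom
convention differs from the analytically integrated Gaussian-Gamma marginal
(ν = 2a, scale `(b/a)(XV_βXᵀ+I)`); rather than resolving the discrepancy by
fiat, the package ships `marginal_log_density_mc`, a prior Monte-Carlo
estimate of ln p(y) with standard error, and the test suite shows the MC
estimate matching the ν = 2a form and flagging the returned convention —
users comparing evidence across models should rely on the iterative
free energies or the MC diagnostic. The improper-prior variant is out of
scope. The spherical ML (`RSS/n`) and ReML (`RSS/(n−p)`) variance
estimators are provided as oracles for the iterative fits.

## Simulation studies

* **Parameter recovery** (default 100 realizations, imprecise N(0, 10·I)
  priors, λ init 0): collects converged estimates for all four methods,
  screens each λ component with an iterative two-sided Grubbs test
  (α = 0.05; a realization is an outlier for a method if any component is
  flagged or the fit failed to converge), and reports cumulative averages
  and variances.
* **Model recovery**: a generator × analyzer crossover between the
  one-regressor (MG1/MA1, first design column) and two-regressor (MG2/MA2)
  models; per generator and method, realizations flagged as λ outliers
  under either analyzer are excluded so both cells average identical sets.
  Note an exact-ML caveat: since MA1 is nested in MA2, the maximized
  likelihood of MA2 can never be smaller, so ML prefers the larger model on
  MG1 data by ≈ ½E[χ²₁] ≈ 0.5 on average — only the techniques whose free
  energies carry complexity penalties (VB, VML, ReML) can identify the
  parsimonious truth. The report includes per-realization free energies
  and win counts, making this visible.
* **Estimation-quality divergence**: true β = (1, 1), λ₂ = −2, λ₁ sweeping
  a noise grid (effect scenario: [6, 12]; covariance scenario: [−1, 1]),
  initializations as in the shipped scenario tables — notably a precise
  prior variance of 1e-2 pinning β₁ at its true value for VB/VML in the
  effect scenario. Reported error is the *mean Euclidean error norm*
  Ê‖θ̂−θ‖₂ (not the root of the mean squared norm) plus per-component
  biases; no outlier screening is applied. At high noise the
  prior-regularized VB/VML keep the β error bounded by the prior geometry
  while ReML/ML errors grow with the noise level.

Problem sizes used by the shipped acceptance script: 100 realizations for
recovery, convergence-speed and model-recovery runs, 50 for the divergence
study at its highest noise level — sizes at which the Monte-Carlo error of
every reported mean is comfortably below the effects of interest.

## Limitations

* The λ split of near-collinear covariance components is unidentified at
  n = 400 under the default basis (above); λ point estimates should be
  interpreted through the identifiable total scale.
* No AR-coefficient estimation: the basis (and τ) is fixed and known.
* Single-series estimation only; the mass-univariate runner loops over
  series columns with no spatial pooling or smoothing.
* No drift/motion/physiological regressors and no image-format (NIfTI)
  handling; inputs are delimited-text matrices.
* Initial-value restarts for the λ ascent are not automated; the
  diagnostics (per-sweep gradient norms, no-progress flags, skipped S_λ
  updates) are exposed so callers can implement their own policies.
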