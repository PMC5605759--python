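"""Simulation studies of estimator quality.

Three experiments probe the four estimation techniques on synthetic data
from the demo model:

* **parameter recovery** — cumulative averages/variances of converged
  estimates over repeated realizations, with iterative Grubbs screening of
  the covariance-component estimates (whose flat, crest-like objective
  surface produces a minority of wildly divergent solutions);
* **model recovery** — a generator x analyzer crossover comparing mean
  converged free energies (log model-evidence approximations) between a
  one-regressor and a two-regressor design;
* **estimation-quality divergence** — RMSE and bias of the estimates over a
  grid of noise levels, contrasting the prior-regularized techniques
  (VB, VML) with the unregularized ones (ReML, ML).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .estimators import (
    FitOptions,
    PriorSpec,
    VariationalState,
    ml_fit,
    reml_fit,
    vb_fit,
    vml_fit,
)
from .model import GLMSpec, TrueParams, simulate_glm

__all__ = [
    "METHODS",
    "RecoveryReport",
    "ModelRecoveryReport",
    "DivergenceReport",
    "grubbs_outliers",
    "parameter_recovery",
    "model_recovery",
    "divergence_experiment",
    "summarize_rmse_bias",
    "table1_priors",
    "fit_all_methods",
]

METHODS = ("VB", "VML", "ReML", "ML")


# ---------------------------------------------------------------------------
# outlier screening
# ---------------------------------------------------------------------------

def grubbs_outliers(values, alpha: float = 0.05) -> np.ndarray:
    """Iterative two-sided Grubbs screen; True marks removed points.

    Repeatedly tests G = max|x_i - xbar| / s against the critical value
    G_crit = ((N-1)/sqrt(N)) sqrt(t^2 / (N-2+t^2)) with
    t = t_{alpha/(2N), N-2}, removing the most extreme point while the test
    rejects. Fewer than 3 points, or zero spread, yield an empty mask.
    """
    x = np.asarray(values, dtype=float)
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    mask = np.zeros(len(x), dtype=bool)
    while True:
        idx = np.flatnonzero(~mask)
        n = len(idx)
        if n < 3:
            break
        sub = x[idx]
        s = sub.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(sub - sub.mean())
        g = dev.max() / s
        t = st.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
        g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
        if g > g_crit:
            mask[idx[int(np.argmax(dev))]] = True
        else:
            break
    return mask


def _cumulative_stats(values: np.ndarray):
    """Cumulative mean and (ddof=1) variance along axis 0."""
    r = np.arange(1, len(values) + 1)[:, None]
    csum = np.cumsum(values, axis=0)
    cavg = csum / r
    csq = np.cumsum(values**2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cvar = (csq - r * cavg**2) / np.maximum(r - 1, 1)
    cvar[0] = np.nan
    return cavg, cvar


# ---------------------------------------------------------------------------
# shared fitting front end
# ---------------------------------------------------------------------------

def fit_all_methods(y, spec: GLMSpec, vb_prior: PriorSpec, vml_prior: PriorSpec,
                    lam_init, beta_init=None, options: FitOptions | None = None,
                    reml_init: VariationalState | None = None) -> dict:
    """Fit one series with all four techniques; returns {method: FitResult}."""
    options = options or FitOptions()
    if beta_init is None:
        beta_init = np.zeros(spec.p)
    return {
        "VB": vb_fit(y, spec, vb_prior, options),
        "VML": vml_fit(y, spec, vml_prior, lam_init, options),
        "ReML": reml_fit(y, spec, lam_init, init_state=reml_init, options=options),
        "ML": ml_fit(y, spec, beta_init, lam_init, options),
    }


def _collect_row(method: str, real: int, fit) -> dict:
    row = {"method": method, "realization": real,
           "converged": fit.converged, "n_iter": fit.n_iter,
           "free_energy": fit.free_energy}
    for j, b in enumerate(np.atleast_1d(fit.state.m_beta), start=1):
        row[f"beta_{j}"] = float(b)
    for j, l in enumerate(np.atleast_1d(fit.state.m_lam), start=1):
        row[f"lam_{j}"] = float(l)
    return row


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Raw estimates plus Grubbs screening and cumulative summaries."""

    estimates: pd.DataFrame
    outlier_mask: dict          # method -> bool array (union over components)
    outlier_mask_by_component: dict  # method -> (n_real, k) bool array
    failed_mask: dict           # method -> bool array of non-converged fits
    truth: TrueParams
    cumulative: dict = field(default_factory=dict)

    def outlier_fraction(self, method: str) -> float:
        return float(np.mean(self.outlier_mask[method]))

    def final_beta_mean(self, method: str) -> np.ndarray:
        sub = self.estimates[self.estimates.method == method]
        cols = [c for c in sub.columns if c.startswith("beta_")]
        return sub[cols].to_numpy().mean(axis=0)

    def final_lam_mean(self, method: str) -> np.ndarray:
        sub = self.estimates[self.estimates.method == method]
        keep = ~self.outlier_mask[method]
        cols = [c for c in sub.columns if c.startswith("lam_")]
        return sub[cols].to_numpy()[keep].mean(axis=0)


def parameter_recovery(n_real: int, spec: GLMSpec, true_params: TrueParams,
                       seed: int, vb_prior: PriorSpec | None = None,
                       vml_prior: PriorSpec | None = None, lam_init=None,
                       options: FitOptions | None = None,
                       grubbs_alpha: float = 0.05) -> RecoveryReport:
    """Repeated-realization recovery study of beta and lambda.

    Each realization is simulated from ``true_params``, fit with all four
    techniques (imprecise zero-mean priors with covariance 10 I by default,
    lambda initialized at 0), and the converged estimates collected. The
    lambda estimates are screened per component with the iterative Grubbs
    test; a realization counts as an outlier for a method if any component
    is flagged or the fit did not converge.
    """
    p, k = spec.p, spec.k
    vb_prior = vb_prior or PriorSpec.imprecise(p, k)
    vml_prior = vml_prior or PriorSpec.imprecise(p)
    lam_init = np.zeros(k) if lam_init is None else np.asarray(lam_init, float)
    seeds = np.random.SeedSequence(seed).generate_state(n_real)

    rows = []
    for r in range(n_real):
        y = simulate_glm(spec, true_params, int(seeds[r]))
        fits = fit_all_methods(y, spec, vb_prior, vml_prior, lam_init, options=options)
        for method, fit in fits.items():
            rows.append(_collect_row(method, r, fit))
    estimates = pd.DataFrame(rows)

    lam_cols = [f"lam_{j}" for j in range(1, k + 1)]
    beta_cols = [f"beta_{j}" for j in range(1, p + 1)]
    outlier_mask, by_comp, failed_mask, cumulative = {}, {}, {}, {}
    for method in METHODS:
        sub = estimates[estimates.method == method].sort_values("realization")
        lam = sub[lam_cols].to_numpy()
        comp = np.column_stack([grubbs_outliers(lam[:, j], grubbs_alpha)
                                for j in range(k)])
        failed = ~sub["converged"].to_numpy()
        mask = comp.any(axis=1) | failed
        outlier_mask[method] = mask
        by_comp[method] = comp
        failed_mask[method] = failed
        beta = sub[beta_cols].to_numpy()
        cavg_b, cvar_b = _cumulative_stats(beta)
        cavg_l, cvar_l = _cumulative_stats(lam[~mask])
        cumulative[method] = {"beta_avg": cavg_b, "beta_var": cvar_b,
                              "lam_avg": cavg_l, "lam_var": cvar_l}

    return RecoveryReport(estimates, outlier_mask, by_comp, failed_mask,
                          true_params, cumulative)


# ---------------------------------------------------------------------------
# model recovery
# ---------------------------------------------------------------------------

@dataclass
class ModelRecoveryReport:
    """Cell means of converged free energies in the crossover design."""

    cell_means: pd.DataFrame    # generator, method, analyzer, mean_F, n_kept
    free_energies: pd.DataFrame
    win_counts: pd.DataFrame    # generator, method, wins of matched analyzer

    def mean_F(self, generator: str, method: str, analyzer: str) -> float:
        m = self.cell_means
        row = m[(m.generator == generator) & (m.method == method)
                & (m.analyzer == analyzer)]
        return float(row["mean_F"].iloc[0])

    def margin(self, generator: str, method: str) -> float:
        """Matched-minus-mismatched mean free energy for one generator."""
        matched = "MA1" if generator == "MG1" else "MA2"
        other = "MA2" if matched == "MA1" else "MA1"
        return self.mean_F(generator, method, matched) - self.mean_F(generator, method, other)


def model_recovery(n_real: int, spec: GLMSpec, true_params: TrueParams, seed: int,
                   options: FitOptions | None = None,
                   grubbs_alpha: float = 0.05) -> ModelRecoveryReport:
    """Generator x analyzer crossover on the demo design.

    MG1/MA1 use only the first design column (true beta_1 from
    ``true_params``); MG2/MA2 use both columns. Each generator's
    realizations are analyzed under both models with all four techniques;
    per generator and method, realizations whose lambda estimates are
    Grubbs outliers under either analysis model (or whose fits failed) are
    excluded from the cell means so both cells average identical sets.
    """
    X1 = spec.X[:, :1]
    spec1 = GLMSpec(X1, spec.Q)
    analyzers = {"MA1": spec1, "MA2": spec}
    gen_params = {
        "MG1": TrueParams(true_params.beta[:1], true_params.lam),
        "MG2": true_params,
    }
    k = spec.k
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_real).reshape(2, n_real)

    rows = []
    for gi, (gname, params) in enumerate(gen_params.items()):
        gspec = spec1 if gname == "MG1" else spec
        for r in range(n_real):
            y = simulate_glm(gspec, params, int(seeds[gi, r]))
            for aname, aspec in analyzers.items():
                fits = fit_all_methods(
                    y, aspec, PriorSpec.imprecise(aspec.p, k),
                    PriorSpec.imprecise(aspec.p), np.zeros(k), options=options)
                for method, fit in fits.items():
                    row = _collect_row(method, r, fit)
                    row.update(generator=gname, analyzer=aname)
                    rows.append(row)
    fe = pd.DataFrame(rows)

    lam_cols = [f"lam_{j}" for j in range(1, k + 1)]
    cell_rows, win_rows = [], []
    for gname in gen_params:
        matched = "MA1" if gname == "MG1" else "MA2"
        other = "MA2" if matched == "MA1" else "MA1"
        for method in METHODS:
            sub = fe[(fe.generator == gname) & (fe.method == method)]
            keep = np.ones(n_real, dtype=bool)
            for aname in analyzers:
                a = sub[sub.analyzer == aname].sort_values("realization")
                lam = a[lam_cols].to_numpy()
                for j in range(k):
                    keep &= ~grubbs_outliers(lam[:, j], grubbs_alpha)
                keep &= a["converged"].to_numpy()
            Fm = {aname: sub[sub.analyzer == aname].sort_values("realization")
                  ["free_energy"].to_numpy() for aname in analyzers}
            for aname in analyzers:
                cell_rows.append({"generator": gname, "method": method,
                                  "analyzer": aname,
                                  "mean_F": float(Fm[aname][keep].mean()),
                                  "n_kept": int(keep.sum())})
            win_rows.append({"generator": gname, "method": method,
                             "wins": int(np.sum(Fm[matched][keep] > Fm[other][keep])),
                             "n_kept": int(keep.sum())})

    return ModelRecoveryReport(pd.DataFrame(cell_rows), fe, pd.DataFrame(win_rows))


# ---------------------------------------------------------------------------
# estimation-quality divergence
# ---------------------------------------------------------------------------

def summarize_rmse_bias(estimates, truth):
    """Mean Euclidean error norm and per-component mean bias.

    The RMSE here is the average of ||theta_hat - theta||_2 over
    realizations (the mean error norm, not the root of the mean squared
    norm).
    """
    est = np.atleast_2d(np.asarray(estimates, float))
    truth = np.atleast_1d(np.asarray(truth, float))
    err = est - truth[None, :]
    rmse = float(np.mean(np.linalg.norm(err, axis=1)))
    bias = err.mean(axis=0)
    return rmse, bias


def table1_priors(scenario: str):
    """Priors/initializations of the two divergence scenarios.

    ``"effect"``: the first effect size carries a precise prior (variance
    1e-2) centered at its true value 1, the second an imprecise one
    (variance 10) centered at 0; lambda initialized at (-1, -1).
    ``"covariance"``: imprecise zero-mean beta priors; VB's lambda prior is
    N((-1, -1), 10 I).
    Returns ``(vb_prior, vml_prior, lam_init, beta_init)``.
    """
    lam_init = np.array([-1.0, -1.0])
    if scenario == "effect":
        mu_b = np.array([1.0, 0.0])
        S_b = np.diag([1e-2, 1e1])
    elif scenario == "covariance":
        mu_b = np.zeros(2)
        S_b = 10.0 * np.eye(2)
    else:
        raise ValueError("scenario must be 'effect' or 'covariance'")
    vb_prior = PriorSpec(mu_b, S_b, lam_init.copy(), 10.0 * np.eye(2))
    vml_prior = PriorSpec(mu_b, S_b)
    return vb_prior, vml_prior, lam_init, mu_b.copy()


@dataclass
class DivergenceReport:
    """RMSE/bias per noise-grid point and method, plus the raw estimates."""

    summary: pd.DataFrame       # lam1, method, block, rmse, bias_1, bias_2
    estimates: pd.DataFrame
    scenario: str

    def rmse(self, lam1: float, method: str) -> float:
        m = self.summary
        row = m[(m.method == method) & (np.isclose(m.lam1, lam1))]
        return float(row["rmse"].iloc[0])

    def bias(self, lam1: float, method: str) -> np.ndarray:
        m = self.summary
        row = m[(m.method == method) & (np.isclose(m.lam1, lam1))]
        return row[[c for c in m.columns if c.startswith("bias_")]].to_numpy()[0]


def divergence_experiment(grid, scenario: str, n_real: int, spec: GLMSpec,
                          seed: int, options: FitOptions | None = None) -> DivergenceReport:
    """RMSE/bias of the four techniques over a noise-level grid.

    True beta = (1, 1) and lambda_2 = -2 throughout; lambda_1 sweeps
    ``grid``. The ``"effect"`` scenario summarizes the beta block, the
    ``"covariance"`` scenario the lambda block. No outlier screening is
    applied.
    """
    vb_prior, vml_prior, lam_init, beta_init = table1_priors(scenario)
    block = "beta" if scenario == "effect" else "lam"
    truth_beta = np.array([1.0, 1.0])
    grid = np.atleast_1d(np.asarray(grid, float))
    seeds = np.random.SeedSequence(seed).generate_state(len(grid) * n_real)
    seeds = seeds.reshape(len(grid), n_real)

    rows = []
    for gi, lam1 in enumerate(grid):
        truth_lam = np.array([lam1, -2.0])
        params = TrueParams(truth_beta, truth_lam)
        for r in range(n_real):
            y = simulate_glm(spec, params, int(seeds[gi, r]))
            fits = fit_all_methods(y, spec, vb_prior, vml_prior, lam_init,
                                   beta_init=beta_init, options=options)
            for method, fit in fits.items():
                row = _collect_row(method, r, fit)
                row["lam1"] = float(lam1)
                rows.append(row)
    estimates = pd.DataFrame(rows)

    summary_rows = []
    cols = [f"{block}_{j}" for j in (1, 2)]
    for lam1 in grid:
        truth = truth_beta if block == "beta" else np.array([lam1, -2.0])
        for method in METHODS:
            sub = estimates[(estimates.method == method)
                            & np.isclose(estimates.lam1, lam1)]
            rmse, bias = summarize_rmse_bias(sub[cols].to_numpy(), truth)
            summary_rows.append({"lam1": float(lam1), "method": method,
                                 "block": block, "rmse": rmse,
                                 "bias_1": float(bias[0]),
                                 "bias_2": float(bias[1])})
    return DivergenceReport(pd.DataFrame(summary_rows), estimates, scenario)
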