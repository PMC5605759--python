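"""Configuration-driven runners behind the command line.

These functions are pure plumbing: they read delimited-text inputs, call the
library estimators, and shape the outputs into tables — a ``run_*`` call
returns exactly what the corresponding library calls produce.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import io as vio
from .estimators import (
    FitOptions,
    PriorSpec,
    VariationalState,
    exceedance_probability,
    ml_fit,
    reml_fit,
    vb_fit,
    vml_fit,
)
from .model import (
    FIXTURE_BETA,
    FIXTURE_LAMBDA,
    DesignConfig,
    GLMSpec,
    TrueParams,
    build_covariance_basis,
    build_design_matrix,
    simulate_glm,
)

__all__ = ["load_spec", "run_fit", "run_maps", "make_fixtures", "validate_config"]

_METHODS = ("vb", "vml", "reml", "ml")


def validate_config(cfg: dict) -> dict:
    """Check the minimal schema of a fit/maps configuration.

    Required: ``method`` in {vb, vml, reml, ml}; ``paths.y`` and
    ``paths.design``; for vb/vml a ``prior`` with ``mu_beta``/``Sigma_beta``
    (vb additionally ``mu_lam``/``Sigma_lam``). Raises ValueError naming the
    offending key.
    """
    method = cfg.get("method")
    if method not in _METHODS:
        raise ValueError(f"config key 'method' must be one of {_METHODS}, got {method!r}")
    paths = cfg.get("paths") or {}
    for key in ("y", "design"):
        if key not in paths:
            raise ValueError(f"config key 'paths.{key}' is missing")
    if method in ("vb", "vml"):
        prior = cfg.get("prior") or {}
        need = ["mu_beta", "Sigma_beta"] + (["mu_lam", "Sigma_lam"] if method == "vb" else [])
        for key in need:
            if key not in prior:
                raise ValueError(f"config key 'prior.{key}' is required for method {method}")
    return cfg


def load_spec(cfg: dict) -> tuple:
    """Load (Y, GLMSpec) from the paths section of a configuration."""
    paths = cfg["paths"]
    Y = vio.read_matrix(paths["y"])
    if Y.shape[0] == 1:
        Y = Y.T
    X = vio.read_matrix(paths["design"])
    if X.shape[1] > X.shape[0]:
        raise ValueError(
            f"design has p={X.shape[1]} > n={X.shape[0]}: rank-deficient model refused")
    if Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"paths.y has {Y.shape[0]} rows but paths.design has {X.shape[0]}")
    if paths.get("q"):
        Q = [vio.read_matrix(q) for q in paths["q"]]
    else:
        Q = build_covariance_basis(X.shape[0], float(paths.get("tau", 0.2)))
    return Y, GLMSpec(X, Q)


def _fit_options(cfg: dict) -> FitOptions:
    opts = dict(cfg.get("options") or {})
    return FitOptions(**opts)


def _fit_one(y, spec, cfg: dict):
    method = cfg["method"]
    options = _fit_options(cfg)
    prior_cfg = cfg.get("prior") or {}
    init = cfg.get("init") or {}
    lam_init = np.asarray(init.get("lam", np.zeros(spec.k)), float)
    beta_init = np.asarray(init.get("beta", np.zeros(spec.p)), float)
    if method == "vb":
        prior = PriorSpec(prior_cfg["mu_beta"], prior_cfg["Sigma_beta"],
                          prior_cfg["mu_lam"], prior_cfg["Sigma_lam"])
        return vb_fit(y, spec, prior, options)
    if method == "vml":
        prior = PriorSpec(prior_cfg["mu_beta"], prior_cfg["Sigma_beta"])
        return vml_fit(y, spec, prior, lam_init, options)
    if method == "reml":
        init_state = None
        if "beta" in init or "S_beta" in init:
            init_state = VariationalState(
                beta_init, np.asarray(init.get("S_beta", np.eye(spec.p)), float))
        return reml_fit(y, spec, lam_init, init_state=init_state, options=options)
    return ml_fit(y, spec, beta_init, lam_init, options)


def run_fit(cfg: dict):
    """Fit every series (column) of paths.y with the configured method.

    Returns ``(fits, table)``: the FitResult list and a per-series estimate
    table with expectations, uncertainty diagonals (where the method
    provides them), free energy, iteration count, and convergence flag.
    """
    validate_config(cfg)
    Y, spec = load_spec(cfg)
    fits, rows = [], []
    for i in range(Y.shape[1]):
        fit = _fit_one(Y[:, i], spec, cfg)
        fits.append(fit)
        row = {"series": i, "method": fit.method, "converged": fit.converged,
               "n_iter": fit.n_iter, "free_energy": fit.free_energy}
        for j, b in enumerate(np.atleast_1d(fit.state.m_beta), 1):
            row[f"beta_{j}"] = float(b)
        for j, l in enumerate(np.atleast_1d(fit.state.m_lam), 1):
            row[f"lam_{j}"] = float(l)
        if fit.state.S_beta is not None:
            for j, v in enumerate(np.diag(fit.state.S_beta), 1):
                row[f"var_beta_{j}"] = float(v)
        if fit.state.S_lam is not None:
            for j, v in enumerate(np.diag(fit.state.S_lam), 1):
                row[f"var_lam_{j}"] = float(v)
        rows.append(row)
    return fits, pd.DataFrame(rows)


def run_maps(cfg: dict):
    """Posterior exceedance-probability table over series.

    The ``maps`` section selects ``parameter`` ("beta" or "lam"), the
    1-based ``component``, and the threshold ``eta``. Methods without an
    uncertainty quantification for the requested block are refused
    (lambda maps exist only under VB; beta maps not under ML).
    """
    maps_cfg = cfg.get("maps") or {}
    parameter = maps_cfg.get("parameter", "beta")
    component = int(maps_cfg.get("component", 1))
    eta = float(maps_cfg.get("eta", 0.0))
    method = cfg.get("method")
    if parameter == "lam" and method != "vb":
        raise ValueError(
            f"lambda exceedance maps require posterior lambda uncertainty: "
            f"not applicable under method {method!r} (VB only)")
    if parameter == "beta" and method == "ml":
        raise ValueError(
            "beta exceedance maps are not applicable under ML "
            "(no posterior beta uncertainty)")
    fits, _ = run_fit(cfg)
    rows = []
    for i, fit in enumerate(fits):
        if parameter == "beta":
            m = float(np.atleast_1d(fit.state.m_beta)[component - 1])
            s = float(np.diag(fit.state.S_beta)[component - 1])
        else:
            m = float(np.atleast_1d(fit.state.m_lam)[component - 1])
            s = float(np.diag(fit.state.S_lam)[component - 1])
        rows.append({"series": i, "parameter": f"{parameter}_{component}",
                     "eta": eta, "m": m, "s": s,
                     "p_exceed": float(exceedance_probability(m, s, eta))})
    return pd.DataFrame(rows)


def make_fixtures(seed: int, outdir: str) -> dict:
    """Write the demo-model fixture bundle.

    The bundle holds the 400 x 2 design (TR 2 s, two conditions), the
    [I, Toeplitz(tau=0.2)] basis, one simulated series with beta = (2, -1),
    lambda = (-0.5, -2), and ready-to-run configurations for all four
    methods (delta = 1e-3, imprecise 10 I priors, lambda init 0).
    """
    import os

    vio.ensure_dir(outdir)
    path = lambda name: os.path.join(outdir, name)
    config = DesignConfig()
    X, onsets = build_design_matrix(config, seed=seed)
    Q = build_covariance_basis(config.n_scans, tau=0.2)
    spec = GLMSpec(X, Q)
    y = simulate_glm(spec, TrueParams(FIXTURE_BETA, FIXTURE_LAMBDA), seed=seed + 1)

    vio.write_matrix(path("X.csv"), X)
    vio.write_matrix(path("Q1.csv"), Q[0])
    vio.write_matrix(path("Q2.csv"), Q[1])
    vio.write_matrix(path("y.csv"), y.reshape(-1, 1))
    vio.write_onsets(path("onsets.csv"), onsets)

    eye2 = np.eye(2)
    base_paths = {"y": path("y.csv"), "design": path("X.csv"),
                  "q": [path("Q1.csv"), path("Q2.csv")]}
    prior10 = {"mu_beta": [0.0, 0.0], "Sigma_beta": (10.0 * eye2).tolist()}
    prior_lam = {"mu_lam": [0.0, 0.0], "Sigma_lam": (10.0 * eye2).tolist()}
    options = {"delta": 1e-3, "max_iter": 64}
    configs = {
        "vb": {"method": "vb", "paths": base_paths,
               "prior": {**prior10, **prior_lam}, "options": options, "seed": seed},
        "vml": {"method": "vml", "paths": base_paths, "prior": prior10,
                "init": {"lam": [0.0, 0.0]}, "options": options, "seed": seed},
        "reml": {"method": "reml", "paths": base_paths,
                 "init": {"lam": [0.0, 0.0], "beta": [0.0, 0.0],
                          "S_beta": (10.0 * eye2).tolist()},
                 "options": options, "seed": seed},
        "ml": {"method": "ml", "paths": base_paths,
               "init": {"lam": [0.0, 0.0], "beta": [0.0, 0.0]},
               "options": options, "seed": seed},
    }
    files = {}
    for name, cfg in configs.items():
        validate_config(cfg)
        cfg_path = path(f"config_{name}.yaml")
        vio.write_config(cfg_path, cfg)
        files[name] = cfg_path
    return files
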