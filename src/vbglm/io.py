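"""Delimited-text I/O and configuration handling.

Matrices travel as comma-separated values without header, rows = scans,
serialized with 17 significant digits so that write/read round-trips are
numerically exact. Onset tables carry a header (condition, onset_s,
duration_s). Configurations are YAML documents.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_onsets",
    "read_onsets",
    "write_config",
    "read_config",
    "write_fit_report",
]

_FMT = "%.17g"


def write_matrix(path, arr) -> None:
    """Write a vector/matrix as headerless CSV at 17 significant digits."""
    np.savetxt(path, np.atleast_2d(np.asarray(arr, float)), fmt=_FMT, delimiter=",")


def read_matrix(path, ndmin: int = 2) -> np.ndarray:
    """Read a headerless CSV matrix."""
    return np.loadtxt(path, delimiter=",", ndmin=ndmin)


def write_onsets(path, onsets: pd.DataFrame) -> None:
    onsets.to_csv(path, index=False, float_format=_FMT)


def read_onsets(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(config), fh, sort_keys=False)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration file {path} does not hold a mapping")
    return cfg


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_fit_report(path, results: list) -> None:
    """Serialize FitResults as a structured YAML report (one entry per
    series): estimates, uncertainty diagonals, free-energy trace, iteration
    count and convergence flag."""
    report = []
    for i, fit in enumerate(results):
        entry = {
            "series": i,
            "method": fit.method,
            "converged": bool(fit.converged),
            "n_iter": int(fit.n_iter),
            "free_energy": float(fit.free_energy),
            "free_energy_trace": [float(f) for f in fit.free_energy_trace],
            "beta": [float(b) for b in np.atleast_1d(fit.state.m_beta)],
            "lam": [float(l) for l in np.atleast_1d(fit.state.m_lam)],
        }
        if fit.state.S_beta is not None:
            entry["var_beta"] = [float(v) for v in np.diag(fit.state.S_beta)]
        if fit.state.S_lam is not None:
            entry["var_lam"] = [float(v) for v in np.diag(fit.state.S_lam)]
        report.append(entry)
    write_config(path, {"fits": report})


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return path
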