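"""GLM with linearly decomposable error covariance: model containers,
design-matrix construction and data simulation.

The model is the standard first-level fMRI time-series GLM

    y = X beta + eps,    eps ~ N(0, V_lambda),
    V_lambda = sum_i exp(lambda_i) Q_i,

where ``X`` is built by convolving condition onset stick functions with the
canonical double-gamma hemodynamic response at micro-time resolution and
downsampling to the scan grid, and the covariance basis ``{Q_1, Q_2}``
encodes white noise plus exponentially decaying serial correlations
(the common AR(1)+white-noise approximation, decay constant ``tau``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from ._linalg import NotPositiveDefiniteError, safe_cholesky, sym

__all__ = [
    "GLMSpec",
    "DesignConfig",
    "TrueParams",
    "CovarianceModel",
    "RankDeficientDesignError",
    "canonical_hrf",
    "build_covariance_basis",
    "assemble_covariance",
    "build_design_matrix",
    "simulate_glm",
    "fixture_spec",
    "FIXTURE_BETA",
    "FIXTURE_LAMBDA",
]

#: Demo model used throughout: two conditions, n = 400 scans, TR = 2 s,
#: tau = 0.2, true beta = (2, -1), true lambda = (-0.5, -2), no offset column.
FIXTURE_BETA = np.array([2.0, -1.0])
FIXTURE_LAMBDA = np.array([-0.5, -2.0])


class RankDeficientDesignError(ValueError):
    """Raised when a constructed design matrix is not of full column rank."""


@dataclass(frozen=True)
class GLMSpec:
    """Design matrix and covariance basis of one GLM instance.

    Attributes
    ----------
    X : (n, p) design matrix, full column rank.
    Q : ordered list of k symmetric (n, n) covariance basis matrices.
    """

    X: np.ndarray
    Q: list

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Q", [np.asarray(q, dtype=float) for q in self.Q])
        n, p = X.shape
        if p > n:
            raise ValueError(f"design has more columns (p={p}) than rows (n={n})")
        if np.linalg.matrix_rank(X) < p:
            raise RankDeficientDesignError("design matrix is rank-deficient")
        if len(self.Q) < 1:
            raise ValueError("at least one covariance basis matrix is required")
        for i, q in enumerate(self.Q):
            if q.shape != (n, n):
                raise ValueError(f"Q[{i}] has shape {q.shape}, expected {(n, n)}")
            if not np.allclose(q, q.T, atol=1e-12):
                raise ValueError(f"Q[{i}] is not symmetric")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def k(self) -> int:
        return len(self.Q)


@dataclass(frozen=True)
class DesignConfig:
    """Configuration of the event-related design simulator.

    ``iti_mean``/``iti_sd`` parameterize the Gaussian inter-trial gaps
    (seconds, truncated below at ``iti_floor``); the hemodynamic response is
    evaluated on a micro-time grid of ``microtime_bins`` bins per TR.
    """

    n_scans: int = 400
    TR: float = 2.0
    conditions: tuple = ("cond1", "cond2")
    iti_mean: float = 6.0
    iti_sd: float = 1.0
    microtime_bins: int = 16
    include_offset: bool = False
    iti_floor: float = 1.0
    #: double-gamma parameters: (peak delay, undershoot delay, peak
    #: dispersion, undershoot dispersion, peak:undershoot ratio, length s)
    hrf_params: tuple = (6.0, 16.0, 1.0, 1.0, 6.0, 32.0)

    def __post_init__(self):
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if not (self.iti_mean > self.iti_sd >= 0):
            raise ValueError("require iti_mean > iti_sd >= 0")
        if self.microtime_bins < 1:
            raise ValueError("microtime_bins must be >= 1")


@dataclass(frozen=True)
class TrueParams:
    """Ground-truth effect sizes beta and log covariance scalings lambda."""

    beta: np.ndarray
    lam: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, float)))
        object.__setattr__(self, "lam", np.atleast_1d(np.asarray(self.lam, float)))


@dataclass(frozen=True)
class CovarianceModel:
    """Decay constant of the serial-correlation basis and its dimension."""

    tau: float = 0.2
    n: int = 400

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def basis(self) -> list:
        return build_covariance_basis(self.n, self.tau)


def canonical_hrf(dt: float, params: tuple = (6.0, 16.0, 1.0, 1.0, 6.0, 32.0)) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at resolution dt.

    The kernel is the difference of two gamma densities (response peaking at
    ~6 s minus an undershoot peaking at ~16 s, scaled by 1/ratio), normalized
    to unit peak so that regression amplitudes are in signal units.
    """
    peak_delay, under_delay, peak_disp, under_disp, ratio, length = params
    t = np.arange(0.0, length + dt / 2, dt)
    h = st.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp) \
        - st.gamma.pdf(t, under_delay / under_disp, scale=under_disp) / ratio
    return h / np.max(h)


def build_covariance_basis(n: int, tau: float = 0.2) -> list:
    """Covariance basis [Q_1, Q_2] with Q_1 = I_n, (Q_2)_ij = exp(-|i-j|/tau).

    ``tau`` is the decay constant of the serial-correlation component in
    units of the scan index; the default 0.2 is the conventional
    AR(1)+white-noise approximation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if tau <= 0:
        raise ValueError("tau must be positive")
    idx = np.arange(n)
    q2 = np.exp(-np.abs(idx[:, None] - idx[None, :]) / tau)
    return [np.eye(n), q2]


def assemble_covariance(lam: np.ndarray, Q: list, require_pd: bool = False):
    """Assemble V_lambda = sum_i exp(lam_i) Q_i.

    Returns ``(V, pd_flag)``; with ``require_pd=True`` a factorization
    failure raises :class:`NotPositiveDefiniteError` instead of flagging.
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if len(lam) != len(Q):
        raise ValueError(f"lam has length {len(lam)} but {len(Q)} basis matrices given")
    V = sym(sum(np.exp(li) * Qi for li, Qi in zip(lam, Q)))
    try:
        safe_cholesky(V, "V_lambda")
        pd_flag = True
    except NotPositiveDefiniteError:
        if require_pd:
            raise
        pd_flag = False
    return V, pd_flag


def _draw_onsets(rng: np.random.Generator, config: DesignConfig) -> np.ndarray:
    """Onset times (s) of one condition: cumulative truncated-Gaussian gaps.

    Onsets are quantized to a fixed grid of TR/16 so that the discretized
    convolution is independent of micro-time refinements beyond 16 bins.
    """
    duration = config.n_scans * config.TR
    grid = config.TR / 16.0
    onsets = []
    t = 0.0
    while True:
        gap = max(rng.normal(config.iti_mean, config.iti_sd), config.iti_floor)
        t += gap
        if t >= duration:
            break
        onsets.append(round(t / grid) * grid)
    return np.asarray(onsets)


def build_design_matrix(config: DesignConfig, seed: int):
    """Simulate an event-related design matrix.

    Per condition, onsets are drawn with Gaussian inter-trial gaps, placed as
    stick functions on a micro-time grid of ``TR / microtime_bins``,
    convolved with the canonical HRF and downsampled to one value per scan.
    Columns are ordered [conditions..., optional constant offset].

    Returns
    -------
    (X, onsets) : the (n_scans, p) design matrix and a tidy onset table with
        columns ``condition``, ``onset_s``, ``duration_s``.
    """
    rng = np.random.default_rng(seed)
    dt = config.TR / config.microtime_bins
    n_micro = config.n_scans * config.microtime_bins
    hrf = canonical_hrf(dt, config.hrf_params)

    cols = []
    rows = []
    for cond in config.conditions:
        onsets = _draw_onsets(rng, config)
        sticks = np.zeros(n_micro)
        for t in onsets:
            i = int(round(t / dt))
            if i < n_micro:
                sticks[i] = 1.0
            rows.append({"condition": cond, "onset_s": t, "duration_s": 0.0})
        reg = np.convolve(sticks, hrf)[:n_micro]
        cols.append(reg[:: config.microtime_bins])
    if config.include_offset:
        cols.append(np.ones(config.n_scans))

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientDesignError(
            "constructed design is rank-deficient (e.g. a condition without events)"
        )
    onset_table = pd.DataFrame(rows, columns=["condition", "onset_s", "duration_s"])
    return X, onset_table


def simulate_glm(spec: GLMSpec, params: TrueParams, seed: int) -> np.ndarray:
    """Draw one data realization y = X beta + eps, eps ~ N(0, V_lambda).

    The noise is generated through the lower Cholesky factor of V_lambda;
    identical seeds give bit-identical output.
    """
    if len(params.beta) != spec.p:
        raise ValueError("beta length does not match design columns")
    V, _ = assemble_covariance(params.lam, spec.Q, require_pd=True)
    L = safe_cholesky(V, "V_lambda")
    rng = np.random.default_rng(seed)
    eps = L @ rng.standard_normal(spec.n)
    return spec.X @ params.beta + eps


def fixture_spec(seed: int = 2017, n_scans: int = 400, tau: float = 0.2) -> GLMSpec:
    """The demo model: 400-scan, TR 2 s, two-condition design, k = 2 basis."""
    config = DesignConfig(n_scans=n_scans)
    X, _ = build_design_matrix(config, seed=seed)
    return GLMSpec(X=X, Q=build_covariance_basis(n_scans, tau))
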