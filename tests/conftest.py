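import numpy as np
import pytest

from vbglm import (
    FIXTURE_BETA,
    FIXTURE_LAMBDA,
    GLMSpec,
    TrueParams,
    build_covariance_basis,
    fixture_spec,
    simulate_glm,
)

#: seed of the shipped demo realization used across the suite
FIXTURE_SEED = 1
DESIGN_SEED = 2017


@pytest.fixture(scope="session")
def spec400():
    """The demo model: 400-scan two-condition design, [I, Toeplitz] basis."""
    return fixture_spec(seed=DESIGN_SEED)


@pytest.fixture(scope="session")
def true_params():
    return TrueParams(FIXTURE_BETA, FIXTURE_LAMBDA)


@pytest.fixture(scope="session")
def fixture_y(spec400, true_params):
    """One data realization of the demo model (the shipped seed)."""
    return simulate_glm(spec400, true_params, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def small_spec():
    """A small (n=80) version of the demo model for fast iteration tests."""
    return fixture_spec(seed=DESIGN_SEED, n_scans=80)


@pytest.fixture(scope="session")
def tiny_noncommuting_spec():
    """n=12, k=3 GLM whose basis matrices do not commute (exercises the
    dense linear-algebra path; two random p.s.d. components beside I)."""
    rng = np.random.default_rng(5)
    n, p = 12, 2
    X = rng.standard_normal((n, p))
    Q = [np.eye(n)]
    for _ in range(2):
        R = rng.standard_normal((n, n))
        Q.append(R @ R.T / n)
    return GLMSpec(X, Q)


@pytest.fixture(scope="session")
def tiny_commuting_spec():
    """n=12 GLM with the standard commuting [I, Toeplitz] basis (fast path)."""
    rng = np.random.default_rng(6)
    X = rng.standard_normal((12, 2))
    return GLMSpec(X, build_covariance_basis(12, tau=0.8))
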