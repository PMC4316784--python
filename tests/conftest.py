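import math

import pytest

import primlearn as pl

THETA_TESTS = (0.0, math.pi / 12, math.pi / 6, math.pi / 4)
P = math.pi / 4


@pytest.fixture(scope="session")
def two_primitive_basis():
    """Tiny hand-checkable basis: PDs at 0 and pi/2, sigma = pi/4."""
    import numpy as np

    return pl.PrimitiveBasis(2, math.pi / 4, np.array([0.0, math.pi / 2]))


@pytest.fixture(scope="session")
def effort_params():
    return pl.default_params(pl.EFFORT_PRIMITIVE)


@pytest.fixture(scope="session")
def wd_params():
    return pl.default_params(pl.WEIGHT_DECAY_PRIMITIVE)


@pytest.fixture(scope="session")
def ss_params():
    return pl.default_params(pl.STATE_SPACE_EFFORT)


@pytest.fixture(scope="session")
def sim1_effort_traces(effort_params):
    """Effort-primitive simulation-1 runs, one per tested direction,
    sharing one basis."""
    return {
        th: pl.run(pl.EFFORT_PRIMITIVE, effort_params,
                   pl.build_simulation1(th, P), basis_seed=2)
        for th in THETA_TESTS
    }


@pytest.fixture(scope="session")
def sim1_wd_traces(wd_params):
    return {
        th: pl.run(pl.WEIGHT_DECAY_PRIMITIVE, wd_params,
                   pl.build_simulation1(th, P), basis_seed=2)
        for th in THETA_TESTS
    }


@pytest.fixture(scope="session")
def sim2_effort_ensemble(effort_params):
    """20-run cycled-design ensemble, reference parameters."""
    return pl.run_ensemble(
        pl.EFFORT_PRIMITIVE, effort_params,
        lambda s: pl.build_simulation2(16, P, s),
        n_runs=20, base_seed=2024,
    )


@pytest.fixture(scope="session")
def sim2_effort_sensitivity_ensemble():
    """Sensitivity pair: eta = 0.8 with per-trial effort product 0.01."""
    params = pl.LearnerParams(eta=0.8, lambda1=0.0, lambda2=0.01 / 0.8)
    return pl.run_ensemble(
        pl.EFFORT_PRIMITIVE, params,
        lambda s: pl.build_simulation2(16, P, s),
        n_runs=20, base_seed=2025,
    )


@pytest.fixture(scope="session")
def sim2_wd_trace(wd_params):
    return pl.run(pl.WEIGHT_DECAY_PRIMITIVE, wd_params,
                  pl.build_simulation2(16, P, 5), basis_seed=5)


@pytest.fixture(scope="session")
def sim2_ss_trace(ss_params):
    return pl.run(pl.STATE_SPACE_EFFORT, ss_params,
                  pl.build_simulation2(16, P, 5))
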