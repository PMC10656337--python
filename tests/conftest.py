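"""Shared fixtures: the identifiability toy example and session-scoped
replication studies reused by several test modules (they are the expensive
part of the suite, so they are computed once)."""

from __future__ import annotations

import numpy as np
import pytest

import difml1 as dm


@pytest.fixture(scope="session")
def quad21() -> dm.QuadratureSpec:
    """Desk-scale quadrature; indistinguishable from the 31-node default here."""
    return dm.QuadratureSpec(21)


@pytest.fixture()
def fig_toy():
    """J=10 one-parameter toy: eight DIF-free items, two with gamma = 1."""
    return np.array([0.0] * 8 + [1.0, 1.0]), np.ones(10)


def _null_params(d_regime: str = "small") -> dm.ModelParams:
    return dm.ModelParams(beta=0.5, sigma2=0.25, a=dm.DISCRIMINATION,
                          d=dm.EASINESS[d_regime], gamma=np.zeros(25))


@pytest.fixture(scope="session")
def null_params() -> dm.ModelParams:
    return _null_params()


def simulate_from_params(params: dm.ModelParams, n: int, seed) -> dm.ResponseData:
    """Draw a dataset from explicit parameters (equal group split)."""
    rng = np.random.default_rng(seed)
    n_ref = n // 2
    groups = np.concatenate([np.zeros(n_ref, dtype=np.int8),
                             np.ones(n - n_ref, dtype=np.int8)])
    theta = np.concatenate([
        rng.standard_normal(n_ref),
        params.beta + params.sigma * rng.standard_normal(n - n_ref),
    ])
    prob = dm.irf_prob(params.a[None, :], params.d[None, :],
                       params.gamma[None, :], theta[:, None], groups[:, None])
    return dm.ResponseData((rng.random((n, params.n_items)) < prob)
                           .astype(np.int8), groups)


@pytest.fixture(scope="session")
def study500(quad21) -> dm.MetricsTable:
    """50 replications of the N=500 / small-d / small-DIF / high design with
    full bootstrap inference (M=2000), the 1-anchor LRT, and 5-anchor Wald
    intervals."""
    return dm.run_study([dm.SimSetting(N=500)], n_reps=50,
                        methods=("proposed", "lrt-1", "wald-5"), M=2000,
                        master_seed=20, quad=quad21, keep_raw=True)


@pytest.fixture(scope="session")
def study1000(quad21) -> dm.MetricsTable:
    """50 replications of the N=1000 / small-d / small-DIF / high design."""
    return dm.run_study([dm.SimSetting(N=1000)], n_reps=50,
                        methods=("proposed",), M=2000, master_seed=21,
                        quad=quad21, keep_raw=True)


@pytest.fixture(scope="session")
def entry500(study500):
    return study500.per_setting[dm.SimSetting(N=500).label]


@pytest.fixture(scope="session")
def entry1000(study1000):
    return study1000.per_setting[dm.SimSetting(N=1000).label]
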