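"""MIMIC 2PL measurement/structural model: containers, response function, marginal likelihood.

The model couples a two-parameter logistic (2PL) measurement model with uniform
(intercept-only) differential item functioning (DIF),

    P(Y_ij = 1 | theta, x_i) = logistic(a_j * theta + d_j + gamma_j * x_i),

with a normal structural model for the latent trait: theta | x=0 ~ N(0, 1) for the
reference group and theta | x=1 ~ N(beta, sigma^2) for the focal group.  exp(gamma_j)
is the odds ratio comparing focal vs. reference respondents at equal trait level;
item j is DIF-free when gamma_j = 0.

The latent trait is always integrated out; the marginal log-likelihood is evaluated
with fixed Gauss-Hermite quadrature after the substitution theta = mu_g + sqrt(2) *
s_g * t for each group.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp

__all__ = [
    "ResponseData",
    "ModelParams",
    "QuadratureSpec",
    "irf_prob",
    "marginal_loglik",
]

_SQRT2 = np.sqrt(2.0)
_SQRTPI = np.sqrt(np.pi)


@dataclass(frozen=True)
class ResponseData:
    """Binary item responses with a two-group membership indicator.

    Parameters
    ----------
    responses
        N x J matrix with entries in {0, 1}.
    groups
        Length-N vector with entries in {0, 1}; 0 is the reference group,
        1 the focal group.
    item_names
        Optional item labels (length J), preserved for reporting.
    """

    responses: np.ndarray
    groups: np.ndarray
    item_names: tuple[str, ...] | None = None

    def __post_init__(self):
        resp = np.asarray(self.responses)
        grp = np.asarray(self.groups)
        if resp.ndim != 2:
            raise ValueError("responses must be a 2-D (N x J) array")
        if grp.ndim != 1 or grp.shape[0] != resp.shape[0]:
            raise ValueError("groups must be a length-N vector matching responses")
        if resp.shape[0] < 1:
            raise ValueError("need at least one respondent")
        if not np.isin(resp, (0, 1)).all():
            raise ValueError("every response entry must be exactly 0 or 1")
        if not np.isin(grp, (0, 1)).all():
            raise ValueError("every group label must be exactly 0 or 1")
        object.__setattr__(self, "responses", resp.astype(np.int8))
        object.__setattr__(self, "groups", grp.astype(np.int8))
        if self.item_names is not None:
            names = tuple(str(s) for s in self.item_names)
            if len(names) != resp.shape[1]:
                raise ValueError("item_names length must equal number of items")
            object.__setattr__(self, "item_names", names)

    @property
    def n_respondents(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def check_fittable(self) -> None:
        """Raise unless the data support maximum-likelihood fitting.

        Fitting requires J >= 3 (the location shift is the only indeterminacy
        then), at least one respondent in each group, and no constant item
        column.
        """
        if self.n_items < 3:
            raise ValueError("fitting requires at least 3 items")
        n_focal = int(self.groups.sum())
        if n_focal == 0 or n_focal == self.n_respondents:
            raise ValueError("fitting requires at least one respondent per group")
        means = self.responses.mean(axis=0)
        bad = np.where((means == 0.0) | (means == 1.0))[0]
        if bad.size:
            labels = [self.item_names[j] if self.item_names else str(j + 1) for j in bad]
            raise ValueError(
                "constant item column(s) (all 0 or all 1): " + ", ".join(labels)
            )


@dataclass(frozen=True)
class ModelParams:
    """Full MIMIC parameter set {beta, sigma^2, a_j, d_j, gamma_j}.

    The reference-group latent distribution is fixed at N(0, 1) and is not a
    parameter.  ``sigma2`` is the focal-group latent variance (must be > 0).
    """

    beta: float
    sigma2: float
    a: np.ndarray
    d: np.ndarray
    gamma: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        d = np.asarray(self.d, dtype=float)
        g = np.asarray(self.gamma, dtype=float)
        if not (a.ndim == d.ndim == g.ndim == 1 and a.shape == d.shape == g.shape):
            raise ValueError("a, d, gamma must be 1-D vectors of equal length")
        for name, arr in (("a", a), ("d", d), ("gamma", g)):
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite entries in {name}")
        if not (np.isfinite(self.beta) and np.isfinite(self.sigma2)):
            raise ValueError("beta and sigma2 must be finite")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "gamma", g)
        object.__setattr__(self, "beta", float(self.beta))
        object.__setattr__(self, "sigma2", float(self.sigma2))

    @property
    def n_items(self) -> int:
        return self.a.shape[0]

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma2))


@functools.lru_cache(maxsize=16)
def _hermgauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.hermite.hermgauss(n)


@dataclass(frozen=True)
class QuadratureSpec:
    """Fixed Gauss-Hermite quadrature rule for integrating the latent trait."""

    n_nodes: int = 31
    rule: str = "gauss-hermite"

    def __post_init__(self):
        if self.rule != "gauss-hermite":
            raise ValueError("only the fixed gauss-hermite rule is supported")
        if self.n_nodes < 5:
            raise ValueError("n_nodes must be >= 5")
        t, w = _hermgauss(self.n_nodes)
        if abs(w.sum() / _SQRTPI - 1.0) > 1e-10:
            raise RuntimeError("quadrature weights fail the unit-mass check")

    @property
    def nodes(self) -> np.ndarray:
        return _hermgauss(self.n_nodes)[0]

    @property
    def log_weights(self) -> np.ndarray:
        """log of normalised weights, so that sum(exp(log_weights)) == 1."""
        return np.log(_hermgauss(self.n_nodes)[1]) - np.log(_SQRTPI)

    def theta_nodes(self, mu: float, s: float) -> np.ndarray:
        """Quadrature abscissae for a N(mu, s^2) latent distribution."""
        return mu + _SQRT2 * s * self.nodes


def irf_prob(a_j, d_j, gamma_j, theta, x):
    """Item response probability P(Y=1 | theta, x) under the 2PL-with-DIF model.

    Computed as logistic(a_j*theta + d_j + gamma_j*x) with an overflow-safe
    logistic; broadcasts over array arguments.
    """
    a_j, d_j, gamma_j, theta = (np.asarray(v, dtype=float) for v in (a_j, d_j, gamma_j, theta))
    x_arr = np.asarray(x)
    if not np.isin(x_arr, (0, 1)).all():
        raise ValueError("group label x must be 0 or 1")
    for v in (a_j, d_j, gamma_j, theta):
        if not np.isfinite(v).all():
            raise ValueError("irf_prob requires finite arguments")
    out = expit(a_j * theta + d_j + gamma_j * x_arr)
    if out.ndim == 0:
        return float(out)
    return out


def _log_pq(params: ModelParams, theta_nodes: np.ndarray, x: int):
    """(log p_jk, log (1-p_jk)) on the J x K grid for group x, overflow-safe."""
    eta = np.outer(params.a, theta_nodes) + (params.d + params.gamma * x)[:, None]
    log_p = -np.logaddexp(0.0, -eta)
    log_q = -np.logaddexp(0.0, eta)
    return log_p, log_q


def _per_respondent_loglik(params: ModelParams, data: ResponseData,
                           quad: QuadratureSpec) -> np.ndarray:
    """Marginal log-likelihood contribution of each respondent (length N)."""
    if params.n_items != data.n_items:
        raise ValueError("parameter and data item counts differ")
    out = np.empty(data.n_respondents)
    logw = quad.log_weights
    for x in (0, 1):
        mask = data.groups == x
        if not mask.any():
            continue
        mu, s = (params.beta, params.sigma) if x == 1 else (0.0, 1.0)
        theta_k = quad.theta_nodes(mu, s)
        log_p, log_q = _log_pq(params, theta_k, x)
        y = data.responses[mask].astype(float)
        # N_g x K conditional log-likelihood at each node, then log-sum-exp
        ll = y @ log_p + (1.0 - y) @ log_q
        out[mask] = logsumexp(ll + logw[None, :], axis=1)
    return out


def marginal_loglik(params: ModelParams, data: ResponseData,
                    quad: QuadratureSpec | None = None) -> float:
    """Marginal log-likelihood log L(Xi) with the latent trait integrated out.

    Deterministic for fixed inputs; always finite and <= 0 (a product of
    probabilities), accumulated in log space.
    """
    quad = quad or QuadratureSpec()
    val = float(_per_respondent_loglik(params, data, quad).sum())
    if not np.isfinite(val):
        raise FloatingPointError("marginal log-likelihood evaluated non-finite")
    return val
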