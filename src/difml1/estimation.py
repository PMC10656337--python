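"""Two-stage anchor-free estimation of the MIMIC 2PL model with DIF.

Stage 1 maximizes the Gauss-Hermite-approximated marginal log-likelihood over the
P = 3J + 1 free parameters with one DIF effect pinned to zero (gamma_1 = 0 by
default) to remove the location indeterminacy; the pinned item need not actually
be DIF-free, and the constraint costs no likelihood.  Stage 2 maps the constrained
MLE to its minimal-L1 representative via the exact weighted-median LAD solver.

The optimizer is quasi-Newton (L-BFGS-B) on the negative log-likelihood with
analytic gradients; sigma is optimized on the log scale for positivity.  The
scaled covariance of sqrt(N) * (Xi_tilde - Xi_dagger) is estimated as N times the
inverse observed information, with the information obtained by central finite
differences of the analytic score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp

from .ml1 import ml1_transform
from .model import ModelParams, QuadratureSpec, ResponseData, marginal_loglik

__all__ = [
    "FitOptions",
    "Stage1Fit",
    "Ml1Fit",
    "fit_constrained_mle",
    "fit_anchored_mle",
    "estimate_covariance",
    "fit_ml1",
]

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for the marginal-likelihood maximization.

    ``tol`` is the relative decrease of the objective below which L-BFGS-B
    stops; ``constraint_item`` is the 0-based index of the DIF effect pinned to
    zero in stage 1.
    """

    tol: float = 1e-10
    max_iter: int = 500
    constraint_item: int = 0


@dataclass
class Stage1Fit:
    """Constrained marginal MLE Xi_tilde with gamma fixed to 0 on `constrained`.

    ``sigma_hat`` (filled by :func:`estimate_covariance`) is the P x P scaled
    covariance of sqrt(N)(Xi_tilde - Xi_dagger) over the free parameters in the
    packing order (a_1..a_J, d_1..d_J, free gammas in item order, beta,
    log sigma).
    """

    params_tilde: ModelParams
    loglik: float
    converged: bool
    n_iter: int
    constrained: tuple[int, ...]
    n_respondents: int
    sigma_hat: np.ndarray | None = None

    @property
    def n_free(self) -> int:
        J = self.params_tilde.n_items
        return 2 * J + (J - len(self.constrained)) + 2


@dataclass
class Ml1Fit:
    """ML1-identified estimate Xi_hat = ml1_transform(Xi_tilde) and the shift."""

    params_hat: ModelParams
    shift: float
    stage1: Stage1Fit


class _Packer:
    """Pack/unpack the free-parameter vector [a, d, gamma_free, beta, log sigma]."""

    def __init__(self, n_items: int, constrained: tuple[int, ...]):
        if not constrained:
            raise ValueError("at least one gamma must be constrained to zero")
        if len(set(constrained)) != len(constrained):
            raise ValueError("duplicate constrained items")
        for j in constrained:
            if not 0 <= j < n_items:
                raise ValueError("constrained item index out of range")
        self.J = n_items
        self.constrained = tuple(sorted(constrained))
        self.free_gamma = np.array(
            [j for j in range(n_items) if j not in set(constrained)], dtype=int
        )
        self.n_free = 2 * n_items + self.free_gamma.size + 2

    def pack(self, params: ModelParams) -> np.ndarray:
        return np.concatenate([
            params.a,
            params.d,
            params.gamma[self.free_gamma],
            [params.beta, 0.5 * np.log(params.sigma2)],
        ])

    def unpack(self, x: np.ndarray) -> ModelParams:
        a, d, gfree, beta, logsig = self.split(x)
        gamma = np.zeros(self.J)
        gamma[self.free_gamma] = gfree
        return ModelParams(beta=beta, sigma2=np.exp(2.0 * logsig), a=a, d=d,
                           gamma=gamma)

    def split(self, x: np.ndarray):
        J = self.J
        nf = self.free_gamma.size
        return (x[:J], x[J:2 * J], x[2 * J:2 * J + nf], float(x[-2]), float(x[-1]))


class _NegLoglik:
    """Negative marginal log-likelihood and analytic gradient, vectorized.

    The per-respondent integrals collapse to matrix products: with posterior
    node weights pi_ik, the score in (a, d, gamma) needs only the node sums
    S_k = sum_i pi_ik and the posterior trait means T_i = sum_k pi_ik theta_k,
    so a full function-plus-gradient evaluation is O(N*K + N*J + J*K).
    """

    def __init__(self, data: ResponseData, quad: QuadratureSpec,
                 packer: _Packer):
        self.packer = packer
        self.t = quad.nodes
        self.logw = quad.log_weights
        self.Y = [
            data.responses[data.groups == x].astype(float) for x in (0, 1)
        ]
        self.Ysum = [y.sum(axis=0) for y in self.Y]

    def __call__(self, x: np.ndarray):
        a, d, gfree, beta, logsig = self.packer.split(x)
        sigma = np.exp(logsig)
        gamma = np.zeros(self.packer.J)
        gamma[self.packer.free_gamma] = gfree

        ll = 0.0
        ga = np.zeros((2, self.packer.J))
        gd = np.zeros((2, self.packer.J))
        for g in (0, 1):
            mu, s = (beta, sigma) if g == 1 else (0.0, 1.0)
            theta = mu + _SQRT2 * s * self.t
            eta = np.outer(a, theta) + (d + gamma * g)[:, None]
            log_p = -np.logaddexp(0.0, -eta)
            log_q = -np.logaddexp(0.0, eta)
            p = expit(eta)
            B = self.Y[g] @ (log_p - log_q) + log_q.sum(axis=0)[None, :] \
                + self.logw[None, :]
            li = logsumexp(B, axis=1)
            ll += li.sum()
            Pi = np.exp(B - li[:, None])
            S = Pi.sum(axis=0)
            T = Pi @ theta
            gd[g] = self.Ysum[g] - p @ S
            ga[g] = self.Y[g].T @ T - (p * theta[None, :]) @ S

        grad_a = ga[0] + ga[1]
        grad_d = gd[0] + gd[1]
        grad_gamma = gd[1][self.packer.free_gamma]
        grad_beta = float(a @ gd[1])
        grad_logsig = float(a @ ga[1] - beta * (a @ gd[1]))
        grad = np.concatenate([grad_a, grad_d, grad_gamma,
                               [grad_beta, grad_logsig]])
        return -ll, -grad


def _default_init(data: ResponseData) -> ModelParams:
    J = data.n_items
    pbar = data.responses.mean(axis=0)
    d0 = np.clip(logit(pbar), -3.0, 3.0)
    return ModelParams(beta=0.0, sigma2=1.0, a=np.ones(J), d=d0,
                       gamma=np.zeros(J))


def fit_anchored_mle(data: ResponseData, constrained: tuple[int, ...],
                     quad: QuadratureSpec | None = None,
                     opts: FitOptions | None = None,
                     init: ModelParams | None = None) -> Stage1Fit:
    """Maximize the marginal log-likelihood with gamma_j = 0 for j in `constrained`.

    The general workhorse behind both the stage-1 fit (one constrained item)
    and anchor-based fits (several).  Indices are 0-based.
    """
    quad = quad or QuadratureSpec()
    opts = opts or FitOptions()
    data.check_fittable()
    packer = _Packer(data.n_items, tuple(constrained))
    fun = _NegLoglik(data, quad, packer)
    x0 = packer.pack(init if init is not None else _default_init(data))
    # a constrained gamma in the init must be zeroed, not carried over
    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": opts.max_iter, "ftol": opts.tol,
                            "gtol": 1e-6, "maxcor": 20})
    params = packer.unpack(res.x)
    converged = bool(res.success)
    if not converged:
        warnings.warn(
            f"marginal MLE did not converge in {res.nit} iterations: "
            f"{res.message}", stacklevel=2)
    loglik = marginal_loglik(params, data, quad)
    return Stage1Fit(params_tilde=params, loglik=loglik, converged=converged,
                     n_iter=int(res.nit), constrained=packer.constrained,
                     n_respondents=data.n_respondents)


def fit_constrained_mle(data: ResponseData, quad: QuadratureSpec | None = None,
                        opts: FitOptions | None = None,
                        init: ModelParams | None = None) -> Stage1Fit:
    """Stage 1: constrained marginal MLE with a single pinned DIF effect."""
    opts = opts or FitOptions()
    return fit_anchored_mle(data, (opts.constraint_item,), quad, opts, init)


def estimate_covariance(fit: Stage1Fit, data: ResponseData,
                        quad: QuadratureSpec | None = None,
                        step_scale: float = 1e-4) -> np.ndarray:
    """Scaled covariance Sigma_hat_N = N * H^{-1} from the observed information.

    H is the negative Hessian of the total marginal log-likelihood at
    Xi_tilde over the free parameters, computed by central finite differences
    of the analytic score with step ``step_scale * max(1, |param|)``,
    symmetrized, then inverted (pseudo-inverse with a warning if numerically
    singular).  The result is floored to be PSD (eigenvalue floor
    1e-10 * trace / P) and stored on ``fit.sigma_hat``.
    """
    quad = quad or QuadratureSpec()
    packer = _Packer(data.n_items, fit.constrained)
    fun = _NegLoglik(data, quad, packer)
    x = packer.pack(fit.params_tilde)
    P = x.size
    H = np.empty((P, P))
    for i in range(P):
        h = step_scale * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        H[:, i] = (fun(xp)[1] - fun(xm)[1]) / (2.0 * h)
    H = 0.5 * (H + H.T)
    try:
        Hinv = np.linalg.inv(H)
        if not np.isfinite(Hinv).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("observed information numerically singular; "
                      "using pseudo-inverse", stacklevel=2)
        Hinv = np.linalg.pinv(H)
    sigma = fit.n_respondents * 0.5 * (Hinv + Hinv.T)
    evals, evecs = np.linalg.eigh(sigma)
    floor = 1e-10 * np.trace(sigma) / P
    evals = np.maximum(evals, floor)
    sigma = (evecs * evals) @ evecs.T
    sigma = 0.5 * (sigma + sigma.T)
    fit.sigma_hat = sigma
    return sigma


def fit_ml1(data: ResponseData, quad: QuadratureSpec | None = None,
            opts: FitOptions | None = None, init: ModelParams | None = None,
            compute_covariance: bool = True) -> Ml1Fit:
    """Two-stage ML1 estimator: constrained MLE, covariance, location correction.

    Returns the ML1-identified estimate Xi_hat together with the applied shift
    c_hat and the full stage-1 fit.  The marginal log-likelihood of Xi_hat
    equals the stage-1 log-likelihood (location invariance), and
    sum_j |gamma_hat_j| <= sum_j |gamma_tilde_j| always.
    """
    stage1 = fit_constrained_mle(data, quad, opts, init)
    if compute_covariance:
        estimate_covariance(stage1, data, quad)
    params_hat, shift = ml1_transform(stage1.params_tilde)
    return Ml1Fit(params_hat=params_hat, shift=shift, stage1=stage1)
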