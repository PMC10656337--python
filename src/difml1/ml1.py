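"""Minimal-L1 (ML1) identification machinery.

The MIMIC 2PL model with DIF is identified only up to a location shift: for any c,
replacing (beta, gamma_j) by (beta + c, gamma_j - a_j*c) leaves the data
distribution unchanged.  The ML1 convention picks, within this equivalence class,
the representative whose DIF vector has strictly the smallest L1 norm, i.e. the
minimizer of the convex piecewise-linear profile

    h(c) = sum_j | gamma_j - a_j * c |.

Minimizing h is a one-dimensional least-absolute-deviations problem whose solution
is a weighted median of the ratios gamma_j / a_j with weights |a_j|.  This module
provides the profile, the exact (lower weighted median) solver, the
necessary-and-sufficient sign condition for the ML1 condition to hold at c = 0, a
simpler sufficient condition in terms of the discrimination spread
rho* = max|a| / min|a|, and the map sending an arbitrary parameter set to its ML1
representative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import ModelParams

__all__ = [
    "Ml1Verdict",
    "l1_profile",
    "weighted_median",
    "ml1_shift",
    "check_prop1",
    "check_cor1",
    "ml1_transform",
]


@dataclass(frozen=True)
class Ml1Verdict:
    """Outcome of an ML1-condition check.

    ``holds`` is True iff ``ineq7_lhs < 0`` and ``ineq8_lhs > 0``.  For the
    sufficient (rho*) check the two margins are recast into the same form, so
    the invariant holds for both check flavours.  ``indicator_counts`` records
    (#{gamma/a >= 0}, #{gamma/a < 0}, #{gamma/a <= 0}, #{gamma/a > 0}).
    """

    holds: bool
    ineq7_lhs: float
    ineq8_lhs: float
    indicator_counts: tuple[int, int, int, int]
    rho_star: float | None = None
    notes: str = ""


def _as_vectors(gamma, a):
    gamma = np.asarray(gamma, dtype=float)
    a = np.asarray(a, dtype=float)
    if gamma.ndim != 1 or a.ndim != 1 or gamma.shape != a.shape:
        raise ValueError("gamma and a must be 1-D vectors of equal length")
    if gamma.size < 1:
        raise ValueError("need at least one item")
    return gamma, a


def l1_profile(gamma, a, c: float) -> float:
    """L1 profile h(c) = sum_j |gamma_j - a_j * c|; convex piecewise-linear in c."""
    gamma, a = _as_vectors(gamma, a)
    return float(np.abs(gamma - a * c).sum())


def weighted_median(points: np.ndarray, weights: np.ndarray) -> float:
    """Lower weighted median: the smallest point r_(m) whose cumulative sorted
    weight reaches half the total.

    This is the smallest minimizer of sum_j w_j |r_j - c|; when the minimizing
    set is an interval (total weight splits exactly in half) the lower endpoint
    is returned, matching the convention of quantile-regression solvers.
    """
    points = np.asarray(points, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any():
        raise ValueError("weights must be nonnegative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    order = np.argsort(points, kind="stable")
    cum = np.cumsum(weights[order])
    idx = int(np.argmax(cum >= 0.5 * total))
    return float(points[order][idx])


def ml1_shift(gamma, a) -> float:
    """argmin_c h(c), solved exactly as a weighted median of gamma_j/a_j.

    Items with a_j = 0 contribute a constant |gamma_j| to h(c); they are
    dropped from the minimization with a warning.  If every a_j is zero the
    problem is degenerate (h is constant) and an error is raised.
    """
    gamma, a = _as_vectors(gamma, a)
    active = a != 0.0
    if not active.any():
        raise ValueError("degenerate LAD problem: all discrimination slopes are zero")
    if not active.all():
        warnings.warn(
            "items with a_j = 0 are constant in c and were excluded from the "
            "ML1 shift",
            stacklevel=2,
        )
        gamma, a = gamma[active], a[active]
    return weighted_median(gamma / a, np.abs(a))


def _indicator_counts(gamma, a):
    r = gamma / a
    return (
        int((r >= 0).sum()),
        int((r < 0).sum()),
        int((r <= 0).sum()),
        int((r > 0).sum()),
    )


def check_prop1(gamma, a) -> Ml1Verdict:
    """Necessary-and-sufficient sign condition for the ML1 condition.

    With r_j = gamma_j / a_j, the ML1 condition (c = 0 is the strict unique
    minimizer of h) holds iff the left derivative of h at 0,
    sum_j |a_j| (-I(r_j >= 0) + I(r_j < 0)), is negative and the right
    derivative, sum_j |a_j| (-I(r_j > 0) + I(r_j <= 0)) taken with the
    opposite sign convention, is positive.
    """
    gamma, a = _as_vectors(gamma, a)
    if (a == 0).any():
        raise ValueError("the sign condition assumes a_j != 0 for all items")
    r = gamma / a
    absa = np.abs(a)
    lhs7 = float((absa * ((r < 0).astype(float) - (r >= 0))).sum())
    lhs8 = float((absa * ((r <= 0).astype(float) - (r > 0))).sum())
    return Ml1Verdict(
        holds=bool(lhs7 < 0 and lhs8 > 0),
        ineq7_lhs=lhs7,
        ineq8_lhs=lhs8,
        indicator_counts=_indicator_counts(gamma, a),
        notes="necessary-and-sufficient sign condition",
    )


def check_cor1(gamma, a) -> Ml1Verdict:
    """Sufficient ML1 check via the discrimination spread rho* = max|a|/min|a|.

    Holds if #{r_j <= 0} > rho* #{r_j > 0} and #{r_j >= 0} > rho* #{r_j < 0}
    (both strict).  Sufficient but not necessary: balanced positive/negative
    DIF can satisfy the sign condition even when these counts fail.  The two
    margins are stored so that ``holds`` iff ``ineq7_lhs < 0 < ineq8_lhs``.
    """
    gamma, a = _as_vectors(gamma, a)
    if (a == 0).any():
        raise ValueError("the sufficient condition assumes a_j != 0 for all items")
    n_ge, n_lt, n_le, n_gt = _indicator_counts(gamma, a)
    rho = float(np.abs(a).max() / np.abs(a).min())
    margin9 = n_le - rho * n_gt   # required > 0
    margin10 = n_ge - rho * n_lt  # required > 0
    return Ml1Verdict(
        holds=bool(margin9 > 0 and margin10 > 0),
        ineq7_lhs=-margin9,
        ineq8_lhs=margin10,
        indicator_counts=(n_ge, n_lt, n_le, n_gt),
        rho_star=rho,
        notes="sufficient rho* count condition",
    )


def ml1_transform(params: ModelParams) -> tuple[ModelParams, float]:
    """Map a parameter set to its ML1 representative.

    Computes c_hat = argmin_c h(c) over the equivalence class of ``params`` and
    returns ({beta + c_hat, sigma^2, a, d, gamma - a*c_hat}, c_hat).  The j-th
    returned DIF value is G_j(params).  Idempotent, and the transformed DIF
    vector never has a larger L1 norm than the input.
    """
    c_hat = ml1_shift(params.gamma, params.a)
    out = ModelParams(
        beta=params.beta + c_hat,
        sigma2=params.sigma2,
        a=params.a,
        d=params.d,
        gamma=params.gamma - params.a * c_hat,
    )
    return out, c_hat
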