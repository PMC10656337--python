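"""Monte-Carlo (parametric bootstrap) inference for the DIF effects.

The sampling error of the ML1 estimate gamma_hat_j is inherited from the
stage-1 constrained MLE, whose scaled error sqrt(N)(Xi_tilde - Xi_dagger) is
asymptotically N(0, Sigma*).  Writing G_j for the map sending any parameter set
to the j-th DIF effect of its ML1 representative, the distribution of
gamma_hat_j - gamma_j* is approximated by that of

    D_j = G_j(Xi_tilde + Z / sqrt(N)) - G_j(Xi_tilde),    Z ~ N(0, Sigma_hat_N),

simulated M times.  Each draw costs one multivariate-normal sample and one
exact weighted-median LAD solve, vectorized across draws.  From the draws we
form basic (pivotal) bootstrap confidence intervals and two-sided add-one
Monte-Carlo p-values, and detect DIF items with the Benjamini-Hochberg step-up
rule.

The pinned stage-1 coordinate receives no perturbation (its Z entry is zero),
but the pinned item still varies through G_j's dependence on every coordinate,
so it is testable like any other item.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .estimation import Ml1Fit, _Packer

__all__ = [
    "InferenceTable",
    "draw_gj_perturbations",
    "confidence_intervals",
    "p_values",
    "bh_select",
    "infer_dif",
]


@dataclass(frozen=True)
class InferenceTable:
    """Per-item DIF inference results plus the run metadata.

    ``table`` has one row per item: item (1-based), gamma_hat, ci_lo, ci_hi,
    p_value, bh_reject.
    """

    table: pd.DataFrame
    M: int
    level: float
    alpha: float
    seed: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def metadata(self) -> dict:
        return {"M": self.M, "level": self.level, "alpha": self.alpha,
                "seed": self.seed}

    def write_metadata(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2)


def _vectorized_lower_weighted_median(ratios: np.ndarray,
                                      weights: np.ndarray) -> np.ndarray:
    """Row-wise lower weighted median of an M x J array of breakpoints."""
    order = np.argsort(ratios, axis=1, kind="stable")
    w_sorted = np.take_along_axis(weights, order, axis=1)
    cum = np.cumsum(w_sorted, axis=1)
    half = 0.5 * cum[:, -1]
    idx = np.argmax(cum >= half[:, None], axis=1)
    r_sorted = np.take_along_axis(ratios, order, axis=1)
    return r_sorted[np.arange(ratios.shape[0]), idx]


def draw_gj_perturbations(fit: Ml1Fit, M: int, seed: int) -> np.ndarray:
    """Sample the M x J matrix D of G_j perturbations (Monte-Carlo bootstrap draws).

    Reproducible given ``seed``.  Requires ``fit.stage1.sigma_hat`` to be a
    valid (PSD) scaled covariance; otherwise re-run ``estimate_covariance``.
    """
    if M < 100:
        raise ValueError("M must be >= 100")
    stage1 = fit.stage1
    if stage1.sigma_hat is None:
        raise ValueError("fit has no covariance; run estimate_covariance first")
    evals, evecs = np.linalg.eigh(stage1.sigma_hat)
    tol = 1e-8 * max(1.0, float(evals.max(initial=0.0)))
    if evals.min() < -tol:
        raise ValueError("Sigma_hat_N is not positive semi-definite; re-run "
                         "estimate_covariance")
    L = evecs * np.sqrt(np.clip(evals, 0.0, None))

    params = stage1.params_tilde
    J = params.n_items
    packer = _Packer(J, stage1.constrained)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((M, packer.n_free)) @ L.T
    scale = 1.0 / np.sqrt(stage1.n_respondents)

    a_pert = params.a[None, :] + scale * Z[:, :J]
    gamma_pert = np.tile(params.gamma, (M, 1))
    gamma_pert[:, packer.free_gamma] += scale * Z[:, 2 * J:2 * J
                                                  + packer.free_gamma.size]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = gamma_pert / a_pert
    # zero slopes carry zero weight in h(c); park their breakpoints at +inf
    ratios[~np.isfinite(ratios)] = np.inf
    c = _vectorized_lower_weighted_median(ratios, np.abs(a_pert))
    gj_pert = gamma_pert - a_pert * c[:, None]
    return gj_pert - fit.params_hat.gamma[None, :]


def confidence_intervals(draws: np.ndarray, gamma_hat: np.ndarray,
                         level: float = 0.95) -> np.ndarray:
    """Basic bootstrap intervals [ghat - q_{(1+L)/2}(D), ghat - q_{(1-L)/2}(D)].

    Returns a J x 2 array (lo, hi) from the empirical quantiles of the draws.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    M = draws.shape[0]
    if (1.0 - level) / 2.0 * (M + 1) < 1.0:
        raise ValueError(f"M={M} draws are too few for a {level:.3f} interval")
    hi_q = np.quantile(draws, (1.0 + level) / 2.0, axis=0)
    lo_q = np.quantile(draws, (1.0 - level) / 2.0, axis=0)
    return np.column_stack([gamma_hat - hi_q, gamma_hat - lo_q])


def p_values(draws: np.ndarray, gamma_hat: np.ndarray) -> np.ndarray:
    """Two-sided add-one Monte-Carlo p-values for H0: gamma_j* = 0.

    p_j = min(1, 2 * min[(1 + #{D >= ghat_j}) / (M+1),
                         (1 + #{D <= ghat_j}) / (M+1)]);
    never smaller than 2/(M+1), approximately uniform under the null.
    """
    M = draws.shape[0]
    ge = (draws >= gamma_hat[None, :]).sum(axis=0)
    le = (draws <= gamma_hat[None, :]).sum(axis=0)
    p = 2.0 * np.minimum(1.0 + ge, 1.0 + le) / (M + 1.0)
    return np.minimum(p, 1.0)


def bh_select(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up detection; returns a boolean reject mask.

    Sort the p-values ascending, find the largest k with p_(k) <= k*alpha/J,
    and reject the k smallest (none if no such k).
    """
    pvals = np.asarray(pvals, dtype=float)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if ((pvals < 0) | (pvals > 1)).any() or not np.isfinite(pvals).all():
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject


def infer_dif(fit: Ml1Fit, M: int = 10_000, seed: int = 0,
              level: float = 0.95, alpha: float = 0.05,
              item_names: tuple[str, ...] | None = None) -> InferenceTable:
    """Full DIF inference: bootstrap draws, CIs, p-values, and B-H detection."""
    draws = draw_gj_perturbations(fit, M, seed)
    gamma_hat = fit.params_hat.gamma
    ci = confidence_intervals(draws, gamma_hat, level)
    p = p_values(draws, gamma_hat)
    reject = bh_select(p, alpha)
    J = gamma_hat.size
    names = item_names if item_names is not None else tuple(
        str(j + 1) for j in range(J))
    table = pd.DataFrame({
        "item": np.arange(1, J + 1),
        "name": names,
        "gamma_hat": gamma_hat,
        "ci_lo": ci[:, 0],
        "ci_hi": ci[:, 1],
        "p_value": p,
        "bh_reject": reject,
    })
    return InferenceTable(table=table, M=M, level=level, alpha=alpha, seed=seed)
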