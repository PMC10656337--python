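"""Anchor-based comparators: per-item likelihood-ratio tests and Wald intervals.

Classical DIF analysis assumes a known anchor set A of DIF-free items.  Fixing
gamma_j = 0 for j in A identifies the model, after which each non-anchor DIF
effect can be tested by a likelihood-ratio test against the chi-square(1)
reference distribution, or covered by a Wald interval from the observed
information.  These serve as the baseline the anchor-free ML1 procedure is
compared against; their validity depends on the anchors truly being DIF-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .estimation import (FitOptions, Stage1Fit, _Packer, estimate_covariance,
                         fit_anchored_mle)
from .model import QuadratureSpec, ResponseData

__all__ = ["AnchorSpec", "lrt_anchor_test", "wald_anchor_intervals"]


@dataclass(frozen=True)
class AnchorSpec:
    """A known set of DIF-free items, 1-based as in user-facing reports."""

    anchor_items: tuple[int, ...]

    def __post_init__(self):
        items = tuple(sorted(set(int(j) for j in self.anchor_items)))
        if not items:
            raise ValueError("anchor set must be nonempty (model unidentified)")
        if items[0] < 1:
            raise ValueError("anchor items are 1-based indices")
        object.__setattr__(self, "anchor_items", items)

    def zero_based(self, n_items: int) -> tuple[int, ...]:
        if self.anchor_items[-1] > n_items:
            raise ValueError("anchor item index exceeds number of items")
        return tuple(j - 1 for j in self.anchor_items)


def lrt_anchor_test(data: ResponseData, anchors: AnchorSpec,
                    quad: QuadratureSpec | None = None,
                    opts: FitOptions | None = None) -> pd.DataFrame:
    """Likelihood-ratio tests of gamma_j = 0 for every non-anchor item.

    Fits the full model with the anchor DIF effects fixed at zero, then for
    each non-anchor item refits with that item's effect additionally fixed
    (warm-started from the full fit).  The statistic 2*(ll_full - ll_null) is
    floored at zero and referred to chi-square with one degree of freedom.

    Returns a DataFrame with columns item (1-based), statistic, p_value,
    converged.
    """
    quad = quad or QuadratureSpec()
    opts = opts or FitOptions()
    A = anchors.zero_based(data.n_items)
    full = fit_anchored_mle(data, A, quad, opts)
    rows = []
    anchor_set = set(A)
    for j in range(data.n_items):
        if j in anchor_set:
            continue
        init = full.params_tilde
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null = fit_anchored_mle(data, tuple(sorted(anchor_set | {j})),
                                    quad, opts, init=init)
        stat = max(0.0, 2.0 * (full.loglik - null.loglik))
        rows.append({
            "item": j + 1,
            "statistic": stat,
            "p_value": float(chi2.sf(stat, df=1)),
            "converged": bool(full.converged and null.converged),
        })
    return pd.DataFrame(rows)


def wald_anchor_intervals(data: ResponseData, anchors: AnchorSpec,
                          quad: QuadratureSpec | None = None,
                          opts: FitOptions | None = None,
                          level: float = 0.95) -> pd.DataFrame:
    """Wald confidence intervals for the non-anchor DIF effects.

    Uses the anchored MLE and the observed-information standard errors
    se_j = sqrt([Sigma_hat_N / N]_jj).
    """
    quad = quad or QuadratureSpec()
    opts = opts or FitOptions()
    A = anchors.zero_based(data.n_items)
    fit = fit_anchored_mle(data, A, quad, opts)
    sigma = estimate_covariance(fit, data, quad)
    packer = _Packer(data.n_items, fit.constrained)
    J = data.n_items
    g_slice = slice(2 * J, 2 * J + packer.free_gamma.size)
    se = np.sqrt(np.diag(sigma)[g_slice] / data.n_respondents)
    z = norm.ppf(0.5 + level / 2.0)
    gam = fit.params_tilde.gamma[packer.free_gamma]
    return pd.DataFrame({
        "item": packer.free_gamma + 1,
        "gamma_hat": gam,
        "ci_lo": gam - z * se,
        "ci_hi": gam + z * se,
        "se": se,
    })
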