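"""Synthetic-data generator and replication engine for the validation study.

The study design: J = 25 items, discrimination slopes cycling through
(1.3, 1.4, 1.5, 1.7, 1.6), two easiness regimes (small: within [-1, 1];
large: within [-2, 2]), and six DIF configurations crossing magnitude
(small: |gamma| around 0.6-0.7; large: doubled) with the number of DIF items
(high/medium/low = 14/10/5 of 25).  Groups are of equal size; the latent trait
is N(0, 1) in the reference group and N(beta, sigma^2) with beta = 0.5,
sigma = 0.5 in the focal group.  Every DIF configuration mixes positive and
negative effects so that the ML1 identification condition holds.

The engine replicates generate -> fit -> infer -> detect with counter-derived
seeds and aggregates mean-squared errors, empirical FDR under B-H detection,
confidence-interval coverage, and vertically averaged ROC curves with AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve

from .estimation import FitOptions, Ml1Fit, fit_ml1
from .inference import bh_select, infer_dif
from .lrt import AnchorSpec, lrt_anchor_test, wald_anchor_intervals
from .model import ModelParams, QuadratureSpec, ResponseData, irf_prob

logger = logging.getLogger(__name__)

__all__ = [
    "DISCRIMINATION",
    "EASINESS",
    "DIF_GAMMA",
    "SimSetting",
    "MetricsTable",
    "generate_dataset",
    "compute_mse",
    "compute_fdr",
    "compute_coverage",
    "compute_roc_auc",
    "run_study",
]

J_ITEMS = 25

DISCRIMINATION = np.tile([1.3, 1.4, 1.5, 1.7, 1.6], 5)

EASINESS = {
    "small": np.tile([0.8, 0.2, -0.4, -1.0, 1.0], 5),
    "large": np.tile([0.8, -0.4, -1.2, -2.0, 2.0], 5),
}

# DIF vectors: high/medium/low carry 14/10/5 nonzero effects of mixed sign.
DIF_GAMMA = {
    ("small", "high"): np.array(
        [0.0] * 11
        + [-0.60, 0.60, -0.65, 0.70]
        + [-0.60, 0.60, -0.65, 0.70, 0.65] * 2),
    ("small", "medium"): np.array(
        [0.0] * 15 + [-0.60, 0.60, -0.65, 0.70, 0.65] * 2),
    ("small", "low"): np.array(
        [0.0] * 20 + [-0.60, 0.60, -0.65, 0.70, 0.65]),
    ("large", "high"): np.array(
        [0.0] * 11
        + [-1.20, 1.20, -1.30, 1.40]
        + [-1.20, 1.20, -1.30, 1.40, 1.30] * 2),
    ("large", "medium"): np.array(
        [0.0] * 15 + [-1.20, 1.20, -1.30, 1.40, 1.30] * 2),
    ("large", "low"): np.array(
        [0.0] * 20 + [-1.20, 1.20, -1.30, 1.40, 1.30]),
}


@dataclass(frozen=True)
class SimSetting:
    """One cell of the study design, resolved to true model parameters."""

    N: int
    d_regime: str = "small"
    dif_magnitude: str = "small"
    dif_proportion: str = "high"
    beta: float = 0.5
    sigma: float = 0.5

    def __post_init__(self):
        if self.d_regime not in EASINESS:
            raise ValueError("d_regime must be 'small' or 'large'")
        if (self.dif_magnitude, self.dif_proportion) not in DIF_GAMMA:
            raise ValueError("unknown DIF magnitude/proportion combination")
        if self.N < 2:
            raise ValueError("N must allow both groups to be nonempty")

    @property
    def params(self) -> ModelParams:
        return ModelParams(
            beta=self.beta,
            sigma2=self.sigma ** 2,
            a=DISCRIMINATION.copy(),
            d=EASINESS[self.d_regime].copy(),
            gamma=DIF_GAMMA[(self.dif_magnitude, self.dif_proportion)].copy(),
        )

    @property
    def label(self) -> str:
        return (f"N{self.N}-{self.d_regime}_d-{self.dif_magnitude}_dif-"
                f"{self.dif_proportion}")


def generate_dataset(setting: SimSetting, seed) -> ResponseData:
    """Draw one dataset: latent traits by group, then Bernoulli item responses.

    ``seed`` may be an int, SeedSequence, or Generator.  Groups are of equal
    size; for odd N the focal group receives the extra respondent (logged).
    The respondent order is reference block then focal block.
    """
    rng = np.random.default_rng(seed)
    params = setting.params
    n_ref = setting.N // 2
    n_focal = setting.N - n_ref
    if setting.N % 2:
        logger.info("odd N=%d: focal group receives the extra respondent",
                    setting.N)
    groups = np.concatenate([np.zeros(n_ref, dtype=np.int8),
                             np.ones(n_focal, dtype=np.int8)])
    theta = np.concatenate([
        rng.standard_normal(n_ref),
        params.beta + params.sigma * rng.standard_normal(n_focal),
    ])
    prob = irf_prob(params.a[None, :], params.d[None, :],
                    params.gamma[None, :], theta[:, None], groups[:, None])
    responses = (rng.random((setting.N, params.n_items)) < prob).astype(np.int8)
    return ResponseData(responses=responses, groups=groups)


def compute_mse(estimates: list[ModelParams], truth: ModelParams) -> dict:
    """Parameter-recovery MSEs: item-averaged for the a/d/gamma blocks,
    scalar for beta and for sigma (the standard deviation, not the variance)."""
    if len(estimates) < 2:
        raise ValueError("need at least 2 replications for an MSE")
    for est in estimates:
        if est.n_items != truth.n_items:
            raise ValueError("estimate/truth item count mismatch")
    a_err = np.mean([(e.a - truth.a) ** 2 for e in estimates], axis=0)
    d_err = np.mean([(e.d - truth.d) ** 2 for e in estimates], axis=0)
    g_err = np.mean([(e.gamma - truth.gamma) ** 2 for e in estimates], axis=0)
    beta_err = np.mean([(e.beta - truth.beta) ** 2 for e in estimates])
    sig_err = np.mean([(e.sigma - truth.sigma) ** 2 for e in estimates])
    return {
        "a": float(a_err.mean()),
        "d": float(d_err.mean()),
        "gamma": float(g_err.mean()),
        "beta": float(beta_err),
        "sigma": float(sig_err),
    }


def compute_fdr(detections: list[np.ndarray], truth_gamma: np.ndarray) -> float:
    """Empirical FDR: per-replication false-discovery proportion (0/0 -> 0),
    averaged over replications."""
    null_mask = truth_gamma == 0.0
    fdps = []
    for det in detections:
        det = np.asarray(det, dtype=bool)
        n_det = int(det.sum())
        n_false = int((det & null_mask).sum())
        fdps.append(n_false / max(1, n_det))
    return float(np.mean(fdps))


def compute_coverage(intervals: list[np.ndarray],
                     truth_gamma: np.ndarray) -> np.ndarray:
    """Per-item fraction of replications whose [lo, hi] contains gamma_j*."""
    hits = [
        (ci[:, 0] <= truth_gamma) & (truth_gamma <= ci[:, 1])
        for ci in intervals
    ]
    return np.mean(hits, axis=0)


def compute_roc_auc(pvals_per_rep: list[np.ndarray], truth_gamma: np.ndarray,
                    item_mask: np.ndarray | None = None,
                    n_grid: int = 512) -> tuple[np.ndarray, np.ndarray, float]:
    """Vertically averaged ROC and its AUC for p-value-based DIF detection.

    Per replication, items are ranked by p-value (small = detected first) and
    the ROC step curve over all thresholds is evaluated on a fixed FPR grid;
    curves are averaged at fixed FPR and the AUC is the trapezoid-rule area
    under the averaged curve.  ``item_mask`` restricts scoring (e.g. to
    non-anchor items for the anchor-based comparator).
    """
    mask = (np.ones_like(truth_gamma, dtype=bool)
            if item_mask is None else np.asarray(item_mask, dtype=bool))
    y_true = (truth_gamma[mask] != 0.0).astype(int)
    if y_true.min() == y_true.max():
        raise ValueError("ROC needs both DIF and non-DIF items in scope")
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = []
    for p in pvals_per_rep:
        fpr, tpr, _ = roc_curve(y_true, -np.asarray(p)[mask])
        tprs.append(np.interp(grid, fpr, tpr))
    mean_tpr = np.mean(tprs, axis=0)
    auc = float(np.trapezoid(mean_tpr, grid))
    return grid, mean_tpr, auc


@dataclass
class MetricsTable:
    """Aggregated study metrics, one entry per setting label."""

    n_reps: int
    M: int
    master_seed: int
    alpha: float
    level: float
    per_setting: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            if isinstance(v, (np.floating, np.integer)):
                return float(v)
            return v

        settings = {
            label: {k: clean(v) for k, v in entry.items() if k != "raw"}
            for label, entry in self.per_setting.items()
        }
        return {
            "n_reps": self.n_reps, "M": self.M,
            "master_seed": self.master_seed,
            "alpha": self.alpha, "level": self.level,
            "settings": settings,
        }


_KNOWN_METHODS = ("proposed", "lrt-1", "lrt-5", "lrt-10", "wald-5")


def _rep_seed(master_seed: int, setting_idx: int, rep: int,
              stream: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([master_seed, setting_idx, rep, stream])


def run_study(settings: list[SimSetting], n_reps: int,
              methods: tuple[str, ...] = ("proposed",), M: int = 10_000,
              master_seed: int = 0, quad: QuadratureSpec | None = None,
              opts: FitOptions | None = None, alpha: float = 0.05,
              level: float = 0.95, point_estimates_only: bool = False,
              keep_raw: bool = False, progress: bool = False) -> MetricsTable:
    """Replicate generate -> fit -> infer -> detect and aggregate the metrics.

    Per-replication seeds derive from ``master_seed`` through a counter-based
    scheme, so results are fully reproducible.  Replications whose fit raises
    are logged, excluded, and counted; a setting aborts if more than 10% fail.
    With ``point_estimates_only`` the proposed method skips covariance and
    bootstrap inference (parameter-recovery studies only need Xi_hat); with
    ``keep_raw`` the per-replication estimates, p-values, intervals and
    detections are retained under each setting's ``raw`` key (excluded from
    ``to_dict``).
    """
    unknown = set(methods) - set(_KNOWN_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    quad = quad or QuadratureSpec()
    opts = opts or FitOptions()
    out = MetricsTable(n_reps=n_reps, M=M, master_seed=master_seed,
                       alpha=alpha, level=level)

    for s_idx, setting in enumerate(settings):
        truth = setting.params
        estimates: list[ModelParams] = []
        detections: list[np.ndarray] = []
        intervals: list[np.ndarray] = []
        pvals: dict[str, list[np.ndarray]] = {m: [] for m in methods}
        wald_ivals: list[np.ndarray] = []
        n_failed = 0
        max_failed = int(0.1 * n_reps)

        for rep in range(n_reps):
            data = generate_dataset(setting, _rep_seed(master_seed, s_idx,
                                                       rep, 0))
            try:
                if "proposed" in methods:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        fit = fit_ml1(data, quad, opts,
                                      compute_covariance=not
                                      point_estimates_only)
                    estimates.append(fit.params_hat)
                    if not point_estimates_only:
                        inf_seed = int(_rep_seed(master_seed, s_idx, rep, 1)
                                       .generate_state(1)[0])
                        res = infer_dif(fit, M=M, seed=inf_seed, level=level,
                                        alpha=alpha)
                        pvals["proposed"].append(
                            res.table["p_value"].to_numpy())
                        detections.append(res.table["bh_reject"].to_numpy())
                        intervals.append(res.table[["ci_lo", "ci_hi"]]
                                         .to_numpy())
                for m in methods:
                    if m.startswith("lrt-"):
                        k = int(m.split("-")[1])
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            lrt = lrt_anchor_test(
                                data, AnchorSpec(tuple(range(1, k + 1))),
                                quad, opts)
                        pvals[m].append(lrt["p_value"].to_numpy())
                if "wald-5" in methods:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        wt = wald_anchor_intervals(
                            data, AnchorSpec((1, 2, 3, 4, 5)), quad, opts,
                            level=level)
                    wald_ivals.append(wt[["ci_lo", "ci_hi"]].to_numpy())
            except Exception:
                n_failed += 1
                logger.exception("replication %d of %s failed; excluded",
                                 rep, setting.label)
                if n_failed > max_failed:
                    raise RuntimeError(
                        f"more than 10% of replications failed in "
                        f"{setting.label}")
                continue
            if progress and (rep + 1) % 10 == 0:
                logger.info("%s: %d/%d replications done", setting.label,
                            rep + 1, n_reps)

        entry: dict = {"n_reps_done": n_reps - n_failed, "n_failed": n_failed}
        if estimates:
            entry["mse"] = compute_mse(estimates, truth) \
                if len(estimates) >= 2 else None
        if detections:
            entry["fdr"] = compute_fdr(detections, truth.gamma)
        if intervals:
            entry["coverage"] = compute_coverage(intervals, truth.gamma)
        if wald_ivals:
            non_anchor = np.ones(truth.n_items, dtype=bool)
            non_anchor[:5] = False
            entry["wald_coverage"] = compute_coverage(
                wald_ivals, truth.gamma[non_anchor])
        entry["auc"] = {}
        entry["roc"] = {}
        for m, plist in pvals.items():
            if not plist:
                continue
            if m.startswith("lrt-"):
                # anchor-based scoring: non-anchor items only, and the
                # returned p-vectors already exclude the k anchors
                k = int(m.split("-")[1])
                grid, tpr, auc = compute_roc_auc(plist, truth.gamma[k:])
            else:
                grid, tpr, auc = compute_roc_auc(plist, truth.gamma)
            entry["auc"][m] = auc
            entry["roc"][m] = {"fpr": grid, "tpr": tpr}
        if keep_raw:
            entry["raw"] = {
                "estimates": estimates,
                "detections": detections,
                "intervals": intervals,
                "pvals": {m: plist for m, plist in pvals.items() if plist},
                "wald_intervals": wald_ivals,
            }
        out.per_setting[setting.label] = entry
    return out
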