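"""The knockoff filter: W statistics, data-dependent threshold, selection.

Pair statistics compare each original column's importance with its
knockoff's.  Any statistic obeying the flip-sign property (swapping a
feature with its knockoff negates W_j) yields finite-sample FDR control
through the knockoff+ threshold

    tau = min{ t > 0 : (1 + #{j: W_j <= -t}) / max(1, #{j: W_j >= t}) <= q }

with selection S = {j : W_j >= tau}.  The default statistic is the
difference of aggregated |SHAP| scores; the Lasso regularization-path entry
statistic is provided as the classical comparator.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression, lasso_path
from sklearn.svm import l1_min_c

from . import importance as imp
from . import knockoffs as ko

__all__ = [
    "WStatistics",
    "SelectionResult",
    "compute_w",
    "knockoff_threshold",
    "select",
    "lasso_path_statistic",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class WStatistics:
    """Antisymmetric per-feature pair statistics."""

    w: np.ndarray
    kind: str  # "shap_diff" | "shap_signed_max" | "lasso_lambda"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if not np.all(np.isfinite(self.w)):
            raise ValueError("W statistics must be finite")


@dataclass
class SelectionResult:
    """Threshold, selected set and diagnostics of one filter run."""

    selected: list[int]          # 0-based sorted indices
    threshold: float             # +inf when nothing can be selected
    q: float
    w: WStatistics
    offset: int = 1
    feature_names: list[str] | None = None
    seed: int | None = None
    stage_seconds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-ready summary; feature indices are reported 1-based."""
        return {
            "selected": [j + 1 for j in self.selected],
            "feature_names": (
                [self.feature_names[j] for j in self.selected] if self.feature_names else None
            ),
            "threshold": self.threshold if np.isfinite(self.threshold) else "inf",
            "q": self.q,
            "statistic": self.w.kind,
            "offset": self.offset,
            "w": self.w.w.tolist(),
            "seed": self.seed,
            "stage_seconds": self.stage_seconds,
        }


def compute_w(z: imp.ImportanceVector | np.ndarray, kind: str = "shap_diff") -> WStatistics:
    """Fold a length-2p importance vector into p pair statistics.

    ``shap_diff``: W_j = Z_j - Z_{j+p}.  ``shap_signed_max``:
    W_j = max(Z_j, Z_{j+p}) signed by which of the pair is larger, zero on
    ties.  Both negate exactly under a swap of columns j and j+p.
    """
    zv = np.asarray(z.z if isinstance(z, imp.ImportanceVector) else z, dtype=float)
    if zv.ndim != 1 or zv.size % 2:
        raise ValueError("importance vector must have even length 2p")
    p = zv.size // 2
    orig, knock = zv[:p], zv[p:]
    if kind == "shap_diff":
        w = orig - knock
    elif kind == "shap_signed_max":
        w = np.maximum(orig, knock) * np.sign(orig - knock)
    else:
        raise ValueError(f"unknown statistic kind {kind!r}")
    return WStatistics(w=w, kind=kind)


def knockoff_threshold(w: WStatistics | np.ndarray, q: float, offset: int = 1) -> float:
    """Data-dependent threshold controlling FDR at level ``q``.

    ``offset=1`` is the knockoff+ variant; ``offset=0`` drops the +1
    correction.  Candidates are exactly the nonzero |W_j|; returns +inf when
    no candidate achieves the bound.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    if offset not in (0, 1):
        raise ValueError("offset must be 0 or 1")
    wv = np.asarray(w.w if isinstance(w, WStatistics) else w, dtype=float)
    candidates = np.unique(np.abs(wv[wv != 0]))
    for t in candidates:
        ratio = (offset + np.sum(wv <= -t)) / max(1, np.sum(wv >= t))
        if ratio <= q:
            return float(t)
    return float("inf")


def select(
    w: WStatistics,
    threshold: float,
    q: float = 0.1,
    offset: int = 1,
    feature_names: list[str] | None = None,
    seed: int | None = None,
) -> SelectionResult:
    """Selected set {j : W_j >= threshold}; empty when threshold is +inf."""
    if np.isfinite(threshold):
        sel = np.where(w.w >= threshold)[0]
    else:
        sel = np.array([], dtype=int)
    return SelectionResult(
        selected=sorted(int(j) for j in sel),
        threshold=float(threshold),
        q=q,
        w=w,
        offset=offset,
        feature_names=feature_names,
        seed=seed,
    )


def lasso_path_statistic(
    x: ko.DesignMatrix,
    k: ko.KnockoffModel,
    y: np.ndarray,
    task: str = "regression",
    n_lambda: int = 100,
) -> imp.ImportanceVector:
    """Regularization-path entry points on the augmented design.

    Z_j is the largest penalty at which coefficient j is active, scanned on
    a descending grid of ``n_lambda`` points spanning [lambda_max,
    1e-3 * lambda_max]; never-active features get Z_j = 0.  Continuous
    responses use the Lasso path, binary ones the l1-penalized logistic path.
    """
    aug = np.hstack([x.values, k.knockoffs])
    aug = (aug - aug.mean(axis=0)) / aug.std(axis=0)
    y = np.asarray(y, dtype=float)
    n, m = aug.shape
    if task == "regression":
        yc = y - y.mean()
        lam_max = np.max(np.abs(aug.T @ yc)) / n
        grid = np.geomspace(lam_max, lam_max * 1e-3, n_lambda)
        _, coefs, _ = lasso_path(aug, yc, alphas=grid)
        active = np.abs(coefs) > 1e-12  # (m, n_lambda)
        z = np.where(active.any(axis=1), grid[np.argmax(active, axis=1)], 0.0)
    elif task == "binary":
        c_min = l1_min_c(aug, y, loss="log")
        grid = np.geomspace(c_min, c_min * 1e3, n_lambda)  # ascending C = descending lambda
        z = np.zeros(m)
        clf = LogisticRegression(
            l1_ratio=1.0, solver="liblinear", tol=1e-4, warm_start=True, max_iter=200
        )
        for c in grid:
            clf.set_params(C=c)
            clf.fit(aug, y)
            newly = (np.abs(clf.coef_.ravel()) > 1e-12) & (z == 0)
            z[newly] = 1.0 / c  # lambda scale
    else:
        raise ValueError("lasso path statistic supports regression or binary tasks")
    return imp.ImportanceVector(z=z, aggregation="lasso_lambda")


def run_pipeline(
    x: ko.DesignMatrix | np.ndarray,
    y: np.ndarray,
    q: float = 0.1,
    cfg: imp.GBDTConfig | None = None,
    seed: int = 0,
    statistic: str = "shap_diff",
    s_method: str = "equi",
    shrinkage: str | float = "auto",
    offset: int = 1,
    tune_budget: int = 0,
) -> SelectionResult:
    """Knockoff-filtered variable selection with a GBDT + SHAP statistic.

    Stages: covariance estimation -> s-vector -> knockoff sampling ->
    augmentation -> (optional tuning) -> boosting -> SHAP attribution ->
    importance aggregation -> W statistic -> threshold -> selection.
    Deterministic given ``(inputs, seed)``; per-stage wall times are
    recorded in the result.
    """
    if not isinstance(x, ko.DesignMatrix):
        x = ko.DesignMatrix(values=np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    if y.shape[0] != x.n:
        raise ValueError("response length does not match the design")
    if cfg is None:
        task = _infer_task(y)
        n_classes = int(y.max()) + 1 if task == "multiclass" else 1
        cfg = imp.default_config(task, n_classes=n_classes, seed=seed)
    else:
        cfg = imp.GBDTConfig(
            task=cfg.task,
            n_classes=cfg.n_classes,
            hyperparameters=dict(cfg.hyperparameters),
            seed=seed,
            deterministic=cfg.deterministic,
            booster=cfg.booster,
        )

    times: dict[str, float] = {}

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        times[name] = time.perf_counter() - t0
        logger.info("stage %-22s %.3fs", name, times[name])
        return out

    cov = _stage("estimate_covariance", lambda: ko.estimate_covariance(x, shrinkage))
    if s_method == "equi":
        svec = _stage("solve_s", lambda: ko.solve_s_equi(cov))
    elif s_method == "sdp":
        svec = _stage("solve_s", lambda: ko.solve_s_sdp(cov))
    else:
        raise ValueError(f"unknown s-vector method {s_method!r}")
    kmod = _stage("sample_knockoffs", lambda: ko.sample_knockoffs(x, cov, svec, seed))
    aug = _stage("augment", lambda: ko.augment(x, kmod))
    if tune_budget:
        cfg = _stage(
            "tune_hyperparameters",
            lambda: imp.tune_hyperparameters(aug, y, cfg, budget=tune_budget, seed=seed),
        )
    booster = _stage("fit_booster", lambda: imp.fit_booster(aug, y, cfg))
    attr = _stage("compute_attributions", lambda: imp.compute_attributions(booster, aug))
    z = _stage("aggregate_importance", lambda: imp.aggregate_importance(attr))
    w = _stage("compute_w", lambda: compute_w(z, kind=statistic))
    w.provenance = {"knockoff_seed": seed, "booster": cfg.booster, "task": cfg.task}
    tau = _stage("knockoff_threshold", lambda: knockoff_threshold(w, q, offset=offset))
    result = select(w, tau, q=q, offset=offset, feature_names=x.feature_names, seed=seed)
    result.stage_seconds = times
    return result


def _infer_task(y: np.ndarray) -> str:
    labels = np.unique(y)
    if labels.size <= 20 and np.allclose(labels, np.round(labels)):
        return "binary" if labels.size == 2 else ("multiclass" if labels.size > 2 else "regression")
    return "regression"
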