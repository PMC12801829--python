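"""Boosted-tree fitting and Shapley-value feature importances.

The learner is consumed through a fit/predict/attribution contract: LightGBM
by default, XGBoost as an alternative.  Per-instance attributions come from
the tree-exact SHAP algorithms built into those libraries (path-dependent
conditional expectations), and are aggregated to one non-negative score per
column by averaging absolute values over instances.  An independent
interventional-mode computation (explicit background sample, per-tree
coalition enumeration) and a model-agnostic brute-force Shapley routine are
provided for cross-checking on small models.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import lightgbm as lgb
import numpy as np
import xgboost as xgb

from .knockoffs import AugmentedDesign

__all__ = [
    "GBDTConfig",
    "FittedBooster",
    "AttributionMatrix",
    "ImportanceVector",
    "default_config",
    "fit_booster",
    "tune_hyperparameters",
    "compute_attributions",
    "brute_force_shapley",
    "aggregate_importance",
]

#: Documented default hyperparameters.  Sized for wide augmented designs
#: (hundreds to thousands of columns, half of them knockoffs): shallow-ish
#: trees, aggressive column subsampling and few, fast boosting rounds.
DEFAULT_HYPERPARAMETERS: dict[str, float | int] = {
    "learning_rate": 0.2,
    "num_leaves": 15,
    "max_depth": -1,
    "min_data_in_leaf": 10,
    "feature_fraction": 0.5,
    "n_estimators": 100,
    "max_bin": 63,
}


@dataclass
class GBDTConfig:
    """Task, hyperparameters and reproducibility switches for the learner."""

    task: str  # "regression" | "binary" | "multiclass"
    n_classes: int = 1
    hyperparameters: dict = field(default_factory=lambda: dict(DEFAULT_HYPERPARAMETERS))
    seed: int = 0
    deterministic: bool = True
    booster: str = "lightgbm"  # or "xgboost"

    def __post_init__(self) -> None:
        if self.task not in ("regression", "binary", "multiclass"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.task == "multiclass" and self.n_classes < 3:
            raise ValueError("multiclass task needs n_classes >= 3")
        if self.booster not in ("lightgbm", "xgboost"):
            raise ValueError(f"unknown booster {self.booster!r}")


def default_config(task: str, n_classes: int = 1, seed: int = 0, booster: str = "lightgbm") -> GBDTConfig:
    """The package's documented fixed default configuration."""
    return GBDTConfig(task=task, n_classes=n_classes, seed=seed, booster=booster)


@dataclass
class FittedBooster:
    """Opaque handle to a trained ensemble plus the metadata callers need."""

    model: object
    task: str
    n_features: int
    class_count: int
    config: GBDTConfig

    def raw_predict(self, x: np.ndarray) -> np.ndarray:
        """Raw-score (margin) predictions; shape (n,) or (n, k) for multiclass."""
        if self.config.booster == "lightgbm":
            return self.model.predict(x, raw_score=True)
        dm = xgb.DMatrix(x)
        return self.model.predict(dm, output_margin=True)

    def to_text(self) -> str:
        """Serialize to the boosting library's native text format."""
        if self.config.booster == "lightgbm":
            return self.model.model_to_string()
        return "\n".join(self.model.get_dump())


@dataclass
class AttributionMatrix:
    """Per-instance, per-column attributions.

    ``values`` has shape (n, m) for regression/binary or (k, n, m) for
    multiclass on the raw-score scale; ``base_value`` holds the matching
    expected predictions, so attributions plus base equal the raw prediction
    row by row (local accuracy).
    """

    values: np.ndarray
    base_value: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.values.shape[-1]


@dataclass
class ImportanceVector:
    """One non-negative aggregated importance per augmented column."""

    z: np.ndarray
    aggregation: str
    per_class: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if np.any(self.z < 0):
            raise ValueError("importances must be non-negative")


def _lgb_params(cfg: GBDTConfig) -> dict:
    hp = cfg.hyperparameters
    params = {
        "learning_rate": hp.get("learning_rate", 0.2),
        "num_leaves": int(hp.get("num_leaves", 15)),
        "max_depth": int(hp.get("max_depth", -1)),
        "min_data_in_leaf": int(hp.get("min_data_in_leaf", 10)),
        "feature_fraction": hp.get("feature_fraction", 0.5),
        "max_bin": int(hp.get("max_bin", 63)),
        "verbose": -1,
        "seed": cfg.seed,
        "num_threads": 1 if cfg.deterministic else 0,
        "deterministic": cfg.deterministic,
        "force_col_wise": True,
    }
    if cfg.task == "regression":
        params["objective"] = "regression"
    elif cfg.task == "binary":
        params["objective"] = "binary"
    else:
        params["objective"] = "multiclass"
        params["num_class"] = cfg.n_classes
    return params


def _xgb_params(cfg: GBDTConfig) -> dict:
    hp = cfg.hyperparameters
    params = {
        "eta": hp.get("learning_rate", 0.2),
        "max_leaves": int(hp.get("num_leaves", 15)),
        "grow_policy": "lossguide",
        "max_depth": 0 if int(hp.get("max_depth", -1)) < 0 else int(hp.get("max_depth")),
        "min_child_weight": int(hp.get("min_data_in_leaf", 10)),
        "colsample_bytree": hp.get("feature_fraction", 0.5),
        "max_bin": int(hp.get("max_bin", 63)),
        "tree_method": "hist",
        "seed": cfg.seed,
        "nthread": 1 if cfg.deterministic else 0,
    }
    if cfg.task == "regression":
        params["objective"] = "reg:squarederror"
    elif cfg.task == "binary":
        params["objective"] = "binary:logistic"
    else:
        params["objective"] = "multi:softprob"
        params["num_class"] = cfg.n_classes
    return params


def _validate_response(y: np.ndarray, cfg: GBDTConfig) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("response contains NaN or infinite values")
    if cfg.task in ("binary", "multiclass"):
        labels = np.unique(y)
        if labels.size < 2:
            raise ValueError("classification response has a single class")
        k = 2 if cfg.task == "binary" else cfg.n_classes
        if not np.all(np.isin(labels, np.arange(k))):
            raise ValueError(f"labels must be integers in 0..{k - 1}")
    return y


def fit_booster(aug: AugmentedDesign, y: Sequence[float], cfg: GBDTConfig) -> FittedBooster:
    """Train a boosted-tree ensemble on the augmented design.

    With ``cfg.deterministic`` and a fixed seed, refitting reproduces the
    ensemble (single-threaded, deterministic histogram construction).
    """
    x = np.asarray(aug.values, dtype=float)
    y = _validate_response(np.asarray(y), cfg)
    if len(y) != x.shape[0]:
        raise ValueError("response length does not match the design")
    rounds = int(cfg.hyperparameters.get("n_estimators", 50))
    if cfg.booster == "lightgbm":
        model = lgb.train(_lgb_params(cfg), lgb.Dataset(x, label=y), num_boost_round=rounds)
    else:
        model = xgb.train(_xgb_params(cfg), xgb.DMatrix(x, label=y), num_boost_round=rounds)
    k = cfg.n_classes if cfg.task == "multiclass" else (2 if cfg.task == "binary" else 1)
    return FittedBooster(model=model, task=cfg.task, n_features=x.shape[1], class_count=k, config=cfg)


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

_SEARCH_SPACE = {
    "learning_rate": (0.05, 0.3),       # log-uniform
    "num_leaves": (7, 15, 31),
    "min_data_in_leaf": (5, 10, 20),
    "feature_fraction": (0.2, 0.8),     # uniform
    "n_estimators": (50, 100),
}


def _cv_loss(aug: AugmentedDesign, y: np.ndarray, cfg: GBDTConfig, nfold: int = 3) -> float:
    params = _lgb_params(cfg)
    metric = {"regression": "l2", "binary": "binary_logloss", "multiclass": "multi_logloss"}[cfg.task]
    params["metric"] = metric
    res = lgb.cv(
        params,
        lgb.Dataset(np.asarray(aug.values), label=y),
        num_boost_round=int(cfg.hyperparameters.get("n_estimators", 50)),
        nfold=nfold,
        seed=cfg.seed,
        shuffle=True,
        stratified=cfg.task != "regression",
    )
    return float(res[f"valid {metric}-mean"][-1])


def tune_hyperparameters(
    aug: AugmentedDesign,
    y: Sequence[float],
    cfg: GBDTConfig | None = None,
    budget: int = 25,
    seed: int = 0,
) -> GBDTConfig:
    """Fixed-budget random search over the documented hyperparameter space.

    Cross-validated loss (3-fold) decides; the default configuration is
    always evaluated first, so the returned config never does worse than the
    default up to CV noise.  ``budget=0`` returns the default unchanged.
    Deterministic per ``seed``.
    """
    if cfg is None:
        cfg = default_config("regression")
    if budget < 0:
        raise ValueError("budget must be >= 0")
    if budget == 0:
        return cfg
    y = _validate_response(np.asarray(y), cfg)
    rng = np.random.default_rng(seed)
    best_cfg = cfg
    best_loss = _cv_loss(aug, y, cfg)
    for _ in range(budget):
        hp = dict(DEFAULT_HYPERPARAMETERS)
        lo, hi = _SEARCH_SPACE["learning_rate"]
        hp["learning_rate"] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        hp["num_leaves"] = int(rng.choice(_SEARCH_SPACE["num_leaves"]))
        hp["min_data_in_leaf"] = int(rng.choice(_SEARCH_SPACE["min_data_in_leaf"]))
        lo, hi = _SEARCH_SPACE["feature_fraction"]
        hp["feature_fraction"] = float(rng.uniform(lo, hi))
        hp["n_estimators"] = int(rng.choice(_SEARCH_SPACE["n_estimators"]))
        trial = replace(cfg, hyperparameters=hp)
        loss = _cv_loss(aug, y, trial)
        if loss < best_loss:
            best_loss, best_cfg = loss, trial
    return best_cfg


# ---------------------------------------------------------------------------
# attributions
# ---------------------------------------------------------------------------


def compute_attributions(
    model: FittedBooster,
    aug: AugmentedDesign,
    mode: str = "path",
    background: np.ndarray | None = None,
) -> AttributionMatrix:
    """Tree-exact Shapley attributions for every instance in ``aug``.

    ``mode="path"`` (default) uses the library's TreeSHAP with
    path-dependent conditional expectations; no background sample is needed.
    ``mode="interventional"`` marginalizes over an explicit ``background``
    sample by per-tree coalition enumeration (small models only); it exists
    chiefly so results can be cross-checked against brute-force Shapley
    values.  Attributions are on the raw-score scale, where local accuracy
    (attributions + base = raw prediction) is exact.
    """
    x = np.asarray(aug.values, dtype=float)
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"design width {x.shape[1]} does not match the fitted width {model.n_features}"
        )
    if mode == "interventional":
        if background is None:
            raise ValueError("interventional mode requires a background sample")
        return _interventional_attributions(model, x, np.asarray(background, dtype=float))
    if mode != "path":
        raise ValueError(f"unknown attribution mode {mode!r}")

    n, m = x.shape
    if model.config.booster == "lightgbm":
        contrib = np.asarray(model.model.predict(x, pred_contrib=True))
        if model.task == "multiclass":
            k = model.class_count
            contrib = contrib.reshape(n, k, m + 1).transpose(1, 0, 2)
            return AttributionMatrix(values=contrib[:, :, :-1], base_value=contrib[:, :, -1])
        return AttributionMatrix(values=contrib[:, :-1], base_value=contrib[:, -1])
    contrib = model.model.predict(xgb.DMatrix(x), pred_contribs=True)
    if model.task == "multiclass":
        contrib = np.transpose(contrib, (1, 0, 2))
        return AttributionMatrix(values=contrib[:, :, :-1], base_value=contrib[:, :, -1])
    return AttributionMatrix(values=contrib[:, :-1], base_value=contrib[:, -1])


def _parse_lgb_trees(model: lgb.Booster) -> tuple[list[dict], int]:
    dump = model.dump_model()
    return dump["tree_info"], dump["num_tree_per_iteration"]


def _tree_features(node: dict, out: set[int]) -> None:
    if "split_feature" in node:
        out.add(int(node["split_feature"]))
        _tree_features(node["left_child"], out)
        _tree_features(node["right_child"], out)


def _eval_tree(node: dict, xrow: np.ndarray, zrow: np.ndarray, coalition: frozenset) -> float:
    while "split_feature" in node:
        f = int(node["split_feature"])
        val = xrow[f] if f in coalition else zrow[f]
        if node["decision_type"] != "<=":
            raise NotImplementedError("only numeric '<=' splits are supported")
        node = node["left_child"] if val <= node["threshold"] else node["right_child"]
    return float(node["leaf_value"])


def _interventional_attributions(
    model: FittedBooster, x: np.ndarray, background: np.ndarray
) -> AttributionMatrix:
    """Exact interventional Shapley values, one tree at a time.

    Each tree's game only involves the features it actually splits on
    (everything else is a null player), so coalitions are enumerated over
    that subset and results summed across trees — Shapley values are
    additive over additive ensembles.  LightGBM models only.
    """
    if model.config.booster != "lightgbm":
        raise NotImplementedError("interventional attributions are implemented for lightgbm models")
    trees, per_iter = _parse_lgb_trees(model.model)
    n, m = x.shape
    k = per_iter
    phi = np.zeros((k, n, m))
    base = np.zeros((k, n))
    for t_idx, tree in enumerate(trees):
        cls = t_idx % per_iter
        root = tree["tree_structure"]
        if "split_feature" not in root:  # constant tree
            base[cls] += float(root.get("leaf_value", root.get("internal_value", 0.0)))
            continue
        used: set[int] = set()
        _tree_features(root, used)
        feats = sorted(used)
        u = len(feats)
        if u > 12:
            raise ValueError("interventional mode supports trees using at most 12 features")
        # v[S][i] = mean over background of the tree with coalition S from x
        values: dict[frozenset, np.ndarray] = {}
        for r in range(u + 1):
            for combo in itertools.combinations(feats, r):
                S = frozenset(combo)
                acc = np.zeros(n)
                for zrow in background:
                    acc += np.array([_eval_tree(root, x[i], zrow, S) for i in range(n)])
                values[S] = acc / background.shape[0]
        base[cls] += values[frozenset()]
        for i_feat in feats:
            others = [f for f in feats if f != i_feat]
            for r in range(u):
                w = math.factorial(r) * math.factorial(u - r - 1) / math.factorial(u)
                for combo in itertools.combinations(others, r):
                    S = frozenset(combo)
                    phi[cls, :, i_feat] += w * (values[S | {i_feat}] - values[S])
    if model.task == "multiclass":
        return AttributionMatrix(values=phi, base_value=base)
    return AttributionMatrix(values=phi[0], base_value=base[0])


def brute_force_shapley(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    instance: np.ndarray,
    background: np.ndarray,
    feature_count: int | None = None,
) -> np.ndarray:
    """Exact Shapley values of ``predict_fn`` at ``instance`` by enumeration.

    The value of a coalition S is the mean prediction over the background
    sample with out-of-coalition features replaced by background values
    (interventional expectation).  Enumerates all 2^p coalitions, so it is
    restricted to at most 12 features; used as the oracle for the tree-based
    attribution algorithms.
    """
    instance = np.asarray(instance, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    p = instance.size if feature_count is None else feature_count
    if p > 12:
        raise ValueError("brute-force Shapley is limited to 12 features")
    if background.shape[1] != instance.size:
        raise ValueError("background width does not match the instance")

    values: dict[frozenset, float] = {}
    for r in range(p + 1):
        for combo in itertools.combinations(range(p), r):
            S = frozenset(combo)
            hybrid = background.copy()
            if combo:
                hybrid[:, list(combo)] = instance[list(combo)]
            values[S] = float(np.mean(predict_fn(hybrid)))

    phi = np.zeros(p)
    for i in range(p):
        others = [f for f in range(p) if f != i]
        for r in range(p):
            w = math.factorial(r) * math.factorial(p - r - 1) / math.factorial(p)
            for combo in itertools.combinations(others, r):
                S = frozenset(combo)
                phi[i] += w * (values[S | {i}] - values[S])
    return phi


def aggregate_importance(attr: AttributionMatrix, aggregation: str = "mean_abs") -> ImportanceVector:
    """Collapse per-instance attributions into one score per column.

    ``mean_abs`` averages |phi_ij| over instances (invariant to n);
    ``sum_abs`` sums them.  The two are proportional, hence identically
    ranked.  For multiclass, columns are aggregated within each class and
    the per-class scores summed.
    """
    if aggregation not in ("mean_abs", "sum_abs"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    vals = np.asarray(attr.values, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("attributions contain non-finite values")
    reducer = np.mean if aggregation == "mean_abs" else np.sum
    if vals.ndim == 3:  # (k, n, m)
        per_class = reducer(np.abs(vals), axis=1)
        return ImportanceVector(z=per_class.sum(axis=0), aggregation=aggregation, per_class=per_class)
    return ImportanceVector(z=reducer(np.abs(vals), axis=0), aggregation=aggregation)
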