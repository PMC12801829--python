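"""Synthetic study scenarios: block-Gaussian designs and six response models.

The design is shared by every scenario: rows are i.i.d. N_p(0, Sigma) with
block-diagonal Sigma made of 10x10 AR(1) blocks, sigma_{jk} = rho^{|j-k|},
rho = 0.1 by default.  Responses cover linear and nonlinear regression,
logistic binary labels and three-class multinomial labels; the default
amplitude puts coefficient 2 on the first ten features (3/2 on the first
two blocks for the linear multiclass case).  Repeated runs of the selection
pipeline yield FDP, power and runtime summaries.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import filtering, importance as imp, knockoffs as ko

__all__ = [
    "SimulationScenario",
    "StudyResult",
    "SCENARIO_KINDS",
    "make_block_sigma",
    "draw_design",
    "gen_response",
    "fdp_and_power",
    "run_study",
]

logger = logging.getLogger(__name__)

SCENARIO_KINDS = (
    "lin_reg",
    "lin_binary",
    "lin_multi3",
    "nonlin_reg",
    "nonlin_binary",
    "nonlin_multi3",
)


@dataclass
class SimulationScenario:
    """One study condition: design size, dependence and response model."""

    kind: str
    n: int = 1000
    p: int = 1000
    rho: float = 0.1
    block_size: int = 10
    amplitude: float = 2.0
    q: float | None = None  # default: 0.1, except 0.2 for nonlin_multi3

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.p % self.block_size:
            raise ValueError("p must be divisible by block_size")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if self.q is None:
            self.q = 0.2 if self.kind == "nonlin_multi3" else 0.1
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        if self.kind in ("nonlin_binary", "nonlin_multi3") and self.p < 10:
            raise ValueError("nonlinear scenarios need p >= 10")

    @property
    def task(self) -> str:
        return {
            "lin_reg": "regression",
            "nonlin_reg": "regression",
            "lin_binary": "binary",
            "nonlin_binary": "binary",
            "lin_multi3": "multiclass",
            "nonlin_multi3": "multiclass",
        }[self.kind]

    @property
    def true_support(self) -> set[int]:
        """0-based indices of the truly relevant features."""
        if self.kind == "lin_multi3":
            return set(range(20))
        return set(range(10))


@dataclass
class StudyResult:
    """Per-repetition records and their summary, one scenario x method."""

    scenario: SimulationScenario
    method: str
    per_rep: list[dict] = field(default_factory=list)
    failures: int = 0

    def summary(self) -> dict:
        fdp = np.array([r["fdp"] for r in self.per_rep])
        power = np.array([r["power"] for r in self.per_rep])
        rt = np.array([r["runtime_seconds"] for r in self.per_rep])
        return {
            "method": self.method,
            "kind": self.scenario.kind,
            "n": self.scenario.n,
            "p": self.scenario.p,
            "q": self.scenario.q,
            "reps": len(self.per_rep),
            "failures": self.failures,
            "fdr_mean": float(fdp.mean()) if fdp.size else float("nan"),
            "fdr_sd": float(fdp.std(ddof=1)) if fdp.size > 1 else 0.0,
            "power_mean": float(power.mean()) if power.size else float("nan"),
            "runtime_mean": float(rt.mean()) if rt.size else float("nan"),
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.per_rep)


def make_block_sigma(p: int, block_size: int = 10, rho: float = 0.1) -> ko.CovarianceModel:
    """Block-diagonal covariance of AR(1) blocks, sigma_{jk} = rho^{|j-k|}."""
    if p % block_size:
        raise ValueError("p must be divisible by block_size")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    idx = np.arange(block_size)
    block = rho ** np.abs(idx[:, None] - idx[None, :])
    sigma = np.zeros((p, p))
    for b in range(p // block_size):
        lo = b * block_size
        sigma[lo : lo + block_size, lo : lo + block_size] = block
    return ko.CovarianceModel(mu=np.zeros(p), sigma=sigma, shrinkage=0.0, unit_diagonal=True)


def draw_design(scenario: SimulationScenario, seed: int) -> ko.DesignMatrix:
    """Rows i.i.d. N_p(0, Sigma) with the scenario's block covariance."""
    rng = ko.stream(seed, key=1)
    bs = scenario.block_size
    idx = np.arange(bs)
    chol = np.linalg.cholesky(scenario.rho ** np.abs(idx[:, None] - idx[None, :]))
    x = rng.standard_normal((scenario.n, scenario.p))
    for b in range(scenario.p // bs):
        lo = b * bs
        x[:, lo : lo + bs] = x[:, lo : lo + bs] @ chol.T
    return ko.DesignMatrix(values=x)


def _beta(scenario: SimulationScenario) -> np.ndarray:
    beta = np.zeros(scenario.p)
    beta[:10] = scenario.amplitude
    return beta


def _softmax_sample(logits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    prob = np.exp(shifted)
    prob /= prob.sum(axis=1, keepdims=True)
    u = rng.random(prob.shape[0])
    return (prob.cumsum(axis=1) < u[:, None]).sum(axis=1)


def nonlinear_binary_score(x: np.ndarray) -> np.ndarray:
    """Quadratic/linear score on the first ten features for binary labels."""
    return (
        2 * x[:, 0] ** 2 + 2 * x[:, 1] ** 2 - 2 * x[:, 2] ** 2 - 2 * x[:, 3] ** 2
        + 2 * x[:, 4] - 2 * x[:, 5] + 2 * x[:, 6] - 2 * x[:, 7] + 2 * x[:, 8] + 2 * x[:, 9]
    )


def nonlinear_class_scores(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """The two class score functions of the nonlinear three-class model."""
    f1 = 2 * x[:, 0] + 2 * x[:, 2] ** 2 - 0.2 * x[:, 4] + 0.4 * x[:, 6] + 3 * x[:, 8]
    f2 = (
        x[:, 0] ** 2 + 0.6 * x[:, 1] - 0.5 * x[:, 3] ** 2
        + 2 * x[:, 5] + 2.5 * x[:, 7] - 3 * x[:, 9]
    )
    return f1, f2


def gen_response(scenario: SimulationScenario, x: ko.DesignMatrix, seed: int) -> np.ndarray:
    """Draw the scenario's response given a realized design.

    lin_reg:    y = X beta + N(0, I), beta = amplitude on features 1..10.
    lin_binary: Bernoulli with logit X beta.
    lin_multi3: multinomial logit with logits (X b1, X b2, 0); b1 = 3 on
                features 1..10, b2 = 2 on 11..20, class 3 the zero-logit
                baseline.
    nonlin_reg: y = (X**2) beta + N(0, I), elementwise square.
    nonlin_binary: score f(x) standardized as (f - median)/sd and passed
                through the logistic function; label ~ Bernoulli.  (The
                source model states only p(x) proportional to f(x), which is
                ill-defined for negative scores; this normalization keeps
                classes balanced and the support on features 1..10.)
    nonlin_multi3: class ~ categorical(softmax(f1, f2, 0)).
    Deterministic per seed; the noise stream is independent of the design
    stream even for equal seeds.
    """
    rng = ko.stream(seed, key=2)
    xv = x.values
    n = xv.shape[0]
    kind = scenario.kind
    if kind == "lin_reg":
        return xv @ _beta(scenario) + rng.standard_normal(n)
    if kind == "nonlin_reg":
        return (xv**2) @ _beta(scenario) + rng.standard_normal(n)
    if kind == "lin_binary":
        prob = 1.0 / (1.0 + np.exp(-(xv @ _beta(scenario))))
        return (rng.random(n) < prob).astype(float)
    if kind == "lin_multi3":
        b1 = np.zeros(scenario.p)
        b1[:10] = 3.0
        b2 = np.zeros(scenario.p)
        b2[10:20] = 2.0
        logits = np.column_stack([xv @ b1, xv @ b2, np.zeros(n)])
        return _softmax_sample(logits, rng).astype(float)
    if kind == "nonlin_binary":
        f = nonlinear_binary_score(xv)
        z = (f - np.median(f)) / f.std()
        prob = 1.0 / (1.0 + np.exp(-z))
        return (rng.random(n) < prob).astype(float)
    if kind == "nonlin_multi3":
        f1, f2 = nonlinear_class_scores(xv)
        logits = np.column_stack([f1, f2, np.zeros(n)])
        return _softmax_sample(logits, rng).astype(float)
    raise ValueError(f"unknown scenario kind {kind!r}")


def fdp_and_power(selected, true_support) -> tuple[float, float]:
    """False discovery proportion and power of a selected set.

    fdp = |selected \\ true| / max(1, |selected|): zero when nothing is
    selected.  power = |selected intersect true| / |true|.
    """
    true = set(true_support)
    if not true:
        raise ValueError("true_support must be non-empty")
    sel = set(selected)
    fdp = len(sel - true) / max(1, len(sel))
    power = len(sel & true) / len(true)
    return fdp, power


def run_study(
    scenario: SimulationScenario,
    reps: int,
    method: str = "gbdt_shap",
    seed: int = 0,
    tune_budget: int = 0,
) -> StudyResult:
    """Repeat draw -> select -> score, with per-rep seeds ``seed + r``.

    Methods: ``gbdt_shap`` (LightGBM + SHAP statistic),
    ``gbdt_shap_alt_booster`` (XGBoost + SHAP), ``lasso_knockoff`` (the
    classical Lasso-path statistic; regression and binary kinds only).
    Per-rep failures are logged, counted and excluded from the summary.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if method not in ("gbdt_shap", "gbdt_shap_alt_booster", "lasso_knockoff"):
        raise ValueError(f"unknown method {method!r}")
    result = StudyResult(scenario=scenario, method=method)
    true = scenario.true_support
    for r in range(reps):
        rep_seed = int((seed + r) % 2**31)
        t0 = time.perf_counter()
        try:
            x = draw_design(scenario, rep_seed)
            y = gen_response(scenario, x, rep_seed)
            if method == "lasso_knockoff":
                sel = _lasso_knockoff_select(scenario, x, y, rep_seed)
            else:
                booster = "xgboost" if method == "gbdt_shap_alt_booster" else "lightgbm"
                n_classes = 3 if scenario.task == "multiclass" else 1
                cfg = imp.default_config(scenario.task, n_classes=n_classes, booster=booster)
                sel = filtering.run_pipeline(
                    x, y, q=scenario.q, cfg=cfg, seed=rep_seed, tune_budget=tune_budget
                )
        except Exception:
            logger.exception("repetition %d failed; recorded as missing", r)
            result.failures += 1
            continue
        fdp, power = fdp_and_power(sel.selected, true)
        result.per_rep.append(
            {
                "rep": r,
                "seed": rep_seed,
                "fdp": fdp,
                "power": power,
                "n_selected": len(sel.selected),
                "runtime_seconds": time.perf_counter() - t0,
            }
        )
    return result


def _lasso_knockoff_select(
    scenario: SimulationScenario, x: ko.DesignMatrix, y: np.ndarray, seed: int
) -> filtering.SelectionResult:
    if scenario.task == "multiclass":
        raise ValueError("the lasso knockoff baseline supports regression and binary tasks")
    cov = ko.estimate_covariance(x, "auto")
    svec = ko.solve_s_equi(cov)
    kmod = ko.sample_knockoffs(x, cov, svec, seed)
    z = filtering.lasso_path_statistic(x, kmod, y, task=scenario.task)
    w = filtering.compute_w(z, kind="shap_signed_max")
    w.kind = "lasso_lambda"
    tau = filtering.knockoff_threshold(w, scenario.q, offset=1)
    return filtering.select(w, tau, q=scenario.q, feature_names=x.feature_names, seed=seed)
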