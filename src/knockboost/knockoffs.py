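"""Second-order Gaussian model-X knockoff construction.

A knockoff copy ``K`` of a design matrix ``X`` mimics the covariance
structure of the original features while carrying no information about the
response.  On the unit-diagonal (correlation) scale the construction targets

    cov([X K]) = [[Sigma, Sigma - diag(s)], [Sigma - diag(s), Sigma]]

where ``s`` is a non-negative vector chosen as large as possible subject to
``2*Sigma - diag(s)`` being positive semidefinite, so that each knockoff is
as decorrelated from its original as feasible.  Sampling uses the Gaussian
conditional ``K | X`` implied by that joint covariance, which is valid for
n < p (the high-dimensional regime) where exact fixed-design constructions
do not exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.covariance import ledoit_wolf

__all__ = [
    "DesignMatrix",
    "CovarianceModel",
    "SVector",
    "KnockoffModel",
    "AugmentedDesign",
    "estimate_covariance",
    "solve_s_equi",
    "solve_s_sdp",
    "sample_knockoffs",
    "augment",
]

logger = logging.getLogger(__name__)

_PSD_TOL = 1e-6
_JITTER = 1e-8


def stream(seed: int, key: int) -> np.random.Generator:
    """An RNG stream independent of other keys derived from the same seed.

    Distinct operations (design generation, knockoff sampling, response
    noise, ...) must never replay each other's random numbers even when
    handed the same integer seed, so each draws from its own spawn key.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class DesignMatrix:
    """An n-samples by p-features numeric matrix with column names."""

    values: np.ndarray
    feature_names: list[str] | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("design matrix must be 2-dimensional")
        n, p = self.values.shape
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 and p >= 1, got shape {(n, p)}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("design matrix contains non-finite entries")
        if self.feature_names is None:
            self.feature_names = [f"V{j + 1}" for j in range(p)]
        if len(self.feature_names) != p:
            raise ValueError("feature_names length does not match column count")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature_names must be unique")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class CovarianceModel:
    """Feature location/scale and a unit-diagonal covariance estimate."""

    mu: np.ndarray
    sigma: np.ndarray
    shrinkage: float
    unit_diagonal: bool = True
    scale: np.ndarray | None = None  # column sd's used for standardization

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        if self.unit_diagonal and not np.allclose(np.diag(self.sigma), 1.0, atol=1e-8):
            raise ValueError("sigma diagonal must be 1 when unit_diagonal is set")
        if self.scale is None:
            self.scale = np.ones(self.sigma.shape[0])
        else:
            self.scale = np.asarray(self.scale, dtype=float)

    @property
    def p(self) -> int:
        return self.sigma.shape[0]

    def min_eigenvalue(self) -> float:
        return float(linalg.eigvalsh(self.sigma, subset_by_index=[0, 0])[0])


@dataclass
class SVector:
    """The per-feature decorrelation amounts, on the unit-diagonal scale."""

    s: np.ndarray
    method: str  # "equi" or "sdp"

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if np.any(self.s < -1e-12) or np.any(self.s > 1.0 + 1e-12):
            raise ValueError("s entries must lie in [0, 1] on the unit-diagonal scale")
        self.s = np.clip(self.s, 0.0, 1.0)


@dataclass
class KnockoffModel:
    """Sampled knockoff matrix together with its generating ingredients."""

    knockoffs: np.ndarray
    s: SVector
    covariance: CovarianceModel
    seed: int


@dataclass
class AugmentedDesign:
    """The n x 2p matrix [X K] plus the original<->knockoff column pairing."""

    values: np.ndarray
    pairing: dict[int, int]
    permutation: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.values.shape[1] // 2


def _standardize(x: DesignMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center columns and scale to unit variance; reject constant columns."""
    mu = x.values.mean(axis=0)
    sd = x.values.std(axis=0)
    bad = np.where(sd == 0)[0]
    if bad.size:
        name = x.feature_names[bad[0]]
        raise ValueError(f"constant column (zero variance): {name!r}")
    return (x.values - mu) / sd, mu, sd


def estimate_covariance(x: DesignMatrix, shrinkage_mode: str | float = "auto") -> CovarianceModel:
    """Estimate a unit-diagonal covariance (correlation) matrix for ``x``.

    Parameters
    ----------
    x
        Design matrix; columns are centered and scaled to unit variance
        internally, so the estimate has unit diagonal.
    shrinkage_mode
        ``"none"`` for the raw sample correlation, ``"auto"`` for Ledoit-Wolf
        shrinkage toward the identity (needed whenever ``n <= p``, where the
        sample estimate is singular), or a float in [0, 1] for a fixed
        shrinkage intensity.  In every mode a final linear shrinkage step
        enforces a smallest eigenvalue of at least 1e-6.
    """
    xs, mu, sd = _standardize(x)
    n, p = xs.shape

    if shrinkage_mode == "auto":
        sigma, alpha = ledoit_wolf(xs, assume_centered=True)
        d = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(d, d)
        alpha = float(alpha)
    elif shrinkage_mode == "none":
        sigma = xs.T @ xs / n
        alpha = 0.0
    else:
        alpha = float(shrinkage_mode)
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("fixed shrinkage must be in [0, 1]")
        sigma = (1.0 - alpha) * (xs.T @ xs / n) + alpha * np.eye(p)

    np.fill_diagonal(sigma, 1.0)
    sigma = (sigma + sigma.T) / 2.0

    # shrinking toward the identity moves eigenvalues linearly, so the minimal
    # extra amount reaching lambda_min >= 1e-6 has a closed form
    lam_min = float(linalg.eigvalsh(sigma, subset_by_index=[0, 0])[0])
    if lam_min < _PSD_TOL:
        extra = (_PSD_TOL - lam_min) / (1.0 - lam_min)
        sigma = (1.0 - extra) * sigma + extra * np.eye(p)
        np.fill_diagonal(sigma, 1.0)
        alpha = alpha + (1.0 - alpha) * extra
        logger.info("covariance floor shrinkage engaged: extra=%.3e", extra)

    return CovarianceModel(mu=mu, sigma=sigma, shrinkage=alpha, unit_diagonal=True, scale=sd)


def solve_s_equi(sigma: CovarianceModel) -> SVector:
    """Equicorrelated s-vector: ``s_j = min(1, 2*lambda_min(Sigma))``."""
    lam_min = sigma.min_eigenvalue()
    if lam_min < -_PSD_TOL:
        raise ValueError(f"sigma is not PSD (lambda_min = {lam_min:.3e})")
    s_val = min(1.0, 2.0 * max(lam_min, 0.0))
    return SVector(s=np.full(sigma.p, s_val), method="equi")


def solve_s_sdp(sigma: CovarianceModel, sweeps: int = 3) -> SVector:
    """Per-feature s maximizing ``sum_j s_j`` subject to ``2*Sigma - diag(s) >= 0``.

    Solved by block-coordinate ascent: starting from the equicorrelated
    solution, each ``s_j`` in turn is pushed to its Schur-complement upper
    bound ``1 / (M^{-1})_{jj}`` where ``M = 2*Sigma - diag(s)`` with ``s_j``
    zeroed.  Every iterate is feasible, so the result always dominates the
    equicorrelated total.  Falls back to the equicorrelated vector if the
    ascent hits numerical trouble.
    """
    p = sigma.p
    s = solve_s_equi(sigma).s.copy() * (1.0 - 1e-6)
    try:
        for _ in range(sweeps):
            for j in range(p):
                m = 2.0 * sigma.sigma - np.diag(s)
                m[j, j] = 2.0 * sigma.sigma[j, j]
                # largest s_j keeping m - s_j e_j e_j' PSD
                ej = np.zeros(p)
                ej[j] = 1.0
                cap = 1.0 / float(linalg.solve(m, ej, assume_a="pos")[j])
                s[j] = min(1.0, cap * (1.0 - 1e-6))
        lam = linalg.eigvalsh(2.0 * sigma.sigma - np.diag(s), subset_by_index=[0, 0])[0]
        if lam < -_PSD_TOL:
            raise linalg.LinAlgError("coordinate ascent left the feasible set")
    except linalg.LinAlgError as exc:  # pragma: no cover - numerical fallback
        logger.warning("sdp s-vector solve failed (%s); falling back to equi", exc)
        return SVector(s=solve_s_equi(sigma).s, method="sdp")
    return SVector(s=s, method="sdp")


def sample_knockoffs(
    x: DesignMatrix, cov: CovarianceModel, s: SVector, seed: int
) -> KnockoffModel:
    """Draw Gaussian model-X knockoffs conditional on the observed design.

    On the standardized scale, rows of K are drawn from

        K | X ~ N( X - X Sigma^{-1} diag(s),  2 diag(s) - diag(s) Sigma^{-1} diag(s) )

    and mapped back to the original units of ``x``.  The construction never
    reads the response and is a pure function of ``(x, cov, s, seed)``.
    """
    n, p = x.values.shape
    if cov.p != p or s.s.shape[0] != p:
        raise ValueError("covariance / s-vector shape does not match the design")

    xs = (x.values - cov.mu) / cov.scale
    ds = np.diag(s.s)
    cho = linalg.cho_factor(cov.sigma)
    sigma_inv_ds = linalg.cho_solve(cho, ds)
    mean = xs - xs @ sigma_inv_ds
    v = 2.0 * ds - ds @ sigma_inv_ds
    v = (v + v.T) / 2.0
    try:
        chol_v = np.linalg.cholesky(v + _JITTER * np.eye(p))
    except np.linalg.LinAlgError as exc:
        raise ValueError("conditional knockoff covariance is not PSD") from exc

    rng = stream(seed, key=3)
    k_std = mean + rng.standard_normal((n, p)) @ chol_v.T
    k = k_std * cov.scale + cov.mu
    return KnockoffModel(knockoffs=k, s=s, covariance=cov, seed=seed)


def augment(
    x: DesignMatrix,
    k: KnockoffModel,
    shuffle: bool = False,
    seed: int | None = None,
) -> AugmentedDesign:
    """Stack ``[X K]`` column-wise, recording the original<->knockoff pairing.

    With ``shuffle=True`` the 2p columns are permuted (recorded permutation)
    so a position-sensitive learner cannot exploit the block layout.
    """
    if k.knockoffs.shape != x.values.shape:
        raise ValueError("knockoff matrix shape does not match the design")
    p = x.p
    values = np.hstack([x.values, k.knockoffs])
    pairing = {j: j + p for j in range(p)}
    names = list(x.feature_names) + [f"{nm}.knockoff" for nm in x.feature_names]
    permutation = None
    if shuffle:
        rng = stream(0 if seed is None else seed, key=4)
        permutation = rng.permutation(2 * p)
        values = values[:, permutation]
        names = [names[j] for j in permutation]
    return AugmentedDesign(values=values, pairing=pairing, permutation=permutation, feature_names=names)


def unshuffle(aug: AugmentedDesign) -> np.ndarray:
    """Invert a recorded column permutation, recovering the ``[X K]`` layout."""
    if aug.permutation is None:
        return aug.values
    inverse = np.argsort(aug.permutation)
    return aug.values[:, inverse]
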