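"""Questionnaire-reliability screen: NIPALS PCA, Hotelling T² ellipse,
the 10% acceptance rule, and per-variable contribution diagnostics.

A questionnaire round is judged reliable when at most 10% of patients fall
outside the 99% Hotelling-T² control ellipse of a two-component PCA of the
adjusted item scores (optionally plus SBP/DBP).  Flagged patients are
diagnosed with a contribution profile that identifies which variables drive
their distance from the model centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

__all__ = [
    "PreprocessSpec",
    "MultivariateModel",
    "HotellingResult",
    "ContributionProfile",
    "preprocess_fit",
    "fit_pca",
    "hotelling_limit",
    "hotelling_t2",
    "screen_questionnaire",
    "contribution_profile",
]

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500

#: Reliability acceptance bound: at most this percentage of observations
#: may fall outside the control ellipse.
ACCEPTANCE_PCT = 10.0


@dataclass(frozen=True)
class PreprocessSpec:
    """Column centering/scaling fitted on the training matrix.

    ``scaling`` is one of ``"uv"`` (unit variance, the SIMCA default),
    ``"pareto"`` (sqrt of the SD) or ``"none"``.  Zero-variance columns
    are dropped with a warning.
    """

    scaling: str
    column_means: np.ndarray
    column_scales: np.ndarray
    kept: np.ndarray  # indices of retained (non-constant) columns

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        one = X.ndim == 1
        X = np.atleast_2d(X)
        out = (X[:, self.kept] - self.column_means) / self.column_scales
        return out[0] if one else out


def preprocess_fit(X: np.ndarray, scaling: str = "uv") -> PreprocessSpec:
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    kept = np.flatnonzero(sds > 0)
    if kept.size < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - kept.size} zero-variance column(s)",
            stacklevel=2)
    sds = sds[kept]
    if scaling == "uv":
        scales = sds
    elif scaling == "pareto":
        scales = np.sqrt(sds)
    elif scaling == "none":
        scales = np.ones_like(sds)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return PreprocessSpec(scaling, means[kept], scales, kept)


@dataclass(frozen=True)
class MultivariateModel:
    """A fitted latent-variable decomposition X ~ T P'.

    Loading vectors (columns of P) have unit norm; score vectors are
    mutually orthogonal; ``r2x`` holds the fraction of preprocessed
    variance explained per component, nonincreasing.
    """

    n_components: int
    scores: np.ndarray      # N x A
    loadings: np.ndarray    # K x A
    r2x: np.ndarray         # per component
    preprocess: PreprocessSpec


def _nipals_component(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extract one principal component by NIPALS iteration."""
    t = X[:, int(np.argmax(X.var(axis=0)))].copy()
    if not np.any(t):
        t = X[:, 0] + 1e-12
    for _ in range(NIPALS_MAX_ITER):
        p = X.T @ t / (t @ t)
        p /= np.linalg.norm(p)
        t_new = X @ p
        if np.linalg.norm(t_new - t) < NIPALS_TOL * max(np.linalg.norm(t_new), 1.0):
            t = t_new
            break
        t = t_new
    return t, p


def fit_pca(
    X: np.ndarray,
    n_components: int = 2,
    scaling: str = "uv",
    preprocess: PreprocessSpec | None = None,
) -> MultivariateModel:
    """NIPALS PCA with deflation after each extracted component.

    Components are extracted one at a time (convergence when the score
    vector changes by less than 1e-10 relative norm, or 500 iterations)
    and the matrix is deflated by the rank-one reconstruction.  If the
    requested number of components exceeds the effective rank, the model
    is truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    n, k = X.shape
    if n < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} observations")
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        inds = np.where(np.isnan(X))
        X = X.copy()
        X[inds] = np.take(col_mean, inds[1])
        warnings.warn("missing values mean-imputed", stacklevel=2)
    spec = preprocess if preprocess is not None else preprocess_fit(X, scaling)
    Xp = spec.apply(X)
    if Xp.shape[1] == 0:
        raise ValueError("matrix is constant: no variance to decompose")

    total_ss = float((Xp**2).sum())
    R = Xp.copy()
    scores, loadings, r2x = [], [], []
    for a in range(n_components):
        if (R**2).sum() / total_ss < 1e-12:
            warnings.warn(
                f"rank exhausted after {a} component(s); truncating",
                stacklevel=2)
            break
        t, p = _nipals_component(R)
        R = R - np.outer(t, p)
        scores.append(t)
        loadings.append(p)
        r2x.append(float(t @ t) / total_ss)
    return MultivariateModel(
        n_components=len(scores),
        scores=np.column_stack(scores),
        loadings=np.column_stack(loadings),
        r2x=np.array(r2x),
        preprocess=spec,
    )


def hotelling_limit(n: int, n_components: int, alpha: float) -> float:
    """Critical T² value of the (1 - alpha) control ellipse.

    limit = A (N-1)(N+1) / (N (N-A)) * F_{1-alpha}(A, N-A), the standard
    ellipse constant for scores of observations inside the training set.
    As N -> inf this tends to the chi-squared quantile with A dof.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    a, n = int(n_components), int(n)
    if n <= a or a < 1:
        raise ValueError(f"need N > A >= 1, got N={n}, A={a}")
    f_crit = stats.f.ppf(1 - alpha, a, n - a)
    return float(a * (n - 1) * (n + 1) / (n * (n - a)) * f_crit)


def hotelling_t2(model: MultivariateModel) -> np.ndarray:
    """Per-observation T² = sum_a t_a² / var(t_a) over the model scores."""
    var = model.scores.var(axis=0, ddof=1)
    return (model.scores**2 / var).sum(axis=1)


@dataclass(frozen=True)
class HotellingResult:
    t2: np.ndarray
    limit: float
    flags: np.ndarray
    outside_fraction: float  # percent
    passed: bool
    model: MultivariateModel


def screen_questionnaire(
    X: np.ndarray,
    n_components: int = 2,
    alpha: float = 0.01,
    scaling: str = "uv",
    acceptance_pct: float = ACCEPTANCE_PCT,
) -> HotellingResult:
    """Fit the PCA, flag observations outside the T² ellipse, and apply
    the 10% acceptance rule.

    With 4 of 96 patients flagged the outside fraction is 4.17%, a pass.
    """
    model = fit_pca(X, n_components=n_components, scaling=scaling)
    t2 = hotelling_t2(model)
    limit = hotelling_limit(X.shape[0], model.n_components, alpha)
    flags = t2 > limit
    pct = Decimal(100 * int(flags.sum())) / Decimal(len(flags))
    outside = float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    return HotellingResult(
        t2=t2, limit=limit, flags=flags, outside_fraction=outside,
        passed=outside <= acceptance_pct, model=model)


@dataclass(frozen=True)
class ContributionProfile:
    observation: int
    contributions: np.ndarray  # per retained variable, signed

    def top(self, k: int) -> np.ndarray:
        """Indices of the k largest |contribution| variables."""
        order = np.argsort(-np.abs(self.contributions), kind="stable")
        return order[:k]


def contribution_profile(
    model: MultivariateModel, X: np.ndarray, observation: int,
) -> ContributionProfile:
    """Score-distance contribution of each variable to an observation's T².

    Each preprocessed value is weighted by the loading magnitudes of the
    model components, each component scaled by the observation's
    normalised score distance |t_a| / var(t_a):

        c_k = x_pre,k * sum_a (|t_ia| / var(t_a)) |p_ka|

    so the contribution carries the sign of the variable's deviation from
    the model centre (below-mean values contribute negatively), and its
    magnitude reflects how strongly that variable loads on the components
    along which the observation is extreme.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if not 0 <= observation < n:
        raise KeyError(f"unknown observation {observation} (N={n})")
    x_pre = model.preprocess.apply(X[observation])
    t = model.scores[observation]
    var = model.scores.var(axis=0, ddof=1)
    weights = np.abs(model.loadings) @ (np.abs(t) / var)
    return ContributionProfile(observation, x_pre * weights)
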