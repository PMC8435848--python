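"""Statistical layer: GLMs with AICc selection, a univariate
smoothing-spline additive model with GCV, and ordinary least squares.

The factorial analysis asks which of temperature, N:P supply ratio and
nitrate concentration (entered numerically) drive each response, comparing
models with first-order effects only, plus second-order interactions, plus
the third-order interaction.  Model choice follows an AICc rule: the more
complex model must improve AICc by at least 10 units; otherwise the
simplest model wins unless a richer model shows a significant (p < 0.05)
interaction term.

The additive-model component quantifies the *amplitude* of the nitrate
effect on a response: a penalized cubic B-spline s(x) with a
second-derivative penalty, smoothing parameter chosen by generalized
cross-validation, effective degrees of freedom = trace of the hat matrix.
The response amplitude is max - min of the centred partial effect over the
observed nitrate range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from scipy.interpolate import BSpline
import statsmodels.api as sm

from .errors import InvalidArgumentError

P_SIGNIFICANT = 0.05

FACTORS: tuple[str, ...] = ("temperature", "np_ratio", "nitrate")


@dataclass(frozen=True)
class ModelSpec:
    """A GLM candidate: response, factors, and interaction order (1..3)."""

    response: str
    factors: tuple[str, ...] = FACTORS
    order: int = 1
    family_link: str = "gaussian_identity"

    def __post_init__(self) -> None:
        if self.order not in (1, 2, 3):
            raise InvalidArgumentError("order must be 1, 2 or 3")
        if self.family_link not in ("gaussian_identity", "gamma_log"):
            raise InvalidArgumentError(f"unknown family {self.family_link!r}")

    def term_names(self) -> list[str]:
        from itertools import combinations

        terms = list(self.factors)
        if self.order >= 2:
            terms += [":".join(c) for c in combinations(self.factors, 2)]
        if self.order >= 3 and len(self.factors) >= 3:
            terms += [":".join(c) for c in combinations(self.factors, 3)]
        return terms


@dataclass
class GLMFit:
    spec: ModelSpec
    coefficients: pd.DataFrame  # index: term; columns: coef, se, t, p
    loglik: float
    k: int  # estimated parameters incl. intercept and dispersion
    n: int
    aicc: float

    def interaction_pvalues(self) -> pd.Series:
        mask = self.coefficients.index.str.contains(":")
        return self.coefficients.loc[mask, "p"]


@dataclass
class GAMFit:
    lambda_: float
    edf: float
    gcv: float
    r2_adj: float
    deviance_explained: float
    intercept: float
    intercept_se: float
    p_smooth: float
    partial_x: np.ndarray
    partial_s: np.ndarray
    knots: np.ndarray = field(repr=False, default=None)
    coefs: np.ndarray = field(repr=False, default=None)
    n: int = 0


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def design_matrix(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Numeric design matrix (with intercept) for a model spec."""
    missing = [f for f in spec.factors if f not in table.columns]
    if missing:
        raise InvalidArgumentError(f"missing factor columns: {missing}")
    X = pd.DataFrame({"Intercept": np.ones(len(table))}, index=table.index)
    for term in spec.term_names():
        parts = term.split(":")
        col = table[parts[0]].astype(float).copy()
        for p in parts[1:]:
            col = col * table[p].astype(float)
        X[term] = col
    return X


def fit_glm(table: pd.DataFrame, spec: ModelSpec) -> GLMFit:
    """Fit one GLM candidate by IRLS (statsmodels backend).

    Default family is Gaussian with identity link; ``gamma_log`` selects a
    Gamma family with log link for strictly positive responses.  ``k``
    counts the regression coefficients plus the dispersion parameter.
    """
    if spec.response not in table.columns:
        raise InvalidArgumentError(f"response {spec.response!r} not in table")
    data = table.dropna(subset=[spec.response, *spec.factors])
    y = data[spec.response].astype(float)
    X = design_matrix(data, spec)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise InvalidArgumentError(
            f"rank-deficient design ({rank} < {X.shape[1]}); "
            f"aliased terms among {list(X.columns)}"
        )
    family = (
        sm.families.Gamma(link=sm.families.links.Log())
        if spec.family_link == "gamma_log"
        else sm.families.Gaussian()
    )
    n = len(y)
    k = X.shape[1] + 1
    if n <= k + 1:
        raise InvalidArgumentError(f"n={n} too small for k={k} (AICc undefined)")
    res = sm.GLM(y, X, family=family).fit()
    coef = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )
    return GLMFit(
        spec=spec,
        coefficients=coef,
        loglik=float(res.llf),
        k=k,
        n=n,
        aicc=aicc(float(res.llf), k, n),
    )


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: ``-2 l + 2k + 2k(k+1)/(n-k-1)``."""
    if n <= k + 1:
        raise InvalidArgumentError("AICc undefined for n <= k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def select_model(candidates: list[GLMFit]) -> GLMFit:
    """AICc-based choice among nested candidates.

    The lowest-AICc model wins only if it improves on every simpler
    candidate by >= 10 units; otherwise the simplest model is chosen,
    unless a more complex candidate contains a significant (p < 0.05)
    interaction term, in which case the best such candidate wins.  The
    result is invariant to the order of ``candidates``.
    """
    if not candidates:
        raise InvalidArgumentError("empty candidate list")
    ranked = sorted(candidates, key=lambda f: (f.k, f.aicc, f.spec.order))
    best = min(ranked, key=lambda f: (f.aicc, f.k))
    simpler = [c for c in ranked if c.k < best.k]
    if all(c.aicc - best.aicc >= 10.0 for c in simpler):
        return best
    simplest = ranked[0]
    with_sig = [
        c
        for c in ranked
        if c.k > simplest.k and (c.interaction_pvalues() < P_SIGNIFICANT).any()
    ]
    if with_sig:
        return min(with_sig, key=lambda f: (f.aicc, f.k))
    return simplest


def _bspline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    return BSpline.design_matrix(x, knots, 3, extrapolate=True).toarray()


def _penalty_matrix(knots: np.ndarray, nb: int) -> np.ndarray:
    """Second-derivative penalty S_jk = integral of B_j'' B_k''.

    Second derivatives of cubic B-splines are piecewise linear, so 2-point
    Gauss-Legendre per inter-knot interval integrates the products exactly.
    """
    from scipy.interpolate import splev

    S = np.zeros((nb, nb))
    gl_x = np.array([-1.0, 1.0]) / math.sqrt(3.0)
    gl_w = np.array([1.0, 1.0])
    uniq = np.unique(knots)
    for a, b in zip(uniq[:-1], uniq[1:]):
        half = 0.5 * (b - a)
        pts = 0.5 * (a + b) + half * gl_x
        vals = np.empty((nb, len(pts)))
        for j in range(nb):
            c = np.zeros(nb)
            c[j] = 1.0
            vals[j] = splev(pts, (knots, c, 3), der=2)
        S += half * (vals * gl_w) @ vals.T
    return S


def fit_gam_1d(
    x,
    y,
    basis_size: int = 10,
    lambda_grid: np.ndarray | None = None,
    grid_points: int = 200,
) -> GAMFit:
    """Penalized cubic-spline regression of y on x with GCV-chosen penalty.

    Interior knots sit at quantiles of the unique x values; the smoothing
    parameter minimises ``GCV = n RSS / (n - edf)^2`` over a 40-point
    log-spaced grid scaled to the data (spanning effectively unpenalized to
    effectively linear fits).  The reported partial effect s(x) is centred
    to mean zero over the observations and the intercept is the response
    mean.  ``p_smooth`` is an approximate F-test of the smooth against a
    constant fit (edf - 1 numerator degrees of freedom).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise InvalidArgumentError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if basis_size < 4:
        raise InvalidArgumentError("basis_size must be >= 4")
    ux = np.unique(x)
    if len(ux) < 4:
        raise InvalidArgumentError("x must have >= 4 distinct values")
    nb = min(basis_size, len(ux))
    if n < nb:
        raise InvalidArgumentError("need n >= basis_size observations")
    n_interior = nb - 4
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(ux, qs)
    else:
        interior = np.array([])
    knots = np.r_[[ux[0]] * 4, interior, [ux[-1]] * 4]
    X = _bspline_basis(x, knots)
    S = _penalty_matrix(knots, nb)
    XtX = X.T @ X
    Xty = X.T @ y
    if lambda_grid is None:
        ref = np.trace(XtX) / max(np.trace(S), 1e-300)
        lambda_grid = ref * np.logspace(-6, 6, 40)
    tss = float(np.sum((y - y.mean()) ** 2))
    # Demmler-Reinsch orthogonalisation: with XtX = L L^T and
    # U diag(s) U^T = L^-1 S L^-T, the edf is sum 1/(1 + lam s_i) and the
    # coefficients follow by elementwise shrinkage -- stable for any lambda
    try:
        L = scipy.linalg.cholesky(XtX, lower=True)
    except scipy.linalg.LinAlgError:
        jitter = 1e-10 * np.trace(XtX) / nb
        L = scipy.linalg.cholesky(XtX + jitter * np.eye(nb), lower=True)
    Linv = scipy.linalg.solve_triangular(L, np.eye(nb), lower=True)
    M = Linv @ S @ Linv.T
    s_eig, U = scipy.linalg.eigh((M + M.T) / 2.0)
    s_eig = np.maximum(s_eig, 0.0)
    # the penalty null space (constants and lines) must stay unpenalized at
    # any lambda: zero out eigenvalues that are numerically zero
    if s_eig.size and s_eig[-1] > 0:
        s_eig[s_eig < 1e-10 * s_eig[-1]] = 0.0
    z = U.T @ (Linv @ Xty)
    best = None
    for lam in np.asarray(lambda_grid, dtype=float):
        shrink = 1.0 / (1.0 + lam * s_eig)
        beta = Linv.T @ (U @ (shrink * z))
        fitted = X @ beta
        rss = float(np.sum((y - fitted) ** 2))
        edf = float(np.sum(shrink))
        denom = n - edf
        if denom <= 0:
            continue
        gcv = n * rss / denom**2
        if not math.isfinite(gcv):
            continue
        if best is None or gcv < best[0]:
            best = (gcv, lam, beta, rss, edf)
    if best is None:
        raise InvalidArgumentError("GCV non-finite over the whole lambda grid")
    gcv, lam, beta, rss, edf = best
    dev_expl = 1.0 - rss / tss if tss > 0 else 1.0
    r2_adj = (
        1.0 - (rss / max(n - edf, 1e-12)) / (tss / (n - 1)) if tss > 0 else 1.0
    )
    scale = rss / max(n - edf, 1e-12)
    intercept = float(y.mean())
    intercept_se = math.sqrt(scale / n)
    # approximate test of the smooth against a constant mean
    df1 = max(edf - 1.0, 1e-6)
    df2 = max(n - edf, 1e-6)
    f_stat = ((tss - rss) / df1) / (rss / df2) if rss > 0 else float("inf")
    p_smooth = float(scipy.stats.f.sf(f_stat, df1, df2)) if math.isfinite(f_stat) else 0.0
    grid = np.linspace(ux[0], ux[-1], grid_points)
    fit_grid = _bspline_basis(grid, knots) @ beta
    fitted_obs = X @ beta
    center = float(fitted_obs.mean())
    return GAMFit(
        lambda_=float(lam),
        edf=edf,
        gcv=float(gcv),
        r2_adj=float(np.clip(r2_adj, -np.inf, 1.0)),
        deviance_explained=float(np.clip(dev_expl, 0.0, 1.0)),
        intercept=intercept,
        intercept_se=intercept_se,
        p_smooth=p_smooth,
        partial_x=grid,
        partial_s=fit_grid - center,
        knots=knots,
        coefs=beta,
        n=n,
    )


def response_amplitude(fit: GAMFit) -> float:
    """Max - min of the partial effect over the observed range (>= 0)."""
    if fit.partial_s is None or len(fit.partial_s) == 0:
        raise InvalidArgumentError("fit carries no partial curve")
    return float(fit.partial_s.max() - fit.partial_s.min())


def ols_regression(x, y) -> RegressionFit:
    """Simple least-squares line with r^2 and a two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise InvalidArgumentError("need >= 3 finite observations")
    if np.ptp(x) == 0:
        raise InvalidArgumentError("x has zero variance")
    if np.ptp(y) == 0:
        # degenerate but well-defined: flat response, no association
        return RegressionFit(
            slope=0.0, intercept=float(y[0]), r2=0.0, p=1.0, n=len(x)
        )
    res = scipy.stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        n=len(x),
    )
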