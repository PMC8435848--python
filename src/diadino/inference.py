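"""Growth-rate and interaction-coefficient inference.

Monocultures give the species' own parameters: ``mu_max`` as the steepest
log-linear slope of the batch curve, and (r, K) from a nonlinear
least-squares fit of the closed-form logistic.  Bicultures give the
interaction coefficients: daily per-capita growth rates in the
semi-continuous phase are regressed on the competition equations with
(r, K) fixed at their monoculture values, which makes the problem linear in
alpha (and in beta) with a closed-form solution.

Per-capita rates are dilution-corrected.  Between consecutive daily counts
the culture both grows and loses a fraction D to renewal, so the gross
per-capita growth over the interval is

    g_i(t) = ln(N_i(t+1) / N_i(t)) - ln(1 - D)

which at steady state equals ``-ln(1 - D) = mu``: growth exactly balances
dilution.  The densities entering the regression are interval means; we use
the logarithmic mean of the interval endpoints, which is exact when
within-day growth is exponential and second-order accurate otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .dynamics import (
    BATCH,
    DETECTION_FLOOR,
    Trajectory,
    advance,
    closed_form_logistic,
)
from .errors import (
    FitFailureError,
    InsufficientDataError,
    InvalidArgumentError,
    UndefinedInteractionError,
)

logger = logging.getLogger(__name__)

DIATOM = "diatom"
DINO = "dino"


@dataclass
class GrowthFit:
    """Monoculture growth parameters.

    ``mu_max`` comes from the exponential-phase log-linear window;
    (r, K) from the logistic fit (NaN when only ``mu_max`` was estimated).
    """

    mu_max: float
    window: tuple[int, int]
    r: float = float("nan")
    K: float = float("nan")
    r_se: float = float("nan")
    K_se: float = float("nan")
    rss: float = float("nan")
    n_points: int = 0


@dataclass
class PerCapitaSeries:
    """Daily per-capita gross growth rates with interval-mean densities.

    ``df`` columns: day (interval start), g_diatom, g_dino (d^-1),
    n_diatom, n_dino (interval-mean densities, 10^4 cells mL^-1).
    """

    df: pd.DataFrame
    dilution_corrected: bool
    D_used: float
    excluded_days: list[float] = field(default_factory=list)


@dataclass
class InteractionEstimate:
    alpha: float
    beta: float
    alpha_se: float
    beta_se: float
    n_points: int
    method: str
    residual_rss: float
    #: point-wise diagnostic values alpha_t, beta_t per usable day
    alpha_pointwise: np.ndarray = field(default_factory=lambda: np.empty(0))
    beta_pointwise: np.ndarray = field(default_factory=lambda: np.empty(0))


def _species_column(species: str) -> str:
    if species not in (DIATOM, DINO):
        raise InvalidArgumentError(f"unknown species {species!r}")
    return f"n_{species}"


def estimate_mu_max(
    batch: Trajectory, species: str = DIATOM, min_window: int = 4
) -> GrowthFit:
    """Maximal growth rate from the exponential phase of a batch culture.

    Scans every contiguous window of at least ``min_window`` daily points
    with positive density and returns the slope of ln(density) vs day for
    the window maximising R^2; ties break toward longer, then earlier,
    windows.  A perfectly constant window has RSS = 0 and counts as
    R^2 = 1, so a flat culture yields ``mu_max = 0``.
    """
    col = _species_column(species)
    rows = batch.phase(BATCH)
    rows = rows[rows[col] > DETECTION_FLOOR]
    days = rows["day"].to_numpy(dtype=float)
    y = np.log(rows[col].to_numpy(dtype=float))
    n = len(days)
    if min_window < 2:
        raise InvalidArgumentError("min_window must be >= 2")
    if n < min_window:
        raise InsufficientDataError(
            f"{n} positive observations < min_window={min_window}"
        )
    best = None  # (r2, length, -start, slope, window)
    for start in range(n):
        for stop in range(start + min_window, n + 1):
            t = days[start:stop]
            yy = y[start:stop]
            tbar, ybar = t.mean(), yy.mean()
            stt = np.sum((t - tbar) ** 2)
            slope = np.sum((t - tbar) * (yy - ybar)) / stt
            resid = yy - ybar - slope * (t - tbar)
            rss = float(np.sum(resid**2))
            tss = float(np.sum((yy - ybar) ** 2))
            r2 = 1.0 if rss <= 1e-300 else (1.0 - rss / tss if tss > 0 else 1.0)
            key = (round(r2, 12), stop - start, -start)
            if best is None or key > best[0]:
                best = (key, slope, (int(t[0]), int(t[-1])))
    _, slope, window = best
    return GrowthFit(mu_max=float(max(slope, 0.0)), window=window, n_points=n)


def fit_logistic_mono(
    mono: Trajectory, species: str = DIATOM, n_restarts: int = 5
) -> GrowthFit:
    """Nonlinear least-squares logistic fit to a monoculture batch curve.

    Initialised at r = mu_max estimate, K = max observed density,
    n0 = first observation; (r, K, n0) are all free, asymptotic standard
    errors come from the Jacobian at the optimum.  Restarts with jittered
    starting values on non-convergence.
    """
    col = _species_column(species)
    rows = mono.phase(BATCH)
    days = rows["day"].to_numpy(dtype=float)
    dens = rows[col].to_numpy(dtype=float)
    keep = dens > DETECTION_FLOOR
    if np.count_nonzero(keep) < 5:
        raise FitFailureError(
            f"logistic fit needs >= 5 positive batch points, got "
            f"{int(np.count_nonzero(keep))}"
        )
    days, dens = days[keep], dens[keep]
    try:
        mu0 = estimate_mu_max(mono, species=species).mu_max
    except InsufficientDataError:
        mu0 = 0.5
    p0 = np.array([max(mu0, 0.05), float(dens.max()), float(dens[0])])
    bounds = ([1e-6, 1e-6, 1e-12], [20.0, 1e9, 1e9])
    rng = np.random.default_rng(0)  # jitter for restarts only; fit is data-driven
    last_err: Exception | None = None
    for attempt in range(n_restarts + 1):
        start = p0 if attempt == 0 else p0 * rng.lognormal(0.0, 0.3, size=3)
        start = np.clip(start, bounds[0], bounds[1])
        try:
            popt, pcov = curve_fit(
                lambda t, r, K, n0: closed_form_logistic(r, K, n0, t),
                days,
                dens,
                p0=start,
                bounds=bounds,
                maxfev=20000,
            )
            resid = dens - closed_form_logistic(popt[0], popt[1], popt[2], days)
            se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
            return GrowthFit(
                mu_max=mu0,
                window=(int(days[0]), int(days[-1])),
                r=float(popt[0]),
                K=float(popt[1]),
                r_se=float(se[0]),
                K_se=float(se[1]),
                rss=float(np.sum(resid**2)),
                n_points=len(days),
            )
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
            last_err = exc
    raise FitFailureError(
        f"logistic fit failed after {n_restarts + 1} attempts", last_err
    )


def _log_mean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Logarithmic mean (b - a) / ln(b / a); exact interval mean of an
    exponential trend, -> arithmetic mean as b -> a."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = 0.5 * (a + b)
    ratio = np.divide(b, a, out=np.ones_like(out), where=a > 0)
    mask = (a > 0) & (b > 0) & (np.abs(np.log(ratio)) > 1e-9)
    out[mask] = (b[mask] - a[mask]) / np.log(ratio[mask])
    return out


def per_capita_rates(
    biculture: Trajectory,
    D: float,
    dilution_corrected: bool = True,
    floor: float = DETECTION_FLOOR,
) -> PerCapitaSeries:
    """Daily per-capita gross growth rates from the semi-continuous phase.

    Uses the pre-dilution daily counts (what a hemocytometer sees);
    ``g_i = ln(N_i(t+1)/N_i(t)) - ln(1-D)`` when ``dilution_corrected``.
    Days where either species is at or below the detection floor are
    excluded and logged.  Interval-mean densities (log-mean of post-dilution
    start and pre-dilution end state) accompany each rate for the
    Lotka-Volterra regression.
    """
    if not 0.0 <= D < 1.0:
        raise InvalidArgumentError("D must be in [0, 1)")
    pre = biculture.pre_dilution_series().sort_values("day")
    post = biculture.post_dilution_series().sort_values("day")
    if len(pre) < 2:
        raise InsufficientDataError("need >= 2 consecutive daily counts")
    # align post-dilution state at day t with pre-dilution state at day t+1
    days = pre["day"].to_numpy(dtype=float)
    n1_pre = pre["n_diatom"].to_numpy(dtype=float)
    n2_pre = pre["n_dino"].to_numpy(dtype=float)
    post_map = post.set_index("day")
    recs, excluded = [], []
    for i in range(len(days) - 1):
        t0, t1 = days[i], days[i + 1]
        if t1 - t0 != 1.0 or t0 not in post_map.index:
            continue
        start1 = float(post_map.loc[t0, "n_diatom"])
        start2 = float(post_map.loc[t0, "n_dino"])
        end1, end2 = n1_pre[i + 1], n2_pre[i + 1]
        if min(start1, end1) <= floor or min(start2, end2) <= floor:
            excluded.append(float(t0))
            continue
        # ln(end/start) across the growth interval already excludes the
        # dilution event, so it equals the corrected form
        # ln(N_pre(t+1)/N_pre(t)) - ln(1-D); the uncorrected variant is the
        # plain log difference of consecutive daily counts.
        g1 = math.log(end1 / start1)
        g2 = math.log(end2 / start2)
        if not dilution_corrected:
            g1 += math.log(1.0 - D)
            g2 += math.log(1.0 - D)
        m1 = float(_log_mean(np.array([start1]), np.array([end1]))[0])
        m2 = float(_log_mean(np.array([start2]), np.array([end2]))[0])
        recs.append((t0, g1, g2, m1, m2, start1, start2, end1, end2))
    if excluded:
        logger.info(
            "per_capita_rates: excluded %d days at/below detection floor: %s",
            len(excluded),
            excluded,
        )
    df = pd.DataFrame(
        recs,
        columns=[
            "day",
            "g_diatom",
            "g_dino",
            "n_diatom",
            "n_dino",
            "n_diatom_start",
            "n_dino_start",
            "n_diatom_end",
            "n_dino_end",
        ],
    )
    return PerCapitaSeries(
        df=df,
        dilution_corrected=dilution_corrected,
        D_used=D,
        excluded_days=excluded,
    )


def _linear_alpha(
    g: np.ndarray, n_self: np.ndarray, n_other: np.ndarray, r: float, K: float
) -> tuple[float, float, float, np.ndarray]:
    """Closed-form least squares for one interaction coefficient.

    Model: g = r (K - n_self - a * n_other) / K, linear in ``a`` through the
    origin after moving the known terms to the left-hand side.
    """
    y = r * (K - n_self) / K - g
    x = r * n_other / K
    sxx = float(np.sum(x * x))
    if sxx <= 0:
        raise UndefinedInteractionError("partner species absent at all points")
    a = float(np.sum(x * y) / sxx)
    resid = y - a * x
    rss = float(np.sum(resid**2))
    n = len(y)
    dof = max(n - 1, 1)
    # consecutive daily rates share a count, so residuals carry lag-1
    # correlation; a Newey-West (lag 1) sandwich keeps the SE honest
    s0 = float(np.sum((x * resid) ** 2))
    s1 = float(np.sum(x[:-1] * x[1:] * resid[:-1] * resid[1:])) if n > 1 else 0.0
    var_hac = (s0 + 2.0 * s1) * n / max(n - 2, 1) / sxx**2
    var_iid = rss / dof / sxx
    se = math.sqrt(max(var_hac, 0.25 * var_iid))
    pointwise = np.where(n_other > 0, (K * (1.0 - g / r) - n_self) / n_other, np.nan)
    return a, se, rss, pointwise


def _model_interval_means(
    start1: np.ndarray,
    start2: np.ndarray,
    r1: float,
    r2: float,
    K1: float,
    K2: float,
    alpha: float,
    beta: float,
    step: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-average densities over each daily interval implied by the model.

    Integrates every interval from its observed post-dilution start state in
    one vectorised sweep and accumulates a trapezoid average of the path.
    """
    n_sub = max(2, round(1.0 / step))
    h = 1.0 / n_sub
    c1 = np.asarray(start1, dtype=float).copy()
    c2 = np.asarray(start2, dtype=float).copy()
    acc1 = 0.5 * c1.copy()
    acc2 = 0.5 * c2.copy()
    for k in range(n_sub):
        c1, c2 = advance(c1, c2, r1, r2, K1, K2, alpha, beta, duration=h, step=h)
        w = 0.5 if k == n_sub - 1 else 1.0
        acc1 += w * c1
        acc2 += w * c2
    return acc1 * h, acc2 * h


def estimate_interaction(
    series: PerCapitaSeries,
    diatom_fit: GrowthFit,
    dino_fit: GrowthFit,
    refine_iterations: int = 4,
) -> InteractionEstimate:
    """Least-squares interaction coefficients with monoculture (r, K) fixed.

    ``alpha`` solves the diatom equation, ``beta`` the dinoflagellate
    equation; both are linear in the coefficient once the daily growth
    identity ``g_i = r_i (K_i - <N_i> - coeff <N_j>) / K_i`` is written in
    terms of interval-mean densities.  A first pass uses the logarithmic
    mean of the interval endpoints; subsequent passes re-derive the interval
    means by integrating the fitted model within each day from the observed
    start states, which removes the quadrature bias of the endpoint
    approximation.  Standard errors come from the residual variance of each
    through-origin regression.  Point-wise diagnostic values
    ``alpha_t = (K1 (1 - g1/r1) - N1) / N2`` are reported alongside.
    """
    df = series.df
    if len(df) < 3:
        raise InsufficientDataError(
            f"interaction estimate needs >= 3 usable points, got {len(df)}"
        )
    g1 = df["g_diatom"].to_numpy(dtype=float)
    g2 = df["g_dino"].to_numpy(dtype=float)
    n1 = df["n_diatom"].to_numpy(dtype=float)
    n2 = df["n_dino"].to_numpy(dtype=float)
    a, a_se, rss1, a_pw = _linear_alpha(g1, n1, n2, diatom_fit.r, diatom_fit.K)
    b, b_se, rss2, b_pw = _linear_alpha(g2, n2, n1, dino_fit.r, dino_fit.K)
    if refine_iterations > 0 and {"n_diatom_start", "n_dino_start"} <= set(df.columns):
        s1 = df["n_diatom_start"].to_numpy(dtype=float)
        s2 = df["n_dino_start"].to_numpy(dtype=float)
        for _ in range(refine_iterations):
            m1, m2 = _model_interval_means(
                s1, s2, diatom_fit.r, dino_fit.r, diatom_fit.K, dino_fit.K, a, b
            )
            a_new, a_se, rss1, a_pw = _linear_alpha(
                g1, m1, m2, diatom_fit.r, diatom_fit.K
            )
            b_new, b_se, rss2, b_pw = _linear_alpha(
                g2, m2, m1, dino_fit.r, dino_fit.K
            )
            shift = max(abs(a_new - a), abs(b_new - b))
            a, b = a_new, b_new
            if shift < 1e-10:
                break
    return InteractionEstimate(
        alpha=a,
        beta=b,
        alpha_se=a_se,
        beta_se=b_se,
        n_points=len(df),
        method="least_squares",
        residual_rss=rss1 + rss2,
        alpha_pointwise=a_pw,
        beta_pointwise=b_pw,
    )


def pointwise_alpha(
    g1: float, r1: float, K1: float, n1: float, n2: float
) -> float:
    """Single-day algebraic inversion of the diatom equation for alpha."""
    if n2 <= 0:
        raise UndefinedInteractionError("partner density must be > 0")
    return (K1 * (1.0 - g1 / r1) - n1) / n2


def classify_superiority(alpha: float, tol: float = 0.0) -> str:
    """Sign rule: alpha > 0 -> dinoflagellate superiority, alpha < 0 ->
    diatom, |alpha| <= tol -> neutral."""
    if not math.isfinite(alpha):
        raise InvalidArgumentError("alpha must be finite")
    if tol < 0:
        raise InvalidArgumentError("tol must be >= 0")
    if alpha > tol:
        return "dinoflagellate"
    if alpha < -tol:
        return "diatom"
    return "neutral"
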