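"""Per-study path analysis linking climate, trait and population growth.

Each study gets a two-equation piecewise structural equation model on
z-transformed variables:

    trait model:   Z ~ C                    (weights 1/Z_se^2, AR(1) residuals)
    growth model:  G ~ C + Z + P            (unit weights, AR(1) residuals)

where C is the detrended windowed climate, Z the annual trait, P population
size and G_t = ln(P_{t+1}/P_t) the annual growth rate.  The standardized
coefficients are the path coefficients CZ, ZG, CG and PG.  Goodness of fit
uses Fisher's C over the single omitted directed claim P -> Z given C.  The
derived trait-mediated effect CZG = CZ*ZG and total effect TotalCG = CZG + CG
get bootstrap medians and 95% intervals by drawing each coefficient from
Normal(estimate, SE^2).

The GLS machinery fits residual covariance sigma^2 * D R(rho) D with
D = diag(SE-derived scales) and R(rho)_ij = rho^{|t_i - t_j|} (calendar-year
gaps respected), estimating rho by profile maximum likelihood on
(-0.95, 0.95).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats

from .climate import ClimateWindowResult
from .containers import StudySeries
from .errors import CollinearityError, DegenerateSeriesError, TooShortSeriesError

RHO_BOUND = 0.95
DEFAULT_N_BOOT = 10_000

__all__ = [
    "AlignedStudy",
    "PathFit",
    "DerivedEffect",
    "GlsAr1Fit",
    "growth_rates",
    "standardize_study",
    "fit_gls_ar1",
    "fit_study_sem",
    "fishers_c",
    "bootstrap_derived_effects",
]


def growth_rates(pop_size: np.ndarray) -> np.ndarray:
    """Annual growth rates G_t = ln(P_{t+1} / P_t), length n-1."""
    p = np.asarray(pop_size, dtype=float)
    if np.any(p <= 0):
        raise ValueError("population sizes must be positive")
    return np.log(p[1:] / p[:-1])


def _zscore(x: np.ndarray, what: str) -> tuple[np.ndarray, float, float]:
    x = np.asarray(x, dtype=float)
    m = float(np.mean(x))
    s = float(np.std(x, ddof=1))
    if s <= 0 or not np.isfinite(s):
        raise DegenerateSeriesError(f"{what} has zero variance; cannot standardize")
    return (x - m) / s, m, s


@dataclass
class AlignedStudy:
    """Standardized, year-aligned variables of one study.

    ``C``, ``Z`` and ``P`` are z-scored over all n years; ``G`` over its n-1
    values, with ``G[t]`` paired to the year-t values of the others.  ``Z_se``
    is the annual trait SE divided by the temporal trait SD (dimensionless).
    """

    years: np.ndarray
    C: np.ndarray
    Z: np.ndarray
    Z_se: np.ndarray
    P: np.ndarray
    G: np.ndarray


def standardize_study(
    study: StudySeries, window: ClimateWindowResult
) -> AlignedStudy:
    """Build the aligned, z-transformed variables entering the SEM."""
    years = np.asarray(window.years, dtype=int)
    idx = {int(y): i for i, y in enumerate(study.years)}
    missing = [int(y) for y in years if int(y) not in idx]
    if missing:
        raise ValueError(f"window years {missing} absent from study years")
    sel = np.array([idx[int(y)] for y in years])
    trait = study.trait_mean[sel]
    se = study.trait_se[sel]
    pop = study.pop_size[sel]

    C, _, _ = _zscore(window.detrended, "detrended climate")
    Z, _, sd_z = _zscore(trait, "trait")
    P, _, _ = _zscore(pop, "population size")
    G_raw = growth_rates(pop)
    G, _, _ = _zscore(G_raw, "growth rate")
    return AlignedStudy(years=years, C=C, Z=Z, Z_se=se / sd_z, P=P, G=G)


@dataclass
class GlsAr1Fit:
    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    rho: float
    sigma2: float
    r2: float
    loglik: float
    n: int
    converged: bool


def _profile_loglik(
    rho: float,
    y: np.ndarray,
    X: np.ndarray,
    scales: np.ndarray,
    gaps: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Profile log-likelihood at rho, with beta and sigma^2 profiled out."""
    n = len(y)
    t = np.cumsum(np.concatenate([[0.0], gaps]))
    R = rho ** np.abs(t[:, None] - t[None, :]) if rho != 0 else np.eye(n)
    S = R * scales[:, None] * scales[None, :]
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        return -np.inf, np.zeros(X.shape[1]), np.eye(X.shape[1]), 1.0
    Xt = linalg.solve_triangular(L, X, lower=True)
    yt = linalg.solve_triangular(L, y, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    if rank < X.shape[1]:
        raise CollinearityError("design matrix is rank deficient")
    r = yt - Xt @ beta
    rss = float(r @ r)
    sigma2_ml = max(rss / n, 1e-300)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * n * (math.log(2 * math.pi) + 1.0 + math.log(sigma2_ml)) - 0.5 * logdet
    XtX = Xt.T @ Xt
    return ll, beta, XtX, rss


def fit_gls_ar1(
    response: np.ndarray,
    design: np.ndarray,
    weights: np.ndarray | None = None,
    time_index: np.ndarray | None = None,
) -> GlsAr1Fit:
    """GLS with AR(1) residuals, rho by profile maximum likelihood.

    ``weights`` are inverse-variance weights (1/SE^2 style); the residual
    covariance is sigma^2 * D R(rho) D with D_i = weights_i^{-1/2}.  Year
    gaps in ``time_index`` enter the correlation as rho^{Delta t}.  Standard
    errors use the degrees-of-freedom-corrected sigma^2 estimate.
    """
    y = np.asarray(response, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p + 2:
        raise TooShortSeriesError(f"need n > p + 2 observations (n={n}, p={p})")
    scales = (
        np.ones(n) if weights is None else 1.0 / np.sqrt(np.asarray(weights, float))
    )
    t = (
        np.arange(n, dtype=float)
        if time_index is None
        else np.asarray(time_index, dtype=float)
    )
    gaps = np.diff(t)

    def neg(rho: float) -> float:
        ll, *_ = _profile_loglik(rho, y, X, scales, gaps)
        return -ll

    res = optimize.minimize_scalar(
        neg, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
        options={"xatol": 1e-6},
    )
    rho = float(res.x)
    converged = bool(res.success)
    ll, beta, XtX, rss = _profile_loglik(rho, y, X, scales, gaps)
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(XtX)
    resid = y - X @ beta
    tss = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else np.nan
    return GlsAr1Fit(
        params=beta,
        bse=np.sqrt(np.diag(cov)),
        cov_params=cov,
        rho=rho,
        sigma2=float(sigma2),
        r2=r2,
        loglik=float(ll),
        n=n,
        converged=converged and np.all(np.isfinite(beta)),
    )


@dataclass
class PathFit:
    """Standardized path coefficients of one study's SEM."""

    cz: float
    cz_se: float
    zg: float
    zg_se: float
    cg: float
    cg_se: float
    pg: float
    pg_se: float
    rho_trait: float
    rho_growth: float
    r2_trait: float
    r2_growth: float
    fisher_c: float
    fisher_df: int
    fisher_p: float
    n_trait: int
    n_growth: int
    converged: bool
    growth_cov: np.ndarray | None = None  # cov of (zg, cg, pg) for joint draws


def _restandardize(x: np.ndarray) -> np.ndarray:
    return (x - np.mean(x)) / np.std(x, ddof=1)


def fishers_c(
    aligned: AlignedStudy, *, weighted: bool = True
) -> tuple[float, int, float]:
    """Fisher's C over the single omitted claim P -> Z given C.

    The claim's p-value is the two-sided Wald p of P in the auxiliary model
    Z ~ C + P (same weighted AR(1) machinery as the trait model); then
    C = -2 ln(p), df = 2, and the goodness-of-fit p is the chi-square upper
    tail — an identity for a one-claim basis set.
    """
    n = len(aligned.Z)
    X = np.column_stack([np.ones(n), aligned.C, aligned.P])
    w = 1.0 / aligned.Z_se**2 if weighted else None
    fit = fit_gls_ar1(aligned.Z, X, weights=w, time_index=aligned.years)
    z = fit.params[2] / fit.bse[2]
    p_claim = 2.0 * stats.norm.sf(abs(z))
    p_claim = min(max(p_claim, 1e-300), 1.0)
    c = -2.0 * math.log(p_claim)
    return c, 2, float(stats.chi2.sf(c, 2))


def fit_study_sem(
    aligned: AlignedStudy, *, include_pop: bool = True
) -> PathFit:
    """Fit the trait and population-growth regressions of one study.

    ``include_pop=False`` drops population size from the growth model (the
    density-dependence sensitivity analysis); PG is then reported as NaN.
    """
    n = len(aligned.Z)
    converged = True
    try:
        trait = fit_gls_ar1(
            aligned.Z,
            np.column_stack([np.ones(n), aligned.C]),
            weights=1.0 / aligned.Z_se**2,
            time_index=aligned.years,
        )
        m = n - 1
        Cg = _restandardize(aligned.C[:m])
        Zg = _restandardize(aligned.Z[:m])
        cols = [np.ones(m), Cg, Zg]
        if include_pop:
            Pg = _restandardize(aligned.P[:m])
            cols.append(Pg)
        growth = fit_gls_ar1(
            aligned.G,
            np.column_stack(cols),
            weights=None,
            time_index=aligned.years[:m],
        )
        fc, fdf, fp = fishers_c(aligned)
    except (TooShortSeriesError, DegenerateSeriesError, CollinearityError):
        nan = float("nan")
        return PathFit(
            cz=nan, cz_se=nan, zg=nan, zg_se=nan, cg=nan, cg_se=nan,
            pg=nan, pg_se=nan, rho_trait=nan, rho_growth=nan,
            r2_trait=nan, r2_growth=nan, fisher_c=nan, fisher_df=2,
            fisher_p=nan, n_trait=n, n_growth=n - 1, converged=False,
        )
    converged = trait.converged and growth.converged
    pg = float(growth.params[3]) if include_pop else float("nan")
    pg_se = float(growth.bse[3]) if include_pop else float("nan")
    gcov_order = [2, 1, 3] if include_pop else [2, 1]  # zg, cg (, pg)
    gcov = growth.cov_params[np.ix_(gcov_order, gcov_order)]
    return PathFit(
        cz=float(trait.params[1]),
        cz_se=float(trait.bse[1]),
        zg=float(growth.params[2]),
        zg_se=float(growth.bse[2]),
        cg=float(growth.params[1]),
        cg_se=float(growth.bse[1]),
        pg=pg,
        pg_se=pg_se,
        rho_trait=trait.rho,
        rho_growth=growth.rho,
        r2_trait=trait.r2,
        r2_growth=growth.r2,
        fisher_c=fc,
        fisher_df=fdf,
        fisher_p=fp,
        n_trait=trait.n,
        n_growth=growth.n,
        converged=converged,
        growth_cov=gcov,
    )


@dataclass
class DerivedEffect:
    """Bootstrap medians and 95% intervals of CZG and TotalCG."""

    czg_median: float
    czg_lo: float
    czg_hi: float
    totalcg_median: float
    totalcg_lo: float
    totalcg_hi: float
    n_boot: int
    seed: int | None
    czg_sd: float = float("nan")
    totalcg_sd: float = float("nan")


def bootstrap_derived_effects(
    fit: PathFit,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    *,
    joint_growth_draw: bool = False,
) -> DerivedEffect:
    """Parametric bootstrap of CZG = CZ*ZG and TotalCG = CZG + CG.

    Each replicate draws every coefficient independently from
    Normal(estimate, SE^2); medians and the 0.025/0.975 quantiles summarize
    the ``n_boot`` replicates.  ``joint_growth_draw=True`` instead draws
    (ZG, CG) jointly from the growth model's coefficient covariance,
    acknowledging that they share a model (off by default).
    """
    import warnings

    if not fit.converged:
        raise ValueError("cannot bootstrap a non-converged fit")
    if n_boot < 100:
        warnings.warn("n_boot < 100: bootstrap intervals will be unreliable")
    rng = np.random.default_rng(seed)
    cz = fit.cz + fit.cz_se * rng.standard_normal(n_boot)
    if joint_growth_draw and fit.growth_cov is not None:
        mean = np.array([fit.zg, fit.cg])
        draws = rng.multivariate_normal(mean, fit.growth_cov[:2, :2], size=n_boot)
        zg, cg = draws[:, 0], draws[:, 1]
    else:
        zg = fit.zg + fit.zg_se * rng.standard_normal(n_boot)
        cg = fit.cg + fit.cg_se * rng.standard_normal(n_boot)
    czg = cz * zg
    total = czg + cg
    lo, hi = 0.025, 0.975
    return DerivedEffect(
        czg_median=float(np.median(czg)),
        czg_lo=float(np.quantile(czg, lo)),
        czg_hi=float(np.quantile(czg, hi)),
        totalcg_median=float(np.median(total)),
        totalcg_lo=float(np.quantile(total, lo)),
        totalcg_hi=float(np.quantile(total, hi)),
        n_boot=n_boot,
        seed=seed,
        czg_sd=float(np.std(czg, ddof=1)),
        totalcg_sd=float(np.std(total, ddof=1)),
    )
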