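"""Across-study inference on standardized path coefficients.

Multilevel random-effects meta-analysis with known sampling variances: the
marginal covariance of the effect vector y is

    V = diag(se^2) + tau2_study * Zs Zs' + tau2_location * Zl Zl'
        + sigma2_n * Zsp Zsp' + sigma2_p * Zsp A Zsp'

where A is the phylogenetic correlation matrix (last term only in the
phylogenetic variant).  Variance components are estimated by REML with the
fixed effects profiled out; fixed effects by GLS at the optimum.  Pagel's
lambda = sigma2_p / (sigma2_n + sigma2_p), Higgins I^2 uses the multilevel
generalization with the typical sampling variance of Higgins & Thompson, and
Q is the weighted residual heterogeneity of the fixed-effects-only fit.
Model choice between the phylogenetic and non-phylogenetic variants uses the
lower marginal AIC (variance components counted as parameters; ties go to
the model without phylogeny).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .trees import PhyloCorrelation, align_to_studies

QUANTITATIVE_MODERATORS = ("abs_latitude", "generation_time")
FACTOR_MODERATORS = ("diet", "migratory_mode")
DEFAULT_MODERATORS = QUANTITATIVE_MODERATORS + FACTOR_MODERATORS

__all__ = [
    "MetaModel",
    "ModelComparison",
    "WaldResult",
    "BinomialSignTest",
    "fit_multilevel_meta",
    "pagels_lambda",
    "heterogeneity_stats",
    "wald_test",
    "compare_phylo_models",
    "moderator_model",
    "binomial_sign_test",
    "adjusted_threshold",
    "lambda_over_trees",
]


@dataclass
class WaldResult:
    chi2: float
    df: int
    p: float


@dataclass
class BinomialSignTest:
    n: int
    n_nonnegative: int
    proportion: float
    p_one_sided: float


@dataclass
class MetaModel:
    """A fitted multilevel meta-analytic model."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    tau2_study: float
    tau2_location: float
    sigma2_n: float
    sigma2_p: float
    lambda_: float
    i2: float
    q_stat: float
    q_df: int
    q_p: float
    reml_loglik: float
    marginal_aic: float
    k: int
    n_components: int
    converged: bool
    use_phylo: bool
    moderator_terms: list[str] = field(default_factory=list)
    wald: dict[str, WaldResult] = field(default_factory=dict)

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def coef_se(self, term: str) -> float:
        return float(self.se[self.terms.index(term)])


def pagels_lambda(sigma2_p: float, sigma2_n: float) -> float:
    """lambda = sigma2_p / (sigma2_n + sigma2_p); 0 when both are 0."""
    if sigma2_p < 0 or sigma2_n < 0:
        raise ValueError("variance components must be non-negative")
    tot = sigma2_p + sigma2_n
    if tot == 0:
        return 0.0
    return sigma2_p / tot


def _grouping_kernel(labels: pd.Series) -> np.ndarray:
    codes = pd.factorize(labels)[0]
    Z = np.eye(codes.max() + 1)[codes]
    return Z @ Z.T


def _build_design(
    records: pd.DataFrame,
    moderators: tuple[str, ...],
    climate_covariates: bool,
) -> tuple[np.ndarray, list[str], list[str]]:
    k = len(records)
    cols: list[np.ndarray] = [np.ones(k)]
    terms = ["intercept"]
    moderator_terms: list[str] = []

    def add_quant(name: str, as_moderator: bool) -> None:
        x = records[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"covariate {name!r} is constant; dropped")
            return
        cols.append(x - x.mean())  # grand-mean centred
        terms.append(name)
        if as_moderator:
            moderator_terms.append(name)

    def add_factor(name: str, as_moderator: bool) -> None:
        levels = sorted(records[name].astype(str).unique())
        if len(levels) < 2:
            warnings.warn(f"factor {name!r} has a single level; dropped")
            return
        for lev in levels[1:]:
            cols.append((records[name].astype(str) == lev).to_numpy(dtype=float))
            terms.append(f"{name}[{lev}]")
            if as_moderator:
                moderator_terms.append(f"{name}[{lev}]")

    if climate_covariates:
        if "p_delta_aicc" in records:
            add_quant("p_delta_aicc", as_moderator=False)
        if "climate_quality" in records:
            add_factor("climate_quality", as_moderator=False)
    for m in moderators:
        if m in QUANTITATIVE_MODERATORS:
            add_quant(m, as_moderator=True)
        elif m in FACTOR_MODERATORS:
            add_factor(m, as_moderator=True)
        else:
            raise ValueError(f"unknown moderator {m!r}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient after centring")
    return X, terms, moderator_terms


def _reml_loglik(
    v: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    se2: np.ndarray,
    kernels: list[np.ndarray],
) -> float:
    k, p = X.shape
    V = np.diag(se2.copy())
    for vj, K in zip(v, kernels):
        V += vj * K
    try:
        c, low = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError:
        return -np.inf
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vi_y = linalg.cho_solve((c, low), y)
    Vi_X = linalg.cho_solve((c, low), X)
    XtViX = X.T @ Vi_X
    try:
        cx = linalg.cho_factor(XtViX)
    except linalg.LinAlgError:
        return -np.inf
    logdet_x = 2.0 * float(np.sum(np.log(np.diag(cx[0]))))
    beta = linalg.cho_solve(cx, X.T @ Vi_y)
    r = y - X @ beta
    quad = float(r @ linalg.cho_solve((c, low), r))
    return -0.5 * (logdet_v + logdet_x + quad + (k - p) * math.log(2 * math.pi))


def _reml_grad(
    v: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    se2: np.ndarray,
    kernels: list[np.ndarray],
) -> np.ndarray:
    """Analytic REML gradient d loglik / d v_j = -tr(P K_j)/2 + y'P K_j P y / 2."""
    V = np.diag(se2.copy())
    for vj, K in zip(v, kernels):
        V += vj * K
    Vi = np.linalg.inv(V)
    ViX = Vi @ X
    P = Vi - ViX @ np.linalg.solve(X.T @ ViX, ViX.T)
    Py = P @ y
    return np.array(
        [-0.5 * np.trace(P @ K) + 0.5 * Py @ K @ Py for K in kernels]
    )


def _optimize_reml(
    y: np.ndarray, X: np.ndarray, se2: np.ndarray, kernels: list[np.ndarray]
) -> tuple[np.ndarray, float, bool]:
    m = len(kernels)
    vtot = max(float(np.var(y, ddof=1)) - float(np.mean(se2)), 1e-3)
    if m == 0:
        return np.zeros(0), _reml_loglik(np.zeros(0), y, X, se2, kernels), True

    def nll_v(v: np.ndarray) -> float:
        return -_reml_loglik(np.maximum(v, 0.0), y, X, se2, kernels)

    if m == 1:
        hi = 10.0 * (vtot + float(np.mean(se2)))
        f = lambda v: nll_v(np.array([v]))
        res = optimize.minimize_scalar(
            f, bounds=(0.0, hi), method="bounded", options={"xatol": 1e-12}
        )
        x = float(res.x)
        # polish on the analytic gradient (bounded Brent floors at ~sqrt(eps))
        g = lambda v: float(
            _reml_grad(np.array([v]), y, X, se2, kernels)[0]
        )
        w = max(1e-4 * (1.0 + x), 1e-8)
        a, b = max(x - w, 0.0), min(x + w, hi)
        if g(a) > 0 > g(b):
            x = float(optimize.brentq(g, a, b, xtol=1e-14))
        v = np.array([max(x, 0.0)])
        if f(0.0) < f(v[0]):
            v = np.zeros(1)
        return v, -nll_v(v), bool(res.success)

    lo, hi = math.log(1e-10), math.log(10.0 * (vtot + float(np.mean(se2))) + 1.0)

    def nll_theta(theta: np.ndarray) -> float:
        return nll_v(np.exp(theta))

    starts = [
        np.full(m, math.log(max(vtot / m, 1e-6))),
        np.full(m, math.log(max(vtot, 1e-6))),
        np.full(m, math.log(1e-4)),
    ]
    best_theta, best_val, ok = None, np.inf, False
    for th0 in starts:
        res = optimize.minimize(
            nll_theta,
            th0,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * m,
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
        )
        if res.fun < best_val:
            best_theta, best_val, ok = res.x, res.fun, bool(res.success)
    polish = optimize.minimize(
        nll_theta,
        best_theta,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 4000},
    )
    if polish.fun <= best_val:
        best_theta, best_val = polish.x, polish.fun
    v = np.exp(np.clip(best_theta, lo, hi))
    v[v < 1e-9] = 0.0
    # boundary check: zeroing any near-boundary component must not hurt
    for j in range(m):
        trial = v.copy()
        trial[j] = 0.0
        if nll_v(trial) <= nll_v(v) + 1e-12:
            v = trial
    return v, -nll_v(v), ok


def heterogeneity_stats(
    records: pd.DataFrame, model: "MetaModel"
) -> tuple[float, float, int, float]:
    """(I^2, Q, df, p): multilevel I^2 and fixed-effects-only Cochran Q."""
    se2 = records["se"].to_numpy(dtype=float) ** 2
    w = 1.0 / se2
    k = len(w)
    s2_typ = (k - 1) * np.sum(w) / (np.sum(w) ** 2 - np.sum(w**2))
    between = model.tau2_study + model.tau2_location + model.sigma2_n + model.sigma2_p
    i2 = between / (between + s2_typ) if (between + s2_typ) > 0 else 0.0

    # Q uses the same fixed-effect structure the model was fitted with
    X = model._X_fixed
    y = records["effect"].to_numpy(dtype=float)
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    q = float(np.sum(w * (y - X @ beta) ** 2))
    df = k - X.shape[1]
    if df <= 0:
        raise ValueError("Q undefined: no residual degrees of freedom")
    return float(i2), q, df, float(stats.chi2.sf(q, df))


def fit_multilevel_meta(
    records: pd.DataFrame,
    *,
    moderators: tuple[str, ...] = (),
    A: PhyloCorrelation | np.ndarray | None = None,
    use_phylo: bool = False,
    climate_covariates: bool = False,
) -> MetaModel:
    """Fit the multilevel random-effects meta-analytic model by REML.

    ``records`` needs columns ``effect``, ``se``, ``study_id``,
    ``location_id``, ``species`` (plus ``p_delta_aicc`` / ``climate_quality``
    when ``climate_covariates`` and any requested moderator columns).
    Components whose grouping cannot be separated from the study component
    (one group per record) are pinned to 0 with a warning.
    """
    records = records.reset_index(drop=True)
    k = len(records)
    if k < 3:
        raise ValueError("need at least 3 effects")
    y = records["effect"].to_numpy(dtype=float)
    se = records["se"].to_numpy(dtype=float)
    if np.any(se <= 0):
        raise ValueError("sampling SEs must be positive")
    X, terms, moderator_terms = _build_design(records, moderators, climate_covariates)

    kernels: list[np.ndarray] = []
    names: list[str] = []

    kernels.append(_grouping_kernel(records["study_id"]))
    names.append("tau2_study")

    def maybe_add(col: str, name: str, K: np.ndarray | None = None) -> None:
        n_groups = records[col].nunique()
        if n_groups >= k or n_groups < 2:
            warnings.warn(
                f"component {name} not identifiable "
                f"({n_groups} groups for {k} effects); pinned to 0"
            )
            return
        kernels.append(K if K is not None else _grouping_kernel(records[col]))
        names.append(name)

    if "location_id" in records:
        maybe_add("location_id", "tau2_location")
    has_species = "species" in records
    if has_species:
        maybe_add("species", "sigma2_n")
    if use_phylo:
        if A is None:
            raise ValueError("use_phylo=True requires a correlation matrix A")
        if isinstance(A, PhyloCorrelation):
            A_rec = align_to_studies(A, list(records["species"]))
        else:
            A_rec = np.asarray(A, dtype=float)
            if A_rec.shape != (k, k):
                raise ValueError("record-level A must be k x k")
        kernels.append(A_rec)
        names.append("sigma2_p")

    v, reml_ll, ok = _optimize_reml(y, X, se**2, kernels)
    comp = dict(zip(names, v))
    tau2_study = float(comp.get("tau2_study", 0.0))
    tau2_location = float(comp.get("tau2_location", 0.0))
    sigma2_n = float(comp.get("sigma2_n", 0.0))
    sigma2_p = float(comp.get("sigma2_p", 0.0))

    V = np.diag(se**2)
    for vj, K in zip(v, kernels):
        V += vj * K
    c, low = linalg.cho_factor(V, lower=True)
    Vi_X = linalg.cho_solve((c, low), X)
    XtViX = X.T @ Vi_X
    cov_beta = np.linalg.inv(XtViX)
    beta = cov_beta @ (X.T @ linalg.cho_solve((c, low), y))
    bse = np.sqrt(np.diag(cov_beta))

    n_comp = len(kernels)
    model = MetaModel(
        terms=terms,
        beta=beta,
        se=bse,
        cov_beta=cov_beta,
        tau2_study=tau2_study,
        tau2_location=tau2_location,
        sigma2_n=sigma2_n,
        sigma2_p=sigma2_p,
        lambda_=pagels_lambda(sigma2_p, sigma2_n) if use_phylo else 0.0,
        i2=0.0,
        q_stat=0.0,
        q_df=0,
        q_p=1.0,
        reml_loglik=float(reml_ll),
        marginal_aic=float(-2.0 * reml_ll + 2.0 * n_comp),
        k=k,
        n_components=n_comp,
        converged=bool(ok),
        use_phylo=use_phylo,
        moderator_terms=moderator_terms,
    )
    model._X_fixed = X  # kept for Q and prediction
    i2, q, qdf, qp = heterogeneity_stats(records, model)
    model.i2, model.q_stat, model.q_df, model.q_p = i2, q, qdf, qp
    for term in terms:
        if term == "intercept":
            continue
        model.wald[term] = wald_test(model, [term])
    return model


def wald_test(model: MetaModel, term_subset: list[str]) -> WaldResult:
    """Joint Wald chi-square of a subset of fixed-effect terms."""
    idx = []
    for t in term_subset:
        if t not in model.terms:
            raise ValueError(f"term {t!r} not in model")
        idx.append(model.terms.index(t))
    g = model.beta[idx]
    C = model.cov_beta[np.ix_(idx, idx)]
    try:
        chi2 = float(g @ np.linalg.solve(C, g))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular coefficient sub-covariance") from exc
    df = len(idx)
    return WaldResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


@dataclass
class ModelComparison:
    chosen: MetaModel
    with_phylo: MetaModel
    without_phylo: MetaModel
    aic_with: float
    aic_without: float
    phylo_chosen: bool


def compare_phylo_models(
    records: pd.DataFrame,
    A: PhyloCorrelation | np.ndarray,
    **kwargs,
) -> ModelComparison:
    """Fit with and without the phylogenetic component (identical fixed
    effects) and keep the lower marginal AIC; ties go to no-phylogeny."""
    m_with = fit_multilevel_meta(records, A=A, use_phylo=True, **kwargs)
    m_without = fit_multilevel_meta(records, use_phylo=False, **kwargs)
    phylo = m_with.marginal_aic < m_without.marginal_aic
    return ModelComparison(
        chosen=m_with if phylo else m_without,
        with_phylo=m_with,
        without_phylo=m_without,
        aic_with=m_with.marginal_aic,
        aic_without=m_without.marginal_aic,
        phylo_chosen=bool(phylo),
    )


def moderator_model(
    records: pd.DataFrame,
    *,
    moderators: tuple[str, ...] = DEFAULT_MODERATORS,
    climate_covariates: bool = True,
    **kwargs,
) -> tuple[MetaModel, WaldResult]:
    """Moderator meta-regression plus the joint Wald test of the moderator
    block against the intercept-only structure.  Quantitative moderators are
    grand-mean centred, so the intercept is the prediction at mean covariate
    values.  The block df equals the number of moderator columns actually
    fitted and is reported, not assumed."""
    model = fit_multilevel_meta(
        records,
        moderators=moderators,
        climate_covariates=climate_covariates,
        **kwargs,
    )
    block = wald_test(model, model.moderator_terms)
    return model, block


def binomial_sign_test(czg_values: np.ndarray) -> BinomialSignTest:
    """One-sided exact binomial test that the proportion of non-negative
    trait-mediated effects exceeds one half."""
    v = np.asarray(czg_values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    n = int(v.size)
    n_nonneg = int(np.sum(v >= 0))
    res = stats.binomtest(n_nonneg, n, p=0.5, alternative="greater")
    return BinomialSignTest(
        n=n,
        n_nonnegative=n_nonneg,
        proportion=n_nonneg / n,
        p_one_sided=float(res.pvalue),
    )


def adjusted_threshold(alpha: float = 0.05, n_models: int = 5) -> float:
    """Multiple-comparison-adjusted p-value threshold (alpha / #models)."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    return alpha / n_models


def lambda_over_trees(
    records: pd.DataFrame, corr_matrices: list[PhyloCorrelation], **kwargs
) -> pd.DataFrame:
    """Refit the phylogenetic model over an ensemble of trees; one row per
    tree with the fitted lambda (reported as estimate plus min/max spread)."""
    rows = []
    for i, A in enumerate(corr_matrices):
        m = fit_multilevel_meta(records, A=A, use_phylo=True, **kwargs)
        rows.append({"tree": i, "lambda": m.lambda_, "marginal_aic": m.marginal_aic})
    return pd.DataFrame(rows)
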