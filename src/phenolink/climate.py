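"""Sliding-window detection of the climate signal driving an annual trait.

For one study the daily climate series is aggregated to weekly resolution and
every contiguous window of weeks within the two years (104 weeks) before a
study-specific *reference day* is tried as a predictor of the annual trait
mean.  Each candidate window is scored by a weighted Gaussian linear model

    trait ~ intercept + window aggregate + year,   weights 1/SE^2,

ranked by small-sample AICc, and the winning window's improvement over the
climate-free null model (delta AICc) is calibrated against scans of
year-randomized data to yield ``p_delta_aicc`` — the probability that the
selected signal is spurious.  The windowed climate is finally detrended on
year; those residuals are the climate variable entering the path models.

Week ``w`` covers the 7 days with backward-day indices ``7(w-1) .. 7w-1``,
where index 0 is the day immediately before (and excluding) the reference
day.  Temperature windows are aggregated by the mean, precipitation windows
by the sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DailyClimate, StudySeries
from .errors import (
    CollinearityError,
    CoverageError,
    TooShortSeriesError,
)

MAX_WEEKS = 104  #: two years of weekly windows
DEFAULT_N_RAND = 200  #: randomization replicates for p_delta_aicc

__all__ = [
    "WindowSpec",
    "ClimateWindowResult",
    "enumerate_windows",
    "aggregate_window",
    "fit_window_model",
    "scan_best_window",
    "randomization_probability",
    "detrend_climate",
    "scan_study",
]


@dataclass(frozen=True, order=True)
class WindowSpec:
    """A contiguous span of weeks before the reference day.

    ``close_week`` is the week nearest the reference day, ``open_week`` the
    farthest; both inclusive, so the duration is ``open - close + 1`` weeks.
    """

    open_week: int
    close_week: int

    def __post_init__(self) -> None:
        if not (1 <= self.close_week <= self.open_week <= MAX_WEEKS):
            raise ValueError(
                f"require 1 <= close <= open <= {MAX_WEEKS}, got "
                f"({self.open_week}, {self.close_week})"
            )

    @property
    def duration_weeks(self) -> int:
        return self.open_week - self.close_week + 1

    @property
    def duration_days(self) -> int:
        return 7 * self.duration_weeks


@dataclass
class WindowModelFit:
    """Weighted regression of trait on one candidate window."""

    aicc: float
    loglik: float
    coef: np.ndarray  # (intercept, covariate, year)
    n: int
    k: int


@dataclass
class ScanResult:
    """Best window of a full scan plus the per-window AICc table."""

    window: WindowSpec
    aicc_best: float
    aicc_null: float
    delta_aicc: float
    table: pd.DataFrame  # open_week, close_week, aicc
    n_years_used: int


@dataclass
class ClimateWindowResult:
    """Selected window with its spuriousness probability and detrended values."""

    window: WindowSpec
    per_year_value: np.ndarray
    years: np.ndarray
    delta_aicc: float
    p_delta_aicc: float
    detrended: np.ndarray
    n_rand: int
    variable: str
    seed: int | None = None


def enumerate_windows(max_weeks: int) -> list[WindowSpec]:
    """All ``max_weeks*(max_weeks+1)/2`` windows, ascending open then close."""
    if not (1 <= max_weeks <= MAX_WEEKS):
        raise ValueError(f"max_weeks must be in 1..{MAX_WEEKS}")
    return [
        WindowSpec(open_week=o, close_week=c)
        for o in range(1, max_weeks + 1)
        for c in range(1, o + 1)
    ]


def _reference_dates(reference_day: int, years: np.ndarray) -> np.ndarray:
    """Calendar date of the reference day in each year (day 366 clamps to 365
    in non-leap years)."""
    out = np.empty(len(years), dtype="datetime64[D]")
    for i, y in enumerate(years):
        doy = reference_day
        last = (pd.Timestamp(int(y), 12, 31)).dayofyear
        if doy > last:
            doy = last
        out[i] = np.datetime64(f"{int(y):04d}-01-01") + (doy - 1)
    return out


def _weekly_sums(
    climate: DailyClimate, reference_day: int, years: np.ndarray, max_weeks: int
) -> np.ndarray:
    """Per-year sums of the ``max_weeks`` backward weeks: shape (n_years, max_weeks)."""
    refs = _reference_dates(reference_day, np.asarray(years, dtype=int))
    r = (refs - climate.start).astype(int)  # index of the reference day itself
    need_lo = r - 7 * max_weeks
    if np.any(need_lo < 0):
        i = int(np.argmax(need_lo < 0))
        missing = refs[i] - 7 * max_weeks
        raise CoverageError(f"daily climate starts after required date {missing}")
    if np.any(r > len(climate.values)):
        i = int(np.argmax(r > len(climate.values)))
        raise CoverageError(
            f"daily climate ends before required date {refs[i] - 1}"
        )
    csum = np.concatenate([[0.0], np.cumsum(climate.values)])
    weeks = np.arange(1, max_weeks + 1)
    hi = r[:, None] - 7 * (weeks[None, :] - 1)  # exclusive upper index
    lo = r[:, None] - 7 * weeks[None, :]
    return csum[hi] - csum[lo]


def aggregate_window(
    climate: DailyClimate,
    reference_day: int,
    years: np.ndarray,
    window: WindowSpec,
    variable: str | None = None,
) -> np.ndarray:
    """Windowed climate per year: mean for temperature, sum for precipitation."""
    variable = variable or climate.variable
    weekly = _weekly_sums(climate, reference_day, years, window.open_week)
    total = weekly[:, window.close_week - 1 : window.open_week].sum(axis=1)
    if variable == "temperature":
        return total / window.duration_days
    return total


def _gaussian_wls_loglik(rss_w: float, n: int, log_w_sum: float) -> float:
    # per-observation variance sigma^2 / w_i, sigma^2 profiled at rss_w / n
    return -0.5 * n * (math.log(2 * math.pi) + 1.0 + math.log(rss_w / n)) + 0.5 * log_w_sum


def _aicc(loglik: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        raise TooShortSeriesError(
            f"AICc undefined: n={n} with k={k} parameters (need n > k + 1)"
        )
    return -2.0 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _usable(*arrays: np.ndarray) -> np.ndarray:
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        mask &= np.isfinite(np.asarray(a, dtype=float))
    return mask


def fit_window_model(
    trait_mean: np.ndarray,
    trait_se: np.ndarray,
    covariate_values: np.ndarray,
    years: np.ndarray,
) -> WindowModelFit:
    """Weighted least squares of trait on intercept + covariate + year.

    Weights are 1/SE^2; the Gaussian log-likelihood uses per-observation
    variance sigma^2 * SE_i^2 with sigma^2 profiled out, and AICc counts the
    residual scale as a parameter (k = 4 here).
    """
    y = np.asarray(trait_mean, dtype=float)
    se = np.asarray(trait_se, dtype=float)
    cov = np.asarray(covariate_values, dtype=float)
    yr = np.asarray(years, dtype=float)
    mask = _usable(y, se, cov, yr)
    y, se, cov, yr = y[mask], se[mask], cov[mask], yr[mask]
    n = len(y)
    if n < 5:
        raise TooShortSeriesError(f"need at least 5 usable years, got {n}")
    if np.any(se <= 0):
        raise ValueError("trait_se must be positive")
    X = np.column_stack([np.ones(n), cov, yr])
    w = 1.0 / se**2
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < X.shape[1]:
        raise CollinearityError("window covariate is collinear with the design")
    rss_w = float(np.sum((yw - Xw @ beta) ** 2))
    rss_w = max(rss_w, 1e-300)
    ll = _gaussian_wls_loglik(rss_w, n, float(np.sum(np.log(w))))
    k = X.shape[1] + 1
    return WindowModelFit(aicc=_aicc(ll, k, n), loglik=ll, coef=beta, n=n, k=k)


def _scan_core(
    y: np.ndarray,
    sw: np.ndarray,
    yr: np.ndarray,
    agg: np.ndarray,
    opens: np.ndarray,
    closes: np.ndarray,
) -> tuple[np.ndarray, float, int]:
    """AICc per window plus null AICc, via Frisch-Waugh on the weighted design.

    ``agg`` is the (n_years, n_windows) matrix of windowed aggregates.  The
    base regression (intercept + year) is orthogonalized once; each window
    column only contributes its partialled-out sum of squares.
    """
    n = len(y)
    base = np.column_stack([np.ones(n), yr]) * sw[:, None]
    Q, _ = np.linalg.qr(base)
    yw = y * sw
    e_y = yw - Q @ (Q.T @ yw)
    rss_null = float(e_y @ e_y)
    rss_null = max(rss_null, 1e-300)
    log_w_sum = float(np.sum(np.log(sw**2)))
    ll_null = _gaussian_wls_loglik(rss_null, n, log_w_sum)
    aicc_null = _aicc(ll_null, 3, n)

    C = agg * sw[:, None]
    E = C - Q @ (Q.T @ C)
    ss = np.einsum("ij,ij->j", E, E)
    num = E.T @ e_y
    gain = np.zeros(len(ss))
    ok = ss > 1e-12 * max(float(np.max(ss)), 1e-300)
    gain[ok] = num[ok] ** 2 / ss[ok]
    rss = np.maximum(rss_null - gain, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi) + 1.0 + np.log(rss / n)) + 0.5 * log_w_sum
    k = 4
    aicc = -2.0 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    return aicc, aicc_null, n


def _best_index(aicc: np.ndarray, opens: np.ndarray, closes: np.ndarray) -> int:
    durs = opens - closes + 1
    order = np.lexsort((closes, durs, aicc))
    return int(order[0])


def _prepare_scan(
    study: StudySeries, climate: DailyClimate, max_weeks: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    mask = _usable(study.trait_mean, study.trait_se)
    y = study.trait_mean[mask]
    se = study.trait_se[mask]
    yr = study.years[mask].astype(float)
    if len(y) < 5:
        raise TooShortSeriesError(
            f"study {study.study_id!r}: need at least 5 usable years, got {len(y)}"
        )
    if len(y) <= 5:  # k=4 plus AICc correction
        raise TooShortSeriesError(
            f"study {study.study_id!r}: AICc needs n > 5 usable years"
        )
    weekly = _weekly_sums(climate, study.reference_day, study.years[mask], max_weeks)
    csum = np.concatenate(
        [np.zeros((weekly.shape[0], 1)), np.cumsum(weekly, axis=1)], axis=1
    )
    specs = enumerate_windows(max_weeks)
    opens = np.array([s.open_week for s in specs])
    closes = np.array([s.close_week for s in specs])
    agg = csum[:, opens] - csum[:, closes - 1]
    if climate.variable == "temperature":
        agg = agg / (7.0 * (opens - closes + 1))
    return y, 1.0 / se, yr, agg, opens, closes


def scan_best_window(
    study: StudySeries, climate: DailyClimate, max_weeks: int = MAX_WEEKS
) -> ScanResult:
    """Exhaustive AICc scan over all windows; ties broken by shorter duration
    then smaller close week.  ``delta_aicc < 0`` means the climate window
    improves on the climate-free null model."""
    y, sw, yr, agg, opens, closes = _prepare_scan(study, climate, max_weeks)
    aicc, aicc_null, n = _scan_core(y, sw, yr, agg, opens, closes)
    i = _best_index(aicc, opens, closes)
    table = pd.DataFrame(
        {"open_week": opens, "close_week": closes, "aicc": aicc}
    )
    return ScanResult(
        window=WindowSpec(int(opens[i]), int(closes[i])),
        aicc_best=float(aicc[i]),
        aicc_null=float(aicc_null),
        delta_aicc=float(aicc[i] - aicc_null),
        table=table,
        n_years_used=n,
    )


def randomization_probability(
    study: StudySeries,
    climate: DailyClimate,
    max_weeks: int = MAX_WEEKS,
    n_rand: int = DEFAULT_N_RAND,
    seed: int | None = None,
) -> tuple[float, np.ndarray, ScanResult]:
    """Spuriousness probability of the best window.

    Each replicate permutes the assignment of study years to climate years
    (trait value, SE and the year covariate travel together), re-runs the
    full scan and records the best delta AICc.  The add-one empirical
    percentile of the observed delta within that null distribution is

        p = (1 + #{delta_rand <= delta_obs}) / (1 + n_rand)
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    y, sw, yr, agg, opens, closes = _prepare_scan(study, climate, max_weeks)
    aicc, aicc_null, n = _scan_core(y, sw, yr, agg, opens, closes)
    i = _best_index(aicc, opens, closes)
    observed = ScanResult(
        window=WindowSpec(int(opens[i]), int(closes[i])),
        aicc_best=float(aicc[i]),
        aicc_null=float(aicc_null),
        delta_aicc=float(aicc[i] - aicc_null),
        table=pd.DataFrame({"open_week": opens, "close_week": closes, "aicc": aicc}),
        n_years_used=n,
    )
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_rand)
    for b in range(n_rand):
        perm = rng.permutation(n)
        aicc_b, aicc_null_b, _ = _scan_core(y, sw, yr, agg[perm], opens, closes)
        deltas[b] = float(np.min(aicc_b) - aicc_null_b)
    p = (1.0 + float(np.sum(deltas <= observed.delta_aicc))) / (1.0 + n_rand)
    return p, deltas, observed


def detrend_climate(per_year_value: np.ndarray, years: np.ndarray) -> np.ndarray:
    """Residuals of OLS of the windowed climate on year (the variable C)."""
    v = np.asarray(per_year_value, dtype=float)
    yr = np.asarray(years, dtype=float)
    if len(v) < 3:
        raise TooShortSeriesError("detrending needs at least 3 years")
    if np.ptp(yr) == 0:
        raise ValueError("years are constant; cannot detrend")
    X = np.column_stack([np.ones(len(yr)), yr])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def scan_study(
    study: StudySeries,
    climate: DailyClimate,
    max_weeks: int = MAX_WEEKS,
    n_rand: int = DEFAULT_N_RAND,
    seed: int | None = None,
) -> ClimateWindowResult:
    """Full per-study climate-signal analysis: scan, randomization, detrend."""
    p, _, scan = randomization_probability(study, climate, max_weeks, n_rand, seed)
    mask = _usable(study.trait_mean, study.trait_se)
    years = study.years[mask]
    values = aggregate_window(
        climate, study.reference_day, years, scan.window, climate.variable
    )
    return ClimateWindowResult(
        window=scan.window,
        per_year_value=values,
        years=years,
        delta_aicc=scan.delta_aicc,
        p_delta_aicc=p,
        detrended=detrend_climate(values, years),
        n_rand=n_rand,
        variable=climate.variable,
        seed=seed,
    )
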