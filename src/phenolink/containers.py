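"""Core data containers: one study's annual series and a daily climate record.

A *study* is a unique combination of species, location and trait: annual mean
trait values with their standard errors, and annual population sizes, observed
over the same run of years.  Daily climate arrives pre-extracted for the study
location as a single contiguous series of temperature (deg C) or precipitation
(mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_STUDY_YEARS = 9

CLIMATE_VARIABLES = ("temperature", "precipitation")
TRAIT_CATEGORIES = ("phenology", "morphology")
CLIMATE_QUALITIES = ("exact", "approximate")


@dataclass
class DailyClimate:
    """A contiguous daily climate series for one location.

    Parameters
    ----------
    variable
        ``"temperature"`` (aggregated by window mean) or ``"precipitation"``
        (aggregated by window sum).
    dates
        Contiguous daily calendar dates (datetime64[D]), no gaps.
    values
        One value per date, same length.
    """

    variable: str
    dates: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.variable not in CLIMATE_VARIABLES:
            raise ValueError(f"variable must be one of {CLIMATE_VARIABLES}")
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.values = np.asarray(self.values, dtype=float)
        if self.dates.shape != self.values.shape:
            raise ValueError("dates and values must have equal length")
        if len(self.dates) > 1:
            deltas = np.diff(self.dates).astype(int)
            if not np.all(deltas == 1):
                gap = self.dates[np.argmax(deltas != 1)]
                raise ValueError(f"dates must be contiguous; gap after {gap}")

    @property
    def start(self) -> np.datetime64:
        return self.dates[0]

    @property
    def end(self) -> np.datetime64:
        return self.dates[-1]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=pd.DatetimeIndex(self.dates))


@dataclass
class StudySeries:
    """Annual trait and population time series for one study.

    All per-year sequences are aligned to ``years`` (strictly increasing
    integers).  Studies shorter than 9 years are rejected, mirroring the
    inclusion rule for the analyses this package implements; per-year trait
    SEs must be positive and population sizes strictly positive.
    """

    study_id: str
    species: str
    location_id: str
    latitude: float
    longitude: float
    trait_category: str
    trait_type: str
    reference_day: int
    years: np.ndarray
    trait_mean: np.ndarray
    trait_se: np.ndarray
    pop_size: np.ndarray
    climate_quality: str = "exact"

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.trait_mean = np.asarray(self.trait_mean, dtype=float)
        self.trait_se = np.asarray(self.trait_se, dtype=float)
        self.pop_size = np.asarray(self.pop_size, dtype=float)
        n = len(self.years)
        for name in ("trait_mean", "trait_se", "pop_size"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from years")
        if n < MIN_STUDY_YEARS:
            raise ValueError(
                f"study {self.study_id!r} has {n} years; at least "
                f"{MIN_STUDY_YEARS} are required"
            )
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if not (1 <= self.reference_day <= 366):
            raise ValueError("reference_day must be a day-of-year in 1..366")
        if np.any(self.trait_se <= 0):
            raise ValueError("trait_se must be positive")
        if np.any(self.pop_size <= 0):
            raise ValueError("pop_size must be positive")
        if self.trait_category not in TRAIT_CATEGORIES:
            raise ValueError(f"trait_category must be one of {TRAIT_CATEGORIES}")
        if self.climate_quality not in CLIMATE_QUALITIES:
            raise ValueError(f"climate_quality must be one of {CLIMATE_QUALITIES}")

    @property
    def n_years(self) -> int:
        return len(self.years)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame, one row per study-year (the on-disk schema)."""
        return pd.DataFrame(
            {
                "study_id": self.study_id,
                "species": self.species,
                "location_id": self.location_id,
                "latitude": self.latitude,
                "longitude": self.longitude,
                "trait_category": self.trait_category,
                "trait_type": self.trait_type,
                "reference_day": self.reference_day,
                "climate_quality": self.climate_quality,
                "year": self.years,
                "trait_mean": self.trait_mean,
                "trait_se": self.trait_se,
                "pop_size": self.pop_size,
            }
        )
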