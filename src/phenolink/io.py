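"""Readers and writers for the plain-text interchange formats.

Schemas
-------
studies.csv
    long format, one row per study-year: study_id, species, location_id,
    latitude, longitude, trait_category, trait_type, reference_day,
    climate_quality, year, trait_mean, trait_se, pop_size.
climate_<location_id>.csv
    date (ISO-8601), value; one file per location per climate variable.
species_attributes.csv
    species, generation_time_years, diet, migratory_mode.
tree.nwk
    Newick with branch lengths; tip labels match the species column.
truth.csv
    per-study generator ground truth (fixtures only).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import DailyClimate, StudySeries

STUDY_META_COLS = [
    "study_id",
    "species",
    "location_id",
    "latitude",
    "longitude",
    "trait_category",
    "trait_type",
    "reference_day",
    "climate_quality",
]


def read_studies(path) -> list[StudySeries]:
    """Read the long-format studies.csv into per-study containers."""
    df = pd.read_csv(path)
    studies = []
    for sid, g in df.groupby("study_id", sort=True):
        g = g.sort_values("year")
        first = g.iloc[0]
        studies.append(
            StudySeries(
                study_id=str(sid),
                species=str(first["species"]),
                location_id=str(first["location_id"]),
                latitude=float(first["latitude"]),
                longitude=float(first["longitude"]),
                trait_category=str(first["trait_category"]),
                trait_type=str(first["trait_type"]),
                reference_day=int(first["reference_day"]),
                climate_quality=str(first["climate_quality"]),
                years=g["year"].to_numpy(dtype=int),
                trait_mean=g["trait_mean"].to_numpy(dtype=float),
                trait_se=g["trait_se"].to_numpy(dtype=float),
                pop_size=g["pop_size"].to_numpy(dtype=float),
            )
        )
    return studies


def write_studies(studies: list[StudySeries], path) -> None:
    pd.concat([s.to_frame() for s in studies], ignore_index=True).to_csv(
        path, index=False
    )


def read_climate(path, variable: str) -> DailyClimate:
    df = pd.read_csv(path)
    return DailyClimate(
        variable=variable,
        dates=df["date"].to_numpy(dtype="datetime64[D]"),
        values=df["value"].to_numpy(dtype=float),
    )


def read_attributes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_fixture_set(directory, variable: str = "temperature"):
    """Read a fixture directory written by
    :func:`phenolink.synthetic.write_fixture_set` back into a collection."""
    from .synthetic import StudyCollection
    from .trees import read_newick

    d = Path(directory)
    studies = read_studies(d / "studies.csv")
    climates = {}
    for p in sorted(d.glob("climate_*.csv")):
        loc = p.stem.removeprefix("climate_")
        climates[loc] = read_climate(p, variable)
    truth_path = d / "truth.csv"
    truths = read_truth(truth_path) if truth_path.exists() else pd.DataFrame()
    attributes = read_attributes(d / "species_attributes.csv")
    tree = read_newick(d / "tree.nwk") if (d / "tree.nwk").exists() else None
    return StudyCollection(
        studies=studies,
        truths=truths,
        attributes=attributes,
        climates=climates,
        tree=tree,
    )
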