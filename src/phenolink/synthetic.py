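"""Seeded generators for study collections with known ground truth.

The generative model deliberately mirrors the fitted analysis — linear,
Gaussian, AR(1) — so that parameter recovery is well posed: a true weekly
climate window drives a latent standardized trait (path ``cz_true``), and
population growth is driven by climate directly (``cg_true``), by the trait
(``zg_true``) and by density dependence (``pg_true``), with the population
updated as P_{t+1} = P_t * exp(scale * g_t).  Between-study heterogeneity in
the climate-trait path combines study, location and phylogenetically
structured species components, the latter with covariance
sigma2_species * (lambda * A + (1 - lambda) * I).

Residual scales default to "auto": they are chosen so the standardized
latent trait and the growth composite have unit marginal variance, which
makes the generative path values land on the same standardized scale the
fitted models estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import dendropy
import numpy as np
import pandas as pd
from scipy import signal

from .climate import WindowSpec, aggregate_window
from .containers import DailyClimate, StudySeries
from .errors import LabellingError
from .trees import correlation_matrix

__all__ = [
    "TruthParams",
    "StudyCollection",
    "simulate_tree",
    "simulate_daily_climate",
    "simulate_study",
    "simulate_collection",
    "simulate_effect_records",
    "default_design",
    "write_fixture_set",
]


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth parameters of the generative model.

    ``trait_resid_sd`` / ``growth_resid_sd`` of ``None`` mean
    auto-calibration to unit marginal variance of the standardized trait and
    growth composite.
    """

    true_window: tuple[int, int] = (6, 3)
    cz_true: float = -0.37
    zg_true: float = 0.05
    cg_true: float = -0.07
    pg_true: float = -0.4
    trait_ar1: float = 0.3
    growth_ar1: float = 0.0
    trait_resid_sd: float | None = None
    growth_resid_sd: float | None = None
    se_scale: float = 0.75
    year_trend_climate: float = 0.03
    year_trend_trait: float = 0.0
    lambda_true: float = 0.65
    tau2_study: float = 0.05
    tau2_location: float = 0.02
    sigma2_species: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        o, c = self.true_window
        if not (1 <= c <= o <= 104):
            raise ValueError("true_window must satisfy 1 <= close <= open <= 104")
        for name in ("trait_ar1", "growth_ar1"):
            if abs(getattr(self, name)) >= 1:
                raise ValueError(f"|{name}| must be < 1")
        for name in ("tau2_study", "tau2_location", "sigma2_species", "se_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("trait_resid_sd", "growth_resid_sd"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.lambda_true <= 1.0):
            raise ValueError("lambda_true must be in [0, 1]")


def simulate_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree, total depth scaled to 1.

    Tips are labelled ``sp001`` .. ``spNNN``; deterministic given the seed.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree()
    birth: dict[int, float] = {}
    t = 0.0
    # start from a single ancestor so the stem edge above the first split is
    # part of the tree (two tips then share a strictly positive path)
    stem = dendropy.Node()
    tree.seed_node.add_child(stem)
    active = [stem]
    birth[id(stem)] = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        node = active[rng.integers(len(active))]
        node.edge.length = t - birth[id(node)]
        a, b = dendropy.Node(), dendropy.Node()
        node.add_child(a)
        node.add_child(b)
        birth[id(a)] = birth[id(b)] = t
        active.remove(node)
        active.extend([a, b])
    t += rng.exponential(1.0 / n_species)
    for node in active:
        node.edge.length = t - birth[id(node)]
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= t
    ns = tree.taxon_namespace
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = ns.new_taxon(label=f"sp{i:03d}")
    return tree


_DOY_PERIOD = 365.0


def simulate_daily_climate(
    start_year: int,
    n_years: int,
    variable: str = "temperature",
    *,
    mean: float | None = None,
    amplitude: float | None = None,
    trend_per_year: float = 0.0,
    noise_sd: float | None = None,
    noise_ar1: float = 0.6,
    peak_doy: float = 196.0,
    seed: int = 0,
) -> DailyClimate:
    """Daily climate = seasonal sinusoid (in day-of-year) + linear year trend
    + AR(1) daily noise; precipitation is clamped at zero."""
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    defaults = {
        "temperature": (8.0, 9.0, 3.0),
        "precipitation": (2.5, 1.5, 2.5),
    }[variable]
    mean = defaults[0] if mean is None else mean
    amplitude = defaults[1] if amplitude is None else amplitude
    noise_sd = defaults[2] if noise_sd is None else noise_sd

    dates = np.arange(
        np.datetime64(f"{start_year:04d}-01-01"),
        np.datetime64(f"{start_year + n_years:04d}-01-01"),
        dtype="datetime64[D]",
    )
    ts = pd.DatetimeIndex(dates)
    doy = np.minimum(ts.dayofyear.to_numpy(), 365)
    year = ts.year.to_numpy()
    seasonal = amplitude * np.cos(2 * np.pi * (doy - peak_doy) / _DOY_PERIOD)
    trend = trend_per_year * (year - start_year)
    values = mean + seasonal + trend
    if noise_sd > 0:
        values = values + _ar1_series(
            np.random.default_rng(seed), len(values), noise_ar1, noise_sd
        )
    if variable == "precipitation":
        values = np.maximum(values, 0.0)
    return DailyClimate(variable=variable, dates=dates, values=values)


def _ar1_series(
    rng: np.random.Generator, n: int, coef: float, marginal_sd: float
) -> np.ndarray:
    """Stationary AR(1) noise with the requested marginal SD."""
    if marginal_sd == 0:
        return np.zeros(n)
    innov_sd = marginal_sd * np.sqrt(max(1.0 - coef**2, 1e-12))
    v = innov_sd * rng.standard_normal(n)
    v[0] = v[0] / innov_sd * marginal_sd  # stationary start
    return signal.lfilter([1.0], [1.0, -coef], v)


def _standardize_or_zero(x: np.ndarray) -> np.ndarray:
    s = np.std(x, ddof=1)
    if s == 0 or not np.isfinite(s):
        return np.zeros_like(x)
    return (x - np.mean(x)) / s


def simulate_study(
    truth: TruthParams,
    climate: DailyClimate,
    n_years: int,
    seed: int,
    *,
    study_id: str = "S001",
    species: str = "sp001",
    location_id: str = "L01",
    latitude: float = 52.0,
    longitude: float = 5.0,
    trait_category: str = "phenology",
    trait_type: str = "onset of breeding",
    reference_day: int = 180,
    climate_quality: str = "exact",
    trait_baseline: float = 120.0,
    trait_sd: float = 5.0,
    pop_baseline: float = 500.0,
    growth_scale: float = 0.15,
    se_lognorm_sd: float = 0.25,
    _damping: float = 1.0,
) -> StudySeries:
    """One study's annual series under the generative model.

    The study years are the last ``n_years`` covered years of the climate
    series, leaving the two-year window lookback intact.
    """
    first = pd.Timestamp(climate.start).year
    last = pd.Timestamp(climate.end).year
    years = np.arange(last - n_years + 1, last + 1)
    if years[0] - 2 < first:
        raise ValueError("climate must cover n_years + 2 years")
    rng = np.random.default_rng(seed)

    window = WindowSpec(*truth.true_window)
    C = aggregate_window(climate, reference_day, years, window, climate.variable)
    Cs = _standardize_or_zero(C)

    cz, zg, cg, pg = (
        truth.cz_true,
        truth.zg_true,
        truth.cg_true,
        truth.pg_true,
    )
    s_z = (
        truth.trait_resid_sd
        if truth.trait_resid_sd is not None
        else np.sqrt(max(1.0 - cz**2, 1e-4))
    )
    e = _ar1_series(rng, n_years, truth.trait_ar1, s_z)
    z = cz * Cs + truth.year_trend_trait * (years - years.mean()) + e

    se = truth.se_scale * np.exp(
        se_lognorm_sd * rng.standard_normal(n_years) - se_lognorm_sd**2 / 2.0
    )
    se = np.maximum(se, 1e-12)
    trait_mean = trait_baseline + trait_sd * z + se * rng.standard_normal(n_years)

    s_g = (
        truth.growth_resid_sd
        if truth.growth_resid_sd is not None
        else np.sqrt(max(1.0 - (cg**2 + zg**2 + pg**2 + 2 * cg * zg * cz), 0.05))
    )
    eta = _ar1_series(rng, n_years, truth.growth_ar1, s_g)
    var_z = cz**2 + s_z**2
    var_u = cg**2 + zg**2 * var_z + 2 * cg * zg * cz + s_g**2
    gscale = growth_scale * _damping
    a = gscale * pg
    if a < 0:
        s_ref = (gscale**2 * var_u + a**2) / (-2.0 * a)
    elif var_u > 0:
        s_ref = gscale * np.sqrt(var_u) * np.sqrt(max(n_years, 2) / 3.0)
    else:
        s_ref = 1.0
    x = np.zeros(n_years)
    if a < 0:
        x[0] = s_ref * rng.standard_normal()
    for t in range(n_years - 1):
        g = cg * Cs[t] + zg * z[t] + pg * (x[t] / s_ref if s_ref > 0 else 0.0) + eta[t]
        x[t + 1] = x[t] + gscale * g
    if np.max(np.abs(x)) > 20.0:
        warnings.warn(
            f"study {study_id!r}: population trajectory diverged; "
            "regenerating with damped effects"
        )
        return simulate_study(
            truth, climate, n_years, seed,
            study_id=study_id, species=species, location_id=location_id,
            latitude=latitude, longitude=longitude,
            trait_category=trait_category, trait_type=trait_type,
            reference_day=reference_day, climate_quality=climate_quality,
            trait_baseline=trait_baseline, trait_sd=trait_sd,
            pop_baseline=pop_baseline, growth_scale=growth_scale,
            se_lognorm_sd=se_lognorm_sd, _damping=_damping * 0.5,
        )
    pop = pop_baseline * np.exp(x)

    return StudySeries(
        study_id=study_id,
        species=species,
        location_id=location_id,
        latitude=latitude,
        longitude=longitude,
        trait_category=trait_category,
        trait_type=trait_type,
        reference_day=reference_day,
        years=years,
        trait_mean=trait_mean,
        trait_se=se,
        pop_size=pop,
        climate_quality=climate_quality,
    )


def default_design(
    n_studies: int, tree: dendropy.Tree, seed: int = 0, n_years: int = 25
) -> pd.DataFrame:
    """A controlled study design: species round-robin over the tree tips,
    two studies per location, latitudes spread over 0-70 degrees, and
    alternating diet / migratory-mode / generation-time contrasts."""
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    diets = ["herbivore", "carnivore", "omnivore"]
    gens = [2.0, 5.0, 10.0, 15.0]
    rows = []
    for i in range(n_studies):
        loc = i // 2
        n_loc = (n_studies + 1) // 2
        lat = 70.0 * loc / max(n_loc - 1, 1)
        sp = tips[i % len(tips)]
        rows.append(
            {
                "study_id": f"S{i + 1:03d}",
                "species": sp,
                "location_id": f"L{loc + 1:02d}",
                "latitude": lat,
                "longitude": float((i * 17) % 360 - 180),
                "trait_category": "phenology",
                "trait_type": "onset of breeding",
                "reference_day": 170 + (i % 4) * 10,
                "climate_quality": "approximate" if i % 7 == 0 else "exact",
                "n_years": n_years,
                "generation_time_years": gens[(i % len(tips)) % len(gens)],
                "diet": diets[(i % len(tips)) % len(diets)],
                "migratory_mode": "migrant" if (i % len(tips)) % 2 else "resident",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class StudyCollection:
    """A simulated set of studies with their climates, truths and phylogeny."""

    studies: list[StudySeries]
    truths: pd.DataFrame
    attributes: pd.DataFrame
    climates: dict[str, DailyClimate]
    tree: dendropy.Tree


def simulate_collection(
    n_studies: int,
    tree: dendropy.Tree,
    truth_base: TruthParams,
    design: pd.DataFrame | None = None,
    seed: int = 0,
    *,
    climate_variable: str = "temperature",
    start_year: int = 1990,
) -> StudyCollection:
    """Simulate ``n_studies`` studies whose true climate-trait path deviates
    from ``truth_base.cz_true`` by study, location and phylogenetically
    correlated species effects."""
    if design is None:
        design = default_design(n_studies, tree, seed)
    design = design.iloc[:n_studies].reset_index(drop=True)
    tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    bad = sorted(set(design["species"]) - tips)
    if bad:
        raise LabellingError(f"species not in tree: {bad}")

    rng = np.random.default_rng(seed)
    used_species = list(dict.fromkeys(design["species"]))
    A = correlation_matrix(tree)
    pos = [A.species.index(s) for s in used_species]
    A_used = A.matrix[np.ix_(pos, pos)]
    lam, s2sp = truth_base.lambda_true, truth_base.sigma2_species
    cov = s2sp * (lam * A_used + (1.0 - lam) * np.eye(len(used_species)))
    cov = cov + 1e-12 * np.eye(len(cov))
    sp_eff = dict(
        zip(used_species, np.linalg.cholesky(cov) @ rng.standard_normal(len(cov)))
    )
    locs = list(dict.fromkeys(design["location_id"]))
    loc_eff = dict(
        zip(locs, np.sqrt(truth_base.tau2_location) * rng.standard_normal(len(locs)))
    )
    st_eff = np.sqrt(truth_base.tau2_study) * rng.standard_normal(n_studies)

    n_years_max = int(design["n_years"].max())
    climates: dict[str, DailyClimate] = {}
    for j, loc in enumerate(locs):
        lat = float(design.loc[design["location_id"] == loc, "latitude"].iloc[0])
        climates[loc] = simulate_daily_climate(
            start_year,
            n_years_max + 2,
            climate_variable,
            mean=25.0 - 0.3 * lat if climate_variable == "temperature" else None,
            trend_per_year=truth_base.year_trend_climate,
            seed=int((seed * 1009 + 7 * j + 1) % 2**31),
        )

    studies: list[StudySeries] = []
    truth_rows = []
    for i, row in design.iterrows():
        cz_i = (
            truth_base.cz_true
            + st_eff[i]
            + loc_eff[row["location_id"]]
            + sp_eff[row["species"]]
        )
        truth_i = replace(truth_base, cz_true=float(cz_i))
        study = simulate_study(
            truth_i,
            climates[row["location_id"]],
            int(row["n_years"]),
            seed=int((seed * 2_000_003 + 31 * i + 17) % 2**31),
            study_id=row["study_id"],
            species=row["species"],
            location_id=row["location_id"],
            latitude=float(row["latitude"]),
            longitude=float(row["longitude"]),
            trait_category=row["trait_category"],
            trait_type=row["trait_type"],
            reference_day=int(row["reference_day"]),
            climate_quality=row["climate_quality"],
        )
        studies.append(study)
        rec = {"study_id": row["study_id"], "cz_true": float(cz_i)}
        for name in (
            "zg_true", "cg_true", "pg_true", "trait_ar1", "growth_ar1",
            "se_scale", "lambda_true", "tau2_study", "tau2_location",
            "sigma2_species",
        ):
            rec[name] = getattr(truth_base, name)
        rec["true_open_week"], rec["true_close_week"] = truth_base.true_window
        truth_rows.append(rec)

    attributes = (
        design[["species", "generation_time_years", "diet", "migratory_mode"]]
        .drop_duplicates("species")
        .reset_index(drop=True)
    )
    return StudyCollection(
        studies=studies,
        truths=pd.DataFrame(truth_rows),
        attributes=attributes,
        climates=climates,
        tree=tree,
    )


def simulate_effect_records(
    n_effects: int,
    tree: dendropy.Tree,
    *,
    mu: float = -0.37,
    tau2_study: float = 0.05,
    tau2_location: float = 0.0,
    sigma2_n: float = 0.0,
    sigma2_p: float = 0.0,
    se_range: tuple[float, float] = (0.05, 0.25),
    n_locations: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Effect-size records straight from the meta-analytic model, bypassing
    the per-study time-series stage — for testing the across-study machinery
    against its own generative truth."""
    rng = np.random.default_rng(seed)
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    A = correlation_matrix(tree).matrix
    species = [tips[i % len(tips)] for i in range(n_effects)]
    n_loc = n_locations or max(n_effects // 2, 1)
    locations = [f"L{(i % n_loc) + 1:02d}" for i in range(n_effects)]

    sp_idx = {s: i for i, s in enumerate(tips)}
    cov_sp = sigma2_n * np.eye(len(tips)) + sigma2_p * A
    if np.any(np.diag(cov_sp) > 0):
        u = np.linalg.cholesky(cov_sp + 1e-12 * np.eye(len(tips)))
        sp_eff = u @ rng.standard_normal(len(tips))
    else:
        sp_eff = np.zeros(len(tips))
    loc_eff = np.sqrt(tau2_location) * rng.standard_normal(n_loc)
    se = rng.uniform(*se_range, size=n_effects)
    y = (
        mu
        + np.sqrt(tau2_study) * rng.standard_normal(n_effects)
        + np.array([loc_eff[int(l[1:]) - 1] for l in locations])
        + np.array([sp_eff[sp_idx[s]] for s in species])
        + se * rng.standard_normal(n_effects)
    )
    return pd.DataFrame(
        {
            "study_id": [f"S{i + 1:03d}" for i in range(n_effects)],
            "species": species,
            "location_id": locations,
            "effect": y,
            "se": se,
            "p_delta_aicc": np.zeros(n_effects),
            "climate_quality": "exact",
        }
    )


def write_fixture_set(collection: StudyCollection, directory) -> dict[str, object]:
    """Write the collection as plain-text fixtures (CSVs + Newick).

    Round-trips losslessly through :func:`phenolink.io.read_fixture_set`.
    """
    from pathlib import Path

    from .trees import write_newick

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {}
    studies = pd.concat([s.to_frame() for s in collection.studies], ignore_index=True)
    paths["studies"] = d / "studies.csv"
    studies.to_csv(paths["studies"], index=False)
    for loc, clim in collection.climates.items():
        p = d / f"climate_{loc}.csv"
        pd.DataFrame(
            {"date": np.datetime_as_string(clim.dates, unit="D"), "value": clim.values}
        ).to_csv(p, index=False)
        paths[f"climate_{loc}"] = p
    paths["attributes"] = d / "species_attributes.csv"
    collection.attributes.to_csv(paths["attributes"], index=False)
    paths["truth"] = d / "truth.csv"
    collection.truths.to_csv(paths["truth"], index=False)
    paths["tree"] = d / "tree.nwk"
    write_newick(collection.tree, paths["tree"])
    paths["climate_variable"] = next(iter(collection.climates.values())).variable
    return paths
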