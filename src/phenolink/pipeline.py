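"""End-to-end orchestration: scan -> detrend -> SEM -> bootstrap -> meta.

A single config drives all stages; one global seed deterministically derives
a per-study sub-seed from a hash of the study id, so adding a study never
perturbs the results of the others.  All outputs are plain CSV plus a JSON
run manifest that records seeds and stage counts; identical config and seed
give byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate as cw
from . import meta as ma
from . import paths as pm
from .errors import PhenolinkError
from .io import read_fixture_set
from .synthetic import StudyCollection
from .trees import correlation_matrix

CLIMATE_DEPENDENT_EFFECTS = {"cz", "cg", "czg", "totalcg"}


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run (defaults are the analysis defaults)."""

    fixture_dir: str = "."
    output_dir: str = "results"
    climate_variable: str = "temperature"
    max_weeks: int = 104
    n_rand: int = 200
    n_boot: int = 10_000
    seed: int = 0
    include_low_support_signals: bool = True
    p_delta_aicc_drop_threshold: float = 0.5
    include_pop_covariate: bool = True
    use_phylo: str = "auto"  # "auto" (AIC choice) | "always" | "never"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def study_subseed(global_seed: int, study_id: str) -> int:
    """Deterministic per-study seed below 2^31."""
    h = zlib.crc32(study_id.encode("utf8"))
    return int((h ^ (global_seed * 1_000_003)) % 2_147_483_647)


@dataclass
class PipelineResult:
    windows: pd.DataFrame
    window_values: pd.DataFrame
    sem_fits: pd.DataFrame
    derived_effects: pd.DataFrame
    meta_results: pd.DataFrame
    meta_varcomp: pd.DataFrame
    binomial: ma.BinomialSignTest | None
    manifest: dict
    report: str = ""


def _effect_records(
    sem_fits: pd.DataFrame,
    derived: pd.DataFrame,
    effect: str,
) -> pd.DataFrame:
    meta_cols = ["study_id", "species", "location_id", "p_delta_aicc",
                 "climate_quality", "abs_latitude"]
    base = sem_fits[meta_cols].copy()
    if effect in ("cz", "zg", "cg", "pg"):
        base["effect"] = sem_fits[effect].to_numpy()
        base["se"] = sem_fits[f"{effect}_se"].to_numpy()
    else:
        d = derived.set_index("study_id")
        base["effect"] = base["study_id"].map(d[f"{effect}_median"]).to_numpy()
        base["se"] = base["study_id"].map(d[f"{effect}_sd"]).to_numpy()
    return base.dropna(subset=["effect", "se"])


def run_pipeline(
    config: PipelineConfig, collection: StudyCollection | None = None
) -> PipelineResult:
    """Run every stage; partial outputs are retained on stage failure and the
    manifest records the failure point."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if collection is None:
        collection = read_fixture_set(config.fixture_dir, config.climate_variable)
    studies = collection.studies
    manifest: dict = {
        "config": asdict(config),
        "studies_in": len(studies),
        "stage": "scan",
        "study_seeds": {
            s.study_id: study_subseed(config.seed, s.study_id) for s in studies
        },
    }

    window_rows, value_rows, sem_rows, derived_rows = [], [], [], []
    failed_scan = failed_sem = excluded = 0
    study_warnings: list[str] = []
    for study in studies:
        sub = study_subseed(config.seed, study.study_id)
        clim = collection.climates[study.location_id]
        try:
            res = cw.scan_study(
                study, clim, config.max_weeks, config.n_rand, seed=sub
            )
        except PhenolinkError as exc:
            failed_scan += 1
            study_warnings.append(f"{study.study_id}: scan failed ({exc})")
            continue
        window_rows.append(
            {
                "study_id": study.study_id,
                "variable": res.variable,
                "open_week": res.window.open_week,
                "close_week": res.window.close_week,
                "delta_aicc": res.delta_aicc,
                "p_delta_aicc": res.p_delta_aicc,
                "n_rand": res.n_rand,
                "seed": sub,
            }
        )
        for y, v, dtr in zip(res.years, res.per_year_value, res.detrended):
            value_rows.append(
                {
                    "study_id": study.study_id,
                    "year": int(y),
                    "window_value": v,
                    "detrended": dtr,
                }
            )
        if (
            not config.include_low_support_signals
            and res.p_delta_aicc > config.p_delta_aicc_drop_threshold
        ):
            excluded += 1
            continue
        try:
            aligned = pm.standardize_study(study, res)
            fit = pm.fit_study_sem(
                aligned, include_pop=config.include_pop_covariate
            )
        except PhenolinkError as exc:
            failed_sem += 1
            study_warnings.append(f"{study.study_id}: SEM failed ({exc})")
            continue
        if not fit.converged:
            failed_sem += 1
            study_warnings.append(f"{study.study_id}: SEM did not converge")
            continue
        row = {
            "study_id": study.study_id,
            "species": study.species,
            "location_id": study.location_id,
            "abs_latitude": abs(study.latitude),
            "climate_quality": study.climate_quality,
            "variable": res.variable,
            "p_delta_aicc": res.p_delta_aicc,
            "cz": fit.cz, "cz_se": fit.cz_se,
            "zg": fit.zg, "zg_se": fit.zg_se,
            "cg": fit.cg, "cg_se": fit.cg_se,
            "rho_trait": fit.rho_trait, "rho_growth": fit.rho_growth,
            "r2_trait": fit.r2_trait, "r2_growth": fit.r2_growth,
            "fisher_c": fit.fisher_c, "fisher_p": fit.fisher_p,
            "n_trait": fit.n_trait, "n_growth": fit.n_growth,
            "converged": fit.converged,
        }
        if config.include_pop_covariate:
            row["pg"] = fit.pg
            row["pg_se"] = fit.pg_se
        sem_rows.append(row)
        boot = pm.bootstrap_derived_effects(fit, config.n_boot, seed=sub)
        derived_rows.append(
            {
                "study_id": study.study_id,
                "variable": res.variable,
                "czg_median": boot.czg_median,
                "czg_lo": boot.czg_lo,
                "czg_hi": boot.czg_hi,
                "czg_sd": boot.czg_sd,
                "totalcg_median": boot.totalcg_median,
                "totalcg_lo": boot.totalcg_lo,
                "totalcg_hi": boot.totalcg_hi,
                "totalcg_sd": boot.totalcg_sd,
                "n_boot": boot.n_boot,
                "seed": sub,
            }
        )

    windows = pd.DataFrame(window_rows)
    window_values = pd.DataFrame(value_rows)
    sem_fits = pd.DataFrame(sem_rows)
    derived = pd.DataFrame(derived_rows)
    manifest.update(
        {
            "stage": "meta",
            "scans_done": len(window_rows),
            "failed_scan": failed_scan,
            "failed_sem": failed_sem,
            "excluded_by_threshold": excluded,
            "converged": len(sem_rows),
            "warnings": study_warnings,
        }
    )

    A = None
    if collection.tree is not None:
        A = correlation_matrix(collection.tree)

    effects = ["cz", "zg", "cg"]
    if config.include_pop_covariate:
        effects.append("pg")
    effects += ["czg", "totalcg"]
    meta_rows, varcomp_rows = [], []
    binom = None
    if len(sem_rows) >= 4:
        for effect in effects:
            records = _effect_records(sem_fits, derived, effect)
            if len(records) < 4:
                continue
            clim_dep = effect in CLIMATE_DEPENDENT_EFFECTS
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if A is not None and config.use_phylo == "auto":
                    comp = ma.compare_phylo_models(
                        records, A, climate_covariates=clim_dep
                    )
                    model = comp.chosen
                elif A is not None and config.use_phylo == "always":
                    model = ma.fit_multilevel_meta(
                        records, A=A, use_phylo=True, climate_covariates=clim_dep
                    )
                else:
                    model = ma.fit_multilevel_meta(
                        records, climate_covariates=clim_dep
                    )
            for i, term in enumerate(model.terms):
                w = model.wald.get(term)
                meta_rows.append(
                    {
                        "model_id": effect,
                        "effect_kind": effect,
                        "term": term,
                        "estimate": float(model.beta[i]),
                        "se": float(model.se[i]),
                        "chi2": w.chi2 if w else np.nan,
                        "df": w.df if w else np.nan,
                        "p": w.p if w else np.nan,
                    }
                )
            varcomp_rows.append(
                {
                    "model_id": effect,
                    "tau2_study": model.tau2_study,
                    "tau2_location": model.tau2_location,
                    "sigma2_n": model.sigma2_n,
                    "sigma2_p": model.sigma2_p,
                    "lambda": model.lambda_,
                    "i2": model.i2,
                    "q_stat": model.q_stat,
                    "q_df": model.q_df,
                    "q_p": model.q_p,
                    "reml_loglik": model.reml_loglik,
                    "marginal_aic": model.marginal_aic,
                    "k": model.k,
                    "use_phylo": model.use_phylo,
                }
            )
        if len(derived):
            binom = ma.binomial_sign_test(derived["czg_median"].to_numpy())
            manifest["binomial"] = {
                "n": binom.n,
                "n_nonnegative": binom.n_nonnegative,
                "proportion": binom.proportion,
                "p_one_sided": binom.p_one_sided,
            }
    meta_results = pd.DataFrame(meta_rows)
    meta_varcomp = pd.DataFrame(varcomp_rows)
    manifest["stage"] = "done"

    bundle = PipelineResult(
        windows=windows,
        window_values=window_values,
        sem_fits=sem_fits,
        derived_effects=derived,
        meta_results=meta_results,
        meta_varcomp=meta_varcomp,
        binomial=binom,
        manifest=manifest,
    )
    bundle.report = summarize_results(bundle)

    windows.to_csv(out / "windows.csv", index=False)
    window_values.to_csv(out / "window_values.csv", index=False)
    sem_fits.to_csv(out / "sem_fits.csv", index=False)
    derived.to_csv(out / "derived_effects.csv", index=False)
    meta_results.to_csv(out / "meta_results.csv", index=False)
    meta_varcomp.to_csv(out / "meta_varcomp.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "report.txt", "w") as fh:
        fh.write(bundle.report)
    return bundle


def summarize_results(bundle: PipelineResult) -> str:
    """Human-readable per-effect summary of a pipeline run."""
    lines = ["phenolink run summary", "====================="]
    m = bundle.manifest
    lines.append(
        f"studies in: {m.get('studies_in', 0)}; converged: {m.get('converged', 0)}; "
        f"failed scan: {m.get('failed_scan', 0)}; failed SEM: {m.get('failed_sem', 0)}; "
        f"excluded by threshold: {m.get('excluded_by_threshold', 0)}"
    )
    if bundle.meta_results.empty:
        lines.append("no converged studies; no meta-analytic models fitted")
        return "\n".join(lines) + "\n"
    inter = bundle.meta_results[bundle.meta_results["term"] == "intercept"]
    vc = bundle.meta_varcomp.set_index("model_id")
    lines.append("")
    lines.append(
        f"{'effect':>8} {'estimate':>10} {'SE':>8} {'I2':>6} {'lambda':>7} "
        f"{'Q':>9} {'Q_p':>8}"
    )
    for _, r in inter.iterrows():
        v = vc.loc[r["model_id"]]
        lines.append(
            f"{r['effect_kind']:>8} {r['estimate']:>10.4f} {r['se']:>8.4f} "
            f"{v['i2']:>6.3f} {v['lambda']:>7.3f} {v['q_stat']:>9.2f} "
            f"{v['q_p']:>8.4f}"
        )
    if bundle.binomial is not None:
        b = bundle.binomial
        lines.append("")
        lines.append(
            f"binomial sign test (CZG >= 0): {b.n_nonnegative}/{b.n} "
            f"(proportion {b.proportion:.2f}), one-sided p = {b.p_one_sided:.3f}"
        )
    return "\n".join(lines) + "\n"
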