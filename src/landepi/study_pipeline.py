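"""End-to-end study orchestration.

``run_study`` executes the full chain — landscape, birth-registry pool,
exposure profiles, outcomes, 6:1 matching, SES quartiles, model fits —
under one :class:`~landepi.config.StudyConfig`, and produces the main
OR tables (total and per tumour subgroup), the crop-specific models, the
industrial-distance sweep, the same-address sensitivity analysis and the
leave-one-region-out sensitivity analysis.  Every output is a pure
function of the config (which carries the master seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geoio
from .association_models import ModelFit, ModelSpec, fit_mixed_logistic, or_table
from .case_control_matching import match_controls, matched_sets_frame
from .config import CROP_CATEGORIES, StudyConfig
from .environment_classification import classify_environments, d_sweep
from .exposure_assessment import crop_indices
from .geoio import Landscape
from .ses_assignment import assign_ses_bulk, ses_quartiles
from .synthetic_landscape import assign_outcomes, generate_landscape, generate_population

logger = logging.getLogger(__name__)

CROP_COLUMNS = [c.lower() for c in CROP_CATEGORIES]

__all__ = [
    "StudyData",
    "StudyReport",
    "build_profiles",
    "simulate_study",
    "run_study",
    "run_replicate",
    "recovery_run",
    "same_address_sensitivity",
    "leave_one_region_out",
]


@dataclass
class StudyData:
    """Intermediate products of one simulated study."""

    landscape: Landscape
    pool: pd.DataFrame
    profiles: pd.DataFrame
    cases: pd.DataFrame
    matched_sets: list
    analysis: pd.DataFrame  # cases + matched controls with model covariates


@dataclass
class StudyReport:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        for name, tbl in self.tables.items():
            tbl.to_csv(os.path.join(outdir, f"{name}.csv"), index=False)
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def build_profiles(pool: pd.DataFrame, landscape: Landscape, cfg: StudyConfig) -> pd.DataFrame:
    """Derived covariates for every validly geocoded subject.

    Invalid geocodes yield all-NaN profile rows; they never enter the
    analysis (matching skips them and cases are drawn among valid
    subjects only).
    """
    valid = pool["geocode_valid"].to_numpy(bool)
    pts = geoio.subject_points(pool.loc[valid])
    crops = crop_indices(pts, cfg.radius_m, landscape)
    env = classify_environments(pts, landscape, cfg.D_m, cfg.outer_m, cfg.urban_pop_threshold)
    ses = assign_ses_bulk(pts, landscape)
    part = pd.concat(
        [crops.reset_index(drop=True), env.reset_index(drop=True), ses.reset_index(drop=True)],
        axis=1,
    )
    part.index = np.flatnonzero(valid)
    prof = part.reindex(np.arange(len(pool)))
    prof.insert(0, "id", pool["id"].to_numpy())
    return prof.reset_index(drop=True)


def simulate_study(cfg: StudyConfig) -> StudyData:
    """Generate one synthetic study: registry, exposures, outcomes, matching."""
    cfg.validate()
    t0 = time.perf_counter()
    landscape = generate_landscape(cfg, cfg.stage_seed("landscape"))
    pool = generate_population(
        landscape, cfg.population.n_pool, cfg, seed=cfg.stage_seed("population")
    )
    profiles = build_profiles(pool, landscape, cfg)

    # generation-time quartiles: whole valid pool as reference
    valid_ses = profiles["ses_value"]
    cuts, labeller = ses_quartiles(valid_ses.dropna().to_numpy(), reference="all")
    profiles["ses_q"] = labeller(valid_ses.to_numpy(float))

    cases, remaining = assign_outcomes(
        pool,
        profiles,
        cfg.params,
        cfg.n_cases,
        seed=cfg.stage_seed("outcomes"),
        subgroup_shares=cfg.subgroup_shares,
    )

    # movers: cases whose diagnosis address differs from the birth address
    rng = np.random.default_rng(cfg.stage_seed("movers"))
    moved = rng.random(len(cases)) < cfg.mover_fraction
    cases = cases.copy()
    cases["same_address"] = ~moved
    if cfg.mover_mode == "relocate" and moved.any():
        x0, y0, x1, y1 = landscape.extent
        cases.loc[moved, "x"] = rng.uniform(x0, x1, int(moved.sum()))
        cases.loc[moved, "y"] = rng.uniform(y0, y1, int(moved.sum()))

    sets = match_controls(
        cases, remaining, ratio=cfg.ratio, seed=cfg.stage_seed("matching"),
        year_window=cfg.birth_year_window,
    )
    control_ids = [cid for s in sets for cid in s.control_ids]
    controls = remaining.set_index("id").loc[control_ids].reset_index()

    analysis = _assemble_analysis(cases, controls, landscape, profiles, cfg)
    logger.info(
        "simulated study: %d cases, %d controls in %.1fs",
        len(cases), len(controls), time.perf_counter() - t0,
    )
    return StudyData(
        landscape=landscape,
        pool=pool,
        profiles=profiles,
        cases=cases,
        matched_sets=sets,
        analysis=analysis,
    )


def _assemble_analysis(cases, controls, landscape, profiles, cfg) -> pd.DataFrame:
    """Merge subjects with exposures; movers re-profiled at diagnosis address."""
    subjects = pd.concat([cases, controls], ignore_index=True)
    prof = profiles.set_index("id")
    cols = ["gci", *CROP_COLUMNS, "env", "d_facility_m", "in_urban", "ses_value", "tract_id"]
    merged = subjects.join(prof[cols], on="id")
    relocated = (subjects["status"] == "case") & ~subjects["same_address"].to_numpy(bool)
    if cfg.mover_mode == "relocate" and relocated.any():
        sub = subjects.loc[relocated]
        pts = geoio.subject_points(sub)
        crops = crop_indices(pts, cfg.radius_m, landscape)
        env = classify_environments(pts, landscape, cfg.D_m, cfg.outer_m, cfg.urban_pop_threshold)
        ses = assign_ses_bulk(pts, landscape)
        idx = merged.index[relocated]
        merged.loc[idx, ["gci", *CROP_COLUMNS]] = crops.to_numpy()
        merged.loc[idx, ["env", "d_facility_m", "in_urban"]] = env.to_numpy(dtype=object)
        merged.loc[idx, ["ses_value", "tract_id"]] = ses.to_numpy(dtype=object)
    # analysis quartiles: controls of the matched study by default
    cuts, labeller = ses_quartiles(
        merged["ses_value"].to_numpy(float),
        status=merged["status"].to_numpy(),
        reference=cfg.quartile_reference,
    )
    merged["ses_q"] = labeller(merged["ses_value"].to_numpy(float))
    return merged


# ---------------------------------------------------------------------------
# analyses

def _fit(analysis: pd.DataFrame, spec: ModelSpec, subgroup: str | None = None) -> ModelFit:
    data = analysis
    if subgroup is not None:
        keep = (data["status"] == "control") | (data["subgroup"] == subgroup)
        data = data.loc[keep]
    return fit_mixed_logistic(data, spec)


def run_study(
    cfg: StudyConfig,
    outdir=None,
    analyses=("main", "subgroups", "crops", "sweep", "same_address", "loro"),
) -> StudyReport:
    """Run the configured study and assemble all report tables."""
    study = simulate_study(cfg)
    report = StudyReport()
    spec = ModelSpec()
    subgroups = sorted(study.cases["subgroup"].dropna().unique())

    fits: dict[str, ModelFit] = {}
    if "main" in analyses:
        fits["total"] = _fit(study.analysis, spec)
    if "subgroups" in analyses:
        for sg in subgroups:
            fits[sg] = _fit(study.analysis, spec, subgroup=sg)
    if fits:
        report.tables["main_or_table"] = or_table(fits)

    if "crops" in analyses:
        crop_fits: dict[str, ModelFit] = {}
        for crop in ["gci", *CROP_COLUMNS]:
            crop_spec = dataclasses.replace(spec, crop_col=crop)
            for sg in [None, *subgroups]:
                name = f"{sg or 'total'}:{crop}"
                try:
                    crop_fits[name] = _fit(study.analysis, crop_spec, subgroup=sg)
                except ValueError as exc:
                    logger.warning("crop model %s failed: %s", name, exc)
        rows = [
            {"model": name, "term": f"{name.split(':')[1]}10",
             "or": f.terms[f"{name.split(':')[1]}10"].or_,
             "ci_low": f.terms[f"{name.split(':')[1]}10"].ci_low,
             "ci_high": f.terms[f"{name.split(':')[1]}10"].ci_high}
            for name, f in crop_fits.items()
        ]
        report.tables["crop_or_table"] = pd.DataFrame(rows)

    if "sweep" in analyses:
        report.tables["d_sweep"] = d_sweep(
            study.analysis, study.landscape, cfg.D_list, cfg.outer_m,
            cfg.urban_pop_threshold, spec,
        )

    if "same_address" in analyses:
        report.tables["same_address_or_table"] = same_address_sensitivity(study, cfg)

    if "loro" in analyses:
        report.tables["leave_one_region_out"] = leave_one_region_out(study, cfg)

    drops = int(study.pool["geocode_valid"].eq(False).sum())
    report.manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stage_seeds": {s: cfg.stage_seed(s)
                        for s in ("landscape", "population", "outcomes", "movers", "matching")},
        "n_cases": int(len(study.cases)),
        "n_controls": int((study.analysis["status"] == "control").sum()),
        "n_invalid_geocode": drops,
        "analyses": list(analyses),
    }
    if outdir is not None:
        report.write(outdir)
        os.makedirs(os.path.join(outdir, "layers"), exist_ok=True)
        geoio.write_landscape(study.landscape, os.path.join(outdir, "layers"))
        geoio.write_subjects(study.pool, os.path.join(outdir, "pool.csv"))
        matched_sets_frame(study.matched_sets).to_csv(
            os.path.join(outdir, "matched.csv"), index=False
        )
        study.analysis.to_csv(os.path.join(outdir, "analysis.csv"), index=False)
    return report


def same_address_sensitivity(study: StudyData, cfg: StudyConfig) -> pd.DataFrame:
    """Refit on cases with the same birth and diagnosis address.

    Movers are simply excluded (their birth address is unknown to the
    analyst); all matched controls are retained.  Subgroups left without
    cases are flagged rather than fitted.
    """
    keep = (study.analysis["status"] == "control") | study.analysis["same_address"].astype(bool)
    sub = study.analysis.loc[keep]
    spec = ModelSpec()
    fits: dict[str, ModelFit] = {"total": fit_mixed_logistic(sub, spec)}
    flagged = []
    for sg in sorted(study.cases["subgroup"].dropna().unique()):
        data = sub.loc[(sub["status"] == "control") | (sub["subgroup"] == sg)]
        if (data["status"] == "case").sum() == 0:
            flagged.append(sg)
            continue
        fits[sg] = fit_mixed_logistic(data, spec)
    table = or_table(fits)
    for sg in flagged:
        table = pd.concat(
            [table, pd.DataFrame([{"subgroup": sg, "term": "insufficient cases"}])],
            ignore_index=True,
        )
    return table


def leave_one_region_out(study: StudyData, cfg: StudyConfig) -> pd.DataFrame:
    """Refit the total-CNS model excluding each region in turn."""
    regions = sorted(study.analysis["region"].unique())
    if len(regions) < 3:
        raise ValueError("leave-one-region-out needs at least 3 regions")
    spec = ModelSpec()
    rows = []
    for reg in regions:
        data = study.analysis.loc[study.analysis["region"] != reg]
        row = {"excluded_region": reg}
        try:
            fit = fit_mixed_logistic(data, spec)
            for term in ("gci10", "ses_q_Q4"):
                if term in fit.terms:
                    t = fit.terms[term]
                    row.update({f"{term}_or": t.or_, f"{term}_ci_low": t.ci_low,
                                f"{term}_ci_high": t.ci_high})
            row["n_cases"] = fit.n_cases
            row["error"] = ""
        except ValueError as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def run_replicate(cfg: StudyConfig, seed: int) -> dict:
    """One recovery replicate: simulate at ``seed``, fit the main model.

    Returns the estimated GCI and SES-Q4 odds ratios with their Wald
    intervals — the quantities tracked by parameter-recovery and
    null-calibration runs.
    """
    rep_cfg = dataclasses.replace(cfg, seed=int(seed))
    study = simulate_study(rep_cfg)
    fit = fit_mixed_logistic(study.analysis, ModelSpec())
    out = {"seed": int(seed), "method": fit.method, "converged": fit.converged,
           "sigma_region": fit.sigma_region}
    for term in ("gci10", "ses_q_Q4", "env_industrial", "env_intersection", "env_urban"):
        if term in fit.terms:
            t = fit.terms[term]
            out[f"{term}_or"] = t.or_
            out[f"{term}_lo"] = t.ci_low
            out[f"{term}_hi"] = t.ci_high
    return out


def recovery_run(cfg: StudyConfig, seeds) -> pd.DataFrame:
    """Replicate ``run_replicate`` over many seeds into one table."""
    return pd.DataFrame([run_replicate(cfg, s) for s in seeds])
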