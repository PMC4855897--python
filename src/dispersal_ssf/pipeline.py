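"""End-to-end orchestration: simulate -> screen -> classify -> segment ->
SSF -> CRW -> report, with one config, reproducible seeds and a manifest.

Every stage writes plain-text outputs (CSV/JSON) into the run directory;
the manifest records the config snapshot, seeds, row counts per stage and
SHA-256 digests of every output file, so a re-run with the same config
reproduces the outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariates as cov
from . import crw as crw_mod
from . import movement_typing as mt
from . import segmentation as seg
from . import ssf as ssf_mod
from . import telemetry as tel
from .landscape import generate_landscape
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["run_all", "RunResult"]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, index=False)
    manifest["outputs"][path.name] = {"sha256": _digest(path), "rows": len(df)}


class RunResult(dict):
    """Dict of stage outputs with attribute access."""

    __getattr__ = dict.__getitem__


def run_all(
    config: SimulationConfig | str | Path,
    out_dir: str | Path,
    *,
    landscape=None,
    terrain_cell: float = 150.0,
    ndvi_cell: float = 500.0,
    n_random_steps: int = 10,
    k_folds: int = 5,
    n_permutations: int = 100,
    psi_bin_width: float = 0.5,
    window_days: int = 26,
) -> RunResult:
    """Run the whole pipeline on a simulated cohort.

    *config* may be a :class:`SimulationConfig` or a path to its text
    form.  The landscape is generated from ``config.rng_seed`` unless one
    is passed in.  Returns the in-memory stage outputs; files land in
    *out_dir*.
    """
    t_start = time.time()
    if not isinstance(config, SimulationConfig):
        config = SimulationConfig.load(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.__dict__.copy(), "outputs": {}, "stages": {}}
    manifest["config"]["fix_success_prob"] = dict(config.fix_success_prob)
    rng = np.random.default_rng(config.rng_seed)

    def stage(name, n_in, n_out, t0):
        manifest["stages"][name] = {
            "n_in": int(n_in),
            "n_out": int(n_out),
            "seconds": round(time.time() - t0, 2),
        }

    # ---- simulate ----------------------------------------------------
    t0 = time.time()
    if landscape is None:
        landscape = generate_landscape(
            rng_seed=config.rng_seed, terrain_cell=terrain_cell, ndvi_cell=ndvi_cell
        )
    traj, truth = simulate_cohort(landscape, config, rng)
    config.save(out / "config.toml")
    manifest["outputs"]["config.toml"] = {"sha256": _digest(out / "config.toml")}
    tel.write_trajectory_csv(traj, out / "trajectories.csv")
    manifest["outputs"]["trajectories.csv"] = {
        "sha256": _digest(out / "trajectories.csv"),
        "rows": len(traj),
    }
    stage("simulate", len(truth), len(traj), t0)

    # ---- screen ------------------------------------------------------
    t0 = time.time()
    trimmed = tel.trim_trajectory(traj)
    screened, removed = tel.screen_outliers(trimmed)
    _write(removed, out / "screening_removed.csv", manifest)
    stage("screen", len(trimmed), len(screened), t0)

    # ---- classify ----------------------------------------------------
    t0 = time.time()
    nsd = tel.compute_nsd(screened)
    classifications = []
    events: dict[str, mt.DispersalEvent] = {}
    for animal_id, prof in nsd.groupby("animal_id", sort=False):
        cls = mt.classify_trajectory(prof, animal_id)
        row = {
            "animal_year_id": animal_id,
            "assigned_type": cls.assigned_type,
            "rationale": ";".join(cls.rationale),
            "pseudo_r2": cls.pseudo_r2,
        }
        if cls.winning_fit is not None:
            row["model"] = cls.winning_fit.model_name
            row["aicc"] = cls.winning_fit.aicc
            row.update({f"param_{k}": v for k, v in cls.winning_fit.params.items()})
        if cls.assigned_type in ("disperser", "exploratory"):
            try:
                ev = mt.extract_dispersal_event(
                    prof,
                    cls.winning_fit,
                    screened[screened["animal_id"] == animal_id],
                    completed=cls.assigned_type == "disperser",
                )
                events[animal_id] = ev
                row.update(
                    dispersal_start_day=ev.start_day,
                    dispersal_end_day=ev.end_day,
                    dispersal_duration_days=ev.duration_days,
                    straight_line_km=ev.straight_line_km,
                )
            except mt.DispersalNotCompletedError:
                row["assigned_type"] = "other"
                row["rationale"] += ";dispersal_not_completed_in_series"
        classifications.append(row)
    cls_df = pd.DataFrame(classifications).merge(
        truth[["animal_id", "sex", "mode"]], left_on="animal_year_id", right_on="animal_id"
    )
    _write(cls_df.drop(columns=["animal_id"]), out / "classifications.csv", manifest)

    # classification-table report (counts by sex and type, percentages)
    cls_df["type_group"] = cls_df["assigned_type"].map(
        {"migrant": "migrant", "resident": "resident", "other": "other"}
    )
    # dispersal-period animals settle as migrant/resident/other post-hoc;
    # count them under 'other' unless data cover the following season
    cls_df["type_group"] = cls_df["type_group"].fillna("other")
    cls_df["dispersal_event"] = cls_df["assigned_type"].isin(["disperser", "exploratory"])
    counts = mt.classification_counts(cls_df)
    n_m = int((cls_df["sex"] == "M").sum())
    n_f = int((cls_df["sex"] == "F").sum())
    n_expl_m = int(((cls_df["assigned_type"] == "exploratory") & (cls_df["sex"] == "M")).sum())
    report = mt.classification_report(counts, n_m, n_f, n_exploratory_male=n_expl_m)
    counts_out = counts.reset_index(names="category")
    _write(counts_out, out / "classification_counts.csv", manifest)
    (out / "classification_report.json").write_text(json.dumps(report, indent=1))
    manifest["outputs"]["classification_report.json"] = {
        "sha256": _digest(out / "classification_report.json")
    }
    stage("classify", nsd["animal_id"].nunique(), len(cls_df), t0)

    # ---- windows + matched residents ---------------------------------
    t0 = time.time()
    anchors = {a: g["timestamp"].iloc[0] for a, g in screened.groupby("animal_id", sort=False)}
    windows = {
        a: mt.make_period_windows(ev, anchor=anchors[a], window_days=window_days)
        for a, ev in events.items()
    }
    resident_ids = cls_df.loc[cls_df["assigned_type"] == "resident", "animal_year_id"]
    coverage = {
        r: (screened[screened["animal_id"] == r]["timestamp"].iloc[0],
            screened[screened["animal_id"] == r]["timestamp"].iloc[-1])
        for r in resident_ids
    }
    pairing, unmatched = mt.match_residents(windows, coverage)
    pairing_df = pd.DataFrame(
        [{"disperser": d, "resident": r} for d, r in pairing.items()]
        + [{"disperser": d, "resident": ""} for d in unmatched]
    )
    _write(pairing_df, out / "resident_pairing.csv", manifest)
    stage("match", len(windows), len(pairing), t0)

    # ---- steps + periods ---------------------------------------------
    t0 = time.time()
    analysis_ids = list(pairing) + list(pairing.values())
    analysis_traj = screened[screened["animal_id"].isin(analysis_ids)]
    steps = tel.build_steps(analysis_traj)
    steps["group"] = np.where(steps["animal_id"].isin(list(pairing)), "dispersers", "residents")
    period = np.full(len(steps), "rest_of_year", dtype=object)
    for disp, res in pairing.items():
        win = windows[disp]
        for aid in (disp, res):
            sel = steps["animal_id"] == aid
            period[sel.to_numpy()] = win.assign(steps.loc[sel, "t_start"])
    steps["period"] = period
    stage("steps", len(analysis_traj), len(steps), t0)

    # ---- movement-rate mixed models ----------------------------------
    t0 = time.time()
    rate_rows = []
    for group in ("dispersers", "residents"):
        sub = steps[steps["group"] == group]
        model = seg.fit_rate_period_model(sub, group)
        tbl = model.coefficients.reset_index(names="period")
        tbl.insert(0, "group", group)
        # raw per-period means/SEs alongside the model-based estimates
        raw = sub.groupby("period")["rate_m_per_hr"].agg(["mean", "sem"]).reset_index()
        tbl = tbl.merge(raw.rename(columns={"mean": "raw_mean", "sem": "raw_se"}), on="period")
        rate_rows.append(tbl)
    _write(pd.concat(rate_rows, ignore_index=True), out / "movement_rate_models.csv", manifest)
    stage("rate_models", len(steps), len(rate_rows), t0)

    # ---- segmented regression + split --------------------------------
    t0 = time.time()
    during = steps[(steps["group"] == "dispersers") & (steps["period"] == "during") & steps["regular"]]
    fit, bins = seg.fit_segmented(during["rate_m_per_min"], bin_width=psi_bin_width)
    _write(bins, out / "rate_bins.csv", manifest)
    psi = fit.psi if fit.breakpoint_found else float(np.median(during["rate_m_per_min"]))
    split, threshold_m = seg.split_steps(during, psi, config.fix_interval_min)
    seg_report = {
        "psi_m_per_min": fit.psi,
        "psi_se": fit.psi_se,
        "r2_segmented": fit.r2,
        "r2_null": fit.r2_null,
        "breakpoint_found": fit.breakpoint_found,
        "threshold_m": threshold_m,
        "n_short": len(split["short"]),
        "n_long": len(split["long"]),
    }
    (out / "segmented_fit.json").write_text(json.dumps(seg_report, indent=1))
    manifest["outputs"]["segmented_fit.json"] = {"sha256": _digest(out / "segmented_fit.json")}
    for name, part in split.items():
        _write(seg.turn_angle_histogram(part), out / f"turn_angles_{name}.csv", manifest)
    step_class = np.full(len(steps), "", dtype=object)
    step_class[steps.index.isin(split["long"].index)] = "long"
    step_class[steps.index.isin(split["short"].index)] = "short"
    steps["step_class"] = step_class
    stage("segmented", len(during), len(split["short"]) + len(split["long"]), t0)

    # ---- fine-scale SSF suite ----------------------------------------
    t0 = time.time()
    in_window = steps[steps["period"].isin(["before", "during", "after"])]
    design_parts = []
    offset = 0
    for animal_id, sub in in_window.groupby("animal_id", sort=False):
        kernel = ssf_mod.build_kernels(steps, animal_id)
        block = ssf_mod.build_strata(
            sub, kernel, landscape, n_random=n_random_steps, rng=rng, stratum_offset=offset
        )
        if len(block) == 0:
            continue
        offset = int(block["stratum_id"].max()) + 1
        lookup = steps.loc[:, ["group", "period", "step_class"]].copy()
        lookup["step_index"] = lookup.index
        design_parts.append(block.merge(lookup, on="step_index"))
    design = pd.concat(design_parts, ignore_index=True)
    scaled_parts = []
    for (grp, per), sub in design.groupby(["group", "period"], sort=False):
        scaled, screen = cov.scale_and_screen(sub)
        scaled_parts.append(scaled)
    design_scaled = pd.concat(scaled_parts, ignore_index=False).sort_index()
    _write(design_scaled, out / "ssf_design.csv", manifest)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        suite = ssf_mod.run_model_suite(
            design_scaled, k=k_folds, rng=rng, n_permutations=n_permutations
        )
    table2 = ssf_mod.suite_report(suite).reset_index(names="model")
    _write(table2, out / "ssf_coefficients.csv", manifest)
    val_rows = []
    for model_id, entry in suite.items():
        if "validation" in entry:
            v = entry["validation"]
            val_rows.append(
                {
                    "model": model_id,
                    "mean_rs": v.mean_rs,
                    "null_q95": v.null_q95,
                    "useful": v.useful,
                }
            )
    _write(pd.DataFrame(val_rows), out / "ssf_validation.csv", manifest)
    stage("ssf", len(design_scaled), len(table2), t0)

    # ---- broad-scale CRW ---------------------------------------------
    t0 = time.time()
    coefs = []
    crw_excluded = []
    for disp in pairing:
        longs = steps[(steps["animal_id"] == disp) & (steps["step_class"] == "long")]
        try:
            null_set = crw_mod.simulate_crw(longs, rng=rng, extent=landscape.extent)
            coefs.append(crw_mod.compare_route(null_set, landscape))
        except (ValueError, FloatingPointError) as exc:
            crw_excluded.append({"animal_id": disp, "reason": str(exc)})
    broad = None
    if len(coefs) >= 5:
        broad = crw_mod.aggregate_population(pd.DataFrame(coefs))
        per_ind = broad.per_individual.reset_index(names="animal_id")
        _write(per_ind, out / "crw_individual_coefficients.csv", manifest)
        summary = pd.DataFrame(
            {
                "mean_beta": broad.mean_beta,
                "wilcoxon_p": broad.wilcoxon_p,
                "n_positive": broad.n_positive,
                "n_negative": broad.n_negative,
            }
        ).reset_index(names="covariate")
        _write(summary, out / "crw_population_summary.csv", manifest)
    if crw_excluded:
        _write(pd.DataFrame(crw_excluded), out / "crw_excluded.csv", manifest)
    stage("crw", len(pairing), len(coefs), t0)

    manifest["seed"] = config.rng_seed
    manifest["total_seconds"] = round(time.time() - t_start, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return RunResult(
        landscape=landscape,
        trajectories=traj,
        truth=truth,
        screened=screened,
        removed=removed,
        classifications=cls_df,
        classification_report=report,
        windows=windows,
        pairing=pairing,
        steps=steps,
        rate_models=pd.concat(rate_rows, ignore_index=True),
        segmented=seg_report,
        design=design_scaled,
        suite=suite,
        broad_scale=broad,
        manifest=manifest,
    )
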