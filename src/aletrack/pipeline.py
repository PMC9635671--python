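"""End-to-end analysis: curve tables in, statistical results out.

Stages: read + validate -> per-curve QC, smoothing and growth parameters ->
spatial normalization against reference colonies -> per-population
adaptation trajectories with LOESS milestones -> strain-level
fitness-predicts-adaptation statistics.  Every filtering step is counted in
a structured log so data loss is auditable.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as ale_io
from .config import RunConfig
from .errors import AletrackError
from .growth import GrowthCurve, QCStatus, process_curve
from .platenorm import normalize_plate_set
from .stats import (FitnessAdaptationResults, regress_adaptation,
                    replicate_repeatability)
from .trajectories import assemble_trajectory, extract_milestones, fit_trajectory

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """All tables and fitted objects produced by one run."""

    cycle_records: pd.DataFrame
    population_milestones: pd.DataFrame
    strain_summaries: pd.DataFrame
    regressions: pd.DataFrame
    outliers: dict              # milestone -> outlier table
    repeatability: dict         # milestone -> R^2
    results: dict               # milestone -> FitnessAdaptationResults
    counts: dict = field(default_factory=dict)


def compute_cycle_records(curve_df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Per colony-cycle growth parameters from the long curve table."""
    rows = []
    for (plate, row, col, cycle), times, cells in ale_io.iter_curves(curve_df):
        try:
            curve = GrowthCurve(times=times, cells=cells, plate_id=str(plate),
                                row=int(row), col=int(col), cycle=int(cycle))
        except AletrackError as exc:
            raise AletrackError(
                f"stage curves: colony ({plate},{row},{col}) cycle {cycle}: {exc}"
            ) from exc
        rec = process_curve(curve, median_window=config.median_window,
                            gaussian_sigma=config.gaussian_sigma,
                            mu_window=config.mu_max_window,
                            thresholds=config.qc)
        rows.append((plate, row, col, cycle, rec.mu_max, rec.doubling_time_h,
                     rec.generations, rec.qc_status.value))
    return pd.DataFrame(rows, columns=[
        "plate_id", "row", "col", "cycle", "mu_max", "doubling_time_h",
        "generations", "qc_status"])


def normalize_cycle_records(records: pd.DataFrame, layout: pd.DataFrame,
                            method: str = "bilinear") -> pd.DataFrame:
    """Add a ``normalized_D_h`` column using reference colonies per cycle.

    Each cycle's plates form one plate set sharing a reference median; a
    plate that cannot be normalized (too few usable references) keeps raw
    doubling times and is flagged in the ``normalized`` column.
    """
    n_rows = int(layout["row"].max()) + 1
    n_cols = int(layout["col"].max()) + 1
    out = records.merge(layout, on=["plate_id", "row", "col"], how="left")
    out["normalized_D_h"] = out["doubling_time_h"]
    out["normalized"] = False
    if method == "none":
        return out
    for cycle, cyc_grp in out.groupby("cycle", sort=True):
        plates = {}
        for pid, grp in cyc_grp.groupby("plate_id", sort=True):
            mat = np.full((n_rows, n_cols), np.nan)
            ok = grp["qc_status"] == QCStatus.OK.value
            mat[grp.loc[ok, "row"], grp.loc[ok, "col"]] = \
                grp.loc[ok, "doubling_time_h"]
            plates[pid] = mat
        try:
            normalized, surfaces, _ = normalize_plate_set(plates)
        except AletrackError as exc:
            log.warning("stage normalize: cycle %s: %s", cycle, exc)
            continue
        for pid, surf in surfaces.items():
            sel = (out["cycle"] == cycle) & (out["plate_id"] == pid)
            d = out.loc[sel, "doubling_time_h"].to_numpy()
            offs = surf.offsets_log2[out.loc[sel, "row"].to_numpy(),
                                     out.loc[sel, "col"].to_numpy()]
            out.loc[sel, "normalized_D_h"] = d / np.exp2(offs)
            out.loc[sel, "normalized"] = True
    return out


def build_population_milestones(records: pd.DataFrame, config: RunConfig
                                ) -> tuple[pd.DataFrame, dict]:
    """Assemble, fit and summarize one trajectory per evolving population."""
    counts = {"populations_seen": 0, "trajectories_excluded": 0}
    strain_rec = records[(records["role"] == "strain") & (records["cycle"] >= 1)]
    rows = []
    milestone_cols = [f"A{g:g}" for g in config.milestones]
    for (sid, rep), grp in strain_rec.groupby(["strain_id", "replicate"],
                                              sort=True):
        counts["populations_seen"] += 1
        grp = grp.sort_values("cycle", kind="stable")
        qc_ok = (grp["qc_status"] == QCStatus.OK.value).to_numpy()
        traj = assemble_trajectory(
            f"{sid}/r{rep}", grp["generations"].to_numpy(),
            grp["normalized_D_h"].to_numpy(), qc_ok)
        if traj is None:
            counts["trajectories_excluded"] += 1
            log.info("population %s/r%s excluded: too few usable cycles", sid, rep)
            continue
        fit_trajectory(traj, config.loess)
        ms = extract_milestones(traj, config.milestones)
        rows.append({"strain_id": sid, "replicate": rep,
                     "n_points": len(traj.generations),
                     "max_generations": traj.max_generations,
                     "preadaptation_D": ms["preadaptation_D"],
                     "first_cycle_D": traj.first_cycle_D,
                     **{c: ms.get(c, np.nan) for c in milestone_cols}})
    df = pd.DataFrame(rows, columns=["strain_id", "replicate", "n_points",
                                     "max_generations", "preadaptation_D",
                                     "first_cycle_D", *milestone_cols])
    return df, counts


def run_pipeline(config: RunConfig, outdir: str | None = None) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Reads the curve and layout tables, derives growth parameters, spatially
    normalizes doubling times, fits adaptation trajectories, and computes
    the fitness-to-adaptation regression, outlier calls and replicate
    repeatability for every milestone.  Deterministic given inputs and
    ``config.seed``.  When ``outdir`` is given, all result tables plus a
    ``log.json`` of stage counts are written there.
    """
    curve_df = ale_io.read_curve_table(config.curve_table)
    layout = ale_io.read_layout_table(config.layout_table)
    counts = {"curve_points_read": int(len(curve_df))}

    records = compute_cycle_records(curve_df, config)
    counts["curves_read"] = int(len(records))
    for status in QCStatus:
        counts[f"curves_{status.value}"] = int(
            (records["qc_status"] == status.value).sum())

    records = normalize_cycle_records(records, layout, config.normalization)
    milestones_df, traj_counts = build_population_milestones(records, config)
    counts.update(traj_counts)

    milestone_cols = [f"A{g:g}" for g in config.milestones]
    strain_summaries = (milestones_df.groupby("strain_id", sort=True)
                        .agg(n_replicates=("replicate", "size"),
                             **{c: (c, "mean") for c in
                                ["preadaptation_D", "first_cycle_D",
                                 *milestone_cols]})
                        .reset_index())

    reg_rows, results, outliers, repeat = [], {}, {}, {}
    for col in milestone_cols:
        defined = milestones_df[col].notna()
        if defined.sum() < 3 or milestones_df.loc[defined, "strain_id"].nunique() < 3:
            log.warning("milestone %s: too few populations for regression", col)
            continue
        res: FitnessAdaptationResults = regress_adaptation(milestones_df, col)
        results[col] = res
        outliers[col] = res.call_outliers(config.q_threshold)
        try:
            repeat[col] = replicate_repeatability(milestones_df, col,
                                                  seed=config.seed)
        except AletrackError:
            repeat[col] = float("nan")
        n_sig = int(outliers[col]["significant"].sum())
        reg_rows.append((col, res.nobs, res.slope, res.intercept, res.rsquared,
                         repeat[col], n_sig))
    regressions = pd.DataFrame(reg_rows, columns=[
        "milestone", "n_strains", "slope", "intercept", "rsquared",
        "replicate_repeatability_r2", "n_significant_outliers"])
    counts["strains_tested"] = int(strain_summaries.shape[0])

    result = PipelineResult(cycle_records=records,
                            population_milestones=milestones_df,
                            strain_summaries=strain_summaries,
                            regressions=regressions, outliers=outliers,
                            repeatability=repeat, results=results,
                            counts=counts)
    if outdir is not None:
        write_results(result, outdir)
    return result


def write_results(result: PipelineResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    ale_io.write_table(result.cycle_records, os.path.join(outdir, "cycle_records.csv"))
    ale_io.write_table(result.population_milestones,
                       os.path.join(outdir, "population_milestones.csv"))
    ale_io.write_table(result.strain_summaries,
                       os.path.join(outdir, "strain_summaries.csv"))
    ale_io.write_table(result.regressions, os.path.join(outdir, "regressions.csv"))
    for col, table in result.outliers.items():
        ale_io.write_table(table, os.path.join(outdir, f"outliers_{col}.csv"))
    with open(os.path.join(outdir, "log.json"), "w") as fh:
        json.dump(result.counts, fh, indent=2, sort_keys=True)
        fh.write("\n")
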