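"""Run-directory workflow: the stages the CLI chains together.

Each stage reads the previous stage's artifacts from a run directory and
writes its own, so stages can be re-run independently. A JSON log with
the stage's configuration and seed is written next to each artifact set.
"""

from __future__ import annotations

import json
import logging
import pickle
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import io as hio
from .attribution import (CATEGORIES, attribution_summary, classify_change,
                          hsa_timeseries)
from .bioclim import annual_predictors, climatological_stack, default_registry
from .brt import BRTConfig, contributions, interactions, response_curve
from .ensemble import EnsembleConfig, EnsembleResult, run_ensemble
from .grid import GridSpec
from .importance import compute_mip, compute_mipc, mip_summary, response_range
from .synthetic import (calibrate_intercept, default_truth_spec,
                        generate_climate, generate_landuse, generate_sea_mask,
                        generate_species_map)

__all__ = ["simulate_stage", "bioclim_stage", "ensemble_stage",
           "attribute_stage", "mip_stage", "report_stage", "DEFAULT_GRID"]

log = logging.getLogger(__name__)

#: Desk-scale default domain: 5W-5E, 35N-45N at 0.25 degrees (40 x 40 cells).
DEFAULT_GRID = GridSpec(-5.0, 5.0, 35.0, 45.0, 0.25)


def _write_log(outdir: Path, stage: str, payload: dict) -> None:
    payload = {"stage": stage, "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
               **payload}
    (outdir / f"{stage}.log.json").write_text(json.dumps(payload, indent=2,
                                                         default=str))


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name}; run the '{produced_by}' stage "
            "first")
    return path


def simulate_stage(outdir: str | Path, grid: GridSpec = DEFAULT_GRID,
                   years: tuple[int, int] = (1970, 2020), seed: int = 0,
                   trend: float = 0.4, drift_rate: float = 0.01,
                   sea_fraction: float = 0.2, noise_sd: float = 0.0,
                   map_year: int | None = None, window: int = 31,
                   target_prevalence: float = 0.4) -> Path:
    """Generate and persist climate, land-use, mask, truth, and species map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cube = generate_climate(grid, years, trend=trend, seed=seed,
                            min_span=window)
    landmask = generate_sea_mask(grid, seed=seed, sea_fraction=sea_fraction)
    lu = generate_landuse(grid, years, drift_rate=drift_rate, seed=seed)
    hio.write_dataset(cube, outdir / "climate.nc")
    hio.write_landuse(lu, outdir / "landuse.nc")
    np.savetxt(outdir / "landmask.txt", landmask.astype(int), fmt="%d")

    map_year = map_year if map_year is not None else years[0] + window - 1
    registry = default_registry()
    stack = climatological_stack(cube, lu, map_year, registry, window=window,
                                 mask=landmask)
    truth = calibrate_intercept(stack, default_truth_spec(),
                                target_prevalence=target_prevalence)
    prob = generate_species_map(stack, truth, noise_sd=noise_sd, seed=seed,
                                mask=landmask)
    hio.write_truth(truth, outdir / "truth.yaml")
    hio.write_species_map(prob, outdir / "species.nc")
    _write_log(outdir, "simulate", {
        "grid": grid.to_dict(), "years": list(years), "seed": seed,
        "trend": trend, "drift_rate": drift_rate, "map_year": map_year,
        "noise_sd": noise_sd})
    return outdir


def bioclim_stage(outdir: str | Path, target_years: list[int],
                  window: int = 31) -> Path:
    """Compute climatological predictor stacks for the target years."""
    outdir = Path(outdir)
    cube = hio.read_dataset(_require(outdir / "climate.nc", "simulate"))
    lu = hio.read_landuse(_require(outdir / "landuse.nc", "simulate"))
    hio.require_same_grid(cube, lu, "climate.nc", "landuse.nc")
    landmask = np.loadtxt(outdir / "landmask.txt").astype(bool)
    registry = default_registry()
    years_needed = sorted(set(
        y for ty in target_years for y in range(ty - window + 1, ty + 1)))
    annual = annual_predictors(cube, registry, years_needed)
    for ty in target_years:
        stack = climatological_stack(None, lu, ty, registry, window=window,
                                     annual=annual, mask=landmask)
        hio.write_stack(stack, outdir / f"stack_{ty}.nc")
    _write_log(outdir, "bioclim", {"target_years": target_years,
                                   "window": window})
    return outdir


def _load_stacks(outdir: Path, years: list[int]) -> dict:
    return {y: hio.read_stack(_require(outdir / f"stack_{y}.nc", "bioclim"))
            for y in years}


def ensemble_stage(outdir: str | Path, config: EnsembleConfig) -> EnsembleResult:
    """Run the 16-setup ensemble and persist its reports."""
    outdir = Path(outdir)
    prob = hio.read_species_map(_require(outdir / "species.nc", "simulate"))
    years = sorted(set([config.reference_year, config.calibration_year,
                        *config.years]))
    stacks = _load_stacks(outdir, years)
    result = run_ensemble(prob, stacks, config)

    rows = []
    for m in result.members:
        row = {"setup_id": m.setup.setup_id,
               "background_method": m.setup.background_method,
               "predictor_method": m.setup.predictor_method,
               "ok": m.ok, "flagged": m.flagged, "error": m.error}
        if m.ok:
            row.update(m.skill.to_dict())
            row["n_trees"] = m.model.n_trees
            row["learning_rate"] = m.model.learning_rate
            row["tree_complexity"] = m.model.tree_complexity
            row["n_predictors"] = len(m.model.predictors)
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "skills.csv", index=False)
    result.quantiles.to_csv(outdir / "hsa_quantiles.csv")
    for m in result.members:
        if m.ok:
            m.hsa.to_csv(outdir / f"hsa_setup_{m.setup.setup_id:02d}.csv")
    with open(outdir / "ensemble.pkl", "wb") as fh:
        pickle.dump(result, fh)
    _write_log(outdir, "ensemble", {
        "seed": config.seed, "reference_year": config.reference_year,
        "years": config.years, "n_presence": config.n_presence,
        "best_setup_id": result.best_setup_id,
        "brt": asdict(config.brt)})
    return result


def _load_ensemble(outdir: Path) -> EnsembleResult:
    with open(_require(outdir / "ensemble.pkl", "ensemble"), "rb") as fh:
        return pickle.load(fh)


def attribute_stage(outdir: str | Path, year: int) -> pd.DataFrame:
    """Classify per-cell changes for the best model and summarize."""
    outdir = Path(outdir)
    result = _load_ensemble(outdir)
    best = result.best
    change = classify_change(best.scenario, year)
    ref_hsa = int(np.nansum(best.scenario.ref))
    summary = attribution_summary(change, ref_hsa)
    frame = pd.DataFrame([{"category": c, "count": summary["counts"][c],
                           "pct_of_ref_hsa": 100.0 * summary["counts"][c]
                           / ref_hsa} for c in CATEGORIES])
    frame.to_csv(outdir / f"change_categories_{year}.csv", index=False)
    flat = {k: v for k, v in summary.items() if k != "counts"}
    pd.DataFrame([flat]).to_csv(outdir / f"attribution_{year}.csv",
                                index=False)
    np.save(outdir / f"change_map_{year}.npy", change, allow_pickle=True)
    best.hsa.to_csv(outdir / "hsa_best.csv")
    _write_log(outdir, "attribute", {"year": year, "reference_hsa": ref_hsa,
                                     **flat})
    return frame


def mip_stage(outdir: str | Path, year: int, group: str = "climate"
              ) -> pd.DataFrame:
    """Most-important-predictor maps/summaries for the best model."""
    outdir = Path(outdir)
    result = _load_ensemble(outdir)
    best = result.best
    model = best.model
    ref_year = best.scenario.reference_year
    stacks = _load_stacks(outdir, [ref_year, year])
    stack_ref, stack_now = stacks[ref_year], stacks[year]

    climate = set(stack_ref.climate_names)
    if group == "climate":
        preds = [p for p in model.predictors if p in climate]
    else:
        preds = [p for p in model.predictors if p not in climate]
    if not preds:
        raise ValueError(f"best model has no {group} predictors")

    contrib = contributions(model)
    ints = interactions(model).sums
    valid = stack_ref.valid_cells()
    curves = {p: response_curve(model, p) for p in preds}
    deltas = np.empty((len(valid), len(preds)))
    raw_deltas = np.empty_like(deltas)
    for j, p in enumerate(preds):
        x_ref = stack_ref.array(p).ravel()[valid]
        x_now = stack_now.array(p).ravel()[valid]
        f = curves[p]
        deltas[:, j] = (np.interp(x_now, f.x, f.response)
                        - np.interp(x_ref, f.x, f.response))
        raw_deltas[:, j] = x_now - x_ref

    record = compute_mip(contrib, ints, deltas, preds)
    change = classify_change(best.scenario, year).ravel()[valid]
    record_c = compute_mipc(contrib, ints, deltas, preds, change)
    summary = mip_summary(record, change, raw_deltas)
    summary_c = mip_summary(record_c, change, raw_deltas)
    summary["kind"] = "MIP"
    summary_c["kind"] = "MIPC"
    table = pd.concat([summary, summary_c], ignore_index=True)
    table.to_csv(outdir / f"mip_{group}_{year}.csv", index=False)
    _write_log(outdir, "mip", {"year": year, "group": group,
                               "predictors": preds})
    return table


def report_stage(outdir: str | Path) -> Path:
    """Collate the tabular outputs into a report directory."""
    outdir = Path(outdir)
    report = outdir / "report"
    report.mkdir(exist_ok=True)
    wanted = ["skills.csv", "hsa_quantiles.csv", "hsa_best.csv"]
    wanted += [p.name for p in outdir.glob("attribution_*.csv")]
    wanted += [p.name for p in outdir.glob("change_categories_*.csv")]
    wanted += [p.name for p in outdir.glob("mip_*.csv")]
    copied = []
    for name in wanted:
        src = outdir / name
        if src.exists():
            (report / name).write_text(src.read_text())
            copied.append(name)
    if not copied:
        raise FileNotFoundError("no report inputs found; run the ensemble "
                                "stage first")
    _write_log(report, "report", {"files": copied})
    return report
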