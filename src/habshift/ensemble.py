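"""The 4 x 4 ensemble of background- and predictor-selection setups.

Each of the 16 setups draws its own calibration sample, tunes a full
model, applies its within-model predictor selection, refits, evaluates
skill and transferability, and projects all years under the varying- and
constant-land-use scenarios. The ensemble exposes unweighted quantile
series of the per-year habitat-suitability-area change and the
highest-scoring member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

from ._rng import substream
from .attribution import ScenarioRun, hsa_timeseries, project_scenarios
from .brt import BRTConfig, FittedBRT, contributions, interactions, simplify, tune
from .evaluation import SkillReport, aoa, skill_report
from .sampling import BACKGROUND_METHODS, CalibrationSample, select_background
from .stack import PredictorStack

__all__ = ["ModelSetup", "SetupResult", "EnsembleResult", "EnsembleConfig",
           "all_setups", "select_predictors", "run_ensemble", "pick_best",
           "PREDICTOR_METHODS"]

log = logging.getLogger(__name__)

PREDICTOR_METHODS = ("I", "II", "III", "IV")

ENSEMBLE_QUANTILES = (0.05, 0.25, 0.50, 0.75, 0.95)


@dataclass(frozen=True)
class ModelSetup:
    background_method: str
    predictor_method: str
    setup_id: int

    def __post_init__(self) -> None:
        if self.background_method not in BACKGROUND_METHODS:
            raise ValueError(f"bad background method {self.background_method!r}")
        if self.predictor_method not in PREDICTOR_METHODS:
            raise ValueError(f"bad predictor method {self.predictor_method!r}")

    @property
    def label(self) -> str:
        return f"{self.background_method}/{self.predictor_method}"


def all_setups() -> list[ModelSetup]:
    """The full cross product: exactly 16 setups."""
    setups = []
    i = 0
    for bg in BACKGROUND_METHODS:
        for pm in PREDICTOR_METHODS:
            setups.append(ModelSetup(bg, pm, i))
            i += 1
    return setups


# ---------------------------------------------------------------------------
# within-model predictor selection
# ---------------------------------------------------------------------------

def _prune_correlated(names: list[str], sample: CalibrationSample,
                      contribution: dict[str, float],
                      r_threshold: float = 0.7) -> list[str]:
    """Greedy removal of correlated pairs, keeping the higher contribution."""
    keep = list(names)
    while True:
        if len(keep) < 2:
            break
        corr = sample.table[keep].corr().abs().values
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= r_threshold:
            break
        drop = keep[i] if contribution.get(keep[i], 0.0) <= \
            contribution.get(keep[j], 0.0) else keep[j]
        keep.remove(drop)
    return keep


def select_predictors(method: str, model: FittedBRT,
                      sample: CalibrationSample,
                      climate_names: set[str],
                      interaction_sums: dict[str, float] | None = None,
                      simplify_kwargs: dict | None = None) -> list[str]:
    """Apply one of the four within-model predictor-selection methods.

    I  — keep everything;
    II — the iterative simplification survivors;
    III — climate predictors with contribution > 1 OR interaction-sum
         above twice the median interaction-sum (land-use passes through);
    IV — method III, then prune climate pairs with |Pearson r| > 0.7,
         keeping the higher-contribution member.
    """
    if method not in PREDICTOR_METHODS:
        raise ValueError(f"unknown predictor-selection method {method!r}")
    predictors = list(model.predictors)
    if method == "I":
        return predictors
    if method == "II":
        return simplify(model, sample, **(simplify_kwargs or {}))

    contribution = contributions(model)
    if interaction_sums is None:
        interaction_sums = interactions(model).sums
    climate = [p for p in predictors if p in climate_names]
    landuse = [p for p in predictors if p not in climate_names]
    sums = np.array([interaction_sums[p] for p in climate])
    cutoff = 2.0 * np.median(sums) if len(sums) else 0.0
    survivors = [p for p in climate
                 if contribution[p] > 1.0 or interaction_sums[p] > cutoff]
    if method == "IV":
        survivors = _prune_correlated(survivors, sample, contribution)
    result = survivors + landuse
    if not result:
        raise ValueError(f"predictor-selection method {method} removed every "
                         "predictor; model would be unfittable")
    return result


# ---------------------------------------------------------------------------
# ensemble orchestration
# ---------------------------------------------------------------------------

@dataclass
class EnsembleConfig:
    reference_year: int
    years: list[int]
    calibration_year: int | None = None     # defaults to reference_year
    n_presence: int = 10000
    n_absence: int = 10000
    brt: BRTConfig = field(default_factory=BRTConfig)
    holdout_fraction: float = 0.5
    include_bss: bool = True
    simplify_kwargs: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.calibration_year is None:
            self.calibration_year = self.reference_year
        if self.reference_year > min(self.years):
            raise ValueError("reference year must not exceed the first "
                             "target year")


@dataclass
class SetupResult:
    setup: ModelSetup
    model: FittedBRT | None = None
    skill: SkillReport | None = None
    scenario: ScenarioRun | None = None
    hsa: pd.DataFrame | None = None
    sample: CalibrationSample | None = None
    calib: CalibrationSample | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None

    @property
    def flagged(self) -> bool:
        return (not self.ok) or (self.model is not None and self.model.flagged)


@dataclass
class EnsembleResult:
    members: list[SetupResult]
    quantiles: pd.DataFrame       # index year, columns q05..q95 of pct change
    best_setup_id: int

    def member(self, setup_id: int) -> SetupResult:
        return self.members[setup_id]

    @property
    def best(self) -> SetupResult:
        return self.member(self.best_setup_id)


def _run_setup(setup: ModelSetup, prob_map: xr.DataArray,
               stacks: dict[int, PredictorStack],
               config: EnsembleConfig) -> SetupResult:
    seed = int(substream(config.seed, f"setup/{setup.setup_id}")
               .integers(0, 2**31 - 1))
    calib_stack = stacks[config.calibration_year]
    sample = select_background(prob_map, calib_stack, setup.background_method,
                               config.n_presence, config.n_absence, seed)
    calib, holdout = sample.split(1.0 - config.holdout_fraction, seed)
    brt_cfg = replace(config.brt, seed=seed)

    full = tune(calib, list(sample.predictor_names), brt_cfg)
    climate = set(calib_stack.climate_names)
    ints = interactions(full).sums if setup.predictor_method in ("III", "IV") \
        else None
    selected = select_predictors(setup.predictor_method, full, calib, climate,
                                 interaction_sums=ints,
                                 simplify_kwargs=config.simplify_kwargs)
    if set(selected) == set(full.predictors):
        model = full
    else:
        model = tune(calib, selected, brt_cfg)   # re-tune the reduced model

    # skill on the held-out half
    p_hold = model.predict(holdout.X)
    eval_lonlat = holdout.table[["lon", "lat"]].values
    calib_pres = calib.table.loc[calib.table["label"] == 1,
                                 ["lon", "lat"]].values
    contrib = contributions(model)
    weights = np.array([contrib[p] / 100.0 for p in model.predictors])
    valid = calib_stack.valid_cells()
    stack_X = np.column_stack([calib_stack.array(p).ravel()[valid]
                               for p in model.predictors])
    aoa_val, _ = aoa(calib.table[model.predictors].values, stack_X, weights,
                     seed=seed)
    skill = skill_report(holdout.y, p_hold, eval_lonlat, calib_pres, aoa_val,
                         include_bss=config.include_bss)

    scenario = project_scenarios(model, stacks, config.reference_year,
                                 skill.tss_max_threshold)
    hsa = hsa_timeseries(scenario)
    return SetupResult(setup, model, skill, scenario, hsa, sample, calib)


def run_ensemble(prob_map: xr.DataArray, stacks: dict[int, PredictorStack],
                 config: EnsembleConfig) -> EnsembleResult:
    """Run all 16 setups and assemble ensemble statistics.

    Individual setup failures are caught, logged, and excluded from the
    quantile series; at least one setup must succeed.
    """
    missing = [y for y in [config.reference_year, *config.years]
               if y not in stacks]
    if missing:
        raise ValueError(f"stacks missing for years {missing}")
    members: list[SetupResult] = []
    for setup in all_setups():
        try:
            members.append(_run_setup(setup, prob_map, stacks, config))
            log.info("setup %s done", setup.label)
        except Exception as exc:  # noqa: BLE001 — setup isolation is the contract
            log.warning("setup %s failed: %s", setup.label, exc)
            members.append(SetupResult(setup, error=str(exc)))

    ok = [m for m in members if m.ok]
    if not ok:
        raise RuntimeError("all 16 setups failed")
    years = sorted(config.years)
    series = pd.DataFrame(
        {m.setup.setup_id: m.hsa["pct_change"].reindex(years) for m in ok})
    quantiles = series.quantile(list(ENSEMBLE_QUANTILES), axis=1).T
    quantiles.columns = [f"q{int(100 * q):02d}" for q in ENSEMBLE_QUANTILES]
    best = pick_best(members)
    return EnsembleResult(members, quantiles, best)


def pick_best(members: list[SetupResult]) -> int:
    """Setup id with the maximal SCORE among unflagged members.

    Ties break toward higher AoA, then lower setup id.
    """
    eligible = [m for m in members if m.ok and not m.flagged]
    if not eligible:
        raise ValueError("no unflagged ensemble members to choose from")
    ranked = sorted(eligible, key=lambda m: (-m.skill.SCORE, -m.skill.AoA,
                                             m.setup.setup_id))
    return ranked[0].setup.setup_id
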