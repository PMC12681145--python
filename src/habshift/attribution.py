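"""Climate vs land-use change attribution.

Three projection streams are compared per year: REF (the reference-year
prediction), CLU (climate varies, land-use frozen at the reference
year) and VLU (everything varies). Each cell's (REF, CLU, VLU) triple
maps to one of eight change categories; counts are reported as percent
of the reference habitat-suitability area (HSA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .brt import FittedBRT, predict_map
from .stack import PredictorStack

__all__ = ["ScenarioRun", "CATEGORIES", "CATEGORY_TABLE", "project_scenarios",
           "classify_change", "hsa_timeseries", "attribution_summary"]

#: The eight change categories, ordered by their (REF, CLU, VLU) triples.
CATEGORY_TABLE: dict[tuple[int, int, int], str] = {
    (1, 1, 1): "P",      # present throughout
    (0, 0, 0): "A",      # absent throughout
    (0, 1, 1): "PCC",    # change to present due to climate change
    (1, 0, 0): "ACC",    # change to absent due to climate change
    (0, 0, 1): "PLUC",   # change to present due to land-use change
    (1, 1, 0): "ALUC",   # change to absent due to land-use change
    (1, 0, 1): "RPLUC",  # remaining present due to land-use change
    (0, 1, 0): "RALUC",  # remaining absent due to land-use change
}

CATEGORIES = ("P", "A", "PCC", "ACC", "PLUC", "ALUC", "RPLUC", "RALUC")


@dataclass
class ScenarioRun:
    """Binary presence maps for the REF / CLU / VLU projection streams."""

    reference_year: int
    ref: np.ndarray                   # (lat, lon) float with NaN mask
    clu: dict[int, np.ndarray]        # year -> binary map
    vlu: dict[int, np.ndarray]
    threshold: float

    def __post_init__(self) -> None:
        if set(self.clu) != set(self.vlu):
            raise ValueError("CLU and VLU must cover the same years")

    @property
    def years(self) -> list[int]:
        return sorted(self.clu)


def _binarize(prob: xr.DataArray, threshold: float) -> np.ndarray:
    v = prob.values
    return np.where(np.isnan(v), np.nan, (v >= threshold).astype(float))


def project_scenarios(model: FittedBRT, stacks: dict[int, PredictorStack],
                      reference_year: int, threshold: float) -> ScenarioRun:
    """Run the REF/CLU/VLU projections.

    For the CLU stream, each year's stack has its land-use predictors
    replaced by the reference year's values before prediction.
    """
    if reference_year not in stacks:
        raise ValueError(f"reference year {reference_year} missing from stacks")
    ref_stack = stacks[reference_year]
    ref = _binarize(predict_map(model, ref_stack), threshold)

    lu_names = [n for n in model.predictors
                if n in ref_stack.landuse_names]
    clu: dict[int, np.ndarray] = {}
    vlu: dict[int, np.ndarray] = {}
    for year, st in stacks.items():
        vlu[year] = _binarize(predict_map(model, st), threshold)
        if lu_names:
            frozen = st.data.copy()
            for n in ref_stack.landuse_names:
                if n in frozen:
                    frozen[n] = ref_stack.data[n]
            st_clu = PredictorStack(st.grid, frozen, st.mask, st.target_year)
            clu[year] = _binarize(predict_map(model, st_clu), threshold)
        else:
            clu[year] = vlu[year]
    return ScenarioRun(reference_year=reference_year, ref=ref, clu=clu,
                       vlu=vlu, threshold=threshold)


def classify_change(run: ScenarioRun, year: int) -> np.ndarray:
    """Per-cell change category for one year (object array; None = masked)."""
    if year not in run.clu:
        raise ValueError(f"year {year} not in scenario run")
    ref, clu, vlu = run.ref, run.clu[year], run.vlu[year]
    out = np.empty(ref.shape, dtype=object)
    out[:] = None
    valid = ~np.isnan(ref)
    triples = np.stack([ref, clu, vlu]).astype(float)
    for (r, c, v), cat in CATEGORY_TABLE.items():
        match = valid & (triples[0] == r) & (triples[1] == c) & (triples[2] == v)
        out[match] = cat
    return out


def hsa_timeseries(run: ScenarioRun) -> pd.DataFrame:
    """HSA cell counts and percent change vs the reference HSA, per year.

    Percent change at year y = 100 * (HSA_VLU(y) - HSA_REF) / HSA_REF.
    """
    hsa_ref = int(np.nansum(run.ref))
    if hsa_ref == 0:
        raise ValueError("reference HSA is empty")
    rows = []
    for year in run.years:
        hsa = int(np.nansum(run.vlu[year]))
        rows.append({"year": year, "hsa": hsa,
                     "pct_change": 100.0 * (hsa - hsa_ref) / hsa_ref})
    return pd.DataFrame(rows).set_index("year")


def attribution_summary(change: np.ndarray, reference_hsa: int) -> dict:
    """Category tallies as percent of the reference HSA.

    Net changes count only cells whose status flipped relative to REF;
    the retention categories (RPLUC/RALUC) are reported separately since
    their status relative to REF is unchanged.
    """
    if reference_hsa <= 0:
        raise ValueError("reference HSA must be positive")
    counts = {cat: int(np.sum(change == cat)) for cat in CATEGORIES}
    pct = {cat: 100.0 * n / reference_hsa for cat, n in counts.items()}
    summary = {
        "counts": counts,
        "climate_gain_pct": pct["PCC"],
        "climate_loss_pct": pct["ACC"],
        "landuse_gain_pct": pct["PLUC"],
        "landuse_loss_pct": pct["ALUC"],
        "net_climate_pct": pct["PCC"] - pct["ACC"],
        "net_landuse_pct": pct["PLUC"] - pct["ALUC"],
        "retained_present_pct": pct["RPLUC"],
        "retained_absent_pct": pct["RALUC"],
    }
    summary["overall_pct"] = (summary["net_climate_pct"]
                              + summary["net_landuse_pct"])
    return summary
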