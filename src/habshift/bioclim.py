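"""Bioclimatic variables (BIO1-19), threshold extremes, absolute humidity,
and assembly of 31-year climatological predictor stacks.

Quarters follow the WorldClim convention: all 12 consecutive 3-month
windows, wrapping within the same calendar year (Jan-Mar, ..., Dec-Feb).
Temperature BIOs are in degC (not degC x 10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridSpec
from .stack import PredictorStack

__all__ = [
    "ExtremeDef",
    "ThresholdRegistry",
    "default_registry",
    "compute_bios",
    "compute_exvs",
    "compute_ahum",
    "annual_predictors",
    "climatological_stack",
    "BIO_NAMES",
]

log = logging.getLogger(__name__)

BIO_NAMES = tuple(f"BIO{i}" for i in range(1, 20))

DEFAULT_WINDOW = 31


# ---------------------------------------------------------------------------
# threshold registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtremeDef:
    """One extreme-variable definition.

    statistic 'ND' counts qualifying days per year; 'LP' is the longest
    consecutive run of qualifying days (runs never wrap across years).
    """

    name: str
    variable: str       # tmean | tmin | tmax | precip
    comparator: str     # '<' or '>'
    threshold: float    # degC or mm/day
    statistic: str      # ND | LP

    def __post_init__(self) -> None:
        if self.variable not in ("tmean", "tmin", "tmax", "precip"):
            raise ValueError(f"unknown variable {self.variable!r}")
        if self.comparator not in ("<", ">"):
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.statistic not in ("ND", "LP"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


@dataclass(frozen=True)
class ThresholdRegistry:
    entries: tuple[ExtremeDef, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("extreme-variable names must be unique")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def default_registry() -> ThresholdRegistry:
    """Default set of 18 extreme variables (user-overridable)."""
    families = [
        ("tmean", "<", 0.0, "tmean_lt0"),
        ("tmax", "<", 0.0, "tmax_lt0"),
        ("tmin", "<", 0.0, "tmin_lt0"),
        ("tmax", ">", 30.0, "tmax_gt30"),
        ("tmax", ">", 35.0, "tmax_gt35"),
        ("tmin", ">", 20.0, "tmin_gt20"),
        ("precip", "<", 1.0, "dry"),
        ("precip", ">", 20.0, "wet20"),
    ]
    entries = []
    for var, cmp_, thr, tag in families:
        entries.append(ExtremeDef(f"ND_{tag}", var, cmp_, thr, "ND"))
        entries.append(ExtremeDef(f"LP_{tag}", var, cmp_, thr, "LP"))
    entries.append(ExtremeDef("ND_wet10", "precip", ">", 10.0, "ND"))
    entries.append(ExtremeDef("ND_tmean_gt25", "tmean", ">", 25.0, "ND"))
    return ThresholdRegistry(tuple(entries))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _year_slice(cube: xr.Dataset, year: int) -> xr.Dataset:
    sel = cube.sel(time=slice(f"{year}-01-01", f"{year}-12-31"))
    t = pd.DatetimeIndex(sel.time.values)
    if len(t) == 0:
        raise ValueError(f"year {year} not covered by climate cube")
    expected = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    if len(t) != len(expected) or t[0] != expected[0] or t[-1] != expected[-1]:
        raise ValueError(f"year {year} is incompletely covered by the cube "
                         f"({len(t)} of {len(expected)} days present)")
    return sel


def _monthly(cube_year: xr.Dataset) -> dict[str, np.ndarray]:
    """Monthly aggregates for one fully-covered calendar year.

    Returns arrays of shape (12, nlat, nlon): means of tmean/tmin/tmax,
    sums of precip.
    """
    month = cube_year.time.dt.month
    out = {}
    for var in ("tmean", "tmin", "tmax"):
        out[var] = (cube_year[var].groupby(month).mean("time")
                    .transpose("month", "lat", "lon").values.astype(float))
    out["precip"] = (cube_year["precip"].groupby(month).sum("time")
                     .transpose("month", "lat", "lon").values.astype(float))
    return out


def quarter_windows(monthly: np.ndarray, reduce: str) -> np.ndarray:
    """All 12 wrap-around 3-month windows of a (12, ...) monthly array.

    reduce 'mean' or 'sum'; returns shape (12, ...), window i covering
    months i, i+1, i+2 (0-based, modulo 12).
    """
    stacked = np.stack([monthly[(np.arange(3) + i) % 12].sum(axis=0)
                        for i in range(12)])
    if reduce == "mean":
        return stacked / 3.0
    if reduce == "sum":
        return stacked
    raise ValueError(reduce)


# ---------------------------------------------------------------------------
# BIO variables
# ---------------------------------------------------------------------------

def compute_bios(cube: xr.Dataset, year: int) -> dict[str, np.ndarray]:
    """The 19 BIOCLIM variables for one calendar year, per cell.

    Definitions follow the standard monthly-aggregate formulation: BIO2 is
    the mean monthly diurnal range, BIO3 = 100*BIO2/BIO7, BIO4 = 100*SD of
    monthly mean temperature, BIO7 = BIO5 - BIO6, BIO15 uses the
    coefficient of variation with the conventional +1 offset on the mean.
    Quarter selection ties resolve to the earliest window.
    """
    m = _monthly(_year_slice(cube, year))
    tmean_m, tmin_m, tmax_m, prec_m = m["tmean"], m["tmin"], m["tmax"], m["precip"]

    qtemp = quarter_windows(tmean_m, "mean")
    qprec = quarter_windows(prec_m, "sum")
    wettest_q = np.argmax(qprec, axis=0)
    driest_q = np.argmin(qprec, axis=0)
    warmest_q = np.argmax(qtemp, axis=0)
    coldest_q = np.argmin(qtemp, axis=0)

    def take(stacked: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return np.take_along_axis(stacked, idx[None], axis=0)[0]

    bio: dict[str, np.ndarray] = {}
    bio["BIO1"] = tmean_m.mean(axis=0)
    bio["BIO2"] = (tmax_m - tmin_m).mean(axis=0)
    bio["BIO4"] = 100.0 * tmean_m.std(axis=0, ddof=1)
    bio["BIO5"] = tmax_m.max(axis=0)
    bio["BIO6"] = tmin_m.min(axis=0)
    bio["BIO7"] = bio["BIO5"] - bio["BIO6"]
    with np.errstate(divide="ignore", invalid="ignore"):
        bio3 = 100.0 * bio["BIO2"] / bio["BIO7"]
    degenerate = bio["BIO7"] <= 0
    if degenerate.any():
        log.warning("BIO7 == 0 at %d cells; BIO3 set to 0 there",
                    int(degenerate.sum()))
    bio["BIO3"] = np.where(degenerate, 0.0, bio3)
    bio["BIO8"] = take(qtemp, wettest_q)
    bio["BIO9"] = take(qtemp, driest_q)
    bio["BIO10"] = qtemp.max(axis=0)
    bio["BIO11"] = qtemp.min(axis=0)
    bio["BIO12"] = prec_m.sum(axis=0)
    bio["BIO13"] = prec_m.max(axis=0)
    bio["BIO14"] = prec_m.min(axis=0)
    bio["BIO15"] = 100.0 * prec_m.std(axis=0, ddof=1) / (1.0 + prec_m.mean(axis=0))
    bio["BIO16"] = qprec.max(axis=0)
    bio["BIO17"] = qprec.min(axis=0)
    bio["BIO18"] = take(qprec, warmest_q)
    bio["BIO19"] = take(qprec, coldest_q)
    return {name: bio[name] for name in BIO_NAMES}


# ---------------------------------------------------------------------------
# extreme variables
# ---------------------------------------------------------------------------

def longest_run(mask: np.ndarray) -> np.ndarray:
    """Longest consecutive run of True along axis 0."""
    cur = np.zeros(mask.shape[1:], dtype=np.int64)
    best = np.zeros(mask.shape[1:], dtype=np.int64)
    for day in mask:
        cur = np.where(day, cur + 1, 0)
        best = np.maximum(best, cur)
    return best


def compute_exvs(cube: xr.Dataset, year: int,
                 registry: ThresholdRegistry) -> dict[str, np.ndarray]:
    """Extreme variables (day counts and longest runs) for one year."""
    sel = _year_slice(cube, year)
    cache: dict[tuple, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for entry in registry:
        key = (entry.variable, entry.comparator, entry.threshold)
        if key not in cache:
            values = sel[entry.variable].values
            if entry.comparator == "<":
                cache[key] = values < entry.threshold
            else:
                cache[key] = values > entry.threshold
        qualifying = cache[key]
        if entry.statistic == "ND":
            out[entry.name] = qualifying.sum(axis=0).astype(float)
        else:
            out[entry.name] = longest_run(qualifying).astype(float)
    return out


# ---------------------------------------------------------------------------
# absolute humidity
# ---------------------------------------------------------------------------

MAGNUS_A = 6.112   # hPa
MAGNUS_B = 17.62
MAGNUS_C = 243.12  # degC
R_VAPOUR = 461.5   # J kg-1 K-1


def absolute_humidity(dewpoint_c: np.ndarray) -> np.ndarray:
    """Absolute humidity (g/m3) from dewpoint (degC).

    Vapour pressure from the Magnus saturation formula evaluated at the
    dewpoint, converted to mass density with the ideal gas law.
    """
    dp = np.asarray(dewpoint_c, dtype=float)
    e_pa = 100.0 * MAGNUS_A * np.exp(MAGNUS_B * dp / (MAGNUS_C + dp))
    return 1000.0 * e_pa / (R_VAPOUR * (dp + 273.15))


def compute_ahum(cube: xr.Dataset, year: int) -> np.ndarray:
    """Annual-mean absolute humidity (g/m3) for one year, per cell."""
    if "dewpoint" not in cube:
        raise ValueError("climate cube has no dewpoint variable")
    sel = _year_slice(cube, year)
    return absolute_humidity(sel["dewpoint"].values).mean(axis=0)


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------

def annual_predictors(cube: xr.Dataset, registry: ThresholdRegistry,
                      years: list[int] | None = None) -> xr.Dataset:
    """Per-year climate predictor values (BIOs + EXVs + AHUM).

    Returns an xr.Dataset with dims (year, lat, lon), one variable per
    predictor. Computing this once and passing it to
    ``climatological_stack`` avoids recomputation across target years.
    """
    t = pd.DatetimeIndex(cube.time.values)
    if years is None:
        years = sorted(set(t.year))
        # drop partially covered edge years
        years = [y for y in years
                 if (t.year == y).sum() >= len(pd.date_range(
                     f"{y}-01-01", f"{y}-12-31", freq="D"))]
    records: dict[str, list[np.ndarray]] = {}
    for year in years:
        vals = compute_bios(cube, year)
        vals.update(compute_exvs(cube, year, registry))
        vals["AHUM"] = compute_ahum(cube, year)
        for name, arr in vals.items():
            records.setdefault(name, []).append(arr)
    return xr.Dataset(
        {name: (("year", "lat", "lon"), np.stack(arrs))
         for name, arrs in records.items()},
        coords={"year": years, "lat": cube.lat.values, "lon": cube.lon.values},
    )


SUBGROUPS = {"BIO": "BIO", "ND": "EXV", "LP": "EXV", "AH": "AHUM"}


def _subgroup(name: str) -> str:
    for prefix, sub in SUBGROUPS.items():
        if name.startswith(prefix):
            return sub
    return "EXV"


def climatological_stack(cube: xr.Dataset | None, landuse: xr.DataArray,
                         target_year: int,
                         registry: ThresholdRegistry | None = None,
                         window: int = DEFAULT_WINDOW,
                         annual: xr.Dataset | None = None,
                         mask: np.ndarray | None = None) -> PredictorStack:
    """Assemble the predictor stack for one target year.

    Climate predictors are arithmetic means of their annual values over
    the ``window`` years ending at (and including) ``target_year``;
    land-use class fractions are taken from ``target_year`` only.
    """
    if registry is None:
        registry = default_registry()
    years_needed = list(range(target_year - window + 1, target_year + 1))
    if annual is None:
        if cube is None:
            raise ValueError("either cube or a precomputed annual table "
                             "must be supplied")
        t = pd.DatetimeIndex(cube.time.values)
        missing = [y for y in years_needed if (t.year == y).sum() == 0]
        if missing:
            raise ValueError(f"climatological window {years_needed[0]}-"
                             f"{target_year} not covered; missing years "
                             f"{missing}")
        annual = annual_predictors(cube, registry, years_needed)
    else:
        have = set(int(y) for y in annual.year.values)
        missing = [y for y in years_needed if y not in have]
        if missing:
            raise ValueError(f"annual predictor table missing years {missing}")

    lats = landuse.lat.values
    lons = landuse.lon.values
    grid = GridSpec(
        lon_min=float(lons[0] - (lons[1] - lons[0]) / 2),
        lon_max=float(lons[-1] + (lons[1] - lons[0]) / 2),
        lat_min=float(lats[0] - (lats[1] - lats[0]) / 2),
        lat_max=float(lats[-1] + (lats[1] - lats[0]) / 2),
        cell_size=float(lons[1] - lons[0]),
    )

    sel = annual.sel(year=years_needed)
    data_vars = {}
    for name in sel.data_vars:
        data_vars[name] = xr.DataArray(
            sel[name].mean("year").values, dims=("lat", "lon"),
            attrs={"group": "climate", "subgroup": _subgroup(name),
                   "target_year": int(target_year),
                   "window_length": int(window)})

    if target_year not in landuse.year.values:
        raise ValueError(f"land-use stack does not cover target year "
                         f"{target_year}")
    lu_year = landuse.sel(year=target_year)
    for cls in lu_year.lu_class.values:
        data_vars[str(cls)] = xr.DataArray(
            lu_year.sel(lu_class=cls).values, dims=("lat", "lon"),
            attrs={"group": "landuse", "subgroup": str(cls),
                   "target_year": int(target_year), "units": "fraction"})

    ds = xr.Dataset(data_vars, coords={"lat": lats, "lon": lons})
    return PredictorStack(grid, ds, mask=mask, target_year=int(target_year))
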