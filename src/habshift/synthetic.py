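"""Synthetic climate, land-use, and species-probability generators.

Every generator is deterministic given a master seed; independent named
substreams keep the outputs of the different generators uncorrelated.
The climate generator produces daily fields with a latitudinal mean
gradient, a sinusoidal seasonal cycle, a linear warming trend, and
AR(1) day-to-day noise; precipitation follows a seasonal wet/dry
Bernoulli-gamma model. The species map is drawn from a known logistic
suitability function (``TruthSpec``) so parameter recovery can be tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal
import xarray as xr
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from ._rng import substream
from .grid import GridSpec
from .stack import LANDUSE_CLASSES, PredictorStack

__all__ = [
    "TruthSpec",
    "Response",
    "generate_climate",
    "generate_landuse",
    "generate_sea_mask",
    "generate_species_map",
    "calibrate_intercept",
    "default_truth_spec",
    "climate_cube_from_arrays",
]

MIN_WINDOW_YEARS = 31


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float = 3.0) -> np.ndarray:
    """Standardized spatially smooth Gaussian random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    sd = f.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _ar1(rng: np.random.Generator, n_time: int, n_cells: int,
         rho: float, sigma: float) -> np.ndarray:
    """AR(1) noise along axis 0, independent across cells."""
    white = rng.standard_normal((n_time, n_cells)) * sigma * math.sqrt(1 - rho**2)
    # x_t = rho x_{t-1} + w_t  ==  IIR filter b=[1], a=[1, -rho]
    return scipy.signal.lfilter([1.0], [1.0, -rho], white, axis=0)


def generate_climate(grid: GridSpec, years: tuple[int, int],
                     trend: float = 0.3, seed: int = 0, *,
                     noise: float = 1.0,
                     min_span: int = MIN_WINDOW_YEARS) -> xr.Dataset:
    """Generate a daily climate cube over ``years`` (inclusive).

    Parameters
    ----------
    grid : GridSpec
    years : (first_year, last_year), both inclusive.
    trend : warming trend in degC per decade applied to all temperatures.
    noise : amplitude multiplier for the stochastic temperature/dewpoint
        components; 0 yields exact sinusoids.
    min_span : minimum number of calendar years required (climatological
        windows must fit downstream).

    Returns
    -------
    xr.Dataset with variables tmean/tmin/tmax (degC), precip (mm/day),
    dewpoint (degC); dims (time, lat, lon); daily calendar time.
    """
    y0, y1 = int(years[0]), int(years[1])
    n_years = y1 - y0 + 1
    if n_years < min_span:
        raise ValueError(
            f"year range {y0}:{y1} spans {n_years} years; at least "
            f"{min_span} are required for climatological windows")
    if grid.n_cells < 100:
        raise ValueError(f"grid has {grid.n_cells} cells; at least 100 required")

    time = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    nt = len(time)
    nlat, nlon = grid.shape
    n_cells = grid.n_cells

    doy = time.dayofyear.values.astype(float)
    year_frac = (time.year.values - y0) + (doy - 1) / 365.25

    lat2d, lon2d = grid.cell_centers()
    lat_rel = (lat2d - grid.lat_min) / max(grid.lat_max - grid.lat_min, 1e-9)
    lon_rel = (lon2d - grid.lon_min) / max(grid.lon_max - grid.lon_min, 1e-9)

    rng_base = substream(seed, "climate/baseline")
    # annual-mean temperature: warm south, cool north, mild smooth texture
    t_base = (24.0 - 14.0 * lat_rel + 1.5 * _smooth_field(rng_base, grid.shape))
    seas_amp = 6.0 + 6.0 * lat_rel + 0.8 * _smooth_field(rng_base, grid.shape)
    dtr = np.clip(7.0 + 3.0 * _smooth_field(rng_base, grid.shape), 2.0, 14.0)
    dew_deficit = np.clip(
        3.0 + 6.0 * (1 - lat_rel) + 1.5 * _smooth_field(rng_base, grid.shape),
        0.5, None)

    seasonal = -np.cos(2 * np.pi * (doy - 15) / 365.25)  # peak late July
    flat = lambda a: a.reshape(1, n_cells)

    tmean = (flat(t_base)
             + seasonal[:, None] * flat(seas_amp)
             + (trend / 10.0) * year_frac[:, None])
    if noise > 0:
        rng_noise = substream(seed, "climate/noise")
        tmean = tmean + noise * _ar1(rng_noise, nt, n_cells, rho=0.7, sigma=2.0)
        dew_jitter = noise * _ar1(substream(seed, "climate/dewnoise"),
                                  nt, n_cells, rho=0.6, sigma=1.0)
    else:
        dew_jitter = 0.0

    half = 0.5 * flat(dtr)
    tmax = tmean + half
    tmin = tmean - half
    dewpoint = np.minimum(tmean - flat(dew_deficit) + dew_jitter, tmean - 0.05)

    # precipitation: seasonally varying wet probability (winter-wet in the
    # south, summer-wet in the north), gamma wet-day amounts
    rng_p = substream(seed, "climate/precip")
    wet_phase = np.pi * lat_rel           # 0 = winter peak, pi = summer peak
    wet_mod = np.cos(2 * np.pi * (doy[:, None] - 15) / 365.25
                     - flat(wet_phase))   # +1 at each cell's wet season peak
    p_wet = np.clip(0.25 + 0.18 * wet_mod
                    + 0.05 * flat(_smooth_field(rng_p, grid.shape)), 0.02, 0.85)
    wet = rng_p.random((nt, n_cells)) < p_wet
    amount_scale = np.clip(6.0 + 3.0 * flat(_smooth_field(rng_p, grid.shape))
                           + 2.0 * wet_mod, 1.0, None)
    amounts = rng_p.gamma(shape=0.8, scale=amount_scale, size=(nt, n_cells))
    precip = np.where(wet, amounts, 0.0)

    def cube(a):
        a = np.broadcast_to(a, (nt, n_cells))
        return (("time", "lat", "lon"),
                np.asarray(a, dtype=np.float32).reshape(nt, nlat, nlon))

    ds = xr.Dataset(
        {
            "tmean": cube(tmean), "tmin": cube(tmin), "tmax": cube(tmax),
            "precip": cube(precip), "dewpoint": cube(dewpoint),
        },
        coords={"time": time, "lat": grid.lats, "lon": grid.lons},
        attrs={"trend_degC_per_decade": float(trend), "seed": int(seed),
               **grid.to_dict()},
    )
    ds["tmean"].attrs["units"] = "degC"
    ds["tmin"].attrs["units"] = "degC"
    ds["tmax"].attrs["units"] = "degC"
    ds["dewpoint"].attrs["units"] = "degC"
    ds["precip"].attrs["units"] = "mm/day"
    return ds


def climate_cube_from_arrays(grid: GridSpec, time: pd.DatetimeIndex,
                             **fields: np.ndarray) -> xr.Dataset:
    """Build a climate cube from explicit per-day arrays (testing helper).

    Each field may be 1-D (n_time,) — broadcast over cells — or 3-D
    (n_time, n_lat, n_lon).
    """
    nt = len(time)
    data = {}
    for name in ("tmean", "tmin", "tmax", "precip", "dewpoint"):
        if name not in fields:
            raise ValueError(f"missing field {name!r}")
        arr = np.asarray(fields[name], dtype=np.float32)
        if arr.ndim == 1:
            arr = np.broadcast_to(arr[:, None, None], (nt, *grid.shape)).copy()
        data[name] = (("time", "lat", "lon"), arr)
    return xr.Dataset(data, coords={"time": time, "lat": grid.lats,
                                    "lon": grid.lons}, attrs=grid.to_dict())


# ---------------------------------------------------------------------------
# land use
# ---------------------------------------------------------------------------

def generate_landuse(grid: GridSpec, years: tuple[int, int],
                     drift_rate: float = 0.01, seed: int = 0,
                     classes: tuple[str, ...] = LANDUSE_CLASSES) -> xr.DataArray:
    """Generate per-cell land-use class fractions for each year.

    The baseline composition is a spatially smoothed softmax field
    (Dirichlet-like); each year the composition takes a random-walk step
    in log-space whose total-variation distance from the previous year is
    capped at ``drift_rate`` per cell.

    Returns an xr.DataArray with dims (year, lu_class, lat, lon); fractions
    sum to 1 over lu_class for every cell-year.
    """
    if drift_rate < 0:
        raise ValueError("drift_rate must be non-negative")
    y0, y1 = int(years[0]), int(years[1])
    n_years = y1 - y0 + 1
    n_classes = len(classes)
    rng = substream(seed, "landuse")

    logits = np.stack([1.2 * _smooth_field(rng, grid.shape, sigma=2.5)
                       for _ in range(n_classes)])
    frac = np.exp(logits)
    frac /= frac.sum(axis=0, keepdims=True)

    out = np.empty((n_years, n_classes, *grid.shape), dtype=np.float64)
    out[0] = frac
    for t in range(1, n_years):
        if drift_rate == 0:
            out[t] = out[t - 1]
            continue
        step = np.stack([0.3 * _smooth_field(rng, grid.shape, sigma=3.0)
                         for _ in range(n_classes)])
        proposal = out[t - 1] * np.exp(step)
        proposal /= proposal.sum(axis=0, keepdims=True)
        tv = 0.5 * np.abs(proposal - out[t - 1]).sum(axis=0)  # per cell
        scale = np.where(tv > drift_rate, drift_rate / np.maximum(tv, 1e-15), 1.0)
        blended = out[t - 1] + scale[None] * (proposal - out[t - 1])
        out[t] = blended / blended.sum(axis=0, keepdims=True)

    return xr.DataArray(
        out,
        dims=("year", "lu_class", "lat", "lon"),
        coords={"year": np.arange(y0, y1 + 1), "lu_class": list(classes),
                "lat": grid.lats, "lon": grid.lons},
        name="landuse_fraction",
        attrs={"drift_rate": float(drift_rate), "seed": int(seed),
               **grid.to_dict()},
    )


def generate_sea_mask(grid: GridSpec, seed: int = 0,
                      sea_fraction: float = 0.2) -> np.ndarray:
    """Fixed random smooth blob of sea cells; True marks LAND (valid) cells."""
    if not 0.0 <= sea_fraction < 1.0:
        raise ValueError("sea_fraction must be in [0, 1)")
    rng = substream(seed, "seamask")
    f = _smooth_field(rng, grid.shape, sigma=4.0)
    thresh = np.quantile(f, sea_fraction)
    return f >= thresh


# ---------------------------------------------------------------------------
# ground-truth suitability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Response:
    """A bounded univariate response on the linear-predictor scale.

    kind 'logistic': scale * expit(slope * (x - center))
    kind 'gaussian': scale * exp(-0.5 ((x - center)/width)^2)
    """

    kind: str
    center: float
    scale: float
    slope: float = 1.0
    width: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("logistic", "gaussian"):
            raise ValueError(f"unknown response kind {self.kind!r}")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "logistic":
            return self.scale * expit(self.slope * (x - self.center))
        return self.scale * np.exp(-0.5 * ((x - self.center) / self.width) ** 2)


@dataclass
class TruthSpec:
    """Known generative suitability model: logit(p) = intercept + sum responses."""

    responses: dict[str, Response]
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if len(self.responses) < 3:
            raise ValueError("TruthSpec needs at least 3 predictors "
                             "(>=2 climate, >=1 land-use)")

    @property
    def predictor_names(self) -> list[str]:
        return list(self.responses)

    def linear_predictor(self, stack: PredictorStack) -> np.ndarray:
        eta = np.full(stack.grid.shape, self.intercept, dtype=float)
        for name, resp in self.responses.items():
            if name not in stack.data:
                raise KeyError(f"truth predictor {name!r} missing from stack")
            eta += resp(stack.array(name))
        return eta

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "responses": {
                n: {"kind": r.kind, "center": r.center, "scale": r.scale,
                    "slope": r.slope, "width": r.width}
                for n, r in self.responses.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthSpec":
        return cls(responses={n: Response(**v)
                              for n, v in d["responses"].items()},
                   intercept=float(d["intercept"]))


def default_truth_spec() -> TruthSpec:
    """Default ground truth: two climate predictors and one land-use class."""
    return TruthSpec(
        responses={
            "BIO1": Response("gaussian", center=16.0, scale=6.0, width=4.0),
            "BIO12": Response("logistic", center=500.0, scale=4.0, slope=0.01),
            "urban": Response("logistic", center=0.12, scale=-3.0, slope=25.0),
        },
        intercept=-5.0,
    )


def generate_species_map(predictors: PredictorStack, truth: TruthSpec,
                         noise_sd: float = 0.0, seed: int = 0,
                         mask: np.ndarray | None = None,
                         zero_floor: float = 0.05) -> xr.DataArray:
    """Species presence-probability map from the known suitability model.

    probability = expit(intercept + sum_p response_p(x_p) + noise); cells
    where ``mask`` (or the stack's mask) is False are set to NaN (sea).
    Probabilities below ``zero_floor`` are truncated to exactly 0,
    emulating published probability maps that report hard zeros outside
    the plausible range (needed for buffered background selection).
    """
    eta = truth.linear_predictor(predictors)
    if noise_sd > 0:
        rng = substream(seed, "speciesmap")
        eta = eta + rng.normal(0.0, noise_sd, size=eta.shape)
    prob = np.clip(expit(eta), 0.0, 1.0)
    if zero_floor > 0:
        prob = np.where(prob < zero_floor, 0.0, prob)
    use_mask = mask if mask is not None else predictors.mask
    if use_mask is not None:
        prob = np.where(use_mask, prob, np.nan)
    return xr.DataArray(prob, dims=("lat", "lon"),
                        coords={"lat": predictors.grid.lats,
                                "lon": predictors.grid.lons},
                        name="probability")


def calibrate_intercept(predictors: PredictorStack, truth: TruthSpec,
                        target_prevalence: float = 0.4,
                        tol: float = 0.01) -> TruthSpec:
    """Bisect the intercept so the fraction of cells with p >= 0.5 hits
    ``target_prevalence`` (noise-free)."""
    base = truth.linear_predictor(predictors) - truth.intercept
    mask = predictors.mask
    vals = base[mask] if mask is not None else base.ravel()

    def prevalence(b: float) -> float:
        return float(np.mean(expit(vals + b) >= 0.5))

    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if prevalence(mid) < target_prevalence:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9:
            break
    b = 0.5 * (lo + hi)
    if abs(prevalence(b) - target_prevalence) > max(tol, 0.1):
        raise RuntimeError("could not calibrate intercept to target prevalence")
    return TruthSpec(responses=dict(truth.responses), intercept=b)
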