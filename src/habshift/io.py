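"""NetCDF / CSV / YAML persistence for the pipeline's artifacts.

NetCDF files are written through xarray's scipy backend (NETCDF3) so no
optional binary backend is required; coordinates follow CF style
(lat/lon/time, cell-center registration, ascending latitude).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .grid import GridSpec
from .sampling import CalibrationSample
from .stack import PredictorStack
from .synthetic import TruthSpec

__all__ = [
    "write_dataset", "read_dataset", "write_landuse", "read_landuse",
    "write_stack", "read_stack", "write_species_map", "read_species_map",
    "write_truth", "read_truth", "write_sample", "read_sample",
    "grid_from_coords", "require_same_grid",
]

ENGINE = "scipy"


def grid_from_coords(lats: np.ndarray, lons: np.ndarray) -> GridSpec:
    """Recover a GridSpec from cell-center coordinate vectors."""
    if len(lats) < 2 or len(lons) < 2:
        raise ValueError("need at least 2 coordinates per axis")
    dlat = float(lats[1] - lats[0])
    dlon = float(lons[1] - lons[0])
    if not np.isclose(dlat, dlon):
        raise ValueError("anisotropic grids are not supported")
    return GridSpec(
        lon_min=round(float(lons[0]) - dlon / 2, 9),
        lon_max=round(float(lons[-1]) + dlon / 2, 9),
        lat_min=round(float(lats[0]) - dlat / 2, 9),
        lat_max=round(float(lats[-1]) + dlat / 2, 9),
        cell_size=round(dlon, 9),
    )


def require_same_grid(a: xr.Dataset | xr.DataArray,
                      b: xr.Dataset | xr.DataArray,
                      name_a: str = "first", name_b: str = "second") -> None:
    if (not np.allclose(a.lat.values, b.lat.values)
            or not np.allclose(a.lon.values, b.lon.values)):
        raise ValueError(f"grid mismatch between {name_a} and {name_b}")


# -- generic datasets (climate cubes etc.) ---------------------------------

def write_dataset(ds: xr.Dataset, path: str | Path) -> None:
    ds.to_netcdf(path, engine=ENGINE)


def read_dataset(path: str | Path) -> xr.Dataset:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ds = xr.open_dataset(path, engine=ENGINE).load()
    for coord in ("lat", "lon"):
        if coord not in ds.coords:
            raise ValueError(f"{path} is missing coordinate {coord!r}")
    return ds


# -- land use ---------------------------------------------------------------

def write_landuse(lu: xr.DataArray, path: str | Path) -> None:
    # NETCDF3 cannot hold variable-length string coords; keep names in attrs
    classes = [str(c) for c in lu.lu_class.values]
    ds = lu.assign_coords(lu_class=np.arange(len(classes))).to_dataset(
        name="landuse_fraction")
    ds.attrs = dict(lu.attrs)
    ds.attrs["lu_class_names"] = json.dumps(classes)
    ds.to_netcdf(path, engine=ENGINE)


def read_landuse(path: str | Path) -> xr.DataArray:
    ds = read_dataset(path)
    classes = json.loads(ds.attrs["lu_class_names"])
    lu = ds["landuse_fraction"].assign_coords(lu_class=classes)
    lu.attrs = {k: v for k, v in ds.attrs.items() if k != "lu_class_names"}
    return lu


# -- predictor stacks -------------------------------------------------------

def write_stack(stack: PredictorStack, path: str | Path) -> None:
    ds = stack.data.copy()
    if stack.mask is not None:
        ds["cell_mask"] = (("lat", "lon"), stack.mask.astype(np.int8),
                           {"group": "internal"})
    ds.attrs.update(stack.grid.to_dict())
    if stack.target_year is not None:
        ds.attrs["target_year"] = int(stack.target_year)
    ds.to_netcdf(path, engine=ENGINE)


def read_stack(path: str | Path) -> PredictorStack:
    ds = read_dataset(path)
    mask = None
    if "cell_mask" in ds:
        mask = ds["cell_mask"].values.astype(bool)
        ds = ds.drop_vars("cell_mask")
    grid = GridSpec.from_dict(dict(ds.attrs))
    target_year = ds.attrs.get("target_year")
    ds.attrs = {}
    return PredictorStack(grid, ds, mask,
                          int(target_year) if target_year is not None else None)


# -- species probability maps ----------------------------------------------

def write_species_map(prob: xr.DataArray, path: str | Path) -> None:
    prob.to_dataset(name="probability").to_netcdf(path, engine=ENGINE)


def read_species_map(path: str | Path) -> xr.DataArray:
    return read_dataset(path)["probability"]


# -- truth spec -------------------------------------------------------------

def write_truth(truth: TruthSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(truth.to_dict(), sort_keys=True))


def read_truth(path: str | Path) -> TruthSpec:
    return TruthSpec.from_dict(yaml.safe_load(Path(path).read_text()))


# -- calibration samples ----------------------------------------------------

def write_sample(sample: CalibrationSample, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    sample.table.to_csv(csv_path, index_label="cell")
    sidecar = {
        "background_method": sample.background_method,
        "seed": sample.seed,
        "n_presence": sample.n_presence,
        "n_absence": sample.n_absence,
        "predictor_names": sample.predictor_names,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_sample(csv_path: str | Path) -> CalibrationSample:
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    table = pd.read_csv(csv_path, index_col="cell")
    return CalibrationSample(table, meta["background_method"], meta["seed"],
                             meta["predictor_names"])
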