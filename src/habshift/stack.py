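"""Named predictor grids plus per-predictor metadata for one target year."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridSpec

__all__ = ["PredictorStack", "LANDUSE_CLASSES"]

#: Canonical land-use class names (14 classes present in the study domain).
LANDUSE_CLASSES = (
    "urban",
    "non_irrigated_crops",
    "irrigated_crops",
    "c3_grass",
    "c4_grass",
    "deciduous_shrubs",
    "coniferous_shrubs",
    "temperate_deciduous_trees",
    "temperate_broadleaf_evergreen_trees",
    "coniferous_trees",
    "mixed_forest",
    "wetlands",
    "bare",
    "water",
)


@dataclass
class PredictorStack:
    """Mapping predictor-name -> (lat, lon) grid, with metadata.

    Climate predictors are multi-year climatological means and carry a
    ``window_length`` attribute; land-use predictors are single-year class
    fractions. ``mask`` marks valid (non-sea) cells; ``None`` means all
    cells are valid.
    """

    grid: GridSpec
    data: xr.Dataset
    mask: np.ndarray | None = None
    target_year: int | None = None

    REQUIRED_ATTRS = ("group",)

    def __post_init__(self) -> None:
        for name, var in self.data.data_vars.items():
            if var.dims != ("lat", "lon"):
                raise ValueError(f"predictor {name!r} has dims {var.dims}, "
                                 "expected ('lat', 'lon')")
            if var.shape != self.grid.shape:
                raise ValueError(f"predictor {name!r} shape {var.shape} does "
                                 f"not match grid {self.grid.shape}")
            if "group" not in var.attrs:
                raise ValueError(f"predictor {name!r} missing 'group' attr")
        if self.mask is not None and self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")

    # -- introspection -------------------------------------------------
    @property
    def names(self) -> list[str]:
        return list(self.data.data_vars)

    def group_of(self, name: str) -> str:
        return self.data[name].attrs["group"]

    @property
    def climate_names(self) -> list[str]:
        return [n for n in self.names if self.group_of(n) == "climate"]

    @property
    def landuse_names(self) -> list[str]:
        return [n for n in self.names if self.group_of(n) == "landuse"]

    def array(self, name: str) -> np.ndarray:
        if name not in self.data:
            raise KeyError(f"predictor {name!r} not in stack "
                           f"(available: {sorted(self.names)})")
        return self.data[name].values

    # -- tabular access ------------------------------------------------
    def valid_cells(self) -> np.ndarray:
        """Flat indices (row-major over (lat, lon)) of unmasked cells."""
        if self.mask is None:
            return np.arange(self.grid.n_cells)
        return np.flatnonzero(self.mask.ravel())

    def to_frame(self, cells: np.ndarray | None = None,
                 names: list[str] | None = None) -> pd.DataFrame:
        """Predictor values at the given flat cell indices as a DataFrame."""
        if cells is None:
            cells = self.valid_cells()
        if names is None:
            names = self.names
        cols = {n: self.array(n).ravel()[cells] for n in names}
        frame = pd.DataFrame(cols, index=pd.Index(cells, name="cell"))
        lat2d, lon2d = self.grid.cell_centers()
        frame.insert(0, "lon", lon2d.ravel()[cells])
        frame.insert(0, "lat", lat2d.ravel()[cells])
        return frame

    def subset(self, names: list[str]) -> "PredictorStack":
        missing = [n for n in names if n not in self.data]
        if missing:
            raise KeyError(f"predictors not in stack: {missing}")
        return PredictorStack(self.grid, self.data[names], self.mask,
                              self.target_year)

    @classmethod
    def from_arrays(cls, grid: GridSpec,
                    arrays: dict[str, np.ndarray],
                    attrs: dict[str, dict] | None = None,
                    mask: np.ndarray | None = None,
                    target_year: int | None = None) -> "PredictorStack":
        attrs = attrs or {}
        ds = xr.Dataset(
            {name: (("lat", "lon"), np.asarray(arr, dtype=float),
                    {"group": "climate", **attrs.get(name, {})})
             for name, arr in arrays.items()},
            coords={"lat": grid.lats, "lon": grid.lons},
        )
        return cls(grid, ds, mask, target_year)
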