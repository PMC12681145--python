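"""Regular lon/lat grid geometry with cell-center registration."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec"]


def _is_multiple(span: float, step: float, tol: float = 1e-9) -> bool:
    ratio = span / step
    return abs(ratio - round(ratio)) < tol


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid.

    Cells are registered at their centers and ordered row-major with
    ascending latitude (rows) then ascending longitude (columns).
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("grid bounds must satisfy min < max")
        if not _is_multiple(self.lon_max - self.lon_min, self.cell_size):
            raise ValueError(
                f"longitude span {self.lon_max - self.lon_min} is not an "
                f"integer multiple of cell_size {self.cell_size}"
            )
        if not _is_multiple(self.lat_max - self.lat_min, self.cell_size):
            raise ValueError(
                f"latitude span {self.lat_max - self.lat_min} is not an "
                f"integer multiple of cell_size {self.cell_size}"
            )

    @property
    def n_lon(self) -> int:
        return round((self.lon_max - self.lon_min) / self.cell_size)

    @property
    def n_lat(self) -> int:
        return round((self.lat_max - self.lat_min) / self.cell_size)

    @property
    def n_cells(self) -> int:
        return self.n_lon * self.n_lat

    @property
    def shape(self) -> tuple[int, int]:
        """(n_lat, n_lon) — the shape of gridded arrays."""
        return (self.n_lat, self.n_lon)

    @property
    def lons(self) -> np.ndarray:
        """Cell-center longitudes, ascending."""
        half = self.cell_size / 2.0
        return self.lon_min + half + self.cell_size * np.arange(self.n_lon)

    @property
    def lats(self) -> np.ndarray:
        """Cell-center latitudes, ascending."""
        half = self.cell_size / 2.0
        return self.lat_min + half + self.cell_size * np.arange(self.n_lat)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Broadcast (lat2d, lon2d) arrays of shape ``self.shape``."""
        lat2d, lon2d = np.meshgrid(self.lats, self.lons, indexing="ij")
        return lat2d, lon2d

    def to_dict(self) -> dict:
        return {
            "lon_min": self.lon_min,
            "lon_max": self.lon_max,
            "lat_min": self.lat_min,
            "lat_max": self.lat_max,
            "cell_size": self.cell_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**{k: d[k] for k in
                      ("lon_min", "lon_max", "lat_min", "lat_max", "cell_size")})
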