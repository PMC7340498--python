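"""Regular longitude-latitude grids stored as plain-text tables.

All gridded quantities (true log relative-risk fields, predicted relative and
absolute risk surfaces, population rasters) share one geometry contract: a
regular lon-lat grid identified by its south-west cell centre, cell size and
shape, row-major from the south-west corner.  Surfaces are exchanged as long
CSV tables (row, col, lon, lat, value) so they remain diffable and
platform-neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class GridGeometryError(ValueError):
    """Two grids that must share a geometry do not."""


@dataclass
class Grid:
    """A regular lon-lat grid with one value per cell.

    Parameters
    ----------
    lon0, lat0
        Cell-centre coordinates of the (row 0, col 0) cell, i.e. the
        south-west corner cell.
    cell
        Cell size in degrees (square cells).
    values
        Array of shape (nrow, ncol); row 0 is the southernmost row.
    """

    lon0: float
    lat0: float
    cell: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be a 2-D array")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def nrow(self) -> int:
        return self.values.shape[0]

    @property
    def ncol(self) -> int:
        return self.values.shape[1]

    @property
    def lons(self) -> np.ndarray:
        return self.lon0 + self.cell * np.arange(self.ncol)

    @property
    def lats(self) -> np.ndarray:
        return self.lat0 + self.cell * np.arange(self.nrow)

    def same_geometry(self, other: "Grid", atol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.lon0 - other.lon0) <= atol
            and abs(self.lat0 - other.lat0) <= atol
            and abs(self.cell - other.cell) <= atol
        )

    def require_same_geometry(self, other: "Grid", what: str = "grid") -> None:
        if not self.same_geometry(other):
            raise GridGeometryError(
                f"{what} geometry mismatch: "
                f"{self.values.shape}@({self.lon0},{self.lat0},{self.cell}) vs "
                f"{other.values.shape}@({other.lon0},{other.lat0},{other.cell}); "
                "resample explicitly before combining grids"
            )

    def to_frame(self, name: str = "value") -> pd.DataFrame:
        rows, cols = np.indices(self.values.shape)
        return pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "lon": self.lon0 + self.cell * cols.ravel(),
                "lat": self.lat0 + self.cell * rows.ravel(),
                name: self.values.ravel(),
            }
        )

    def to_csv(self, path, name: str = "value") -> None:
        self.to_frame(name).to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, name: str = "value") -> "Grid":
        nrow = int(frame["row"].max()) + 1
        ncol = int(frame["col"].max()) + 1
        values = np.full((nrow, ncol), np.nan)
        values[frame["row"].to_numpy(int), frame["col"].to_numpy(int)] = frame[
            name
        ].to_numpy(float)
        sw = frame.loc[(frame["row"] == 0) & (frame["col"] == 0)].iloc[0]
        if nrow > 1:
            second = frame.loc[(frame["row"] == 1) & (frame["col"] == 0)].iloc[0]
            cell = float(second["lat"] - sw["lat"])
        elif ncol > 1:
            second = frame.loc[(frame["row"] == 0) & (frame["col"] == 1)].iloc[0]
            cell = float(second["lon"] - sw["lon"])
        else:
            cell = 1.0
        return cls(lon0=float(sw["lon"]), lat0=float(sw["lat"]), cell=cell, values=values)

    @classmethod
    def from_csv(cls, path, name: str = "value") -> "Grid":
        return cls.from_frame(pd.read_csv(path), name)

    def interpolate_to(self, lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of cell-centre values at arbitrary points.

        Points outside the grid are clamped to the nearest edge cell.
        """
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (self.lats, self.lons),
            self.values,
            bounds_error=False,
            fill_value=None,  # linear extrapolation, then clamp below
        )
        lats_c = np.clip(lats, self.lats[0], self.lats[-1])
        lons_c = np.clip(lons, self.lons[0], self.lons[-1])
        return interp(np.column_stack([lats_c, lons_c]))
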