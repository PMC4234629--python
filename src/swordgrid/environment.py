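"""Gridded environment: reference SST climatology over a Grid.

Reference SST is stored as twelve monthly fields and interpolated linearly
in time between month mid-points, which keeps the structure serializable to
NetCDF while still giving a smooth seasonal cycle for simulation.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import xarray as xr

from .grid import Grid

__all__ = ["Environment"]

_MONTH_MID_DOY = np.array(
    [15.5, 45.0, 74.5, 105.0, 135.5, 166.0, 196.5, 227.5, 258.0, 288.5, 319.0, 349.5]
)


@dataclass
class Environment:
    """Grid plus monthly reference SST fields (``(12, nlat, nlon)``, degC)."""

    grid: Grid
    sst_monthly: np.ndarray

    def __post_init__(self) -> None:
        self.sst_monthly = np.asarray(self.sst_monthly, dtype=float)
        if self.sst_monthly.shape != (12, self.grid.nlat, self.grid.nlon):
            raise ValueError("sst_monthly must have shape (12, nlat, nlon)")
        w = self.grid.water
        if not np.all(np.isfinite(self.sst_monthly[:, w])):
            raise ValueError("reference SST must be finite on water")

    def ref_sst(self, date: dt.date) -> np.ndarray:
        """Reference SST field (degC) for one calendar day."""
        doy = date.timetuple().tm_yday
        mids = _MONTH_MID_DOY
        if doy <= mids[0] or doy >= mids[-1]:
            # wrap across new year
            span = (365.0 - mids[-1]) + mids[0]
            t = ((doy - mids[-1]) % 365.0) / span
            return (1 - t) * self.sst_monthly[11] + t * self.sst_monthly[0]
        k = int(np.searchsorted(mids, doy)) - 1
        t = (doy - mids[k]) / (mids[k + 1] - mids[k])
        return (1 - t) * self.sst_monthly[k] + t * self.sst_monthly[k + 1]

    # -- serialization ------------------------------------------------------

    def to_dataset(self) -> xr.Dataset:
        g = self.grid
        return xr.Dataset(
            {
                "sst": (("month", "lat", "lon"), self.sst_monthly),
                "water": (("lat", "lon"), g.water.astype(np.int8)),
                "bathymetry": (("lat", "lon"), g.bathymetry),
            },
            coords={"month": np.arange(1, 13), "lat": g.lat, "lon": g.lon},
            attrs={"resolution_km": g.resolution_km, "planar": int(g.planar)},
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "Environment":
        grid = Grid(
            lon=ds["lon"].values,
            lat=ds["lat"].values,
            resolution_km=float(ds.attrs["resolution_km"]),
            water=ds["water"].values.astype(bool),
            bathymetry=ds["bathymetry"].values,
            planar=bool(int(ds.attrs.get("planar", 0))),
        )
        return cls(grid, ds["sst"].values)

    @classmethod
    def from_netcdf(cls, path) -> "Environment":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())
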