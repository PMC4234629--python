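"""Discretized lon/lat domain and mass-conserving advection-diffusion dynamics.

The prediction step is an explicit flux-form finite-volume update.  Every
face between two water cells carries a diffusive flux (centred) and an
optional advective flux (upwind); faces touching land or the domain edge
carry exactly zero flux, so probability mass can never leak onto land or out
of the domain.  Sub-stepping keeps the explicit scheme stable and
nonnegative.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["KM_PER_DEG", "Grid", "ProbField", "MovementParams", "build_grid",
           "delta_field", "predict_step"]

#: kilometres per degree of a great circle (mean Earth radius)
KM_PER_DEG = 111.195


@dataclass
class Grid:
    """Regular lon/lat grid with land mask and bathymetry.

    ``water`` and ``bathymetry`` have shape ``(nlat, nlon)``; bathymetry is
    metres, positive down, and is zero on land.  Cell widths in km scale with
    cos(latitude) per row unless ``planar`` is set (useful for idealized
    test basins where exact symmetry is wanted).
    """

    lon: np.ndarray
    lat: np.ndarray
    resolution_km: float
    water: np.ndarray
    bathymetry: np.ndarray
    planar: bool = False

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.water = np.asarray(self.water, dtype=bool)
        self.bathymetry = np.asarray(self.bathymetry, dtype=float)
        if self.resolution_km <= 0:
            raise ValueError("resolution_km must be > 0")
        if self.water.shape != (self.nlat, self.nlon):
            raise ValueError("water mask shape does not match grid")
        if self.bathymetry.shape != self.water.shape:
            raise ValueError("bathymetry shape does not match grid")
        if not self.water.any():
            raise ValueError("grid has no water cells")
        if np.any(self.bathymetry[self.water] < 0):
            raise ValueError("bathymetry must be >= 0 on water")
        self.dlon = float(self.lon[1] - self.lon[0]) if self.nlon > 1 else self.resolution_km / KM_PER_DEG
        self.dlat = float(self.lat[1] - self.lat[0]) if self.nlat > 1 else self.resolution_km / KM_PER_DEG
        self.dy_km = self.dlat * KM_PER_DEG
        if self.planar:
            self.dx_km = np.full(self.nlat, self.dlon * KM_PER_DEG)
        else:
            self.dx_km = self.dlon * KM_PER_DEG * np.cos(np.deg2rad(self.lat))
        self.cell_area_km2 = self.dx_km[:, None] * self.dy_km * np.ones((1, self.nlon))

    @property
    def nlon(self) -> int:
        return self.lon.size

    @property
    def nlat(self) -> int:
        return self.lat.size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    @property
    def n_water(self) -> int:
        return int(self.water.sum())

    @classmethod
    def regular(
        cls,
        bbox: tuple[float, float, float, float],
        resolution_km: float,
        water: Optional[np.ndarray] = None,
        bathymetry: Optional[np.ndarray] = None,
        planar: bool = False,
    ) -> "Grid":
        """Build a grid covering ``bbox = (lon_min, lat_min, lon_max, lat_max)``.

        Cell spacing is ``resolution_km`` converted to degrees of latitude,
        used for both axes (so a 111.195-km resolution gives 1-degree cells).
        Defaults to all-water, flat 4000-m bathymetry.
        """
        lon_min, lat_min, lon_max, lat_max = bbox
        if lon_max <= lon_min or lat_max <= lat_min:
            raise ValueError("invalid bbox")
        step = resolution_km / KM_PER_DEG
        nlon = max(1, int(round((lon_max - lon_min) / step)))
        nlat = max(1, int(round((lat_max - lat_min) / step)))
        lon = lon_min + (np.arange(nlon) + 0.5) * step
        lat = lat_min + (np.arange(nlat) + 0.5) * step
        if water is None:
            water = np.ones((nlat, nlon), dtype=bool)
        if bathymetry is None:
            bathymetry = np.where(water, 4000.0, 0.0)
        return cls(lon, lat, resolution_km, water, bathymetry, planar=planar)

    # -- coordinate helpers -------------------------------------------------

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Index (iy, ix) of the cell containing a point (half-open cells)."""
        ix = int(math.floor((lon - (self.lon[0] - self.dlon / 2.0)) / self.dlon))
        iy = int(math.floor((lat - (self.lat[0] - self.dlat / 2.0)) / self.dlat))
        if not (0 <= ix < self.nlon and 0 <= iy < self.nlat):
            raise ValueError(f"point ({lon}, {lat}) outside grid")
        return iy, ix

    def contains(self, lon: float, lat: float) -> bool:
        try:
            self.cell_of(lon, lat)
            return True
        except ValueError:
            return False

    def is_water(self, lon: float, lat: float) -> bool:
        iy, ix = self.cell_of(lon, lat)
        return bool(self.water[iy, ix])


def build_grid(
    bbox: tuple[float, float, float, float],
    resolution_km: float,
    landmask_raster,
    bathymetry_raster,
    planar: bool = False,
) -> Grid:
    """Resample land-mask / bathymetry rasters onto a new grid.

    Rasters are ``xarray.DataArray`` objects with ``lon``/``lat`` coordinates
    covering ``bbox``; the mask uses nearest-neighbour sampling (truthy =
    water) and bathymetry bilinear interpolation.
    """
    g = Grid.regular(bbox, resolution_km, planar=planar)
    lon = g.lon
    lat = g.lat
    wm = landmask_raster.interp(lon=lon, lat=lat, method="nearest")
    water = np.asarray(wm.values, dtype=float) > 0.5
    if not water.any():
        raise ValueError("resampled domain contains no water cells")
    bat = bathymetry_raster.interp(lon=lon, lat=lat, method="linear")
    bathy = np.nan_to_num(np.asarray(bat.values, dtype=float), nan=0.0)
    bathy = np.where(water, np.maximum(bathy, 0.0), 0.0)
    return Grid(lon, lat, resolution_km, water, bathy, planar=planar)


@dataclass
class ProbField:
    """Nonnegative cell probabilities on a grid, summing to one over water."""

    grid: Grid
    values: np.ndarray
    date: Optional[dt.date] = None
    snapped: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("field shape does not match grid")

    def normalize(self) -> "ProbField":
        s = self.values.sum()
        if s <= 0:
            raise ValueError("cannot normalize a zero field")
        self.values = self.values / s
        return self

    def total(self) -> float:
        return float(self.values.sum())

    def mode_cell(self) -> tuple[int, int]:
        iy, ix = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return int(iy), int(ix)

    def copy(self) -> "ProbField":
        return ProbField(self.grid, self.values.copy(), self.date, self.snapped)

    @classmethod
    def uniform_water(cls, grid: Grid, date: Optional[dt.date] = None) -> "ProbField":
        v = grid.water.astype(float)
        return cls(grid, v / v.sum(), date)


def delta_field(grid: Grid, lon: float, lat: float, date: Optional[dt.date] = None,
                snap_cells: int = 2) -> ProbField:
    """All probability mass in the cell containing (lon, lat).

    A point falling on a land cell is snapped to the nearest water cell
    within a Chebyshev radius of ``snap_cells`` (flagged via ``snapped``);
    beyond that it is an error.
    """
    iy, ix = grid.cell_of(lon, lat)
    snapped = False
    if not grid.water[iy, ix]:
        best = None
        for dy in range(-snap_cells, snap_cells + 1):
            for dx in range(-snap_cells, snap_cells + 1):
                jy, jx = iy + dy, ix + dx
                if 0 <= jy < grid.nlat and 0 <= jx < grid.nlon and grid.water[jy, jx]:
                    d2 = dy * dy + dx * dx
                    if best is None or d2 < best[0]:
                        best = (d2, jy, jx)
        if best is None:
            raise ValueError(f"point ({lon}, {lat}) is on land with no nearby water cell")
        _, iy, ix = best
        snapped = True
    v = np.zeros(grid.shape)
    v[iy, ix] = 1.0
    return ProbField(grid, v, date, snapped=snapped)


@dataclass
class MovementParams:
    """Advection-diffusion parameters for one daily prediction step.

    ``D`` is horizontal diffusivity in km^2/day; optional cell-centred
    velocities ``u`` (east, km/day) and ``v`` (north, km/day).  The number of
    explicit sub-steps is derived automatically from the stability bound.
    """

    D: float
    dt: float = 1.0
    u: Optional[np.ndarray] = None
    v: Optional[np.ndarray] = None
    safety: float = 0.9

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    def n_substeps(self, grid: Grid) -> int:
        dx_min = float(np.min(grid.dx_km))
        dy = grid.dy_km
        limits = []
        if self.D > 0:
            limits.append(0.5 / (self.D * (1.0 / dx_min**2 + 1.0 / dy**2)))
        vmax = 0.0
        if self.u is not None:
            vmax = max(vmax, float(np.max(np.abs(self.u))))
        if self.v is not None:
            vmax = max(vmax, float(np.max(np.abs(self.v))))
        if vmax > 0:
            limits.append(min(dx_min, dy) / vmax)
        if not limits:
            return 1
        dt_sub = self.safety * min(limits)
        return max(1, int(math.ceil(self.dt / dt_sub)))


def _face_masks(grid: Grid):
    w = grid.water
    open_x = w[:, :-1] & w[:, 1:]
    open_y = w[:-1, :] & w[1:, :]
    return open_x, open_y


def _step_once(p: np.ndarray, grid: Grid, D: float, dt: float,
               u: Optional[np.ndarray], v: Optional[np.ndarray],
               open_x: np.ndarray, open_y: np.ndarray) -> np.ndarray:
    A = grid.cell_area_km2
    c = p / A
    dx = grid.dx_km[:, None]
    dy = grid.dy_km
    out = p.copy()

    if D > 0:
        # diffusive mass through x-faces: D*dt*(face length dy)/(spacing dx)*dC
        kx = (D * dt * dy / dx) * open_x
        fx = kx * (c[:, 1:] - c[:, :-1])
        out[:, :-1] += fx
        out[:, 1:] -= fx
        # y-faces: face length is mean of the adjoining rows' dx
        Lx = 0.5 * (grid.dx_km[:-1] + grid.dx_km[1:])[:, None]
        ky = (D * dt * Lx / dy) * open_y
        fy = ky * (c[1:, :] - c[:-1, :])
        out[:-1, :] += fy
        out[1:, :] -= fy

    if u is not None:
        uf = 0.5 * (u[:, :-1] + u[:, 1:]) * open_x
        cup = np.where(uf > 0, c[:, :-1], c[:, 1:])
        fx = dt * dy * uf * cup  # mass per face, positive eastward
        out[:, :-1] -= fx
        out[:, 1:] += fx
    if v is not None:
        Lx = 0.5 * (grid.dx_km[:-1] + grid.dx_km[1:])[:, None]
        vf = 0.5 * (v[:-1, :] + v[1:, :]) * open_y
        cup = np.where(vf > 0, c[:-1, :], c[1:, :])
        fy = dt * Lx * vf * cup
        out[:-1, :] -= fy
        out[1:, :] += fy
    return out


def predict_step(p: ProbField, mp: MovementParams, adjoint: bool = False) -> ProbField:
    """One daily advection-diffusion prediction step with zero-flux boundaries.

    With ``adjoint=True`` the transpose of the forward linear operator is
    applied (used by the backward information filter).  The flux operator is
    self-adjoint under the cell-area inner product, so the exact transpose is
    ``(1/A) * M(A * x)`` with advective velocities negated.
    """
    grid = p.grid
    if mp.D == 0 and mp.u is None and mp.v is None:
        return p.copy()
    n = mp.n_substeps(grid)
    dt_sub = mp.dt / n
    open_x, open_y = _face_masks(grid)
    u, v = mp.u, mp.v
    if adjoint:
        u = -u if u is not None else None
        v = -v if v is not None else None
    A = grid.cell_area_km2
    vals = p.values
    if adjoint:
        # K^T v = (1/A) K (A v): the face-symmetric flux coefficients make the
        # operator self-adjoint under the cell-area inner product.
        vals = vals * A
    out = vals.copy()
    for _ in range(n):
        out = _step_once(out, grid, mp.D, dt_sub, u, v, open_x, open_y)
    if adjoint:
        out = out / A
    return ProbField(grid, out, p.date)
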