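"""Utilization distributions: pooling, HPD regions, point coverage.

Smoothed daily posteriors are pooled (equal weight per fish-day) into a
normalized occupancy surface per stratum (calendar quarter x maturity
class).  Highest-density regions are cumulative-mass prefixes of cells
ranked by density, which guarantees nestedness across levels.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .grid import Grid
from .hmm import SmoothedTrack
from .preprocess import Deployment

__all__ = [
    "MATURITY_LJFL_CM",
    "Stratum",
    "UD",
    "HPDRegions",
    "classify_maturity",
    "quarter_of",
    "pool_ud",
    "hpd_regions",
    "point_coverage",
]

#: lower-jaw fork length threshold (cm): mature iff LJFL >= this
MATURITY_LJFL_CM = 179.0

QUARTERS = ("Q1", "Q2", "Q3", "Q4")


def classify_maturity(ljfl_cm: float) -> str:
    """Maturity class from lower-jaw fork length (mature iff >= 179 cm)."""
    if not (ljfl_cm > 0):
        raise ValueError(f"LJFL must be positive, got {ljfl_cm}")
    return "mature" if ljfl_cm >= MATURITY_LJFL_CM else "immature"


def quarter_of(date: dt.date) -> str:
    return QUARTERS[(date.month - 1) // 3]


@dataclass(frozen=True)
class Stratum:
    """Pooling stratum: calendar quarter and maturity class ('all' pools)."""

    quarter: str = "all"
    maturity: str = "all"

    def __post_init__(self) -> None:
        if self.quarter not in QUARTERS + ("all",):
            raise ValueError(f"unknown quarter {self.quarter!r}")
        if self.maturity not in ("immature", "mature", "all"):
            raise ValueError(f"unknown maturity class {self.maturity!r}")

    def matches(self, date: dt.date, ljfl_cm: float) -> bool:
        if self.quarter != "all" and quarter_of(date) != self.quarter:
            return False
        if self.maturity != "all" and classify_maturity(ljfl_cm) != self.maturity:
            return False
        return True


@dataclass
class UD:
    """Pooled, normalized occupancy surface for one stratum."""

    grid: Grid
    values: np.ndarray
    stratum: Stratum
    n_fish_days: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("UD shape does not match grid")


@dataclass
class HPDRegions:
    """Nested boolean highest-density masks keyed by mass level."""

    grid: Grid
    levels: tuple[float, ...]
    masks: dict

    def mask(self, level: float) -> np.ndarray:
        return self.masks[level]

    def area_km2(self, level: float) -> float:
        return float(self.grid.cell_area_km2[self.masks[level]].sum())


def pool_ud(
    tracks: Iterable[tuple[SmoothedTrack, Deployment]],
    stratum: Stratum = Stratum(),
) -> UD:
    """Mean of all daily smoothed fields matching the stratum, renormalized.

    Each fish-day contributes equal weight.  Raises if the stratum is empty.
    """
    acc: Optional[np.ndarray] = None
    grid: Optional[Grid] = None
    n = 0
    for track, dep in tracks:
        grid = track.grid if grid is None else grid
        if track.grid is not grid and track.grid.shape != grid.shape:
            raise ValueError("all tracks must share one grid")
        for i, date in enumerate(track.dates):
            if not stratum.matches(date, dep.ljfl_cm):
                continue
            acc = track.fields[i].copy() if acc is None else acc + track.fields[i]
            n += 1
    if acc is None or n == 0 or grid is None:
        raise ValueError(
            f"no fish-days in stratum quarter={stratum.quarter} maturity={stratum.maturity}"
        )
    acc = acc / acc.sum()
    acc[~grid.water] = 0.0
    s = acc.sum()
    if s <= 0:
        raise ValueError("pooled UD has no mass on water")
    return UD(grid, acc / s, stratum, n)


def hpd_regions(ud: UD, levels: Sequence[float] = (0.5, 0.75, 0.95)) -> HPDRegions:
    """Smallest cell sets (densest first) capturing each mass level.

    Cells are ranked by density descending with index order breaking ties,
    so regions are deterministic and nested across levels.
    """
    levels = tuple(sorted(float(lv) for lv in levels))
    if any(not (0 < lv < 1) for lv in levels):
        raise ValueError("levels must lie in (0, 1)")
    flat = ud.values.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))
    csum = np.cumsum(flat[order])
    total = csum[-1]
    masks = {}
    for lv in levels:
        # relative slack absorbs cumsum rounding so exact-tie prefixes are minimal
        k = int(np.searchsorted(csum, lv * total * (1.0 - 1e-9))) + 1
        m = np.zeros(flat.size, dtype=bool)
        m[order[:min(k, flat.size)]] = True
        masks[lv] = m.reshape(ud.values.shape)
    return HPDRegions(ud.grid, levels, masks)


def point_coverage(
    points: pd.DataFrame,
    regions_by_quarter: dict,
    level: float = 0.95,
) -> tuple[float, pd.DataFrame]:
    """Fraction of points falling inside their quarter's HPD region.

    ``points`` has columns lon, lat, date.  Points off the grid (or in a
    quarter with no region) are excluded from the fraction and reported in
    the per-quarter table.
    """
    rows = {q: {"n": 0, "covered": 0, "off_grid": 0} for q in QUARTERS}
    for _, row in points.iterrows():
        date = pd.Timestamp(row["date"]).date()
        q = quarter_of(date)
        regions = regions_by_quarter.get(q)
        if regions is None:
            rows[q]["off_grid"] += 1
            continue
        grid = regions.grid
        try:
            iy, ix = grid.cell_of(float(row["lon"]), float(row["lat"]))
        except ValueError:
            rows[q]["off_grid"] += 1
            continue
        if not grid.water[iy, ix]:
            rows[q]["off_grid"] += 1
            continue
        rows[q]["n"] += 1
        if regions.mask(level)[iy, ix]:
            rows[q]["covered"] += 1
    table = pd.DataFrame(
        [
            {
                "quarter": q,
                "n": v["n"],
                "covered": v["covered"],
                "off_grid": v["off_grid"],
                "fraction": (v["covered"] / v["n"]) if v["n"] else np.nan,
            }
            for q, v in rows.items()
        ]
    )
    n_tot = int(table["n"].sum())
    frac = float(table["covered"].sum() / n_tot) if n_tot else float("nan")
    return frac, table
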