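"""Tag preprocessing: daily records and set-membership feasibility cleaning.

Raw sensor series (timestamp, depth, temperature) are reduced to one record
per day: a daily SST estimate (median temperature in the top 15 m, when
visited), the maximum measured depth, and any externally supplied
sunrise/sunset times.  Daily feasible position sets are then propagated from
both tag endpoints under speed, land, SST and depth constraints, and event
times inconsistent with their day's feasible set are discarded.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from . import solar
from .environment import Environment
from .grid import Grid

__all__ = [
    "SST_LAYER_MAX_DEPTH_M",
    "DailyRecord",
    "Deployment",
    "FeasibleSet",
    "daily_sst_estimate",
    "daily_max_depth",
    "build_daily_records",
    "propagate_feasible_sets",
    "screen_event_times",
]

#: depth (m) bounding the near-surface layer used for the daily SST estimate
SST_LAYER_MAX_DEPTH_M = 15.0


@dataclass
class DailyRecord:
    """One tag-day of observations; absent fields are ``None``."""

    date: dt.date
    sst: Optional[float] = None
    sunrise_ut: Optional[float] = None
    sunset_ut: Optional[float] = None
    max_depth: float = 0.0
    flags: dict = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return self.sst is None and self.sunrise_ut is None and self.sunset_ut is None


@dataclass
class Deployment:
    tag_id: str
    release_date: dt.date
    release_lon: float
    release_lat: float
    popup_date: dt.date
    popup_lon: float
    popup_lat: float
    ljfl_cm: float = float("nan")
    agency: str = ""

    def __post_init__(self) -> None:
        if self.popup_date <= self.release_date:
            raise ValueError(f"tag {self.tag_id}: popup date must follow release date")

    @property
    def n_days(self) -> int:
        return (self.popup_date - self.release_date).days + 1

    @property
    def duration_days(self) -> int:
        return (self.popup_date - self.release_date).days

    def dates(self) -> list[dt.date]:
        return [self.release_date + dt.timedelta(days=i) for i in range(self.n_days)]


@dataclass
class FeasibleSet:
    """Boolean per-cell mask of positions consistent with the day's constraints."""

    date: dt.date
    mask: np.ndarray
    relaxed: bool = False

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())


def _day_samples(series: pd.DataFrame, date: dt.date) -> pd.DataFrame:
    ts = pd.to_datetime(series["timestamp"], utc=True)
    return series.loc[ts.dt.date == date]


def daily_sst_estimate(series: pd.DataFrame, date: dt.date) -> Optional[float]:
    """Median temperature measured at <= 15 m depth that day, if any."""
    day = _day_samples(series, date)
    layer = day.loc[(day["depth_m"] >= 0) & (day["depth_m"] <= SST_LAYER_MAX_DEPTH_M)]
    if layer.empty:
        return None
    return float(layer["temp_c"].median())


def daily_max_depth(series: pd.DataFrame, date: dt.date) -> float:
    """Maximum valid (nonnegative) depth that day; 0 when no samples."""
    day = _day_samples(series, date)
    valid = day.loc[day["depth_m"] >= 0, "depth_m"]
    if valid.empty:
        return 0.0
    return float(valid.max())


def build_daily_records(
    series: pd.DataFrame,
    dep: Deployment,
    events: Optional[pd.DataFrame] = None,
) -> list[DailyRecord]:
    """One DailyRecord per deployment day.

    ``series`` has columns timestamp, depth_m, temp_c.  ``events`` optionally
    supplies externally derived sunrise/sunset times (columns date,
    sunrise_ut, sunset_ut; NaN = absent).  Days without any sensor samples
    get an all-absent record flagged ``no_samples`` (pure prediction days
    downstream).
    """
    series = series.copy()
    ts = pd.to_datetime(series["timestamp"], utc=True)
    series["_date"] = ts.dt.date
    n_neg = int((series["depth_m"] < 0).sum())

    ev_by_date: dict[dt.date, tuple[Optional[float], Optional[float]]] = {}
    if events is not None and not events.empty:
        for _, row in events.iterrows():
            d = pd.Timestamp(row["date"]).date()
            sr = row.get("sunrise_ut")
            ss = row.get("sunset_ut")
            ev_by_date[d] = (
                float(sr) if sr is not None and np.isfinite(sr) else None,
                float(ss) if ss is not None and np.isfinite(ss) else None,
            )

    records = []
    grouped = {d: g for d, g in series.groupby("_date")}
    for date in dep.dates():
        day = grouped.get(date)
        flags: dict = {}
        if day is None or day.empty:
            flags["no_samples"] = True
            sst, maxd = None, 0.0
        else:
            if (day["depth_m"] < 0).any():
                flags["negative_depth_samples"] = int((day["depth_m"] < 0).sum())
            layer = day.loc[(day["depth_m"] >= 0) & (day["depth_m"] <= SST_LAYER_MAX_DEPTH_M)]
            sst = float(layer["temp_c"].median()) if not layer.empty else None
            valid = day.loc[day["depth_m"] >= 0, "depth_m"]
            maxd = float(valid.max()) if not valid.empty else 0.0
        sr, ss = ev_by_date.get(date, (None, None))
        records.append(
            DailyRecord(date=date, sst=sst, sunrise_ut=sr, sunset_ut=ss,
                        max_depth=maxd, flags=flags)
        )
    if n_neg:
        records[0].flags.setdefault("series_negative_depth_total", n_neg)
    return records


_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-neighbour dilation structure


def _dilate(mask: np.ndarray, water: np.ndarray, n_iter: int) -> np.ndarray:
    if n_iter <= 0:
        return mask & water
    return ndimage.binary_dilation(mask, structure=_STRUCT8, iterations=n_iter, mask=water)


def _day_constraints(
    rec: Optional[DailyRecord],
    env: Environment,
    k_sst: float,
    sigma_sst: float,
) -> np.ndarray:
    """Water cells passing the day's SST and max-depth gates."""
    grid = env.grid
    ok = grid.water.copy()
    if rec is None:
        return ok
    if rec.max_depth > 0:
        ok &= grid.bathymetry >= rec.max_depth
    if rec.sst is not None:
        ref = env.ref_sst(rec.date)
        with np.errstate(invalid="ignore"):
            ok &= np.abs(ref - rec.sst) <= k_sst * sigma_sst
    return ok


def _one_way_pass(
    start_field: np.ndarray,
    dates: list[dt.date],
    rec_by_date: dict,
    env: Environment,
    n_dilate: int,
    k_sst: float,
    sigma_sst: float,
) -> tuple[list[np.ndarray], list[bool]]:
    grid = env.grid
    masks, relaxed = [], []
    cur = start_field & grid.water
    for i, date in enumerate(dates):
        if i > 0:
            cur = _dilate(cur, grid.water, n_dilate)
        gate = _day_constraints(rec_by_date.get(date), env, k_sst, sigma_sst)
        nxt = cur & gate
        if not nxt.any():
            nxt = cur.copy()  # keep speed+land; drop SST/depth for the day
            relaxed.append(True)
        else:
            relaxed.append(False)
        masks.append(nxt)
        cur = nxt
    return masks, relaxed


def propagate_feasible_sets(
    dep: Deployment,
    records: Iterable[DailyRecord],
    env: Environment,
    vmax_km_day: float = 150.0,
    k_sst: float = 3.0,
    sigma_sst: float = 1.0,
) -> list[FeasibleSet]:
    """Daily feasible position sets from a forward and a backward pass.

    Day ``t``'s set is the dilation of day ``t-1``'s by the daily speed
    limit, restricted to water, to cells deep enough for the day's maximum
    depth, and to cells whose reference SST matches the day's SST estimate
    within ``k_sst * sigma_sst``; the final set is the intersection of the
    pass from the release position with the reversed pass from the pop-up
    position.  When a day's gates would empty the set, SST/depth are dropped
    for that day (speed and land are never relaxed) and the day is flagged.
    """
    if vmax_km_day <= 0:
        raise ValueError("vmax_km_day must be > 0")
    grid = env.grid
    riy, rix = grid.cell_of(dep.release_lon, dep.release_lat)
    piy, pix = grid.cell_of(dep.popup_lon, dep.popup_lat)
    if not grid.water[riy, rix]:
        raise ValueError(f"tag {dep.tag_id}: release position is on land")
    if not grid.water[piy, pix]:
        raise ValueError(f"tag {dep.tag_id}: pop-up position is on land")

    dates = dep.dates()
    rec_by_date = {r.date: r for r in records}
    min_cell = min(float(np.min(grid.dx_km)), grid.dy_km)
    n_dilate = max(1, int(np.ceil(vmax_km_day / min_cell)))

    start_f = np.zeros(grid.shape, dtype=bool)
    start_f[riy, rix] = True
    start_b = np.zeros(grid.shape, dtype=bool)
    start_b[piy, pix] = True

    fwd, rel_f = _one_way_pass(start_f, dates, rec_by_date, env, n_dilate, k_sst, sigma_sst)
    bwd_rev, rel_b_rev = _one_way_pass(
        start_b, dates[::-1], rec_by_date, env, n_dilate, k_sst, sigma_sst
    )
    bwd = bwd_rev[::-1]
    rel_b = rel_b_rev[::-1]

    out = []
    for i, date in enumerate(dates):
        mask = fwd[i] & bwd[i]
        relaxed = rel_f[i] or rel_b[i]
        if not mask.any():
            # fall back to speed+land reachability from both endpoints
            f = _dilate(start_f, grid.water, n_dilate * i) if i else (start_f & grid.water)
            b = (
                _dilate(start_b, grid.water, n_dilate * (len(dates) - 1 - i))
                if i < len(dates) - 1
                else (start_b & grid.water)
            )
            mask = f & b
            relaxed = True
            if not mask.any():
                raise ValueError(
                    f"tag {dep.tag_id}: endpoints not mutually reachable at "
                    f"vmax={vmax_km_day} km/day (day {date})"
                )
        out.append(FeasibleSet(date=date, mask=mask, relaxed=relaxed))
    return out


def screen_event_times(
    records: list[DailyRecord],
    fsets: list[FeasibleSet],
    grid: Grid,
    h0: float = solar.DEFAULT_TWILIGHT_DEG,
    sigma_min: float = 20.0,
    k_reject: float = 3.0,
) -> tuple[list[DailyRecord], pd.DataFrame]:
    """Discard event times incompatible with the day's feasible set.

    For each observed sunrise/sunset, the predicted time is evaluated over
    every feasible cell; the observation is kept iff its minimal circular
    distance to those predicted times is within ``k_reject * sigma_min``.
    Returns cleaned copies of the records plus a per-observation report.
    """
    fs_by_date = {f.date: f for f in fsets}
    rows = []
    cleaned: list[DailyRecord] = []
    for rec in records:
        new = DailyRecord(rec.date, rec.sst, rec.sunrise_ut, rec.sunset_ut,
                          rec.max_depth, dict(rec.flags))
        fs = fs_by_date.get(rec.date)
        for kind in ("sunrise", "sunset"):
            obs = getattr(rec, f"{kind}_ut")
            if obs is None:
                continue
            if fs is None or not fs.mask.any():
                rows.append((rec.date, kind, obs, np.nan, True, "no_feasible_set"))
                continue
            iy, ix = np.nonzero(fs.mask)
            glat = grid.lat[iy]
            glon = grid.lon[ix]
            et = solar.predict_event_times(glon, glat, rec.date, h0=h0)
            pred = et.sunrise_ut if kind == "sunrise" else et.sunset_ut
            pred = np.atleast_1d(np.asarray(pred, dtype=float))
            pred = pred[np.isfinite(pred)]
            if pred.size == 0:
                rows.append((rec.date, kind, obs, np.nan, True, "polar_feasible_set"))
                continue
            dist = float(np.min(np.abs(solar.circular_residual_minutes(obs, pred))))
            keep = dist <= k_reject * sigma_min
            reason = "ok" if keep else "outside_feasible_interval"
            rows.append((rec.date, kind, obs, dist, keep, reason))
            if not keep:
                setattr(new, f"{kind}_ut", None)
                new.flags[f"{kind}_rejected"] = True
        cleaned.append(new)
    report = pd.DataFrame(
        rows, columns=["date", "event", "obs_min", "dist_min", "keep", "reason"]
    )
    return cleaned, report
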