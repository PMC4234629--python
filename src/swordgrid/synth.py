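"""Synthetic ocean, tracks and tag records for end-to-end testing.

The generated world mirrors the observation regime of sparse archival-tag
data: roughly 7% of days carry sunrise/sunset times and 41% carry an SST
estimate, with Gaussian noise of 20 min and 1 degC respectively.  Tracks are
simulated under the same diffusive movement model the filter assumes
(reflected random walk, per-day step variance 2 D per axis).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from . import solar
from .environment import Environment
from .grid import KM_PER_DEG, Grid, MovementParams
from .hmm import ObservationParams, smooth_deployment
from .preprocess import DailyRecord, Deployment

__all__ = ["SimConfig", "make_environment", "simulate_track",
           "simulate_tag_records", "calibration_experiment", "records_to_frames"]


@dataclass
class SimConfig:
    """Simulation parameters; the seed fixes all randomness."""

    D_true: float = 300.0
    n_days: int = 60
    start_lon: float = -55.0
    start_lat: float = 32.0
    p_event_day: float = 0.07
    p_sst_day: float = 0.41
    sigma_sst: float = 1.0
    sigma_event: float = 20.0
    h0: float = solar.DEFAULT_TWILIGHT_DEG
    start_date: dt.date = dt.date(2008, 6, 1)
    drift_u: float = 0.0  # km/day east
    drift_v: float = 0.0  # km/day north
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_event_day, self.p_sst_day):
            if not (0.0 <= p <= 1.0):
                raise ValueError("sparsity probabilities must be in [0, 1]")
        if self.D_true < 0:
            raise ValueError("D_true must be >= 0")


def make_environment(
    bbox: tuple[float, float, float, float] = (-65.0, 22.0, -45.0, 42.0),
    resolution_km: float = 50.0,
    seed: int = 0,
    land_fraction: float = 0.18,
    planar: bool = False,
) -> Environment:
    """Synthetic ocean: western coastline, shelf bathymetry, seasonal SST.

    SST is a latitudinal gradient plus a sinusoidal seasonal cycle and
    smooth, seed-fixed spatial noise, spanning roughly 5-30 degC over a
    subtropical-to-temperate domain.
    """
    lon_min, lat_min, lon_max, lat_max = bbox
    grid0 = Grid.regular(bbox, resolution_km, planar=planar)
    nlat, nlon = grid0.shape
    rng = np.random.default_rng(seed)

    # wiggly western landmass occupying ~land_fraction of the domain width
    lat2d = np.repeat(grid0.lat[:, None], nlon, axis=1)
    lon2d = np.repeat(grid0.lon[None, :], nlat, axis=0)
    coast = lon_min + land_fraction * (lon_max - lon_min) * (
        1.0 + 0.35 * np.sin(2.0 * np.pi * (lat2d - lat_min) / (lat_max - lat_min) * 1.5)
    )
    water = lon2d >= coast

    # bathymetry: shallow shelf near the coast deepening offshore
    dist_cells = ndimage.distance_transform_edt(water)
    dist_km = dist_cells * resolution_km
    bathy = np.where(water, np.minimum(60.0 + 2.2 * dist_km, 5200.0), 0.0)

    grid = Grid(grid0.lon, grid0.lat, resolution_km, water, bathy, planar=planar)

    # static smooth spatial noise, shared by all months
    noise = ndimage.gaussian_filter(rng.standard_normal((nlat, nlon)), sigma=3.0)
    noise = noise / max(noise.std(), 1e-12) * 0.5

    lat_mid = 0.5 * (lat_min + lat_max)
    months = np.arange(12)
    phase = 2.0 * np.pi * (months + 0.5 - 7.0) / 12.0  # warmest near end of July
    sst = np.empty((12, nlat, nlon))
    for m in months:
        sst[m] = (
            18.0
            - 0.70 * (lat2d - lat_mid)
            + 3.0 * np.cos(phase[m])
            + noise
        )
    sst = np.clip(sst, 3.5, 31.5)
    return Environment(grid, sst)


def _drift(cfg: SimConfig, date: dt.date) -> tuple[float, float]:
    return cfg.drift_u, cfg.drift_v


def simulate_track(
    env: Environment,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    drift_fn: Optional[Callable[[dt.date], tuple[float, float]]] = None,
) -> pd.DataFrame:
    """Daily true positions as a reflected random walk in open water.

    Each day's displacement is Gaussian with variance ``2 * D_true`` per
    axis (km) plus optional drift; steps that would land on land or leave
    the domain are reflected about the current position, and dropped if the
    reflection is also infeasible.
    """
    grid = env.grid
    if not grid.is_water(cfg.start_lon, cfg.start_lat):
        raise ValueError("track start position is on land")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    step_sd = float(np.sqrt(2.0 * cfg.D_true))
    lon, lat = float(cfg.start_lon), float(cfg.start_lat)
    rows = []
    for i in range(cfg.n_days):
        date = cfg.start_date + dt.timedelta(days=i)
        rows.append({"date": date, "lon": lon, "lat": lat})
        if i == cfg.n_days - 1:
            break
        du, dv = drift_fn(date) if drift_fn else _drift(cfg, date)
        dx_km = rng.normal(du, step_sd)
        dy_km = rng.normal(dv, step_sd)
        placed = False
        for sx, sy in ((1, 1), (-1, 1), (1, -1), (-1, -1)):
            cand_lat = lat + sy * dy_km / KM_PER_DEG
            scale = KM_PER_DEG if grid.planar else KM_PER_DEG * np.cos(np.deg2rad(lat))
            cand_lon = lon + sx * dx_km / scale
            if grid.contains(cand_lon, cand_lat) and grid.is_water(cand_lon, cand_lat):
                lon, lat = cand_lon, cand_lat
                placed = True
                break
        # if every reflection fails the fish holds position for the day
    return pd.DataFrame(rows)


def simulate_tag_records(
    track: pd.DataFrame,
    env: Environment,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    tag_id: str = "sim-000",
    ljfl_cm: float = 160.0,
) -> tuple[Deployment, list[DailyRecord]]:
    """Emit a deployment and daily records from a true track.

    Each day independently carries an SST estimate with probability
    ``p_sst_day`` (reference SST at the true cell plus Gaussian noise) and a
    sunrise/sunset pair with probability ``p_event_day`` (solar predictions
    at the true position plus circular Gaussian noise).  The daily maximum
    depth is drawn below the local bathymetry, so the true cell always
    passes the depth gate.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    grid = env.grid
    records = []
    for _, row in track.iterrows():
        date = row["date"]
        iy, ix = grid.cell_of(row["lon"], row["lat"])
        sst = None
        if rng.random() < cfg.p_sst_day:
            ref = env.ref_sst(date)
            sst = float(ref[iy, ix] + rng.normal(0.0, cfg.sigma_sst))
        sr = ss = None
        if rng.random() < cfg.p_event_day:
            et = solar.predict_event_times(row["lon"], row["lat"], date, h0=cfg.h0)
            if et.status == solar.STATUS_NORMAL:
                sr = float((et.sunrise_ut + rng.normal(0.0, cfg.sigma_event)) % 1440.0)
                ss = float((et.sunset_ut + rng.normal(0.0, cfg.sigma_event)) % 1440.0)
        max_depth = float(rng.uniform(0.05, 0.85) * grid.bathymetry[iy, ix])
        records.append(DailyRecord(date=date, sst=sst, sunrise_ut=sr,
                                   sunset_ut=ss, max_depth=max_depth))
    first, last = track.iloc[0], track.iloc[-1]
    dep = Deployment(
        tag_id=tag_id,
        release_date=first["date"], release_lon=float(first["lon"]),
        release_lat=float(first["lat"]),
        popup_date=last["date"], popup_lon=float(last["lon"]),
        popup_lat=float(last["lat"]),
        ljfl_cm=ljfl_cm, agency="SIM",
    )
    return dep, records


def records_to_frames(
    dep: Deployment, records: list[DailyRecord], rng: Optional[np.random.Generator] = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Render (series, events, metadata) CSV frames in the reader schemas.

    The sensor series is a minimal reconstruction: each day with an SST
    estimate gets three near-surface samples whose median reproduces it, and
    every day gets one sample at the day's maximum depth.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    srows = []
    erows = []
    for rec in records:
        base = dt.datetime(rec.date.year, rec.date.month, rec.date.day, tzinfo=dt.timezone.utc)
        if rec.sst is not None:
            for k, (d_m, off) in enumerate(((2.0, 0.0), (6.0, -0.3), (10.0, 0.3))):
                srows.append(
                    {
                        "tag_id": dep.tag_id,
                        "timestamp": (base + dt.timedelta(hours=10, minutes=10 * k)).isoformat(),
                        "depth_m": d_m,
                        "temp_c": rec.sst + off,
                    }
                )
        if rec.max_depth > 0:
            srows.append(
                {
                    "tag_id": dep.tag_id,
                    "timestamp": (base + dt.timedelta(hours=3)).isoformat(),
                    "depth_m": rec.max_depth,
                    "temp_c": 8.0,
                }
            )
        if rec.sunrise_ut is not None or rec.sunset_ut is not None:
            erows.append(
                {
                    "tag_id": dep.tag_id,
                    "date": rec.date.isoformat(),
                    "sunrise_ut": rec.sunrise_ut if rec.sunrise_ut is not None else np.nan,
                    "sunset_ut": rec.sunset_ut if rec.sunset_ut is not None else np.nan,
                }
            )
    series = pd.DataFrame(srows, columns=["tag_id", "timestamp", "depth_m", "temp_c"])
    events = pd.DataFrame(erows, columns=["tag_id", "date", "sunrise_ut", "sunset_ut"])
    meta = pd.DataFrame(
        [
            {
                "tag_id": dep.tag_id,
                "release_date": dep.release_date.isoformat(),
                "release_lon": dep.release_lon,
                "release_lat": dep.release_lat,
                "popup_date": dep.popup_date.isoformat(),
                "popup_lon": dep.popup_lon,
                "popup_lat": dep.popup_lat,
                "ljfl_cm": dep.ljfl_cm,
                "agency": dep.agency,
            }
        ]
    )
    return series, events, meta


def calibration_experiment(
    cfg: SimConfig,
    n_tags: int,
    env: Optional[Environment] = None,
    D_filter: Optional[float] = None,
    hpd_level: float = 0.95,
    seed: Optional[int] = None,
) -> dict:
    """Full simulate -> filter -> smooth loop over a cohort of tags.

    Reports the fraction of fish-days whose true cell lies inside the daily
    smoothed HPD region at ``hpd_level``, the mean HPD area, and endpoint
    mode errors.  Per-tag failures are recorded with identifiers rather than
    aborting the cohort.
    """
    if n_tags < 1:
        raise ValueError("n_tags must be >= 1")
    env = make_environment(seed=cfg.seed) if env is None else env
    base_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    mp = MovementParams(D=cfg.D_true if D_filter is None else D_filter)
    op = ObservationParams(sigma_sst=cfg.sigma_sst, sigma_event=cfg.sigma_event, h0=cfg.h0)

    covered = 0
    total = 0
    areas = []
    endpoint_err_cells = []
    per_tag = []
    failures = []
    for k in range(n_tags):
        tag_cfg = SimConfig(**{**cfg.__dict__, "seed": base_seed + 1000 + k})
        try:
            track = simulate_track(env, tag_cfg, rng=rng)
            dep, records = simulate_tag_records(track, env, tag_cfg, rng=rng,
                                                tag_id=f"sim-{k:03d}")
            smoothed, fwd, bwd = smooth_deployment(dep, records, env, mp, op)
        except Exception as exc:  # pragma: no cover - defensive per-tag guard
            failures.append({"tag": f"sim-{k:03d}", "error": str(exc)})
            continue
        tag_cov = 0
        for i, row in track.reset_index(drop=True).iterrows():
            iy, ix = env.grid.cell_of(row["lon"], row["lat"])
            m = smoothed.hpd_mask(i, hpd_level)
            total += 1
            if m[iy, ix]:
                covered += 1
                tag_cov += 1
            areas.append(float(env.grid.cell_area_km2[m].sum()))
        modes = smoothed.mode_cells()
        for i in (0, len(modes) - 1):
            iy, ix = env.grid.cell_of(track.iloc[i]["lon"], track.iloc[i]["lat"])
            endpoint_err_cells.append(abs(modes[i][0] - iy) + abs(modes[i][1] - ix))
        per_tag.append({"tag": f"sim-{k:03d}", "n_days": len(track),
                        "coverage": tag_cov / len(track)})
    if total == 0:
        raise RuntimeError(f"all {n_tags} tags failed: {failures}")
    return {
        "hpd_level": hpd_level,
        "n_tags": n_tags,
        "n_days": total,
        "coverage": covered / total,
        "mean_hpd_area_km2": float(np.mean(areas)),
        "median_endpoint_mode_error_cells": float(np.median(endpoint_err_cells)),
        "per_tag": pd.DataFrame(per_tag),
        "failures": failures,
    }
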