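"""End-to-end pipeline tying the stages together.

preprocess -> feasible sets -> event screening -> forward/backward filter ->
two-filter smoothing -> pooled UDs -> optional point-coverage validation.
Deterministic given (inputs, config, seed); per-tag failures are logged and
skipped, and the run fails only if every tag fails.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__, io
from .config import RunConfig, ensure_output_dir
from .environment import Environment
from .grid import MovementParams
from .hmm import ObservationParams, fit_diffusion, smooth_deployment
from .preprocess import build_daily_records, propagate_feasible_sets, screen_event_times
from .ud import QUARTERS, Stratum, hpd_regions, point_coverage, pool_ud

log = logging.getLogger("swordgrid")

__all__ = ["run_pipeline"]


def run_pipeline(cfg: RunConfig, tags: Optional[list[str]] = None) -> dict:
    """Run the full pipeline; returns a manifest of produced artifacts."""
    out = ensure_output_dir(cfg)
    prov = {"config_hash": io.config_hash(cfg.to_dict()), "software_version": __version__}

    if cfg.environment_nc is None:
        raise ValueError("config must set environment_nc (NetCDF environment)")
    if not Path(cfg.environment_nc).exists():
        raise FileNotFoundError(f"environment raster not found: {cfg.environment_nc}")
    env = Environment.from_netcdf(cfg.environment_nc)

    meta = io.read_metadata_csv(cfg.metadata_csv)
    deps = io.deployments_from_metadata(meta)
    if tags:
        deps = [d for d in deps if d.tag_id in set(tags)]
    deps, selection = io.select_tags(deps, min_days=cfg.min_deployment_days)
    selection.to_csv(out / "tag_selection.csv", index=False)
    if not deps:
        raise ValueError("no deployments meet the minimum duration criterion")

    series_all = io.read_series_csv(cfg.series_csv)
    events_all = io.read_events_csv(cfg.events_csv) if cfg.events_csv else None

    op = ObservationParams(sigma_sst=cfg.sigma_sst, sigma_event=cfg.sigma_event_min,
                           h0=cfg.h0_deg, bathy_gate=cfg.bathy_gate)

    tracks = []
    failures = []
    manifest = {"provenance": prov, "tags": {}, "outputs": []}
    for dep in deps:
        try:
            series = series_all.loc[series_all["tag_id"].astype(str) == dep.tag_id]
            events = (
                events_all.loc[events_all["tag_id"].astype(str) == dep.tag_id]
                if events_all is not None
                else None
            )
            records = build_daily_records(series, dep, events)
            fsets = propagate_feasible_sets(
                dep, records, env, vmax_km_day=cfg.vmax_km_day,
                k_sst=cfg.k_sst, sigma_sst=cfg.sigma_sst,
            )
            records, report = screen_event_times(
                records, fsets, env.grid, h0=cfg.h0_deg,
                sigma_min=cfg.sigma_event_min, k_reject=cfg.k_reject,
            )
            report.to_csv(out / f"{dep.tag_id}_event_screening.csv", index=False)

            if cfg.fit_diffusivity:
                d_hat, profile = fit_diffusion(dep, records, env, op, cfg.diffusivity_grid)
                profile.to_csv(out / f"{dep.tag_id}_diffusivity_profile.csv", index=False)
            else:
                d_hat = cfg.diffusivity_km2_day
            mp = MovementParams(D=d_hat)

            smoothed, fwd, bwd = smooth_deployment(dep, records, env, mp, op)
            nc_path = out / f"{dep.tag_id}_smoothed.nc"
            io.write_smoothed_netcdf(smoothed, nc_path, attrs={**prov, "tag_id": dep.tag_id})
            smoothed.summary(cfg.hpd_levels).to_csv(
                out / f"{dep.tag_id}_daily_summary.csv", index=False
            )
            tracks.append((smoothed, dep))
            manifest["tags"][dep.tag_id] = {
                "log_likelihood": fwd.log_likelihood,
                "diffusivity_km2_day": d_hat,
                "n_days": dep.n_days,
            }
        except Exception as exc:
            log.exception("tag %s failed", dep.tag_id)
            failures.append({"tag_id": dep.tag_id, "error": str(exc)})
    if not tracks:
        raise RuntimeError(f"all tags failed: {failures}")
    manifest["failures"] = failures

    regions_by_quarter = {}
    for quarter in QUARTERS + ("all",):
        try:
            ud = pool_ud(tracks, Stratum(quarter=quarter))
        except ValueError:
            continue
        io.write_ud_netcdf(ud, out / f"ud_{quarter}.nc", attrs=prov)
        regions = hpd_regions(ud, cfg.hpd_levels)
        gj = io.hpd_regions_to_geojson(regions, properties={"quarter": quarter, **prov})
        (out / f"ud_{quarter}_hpd.geojson").write_text(json.dumps(gj))
        if quarter != "all":
            regions_by_quarter[quarter] = regions
        manifest["outputs"].append(f"ud_{quarter}.nc")

    if cfg.points_csv:
        points = io.read_points_csv(cfg.points_csv)
        frac, table = point_coverage(points, regions_by_quarter, level=cfg.coverage_level)
        table.to_csv(out / "point_coverage.csv", index=False)
        manifest["point_coverage_fraction"] = frac

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
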