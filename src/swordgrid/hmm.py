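"""Grid-filter HMM: likelihood fields, forward/backward filters, smoothing.

Observations enter as per-cell Gaussian log-likelihoods (SST against the
reference field, sunrise/sunset against per-cell solar predictions) plus a
hard bathymetry gate from the day's maximum depth.  The forward filter runs
from the release position, the backward filter from the pop-up position
using the exact adjoint of the daily transition operator, and the two-filter
smoother multiplies forward-updated with backward-predicted densities so
each observation enters exactly once.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import solar
from .environment import Environment
from .grid import Grid, MovementParams, ProbField, delta_field, predict_step
from .preprocess import DailyRecord, Deployment

__all__ = [
    "ObservationParams",
    "FilterResult",
    "SmoothedTrack",
    "observation_log_likelihood_field",
    "forward_filter",
    "backward_filter",
    "two_filter_smooth",
    "smooth_deployment",
    "fit_diffusion",
]

_NEG_INF = -np.inf


@dataclass
class ObservationParams:
    """Observation-error model: 1 degC SST, 20 min event times by default."""

    sigma_sst: float = 1.0
    sigma_event: float = 20.0
    h0: float = solar.DEFAULT_TWILIGHT_DEG
    bathy_gate: bool = True
    solar_iters: int = 3

    def __post_init__(self) -> None:
        if self.sigma_sst <= 0 or self.sigma_event <= 0:
            raise ValueError("observation sigmas must be > 0")


@dataclass
class FilterResult:
    """Per-day predicted/updated probability fields and log-likelihood."""

    dates: list[dt.date]
    predicted: list[np.ndarray]
    updated: list[np.ndarray]
    log_norms: np.ndarray
    direction: str
    flags: dict = field(default_factory=dict)

    @property
    def log_likelihood(self) -> float:
        return float(np.sum(self.log_norms))

    @property
    def n_days(self) -> int:
        return len(self.dates)


@dataclass
class SmoothedTrack:
    """Per-day smoothed fields with mode cells and HPD areas."""

    grid: Grid
    dates: list[dt.date]
    fields: list[np.ndarray]
    flags: dict = field(default_factory=dict)

    @property
    def n_days(self) -> int:
        return len(self.dates)

    def field_at(self, i: int) -> ProbField:
        return ProbField(self.grid, self.fields[i], self.dates[i])

    def mode_cells(self) -> list[tuple[int, int]]:
        out = []
        for f in self.fields:
            iy, ix = np.unravel_index(int(np.argmax(f)), f.shape)
            out.append((int(iy), int(ix)))
        return out

    def hpd_mask(self, i: int, level: float = 0.95) -> np.ndarray:
        return _hpd_mask(self.fields[i], level)

    def hpd_area_km2(self, i: int, level: float = 0.95) -> float:
        return float(self.grid.cell_area_km2[self.hpd_mask(i, level)].sum())

    def summary(self, levels: Sequence[float] = (0.5, 0.75, 0.95)) -> pd.DataFrame:
        rows = []
        for i, date in enumerate(self.dates):
            iy, ix = np.unravel_index(int(np.argmax(self.fields[i])), self.fields[i].shape)
            row = {
                "date": date,
                "mode_lon": self.grid.lon[ix],
                "mode_lat": self.grid.lat[iy],
            }
            for lv in levels:
                row[f"hpd{int(lv * 100)}_km2"] = self.hpd_area_km2(i, lv)
            rows.append(row)
        return pd.DataFrame(rows)


def _hpd_mask(values: np.ndarray, level: float) -> np.ndarray:
    flat = values.ravel()
    order = np.argsort(flat, kind="stable")[::-1]
    csum = np.cumsum(flat[order])
    total = csum[-1]
    k = int(np.searchsorted(csum, level * total * (1.0 - 1e-9))) + 1
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:min(k, flat.size)]] = True
    return mask.reshape(values.shape)


def observation_log_likelihood_field(
    rec: Optional[DailyRecord],
    env_sst: Optional[np.ndarray],
    grid: Grid,
    op: ObservationParams,
    date: Optional[dt.date] = None,
) -> np.ndarray:
    """Per-cell log-likelihood of one day's observations.

    Land cells are -inf.  An absent/empty record gives a field uniform over
    water (zero log-likelihood), i.e. a pure prediction day.
    """
    ll = np.where(grid.water, 0.0, _NEG_INF)
    if rec is None:
        return ll
    if rec.sst is not None:
        if env_sst is None:
            raise ValueError("SST observation present but no reference SST field")
        r = (rec.sst - env_sst) / op.sigma_sst
        ll = ll + (-np.log(op.sigma_sst * np.sqrt(2 * np.pi)) - 0.5 * r * r)
    if rec.sunrise_ut is not None or rec.sunset_ut is not None:
        d = rec.date if rec.date is not None else date
        lon2d, lat2d = np.meshgrid(grid.lon, grid.lat)
        et = solar.predict_event_times(lon2d, lat2d, d, h0=op.h0, n_iter=op.solar_iters)
        if rec.sunrise_ut is not None:
            ll = ll + solar.event_log_likelihood(rec.sunrise_ut, et.sunrise_ut, op.sigma_event)
        if rec.sunset_ut is not None:
            ll = ll + solar.event_log_likelihood(rec.sunset_ut, et.sunset_ut, op.sigma_event)
    if op.bathy_gate and rec.max_depth > 0:
        ll = np.where(grid.bathymetry >= rec.max_depth, ll, _NEG_INF)
    return np.where(grid.water, ll, _NEG_INF)


def _precompute_log_likelihoods(
    dates: list[dt.date],
    records: Sequence[DailyRecord],
    env: Environment,
    op: ObservationParams,
) -> dict:
    rec_by_date = {r.date: r for r in records}
    out = {}
    for date in dates:
        rec = rec_by_date.get(date)
        ref = env.ref_sst(date) if (rec is not None and rec.sst is not None) else None
        out[date] = observation_log_likelihood_field(rec, ref, env.grid, op, date)
    return out


def _bayes_update(prior: np.ndarray, log_lik: np.ndarray, water: np.ndarray,
                  flags: dict, date: dt.date) -> tuple[np.ndarray, float]:
    """Multiply prior by exp(log_lik); return normalized posterior + log-normalizer."""
    active = (prior > 0) & np.isfinite(log_lik)
    if not active.any():
        # every positive-prior cell gated out: drop the hard gates for the day
        flags.setdefault("gate_relaxed", []).append(date)
        soft = np.where(np.isfinite(log_lik), log_lik, 0.0)
        soft = np.where(water, soft, _NEG_INF)
        active = (prior > 0) & np.isfinite(soft)
        log_lik = soft
        if not active.any():
            flags.setdefault("uniform_fallback", []).append(date)
            post = prior / prior.sum()
            return post, 0.0
    m = float(np.max(log_lik[active]))
    w = np.where(active, prior * np.exp(np.where(active, log_lik, 0.0) - m), 0.0)
    z = float(w.sum())
    return w / z, float(np.log(z) + m)


def _run_filter(
    dates: list[dt.date],
    init: np.ndarray,
    final_delta: Optional[np.ndarray],
    log_liks: dict,
    grid: Grid,
    mp: MovementParams,
    adjoint: bool,
    direction: str,
) -> FilterResult:
    flags: dict = {}
    predicted, updated, log_norms = [], [], []
    p = init.copy()
    for i, date in enumerate(dates):
        if i > 0:
            p = predict_step(ProbField(grid, p), mp, adjoint=adjoint).values
        predicted.append(p.copy())
        post, ln = _bayes_update(p, log_liks[date], grid.water, flags, date)
        if i == len(dates) - 1 and final_delta is not None:
            anchored = post * final_delta
            z = anchored.sum()
            if z <= 0:
                flags["endpoint_conflict"] = True
                # final delta unreachable under gates: anchor on the prediction
                anchored = p * final_delta
                z = anchored.sum()
                if z <= 0:
                    raise ValueError(f"{direction} filter: endpoint has zero mass on {date}")
            post = anchored / z
            ln += float(np.log(z))
        updated.append(post)
        log_norms.append(ln)
        p = post
    return FilterResult(dates, predicted, updated, np.asarray(log_norms), direction, flags)


def forward_filter(
    dep: Deployment,
    records: Sequence[DailyRecord],
    env: Environment,
    mp: MovementParams,
    op: ObservationParams,
    log_liks: Optional[dict] = None,
) -> FilterResult:
    """Filter from the release position forward to the pop-up day.

    Day 0 is a delta at the release position (updated with day-0
    observations); the final day is additionally anchored on the pop-up cell.
    The summed log-normalizers form the data log-likelihood used for
    diffusivity estimation.
    """
    dates = dep.dates()
    if log_liks is None:
        log_liks = _precompute_log_likelihoods(dates, records, env, op)
    grid = env.grid
    init = delta_field(grid, dep.release_lon, dep.release_lat).values
    final = delta_field(grid, dep.popup_lon, dep.popup_lat).values
    return _run_filter(dates, init, final, log_liks, grid, mp, False, "forward")


def backward_filter(
    dep: Deployment,
    records: Sequence[DailyRecord],
    env: Environment,
    mp: MovementParams,
    op: ObservationParams,
    log_liks: Optional[dict] = None,
) -> FilterResult:
    """Mirror filter from the pop-up position backward to the release day.

    Runs on the reversed timeline with the adjoint transition operator
    (velocities negated; pure diffusion is self-adjoint), anchored on the
    release cell at its final (earliest) day.  Fields in the result are in
    *backward* time order: ``dates[0]`` is the pop-up day.
    """
    dates = dep.dates()
    if log_liks is None:
        log_liks = _precompute_log_likelihoods(dates, records, env, op)
    grid = env.grid
    init = delta_field(grid, dep.popup_lon, dep.popup_lat).values
    final = delta_field(grid, dep.release_lon, dep.release_lat).values
    return _run_filter(dates[::-1], init, final, log_liks, grid, mp, True, "backward")


def two_filter_smooth(fwd: FilterResult, bwd: FilterResult, grid: Grid) -> SmoothedTrack:
    """Combine forward-updated with backward-predicted densities.

    ``smoothed(t) ~ fwd.updated(t) * bwd.predicted(t)``; the backward
    predicted field excludes day-t observations, so each observation enters
    exactly once.  Endpoint days reduce to the release/pop-up deltas.  A
    cellwise product that is identically zero falls back to the forward
    density for that day and is flagged.
    """
    if fwd.n_days != bwd.n_days:
        raise ValueError("forward/backward filters cover different day spans")
    T = fwd.n_days - 1
    flags: dict = {}
    fields = []
    for t in range(T + 1):
        f = fwd.updated[t]
        b = bwd.predicted[T - t]  # backward runs on reversed dates
        prod = f * b
        z = prod.sum()
        if z <= 0:
            flags.setdefault("product_zero", []).append(fwd.dates[t])
            prod = f.copy()
            z = prod.sum()
        fields.append(prod / z)
    return SmoothedTrack(grid, list(fwd.dates), fields, flags)


def smooth_deployment(
    dep: Deployment,
    records: Sequence[DailyRecord],
    env: Environment,
    mp: MovementParams,
    op: ObservationParams,
) -> tuple[SmoothedTrack, FilterResult, FilterResult]:
    """Convenience wrapper: shared likelihood fields, both filters, smoother."""
    dates = dep.dates()
    log_liks = _precompute_log_likelihoods(dates, records, env, op)
    fwd = forward_filter(dep, records, env, mp, op, log_liks=log_liks)
    bwd = backward_filter(dep, records, env, mp, op, log_liks=log_liks)
    return two_filter_smooth(fwd, bwd, env.grid), fwd, bwd


def fit_diffusion(
    dep,
    records,
    env: Environment,
    op: ObservationParams,
    D_candidates: Sequence[float],
    dt: float = 1.0,
) -> tuple[float, pd.DataFrame]:
    """Profile the forward-filter log-likelihood over candidate diffusivities.

    ``dep``/``records`` may be a single deployment with its records or
    parallel sequences of several (a pooled, global diffusivity estimate —
    per-fish versus global estimation is a configuration choice).  Returns
    the maximizing candidate and the full profile; a single candidate is
    returned as-is.
    """
    cands = list(D_candidates)
    if len(cands) == 0:
        raise ValueError("need at least one candidate diffusivity")
    if isinstance(dep, Deployment):
        deps, rec_sets = [dep], [records]
    else:
        deps, rec_sets = list(dep), list(records)
        if len(deps) != len(rec_sets):
            raise ValueError("need one record set per deployment")
    cached = [
        _precompute_log_likelihoods(d.dates(), r, env, op)
        for d, r in zip(deps, rec_sets)
    ]
    rows = []
    for D in cands:
        mp = MovementParams(D=D, dt=dt)
        total = 0.0
        for d, r, ll in zip(deps, rec_sets, cached):
            total += forward_filter(d, r, env, mp, op, log_liks=ll).log_likelihood
        rows.append({"D": float(D), "log_likelihood": total})
    profile = pd.DataFrame(rows)
    if not np.any(np.isfinite(profile["log_likelihood"])):
        raise ValueError("log-likelihood non-finite for every candidate diffusivity")
    best = profile.loc[profile["log_likelihood"].idxmax(), "D"]
    return float(best), profile
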