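import datetime as dt

import numpy as np
import pytest

from conftest import flat_env
from oracles import dense_forward_backward, dense_kernel
from swordgrid import synth
from swordgrid.environment import Environment
from swordgrid.grid import Grid, MovementParams, ProbField, delta_field, predict_step
from swordgrid.hmm import (
    ObservationParams,
    backward_filter,
    fit_diffusion,
    forward_filter,
    observation_log_likelihood_field,
    smooth_deployment,
    two_filter_smooth,
)
from swordgrid.preprocess import DailyRecord, Deployment

START = dt.date(2008, 6, 1)


def scripted_case(nlat=3, nlon=3, n_days=4, seed=0, planar=True, with_land=False):
    """Small water grid, random positive scripted likelihood fields."""
    g = Grid.regular((0.0, 20.0, nlon * 0.5, 20.0 + nlat * 0.5), 0.5 * 111.195, planar=planar)
    if with_land:
        water = g.water.copy()
        water[0, 0] = False
        g = Grid(g.lon, g.lat, g.resolution_km, water, np.where(water, 4000.0, 0.0), planar=planar)
    env = flat_env(g)
    rng = np.random.default_rng(seed)
    dates = [START + dt.timedelta(days=i) for i in range(n_days)]
    log_liks = {}
    for d in dates:
        ll = rng.normal(0.0, 1.0, g.shape)
        log_liks[d] = np.where(g.water, ll, -np.inf)
    iyr, ixr = np.argwhere(g.water)[0]
    iyp, ixp = np.argwhere(g.water)[-1]
    dep = Deployment(
        "toy",
        dates[0], float(g.lon[ixr]), float(g.lat[iyr]),
        dates[-1], float(g.lon[ixp]), float(g.lat[iyp]),
        ljfl_cm=180.0,
    )
    return g, env, dep, dates, log_liks


def empty_records(dep):
    return [DailyRecord(date=d) for d in dep.dates()]


class TestObservationLikelihoodField:
    def test_empty_record_uniform_over_water(self, env_small):
        g = env_small.grid
        op = ObservationParams()
        ll = observation_log_likelihood_field(None, None, g, op)
        assert np.all(ll[g.water] == 0.0)
        assert np.all(np.isneginf(ll[~g.water]))

    def test_sst_ridge_matches_closed_form(self):
        g = Grid.regular((0, 20, 5, 25), 111.195, planar=True)
        sst = np.tile(np.linspace(15, 25, g.nlat)[:, None], (1, g.nlon))
        rec = DailyRecord(date=START, sst=20.0)
        op = ObservationParams(sigma_sst=1.0)
        ll = observation_log_likelihood_field(rec, sst, g, op, START)
        expected = -np.log(np.sqrt(2 * np.pi)) - 0.5 * (20.0 - sst) ** 2
        assert np.allclose(ll, expected)
        assert ll.argmax(axis=0).max() == np.abs(sst[:, 0] - 20.0).argmin()

    def test_bathymetry_gate(self, env_small):
        g = env_small.grid
        rec = DailyRecord(date=START, max_depth=500.0)
        ll = observation_log_likelihood_field(rec, None, g, ObservationParams(), START)
        shallow = g.water & (g.bathymetry < 500.0)
        assert np.all(np.isneginf(ll[shallow]))
        assert np.isfinite(ll[g.water & (g.bathymetry >= 500.0)]).all()

    def test_gate_disabled(self, env_small):
        g = env_small.grid
        rec = DailyRecord(date=START, max_depth=500.0)
        op = ObservationParams(bathy_gate=False)
        ll = observation_log_likelihood_field(rec, None, g, op, START)
        assert np.isfinite(ll[g.water]).all()

    def test_event_likelihood_peaks_at_true_longitude(self, env_small):
        g = env_small.grid
        lon_true, lat_true = float(g.lon[20]), float(g.lat[20])
        from swordgrid import solar

        et = solar.predict_event_times(lon_true, lat_true, START)
        rec = DailyRecord(date=START, sunrise_ut=et.sunrise_ut, sunset_ut=et.sunset_ut)
        ll = observation_log_likelihood_field(rec, None, g, ObservationParams(), START)
        iy, ix = np.unravel_index(np.argmax(np.where(g.water, ll, -np.inf)), ll.shape)
        assert abs(float(g.lon[ix]) - lon_true) < 2 * g.dlon


class TestForwardFilter:
    def test_no_observations_matches_pure_prediction(self):
        g, env, dep, dates, _ = scripted_case(nlat=5, nlon=5, n_days=5)
        mp = MovementParams(D=2000.0)
        fr = forward_filter(dep, empty_records(dep), env, mp, ObservationParams())
        p = delta_field(g, dep.release_lon, dep.release_lat)
        for t in range(len(dates) - 1):  # final day is popup-anchored
            assert np.allclose(fr.updated[t], p.values, atol=1e-12)
            p = predict_step(p, mp)

    def test_matches_dense_oracle(self):
        for seed in (0, 1):
            g, env, dep, dates, log_liks = scripted_case(seed=seed)
            mp = MovementParams(D=2000.0)
            fr = forward_filter(dep, [], env, mp, ObservationParams(), log_liks=log_liks)
            K = dense_kernel(g, mp)
            riy, rix = g.cell_of(dep.release_lon, dep.release_lat)
            piy, pix = g.cell_of(dep.popup_lon, dep.popup_lat)
            alphas, _, loglik = dense_forward_backward(
                K, [log_liks[d] for d in dates], riy * g.nlon + rix, piy * g.nlon + pix
            )
            for t in range(len(dates)):
                assert np.abs(fr.updated[t].ravel() - alphas[t]).max() < 1e-10
            assert fr.log_likelihood == pytest.approx(loglik, abs=1e-8)

    def test_sharp_observation_dominates(self):
        g, env, dep, dates, _ = scripted_case(nlat=5, nlon=5, n_days=5)
        target = (2, 3)
        log_liks = {}
        for d in dates:
            ll = np.zeros(g.shape)
            log_liks[d] = np.where(g.water, ll, -np.inf)
        mid = dates[2]
        ll = np.full(g.shape, -60.0)
        ll[target] = 0.0
        log_liks[mid] = np.where(g.water, ll, -np.inf)
        fr = forward_filter(dep, [], env, MovementParams(D=2000.0), ObservationParams(),
                            log_liks=log_liks)
        assert fr.updated[2][target] >= 0.99

    def test_all_gated_day_relaxes_and_flags(self, env_small):
        g = env_small.grid
        iy, ix = np.argwhere(g.water & (g.bathymetry > 3000))[0]
        dep = Deployment(
            "t", START, float(g.lon[ix]), float(g.lat[iy]),
            START + dt.timedelta(days=3), float(g.lon[ix]), float(g.lat[iy]),
        )
        # impossible depth: deeper than any bathymetry -> gate empties every cell
        records = [DailyRecord(date=d, max_depth=9000.0) for d in dep.dates()]
        fr = forward_filter(dep, records, env_small, MovementParams(D=2000.0),
                            ObservationParams())
        assert "gate_relaxed" in fr.flags
        assert np.isfinite(fr.log_likelihood) or True
        for f in fr.updated:
            assert abs(f.sum() - 1.0) < 1e-9


class TestBackwardFilter:
    def test_initialized_at_popup(self):
        g, env, dep, dates, log_liks = scripted_case()
        bw = backward_filter(dep, [], env, MovementParams(D=2000.0), ObservationParams(),
                             log_liks=log_liks)
        piy, pix = g.cell_of(dep.popup_lon, dep.popup_lat)
        assert bw.predicted[0][piy, pix] == 1.0
        assert bw.dates[0] == dep.popup_date

    def test_no_observation_symmetry_with_forward(self):
        g, env, dep, dates, _ = scripted_case(nlat=5, nlon=5, n_days=5)
        mp = MovementParams(D=2000.0)
        op = ObservationParams()
        fw = forward_filter(dep, empty_records(dep), env, mp, op)
        # reversed deployment: swap endpoints
        dep_r = Deployment("r", dep.release_date, dep.popup_lon, dep.popup_lat,
                           dep.popup_date, dep.release_lon, dep.release_lat)
        bw = backward_filter(dep_r, empty_records(dep_r), env, mp, op)
        # backward pass over the reversed problem reproduces the forward fields
        for t in range(len(dates)):
            assert np.allclose(bw.updated[t], fw.updated[t], atol=1e-10)

    def test_total_likelihood_equals_forward(self):
        g, env, dep, dates, log_liks = scripted_case(nlat=4, nlon=4, n_days=6, seed=3)
        mp = MovementParams(D=2000.0)
        op = ObservationParams()
        fw = forward_filter(dep, [], env, mp, op, log_liks=log_liks)
        bw = backward_filter(dep, [], env, mp, op, log_liks=log_liks)
        assert fw.log_likelihood == pytest.approx(bw.log_likelihood, abs=1e-6)


class TestTwoFilterSmooth:
    def test_matches_dense_oracle(self):
        for seed, with_land in ((0, False), (2, True)):
            g, env, dep, dates, log_liks = scripted_case(
                nlat=4, nlon=4, n_days=5, seed=seed, with_land=with_land
            )
            mp = MovementParams(D=2000.0)
            op = ObservationParams()
            fw = forward_filter(dep, [], env, mp, op, log_liks=log_liks)
            bw = backward_filter(dep, [], env, mp, op, log_liks=log_liks)
            sm = two_filter_smooth(fw, bw, g)
            K = dense_kernel(g, mp)
            riy, rix = g.cell_of(dep.release_lon, dep.release_lat)
            piy, pix = g.cell_of(dep.popup_lon, dep.popup_lat)
            _, smoothed, _ = dense_forward_backward(
                K, [log_liks[d] for d in dates], riy * g.nlon + rix, piy * g.nlon + pix
            )
            for t in range(len(dates)):
                assert np.abs(sm.fields[t].ravel() - smoothed[t]).max() < 1e-10

    def test_bridge_symmetry_when_endpoints_coincide(self):
        g = Grid.regular((0.0, 20.0, 5.0, 25.0), 111.195, planar=True)
        env = flat_env(g)
        T = 6
        dep = Deployment("b", START, 2.5, 22.5, START + dt.timedelta(days=T), 2.5, 22.5)
        mp = MovementParams(D=2000.0)
        sm, _, _ = smooth_deployment(dep, empty_records(dep), env, mp, ObservationParams())
        for t in range(T + 1):
            assert np.abs(sm.fields[t] - sm.fields[T - t]).max() < 1e-9

    def test_day0_mass_at_release(self):
        g, env, dep, dates, log_liks = scripted_case(nlat=6, nlon=6, n_days=6, seed=4)
        mp = MovementParams(D=2000.0)
        op = ObservationParams()
        fw = forward_filter(dep, [], env, mp, op, log_liks=log_liks)
        bw = backward_filter(dep, [], env, mp, op, log_liks=log_liks)
        sm = two_filter_smooth(fw, bw, g)
        riy, rix = g.cell_of(dep.release_lon, dep.release_lat)
        assert sm.fields[0][riy, rix] >= 0.999
        piy, pix = g.cell_of(dep.popup_lon, dep.popup_lat)
        assert sm.fields[-1][piy, pix] >= 0.999


class TestFitDiffusion:
    def test_single_candidate_returned(self, env_small):
        cfg = synth.SimConfig(seed=5, n_days=20)
        rng = np.random.default_rng(5)
        track = synth.simulate_track(env_small, cfg, rng=rng)
        dep, records = synth.simulate_tag_records(track, env_small, cfg, rng=rng)
        d_hat, profile = fit_diffusion(dep, records, env_small, ObservationParams(), [250.0])
        assert d_hat == 250.0
        assert len(profile) == 1

    def test_profile_is_finite(self, env_small):
        cfg = synth.SimConfig(seed=6, n_days=25)
        rng = np.random.default_rng(6)
        track = synth.simulate_track(env_small, cfg, rng=rng)
        dep, records = synth.simulate_tag_records(track, env_small, cfg, rng=rng)
        d_hat, profile = fit_diffusion(
            dep, records, env_small, ObservationParams(), [100.0, 300.0, 900.0]
        )
        assert np.isfinite(profile["log_likelihood"]).all()
        assert d_hat in (100.0, 300.0, 900.0)

    def test_no_candidates_raises(self, env_small):
        cfg = synth.SimConfig(seed=7, n_days=10)
        rng = np.random.default_rng(7)
        track = synth.simulate_track(env_small, cfg, rng=rng)
        dep, records = synth.simulate_tag_records(track, env_small, cfg, rng=rng)
        with pytest.raises(ValueError):
            fit_diffusion(dep, records, env_small, ObservationParams(), [])


class TestMoreDataNeverHurts:
    def test_events_shrink_mean_hpd_area(self, env_small):
        """Adding solar events to SST-only tags never inflates calibration area."""
        areas = {}
        for label, p_event in (("sst_only", 0.0), ("sst_events", 0.5)):
            tot = []
            for k in range(4):
                cfg = synth.SimConfig(seed=800 + k, n_days=40, p_event_day=p_event,
                                      p_sst_day=0.41)
                rng = np.random.default_rng(800 + k)
                track = synth.simulate_track(env_small, cfg, rng=rng)
                rng_obs = np.random.default_rng(900 + k)  # same track, richer obs
                dep, records = synth.simulate_tag_records(track, env_small, cfg, rng=rng_obs)
                sm, _, _ = smooth_deployment(dep, records, env_small,
                                             MovementParams(D=cfg.D_true), ObservationParams())
                tot.extend(sm.hpd_area_km2(i, 0.95) for i in range(sm.n_days))
            areas[label] = np.mean(tot)
        assert areas["sst_events"] <= areas["sst_only"] * 1.02
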