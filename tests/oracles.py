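"""Independent oracles used by the tests.

Everything here deliberately avoids the library's own computational paths:
the solar oracles are different published series, and the HMM oracle is a
dense transition-matrix forward-backward recursion built by probing the
prediction operator with basis vectors.
"""

from __future__ import annotations

import datetime as dt

import numpy as np

from swordgrid.grid import Grid, MovementParams, ProbField, predict_step


# ---------------------------------------------------------------------------
# solar oracles


def almanac_declination(t: dt.datetime) -> float:
    """Solar declination (deg) via the Astronomical Almanac low-precision series."""
    if t.tzinfo is None:
        t = t.replace(tzinfo=dt.timezone.utc)
    n = (t - dt.datetime(2000, 1, 1, 12, tzinfo=dt.timezone.utc)).total_seconds() / 86400.0
    L = (280.460 + 0.9856474 * n) % 360.0
    g = np.deg2rad((357.528 + 0.9856003 * n) % 360.0)
    lam = np.deg2rad(L + 1.915 * np.sin(g) + 0.020 * np.sin(2.0 * g))
    eps = np.deg2rad(23.439 - 0.0000004 * n)
    return float(np.rad2deg(np.arcsin(np.sin(eps) * np.sin(lam))))


def gmst_hours_iau1982(t: dt.datetime) -> float:
    """GMST via the IAU 1982 polynomial evaluated directly in hours."""
    if t.tzinfo is None:
        t = t.replace(tzinfo=dt.timezone.utc)
    d = (t - dt.datetime(2000, 1, 1, 12, tzinfo=dt.timezone.utc)).total_seconds() / 86400.0
    T = d / 36525.0
    sec = 67310.54841 + (876600.0 * 3600.0 + 8640184.812866) * T + 0.093104 * T**2 - 6.2e-6 * T**3
    return float((sec / 3600.0) % 24.0)


def almanac_event_times(lon: float, lat: float, date: dt.date, h0: float = 0.0):
    """Sunrise/sunset (minutes UT) via the Almanac series + equation of time.

    Returns None for polar day/night.  Independent path: the solar position
    comes from the Almanac low-precision series (different coefficients) and
    UT is obtained from solar noon and the equation of time (mean longitude
    minus apparent right ascension) rather than from sidereal time.
    """
    phi = np.deg2rad(lat)

    def sun(n: float):
        L = (280.460 + 0.9856474 * n) % 360.0
        g = np.deg2rad((357.528 + 0.9856003 * n) % 360.0)
        lam = np.deg2rad(L + 1.915 * np.sin(g) + 0.020 * np.sin(2.0 * g))
        eps = np.deg2rad(23.439 - 0.0000004 * n)
        decl = np.arcsin(np.sin(eps) * np.sin(lam))
        ra = np.rad2deg(np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam))) % 360.0
        eot_min = 4.0 * (((L - ra + 180.0) % 360.0) - 180.0)
        return decl, eot_min

    n0 = (
        dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc)
        - dt.datetime(2000, 1, 1, 12, tzinfo=dt.timezone.utc)
    ).total_seconds() / 86400.0
    out = []
    for sign in (-1, +1):
        minutes = 720.0 - 4.0 * lon + sign * 360.0
        for _ in range(3):
            decl, eot = sun(n0 + minutes / 1440.0)
            cosw = (np.sin(np.deg2rad(h0)) - np.sin(phi) * np.sin(decl)) / (
                np.cos(phi) * np.cos(decl)
            )
            if abs(cosw) > 1.0:
                return None
            w = np.rad2deg(np.arccos(cosw))
            minutes = 720.0 - 4.0 * lon - eot + sign * 4.0 * w
        out.append(minutes % 1440.0)
    return tuple(out)


# ---------------------------------------------------------------------------
# dense HMM oracle


def dense_kernel(grid: Grid, mp: MovementParams) -> np.ndarray:
    """Dense one-day transition matrix, columns = predict_step on basis vectors."""
    n = grid.nlat * grid.nlon
    K = np.zeros((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        K[:, j] = predict_step(ProbField(grid, e.reshape(grid.shape)), mp).values.ravel()
    return K


def dense_forward_backward(
    K: np.ndarray,
    log_liks: list[np.ndarray],
    release_idx: int,
    popup_idx: int,
):
    """Endpoint-conditioned forward-backward smoother on the dense kernel.

    Returns (filtered, smoothed, log_likelihood); filtered[t] is the
    normalized forward density after the day-t update (with the pop-up delta
    folded into the final day), smoothed[t] the full-information marginal.
    """
    T = len(log_liks) - 1
    n = K.shape[0]
    Ls = []
    shifts = []
    for ll in log_liks:
        flat = ll.ravel()
        m = np.max(flat[np.isfinite(flat)])
        Ls.append(np.where(np.isfinite(flat), np.exp(flat - m), 0.0))
        shifts.append(m)

    alphas = []
    loglik = 0.0
    a = np.zeros(n)
    a[release_idx] = 1.0
    for t in range(T + 1):
        if t > 0:
            a = K @ a
        a = a * Ls[t]
        if t == T:
            mask = np.zeros(n)
            mask[popup_idx] = 1.0
            a = a * mask
        z = a.sum()
        loglik += np.log(z) + shifts[t]
        a = a / z
        alphas.append(a)

    betas = [None] * (T + 1)
    b = np.zeros(n)
    b[popup_idx] = 1.0
    betas[T] = b
    for t in range(T - 1, -1, -1):
        b = K.T @ (Ls[t + 1] * betas[t + 1])
        b = b / b.sum()
        betas[t] = b

    smoothed = []
    for t in range(T + 1):
        s = alphas[t] * betas[t] if t < T else alphas[T]
        smoothed.append(s / s.sum())
    return alphas, smoothed, loglik


# ---------------------------------------------------------------------------
# brute-force feasibility


def brute_force_feasible(
    water: np.ndarray,
    start: tuple[int, int],
    end: tuple[int, int],
    n_days: int,
    reach: int,
    gates: list[np.ndarray],
):
    """Enumerate daily feasible sets by breadth-first Chebyshev expansion.

    ``reach`` is cells/day; ``gates[t]`` the per-day constraint mask.  The
    forward pass from ``start`` and backward pass from ``end`` are
    intersected, mirroring the definition rather than the implementation.
    """
    nlat, nlon = water.shape

    def expand(mask):
        out = np.zeros_like(mask)
        iy, ix = np.nonzero(mask)
        for y, x in zip(iy, ix):
            for dy in range(-1, 2):
                for dx in range(-1, 2):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < nlat and 0 <= xx < nlon and water[yy, xx]:
                        out[yy, xx] = True
        return out

    def one_pass(origin, order):
        cur = np.zeros_like(water)
        cur[origin] = True
        cur &= water
        masks = []
        for i, t in enumerate(order):
            if i > 0:
                for _ in range(reach):
                    cur = expand(cur)
            nxt = cur & gates[t]
            if not nxt.any():
                nxt = cur.copy()
            masks.append(nxt)
            cur = nxt
        return masks

    fwd = one_pass(start, list(range(n_days)))
    bwd = one_pass(end, list(range(n_days - 1, -1, -1)))[::-1]
    return [f & b for f, b in zip(fwd, bwd)]
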