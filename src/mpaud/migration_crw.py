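"""Daily-step correlated random walk state-space smoother for migrations.

Argos fixes along a migratory track are irregular in time and noisy in
space. A first-difference correlated random walk (CRW) with velocity
persistence gamma is used as the process model on a regular one-day step:

    x_d = x_{d-1} + v_d,        v_d = gamma * v_{d-1} + eta_d,
    eta_d ~ N(0, sigma_p^2 I)

Observations at fractional day t between daily states d-1 and d are
linear interpolations of the bracketing positions plus Argos error:

    y = (1 - a) x_{d-1} + a x_d + eps,   a = t - (d - 1),
    eps ~ N(0, (k * err_LC)^2 I)

The model is linear-Gaussian, so (gamma, sigma_p, k) are estimated by
maximum likelihood through the Kalman filter and one "true" position per
day comes from the Rauch-Tung-Striebel smoothing pass. Per-LC errors come
from the error table, inflated by the single fitted factor k (nominal
Argos errors are known to be optimistic).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from mpaud.track_io import ProjectedTrack, Track, haversine_km
from mpaud.movement_weights import LCErrorTable

logger = logging.getLogger(__name__)

_ERR_FLOOR_M = 1.0  # numerical floor on observation sd


@dataclass
class CRWFit:
    """Fitted CRW: daily smoothed positions and travel speeds."""

    gamma: float  # move persistence in [0, 1]
    sigma_p: float  # process sd, m/day
    error_scale: float  # fitted inflation k on the LC error table
    days: np.ndarray  # 0..D
    daily_xy: np.ndarray  # (D+1, 2) smoothed planar positions, m
    daily_lonlat: np.ndarray  # (D+1, 2) via inverse projection
    speeds_kmd: np.ndarray  # (D,) consecutive daily displacements
    mean_speed_kmd: float
    sd_speed_kmd: float
    loglik: float
    converged: bool


def mean_fix_interval(track: Track) -> float:
    """Mean of successive fix time differences, in days."""
    if len(track) < 2:
        raise ValueError(f"{track.animal_id}: need >= 2 fixes for a fix interval")
    t = track.times_s()
    return float(np.mean(np.diff(t)) / 86400.0)


def raw_speed_stats(track: Track) -> tuple[float, float]:
    """Speed statistics from raw fixes: displacement / elapsed per segment.

    Returned as (mean, sd) in km/d with the n-1 sd denominator; an
    alternative basis to the smoothed daily speeds.
    """
    if len(track) < 2:
        raise ValueError("need >= 2 fixes")
    ll = track.lonlat()
    t = track.times_s() / 86400.0
    speeds = []
    for i in range(len(ll) - 1):
        dt = t[i + 1] - t[i]
        if dt <= 0:
            continue
        speeds.append(haversine_km(ll[i], ll[i + 1]) / dt)
    speeds = np.asarray(speeds)
    sd = float(np.std(speeds, ddof=1)) if len(speeds) > 1 else 0.0
    return float(np.mean(speeds)), sd


def _build_system(gamma: float, sigma_p: float):
    """Transition matrix and process covariance for the daily state.

    State z = (x, y, vx, vy). Because x_d = x_{d-1} + v_d identically,
    the previous-day position needed by fractional-day observations is
    recoverable as x - v and need not be carried in the state.
    """
    F = np.array([
        [1.0, 0.0, gamma, 0.0],
        [0.0, 1.0, 0.0, gamma],
        [0.0, 0.0, gamma, 0.0],
        [0.0, 0.0, 0.0, gamma],
    ])
    # eta enters both the new position and the new velocity
    G = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
    Q = sigma_p**2 * (G @ G.T)
    return F, Q


def _obs_matrix(alpha: float) -> np.ndarray:
    """y = (1-a) x_{d-1} + a x_d = x_d - (1-a) v_d."""
    b = 1.0 - alpha
    return np.array([
        [1.0, 0.0, -b, 0.0],
        [0.0, 1.0, 0.0, -b],
    ])


def _group_by_day(t_days: np.ndarray, n_days: int) -> list[list[int]]:
    """Indices of observations in each interval (d-1, d]; day 0 holds t=0."""
    groups: list[list[int]] = [[] for _ in range(n_days + 1)]
    for i, t in enumerate(t_days):
        if t <= 1e-12:
            groups[0].append(i)
        else:
            d = int(math.ceil(t - 1e-9))
            d = min(max(d, 1), n_days)
            groups[d].append(i)
    return groups


def _kalman(t_days, obs_xy, obs_sd, gamma, sigma_p, n_days, smooth=False):
    """Kalman filter (and optional RTS smoother) over daily states.

    Returns (loglik, smoothed daily positions or None).
    """
    F, Q = _build_system(gamma, sigma_p)
    groups = _group_by_day(t_days, n_days)

    big = (500_000.0) ** 2  # diffuse-ish prior, m^2
    m = np.zeros(4)
    m[0] = obs_xy[0, 0]
    m[1] = obs_xy[0, 1]
    P = np.diag([big, big, (200_000.0) ** 2, (200_000.0) ** 2])

    loglik = 0.0
    means_f, covs_f, means_p, covs_p = [], [], [], []
    I6 = np.eye(4)

    def update(m, P, idx):
        nonlocal loglik
        for i in idx:
            t = t_days[i]
            if t > 1e-12:
                a = t - math.ceil(t - 1e-9) + 1.0  # position within (d-1, d]
            else:
                a = 1.0  # day 0: x == p, either row works
            H = _obs_matrix(a)
            R = np.eye(2) * max(obs_sd[i], _ERR_FLOOR_M) ** 2
            y = obs_xy[i]
            v = y - H @ m
            S = H @ P @ H.T + R
            try:
                Sinv = np.linalg.inv(S)
            except np.linalg.LinAlgError:
                Sinv = np.linalg.inv(S + 1e-6 * np.eye(2))
            loglik += float(
                -0.5 * (v @ Sinv @ v) - 0.5 * np.log(np.linalg.det(2 * np.pi * S))
            )
            K = P @ H.T @ Sinv
            m = m + K @ v
            P = (I6 - K @ H) @ P @ (I6 - K @ H).T + K @ R @ K.T  # Joseph form
        return m, P

    m, P = update(m, P, groups[0])
    means_f.append(m.copy())
    covs_f.append(P.copy())
    for d in range(1, n_days + 1):
        m = F @ m
        P = F @ P @ F.T + Q
        means_p.append(m.copy())
        covs_p.append(P.copy())
        m, P = update(m, P, groups[d])
        means_f.append(m.copy())
        covs_f.append(P.copy())

    if not smooth:
        return loglik, None

    # RTS smoother
    ms = [None] * (n_days + 1)
    Ps = [None] * (n_days + 1)
    ms[-1], Ps[-1] = means_f[-1], covs_f[-1]
    for d in range(n_days - 1, -1, -1):
        Pp = covs_p[d] + 1e-6 * I6
        Gk = np.linalg.solve(Pp, (F @ covs_f[d].T)).T
        ms[d] = means_f[d] + Gk @ (ms[d + 1] - means_p[d])
        Ps[d] = covs_f[d] + Gk @ (Ps[d + 1] - covs_p[d]) @ Gk.T
    daily_xy = np.array([s[:2] for s in ms])
    return loglik, daily_xy


def fit_crw(ptrack: ProjectedTrack, lc_error: LCErrorTable | None = None) -> CRWFit:
    """Fit the daily CRW state-space model by maximum likelihood.

    Requires >= 4 fixes spanning >= 2 days (the migration filtering
    regime, retaining every LC but Z, should be applied upstream).
    """
    lc_error = lc_error or LCErrorTable.default()
    t_days = np.asarray(ptrack.times, dtype=float) / 86400.0
    obs_xy = np.asarray(ptrack.xy, dtype=float)
    if len(t_days) < 4:
        raise ValueError(f"{ptrack.animal_id}: CRW fit needs >= 4 fixes, got {len(t_days)}")
    span = t_days[-1] - t_days[0]
    if span < 2.0:
        raise ValueError(f"{ptrack.animal_id}: CRW fit needs a span >= 2 days, got {span:.2f}")
    t_days = t_days - t_days[0]
    n_days = int(math.ceil(span))
    obs_sd = np.array([lc_error.error(lc) for lc in ptrack.lcs], dtype=float)

    # moment-based starting values
    disp = np.linalg.norm(np.diff(obs_xy, axis=0), axis=1)
    dts = np.maximum(np.diff(t_days), 1e-6)
    v_typ = max(float(np.median(disp / dts)), 100.0)  # m/day

    best = {"nll": np.inf, "theta": None}

    def nll(theta):
        g = 1.0 / (1.0 + np.exp(-theta[0]))
        sp = np.exp(theta[1])
        k = np.exp(theta[2])
        if not np.isfinite(sp) or sp > 1e7:
            return 1e12
        ll, _ = _kalman(t_days, obs_xy, k * obs_sd, g, sp, n_days)
        val = -ll
        if val < best["nll"]:
            best["nll"], best["theta"] = val, np.array(theta)
        return val if np.isfinite(val) else 1e12

    x0 = np.array([0.0, np.log(v_typ), 0.0])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 2000})
    theta = best["theta"] if best["theta"] is not None else res.x
    converged = bool(res.success)
    if not converged:
        logger.warning("%s: CRW optimizer did not converge; using best point",
                       ptrack.animal_id)

    gamma = float(1.0 / (1.0 + np.exp(-theta[0])))
    sigma_p = float(np.exp(theta[1]))
    k = float(np.exp(theta[2]))
    ll, daily_xy = _kalman(t_days, obs_xy, k * obs_sd, gamma, sigma_p, n_days, smooth=True)

    lon, lat = ptrack.projection.inverse(daily_xy[:, 0], daily_xy[:, 1])
    daily_lonlat = np.column_stack([lon, lat])
    speeds = np.array([
        haversine_km(daily_lonlat[i], daily_lonlat[i + 1]) for i in range(n_days)
    ])
    sd = float(np.std(speeds, ddof=1)) if len(speeds) > 1 else 0.0
    return CRWFit(gamma=gamma, sigma_p=sigma_p, error_scale=k,
                  days=np.arange(n_days + 1), daily_xy=daily_xy,
                  daily_lonlat=daily_lonlat, speeds_kmd=speeds,
                  mean_speed_kmd=float(np.mean(speeds)), sd_speed_kmd=sd,
                  loglik=float(ll), converged=converged)


def speed_stats(fit: CRWFit) -> tuple[float, float]:
    """(mean, sd) of the smoothed daily travel speeds, km/d (sd with n-1)."""
    if len(fit.daily_xy) < 2:
        raise ValueError("need >= 2 daily states")
    return fit.mean_speed_kmd, fit.sd_speed_kmd


def write_daily_path(fit: CRWFit, path) -> None:
    """Daily states as CSV: day,lon,lat,speed_kmd (speed of the step ending that day)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["day", "lon", "lat", "speed_kmd"])
        for d in fit.days:
            spd = "" if d == 0 else f"{fit.speeds_kmd[d - 1]:.4f}"
            w.writerow([int(d), f"{fit.daily_lonlat[d, 0]:.6f}",
                        f"{fit.daily_lonlat[d, 1]:.6f}", spd])
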