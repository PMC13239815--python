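"""Per-fix weights for autocorrelation- and error-aware kernel density.

Serially correlated tracking data over-represent oversampled periods, and
Argos fixes of poor location class carry large positional error. Each fix
therefore receives a two-part weight:

1. an *autocorrelation weight* derived from a fitted Ornstein-Uhlenbeck
   (OU) movement model — the minimum-variance weights ``w ∝ C⁻¹·1`` for
   estimating a mean under the OU correlation matrix
   ``C_ij = exp(-|t_i - t_j|/tau)``, clipped at zero and normalized to sum
   to one per individual, so each animal contributes equally to pooled
   population-level analyses;
2. an *Argos error weight* proportional to the inverse of the mean metric
   error of the fix's location class.

The two are multiplied and renormalized per individual to form the single
KDE weight.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from mpaud.track_io import LocationClass, ProjectedTrack

logger = logging.getLogger(__name__)

#: Mean Argos metric error per location class, meters. Literature-derived
#: defaults (free-ranging sea-turtle ground-truthing studies); LC Z has no
#: published estimate and is assigned the LC B value. Override via
#: LCErrorTable.from_csv.
DEFAULT_LC_ERRORS_M = {
    LocationClass.LC3: 490.0,
    LocationClass.LC2: 1010.0,
    LocationClass.LC1: 1200.0,
    LocationClass.LC0: 4180.0,
    LocationClass.A: 6190.0,
    LocationClass.B: 10280.0,
    LocationClass.Z: 10280.0,
}


@dataclass(frozen=True)
class LCErrorTable:
    """Mapping from location class to mean metric error (meters)."""

    errors_m: dict[LocationClass, float]

    def __post_init__(self) -> None:
        for lc, err in self.errors_m.items():
            if not err > 0:
                raise ValueError(f"error for LC {lc} must be > 0, got {err}")
        ranks = sorted(self.errors_m, key=lambda lc: lc.accuracy_rank)
        vals = [self.errors_m[lc] for lc in ranks if lc is not LocationClass.Z]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("LC errors must be non-decreasing from LC 3 to LC B")

    @classmethod
    def default(cls) -> "LCErrorTable":
        return cls(dict(DEFAULT_LC_ERRORS_M))

    @classmethod
    def from_csv(cls, path) -> "LCErrorTable":
        """Read a 2-column CSV with header ``lc,error_m``."""
        errors: dict[LocationClass, float] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                errors[LocationClass.parse(row["lc"])] = float(row["error_m"])
        return cls(errors)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["lc", "error_m"])
            for lc in sorted(self.errors_m, key=lambda lc: lc.accuracy_rank):
                writer.writerow([lc.value, self.errors_m[lc]])

    def error(self, lc: LocationClass) -> float:
        try:
            return self.errors_m[lc]
        except KeyError:
            raise KeyError(f"location class {lc.value} missing from error table") from None


@dataclass
class OUFit:
    """Maximum-likelihood isotropic Ornstein-Uhlenbeck fit.

    mu: stationary center (m); sigma2: stationary per-axis variance (m²);
    tau: autocorrelation timescale (s). tau=0 denotes the IID limit.
    """

    mu: np.ndarray
    sigma2: float
    tau: float
    loglik: float
    converged: bool
    degenerate: bool = False


_SIGMA2_FLOOR = 1e-6  # m²; guards the all-points-coincident case


def _ou_profile_loglik(tau: float, times: np.ndarray, xy: np.ndarray):
    """Profile log-likelihood of the OU model at fixed tau.

    mu is profiled by GLS and sigma2 in closed form, per axis with shared
    (sigma2, tau) across x/y. Uses the Markov sequential factorization:
    x_1 ~ N(mu, sigma2); x_{i+1}|x_i ~ N(mu + phi_i (x_i - mu),
    sigma2 (1 - phi_i^2)), phi_i = exp(-dt_i / tau).
    """
    n = len(times)
    dt = np.diff(times)
    if tau <= 0:
        phi = np.zeros_like(dt)
    else:
        phi = np.exp(-dt / tau)
    phi = np.clip(phi, 0.0, 1.0 - 1e-12)
    v = 1.0 - phi**2  # transition variance / sigma2

    # GLS for mu: residual_i = (x_{i+1} - phi_i x_i) - mu (1 - phi_i),
    # var sigma2 v_i; plus the stationary first term x_1 - mu, var sigma2.
    a = np.concatenate([[1.0], 1.0 - phi])  # coefficient on mu
    denom = np.concatenate([[1.0], v])
    mu = np.empty(2)
    ss = 0.0
    for axis in range(2):
        x = xy[:, axis]
        b = np.concatenate([[x[0]], x[1:] - phi * x[:-1]])
        w = a / denom
        mu[axis] = float(np.dot(w, b) / np.dot(w, a))
        resid = b - mu[axis] * a
        ss += float(np.sum(resid**2 / denom))
    # sigma2 MLE over both axes (2n standardized residuals)
    sigma2 = max(ss / (2 * n), _SIGMA2_FLOOR)
    loglik = -n * np.log(2 * np.pi * sigma2) - np.sum(np.log(denom)) - ss / (2 * sigma2)
    return loglik, mu, sigma2


def fit_ou(ptrack: ProjectedTrack) -> OUFit:
    """Fit an isotropic OU model by maximum likelihood.

    mu and sigma2 are profiled analytically, leaving a bounded 1-D search
    over log tau (coarse grid multistart, then local refinement) — robust
    for tracks as short as a handful of fixes.
    """
    times = np.asarray(ptrack.times, dtype=float)
    xy = np.asarray(ptrack.xy, dtype=float)
    if len(times) < 5:
        raise ValueError(
            f"{ptrack.animal_id}: OU fit needs >= 5 fixes (got {len(times)}); "
            "use the IID fallback (tau=0) via autocorr_weights"
        )
    if len(np.unique(times)) < 2:
        raise ValueError(f"{ptrack.animal_id}: OU fit needs >= 2 distinct fix times")

    if np.allclose(xy, xy[0], atol=1e-9):
        return OUFit(mu=xy[0].copy(), sigma2=_SIGMA2_FLOOR, tau=0.0,
                     loglik=np.nan, converged=True, degenerate=True)

    dt = np.diff(times)
    dt_pos = dt[dt > 0]
    lo = max(np.min(dt_pos) / 100.0, 1e-3)
    hi = (times[-1] - times[0]) * 100.0

    def neg_ll(log_tau: float) -> float:
        ll, _, _ = _ou_profile_loglik(np.exp(log_tau), times, xy)
        return -ll

    grid = np.linspace(np.log(lo), np.log(hi), 25)
    vals = [neg_ll(g) for g in grid]
    best = int(np.argmin(vals))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, len(grid) - 1)]
    converged = True
    try:
        res = optimize.minimize_scalar(neg_ll, bounds=(a, b), method="bounded",
                                       options={"xatol": 1e-6})
        log_tau = res.x if res.fun <= vals[best] else grid[best]
        converged = bool(res.success)
    except Exception:  # pragma: no cover - optimizer pathologies
        log_tau = grid[best]
        converged = False

    tau = float(np.exp(log_tau))
    loglik, mu, sigma2 = _ou_profile_loglik(tau, times, xy)
    # tau at the lower search bound: indistinguishable from white noise
    if log_tau <= np.log(lo) + 1e-9:
        tau = min(tau, float(np.min(dt_pos)) / 100.0)
    return OUFit(mu=mu, sigma2=sigma2, tau=tau, loglik=float(loglik), converged=converged)


def autocorr_weights(fit: OUFit | None, times: np.ndarray) -> np.ndarray:
    """Minimum-variance autocorrelation weights, summing to one.

    ``w ∝ C⁻¹·1`` with ``C_ij = exp(-|t_i - t_j|/tau)``; negative entries
    are clipped to zero and the vector renormalized. ``fit=None`` or
    ``tau=0`` is the IID fallback giving uniform ``1/n``.
    """
    times = np.asarray(times, dtype=float)
    n = len(times)
    if n == 0:
        raise ValueError("autocorr_weights needs at least one fix")
    if n == 1:
        return np.array([1.0])
    tau = 0.0 if fit is None else float(fit.tau)
    if tau <= 0:
        return np.full(n, 1.0 / n)
    C = np.exp(-np.abs(times[:, None] - times[None, :]) / tau)
    ones = np.ones(n)
    try:
        w = linalg.solve(C, ones, assume_a="pos")
    except linalg.LinAlgError:
        logger.info("correlation matrix singular (duplicate times?); adding 1e-8 jitter")
        w = linalg.solve(C + 1e-8 * np.eye(n), ones, assume_a="pos")
    w = np.clip(w, 0.0, None)
    total = w.sum()
    if total <= 0:  # pathological: fall back to uniform
        return np.full(n, 1.0 / n)
    return w / total


def argos_error_weights(lcs: list[LocationClass], table: LCErrorTable) -> np.ndarray:
    """Inverse-error weights, scaled so the most accurate class present is 1."""
    if not lcs:
        raise ValueError("argos_error_weights needs at least one fix")
    inv = np.array([1.0 / table.error(lc) for lc in lcs])
    return inv / inv.max()


@dataclass
class WeightedFixSet:
    """Planar fixes with their autocorrelation, error and combined weights."""

    animal_id: str
    xy: np.ndarray
    w_auto: np.ndarray
    w_error: np.ndarray
    w: np.ndarray  # normalized product, sums to 1 per individual


def combine_weights(animal_id: str, xy: np.ndarray, w_auto: np.ndarray,
                    w_error: np.ndarray) -> WeightedFixSet:
    """Multiply the two weights and renormalize to sum to one per animal.

    The per-individual renormalization means each of k pooled animals
    contributes total weight 1 (the population pool sums to k).
    """
    w_auto = np.asarray(w_auto, dtype=float)
    w_error = np.asarray(w_error, dtype=float)
    if w_auto.shape != w_error.shape:
        raise ValueError(f"weight length mismatch: {w_auto.shape} vs {w_error.shape}")
    w = w_auto * w_error
    total = w.sum()
    if total <= 0:
        raise ValueError("combined weights sum to zero")
    return WeightedFixSet(animal_id=animal_id, xy=np.asarray(xy, dtype=float),
                          w_auto=w_auto, w_error=w_error, w=w / total)


def weights_for_track(ptrack: ProjectedTrack, table: LCErrorTable | None = None) -> WeightedFixSet:
    """Convenience: OU fit (with IID fallback below 5 fixes) → combined weights."""
    table = table or LCErrorTable.default()
    try:
        fit = fit_ou(ptrack)
    except ValueError:
        fit = None
    w_auto = autocorr_weights(fit, ptrack.times)
    w_err = argos_error_weights(ptrack.lcs, table)
    return combine_weights(ptrack.animal_id, ptrack.xy, w_auto, w_err)
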