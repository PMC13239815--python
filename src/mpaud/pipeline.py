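"""Config-driven orchestration: filter → project → fit → weights →
bandwidth sweep → UDs → MPA containment, plus the migration branch.

Every intermediate (filtered fixes, OU fits, weights, UD grid, contours,
containment table) is persisted under the output directory so each report
number is recomputable; reruns with the same config and inputs are
deterministic.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from mpaud._version import __version__ as _version
from mpaud.track_io import (
    AzimuthalEquidistant,
    Track,
    filter_fixes,
    haversine_km,
    project,
    read_fixes,
    write_fixes,
)
from mpaud.movement_weights import (
    LCErrorTable,
    autocorr_weights,
    argos_error_weights,
    combine_weights,
    fit_ou,
)
from mpaud.ud_estimation import (
    DEFAULT_CELL_M,
    DEFAULT_EXTENT,
    GridSpec,
    SWEEP_STEP_M,
    select_bandwidth,
    ud_contour,
    weighted_kde,
)
from mpaud.containment import percent_contained, read_boundary
from mpaud.migration_crw import fit_crw, mean_fix_interval, raw_speed_stats, write_daily_path

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for one analysis run."""

    fixes_csv: str
    outdir: str
    boundary_geojson: str | None = None
    lc_error_csv: str | None = None
    # projection: None = azimuthal equidistant on the pooled fix centroid
    proj_lon0: float | None = None
    proj_lat0: float | None = None
    # fixed working extent, meters
    extent_width_m: float = DEFAULT_EXTENT[0]
    extent_height_m: float = DEFAULT_EXTENT[1]
    cell_m: float = DEFAULT_CELL_M
    # bandwidth sweep
    h_start_m: float | None = None  # None = weighted Silverman, rounded up
    h_min_m: float = SWEEP_STEP_M
    sweep_step_m: float = SWEEP_STEP_M
    ud_levels: tuple[float, ...] = (0.5, 0.9)
    # residency assignment: explicit list wins over the displacement rule
    migrant_ids: list[str] | None = None
    displacement_threshold_km: float = 50.0
    seed: int = 0
    csv_dialect: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in self.ud_levels:
            if not 0.0 < p < 1.0:
                raise ValueError(f"UD level {p} outside (0, 1)")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load from YAML or JSON."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        data.update(overrides)
        if "ud_levels" in data:
            data["ud_levels"] = tuple(data["ud_levels"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def error_table(self) -> LCErrorTable:
        if self.lc_error_csv:
            return LCErrorTable.from_csv(self.lc_error_csv)
        return LCErrorTable.default()


@dataclass
class RunReport:
    """Run summary; every number is recomputable from persisted files."""

    version: str
    config_hash: str
    per_animal: dict
    population: dict
    migration: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=_json_default)

    def summary_lines(self) -> list[str]:
        lines = [f"mpaud {self.version} run {self.config_hash}"]
        n_raw = sum(a["n_raw"] for a in self.per_animal.values())
        n_kept = sum(a["n_filtered"] for a in self.per_animal.values())
        if n_raw:
            lines.append(
                f"fixes: {n_raw} raw, {n_kept} retained "
                f"({100.0 * (n_raw - n_kept) / n_raw:.0f}% excluded)"
            )
        pop = self.population
        if pop:
            lines.append(
                f"population bandwidth: {pop['chosen_h_m']:.0f} m ({pop['rule']})"
            )
            for c in pop.get("containment", []):
                lines.append(
                    f"  {int(round(c['level'] * 100))}% UD: {c['contour_km2']:.2f} km², "
                    f"{c['percent_contained']:.1f}% inside MPA"
                )
        if self.migration:
            m = self.migration
            lines.append(
                f"migrant {m['animal_id']}: mean speed {m['mean_speed_kmd']:.2f} "
                f"± {m['sd_speed_kmd']:.2f} km/d (smoothed), "
                f"{m['raw_mean_speed_kmd']:.2f} ± {m['raw_sd_speed_kmd']:.2f} km/d (raw); "
                f"mean fix interval {m['mean_fix_interval_days']:.2f} d"
            )
        return lines


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def classify_residency(tracks: list[Track], threshold_km: float = 50.0,
                       explicit_migrants: list[str] | None = None) -> dict[str, str]:
    """Label each track ``resident`` or ``migrant``.

    Default rule: migrant iff net displacement from the first fix exceeds
    the threshold and keeps increasing (non-decreasing within a 5-km
    slack) over the final third of fixes. An explicit migrant list
    overrides the rule.
    """
    labels: dict[str, str] = {}
    for track in tracks:
        if explicit_migrants is not None:
            labels[track.animal_id] = (
                "migrant" if track.animal_id in explicit_migrants else "resident"
            )
            continue
        if len(track) < 2:
            logger.warning("%s: too few fixes to classify; defaulting to resident",
                           track.animal_id)
            labels[track.animal_id] = "resident"
            continue
        ll = track.lonlat()
        disp = np.array([haversine_km(ll[0], p) for p in ll])
        final = disp[max(len(disp) - max(len(disp) // 3, 2), 0):]
        increasing = bool(np.all(np.diff(final) > -5.0) and final[-1] > final[0])
        labels[track.animal_id] = (
            "migrant" if disp[-1] > threshold_km and increasing else "resident"
        )
    return labels


def run_residency(config: RunConfig) -> RunReport:
    """Execute the residency analysis end-to-end and persist intermediates."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = config.error_table()

    tracks = read_fixes(config.fixes_csv, dialect=config.csv_dialect or None)
    tracks.sort(key=lambda t: t.animal_id)
    if not tracks:
        raise ValueError("no tracks in input")

    labels = classify_residency(tracks, config.displacement_threshold_km,
                                config.migrant_ids)
    residents = [t for t in tracks if labels[t.animal_id] == "resident"]
    if not residents:
        raise ValueError(
            "no resident tracks after classification "
            f"(rule: threshold {config.displacement_threshold_km} km, "
            f"explicit list {config.migrant_ids})"
        )

    per_animal: dict[str, dict] = {}
    filtered: list[Track] = []
    for track in tracks:
        ft = filter_fixes(track, "home_range")
        entry = {
            "label": labels[track.animal_id],
            "n_raw": len(track),
            "n_filtered": len(ft),
            "pct_excluded": (100.0 * (len(track) - len(ft)) / len(track)) if len(track) else 0.0,
            "lc_counts_raw": track.lc_counts(),
        }
        per_animal[track.animal_id] = entry
        if labels[track.animal_id] == "resident" and len(ft) > 0:
            filtered.append(ft)
    if not filtered:
        raise ValueError("stage filter: no resident fixes retained under home_range regime")

    write_fixes(filtered, outdir / "filtered_home_range.csv", regime="home_range")

    # shared working projection: centroid of the retained resident fixes
    all_ll = np.vstack([t.lonlat() for t in filtered])
    if config.proj_lon0 is not None and config.proj_lat0 is not None:
        proj = AzimuthalEquidistant(config.proj_lon0, config.proj_lat0)
    else:
        proj = AzimuthalEquidistant(float(all_ll[:, 0].mean()), float(all_ll[:, 1].mean()))

    # per-animal OU fits and weights
    pool_xy, pool_w = [], []
    ou_rows, weight_rows = [], []
    for t in filtered:
        pt = project(t, crs=proj)
        try:
            fit = fit_ou(pt)
        except ValueError:
            fit = None
            logger.info("%s: <5 fixes, IID autocorrelation fallback", t.animal_id)
        w_auto = autocorr_weights(fit, pt.times)
        w_err = argos_error_weights(pt.lcs, table)
        wset = combine_weights(t.animal_id, pt.xy, w_auto, w_err)
        pool_xy.append(wset.xy)
        pool_w.append(wset.w)
        per_animal[t.animal_id].update({
            "ou_tau_s": None if fit is None else fit.tau,
            "ou_sigma2_m2": None if fit is None else fit.sigma2,
        })
        ou_rows.append([t.animal_id,
                        "" if fit is None else f"{fit.mu[0]:.1f}",
                        "" if fit is None else f"{fit.mu[1]:.1f}",
                        "" if fit is None else f"{fit.sigma2:.1f}",
                        "" if fit is None else f"{fit.tau:.1f}",
                        "" if fit is None else str(fit.converged)])
        for i in range(len(wset.w)):
            weight_rows.append([t.animal_id, f"{wset.xy[i, 0]:.2f}", f"{wset.xy[i, 1]:.2f}",
                                f"{wset.w_auto[i]:.8g}", f"{wset.w_error[i]:.8g}",
                                f"{wset.w[i]:.8g}"])

    _write_csv(outdir / "ou_fits.csv",
               ["animal_id", "mu_x_m", "mu_y_m", "sigma2_m2", "tau_s", "converged"], ou_rows)
    _write_csv(outdir / "weights.csv",
               ["animal_id", "x_m", "y_m", "w_auto", "w_error", "w"], weight_rows)

    points = np.vstack(pool_xy)
    weights = np.concatenate(pool_w)

    # fixed extent centered on the weighted centroid of the pool
    cx, cy = np.average(points, axis=0, weights=weights)
    spec = GridSpec.centered_on(float(cx), float(cy), config.extent_width_m,
                                config.extent_height_m, config.cell_m)

    sel = select_bandwidth(points, weights, spec, h_start=config.h_start_m,
                           h_min=config.h_min_m, step=config.sweep_step_m)
    grid = weighted_kde(points, weights, spec, sel.chosen_h)
    grid.to_csv(outdir / "population_ud.csv")

    boundary = read_boundary(config.boundary_geojson) if config.boundary_geojson else None
    containment = []
    for p in sorted(config.ud_levels):
        contour = ud_contour(grid, p)
        contour.to_geojson(outdir / f"population_ud_{int(round(100 * p))}.geojson",
                           projection=proj)
        if boundary is not None:
            res = percent_contained(contour, boundary, proj)
            containment.append({
                "level": p,
                "contour_km2": res.contour_km2,
                "intersect_km2": res.intersect_km2,
                "percent_contained": res.percent_contained,
            })
    if containment:
        _write_csv(outdir / "containment.csv",
                   ["level", "contour_km2", "intersect_km2", "percent"],
                   [[c["level"], f"{c['contour_km2']:.4f}", f"{c['intersect_km2']:.4f}",
                     f"{c['percent_contained']:.1f}"] for c in containment])

    population = {
        "n_residents": len(filtered),
        "pool_size": int(len(points)),
        "chosen_h_m": sel.chosen_h,
        "rule": sel.rule,
        "floor_reached": sel.floor_reached,
        "sweep_candidates_m": sel.candidates,
        "sweep_n_components": sel.n_components,
        "containment": containment,
        "projection": proj.spec(),
        "extent_m": [config.extent_width_m, config.extent_height_m],
        "cell_m": config.cell_m,
    }

    report = RunReport(version=_version, config_hash=config.config_hash(),
                       per_animal=per_animal, population=population)
    report.to_json(outdir / "report.json")
    for line in report.summary_lines():
        logger.info(line)
    return report


def run_migration(config: RunConfig, animal_id: str) -> dict:
    """Fit the daily CRW to one migratory track; returns a report fragment."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = config.error_table()
    tracks = {t.animal_id: t for t in read_fixes(config.fixes_csv,
                                                 dialect=config.csv_dialect or None)}
    if animal_id not in tracks:
        raise ValueError(f"animal {animal_id!r} not found in {config.fixes_csv}")
    track = tracks[animal_id]

    labels = classify_residency([track], config.displacement_threshold_km,
                                config.migrant_ids)
    if labels[animal_id] != "migrant":
        logger.warning("%s does not meet the migrant displacement rule; fitting anyway",
                       animal_id)

    ft = filter_fixes(track, "migration")
    if len(ft) < 4:
        raise ValueError(f"{animal_id}: {len(ft)} migration-regime fixes; need >= 4")
    pt = project(ft)  # own centroid frame: the track spans far beyond the UD extent
    fit = fit_crw(pt, lc_error=table)
    write_daily_path(fit, outdir / f"migration_{animal_id}_daily.csv")
    raw_mean, raw_sd = raw_speed_stats(ft)
    fragment = {
        "animal_id": animal_id,
        "n_fixes": len(ft),
        "mean_fix_interval_days": mean_fix_interval(ft),
        "gamma": fit.gamma,
        "sigma_p_m_per_day": fit.sigma_p,
        "error_scale": fit.error_scale,
        "n_daily_states": int(len(fit.daily_xy)),
        "mean_speed_kmd": fit.mean_speed_kmd,
        "sd_speed_kmd": fit.sd_speed_kmd,
        "raw_mean_speed_kmd": raw_mean,
        "raw_sd_speed_kmd": raw_sd,
        "converged": fit.converged,
    }
    with open(outdir / f"migration_{animal_id}.json", "w") as fh:
        json.dump(fragment, fh, indent=2, sort_keys=True)
    return fragment


def _write_csv(path, header, rows) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)
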