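# mpaud

Satellite-telemetry spatial-use analysis for marine protected areas
(MPAs): Argos fix filtering, autocorrelation- and error-weighted kernel
utilization distributions with contiguity-based bandwidth selection, MPA
containment percentages, and a daily-step correlated-random-walk
smoother for migratory tracks.

The package is aimed at movement ecologists asking a concrete management
question: *does a protected-area boundary contain the core activity
space of a resident population tracked by Argos?* Argos data are noisy
(kilometre-scale errors for the poorer location classes) and serially
autocorrelated (duty-cycled transmitters oversample some periods), so a
naive KDE over raw fixes misleads. `mpaud` implements the standard
corrective pipeline:

1. **Filter** fixes by location class (LC): home-range analyses keep
   {3, 2, 1, A}; migration analyses drop only Z.
2. **Weight** each fix by the product of (a) minimum-variance
   autocorrelation weights w ∝ C⁻¹·1 from a fitted Ornstein–Uhlenbeck
   movement model (C_ij = exp(−|t_i − t_j|/τ), per-animal weights sum
   to 1) and (b) inverse LC metric error.
3. **Estimate** the utilization distribution (UD) with a weighted
   Gaussian KDE on a fixed 33.7 × 19.3 km extent; extract p-level
   isopleths as highest-density cell regions; select the bandwidth by
   descending 250-m steps until the 50% UD fragments.
4. **Overlay** the 50%/90% UD polygons on the MPA boundary and report
   percent containment by area.
5. For the **migrant**, fit a linear-Gaussian correlated random walk
   (x_d = x_{d−1} + v_d, v_d = γv_{d−1} + η) by maximum likelihood and
   smooth one position per day, reporting travel speed (mean ± sd km/d).

A fully seeded synthetic-data module generates island scenarios with
known ground truth (resident OU movement, a southward migrant, 6-h duty
cycling, a B-dominated LC mix), so the entire pipeline is testable
without any data download. See `docs/methods.md` for the models and
design decisions.

## Worked example

```sh
mpaud simulate --seed 3 --outdir demo
cat > demo/run.yaml <<EOF
fixes_csv: demo/fixes.csv
boundary_geojson: demo/boundary.geojson
outdir: demo/run
seed: 3
EOF
mpaud run --config demo/run.yaml
mpaud migrate --config demo/run.yaml --animal-id migrant_10
```

The run prints:

```
mpaud 0.1.0 run 15e1b974932e
fixes: 624 raw, 178 retained (71% excluded)
population bandwidth: 750 m (last_contiguous)
  50% UD: 27.60 km², 100.0% inside MPA
  90% UD: 109.14 km², 100.0% inside MPA
```

Read: of 624 simulated Argos fixes, 71% carried location classes too
inaccurate for fine-scale work (0/B/Z) and were excluded. The bandwidth
sweep stopped at 750 m — the last bandwidth at which the population 50%
UD was a single polygon. The core (50%) activity area of 27.6 km² lies
entirely inside the MPA; so does the broader 90% area in this scenario.
The `migrate` command prints the fitted persistence γ, the smoothed
daily path, and mean ± sd travel speed in km/d for the migrant.

The same analysis is available as a library:

```python
from mpaud import RunConfig, run_residency
report = run_residency(RunConfig(fixes_csv="demo/fixes.csv",
                                 boundary_geojson="demo/boundary.geojson",
                                 outdir="demo/run"))
print(report.population["containment"])
```

All intermediates (filtered fixes, OU fits, per-fix weights, UD grid,
contour GeoJSON, containment table, `report.json`) are persisted in the
output directory.

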