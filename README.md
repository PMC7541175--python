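# pathsel — path-selection functions and movement-quality surfaces

`pathsel` turns GPS telemetry of slow, resident animals (its motivating
system is the Mojave desert tortoise, *Gopherus agassizii*) into landscape
resistance maps. It cleans hourly GPS fixes, segments them into movement
paths, matches each observed path with correlated-random-walk availability
paths, fits hierarchical conditional-logistic *path-selection functions*
over natural and anthropogenic covariates, ranks candidate models by WAIC,
and predicts a Movement Quality Index surface from which contiguous
corridors can be extracted. It is aimed at movement ecologists and
connectivity planners who need resistance surfaces grounded in observed
movement rather than habitat suitability alone.

## The model

Each qualifying observed path (≥3 hourly fixes, steps >10 m, total >100 m)
is matched with N = 10 correlated random walks that start at the same
location and take the same number of steps, with step lengths drawn from a
pooled gamma fit and turning angles from a pooled wrapped-normal fit over
*all* observed paths. The observed path plus its random paths form one
stratum (choice set); each path is reduced to the mean of every covariate
raster along its track. The probability that the observed path is the one
taken is conditional-logistic:

```
P(obs | stratum s) = exp(x_obs' β) / Σ_m exp(x_m' β)
```

This likelihood is exactly equivalent to a Poisson regression with one free
intercept per stratum, which is what allows per-animal random selection
coefficients; `pathsel` fits the hierarchical model by maximizing a
Laplace-approximated marginal likelihood and verifies the Poisson
equivalence through an independent GLM route. Covariates are z-scored;
quadratic (`slope^2`) and interaction (`road:wash`) terms are built from
the standardized linear columns. Animals whose home range never intersects
a road/fence/berm/railroad are uninformed about that feature, so its
distance covariate is set missing for them (missing contributes zero to the
linear predictor). Distance-to-feature rasters are log-flattened:
`ln(min(d, 60 m) + 1)`, preserving short-range disturbance effects while
capping influence beyond 60 m. Models are compared by WAIC from
stratum-level pointwise likelihoods. Prediction holds barrier distances at
the far plateau (so barrier-following does not read as good habitat),
exponentiates the centred predictor, and bins it into 10 empirical
quantiles (the MQI).

Because the kind of telemetry that motivates the package cannot be shared,
a first-class synthetic module generates landscapes, choice sets and
agent-based GPS telemetry with known coefficients, so every stage is
testable by exact oracles and parameter recovery.

## Worked example

The numbered scripts under `analysis/` run the whole study on a seeded
synthetic world (they chain through `scratch/analysis/` and write summary
tables to `results/`):

```sh
python analysis/01_simulate_study_system.py 0   # landscape + 30 agents
python analysis/02_clean_telemetry.py 0         # the three GPS filters
python analysis/03_build_paths_and_availability.py 0
python analysis/04_fit_selection_models.py 0    # clogit fit + WAIC ladder
python analysis/05_predict_movement_quality.py 0
```

With seed 0 this prints, among other things (abridged):

```
simulated 35915 hourly fixes for 30 agents on a 100x100 landscape (seed 0)
removed: elevation_error 65 / spike 33 of 35915 fixes
qualifying paths 3382, eligible animals 30
        term  estimate       se   beta_true  sign_recovered
       slope -0.157    0.059        -0.50            True
        wash  0.306    0.056         0.40            True
     habitat  0.573    0.156         0.50            True
        road  0.191    0.042         0.40            True
       fence -1.542    0.055        -0.40            True
...
ladder top model: slope + slope^2 + wash + wash^2 + veg + veg^2 + habitat
                  + road + fence + floodcontrol + rail   (ΔWAIC 0.00)
largest top-quality patch: 118.9 ha, bbox 2790 m long, min width 594 m
```

Reading this: every generating coefficient's sign is recovered (positive
`road` means selection for being *farther* from roads; negative `fence`
means movement concentrates *near* fences — barrier-following), the
generating model form wins the 19-model WAIC ladder, and the MQI surface
yields one large high-quality corridor patch whose minimum width is
estimated from the skeleton of its distance transform.

The same stages are available as a CLI (`pathsel simulate`,
`rasterize-distances`, `clean`, `fit`, `predict`) for file-based use.

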