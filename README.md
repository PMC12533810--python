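# smokewave

Analysis pipeline for short, severe wildfire-smoke PM2.5 episodes: it
quantifies how much of a simulated smoke plume's uncertainty comes from the
choice of wildfire-emissions inventory versus meteorological driver, scores
gridded concentration fields against monitor observations, converts the
episode's concentration change into county-level health burdens and
incidence rate ratios (IRRs), and validates those modeled IRRs against
emergency-department (ED) visit counts. It is aimed at air-quality and
environmental-health modelers who run factorial sensitivity ensembles of a
chemical-transport model and want the downstream uncertainty and
health-impact arithmetic as tested, reusable code rather than ad-hoc
scripts.

## The model

**Factorial uncertainty decomposition.** Given the 2×2 ensemble over
emissions inventory e ∈ {CAMS, QFED} and meteorology m ∈ {FNL, NAM}, the
reference field is the cell-wise ensemble average and the factor
contributions are signed half-sums:

    emis_unc = ½ [(QFED_FNL − CAMS_FNL) + (QFED_NAM − CAMS_NAM)]
    met_unc  = ½ [(CAMS_FNL − CAMS_NAM) + (QFED_FNL − QFED_NAM)]

with relative uncertainty 100·unc/average per cell (masked where the
average is below a floor).

**Health impact.** Per county, with exposure change Δx (episode-mean
µg m⁻³ versus the no-wildfire control), baseline rate y0 (events per
person-day), population Pop, episode length n days, and a log-linear
concentration–response coefficient β:

    ΔY = y0 · Pop · (1 − e^(−β·Δx)) · n,   Var(ΔY) by the delta method in SE(β)

and over any county grouping

    IRR = ΣΔY / Σbaseline + 1,   CI95 = (ΣΔY ± 1.96 √ΣVar)/Σbaseline + 1.

**Validation.** Observed IRR = smoke-day over baseline-day mean daily ED
visits, with a Poisson rate-ratio CI, exp(log IRR ± 1.96·√(1/Σs + 1/Σb)),
compared region-by-region with the modeled IRR.

A synthetic-data module generates every input — factorial Gaussian-plume
ensembles, controls, noisy monitors, county crosswalks, Poisson visit
counts — with known ground truth, so the whole chain is testable without
any external data. See `docs/methods.md` for assumptions, defaults and
limitations.

## Worked example

```python
import smokewave as sw

cfg = sw.SyntheticConfig(seed=1)          # 40x50 grid, 3-day plume episode
ens, controls = sw.make_ensemble(cfg)
avg = sw.ensemble_average(ens)
print(round(float(avg.values.max()), 1))  # 181.6  (peak ensemble-average PM2.5, ug/m3)

emis = sw.factor_uncertainty(ens, "emissions")
import numpy as np
core = np.unravel_index(np.argmax(avg.values), avg.values.shape)
print(sw.round_half_up(float(emis.relative[core])))  # 28.6  (% of ensemble average at the plume core)

profiles, xwalk = sw.make_counties(cfg)
expo = sw.county_exposure(sw.episode_mean(avg, cfg.days),
                          sw.episode_mean(controls[0], cfg.days), xwalk)
hif = sw.HealthImpactFunction("asthma_ed_visits", beta=cfg.beta, beta_se=cfg.beta_se)
burdens = sw.county_burdens(hif, profiles, expo, cfg.n_days)
top = burdens.sort_values("irr", ascending=False).iloc[0]
print(top.county_id, round(top.delta_x, 1), round(top.irr, 3))
# C0202 51.3 1.23  (worst-hit county: +51.3 ug/m3 3-day mean, 23% more asthma ED visits)
```

The peak of 181.6 µg m⁻³ is the plume core in the ensemble-average field;
switching emissions inventories moves the simulation by ~29% of that
average at the core; the hardest-hit county sees a 51 µg m⁻³ episode-mean
exposure increase, which the health impact function converts to an IRR of
1.23 (a 23% rise in asthma ED visits over its baseline).

The same chain is available from a shell:

```sh
smokewave simulate --out-dir fixtures/
smokewave uncertainty --ensemble-dir fixtures/ --factor emissions \
    --days 2023-06-06:2023-06-08 --out emis.nc --report emis.csv
smokewave run-all --config run.yaml --out-dir out/   # full workflow + manifest
```

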