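# pmbod

Comparative burden-of-disease assessment for ambient PM2.5: attributable
deaths and DALYs computed from binned population exposure distributions,
a family of concentration-response curves (shape × relative risk ×
cut-off), endpoint-substitution uncertainty propagation, and a scenario
engine that quantifies the influence of each methodological choice
relative to a reference configuration.

## What it computes

The population attributable fraction (PAF) over a binned exposure
distribution,

    PAF = (Σ RR_i · EF_i − 1) / (Σ RR_i · EF_i)

with the relative risk RR evaluated at each bin's midpoint
concentration, or via the population-weighted-concentration (PWC)
shortcut `PAF = (RR_PWC − 1)/RR_PWC`. Attributable burden is
`AB = PAF × BoD` for deaths, YLL, YLD or DALY. Curve families: linear,
log-linear and log-log (each parameterised by an RR per 10 µg/m³ and a
counterfactual cut-off below which RR ≡ 1), plus tabulated non-linear
curves (GEMM/MR-BRT style) with piecewise-linear interpolation and an
intrinsic cut-off. Uncertainty is propagated by substituting the 2.5%
and 97.5% endpoints of exactly one input category (relative risk,
exposure distribution, or health table) at a time.

## Modules

| module | contents |
| --- | --- |
| `pmbod.exposure` | binned distributions, PWC, shifting, PWC collapse, CSV I/O |
| `pmbod.curves` | the four curve families, cut-off semantics, curve CSV I/O |
| `pmbod.attribution` | PAF, attributable burden per cause, DALY decomposition, health tables |
| `pmbod.uncertainty_scenarios` | endpoint substitution, percent changes, the scenario grid |
| `pmbod.synthetic_data` | seeded generators for exposure, health tables and tabulated curves |
| `pmbod.config` / `pmbod.cli` | JSON/YAML run configs and the `pmbod` command |

## CLI

```sh
# synthetic dataset (exposure.csv, health_gbd.csv, health_registry.csv, curves)
pmbod simulate --out data/ --seed 1 --pwc 5.0

# single scenario -> per-cause attributable burden
pmbod compute --config run.yaml --out results.csv

# scenario grid -> percent-change ledger vs the reference scenario
pmbod scenarios --config grid.yaml --out ledger.csv --uncertainty rr

# check a config resolves without running it
pmbod validate --config grid.yaml
```

Exit codes: 0 success, 2 configuration error, 3 data error. A scenario
block looks like

```yaml
scenarios:
  - id: reference
    exposure: {synthetic: {target_pwc: 5.0, seed: 1}}   # or {path: exposure.csv} or {pwc: 5.0, pwc_lo: 4.0, pwc_hi: 6.0}
    curve: {shape: linear, rr10: 1.08, rr10_lo: 1.03, rr10_hi: 1.13, cutoff: 0}
    health: {synthetic: {}}                             # or {path: health.csv, source: GBD}
    measure: deaths
reference: reference
```

Per-cause curve sets use `curves: {IHD: {...}, stroke: {...}}`;
tabulated curves use `curve: {table: curve_gemm.csv, cutoff: 2.4}`.

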