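# microstab

Temporal-stability analysis of longitudinal microbiome profiles.

Given a subject's taxa × time abundance table, `microstab` quantifies how
stable that microbiota is, using the statistics of its abundance
fluctuations rather than its composition:

- **Fluctuation scaling (Taylor's law).** Across taxa, the temporal standard
  deviation of relative abundance follows a power law σ = V·x̄^β. The
  exponent β identifies the fluctuation class (β = 1/2 Poisson-like,
  β = 1 exponential-like); the amplitude V is the fluctuation level a
  hypothetically dominant taxon would attain. Both are fitted with an
  errors-in-variables bootstrap that propagates the per-taxon SEM of the
  mean axis (`fit_taylor_xweighted`), with a deterministic
  inverse-regression alternative (`fit_taylor_inversion`).
- **Healthy-zone standardization.** Within a study, the healthy subjects'
  (V, β) values are reduced with inverse-variance weights to a reference
  mean and SD; every subject is then mapped to z-scores. By construction the
  healthy group has weighted mean 0 and weighted SD 1, so zone radii
  (1.0 ≈ 68%, 2.8 ≈ 98%) are comparable across studies
  (`standardize_study`, `zone_membership`).
- **Stochastic community model.** A Langevin equation
  ẋᵢ = Fᵢxᵢ^α + Vxᵢ^β ξᵢ − φ(t)xᵢ with a normalization drift conserving
  Σxᵢ = 1 links the fitted fluctuation parameters to community dynamics.
  The stationary Fokker–Planck density P₀(x) is computed in closed form up
  to normalization; its interior maximum exists only above a critical
  fitness, separating an **ordered** (stable) from a **disordered**
  (noise-dominated) phase (`simulate`, `steady_state_pdf`,
  `classify_phase`). Fitness can be inferred back from an observed series
  by stationary-likelihood maximization (`infer_fitness`).
- **Rank dynamics.** A rank stability index
  RSI = (1 − D/((N−1)(t−1)))^p summarizes how much a taxon's abundance rank
  wanders (D = cumulative absolute rank displacement), with per-timepoint
  rank variability (RV), difference variability (DV) and detection of
  mid-rank "stability islands" (`rank_report`, `stability_islands`).
- **Sliding windows.** Short-window Taylor fits resolve V and β in time and
  localize transient instability such as an antibiotic course
  (`sliding_taylor`).
- **Synthetic data.** Generators for Poisson, exponential and exact
  power-law communities and for full Langevin cohorts with multinomial
  sequencing noise (`gen_langevin_cohort`) support validation end to end.

## Worked example

Fit Taylor's law on a synthetic Poisson community (50 taxa, means spanning
four decades, 100 timepoints) — the exponent must come out at 1/2:

```python
import numpy as np
from microstab import gen_poisson_community, compute_stats, fit_taylor_xweighted

table = gen_poisson_community(np.geomspace(10, 1e5, 50), n_timepoints=100, seed=1)
stats = compute_stats(table)
fit = fit_taylor_xweighted(stats, n_replicates=1000, seed=7)
print(f"V    = {fit.V:.4g} +- {fit.err_V:.2g}")
print(f"beta = {fit.beta:.4g} +- {fit.err_beta:.2g}")
print(f"r2   = {fit.r2:.4f}")
```

```
V    = 1.027 +- 0.0038
beta = 0.4958 +- 0.00042
r2   = 0.9973
```

Classify a community state on the phase diagram (α = β = 0.75, dominant
taxon, where the phase line is F = 3V²):

```python
from microstab import classify_phase

diag = classify_phase(0.75, 0.75, F=2.0, V=0.2)
print(diag.phase, f"F_crit={diag.F_crit:.3f}", f"x_M={diag.x_M:.4f}")
```

```
ordered F_crit=0.120 x_M=0.9404
```

The same operations are available from the command line:

```sh
microstab taylor --input subject.tsv --metadata metadata.tsv --out fit.json
microstab phase --alpha 0.75 --beta 0.75 --f 2.0 --v 0.2
microstab run --config study.yaml     # full pipeline with manifest
```

## Layout

- `src/microstab/` — library: `abundance` (tables, stats, IO),
  `taylor` (fits), `standardize` (z-space), `langevin`
  (simulation, Fokker–Planck, phase, fitness inference), `ranks`,
  `windows`, `synthetic` (generators), `pipeline` + `cli`.
- `analysis/` — numbered driver scripts over the library.
- `tests/` — pytest suite, including end-to-end validation of the
  universal and analytic claims in `tests/test_acceptance.py`.
- `docs/methods.md` — models, estimators, numerical choices, limitations.
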