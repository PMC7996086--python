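# commoccu

Hierarchical community occupancy modelling of camera-trap surveys.

`commoccu` turns raw camera-trap tables (photographic records, station
deployments, cell covariates) into weekly detection histories, screens
habitat covariates with single-season occupancy MLEs ranked by a
community-level AICc, fits a multi-species hierarchical Bayesian occupancy
model with a purpose-built Metropolis-within-Gibbs sampler, and derives
species-richness surfaces, occupied-area fractions, block summaries and
predator–prey correlations from the posterior of the latent occurrence
states. A synthetic-data generator with known community hyperparameters
supports end-to-end validation by parameter recovery.

The scientific setting is grid-based surveys of medium and large mammal
communities — the packaged species register covers 25 Mesoamerican species
including jaguar and puma and their prey — where imperfect detection makes
naive occupancy misleading, and where interest centres on community-level
effects of habitat covariates (forest cover, human presence, EVI, distance
to protected areas, terrain ruggedness) and on how prey richness
co-varies with the big cats' habitat use. Because large mammals range
widely, occupancy is interpreted as probability of *habitat use*. See
[docs/methods.md](docs/methods.md) for the full model specification,
priors, sampler design and known limitations.

## Worked example

Simulate a small 12-species survey, screen covariates, fit the community
model, and compare derived richness against the generating truth:

```python
import dataclasses
import numpy as np
import commoccu as co

sc = dataclasses.replace(co.toy_scenario(), n_species=12)
ds = co.simulate_community(sc, seed=1)
summary = co.survey_summary(ds.deployments, ds.grid())
print(f"trap nights: {summary.total_trap_nights}, "
      f"stations: {summary.n_stations}, "
      f"cells surveyed: {summary.n_cells_surveyed}/{summary.n_cells_total} "
      f"({summary.percent_surveyed}%)")

tensor, cov = ds.to_tensor()
print("detection tensor:", tensor.y.shape)

ranking = co.select_models(tensor, cov, starts=2, seed=1)
print(ranking[["model_id", "K", "AICc", "delta_AICc"]].head(3).to_string(index=False))

data = co.CommunityData.from_tensors(tensor, cov)
cfg = co.ChainConfig(n_chains=2, n_iter=2000, burn_in=500, thin=2, seed=1)
post = co.run_mcmc(data, config=cfg)
print(post.hyper_summary()[["parameter", "mean", "cri95_low", "cri95_high",
                            "rhat"]].head(6).to_string(index=False))

subs = co.prey_subsets(ds.species)
rich = co.richness_from_z(post.z_draws(), subs["all_native"],
                          post.species, post.cells)
print("native richness by cell:", np.round(rich.cell_means, 2).tolist())
print("generating-truth richness:", ds.truth.z.sum(axis=0).tolist())
```

Output:

```
trap nights: 313, stations: 12, cells surveyed: 6/8 (75.0%)
detection tensor: (12, 6, 4)
                             model_id  K       AICc  delta_AICc
psi(forest+human_presence)p(1+effort)  5 178.629498    0.000000
               psi(forest)p(1+effort)  4 185.902572    7.273074
       psi(human_presence)p(1+effort)  4 202.298827   23.669328
                parameter      mean  cri95_low  cri95_high     rhat
                    mu_xi  0.913337  -0.848525    2.919629 1.036863
                   tau_xi  1.048789   0.023391   10.388496 1.346142
         mu_alpha[forest]  1.313725  -0.688620    3.361217 1.039829
 mu_alpha[human_presence] -2.009647  -3.921921   -0.177597 1.092206
        tau_alpha[forest]  0.738503   0.026363    6.200913 1.023274
tau_alpha[human_presence]  2.280523   0.043717   14.650925 1.003146
native richness by cell: [3.05, 10.4, 4.55, 7.35, 7.04, 7.71]
generating-truth richness: [3, 9, 4, 7, 7, 5]
```

(The chains in this deliberately tiny example are short; at these lengths
some precision parameters still show R-hat > 1.1, which the report stage
flags. The derived richness already tracks the generating truth.)

## Command-line pipeline

```bash
# generate a synthetic study-scale dataset
commoccu simulate --scenario study --seed 1 --out data/

# run the full pipeline: prepare -> select -> fit -> derive -> report
commoccu run --data-dir data/ --seed 1 --out out/

# or stop after any stage, with settings from a YAML config
commoccu fit --config analysis.yml --data-dir data/ --out out/
```

Every run writes `manifest.json` (package and library versions, seed,
effective configuration, SHA-256 input checksums, stage timings) next to
the stage outputs: detection histories, effort matrix, AICc ranking,
compressed posterior draws, posterior summaries, richness-by-cell and
richness-by-block tables, occupied-area fractions, predator–prey
correlations, and report tables with convergence flags.

## Package layout

| module | contents |
|---|---|
| `commoccu.survey_data` | record/deployment/covariate containers, independence filtering, detection histories, effort, survey summaries |
| `commoccu.model_selection` | single-season occupancy likelihood and MLE, candidate-model enumeration under a collinearity threshold, community AICc ranking |
| `commoccu.community_mcmc` | the hierarchical community model, Metropolis-within-Gibbs sampler, R-hat, posterior containers |
| `commoccu.derived_quantities` | richness surfaces, area fractions, block summaries, predator–prey correlations |
| `commoccu.synthetic_data` | scenario definitions and the survey generator with known truth |
| `commoccu.cli` | pipeline orchestration, YAML config, manifest, `commoccu` command |
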