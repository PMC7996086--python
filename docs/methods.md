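# Methods

This document specifies the statistical models implemented in `commoccu`,
the meaning, units and defaults of every user-facing parameter, the design
of the synthetic-data generator, and the numerical choices made in the
samplers and optimizers.

## 1. Data model

The package analyses camera-trap surveys laid out on a grid of equal-area
cells (default 16 km² per cell), grouped into *survey blocks* that may be
run in different field seasons. Within each surveyed cell, one or more
camera stations operate over a deployment interval. The raw inputs are
four tables:

- **records** — one row per photographic event: `station_id`,
  `species_code`, `timestamp`, `count`.
- **deployments** — one row per station: `station_id`, `cell_id`,
  `on_trail`, `active_start`, `active_end` (dates, inclusive).
- **covariates** — one row per surveyed cell: `cell_id`, `block`, plus
  one column per habitat covariate on its raw scale.
- **species** — the species register: `species_code`, `common_name`,
  `size_class` (`medium`/`large`), `native`, `jaguar_prey`, `puma_prey`
  (0/1 flags). A packaged register of 25 Mesoamerican medium/large
  mammals is the default.

### Detection histories

Records are collapsed into weekly *occasions* (default `occasion_length =
7` days). Occasions are indexed per block from that block's earliest
deployment start, so blocks surveyed in different seasons align on
occasion number rather than calendar date. The detection history
`y[i, j, k]` for species `i`, cell `j`, occasion `k` is:

- `1` if any station in the cell recorded the species in that week,
- `0` if at least one station was active but none recorded it,
- `NA` if no station in the cell was active (zero trap nights).

The `NA` ⇔ zero-effort duality is enforced structurally by the
`DetectionHistoryTensor` container. Effort `effort[j, k]` is the number of
trap nights (station-nights) in the cell-week; for modelling it is z-scored
over the active (positive) entries only.

### Independent records

For summaries that count events (e.g. the human detection-rate covariate),
records of the same species at the same station within a 24-hour window
(default `independence_window_hours = 24`) are collapsed by a greedy
forward scan: a record is kept if it is the first, or at least the window
length after the last *kept* record. Weekly detection histories are
unaffected by this filter because they only use presence within a week.

## 2. Single-species occupancy MLE and model selection

For screening covariates, each species is fit separately with the standard
single-season occupancy likelihood. With occupancy probability
`ψ_j = logit⁻¹(x_jᵀ a)` and per-occasion detection
`p_jk = logit⁻¹(w_jkᵀ b)`, the marginal likelihood of cell `j` is

- `ψ_j · Π_k p_jk^y (1−p_jk)^(1−y)` if the species was detected at least
  once in the cell, and
- `ψ_j · Π_k (1−p_jk) + (1−ψ_j)` if never detected,

with products taken over active occasions only (NA occasions drop out).
Detection always includes an intercept and the standardized effort slope.
The negative log-likelihood is minimized by L-BFGS-B from a naive-logit
starting point plus jittered restarts (`starts = 5` by default; jitter is
seeded, so fits are reproducible). Species with zero detections are flagged
non-estimable and excluded (with a warning) from model totals.

Candidate occupancy-covariate sets are all subsets of the supplied
covariates that contain no pair with |Pearson r| above the collinearity
threshold (default `0.60`). Models are ranked by a community-level AICc,

    AICc = −2 Σᵢ logLᵢ + 2K + 2K(K+1)/(n − K − 1),

where the sum is over species, `K` counts parameters (occupancy
coefficients + detection intercept + effort slope) and the sample size `n`
is the number of species. AICc is undefined when `n − K − 1 ≤ 0` and the
package raises an error rather than reporting a meaningless value — model
selection therefore needs more species than parameters, which excludes
very small communities.

The default final structure (`final_community_model()`) places five
habitat covariates on occupancy — forest cover, human presence, EVI
(enhanced vegetation index), distance to protected area, terrain
ruggedness — and effort on detection.

## 3. Hierarchical community occupancy model

The primary analysis is a multi-species hierarchical occupancy model.
For species `i`, cell `j` in block `l(j)`, occasion `k`:

    z_ij ~ Bernoulli(Ψ_ij),            logit(Ψ_ij) = ξ_il(j) + αᵢᵀ D_j
    y_ijk | z_ij ~ Bernoulli(p_ijk z_ij), logit(p_ijk) = ν_il(j) + β_i e_jk

where `D_j` are the standardized cell covariates and `e_jk` the
standardized effort. Because cell closure over a season is not guaranteed
for wide-ranging mammals, `Ψ` is interpreted as a probability of *habitat
use* rather than strict occupancy.

Species-level coefficients are drawn from community hyperdistributions:
`α_im ~ N(μ_α,m, 1/τ_α,m)`, `β_i ~ N(μ_β, 1/τ_β)`, and the per-block
intercept pair is bivariate normal,

    (ξ_il, ν_il) ~ N₂( (μ_ξ, μ_ν), Σ ),  Σ from (τ_ξ, τ_ν, ρ),

with `ρ` the occupancy–detection intercept correlation that absorbs
abundance-mediated covariation between habitat use and detectability.

Hyperpriors (`Priors` dataclass): means `N(0, sd = 2.25)` (≈ flat on the
probability scale after the logit transform), precisions
`Gamma(shape = 0.1, rate = 0.1)`, and `ρ ~ Uniform(−1, 1)`.

### Sampler

`run_mcmc` runs a Metropolis-within-Gibbs sampler
(`ChainConfig` defaults: 3 chains × 30,000 iterations, 5,000 burn-in,
thin 3):

1. **Latent states** `z_ij` are drawn exactly from their Bernoulli full
   conditional: cells with a detection have `z = 1`; otherwise
   `P(z=1|·) = Ψq / (Ψq + 1 − Ψ)` with `q = Π_k (1 − p_ijk)` over active
   occasions.
2. **Species coefficients** (`ξ, α, ν, β`) take element-wise random-walk
   Metropolis steps, vectorized across species/blocks because entries are
   conditionally independent given `z`.
3. **Hypermeans** are conjugate-normal draws; `(μ_ξ, μ_ν)` is drawn
   jointly from its bivariate normal full conditional (the bivariate layer
   couples them through `ρ`).
4. **Precisions** of the univariate slope layers (`τ_α, τ_β`) are
   conjugate Gamma draws. The intercept-layer precisions `(τ_ξ, τ_ν)` are
   *not* conditionally Gamma when `ρ ≠ 0`, so they take log-scale
   Metropolis steps (with the Jacobian term); `ρ` takes a random-walk
   Metropolis step with proposals outside (−1, 1) rejected.

Proposal scales adapt toward a 0.30–0.45 acceptance rate in windows of 50
iterations **during burn-in only**; scales are frozen afterwards so the
retained chain is a time-homogeneous Markov chain with the correct
stationary distribution.

### Numerical choices

- Bernoulli log-likelihood terms use the identity
  `y log p + (1−y) log(1−p) = log σ((2y−1)η)` on the linear predictor η
  (`log_expit`), which is overflow-safe at extreme logits.
- Per-cell occupancy and detection log-likelihood contributions are cached
  and updated incrementally on Metropolis acceptance, and the detection
  cache is reused as `log q` in the z-update.
- The detection-side cache uses float32 with preallocated buffers: at
  study scale (25 species × 55 cells × 13 occasions) this halves memory
  traffic in the hot loop with error far below Monte-Carlo noise.
- Chain seeds derive from `numpy.random.SeedSequence(seed).spawn()`, so
  runs are bit-for-bit reproducible for a given configuration and chains
  are mutually independent.
- `z` draws are stored as `uint8`, `Ψ` draws as float32, to keep
  study-scale posteriors within a few hundred MB of memory.

Convergence is summarized by the split-chain Gelman–Rubin R-hat (each
chain is halved, so within-chain drift is penalized); values below 1.1 are
flagged as converged in the report stage. Posterior intervals are
equal-tailed 95% and 50% quantile CRIs over pooled chains.

With `sample_hyper=False` the hyper layer is frozen at independent vague
priors (mean 0, sd 2.25, ρ = 0), giving a flat-prior single- or
multi-species sampler used for MLE-agreement validation.

## 4. Derived quantities

All derived quantities propagate posterior uncertainty by being computed
per retained draw:

- **Richness surfaces** — per draw, `z` is summed over a species subset in
  each cell; reported as per-cell posterior mean ± sd. Subsets from the
  species register: all native species, large prey (of either cat,
  including the introduced domestic pig), and jaguar/puma medium prey.
- **Area fraction** — percent of surveyed cells with `z = 1`, averaged
  over draws, per species.
- **Block summaries** — mean and across-cell sd of cell-level posterior
  means within each block, with pooled rows (the two JCU blocks; the two
  corridor blocks) when the block labels match the default study layout.
- **Predator–prey correlation** — Pearson r between a predator's per-cell
  habitat-use posterior means and a prey subset's per-cell richness means,
  with the usual t-distribution p-value on n − 2 df; a draw-wise r
  distribution is also available.

## 5. Synthetic-data generator

`simulate_community(scenario, seed)` generates raw tables with exactly the
structure the analysis assumes, plus the generating truth, so estimators
can be validated end-to-end by parameter recovery.

The default study-scale scenario (`default_study_scenario()`) emulates the
survey design the package targets:

| parameter | default | rationale |
|---|---|---|
| grid | 63 cells of 16 km², 55 surveyed | 87.30% coverage, 880 km² |
| blocks | CVC, Corridor1, Corridor2, TC (14/14/13/14 cells) | two core areas bridged by two corridor blocks, run in different seasons |
| species | 25 (packaged register) | medium/large mammal community |
| occasions | 13 weekly per block | one field season per block |
| stations | 4 per cell; 5% never deployed | field attrition |
| station failure | 0.003 per night (geometric lifetime) | camera theft/failure; yields ≈ 17,000 trap nights from ≈ 200+ stations |
| covariates | 5, equicorrelated MVN (r = 0.2) | realistic mild collinearity |
| hyper truth | μ_ξ = −0.25, sd 1.25; μ_α = (0.34, 0.10, −0.08, −0.08, −0.02), sd 0.75; μ_ν = −1.7, sd 0.7; μ_β = 0.39, sd 0.2; ρ = 0.26 | dominant positive forest effect; weekly detection ≈ 0.15 at average effort |

Weekly detections are drawn directly at the cell-week level and then
expanded into timestamped records at uniformly chosen active
station-nights, with a Poisson number of extra photographic events (rate
0.7) and Poisson-inflated counts, so the 24-hour independence filter is
exercised without changing the weekly histories. Effort is computed through
the same `build_effort` code path the analysis uses.

**What the generator deliberately omits:** no spatial autocorrelation
beyond what the covariates induce, no within-season colonization or
extinction (closure holds exactly, unlike the interpretation caveat for
real data), no species interactions, no on-trail/off-trail detection
difference (the flag is emitted but not used in generation), and no
mid-deployment camera recovery. These omissions make the generator match
the fitted model's assumptions, which is the point for validation, but
they mean recovery results are best-case with respect to model
misspecification.

A `toy_scenario()` (3 species, 8 cells, 4 occasions) is small enough for
brute-force enumeration oracles and fast CI.

## 6. Pipeline

`commoccu run` (or `run_pipeline`) chains five stages — `prepare`,
`select`, `fit`, `derive`, `report` — under a YAML-configurable
`RunConfig`, writing CSV/JSON artifacts per stage plus a `manifest.json`
with package and library versions, the seed, the full effective config,
SHA-256 checksums of the inputs, and per-stage timings. Stage failures are
wrapped in a `StageError` naming the failing stage. Identical
configurations and seeds reproduce output files byte-for-byte.

## 7. Known limitations

- **Hypermean interval calibration at study scale.** With 55 cells,
  correlated covariates and 25 species, species-level slopes are weakly
  identified; the classic downward bias of variance components estimated
  from weakly identified group effects narrows hypermean credible
  intervals somewhat. In recovery experiments at the default study scale,
  95% CRI coverage of individual slope hypermeans ranged roughly
  0.85–1.00 across replicates rather than uniformly ≥ 0.95. Point
  estimation is unbiased in the same experiments. Longer chains do not
  change this (it is a posterior property, not a mixing failure).
- **Precision tails.** The log-scale Metropolis steps on `(τ_ξ, τ_ν)` mix
  slowly into the extreme tails of the Gamma(0.1, 0.1) prior; prior mass
  at very small precisions is reachable but slowly explored. This matters
  only in near-data-free settings.
- **AICc needs n_species > K + 1** (see §2).
- The occupancy/habitat-use interpretation under closure violation is
  inherited from the model class; the generator simulates true closure.
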