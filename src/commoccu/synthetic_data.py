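"""Synthetic camera-trap surveys with known parameters.

Generates raw record/deployment/covariate tables with exactly the
statistical structure the occupancy analysis assumes: species-level
logit-linear coefficients drawn from community hyperdistributions (with
correlated habitat-use and detection intercepts), latent occurrence drawn
per species and cell, weekly detections thinned by survey effort, and
camera dropout producing the NA structure of real deployments.  The
generating truth is returned alongside the tables so estimators can be
validated by parameter recovery.

The default study-scale scenario emulates the survey design the package
targets: a 63-cell grid of 16 km^2 cells in four survey blocks run in
different seasons, 55 cells surveyed with ~4 stations each over ~13 weekly
occasions, and 25 species.  The toy scenario is small enough for exact
brute-force oracles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import survey_data
from .model_selection import FINAL_MODEL_COVARIATES


@dataclass(frozen=True)
class HyperTruth:
    """Community hyperparameters used to generate species coefficients.

    Defaults are magnitudes typical of tropical medium/large mammal
    communities: a weakly negative community habitat-use intercept, a
    dominant positive forest-cover effect, weekly detection probabilities
    around 0.15 at average effort with a positive effort slope, and a small
    positive occupancy-detection correlation.
    """
    mu_xi: float = -0.25
    sd_xi: float = 1.25
    mu_alpha: tuple = (0.34, 0.10, -0.08, -0.08, -0.02)
    sd_alpha: tuple = (0.75, 0.75, 0.75, 0.75, 0.75)
    mu_nu: float = -1.7
    sd_nu: float = 0.7
    mu_beta: float = 0.39
    sd_beta: float = 0.2
    rho: float = 0.26


@dataclass(frozen=True)
class SimulationScenario:
    n_species: int
    n_cells_total: int
    cells_per_block: tuple          # surveyed cells per block
    block_labels: tuple
    block_starts: tuple             # ISO dates, one per block
    n_occasions: int                # planned weekly occasions per block
    stations_per_cell: int
    hyper: HyperTruth
    covariate_names: tuple
    covariate_means: tuple
    covariate_sds: tuple
    covariate_corr: float = 0.2     # common pairwise correlation
    station_failure_prob: float = 0.003   # per-night permanent failure
    station_missing_prob: float = 0.05    # planned station never deployed
    extra_events_rate: float = 0.7  # extra photo events per detected week
    occasion_length: int = 7
    cell_area: float = 16.0

    def __post_init__(self):
        if min(self.n_species, self.n_cells_total, self.n_occasions,
               self.stations_per_cell) <= 0:
            raise ValueError("all scenario counts must be positive")
        if len(self.cells_per_block) != len(self.block_labels):
            raise ValueError("cells_per_block and block_labels mismatch")
        if sum(self.cells_per_block) > self.n_cells_total:
            raise ValueError("more surveyed cells than grid cells")
        if not -1.0 / max(len(self.covariate_names) - 1, 1) \
                < self.covariate_corr < 1.0:
            raise ValueError("covariate correlation not positive definite")

    @property
    def n_surveyed(self) -> int:
        return sum(self.cells_per_block)


@dataclass
class SimulatedTruth:
    hyper: HyperTruth
    xi: np.ndarray        # (S, L)
    nu: np.ndarray        # (S, L)
    alpha: np.ndarray     # (S, M)
    beta: np.ndarray      # (S,)
    psi: np.ndarray       # (S, J surveyed)
    z: np.ndarray         # (S, J surveyed)


@dataclass
class SimulatedDataset:
    scenario: SimulationScenario
    records: pd.DataFrame
    deployments: pd.DataFrame
    covariates: pd.DataFrame
    species: pd.DataFrame
    truth: SimulatedTruth
    seed: int

    def grid(self) -> survey_data.SurveyGrid:
        return survey_data.grid_from_tables(
            self.deployments, self.covariates,
            n_cells_total=self.scenario.n_cells_total,
            cell_area=self.scenario.cell_area)

    def to_tensor(self):
        """Round-trip through the survey-data stage: (tensor, covariate table)."""
        tensor = survey_data.build_detection_histories(
            self.records, self.deployments, self.grid(),
            species=tuple(self.species["species_code"]),
            occasion_length=self.scenario.occasion_length)
        cov = survey_data.standardize_covariates(self.covariates)
        return tensor, cov

    def write(self, outdir) -> dict:
        """Write the four CSV tables plus the generating truth as JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        rec = self.records.copy()
        rec["timestamp"] = rec["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
        dep = self.deployments.copy()
        for c in ("active_start", "active_end"):
            dep[c] = dep[c].dt.strftime("%Y-%m-%d")
        for name, df in (("records", rec), ("deployments", dep),
                         ("covariates", self.covariates),
                         ("species", self.species)):
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = str(p)
        truth = {"seed": self.seed, "hyper": asdict(self.truth.hyper)}
        for k in ("xi", "nu", "alpha", "beta", "psi", "z"):
            truth[k] = np.asarray(getattr(self.truth, k)).tolist()
        p = outdir / "truth.json"
        p.write_text(json.dumps(truth, indent=1))
        paths["truth"] = str(p)
        return paths


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def default_study_scenario() -> SimulationScenario:
    """Study-scale defaults: 63-cell grid, 55 surveyed in 4 blocks, 25
    species, 4 stations per cell, ~13 weekly occasions per block."""
    return SimulationScenario(
        n_species=25,
        n_cells_total=63,
        cells_per_block=(14, 14, 13, 14),
        block_labels=("CVC", "Corridor1", "Corridor2", "TC"),
        block_starts=("2014-08-15", "2013-10-15", "2014-01-20", "2016-09-15"),
        n_occasions=13,
        stations_per_cell=4,
        hyper=HyperTruth(),
        covariate_names=FINAL_MODEL_COVARIATES,
        covariate_means=(60.0, 20.0, 0.55, 8.0, 30.0),
        covariate_sds=(20.0, 15.0, 0.10, 5.0, 15.0),
    )


def toy_scenario() -> SimulationScenario:
    """A brute-force-oracle-sized scenario (3 species, 6 surveyed cells,
    4 occasions)."""
    return SimulationScenario(
        n_species=3,
        n_cells_total=8,
        cells_per_block=(3, 3),
        block_labels=("A", "B"),
        block_starts=("2020-01-01", "2020-03-01"),
        n_occasions=4,
        stations_per_cell=2,
        hyper=HyperTruth(mu_xi=0.0, mu_alpha=(0.5, -0.3),
                         sd_alpha=(0.5, 0.5), mu_nu=-0.5),
        covariate_names=("forest", "human_presence"),
        covariate_means=(60.0, 20.0),
        covariate_sds=(20.0, 15.0),
        station_failure_prob=0.01,
        station_missing_prob=0.0,
    )


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def draw_species_params(scenario: SimulationScenario, rng) -> tuple:
    """Species coefficients from the community hyperdistributions; the
    intercept pair (xi_il, nu_il) is bivariate normal with correlation rho."""
    h = scenario.hyper
    S, L = scenario.n_species, len(scenario.block_labels)
    M = len(scenario.covariate_names)
    if len(h.mu_alpha) != M or len(h.sd_alpha) != M:
        raise ValueError("hyper slope dimensions do not match covariates")
    cov = np.array([[h.sd_xi ** 2, h.rho * h.sd_xi * h.sd_nu],
                    [h.rho * h.sd_xi * h.sd_nu, h.sd_nu ** 2]])
    pairs = rng.multivariate_normal([h.mu_xi, h.mu_nu], cov, size=(S, L))
    xi, nu = pairs[..., 0], pairs[..., 1]
    alpha = rng.normal(h.mu_alpha, h.sd_alpha, (S, M))
    beta = rng.normal(h.mu_beta, h.sd_beta, S)
    return xi, nu, alpha, beta


def _species_table(n_species: int) -> pd.DataFrame:
    if n_species == 25:
        return survey_data.load_species_table()
    return pd.DataFrame({
        "species_code": [f"sp_{i:02d}" for i in range(n_species)],
        "common_name": [f"Synthetic species {i}" for i in range(n_species)],
        "size_class": "medium", "native": 1,
        "jaguar_prey": 0, "puma_prey": 0,
    })


def simulate_community(scenario: SimulationScenario, seed: int
                       ) -> SimulatedDataset:
    """Generate one synthetic survey: tables + generating truth.

    Detection events within a detected cell-week are placed at uniformly
    random timestamps within that week's active station-nights; a Poisson
    number of extra photographic events exercises the 24-h independence
    filter without changing the weekly histories.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    S = scenario.n_species
    L = len(scenario.block_labels)
    M = len(scenario.covariate_names)
    species_df = _species_table(S)
    sp_codes = list(species_df["species_code"])

    # --- cells and blocks ---------------------------------------------------
    cell_ids, block_of_cell = [], {}
    c = 0
    for b, nb in zip(scenario.block_labels, scenario.cells_per_block):
        for _ in range(nb):
            cid = f"cell_{c:02d}"
            cell_ids.append(cid)
            block_of_cell[cid] = b
            c += 1
    block_idx = np.array([scenario.block_labels.index(block_of_cell[c])
                          for c in cell_ids])
    J = len(cell_ids)

    # --- covariates (equicorrelated multivariate normal, raw scale) ---------
    R = np.full((M, M), scenario.covariate_corr)
    np.fill_diagonal(R, 1.0)
    sds = np.asarray(scenario.covariate_sds)
    cov = R * np.outer(sds, sds)
    D_raw = rng.multivariate_normal(scenario.covariate_means, cov, size=J)
    covariates = pd.DataFrame(D_raw, columns=list(scenario.covariate_names))
    covariates.insert(0, "block", [block_of_cell[c] for c in cell_ids])
    covariates.insert(0, "cell_id", cell_ids)

    # --- deployments with permanent-failure dropout --------------------------
    starts = {b: pd.Timestamp(d) for b, d in
              zip(scenario.block_labels, scenario.block_starts)}
    planned_nights = scenario.n_occasions * scenario.occasion_length
    rows = []
    for cid in cell_ids:
        b = block_of_cell[cid]
        for s in range(scenario.stations_per_cell):
            if rng.random() < scenario.station_missing_prob:
                continue
            lifetime = planned_nights
            if scenario.station_failure_prob > 0:
                fail = rng.geometric(scenario.station_failure_prob)
                lifetime = min(planned_nights, int(fail))
            rows.append({
                "station_id": f"{cid}_st{s}",
                "cell_id": cid,
                "on_trail": bool(s % 2 == 0),
                "active_start": starts[b],
                "active_end": starts[b] + pd.Timedelta(days=lifetime - 1),
            })
    deployments = pd.DataFrame(rows)
    if deployments.empty:
        raise ValueError("infeasible scenario: no stations deployed")

    # --- effort via the same code path the analysis uses ---------------------
    grid = survey_data.grid_from_tables(
        deployments, covariates, n_cells_total=scenario.n_cells_total,
        cell_area=scenario.cell_area)
    eff = survey_data.build_effort(deployments, grid,
                                   scenario.occasion_length)
    K = eff.effort.shape[1]

    # --- truth: species params, occupancy, weekly detections -----------------
    xi, nu, alpha, beta = draw_species_params(scenario, rng)
    cov_table = survey_data.standardize_covariates(covariates)
    psi = expit(xi[:, block_idx] + alpha @ cov_table.D_std.T)     # (S, J)
    z = (rng.random((S, J)) < psi).astype(np.int8)
    p = expit(nu[:, block_idx][:, :, None]
              + beta[:, None, None] * eff.effort_std[None])       # (S, J, K)
    active = eff.effort > 0
    y = ((rng.random((S, J, K)) < p) & z[:, :, None].astype(bool)
         & active[None]).astype(np.int8)

    # --- expand detected weeks into timestamped records ----------------------
    night_pool = _active_nights(deployments, eff)
    rec_rows = []
    for i, j, k in zip(*np.nonzero(y)):
        pool = night_pool[(eff.cells[j], k)]
        n_events = 1 + rng.poisson(scenario.extra_events_rate)
        picks = rng.integers(0, len(pool), n_events)
        minutes = rng.integers(0, 24 * 60, n_events)
        for e in range(n_events):
            st, night = pool[picks[e]]
            rec_rows.append({
                "station_id": st,
                "species_code": sp_codes[i],
                "timestamp": night + pd.Timedelta(minutes=int(minutes[e])),
                "count": 1 + int(rng.poisson(0.2)),
            })
    records = pd.DataFrame(
        rec_rows, columns=["station_id", "species_code", "timestamp", "count"])
    if len(records):
        records = records.sort_values(
            ["timestamp", "station_id", "species_code"],
            kind="mergesort").reset_index(drop=True)

    truth = SimulatedTruth(hyper=scenario.hyper, xi=xi, nu=nu, alpha=alpha,
                           beta=beta, psi=psi, z=z)
    return SimulatedDataset(scenario=scenario, records=records,
                            deployments=deployments, covariates=covariates,
                            species=species_df, truth=truth, seed=seed)


def _active_nights(deployments: pd.DataFrame, eff) -> dict:
    """(cell, occasion) -> list of (station_id, night Timestamp) active pairs."""
    pool = {}
    for j, cell in enumerate(eff.cells):
        g = deployments[deployments["cell_id"] == cell]
        for k in range(eff.effort.shape[1]):
            if eff.effort[j, k] == 0:
                continue
            lo, hi = eff.occasion_window(cell, k)
            nights = []
            for row in g.itertuples():
                a = max(row.active_start, lo)
                b = min(row.active_end, hi)
                d = a
                while d <= b:
                    nights.append((row.station_id, d))
                    d += pd.Timedelta(days=1)
            pool[(cell, k)] = nights
    return pool
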