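"""Ecological quantities derived from the community posterior.

Species richness per grid cell is a derived parameter: in each retained
MCMC draw, the latent occurrence indicators z_ij are summed over a species
subset, so richness uncertainty propagates directly from the occupancy
model.  Subsets of interest are the full native community and the jaguar /
puma prey groups flagged in the registered species table.  Block summaries
average the per-cell posterior means within each survey block; predator-
prey association is the Pearson correlation between a predator's per-cell
habitat-use posterior means and a prey subset's per-cell richness means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: species excluded from the native community subset
NON_NATIVE = ("sus_scrofa",)


@dataclass(frozen=True)
class SpeciesSubset:
    label: str
    members: tuple


@dataclass
class RichnessSurface:
    """Per-cell posterior of summed latent occurrence over a species subset."""
    subset: SpeciesSubset
    cells: tuple
    draws: np.ndarray        # (n_draws, n_cells) integer sums

    @property
    def cell_means(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    @property
    def cell_sds(self) -> np.ndarray:
        return self.draws.std(axis=0, ddof=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cells,
                             "richness_mean": self.cell_means,
                             "richness_sd": self.cell_sds})


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


# ---------------------------------------------------------------------------
# species subsets
# ---------------------------------------------------------------------------

def prey_subsets(species_table: pd.DataFrame) -> dict:
    """The four analysis subsets from the species-table flags.

    all_native: every native species (domestic pig excluded);
    large_prey: large-bodied prey of both cats, domestic pig included;
    jaguar_medium_prey / puma_medium_prey: medium-bodied prey per predator.
    """
    for col in ("species_code", "size_class", "native",
                "jaguar_prey", "puma_prey"):
        if col not in species_table.columns:
            raise ValueError(f"species table lacks required column {col!r}")
    t = species_table
    native = t.loc[t["native"] == 1, "species_code"]
    large = t["size_class"] == "large"
    medium = t["size_class"] == "medium"
    large_prey = t.loc[large & ((t["jaguar_prey"] == 1) | (t["puma_prey"] == 1)),
                       "species_code"]
    jmp = t.loc[medium & (t["jaguar_prey"] == 1), "species_code"]
    pmp = t.loc[medium & (t["puma_prey"] == 1), "species_code"]
    return {
        "all_native": SpeciesSubset("all_native", tuple(native)),
        "large_prey": SpeciesSubset("large_prey", tuple(large_prey)),
        "jaguar_medium_prey": SpeciesSubset("jaguar_medium_prey", tuple(jmp)),
        "puma_medium_prey": SpeciesSubset("puma_medium_prey", tuple(pmp)),
    }


# ---------------------------------------------------------------------------
# richness and occurrence
# ---------------------------------------------------------------------------

def _subset_indices(subset: SpeciesSubset, species) -> np.ndarray:
    species = list(species)
    missing = [m for m in subset.members if m not in species]
    if missing:
        raise ValueError(f"subset {subset.label!r} has species not in the "
                         f"posterior: {missing}")
    if not subset.members:
        raise ValueError("species subset is empty")
    return np.array([species.index(m) for m in subset.members])


def richness_from_z(z_draws: np.ndarray, subset: SpeciesSubset,
                    species, cells) -> RichnessSurface:
    """Per-draw, per-cell summed occurrence over the subset.

    ``z_draws`` is (n_draws, n_species, n_cells) pooled over chains.
    """
    idx = _subset_indices(subset, species)
    sums = z_draws[:, idx, :].sum(axis=1)
    return RichnessSurface(subset=subset, cells=tuple(cells),
                           draws=sums.astype(float))


def area_fraction(z_draws: np.ndarray, species_code: str, species) -> float:
    """Percent of surveyed cells occupied by one species, posterior mean."""
    i = list(species).index(species_code)
    return float(z_draws[:, i, :].mean(axis=1).mean() * 100.0)


def area_fraction_table(z_draws: np.ndarray, species) -> pd.DataFrame:
    rows = [{"species_code": sp,
             "percent_of_area": area_fraction(z_draws, sp, species)}
            for sp in species]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# block summaries
# ---------------------------------------------------------------------------

#: block label -> pooled group used in reporting (JCUs vs Corridor)
DEFAULT_BLOCK_GROUPS = {"CVC": "JCU", "TC": "JCU",
                        "Corridor1": "Corridor", "Corridor2": "Corridor"}


def block_summary(cell_means: np.ndarray, cells, block_of_cell: dict,
                  groups: dict | None = None, ddof: int = 1) -> pd.DataFrame:
    """Mean and SD of cell-level posterior means within each block.

    SDs are across cells (sample SD by default), the convention for
    "mean +/- SD" block reporting.  Pooled groups (e.g. both JCUs, the two
    Corridor blocks) are appended when a grouping is supplied or when block
    labels match the default study layout.
    """
    cell_means = np.asarray(cell_means, dtype=float)
    labels = [block_of_cell[c] for c in cells]
    df = pd.DataFrame({"block": labels, "value": cell_means})
    rows = []
    for b, g in df.groupby("block", sort=False):
        if g.empty:
            warnings.warn(f"block {b} has no cells")
            rows.append({"block": b, "mean": np.nan, "sd": np.nan, "n_cells": 0})
        else:
            rows.append({"block": b, "mean": g["value"].mean(),
                         "sd": g["value"].std(ddof=ddof) if len(g) > ddof
                         else 0.0, "n_cells": len(g)})
    if groups is None and set(df["block"]) <= set(DEFAULT_BLOCK_GROUPS):
        groups = DEFAULT_BLOCK_GROUPS
    if groups:
        df["group"] = df["block"].map(groups)
        for grp, g in df.dropna(subset=["group"]).groupby("group", sort=False):
            rows.append({"block": f"pooled_{grp}", "mean": g["value"].mean(),
                         "sd": g["value"].std(ddof=ddof) if len(g) > ddof
                         else 0.0, "n_cells": len(g)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# predator-prey correlation
# ---------------------------------------------------------------------------

def predator_prey_correlation(psi_means, richness_means) -> CorrelationResult:
    """Pearson correlation between per-cell habitat-use means of a predator
    and per-cell prey-richness means; p from the t distribution (n-2 df)."""
    x = np.asarray(psi_means, dtype=float)
    y = np.asarray(richness_means, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D and paired over the same cells")
    if len(x) < 3:
        raise ValueError("need at least 3 cells")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=len(x))


def correlation_draws(psi_draws_1cell_axis, richness: RichnessSurface
                      ) -> np.ndarray:
    """Optional draw-wise Pearson r distribution (one r per posterior draw)."""
    psi = np.asarray(psi_draws_1cell_axis, dtype=float)
    rz = richness.draws
    if psi.shape != rz.shape:
        raise ValueError("draw arrays must align (draws, cells)")
    px = psi - psi.mean(axis=1, keepdims=True)
    py = rz - rz.mean(axis=1, keepdims=True)
    denom = np.sqrt((px ** 2).sum(axis=1) * (py ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (px * py).sum(axis=1) / denom
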