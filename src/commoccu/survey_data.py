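"""Preparation of camera-trap survey data for occupancy modelling.

Raw inputs are three delimited tables:

* ``records`` — one row per photographic event:
  ``station_id, species_code, timestamp, count``
* ``deployments`` — one row per active interval of a camera station:
  ``station_id, cell_id, on_trail, active_start, active_end``
  (closed date intervals; a station belongs to exactly one grid cell)
* ``covariates`` — one row per surveyed grid cell:
  ``cell_id, block`` followed by one column per site covariate

From these the module builds the objects the occupancy models consume: a
species x cell x week detection-history tensor with values {0, 1, NA}, a
cell x week matrix of survey effort (trap nights), and z-scored covariate
design matrices.

Sampling occasions are 7-day windows aligned to each survey block's first
active night, because blocks were run in different seasons.  A week in
which no camera in a cell was active has zero effort and yields NA
detection entries; partial weeks at the edges of a deployment are kept as
occasions with reduced effort.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

DEFAULT_OCCASION_DAYS = 7
DEFAULT_INDEPENDENCE_WINDOW = pd.Timedelta(hours=24)
DEFAULT_CELL_AREA_KM2 = 16.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurveyGrid:
    """The sampling grid: all cells, their block labels, and cell area.

    ``block_of_cell`` maps every *surveyed* cell to its survey block label
    (e.g. CVC, Corridor1, Corridor2, TC); cells absent from the map are
    unsurveyed.
    """

    cell_ids: tuple
    block_of_cell: dict
    cell_area: float = DEFAULT_CELL_AREA_KM2

    def __post_init__(self):
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        missing = set(self.block_of_cell) - set(self.cell_ids)
        if missing:
            raise ValueError(f"block labels for unknown cells: {sorted(missing)}")

    @property
    def surveyed_cells(self) -> tuple:
        return tuple(c for c in self.cell_ids if c in self.block_of_cell)

    @property
    def blocks(self) -> tuple:
        seen = []
        for c in self.surveyed_cells:
            b = self.block_of_cell[c]
            if b not in seen:
                seen.append(b)
        return tuple(seen)


@dataclass
class EffortMatrix:
    """Trap nights per (cell, occasion) plus a z-scored copy.

    Standardization statistics are computed over the entries with positive
    effort (zero-effort cell-weeks are NA in the detection histories and
    never enter a likelihood).
    """

    cells: tuple
    effort: np.ndarray          # (n_cells, n_occasions)
    effort_std: np.ndarray
    mean: float
    sd: float
    occasion_length: int
    block_starts: dict          # block label -> first active date (Timestamp)
    block_n_occasions: dict     # block label -> occasions in that block
    block_of_cell: dict

    def occasion_window(self, cell, k):
        """Date range [start, end] (closed) of occasion ``k`` for ``cell``."""
        start = self.block_starts[self.block_of_cell[cell]]
        lo = start + pd.Timedelta(days=k * self.occasion_length)
        hi = lo + pd.Timedelta(days=self.occasion_length - 1)
        return lo, hi


@dataclass
class DetectionHistoryTensor:
    """Weekly detection histories y[species, cell, occasion] in {0, 1, NA}.

    Stored as float with ``np.nan`` for NA.  NA occurs exactly where the
    cell had zero trap nights in that week.
    """

    species: tuple
    cells: tuple
    y: np.ndarray               # (n_species, n_cells, n_occasions), float
    effort: EffortMatrix

    def __post_init__(self):
        na = np.isnan(self.y)
        zero = (self.effort.effort == 0)[None, :, :]
        if not np.array_equal(na, np.broadcast_to(zero, self.y.shape)):
            raise ValueError("y is NA iff effort is zero — violated")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (species, cell, occasion, y)."""
        s, j, k = np.meshgrid(
            np.arange(len(self.species)), np.arange(len(self.cells)),
            np.arange(self.y.shape[2]), indexing="ij")
        return pd.DataFrame({
            "species_code": np.asarray(self.species)[s.ravel()],
            "cell_id": np.asarray(self.cells)[j.ravel()],
            "occasion": k.ravel(),
            "y": self.y.ravel(),
        })


@dataclass
class CovariateTable:
    """Per-cell site covariates, raw and z-scored, with their correlations."""

    cells: tuple
    names: tuple
    D: np.ndarray               # (n_cells, n_covariates) raw
    D_std: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    correlations: pd.DataFrame = field(repr=False)

    def unstandardize(self) -> np.ndarray:
        return self.D_std * self.sds + self.means

    def column(self, name: str, standardized: bool = True) -> np.ndarray:
        m = list(self.names).index(name)
        return (self.D_std if standardized else self.D)[:, m]


@dataclass(frozen=True)
class SurveySummary:
    total_trap_nights: int
    n_stations: int
    n_cells_surveyed: int
    n_cells_total: int
    percent_surveyed: float
    surveyed_area_km2: float


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return df


def read_deployments(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["active_start", "active_end"])
    validate_deployments(df)
    return df


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_species_table(path=None) -> pd.DataFrame:
    """The registered species table (packaged transcription by default).

    Columns: species_code, common_name, size_class {medium, large},
    native {0,1}, jaguar_prey {0,1}, puma_prey {0,1}.
    """
    if path is not None:
        return pd.read_csv(path)
    with resources.files("commoccu.data").joinpath("species.csv").open() as fh:
        return pd.read_csv(fh)


def grid_from_tables(deployments: pd.DataFrame, covariates: pd.DataFrame,
                     n_cells_total: int | None = None,
                     cell_area: float = DEFAULT_CELL_AREA_KM2) -> SurveyGrid:
    """Assemble a :class:`SurveyGrid` from the deployment and covariate tables.

    ``covariates`` must carry ``cell_id`` and ``block`` columns for every
    surveyed cell.  ``n_cells_total`` pads the grid with unsurveyed
    placeholder cells when the full grid exceeds the surveyed set.
    """
    block_of_cell = dict(zip(covariates["cell_id"], covariates["block"]))
    surveyed = set(deployments["cell_id"])
    missing = surveyed - set(block_of_cell)
    if missing:
        raise ValueError(f"surveyed cells without a block label: {sorted(missing)}")
    cell_ids = list(covariates["cell_id"])
    if n_cells_total is not None:
        for i in range(n_cells_total - len(cell_ids)):
            cell_ids.append(f"unsurveyed_{i:02d}")
    return SurveyGrid(tuple(cell_ids), block_of_cell, cell_area)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_deployments(deployments: pd.DataFrame) -> None:
    """Check station->cell uniqueness and per-station interval ordering."""
    cells = deployments.groupby("station_id")["cell_id"].nunique()
    bad = cells[cells > 1]
    if len(bad):
        raise ValueError(f"stations mapped to multiple cells: {list(bad.index)}")
    if (deployments["active_end"] < deployments["active_start"]).any():
        raise ValueError("deployment interval with end before start")
    for st, g in deployments.groupby("station_id"):
        g = g.sort_values("active_start")
        if (g["active_start"].values[1:] <= g["active_end"].values[:-1]).any():
            raise ValueError(f"overlapping active intervals for station {st}")


def validate_records(records: pd.DataFrame, deployments: pd.DataFrame,
                     species_codes=None) -> None:
    """Every record must fall inside an active interval of its station."""
    if species_codes is not None:
        unknown = set(records["species_code"]) - set(species_codes)
        if unknown:
            raise ValueError(f"unregistered species codes: {sorted(unknown)}")
    by_station = {st: g for st, g in deployments.groupby("station_id")}
    for row in records.itertuples():
        g = by_station.get(row.station_id)
        ok = False
        if g is not None:
            d = pd.Timestamp(row.timestamp).normalize()
            ok = bool(((g["active_start"] <= d) & (d <= g["active_end"])).any())
        if not ok:
            raise ValueError(
                f"record outside any deployment interval: station={row.station_id} "
                f"species={row.species_code} timestamp={row.timestamp}")


# ---------------------------------------------------------------------------
# independence filtering
# ---------------------------------------------------------------------------

def filter_independent_records(records: pd.DataFrame,
                               window: pd.Timedelta = DEFAULT_INDEPENDENCE_WINDOW,
                               deployments: pd.DataFrame | None = None,
                               ) -> pd.DataFrame:
    """Reduce raw photographic events to independent detection records.

    Records of the same species at the same station are scanned greedily in
    time order; a record is retained iff at least ``window`` has elapsed
    since the previously *retained* record of that species at that station.
    Records at different stations never suppress each other.

    When ``deployments`` is supplied, records are first validated against
    the stations' active intervals.
    """
    if deployments is not None:
        validate_records(records, deployments)
    window = pd.Timedelta(window)
    keep = []
    ordered = records.sort_values("timestamp", kind="mergesort")
    for _, g in ordered.groupby(["species_code", "station_id"], sort=False):
        last = None
        for idx, ts in zip(g.index, g["timestamp"]):
            if last is None or ts - last >= window:
                keep.append(idx)
                last = ts
    return records.loc[keep].sort_values("timestamp", kind="mergesort")


# ---------------------------------------------------------------------------
# effort and detection histories
# ---------------------------------------------------------------------------

def _nights_in_window(starts, ends, win_lo, win_hi):
    """Count station-nights of [starts, ends] intervals inside [win_lo, win_hi]."""
    lo = np.maximum(starts, win_lo)
    hi = np.minimum(ends, win_hi)
    nights = (hi - lo).astype("timedelta64[D]").astype(int) + 1
    return int(np.clip(nights, 0, None).sum())


def build_effort(deployments: pd.DataFrame, grid: SurveyGrid,
                 occasion_length: int = DEFAULT_OCCASION_DAYS) -> EffortMatrix:
    """Sum trap nights per (cell, occasion).

    Occasion windows are ``occasion_length``-day blocks counted from the
    first active night of each survey block; the matrix is padded with
    zero-effort occasions so all cells share one occasion axis.
    """
    validate_deployments(deployments)
    dep = deployments.copy()
    dep["block"] = dep["cell_id"].map(grid.block_of_cell)
    if dep["block"].isna().any():
        bad = dep.loc[dep["block"].isna(), "cell_id"].unique()
        raise ValueError(f"deployments in cells without a block label: {list(bad)}")

    block_starts, block_n = {}, {}
    for b, g in dep.groupby("block"):
        start = g["active_start"].min()
        end = g["active_end"].max()
        block_starts[b] = start
        block_n[b] = math.ceil(((end - start).days + 1) / occasion_length)

    cells = grid.surveyed_cells
    K = max(block_n.values())
    effort = np.zeros((len(cells), K), dtype=float)
    for j, cell in enumerate(cells):
        g = dep[dep["cell_id"] == cell]
        if g.empty:
            continue
        b = grid.block_of_cell[cell]
        starts = g["active_start"].values
        ends = g["active_end"].values
        for k in range(block_n[b]):
            lo = block_starts[b] + pd.Timedelta(days=k * occasion_length)
            hi = lo + pd.Timedelta(days=occasion_length - 1)
            effort[j, k] = _nights_in_window(starts, ends, np.datetime64(lo),
                                             np.datetime64(hi))

    pos = effort > 0
    if pos.any():
        mean = float(effort[pos].mean())
        sd = float(effort[pos].std(ddof=0))
    else:
        mean, sd = 0.0, 1.0
    sd = sd if sd > 0 else 1.0
    return EffortMatrix(
        cells=cells, effort=effort, effort_std=(effort - mean) / sd,
        mean=mean, sd=sd, occasion_length=occasion_length,
        block_starts=block_starts, block_n_occasions=block_n,
        block_of_cell={c: grid.block_of_cell[c] for c in cells})


def build_detection_histories(records: pd.DataFrame, deployments: pd.DataFrame,
                              grid: SurveyGrid, species=None,
                              occasion_length: int = DEFAULT_OCCASION_DAYS,
                              apply_independence_filter: bool = False,
                              ) -> DetectionHistoryTensor:
    """Collapse records to the weekly {0, 1, NA} detection-history tensor.

    All stations of a cell are pooled: y[i, j, k] = 1 if any station in
    cell j recorded species i during occasion k, 0 if the cell had effort
    but no record, NA (nan) if no camera in the cell was active.  The
    tensor is identical whether or not the 24-h independence filter was
    applied first (any record in a week yields a 1), so filtering is off
    by default.
    """
    validate_records(records, deployments,
                     species_codes=None if species is None else species)
    if apply_independence_filter:
        records = filter_independent_records(records)

    eff = build_effort(deployments, grid, occasion_length)
    if species is None:
        species = tuple(sorted(records["species_code"].unique()))
    else:
        species = tuple(species)
    cells = eff.cells
    cell_index = {c: j for j, c in enumerate(cells)}
    sp_index = {s: i for i, s in enumerate(species)}
    station_cell = dict(zip(deployments["station_id"], deployments["cell_id"]))

    y = np.zeros((len(species), len(cells), eff.effort.shape[1]), dtype=float)
    y[:, eff.effort == 0] = np.nan

    for row in records.itertuples():
        cell = station_cell.get(row.station_id)
        if cell is None or cell not in cell_index:
            raise ValueError(f"record at station {row.station_id} in unknown cell")
        if row.species_code not in sp_index:
            raise ValueError(f"unknown species code {row.species_code}")
        j = cell_index[cell]
        b = grid.block_of_cell[cell]
        d = pd.Timestamp(row.timestamp).normalize()
        k = (d - eff.block_starts[b]).days // occasion_length
        if not (0 <= k < eff.effort.shape[1]) or eff.effort[j, k] == 0:
            raise ValueError(
                f"record at {row.timestamp} falls in a zero-effort occasion "
                f"for cell {cell} — inconsistent deployments")
        y[sp_index[row.species_code], j, k] = 1.0

    return DetectionHistoryTensor(species=species, cells=cells, y=y, effort=eff)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def standardize_covariates(covariates: pd.DataFrame, names=None) -> CovariateTable:
    """z-score covariate columns over the surveyed cells.

    Stores means/SDs so the transform round-trips, plus the pairwise
    Pearson correlation matrix of the raw columns (used by the
    collinearity rule in model enumeration).
    """
    if names is None:
        names = tuple(c for c in covariates.columns
                      if c not in ("cell_id", "block"))
    else:
        names = tuple(names)
    D = covariates[list(names)].to_numpy(dtype=float)
    means = D.mean(axis=0)
    sds = D.std(axis=0, ddof=0)
    sds = np.where(sds > 0, sds, 1.0)
    corr = pd.DataFrame(np.corrcoef(D, rowvar=False), index=names, columns=names)
    return CovariateTable(cells=tuple(covariates["cell_id"]), names=names,
                          D=D, D_std=(D - means) / sds,
                          means=means, sds=sds, correlations=corr)


# ---------------------------------------------------------------------------
# per-cell detection-rate covariate and survey summary
# ---------------------------------------------------------------------------

def detection_rate_covariate(records: pd.DataFrame, deployments: pd.DataFrame,
                             grid: SurveyGrid, target_species: str,
                             per: float = 1000.0,
                             window: pd.Timedelta = DEFAULT_INDEPENDENCE_WINDOW,
                             ) -> pd.Series:
    """Independent detections of one species per ``per`` trap nights per cell.

    Used to turn e.g. human photographic records into a site covariate
    (human presence = detections per 1,000 trap nights).  Cells with zero
    trap nights get NA with a warning.
    """
    target = records[records["species_code"] == target_species]
    indep = filter_independent_records(target, window=window)
    station_cell = dict(zip(deployments["station_id"], deployments["cell_id"]))
    counts = indep["station_id"].map(station_cell).value_counts()

    nights = deployments.assign(
        n=(deployments["active_end"] - deployments["active_start"]).dt.days + 1
    ).groupby("cell_id")["n"].sum()

    out = {}
    for cell in grid.surveyed_cells:
        tn = float(nights.get(cell, 0))
        if tn == 0:
            warnings.warn(f"cell {cell} has zero trap nights; rate is NA")
            out[cell] = np.nan
        else:
            out[cell] = float(counts.get(cell, 0)) / tn * per
    return pd.Series(out, name=f"{target_species}_per_{per:g}_trap_nights")


def survey_summary(deployments: pd.DataFrame, grid: SurveyGrid) -> SurveySummary:
    """Headline effort numbers: trap nights, stations, coverage, area."""
    nights = int(((deployments["active_end"] - deployments["active_start"])
                  .dt.days + 1).sum()) if len(deployments) else 0
    n_stations = deployments["station_id"].nunique() if len(deployments) else 0
    surveyed = deployments["cell_id"].nunique() if len(deployments) else 0
    total = len(grid.cell_ids)
    pct = round(surveyed / total * 100, 2) if total else 0.0
    return SurveySummary(
        total_trap_nights=nights, n_stations=n_stations,
        n_cells_surveyed=surveyed, n_cells_total=total,
        percent_surveyed=pct, surveyed_area_km2=surveyed * grid.cell_area)
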