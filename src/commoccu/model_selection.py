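"""Single-species occupancy MLE and cross-species AICc model ranking.

The single-season occupancy model treats true presence z_j of a species in
cell j as Bernoulli(psi_j) and each weekly observation y_jk, conditional on
presence, as Bernoulli(p_jk); both probabilities are logit-linear in
covariates.  The marginal likelihood of a cell with at least one detection
is psi_j * prod_k p^y (1-p)^(1-y); an all-zero cell contributes
psi_j * prod_k (1-p_jk) + (1 - psi_j).  NA occasions (no active camera)
contribute no factors.

Candidate models share a fixed detection structure (intercept + effort) and
differ in their occupancy covariate subsets; subsets containing a pair of
covariates correlated beyond a threshold are excluded.  Models are ranked
community-wide by summing each model's maximized log-likelihood across all
species and applying the small-sample AIC correction with n = number of
species.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit

DEFAULT_COLLINEARITY_THRESHOLD = 0.60

#: Occupancy covariates of the packaged final community model.
FINAL_MODEL_COVARIATES = (
    "forest", "human_presence", "evi", "dist_protected", "ruggedness")


@dataclass(frozen=True)
class ModelDefinition:
    """A candidate model: occupancy covariate subset; detection is always
    intercept + effort."""

    psi_covariates: tuple
    p_covariates: tuple = ("effort",)

    @property
    def id(self) -> str:
        psi = "+".join(self.psi_covariates) if self.psi_covariates else "1"
        return f"psi({psi})p({'+'.join(('1',) + tuple(self.p_covariates))})"

    @property
    def K(self) -> int:
        # psi intercept + slopes, p intercept + effort slope
        return len(self.psi_covariates) + 2 + len(self.p_covariates)


def final_community_model() -> ModelDefinition:
    """The packaged top community model (five occupancy covariates)."""
    return ModelDefinition(FINAL_MODEL_COVARIATES)


@dataclass
class ModelFit:
    model: ModelDefinition
    species: str
    logL: float
    K: int
    converged: bool
    estimable: bool
    estimates: dict = field(default_factory=dict)
    n_detections: int = 0


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def occupancy_neg_loglik(params: np.ndarray, y: np.ndarray,
                         X_psi: np.ndarray, X_p: np.ndarray) -> float:
    """Negative marginal log-likelihood of one species' detection history.

    Parameters
    ----------
    params : concatenated (psi coefficients, p coefficients) on logit scale.
    y : (n_cells, n_occasions) history with NaN for inactive occasions.
    X_psi : (n_cells, q_psi) occupancy design matrix (intercept first).
    X_p : (n_cells, n_occasions, q_p) detection design.
    """
    q_psi = X_psi.shape[1]
    eta_psi = X_psi @ params[:q_psi]                     # (J,)
    eta_p = X_p @ params[q_psi:]                         # (J, K)

    obs = ~np.isnan(y)
    all_na = ~obs.any(axis=1)
    if all_na.any():
        warnings.warn(f"{int(all_na.sum())} cell(s) with no active occasions "
                      "dropped from the likelihood")
    y0 = np.where(obs, y, 0.0)

    log_p = log_expit(eta_p)
    log_1mp = log_expit(-eta_p)
    log_psi = log_expit(eta_psi)
    log_1mpsi = log_expit(-eta_psi)

    ll_det = np.where(obs, y0 * log_p + (1.0 - y0) * log_1mp, 0.0).sum(axis=1)
    ll_none = np.where(obs, log_1mp, 0.0).sum(axis=1)

    detected = y0.sum(axis=1) > 0
    ll = np.where(detected, log_psi + ll_det,
                  np.logaddexp(log_psi + ll_none, log_1mpsi))
    total = ll[~all_na].sum()
    if not np.isfinite(total):
        raise FloatingPointError("non-finite occupancy log-likelihood")
    return -float(total)


def _design_matrices(covariate_table, effort_std: np.ndarray,
                     model: ModelDefinition):
    J, K = effort_std.shape
    X_psi = np.column_stack(
        [np.ones(J)] + [covariate_table.column(n) for n in model.psi_covariates])
    X_p = np.stack([np.ones((J, K)), effort_std], axis=-1)
    return X_psi, X_p


def fit_single_species(y_i: np.ndarray, covariate_table, effort_std: np.ndarray,
                       model: ModelDefinition, species: str = "",
                       starts: int = 5, seed: int = 0) -> ModelFit:
    """Maximize the single-species likelihood from several jittered starts.

    A species with no detections is returned non-estimable (logL = NaN);
    the best of ``starts`` quasi-Newton runs is kept otherwise.
    """
    n_det = int(np.nansum(y_i))
    fit = ModelFit(model=model, species=species, logL=np.nan, K=model.K,
                   converged=False, estimable=n_det > 0, n_detections=n_det)
    if not fit.estimable:
        return fit

    X_psi, X_p = _design_matrices(covariate_table, effort_std, model)
    rng = np.random.default_rng(seed)

    # naive starting point: logit of naive occupancy / detection frequency
    naive_occ = np.clip((np.nansum(y_i, axis=1) > 0).mean(), 0.05, 0.95)
    naive_det = np.clip(np.nanmean(y_i), 0.02, 0.9)
    base = np.zeros(X_psi.shape[1] + X_p.shape[-1])
    base[0] = np.log(naive_occ / (1 - naive_occ))
    base[X_psi.shape[1]] = np.log(naive_det / (1 - naive_det))

    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in range(starts):
            x0 = base if s == 0 else base + rng.normal(0, 0.5, base.shape)
            try:
                res = minimize(occupancy_neg_loglik, x0,
                               args=(y_i, X_psi, X_p), method="L-BFGS-B",
                               options={"maxiter": 500, "ftol": 1e-12,
                                        "gtol": 1e-7})
            except FloatingPointError:
                continue
            if best is None or res.fun < best.fun:
                best = res
    if best is None or not np.isfinite(best.fun):
        warnings.warn(f"optimizer failed for species {species!r}, "
                      f"model {model.id}")
        return fit

    names = (["psi_intercept"] + [f"psi_{n}" for n in model.psi_covariates]
             + ["p_intercept"] + [f"p_{n}" for n in model.p_covariates])
    fit.logL = -float(best.fun)
    fit.converged = bool(best.success)
    fit.estimates = dict(zip(names, best.x))
    return fit


# ---------------------------------------------------------------------------
# model enumeration under the collinearity rule
# ---------------------------------------------------------------------------

def enumerate_models(names, correlations,
                     threshold: float = DEFAULT_COLLINEARITY_THRESHOLD):
    """All additive occupancy covariate subsets with no pair |r| > threshold.

    Includes the intercept-only model.  ``correlations`` may be a DataFrame
    indexed by covariate name or an array in the order of ``names``.
    """
    if not (0 < threshold <= 1):
        raise ValueError("collinearity threshold must be in (0, 1]")
    names = tuple(names)
    if isinstance(correlations, pd.DataFrame):
        corr = correlations.loc[list(names), list(names)].to_numpy()
    else:
        corr = np.asarray(correlations, dtype=float)
    if corr.shape != (len(names), len(names)):
        raise ValueError("correlation matrix does not match covariate names")
    if not np.allclose(corr, corr.T):
        raise ValueError("correlation matrix must be symmetric")

    forbidden = {(i, j)
                 for i, j in itertools.combinations(range(len(names)), 2)
                 if abs(corr[i, j]) > threshold}
    models = []
    for r in range(len(names) + 1):
        for subset in itertools.combinations(range(len(names)), r):
            if any((i, j) in forbidden
                   for i, j in itertools.combinations(subset, 2)):
                continue
            models.append(ModelDefinition(tuple(names[i] for i in subset)))
    return models


# ---------------------------------------------------------------------------
# community-level AICc
# ---------------------------------------------------------------------------

def community_aicc(sum_logL: float, K: int, n_species: int) -> float:
    """Small-sample AIC of a model's log-likelihood summed across species,
    with sample size n = number of species."""
    if n_species - K - 1 <= 0:
        raise ValueError(f"AICc undefined for K={K} with n={n_species} "
                         "(denominator n - K - 1 <= 0)")
    return -2.0 * sum_logL + 2.0 * K + 2.0 * K * (K + 1) / (n_species - K - 1)


def rank_models(fits_by_model: dict, n_species: int) -> pd.DataFrame:
    """Community ranking table from per-species fits of each model.

    ``fits_by_model`` maps a model id to its list of ModelFit (one per
    species).  Non-converged or non-estimable fits are excluded from the
    log-likelihood sum with a warning.
    """
    rows = []
    for model_id, fits in fits_by_model.items():
        usable = [f for f in fits if f.estimable and f.converged
                  and np.isfinite(f.logL)]
        dropped = len(fits) - len(usable)
        if dropped:
            warnings.warn(f"model {model_id}: {dropped} species fit(s) "
                          "excluded from the log-likelihood sum")
        if not usable:
            continue
        K = usable[0].K
        sum_logL = sum(f.logL for f in usable)
        rows.append({
            "model_id": model_id,
            "covariates": "+".join(usable[0].model.psi_covariates) or "1",
            "K": K, "sum_logL": sum_logL,
            "AICc": community_aicc(sum_logL, K, n_species),
            "n_converged_species": len(usable),
        })
    out = pd.DataFrame(rows).sort_values("AICc", kind="mergesort")
    out["delta_AICc"] = out["AICc"] - out["AICc"].iloc[0]
    return out.reset_index(drop=True)


def select_models(tensor, covariate_table, models=None,
                  threshold: float = DEFAULT_COLLINEARITY_THRESHOLD,
                  starts: int = 5, seed: int = 0) -> pd.DataFrame:
    """Fit every candidate model to every species and rank by community AICc."""
    if models is None:
        models = enumerate_models(covariate_table.names,
                                  covariate_table.correlations, threshold)
    effort_std = tensor.effort.effort_std
    fits_by_model = {}
    for m in models:
        fits = [fit_single_species(tensor.y[i], covariate_table, effort_std,
                                   m, species=sp, starts=starts, seed=seed)
                for i, sp in enumerate(tensor.species)]
        fits_by_model[m.id] = fits
    return rank_models(fits_by_model, n_species=len(tensor.species))
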