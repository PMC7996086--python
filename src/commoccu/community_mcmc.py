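"""Metropolis-within-Gibbs sampler for the hierarchical community occupancy
model.

Model
-----
For species i, grid cell j (in survey block l = l(j)) and weekly occasion k:

    logit(Psi_ij)  = xi_il  + alpha_i . D_j          (habitat use)
    logit(p_ijk)   = nu_il  + beta_i  * effort_jk    (detection)
    z_ij  ~ Bernoulli(Psi_ij)                        (latent occurrence)
    y_ijk ~ Bernoulli(p_ijk * z_ij)                  (observations)

Species-level coefficients are drawn from community hyperdistributions:
slopes alpha_im ~ N(mu_alpha_m, 1/tau_alpha_m) and beta_i ~ N(mu_beta,
1/tau_beta); the per-species-per-block intercept pair (xi_il, nu_il) is
bivariate normal with means (mu_xi, mu_nu), precisions (tau_xi, tau_nu) and
correlation rho, which absorbs abundance-mediated covariation between
habitat use and detectability.

Sampler
-------
Each iteration alternates (a) exact Gibbs draws of the latent z matrix,
(b) element-wise random-walk Metropolis on all species-level coefficients
(vectorized: entries are conditionally independent given z), (c) conjugate
normal draws for hyper-means and conjugate gamma draws for the precisions
of the univariate slope layers, and (d) Metropolis steps for rho and for
the two intercept-layer precisions, whose full conditionals under the
correlated bivariate layer are not gamma.  Proposal scales adapt toward a
0.3-0.45 acceptance rate during burn-in only and are frozen afterwards so
retained draws target the exact posterior.

Hyperpriors default to N(0, sd 2.25) on hyper-means, Gamma(0.1, 0.1) on
precisions, and Uniform(-1, 1) on rho; all are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Priors:
    """Vague community hyperpriors."""
    mean_sd: float = 2.25       # N(0, mean_sd^2) on every hyper-mean
    prec_shape: float = 0.1     # Gamma(shape, rate) on every precision
    prec_rate: float = 0.1
    # rho ~ Uniform(-1, 1)


@dataclass(frozen=True)
class ChainConfig:
    n_chains: int = 3
    n_iter: int = 30000
    burn_in: int = 5000
    thin: int = 3
    seed: int = 0
    adapt_interval: int = 50
    accept_low: float = 0.30
    accept_high: float = 0.45
    sample_hyper: bool = True   # False: fix hyper layer (flat-prior mode)
    save_z: bool = True
    save_psi: bool = True

    def __post_init__(self):
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass
class CommunityData:
    """Validated model inputs on aligned axes."""
    y: np.ndarray            # (S, J, K) with NaN for inactive occasions
    D_std: np.ndarray        # (J, M) standardized site covariates
    effort_std: np.ndarray   # (J, K) standardized effort
    block_idx: np.ndarray    # (J,) integer block index
    species: tuple
    blocks: tuple
    cells: tuple
    covariate_names: tuple

    def __post_init__(self):
        S, J, K = self.y.shape
        if self.D_std.shape[0] != J or self.effort_std.shape != (J, K):
            raise ValueError("covariate/effort dimensions inconsistent with y")
        if len(self.block_idx) != J:
            raise ValueError("block index length mismatch")
        obs = ~np.isnan(self.y)
        if not (obs == obs[:1]).all():
            raise ValueError("NA pattern must be shared across species")

    @property
    def n_species(self):
        return self.y.shape[0]

    @property
    def n_blocks(self):
        return len(self.blocks)

    @classmethod
    def from_tensors(cls, tensor, covariate_table, covariates=None,
                     grid=None) -> "CommunityData":
        """Assemble from a DetectionHistoryTensor and CovariateTable."""
        names = tuple(covariates) if covariates is not None \
            else tuple(covariate_table.names)
        cov_cells = list(covariate_table.cells)
        rows = [cov_cells.index(c) for c in tensor.cells]
        D = covariate_table.D_std[rows][:, [list(covariate_table.names).index(n)
                                            for n in names]]
        block_of_cell = tensor.effort.block_of_cell
        blocks = tuple(dict.fromkeys(block_of_cell[c] for c in tensor.cells))
        bidx = np.array([blocks.index(block_of_cell[c]) for c in tensor.cells])
        return cls(y=tensor.y, D_std=D, effort_std=tensor.effort.effort_std,
                   block_idx=bidx, species=tuple(tensor.species),
                   blocks=blocks, cells=tuple(tensor.cells),
                   covariate_names=names)


# ---------------------------------------------------------------------------
# elementary model quantities
# ---------------------------------------------------------------------------

def habitat_use_prob(xi_il, alpha_i, D_j):
    """Psi = logit^-1(xi_il + alpha_i . D_j)."""
    return expit(np.asarray(xi_il) + np.dot(np.asarray(alpha_i),
                                            np.asarray(D_j)))


def detection_prob(nu_il, beta_i, effort_jk):
    """p = logit^-1(nu_il + beta_i * effort_jk)."""
    return expit(np.asarray(nu_il) + np.asarray(beta_i) * np.asarray(effort_jk))


def z_conditional_prob(y_row, psi, p_row):
    """P(z = 1 | y, psi, p) for one species-cell.

    With any detection the state is certainly occupied.  With an all-zero
    (or all-NA) history, Bayes' rule gives psi*q / (psi*q + 1 - psi) where
    q is the probability of missing the species on every active occasion.
    """
    y_row = np.asarray(y_row, dtype=float)
    obs = ~np.isnan(y_row)
    if np.nansum(y_row) > 0:
        return 1.0
    q = float(np.prod(1.0 - np.asarray(p_row)[obs])) if obs.any() else 1.0
    return psi * q / (psi * q + 1.0 - psi)


def gibbs_update_z(y_row, psi, p_row, rng) -> int:
    """One Gibbs draw of the latent occurrence state for one species-cell."""
    return int(rng.random() < z_conditional_prob(y_row, psi, p_row))


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def rhat(draws: np.ndarray) -> np.ndarray:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    ``draws`` has shape (chains, iterations, ...); each chain is split in
    half, so convergence within a chain is also penalized.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim < 2 or draws.shape[0] < 2:
        raise ValueError("R-hat requires at least two chains")
    c, t = draws.shape[:2]
    half = t // 2
    if half < 2:
        raise ValueError("chains too short for split R-hat")
    parts = np.concatenate([draws[:, :half], draws[:, half:2 * half]], axis=0)
    m, n = parts.shape[:2]
    means = parts.mean(axis=1)
    w = parts.var(axis=1, ddof=1).mean(axis=0)
    b = n * means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * w + b / n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(var_plus / w)
    return np.where(w > 0, r, 1.0)


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

@dataclass
class CommunityPosterior:
    """Thinned post-burn-in draws keyed by parameter name.

    Every array is (n_chains, n_draws, *param_shape).  Hyperparameters are
    scalars or length-M vectors; species-level parameters carry species
    (and block/covariate) axes; ``z`` and ``psi`` carry species x cell.
    """
    draws: dict
    species: tuple
    blocks: tuple
    cells: tuple
    covariate_names: tuple
    config: ChainConfig
    priors: Priors

    HYPER_NAMES = ("mu_xi", "tau_xi", "mu_nu", "tau_nu", "mu_beta",
                   "tau_beta", "rho")

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one parameter pooled over chains: (chains*draws, ...)."""
        d = self.draws[name]
        return d.reshape((-1,) + d.shape[2:])

    def scalar_elements(self):
        """Yield (label, (chains, draws) array) for every scalar element."""
        for name, arr in self.draws.items():
            if name in ("z", "psi"):
                continue
            shape = arr.shape[2:]
            if not shape:
                yield name, arr
                continue
            labels = _element_labels(name, shape, self.species, self.blocks,
                                     self.covariate_names)
            flat = arr.reshape(arr.shape[:2] + (-1,))
            for e, lab in enumerate(labels):
                yield lab, flat[:, :, e]

    def summary(self, include=None) -> pd.DataFrame:
        """Posterior mean, SD, 95% and 50% equal-tailed CRIs and R-hat."""
        rows = []
        for label, a in self.scalar_elements():
            if include is not None and not any(label.startswith(p)
                                               for p in include):
                continue
            pooled = a.reshape(-1)
            q = np.quantile(pooled, [0.025, 0.25, 0.75, 0.975])
            rows.append({"parameter": label, "mean": pooled.mean(),
                         "sd": pooled.std(ddof=1),
                         "cri95_low": q[0], "cri95_high": q[3],
                         "cri50_low": q[1], "cri50_high": q[2],
                         "rhat": float(rhat(a)) if a.shape[0] > 1 else np.nan})
        return pd.DataFrame(rows)

    def hyper_summary(self) -> pd.DataFrame:
        keep = ("mu_xi", "tau_xi", "mu_alpha", "tau_alpha", "mu_nu", "tau_nu",
                "mu_beta", "tau_beta", "rho")
        return self.summary(include=keep)

    def z_draws(self) -> np.ndarray:
        """(chains*draws, S, J) latent occurrence draws."""
        return self.stacked("z")

    def psi_draws(self) -> np.ndarray:
        return self.stacked("psi")


#: known axis semantics per parameter name (sizes can coincide, so the
#: dimension size alone cannot identify the axis)
_PARAM_AXES = {"xi": ("species", "blocks"), "nu": ("species", "blocks"),
               "alpha": ("species", "covs"), "beta": ("species",),
               "mu_alpha": ("covs",), "tau_alpha": ("covs",)}


def _element_labels(name, shape, species, blocks, covs):
    named = {"species": list(species), "blocks": list(blocks),
             "covs": list(covs)}
    kinds = _PARAM_AXES.get(name, ())
    axes = []
    for d, dim in enumerate(shape):
        if d < len(kinds) and len(named[kinds[d]]) == dim:
            axes.append(named[kinds[d]])
        else:
            axes.append([str(i) for i in range(dim)])
    labels = []
    for idx in np.ndindex(*shape):
        suffix = ",".join(str(axes[a][i]) for a, i in enumerate(idx))
        labels.append(f"{name}[{suffix}]")
    return labels


def summarize_posterior(draws) -> pd.DataFrame:
    """Summaries for a bare (chains, iterations[, ...]) draw array or a
    CommunityPosterior."""
    if isinstance(draws, CommunityPosterior):
        return draws.summary()
    a = np.asarray(draws, dtype=float)
    pooled = a.reshape(-1) if a.ndim <= 2 else a.reshape(-1, *a.shape[2:])
    q = np.quantile(pooled, [0.025, 0.25, 0.75, 0.975], axis=0)
    return pd.DataFrame({
        "mean": np.atleast_1d(pooled.mean(axis=0)),
        "sd": np.atleast_1d(pooled.std(axis=0, ddof=1)),
        "cri95_low": np.atleast_1d(q[0]), "cri95_high": np.atleast_1d(q[3]),
        "cri50_low": np.atleast_1d(q[1]), "cri50_high": np.atleast_1d(q[2]),
        "rhat": np.atleast_1d(rhat(a)) if a.shape[0] > 1 else np.nan,
    })


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

def _bvn_loglik(x, v, mu_x, mu_v, tau_x, tau_v, rho):
    """Bivariate-normal log density summed over paired samples."""
    sx = (x - mu_x) * np.sqrt(tau_x)
    sv = (v - mu_v) * np.sqrt(tau_v)
    n = x.size
    quad = np.sum(sx * sx - 2.0 * rho * sx * sv + sv * sv)
    return (n * (0.5 * np.log(tau_x) + 0.5 * np.log(tau_v)
                 - 0.5 * np.log1p(-rho * rho) - LOG_2PI)
            - quad / (2.0 * (1.0 - rho * rho)))


class _AdaptiveScale:
    """Per-element random-walk scales tuned during burn-in only."""

    def __init__(self, shape, lo, hi, interval, init=0.5):
        self.step = np.full(shape, init)
        self.accepts = np.zeros(shape)
        self.lo, self.hi, self.interval = lo, hi, interval
        self.count = 0

    def record(self, accepted):
        self.accepts += accepted
        self.count += 1
        if self.count >= self.interval:
            rate = self.accepts / self.count
            self.step *= np.where(rate < self.lo, 0.85,
                                  np.where(rate > self.hi, 1.15, 1.0))
            np.clip(self.step, 1e-3, 10.0, out=self.step)
            self.accepts[...] = 0.0
            self.count = 0


class _ChainState:
    def __init__(self, data: CommunityData, priors: Priors,
                 config: ChainConfig, rng: np.random.Generator):
        self.data, self.priors, self.config, self.rng = data, priors, config, rng
        S, J, K = data.y.shape
        L, M = data.n_blocks, data.D_std.shape[1]
        self.S, self.J, self.K, self.L, self.M = S, J, K, L, M

        self.obs = ~np.isnan(data.y[0])                      # (J, K)
        self.y0 = np.nan_to_num(data.y)                      # (S, J, K)
        # y log p + (1-y) log(1-p) == log_expit(sign * eta), sign = 2y - 1;
        # sign is zeroed on inactive occasions so they contribute nothing
        # (log_expit(0) would not be 0, so those entries are masked below).
        # detection-side arrays are float32: the (S, J, K) passes dominate
        # runtime and MH acceptance ratios tolerate single precision
        self.sign = np.where(self.obs[None], 2.0 * self.y0 - 1.0,
                             0.0).astype(np.float32)
        self.obs32 = self.obs.astype(np.float32)
        self.effort32 = data.effort_std.astype(np.float32)
        self._ll_buf = np.empty_like(self.sign)
        self.detected = np.nansum(data.y, axis=2) > 0        # (S, J)
        self.G = np.zeros((J, L))
        self.G[np.arange(J), data.block_idx] = 1.0

        # species-level state
        self.xi = rng.normal(0.0, 1.0, (S, L))
        self.nu = rng.normal(-1.0, 1.0, (S, L))
        self.alpha = rng.normal(0.0, 0.5, (S, M))
        self.beta = rng.normal(0.0, 0.5, S)
        self.z = self.detected | (rng.random((S, J)) < 0.5)

        # hyper state
        self.mu_xi, self.mu_nu, self.mu_beta = 0.0, 0.0, 0.0
        self.mu_alpha = np.zeros(M)
        self.tau_xi = self.tau_nu = self.tau_beta = 1.0
        self.tau_alpha = np.ones(M)
        self.rho = 0.0
        if not config.sample_hyper:
            # flat-prior mode: fixed vague independent species-level priors
            t = 1.0 / priors.mean_sd ** 2
            self.tau_xi = self.tau_nu = self.tau_beta = t
            self.tau_alpha = np.full(M, t)

        ai = config.adapt_interval
        lo, hi = config.accept_low, config.accept_high
        self.s_xi = _AdaptiveScale((S, L), lo, hi, ai)
        self.s_nu = _AdaptiveScale((S, L), lo, hi, ai)
        self.s_alpha = _AdaptiveScale((S, M), lo, hi, ai)
        self.s_beta = _AdaptiveScale((S,), lo, hi, ai)
        self.s_tau = _AdaptiveScale((2,), lo, hi, ai)
        self.s_rho = _AdaptiveScale((), lo, hi, ai, init=0.2)

        self.psi_eta = self._psi_eta()
        self.p_eta = self._p_eta()
        self.det_ll = self._det_ll_cells(self.p_eta)   # cache, z-independent

    # --- linear predictors -------------------------------------------------
    def _psi_eta(self):
        return self.xi[:, self.data.block_idx] + self.alpha @ self.data.D_std.T

    def _p_eta(self):
        return (self.nu[:, self.data.block_idx][:, :, None].astype(np.float32)
                + self.beta[:, None, None].astype(np.float32)
                * self.effort32[None])

    # --- log-likelihood pieces ---------------------------------------------
    def _occ_ll(self, eta):
        # z log psi + (1-z) log(1-psi) == log_expit((2z-1) * eta)
        return log_expit(self.zs * eta)                        # (S, J)

    def _det_ll_cells(self, p_eta):
        """Detection log-lik per species-cell if present (z = 1), no z mask."""
        buf = self._ll_buf
        np.multiply(self.sign, p_eta, out=buf)
        log_expit(buf, out=buf)
        buf *= self.obs32[None]
        return buf.sum(axis=2, dtype=np.float64)                # (S, J)

    # --- Gibbs update of z --------------------------------------------------
    def update_z(self):
        # for cells with no detection, sign = -1 on every active occasion,
        # so the cached detection log-lik equals log prod_k (1 - p_ijk);
        # detected cells have z forced to 1 and never read log_q
        log_q = self.det_ll                                     # (S, J)
        log_psi = log_expit(self.psi_eta)
        log_1mpsi = log_expit(-self.psi_eta)
        log_num = log_psi + log_q
        pz = np.exp(log_num - np.logaddexp(log_num, log_1mpsi))
        self.z = self.detected | (self.rng.random((self.S, self.J)) < pz)
        self.zs = 2.0 * self.z - 1.0
        self.occ_ll = self._occ_ll(self.psi_eta)

    # --- Metropolis updates on species-level parameters ---------------------
    def _cond_intercept_prior(self, which):
        """Conditional normal prior of xi given nu (or vice versa)."""
        sd_x = 1.0 / np.sqrt(self.tau_xi)
        sd_v = 1.0 / np.sqrt(self.tau_nu)
        if which == "xi":
            m = self.mu_xi + self.rho * sd_x / sd_v * (self.nu - self.mu_nu)
            var = sd_x ** 2 * (1.0 - self.rho ** 2)
        else:
            m = self.mu_nu + self.rho * sd_v / sd_x * (self.xi - self.mu_xi)
            var = sd_v ** 2 * (1.0 - self.rho ** 2)
        return m, var

    def update_xi(self, adapt):
        prop = self.xi + self.s_xi.step * self.rng.standard_normal((self.S, self.L))
        eta_new = self.psi_eta + (prop - self.xi)[:, self.data.block_idx]
        occ_new = self._occ_ll(eta_new)
        d_ll = (occ_new - self.occ_ll) @ self.G
        m, var = self._cond_intercept_prior("xi")
        d_prior = -0.5 * ((prop - m) ** 2 - (self.xi - m) ** 2) / var
        acc = np.log(self.rng.random((self.S, self.L))) < d_ll + d_prior
        self.xi = np.where(acc, prop, self.xi)
        acc_cells = acc[:, self.data.block_idx]
        self.psi_eta = np.where(acc_cells, eta_new, self.psi_eta)
        self.occ_ll = np.where(acc_cells, occ_new, self.occ_ll)
        if adapt:
            self.s_xi.record(acc)

    def update_alpha(self, adapt):
        acc_all = np.zeros((self.S, self.M))
        for m_idx in range(self.M):
            prop = (self.alpha[:, m_idx]
                    + self.s_alpha.step[:, m_idx] * self.rng.standard_normal(self.S))
            d_eta = np.outer(prop - self.alpha[:, m_idx],
                             self.data.D_std[:, m_idx])
            eta_new = self.psi_eta + d_eta
            occ_new = self._occ_ll(eta_new)
            d_ll = (occ_new - self.occ_ll).sum(axis=1)
            mu, tau = self.mu_alpha[m_idx], self.tau_alpha[m_idx]
            d_prior = -0.5 * tau * ((prop - mu) ** 2
                                    - (self.alpha[:, m_idx] - mu) ** 2)
            acc = np.log(self.rng.random(self.S)) < d_ll + d_prior
            self.alpha[:, m_idx] = np.where(acc, prop, self.alpha[:, m_idx])
            self.psi_eta = np.where(acc[:, None], eta_new, self.psi_eta)
            self.occ_ll = np.where(acc[:, None], occ_new, self.occ_ll)
            acc_all[:, m_idx] = acc
        if adapt:
            self.s_alpha.record(acc_all)

    def update_nu(self, adapt):
        prop = self.nu + self.s_nu.step * self.rng.standard_normal((self.S, self.L))
        p_eta_new = self.p_eta + ((prop - self.nu)[:, self.data.block_idx]
                                  [:, :, None]).astype(np.float32)
        det_ll_new = self._det_ll_cells(p_eta_new)
        d_ll = ((det_ll_new - self.det_ll) * self.z) @ self.G
        m, var = self._cond_intercept_prior("nu")
        d_prior = -0.5 * ((prop - m) ** 2 - (self.nu - m) ** 2) / var
        acc = np.log(self.rng.random((self.S, self.L))) < d_ll + d_prior
        self.nu = np.where(acc, prop, self.nu)
        acc_cells = acc[:, self.data.block_idx]
        self.p_eta = np.where(acc_cells[:, :, None], p_eta_new, self.p_eta)
        self.det_ll = np.where(acc_cells, det_ll_new, self.det_ll)
        if adapt:
            self.s_nu.record(acc)

    def update_beta(self, adapt):
        prop = self.beta + self.s_beta.step * self.rng.standard_normal(self.S)
        p_eta_new = self.p_eta + ((prop - self.beta)[:, None, None]
                                  .astype(np.float32) * self.effort32[None])
        det_ll_new = self._det_ll_cells(p_eta_new)
        d_ll = ((det_ll_new - self.det_ll) * self.z).sum(axis=1)
        d_prior = -0.5 * self.tau_beta * ((prop - self.mu_beta) ** 2
                                          - (self.beta - self.mu_beta) ** 2)
        acc = np.log(self.rng.random(self.S)) < d_ll + d_prior
        self.beta = np.where(acc, prop, self.beta)
        self.p_eta = np.where(acc[:, None, None], p_eta_new, self.p_eta)
        self.det_ll = np.where(acc[:, None], det_ll_new, self.det_ll)
        if adapt:
            self.s_beta.record(acc)

    # --- hyper-layer updates -------------------------------------------------
    def _update_univariate_hyper(self, values, tau):
        """Conjugate normal/gamma update for one univariate coefficient layer."""
        pr = self.priors
        n = values.size
        prec0 = 1.0 / pr.mean_sd ** 2
        prec = tau * n + prec0
        mean = tau * values.sum() / prec
        mu_new = self.rng.normal(mean, 1.0 / np.sqrt(prec))
        shape = pr.prec_shape + 0.5 * n
        rate = pr.prec_rate + 0.5 * np.sum((values - mu_new) ** 2)
        tau_new = self.rng.gamma(shape, 1.0 / rate)
        return mu_new, tau_new

    def update_hyper(self, adapt):
        pr = self.priors
        for m_idx in range(self.M):
            self.mu_alpha[m_idx], self.tau_alpha[m_idx] = \
                self._update_univariate_hyper(self.alpha[:, m_idx],
                                              self.tau_alpha[m_idx])
        self.mu_beta, self.tau_beta = self._update_univariate_hyper(
            self.beta, self.tau_beta)

        # joint conjugate draw of (mu_xi, mu_nu) under the bivariate layer
        x, v = self.xi.ravel(), self.nu.ravel()
        n = x.size
        sx2, sv2 = 1.0 / self.tau_xi, 1.0 / self.tau_nu
        cov = self.rho * np.sqrt(sx2 * sv2)
        sig = np.array([[sx2, cov], [cov, sv2]])
        sig_inv = np.linalg.inv(sig)
        lam = n * sig_inv + np.eye(2) / pr.mean_sd ** 2
        lam_inv = np.linalg.inv(lam)
        mean = lam_inv @ (sig_inv @ np.array([x.sum(), v.sum()]))
        chol = np.linalg.cholesky(lam_inv)
        mu = mean + chol @ self.rng.standard_normal(2)
        self.mu_xi, self.mu_nu = float(mu[0]), float(mu[1])

        # Metropolis on log-precisions of the correlated intercept layer
        # (full conditionals are not gamma once rho != 0); the gamma prior
        # plus the log-scale proposal Jacobian give shape*log(tau) terms.
        tau_acc = np.zeros(2)
        for t_idx, name in enumerate(("tau_xi", "tau_nu")):
            tau = getattr(self, name)
            log_prop = np.log(tau) + self.s_tau.step[t_idx] \
                * self.rng.standard_normal()
            tau_p = float(np.exp(log_prop))
            cur = (_bvn_loglik(x, v, self.mu_xi, self.mu_nu, self.tau_xi,
                               self.tau_nu, self.rho)
                   + (pr.prec_shape * np.log(tau) - pr.prec_rate * tau))
            setattr(self, name, tau_p)
            new = (_bvn_loglik(x, v, self.mu_xi, self.mu_nu, self.tau_xi,
                               self.tau_nu, self.rho)
                   + (pr.prec_shape * np.log(tau_p) - pr.prec_rate * tau_p))
            if np.log(self.rng.random()) < new - cur:
                tau_acc[t_idx] = 1.0
            else:
                setattr(self, name, tau)
        if adapt:
            self.s_tau.record(tau_acc)

        # Metropolis on rho, Uniform(-1, 1) prior
        prop = self.rho + float(self.s_rho.step) * self.rng.standard_normal()
        acc = False
        if -1.0 < prop < 1.0:
            cur = _bvn_loglik(x, v, self.mu_xi, self.mu_nu, self.tau_xi,
                              self.tau_nu, self.rho)
            new = _bvn_loglik(x, v, self.mu_xi, self.mu_nu, self.tau_xi,
                              self.tau_nu, prop)
            if np.log(self.rng.random()) < new - cur:
                self.rho = prop
                acc = True
        if adapt:
            self.s_rho.record(float(acc))

        for nm, val in (("tau_xi", self.tau_xi), ("tau_nu", self.tau_nu),
                        ("tau_beta", self.tau_beta), ("mu_xi", self.mu_xi)):
            if not np.isfinite(val) or (nm.startswith("tau") and val <= 0):
                raise RuntimeError(
                    f"non-finite or invalid posterior state for {nm}: {val!r}")

    def iterate(self, adapt):
        self.update_z()
        self.update_xi(adapt)
        self.update_alpha(adapt)
        self.update_nu(adapt)
        self.update_beta(adapt)
        if self.config.sample_hyper:
            self.update_hyper(adapt)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_mcmc(data: CommunityData, priors: Priors | None = None,
             config: ChainConfig | None = None) -> CommunityPosterior:
    """Run the Metropolis-within-Gibbs sampler and collect thinned draws.

    Per-chain random generators are spawned from ``config.seed`` so results
    are reproducible bit-for-bit for a given seed and package version.
    """
    priors = priors or Priors()
    config = config or ChainConfig()
    S, J, K = data.y.shape
    L, M = data.n_blocks, data.D_std.shape[1]
    C, T = config.n_chains, config.n_draws

    draws = {
        "xi": np.empty((C, T, S, L)), "alpha": np.empty((C, T, S, M)),
        "nu": np.empty((C, T, S, L)), "beta": np.empty((C, T, S)),
        "mu_xi": np.empty((C, T)), "tau_xi": np.empty((C, T)),
        "mu_alpha": np.empty((C, T, M)), "tau_alpha": np.empty((C, T, M)),
        "mu_nu": np.empty((C, T)), "tau_nu": np.empty((C, T)),
        "mu_beta": np.empty((C, T)), "tau_beta": np.empty((C, T)),
        "rho": np.empty((C, T)),
    }
    if config.save_z:
        draws["z"] = np.empty((C, T, S, J), dtype=np.uint8)
    if config.save_psi:
        draws["psi"] = np.empty((C, T, S, J), dtype=np.float32)

    seeds = np.random.SeedSequence(config.seed).spawn(C)
    for c in range(C):
        state = _ChainState(data, priors, config,
                            np.random.default_rng(seeds[c]))
        t = 0
        for it in range(config.n_iter):
            state.iterate(adapt=it < config.burn_in)
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                draws["xi"][c, t] = state.xi
                draws["alpha"][c, t] = state.alpha
                draws["nu"][c, t] = state.nu
                draws["beta"][c, t] = state.beta
                draws["mu_xi"][c, t] = state.mu_xi
                draws["tau_xi"][c, t] = state.tau_xi
                draws["mu_alpha"][c, t] = state.mu_alpha
                draws["tau_alpha"][c, t] = state.tau_alpha
                draws["mu_nu"][c, t] = state.mu_nu
                draws["tau_nu"][c, t] = state.tau_nu
                draws["mu_beta"][c, t] = state.mu_beta
                draws["tau_beta"][c, t] = state.tau_beta
                draws["rho"][c, t] = state.rho
                if config.save_z:
                    draws["z"][c, t] = state.z
                if config.save_psi:
                    draws["psi"][c, t] = expit(state.psi_eta)
                t += 1

    return CommunityPosterior(draws=draws, species=data.species,
                              blocks=data.blocks, cells=data.cells,
                              covariate_names=data.covariate_names,
                              config=config, priors=priors)
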