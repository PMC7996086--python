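"""Hierarchical community sampler: conditionals, diagnostics, recovery."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

import commoccu as co
from commoccu.community_mcmc import z_conditional_prob


def _tiny_data(S=2, J=4, K=3, L=2, M=2, seed=0, y=None):
    rng = np.random.default_rng(seed)
    if y is None:
        y = (rng.random((S, J, K)) < 0.3).astype(float)
    return co.CommunityData(
        y=y, D_std=rng.normal(size=(J, M)), effort_std=rng.normal(size=(J, K)),
        block_idx=np.arange(J) % L, species=tuple(f"sp{i}" for i in range(S)),
        blocks=tuple("AB"[:L]), cells=tuple(f"c{j}" for j in range(J)),
        covariate_names=tuple(f"v{m}" for m in range(M)))


class TestLinkFunctions:
    def test_habitat_use_prob_values(self):
        assert co.habitat_use_prob(0.0, np.zeros(5), np.zeros(5)) == 0.5
        assert co.habitat_use_prob(np.log(4), np.zeros(2), np.zeros(2)) == \
            pytest.approx(0.8, abs=1e-12)
        # forest-only effect: logit^-1(0.3 + 0.34)
        val = co.habitat_use_prob(0.3, np.array([0.34, 0, 0, 0, 0]),
                                  np.array([1.0, 0, 0, 0, 0]))
        assert val == pytest.approx(1 / (1 + np.exp(-0.64)), abs=1e-12)

    def test_detection_prob_monotone_in_effort(self):
        assert co.detection_prob(0.0, 0.0, 0.0) == 0.5
        efforts = np.linspace(-2, 2, 9)
        p = co.detection_prob(-0.5, 0.8, efforts)
        assert (np.diff(p) > 0).all()
        assert co.detection_prob(-0.5, 0.8, 1.3) == \
            pytest.approx(expit(-0.5 + 0.8 * 1.3), abs=1e-12)


class TestZConditional:
    def test_detection_forces_presence(self):
        rng = np.random.default_rng(0)
        draws = [co.gibbs_update_z([1, 0, np.nan], 0.2, [0.5, 0.5, 0.5], rng)
                 for _ in range(20)]
        assert all(d == 1 for d in draws)

    def test_all_zero_history_bayes_rule(self):
        # psi = p = 0.5, two active zero occasions: 0.125 / 0.625 = 0.2
        assert z_conditional_prob([0, 0], 0.5, [0.5, 0.5]) == \
            pytest.approx(0.2, abs=1e-12)

    def test_all_na_returns_prior(self):
        assert z_conditional_prob([np.nan, np.nan], 0.37, [0.5, 0.5]) == \
            pytest.approx(0.37, abs=1e-12)


class TestGibbsAgainstEnumeration:
    def test_z_marginals_match_bruteforce(self):
        """Gibbs draws of z at fixed parameters reproduce the enumerated
        conditional P(z=1 | y, theta) on a 2x4x3 instance within 3 MC SE."""
        S, J, K = 2, 4, 3
        rng = np.random.default_rng(5)
        y = (rng.random((S, J, K)) < 0.25).astype(float)
        y[:, 0, 1] = np.nan
        psi = rng.uniform(0.2, 0.8, (S, J))
        p = rng.uniform(0.1, 0.6, (S, J, K))
        obs = ~np.isnan(y)

        # oracle: brute-force sum over all 2^(S*J) latent configurations
        idx = list(itertools.product((0, 1), repeat=S * J))
        post_num = np.zeros((S, J))
        norm = 0.0
        for flat in idx:
            z = np.array(flat).reshape(S, J)
            pr = 1.0
            for i in range(S):
                for j in range(J):
                    pr *= psi[i, j] if z[i, j] else 1 - psi[i, j]
                    for k in range(K):
                        if not obs[i, j, k]:
                            continue
                        pd_ = p[i, j, k] * z[i, j]
                        pr *= pd_ if y[i, j, k] == 1 else 1 - pd_
            norm += pr
            post_num += pr * z
        truth = post_num / norm

        n_draws = 50_000
        acc = np.zeros((S, J))
        for _ in range(n_draws):
            for i in range(S):
                for j in range(J):
                    acc[i, j] += co.gibbs_update_z(y[i, j], psi[i, j],
                                                   p[i, j], rng)
        est = acc / n_draws
        se = np.sqrt(np.maximum(truth * (1 - truth), 1e-12) / n_draws)
        assert (np.abs(est - truth) <= 3 * se + 1e-9).all()


class TestRhat:
    def test_zero_between_variance_gives_floor(self):
        # all four split chains identical -> B = 0 exactly, so the split
        # estimator returns its floor sqrt((n-1)/n)
        half = np.random.default_rng(0).normal(size=250)
        x = np.concatenate([half, half])
        assert co.rhat(np.stack([x, x])) == pytest.approx(
            np.sqrt(249 / 250), abs=1e-12)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 800), rng.normal(5, 1, 800)
        assert co.rhat(np.stack([a, b])) > 2.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            co.rhat(np.zeros((1, 100)))

    def test_white_noise_matches_reference_implementation(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        draws = rng.normal(size=(3, 1000))
        ours = co.rhat(draws)
        assert ours < 1.05
        ref = float(np.asarray(
            arviz.rhat(arviz.convert_to_dataset(draws[..., None]))
            .to_array().values).squeeze())
        assert ours == pytest.approx(ref, abs=0.02)


class TestSummaries:
    def test_mean_and_quantile_oracle(self):
        draws = np.array([[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]])
        s = co.summarize_posterior(draws)
        assert s["mean"].iloc[0] == 4.5
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 2000))
        s = co.summarize_posterior(x)
        pooled = x.reshape(-1)
        assert s["cri95_low"].iloc[0] == pytest.approx(
            np.quantile(pooled, 0.025), abs=1e-12)
        assert s["cri50_high"].iloc[0] == pytest.approx(
            np.quantile(pooled, 0.75), abs=1e-12)

    def test_element_labels_disambiguate_equal_sized_axes(self,
                                                          short_posterior):
        # 2 covariates and 2 blocks: slope hypermeans must be labeled by
        # covariate, intercepts by (species, block)
        labels = set(short_posterior.hyper_summary()["parameter"])
        assert {"mu_alpha[v0]", "mu_alpha[v1]", "tau_alpha[v0]"} <= labels
        full = set(short_posterior.summary()["parameter"])
        assert {"xi[sp0,A]", "nu[sp2,B]", "alpha[sp1,v1]",
                "beta[sp0]"} <= full

    def test_cri_nesting_in_full_run(self, short_posterior):
        s = short_posterior.summary()
        assert (s["cri50_low"] >= s["cri95_low"]).all()
        assert (s["cri50_high"] <= s["cri95_high"]).all()


@pytest.fixture(scope="module")
def short_posterior():
    data = _tiny_data(S=3, J=6, K=4, seed=9)
    cfg = co.ChainConfig(n_chains=2, n_iter=600, burn_in=200, thin=2, seed=4)
    return co.run_mcmc(data, config=cfg)


class TestSamplerInvariants:
    def test_z_forced_at_detected_cells(self, short_posterior):
        data = _tiny_data(S=3, J=6, K=4, seed=9)
        detected = np.nansum(data.y, axis=2) > 0
        z = short_posterior.z_draws()
        assert (z[:, detected] == 1).all()

    def test_bounded_draws(self, short_posterior):
        psi = short_posterior.psi_draws()
        assert psi.min() >= 0.0 and psi.max() <= 1.0
        for name in ("tau_xi", "tau_nu", "tau_beta"):
            assert (short_posterior.stacked(name) > 0).all()
        assert (np.abs(short_posterior.stacked("rho")) < 1).all()
        assert (short_posterior.stacked("tau_alpha") > 0).all()

    def test_flat_prior_posterior_matches_mle(self):
        """Single-species run with fixed vague priors agrees with the MLE."""
        rng = np.random.default_rng(11)
        J, K = 200, 10
        z = rng.random(J) < 0.6
        y = ((rng.random((J, K)) < 0.3) & z[:, None]).astype(float)

        class _NC:
            names = ()

            def column(self, *a, **k):
                raise KeyError

        fit = co.fit_single_species(y, _NC(), np.zeros((J, K)),
                                    co.ModelDefinition(()), species="x")
        data = co.CommunityData(
            y=y[None], D_std=np.zeros((J, 0)), effort_std=np.zeros((J, K)),
            block_idx=np.zeros(J, dtype=int), species=("x",), blocks=("A",),
            cells=tuple(range(J)), covariate_names=())
        cfg = co.ChainConfig(n_chains=2, n_iter=4000, burn_in=1000, thin=2,
                             seed=3, sample_hyper=False, save_psi=False,
                             save_z=False)
        post = co.run_mcmc(data, config=cfg)
        for draw_name, mle_name in (("xi", "psi_intercept"),
                                    ("nu", "p_intercept")):
            d = post.stacked(draw_name)[:, 0, 0]
            assert abs(d.mean() - fit.estimates[mle_name]) < 2 * d.std()

    def test_prior_predictive_recovers_hypermean_prior(self):
        """With no observations the posterior of mu_xi is its N(0, 2.25)
        prior (KS on near-independent thinned draws)."""
        S, J, K = 2, 3, 2
        y = np.full((S, J, K), np.nan)
        data = co.CommunityData(
            y=y, D_std=np.random.default_rng(0).normal(size=(J, 1)),
            effort_std=np.zeros((J, K)), block_idx=np.array([0, 0, 0]),
            species=("a", "b"), blocks=("A",), cells=("x", "y", "z"),
            covariate_names=("v",))
        cfg = co.ChainConfig(n_chains=2, n_iter=21000, burn_in=1000,
                             thin=100, seed=17, save_psi=False, save_z=False)
        post = co.run_mcmc(data, config=cfg)
        mu = post.stacked("mu_xi")
        ks = stats.kstest(mu, "norm", args=(0, 2.25))
        assert ks.pvalue > 0.01
        rho = post.stacked("rho")
        assert stats.kstest(rho, "uniform", args=(-1, 2)).pvalue > 0.01

    def test_determinism_same_seed(self):
        data = _tiny_data(S=2, J=4, K=3, seed=1)
        cfg = co.ChainConfig(n_chains=2, n_iter=300, burn_in=100, thin=1,
                             seed=21)
        a = co.run_mcmc(data, config=cfg)
        b = co.run_mcmc(data, config=cfg)
        for k in a.draws:
            assert np.array_equal(a.draws[k], b.draws[k])


class TestConfigValidation:
    def test_bad_chain_config(self):
        with pytest.raises(ValueError):
            co.ChainConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            co.ChainConfig(thin=0)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            co.CommunityData(
                y=rng.random((2, 4, 3)), D_std=rng.normal(size=(5, 2)),
                effort_std=rng.normal(size=(4, 3)),
                block_idx=np.zeros(4, dtype=int), species=("a", "b"),
                blocks=("A",), cells=("1", "2", "3", "4"),
                covariate_names=("u", "v"))
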