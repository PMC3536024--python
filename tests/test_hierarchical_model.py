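"""Sampler correctness: likelihood, conditionals, oracle equivalence,
prior recovery, determinism and diagnostics."""

import numpy as np
import pytest

import isobayes as ib
from isobayes.hierarchical_model import _default_mu0


def _state(beta, indicator, tau, tau0):
    return ib.LatentState(
        beta=np.asarray(beta, dtype=float),
        indicator=np.asarray(indicator),
        tau=np.asarray(tau, dtype=float),
        tau0=np.asarray(tau0, dtype=float),
    )


class TestLogLikelihood:
    def test_zero_residual_large_mean_limit(self, single_isoform_partition):
        """mu = y with negligible truncation: each exon contributes log phi(0)."""
        y = np.full((3, 1), 50.0)
        data = ib.GeneData(single_isoform_partition, y, ["S1"])
        state = _state([[50.0]], [[1]], [1.0], [1.0])
        ll = ib.log_likelihood(data, state, 0)
        assert ll == pytest.approx(3 * (-0.5 * np.log(2 * np.pi)), abs=1e-9)

    def test_halving_correction_at_zero_mean(self, single_isoform_partition):
        """mu = 0, tau = 1: density is 2*phi(y); the truncation term is
        exactly log 2 per exon."""
        y = np.array([[0.5], [1.0], [2.0]])
        data = ib.GeneData(single_isoform_partition, y, ["S1"])
        state = _state([[3.0]], [[0]], [1.0], [1.0])
        expected = sum(
            -0.5 * v**2 - 0.5 * np.log(2 * np.pi) + np.log(2.0) for v in y[:, 0]
        )
        assert ib.log_likelihood(data, state, 0) == pytest.approx(expected, abs=1e-9)

    def test_all_indicators_zero_equals_zero_mean_density(self, two_isoform_partition):
        y = np.array([[1.0], [2.0], [0.5]])
        data = ib.GeneData(two_isoform_partition, y, ["S1"])
        off = _state([[4.0], [2.0]], [[0], [0]], [2.0], [1.0, 1.0])
        ll = ib.log_likelihood(data, off, 0)
        assert ll == pytest.approx(ib.truncnorm_loglik(y[:, 0], np.zeros(3), 2.0))

    def test_rejects_nonfinite_state(self, single_isoform_partition):
        data = ib.GeneData(single_isoform_partition, np.ones((3, 1)), ["S1"])
        bad = _state([[np.inf]], [[1]], [1.0], [1.0])
        with pytest.raises(ValueError):
            ib.log_likelihood(data, bad, 0)


class TestUpdateIndicator:
    def test_beta_zero_recovers_prior(self, single_isoform_partition):
        """With beta = 0 the two likelihoods coincide and P(I=1|rest) = p."""
        data = ib.GeneData(single_isoform_partition, np.ones((3, 1)) * 2, ["S1"])
        state = _state([[0.0]], [[1]], [1.0], [1.0])
        hyper = ib.Hyperparameters(p=0.3)
        rng = np.random.default_rng(0)
        draws = [ib.update_indicator(state, data, 0, 0, hyper, rng) for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(0.3, abs=0.025)

    def test_p_near_one_forces_presence(self, single_isoform_partition):
        # mild data contradiction cannot overcome a near-degenerate prior
        data = ib.GeneData(single_isoform_partition, np.zeros((3, 1)), ["S1"])
        state = _state([[0.3]], [[1]], [1.0], [1.0])
        hyper = ib.Hyperparameters(p=1 - 1e-12)
        rng = np.random.default_rng(1)
        assert all(ib.update_indicator(state, data, 0, 0, hyper, rng) for _ in range(50))

    def test_single_exon_odds_match_hand_computation(self):
        """Direct evaluation of the Bernoulli-conditional odds formula."""
        part = ib.PseudoExonPartition("g", "c", [(0, 10)], np.ones((1, 1), dtype=np.int8), ["i"])
        y, beta, tau, p = 3.0, 2.5, 1.3, 0.4
        data = ib.GeneData(part, np.array([[y]]), ["S1"])
        state = _state([[beta]], [[1]], [tau], [1.0])
        ll1 = ib.truncnorm_loglik(np.array([y]), np.array([beta]), tau)
        ll0 = ib.truncnorm_loglik(np.array([y]), np.array([0.0]), tau)
        expected = 1.0 / (1.0 + np.exp(-(np.log(p / (1 - p)) + ll1 - ll0)))
        rng = np.random.default_rng(2)
        hyper = ib.Hyperparameters(p=p)
        draws = [ib.update_indicator(state, data, 0, 0, hyper, rng) for _ in range(6000)]
        assert np.mean(draws) == pytest.approx(expected, abs=0.02)


class TestFitGene:
    def test_constant_signal_recovered(self, single_isoform_partition):
        """Single isoform, y = (5,5,5): posterior beta* within 2 MCSE of 5,
        presence probability near 1 (conjugate closed form, truncation
        negligible at mu/sigma >> 0)."""
        data = ib.GeneData(single_isoform_partition, np.full((3, 1), 5.0), ["S1"])
        fit = ib.fit_gene(data, ib.Hyperparameters(), ib.MCMCSettings(chains=2, iterations=2000, burn_in=500, seed=1))
        bs = fit.pooled("beta_star")[:, 0, 0]
        diag = ib.diagnostics(fit)
        mcse = diag.loc[diag.parameter.str.startswith("beta_star"), "mcse"].iloc[0]
        assert abs(bs.mean() - 5.0) < 2 * max(mcse, 0.01) + 0.05
        assert fit.presence_prob()[0, 0] > 0.95

    def test_all_zero_y_presence_not_above_prior(self, single_isoform_partition):
        data = ib.GeneData(single_isoform_partition, np.zeros((3, 1)), ["S1"])
        hyper = ib.Hyperparameters(p=0.5, mu0=3.0)
        fit = ib.fit_gene(data, hyper, ib.MCMCSettings(chains=2, iterations=2000, burn_in=500, seed=2))
        assert fit.presence_prob()[0, 0] <= hyper.p + 0.03
        assert any("all-zero" in w for w in fit.warnings)

    def test_duplicate_columns_warned_but_sampled(self):
        part = ib.PseudoExonPartition(
            "g", "c", [(0, 100)], np.ones((1, 2), dtype=np.int8), ["a", "b"]
        )
        data = ib.GeneData(part, np.array([[4.0]]), ["S1"])
        fit = ib.fit_gene(data, mcmc=ib.MCMCSettings(chains=1, iterations=200, burn_in=50, seed=0))
        assert any("unidentifiable" in w for w in fit.warnings)
        assert fit.beta.shape[2] == 2

    def test_deterministic_under_seed(self, two_isoform_partition):
        data = ib.GeneData(two_isoform_partition, np.array([[4.0, 1.0]] * 3), ["S1", "S2"])
        kw = dict(mcmc=ib.MCMCSettings(chains=2, iterations=300, burn_in=100, seed=42))
        a = ib.fit_gene(data, **kw)
        b = ib.fit_gene(data, **kw)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.indicator, b.indicator)
        assert np.array_equal(a.tau, b.tau)

    def test_fit_genes_order_invariant(self, two_isoform_partition, single_isoform_partition):
        d1 = ib.GeneData(single_isoform_partition, np.full((3, 1), 3.0), ["S1"])
        p2 = ib.PseudoExonPartition(
            "other", "c", two_isoform_partition.segments,
            two_isoform_partition.design, two_isoform_partition.isoform_ids,
        )
        d2 = ib.GeneData(p2, np.array([[4.0], [6.0], [2.0]]), ["S1"])
        mcmc = ib.MCMCSettings(chains=1, iterations=200, burn_in=50, seed=3)
        fwd = ib.fit_genes([d1, d2], mcmc=mcmc)
        rev = ib.fit_genes([d2, d1], mcmc=mcmc)
        for gid in fwd:
            assert np.array_equal(fwd[gid].beta, rev[gid].beta)


class TestPriorRecovery:
    def test_tau_reproduces_gamma_prior(self, single_isoform_partition):
        """Likelihood off: tau draws match Gamma(a1, a2) mean a1/a2 and
        variance a1/a2^2 within Monte Carlo error."""
        data = ib.GeneData(single_isoform_partition, np.ones((3, 2)), ["S1", "S2"])
        hyper = ib.Hyperparameters(alpha1=3.0, alpha2=1.5, p=0.35)
        fit = ib.fit_gene(
            data, hyper, ib.MCMCSettings(chains=2, iterations=4000, burn_in=100, seed=7),
            prior_only=True,
        )
        tau = fit.pooled("tau").ravel()
        assert tau.mean() == pytest.approx(3.0 / 1.5, rel=0.05)
        assert tau.var() == pytest.approx(3.0 / 1.5**2, rel=0.12)
        assert fit.pooled("indicator").mean() == pytest.approx(0.35, abs=0.02)


class TestOracleEquivalence:
    def test_indicator_marginals_match_enumeration(self, two_isoform_partition):
        """MCMC joint indicator posterior vs brute-force grid quadrature on a
        3-segment, 2-isoform, 1-sample gene (TV <= 0.05)."""
        y = np.array([[4.8], [5.3], [0.4]])
        data = ib.GeneData(two_isoform_partition, y, ["S1"])
        hyper = ib.Hyperparameters(
            alpha1=2.0, alpha2=2.0, alpha1_0=1e6, alpha2_0=1e6, mu0=4.0, p=0.5
        )
        grid_post = ib.grid_indicator_posterior(
            data, hyper, tau0=1.0,
            beta_grid=np.linspace(0, 10, 61), tau_grid=np.linspace(0.05, 6, 40),
        )
        fit = ib.fit_gene(data, hyper, ib.MCMCSettings(chains=2, iterations=6000, burn_in=1000, seed=3))
        I = fit.pooled("indicator")[:, :, 0]
        n = I.shape[0]
        from collections import Counter

        counts = Counter(map(tuple, I.tolist()))
        tv = 0.5 * sum(abs(grid_post[c] - counts.get(c, 0) / n) for c in grid_post)
        assert tv <= 0.05


class TestDiagnostics:
    def _make_samples(self, chain_arrays):
        arr = np.stack(chain_arrays)[:, :, None, None]  # (C, D, 1, 1)
        C, D = arr.shape[:2]
        return ib.PosteriorSamples(
            gene_id="g", isoform_ids=["i"], sample_ids=["S1"], n_segments=1,
            beta=arr, indicator=np.ones_like(arr, dtype=np.int8),
            tau=np.ones((C, D, 1)), tau0=np.ones((C, D, 1)),
            burn_in=0, thin=1, seed=0,
        )

    def test_well_mixed_chains_rhat_near_one(self):
        rng = np.random.default_rng(0)
        s = self._make_samples([rng.normal(0, 1, 4000), rng.normal(0, 1, 4000)])
        diag = ib.diagnostics(s)
        row = diag[diag.parameter.str.startswith("beta_star")].iloc[0]
        assert row["rhat"] == pytest.approx(1.0, abs=0.01)
        assert not row["flagged"]

    def test_disjoint_chains_flagged_by_rhat(self):
        rng = np.random.default_rng(1)
        s = self._make_samples(
            [rng.normal(0, 0.1, 2000), rng.normal(10, 0.1, 2000)]
        )
        diag = ib.diagnostics(s)
        row = diag[diag.parameter.str.startswith("beta_star")].iloc[0]
        # rank-normalized split-Rhat saturates around 1.7-2 for disjoint chains
        assert row["rhat"] > 1.5

    def test_mcse_matches_iid_closed_form(self):
        rng = np.random.default_rng(2)
        n, sd = 5000, 2.0
        s = self._make_samples([rng.normal(0, sd, n), rng.normal(0, sd, n)])
        diag = ib.diagnostics(s)
        row = diag[diag.parameter.str.startswith("beta_star")].iloc[0]
        assert row["mcse"] == pytest.approx(sd / np.sqrt(2 * n), rel=0.10)


def test_default_mu0_is_trimmed_mean():
    y = np.arange(1.0, 101.0).reshape(50, 2)
    mu0 = _default_mu0(y, 3)
    body = np.arange(11.0, 90.0)  # strictly between nearest-rank P10=10 and P90=90
    assert mu0.shape == (3,)
    assert mu0[0] == pytest.approx(body.mean())
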