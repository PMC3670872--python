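"""Bayesian MTC engine: oracle agreement, consistency, contrasts, ranks."""

import numpy as np
import pytest

from mtcsim.engine import (
    MCMCConfig,
    MTCModelSpec,
    PosteriorSamples,
    contrast_estimates,
    contrast_table,
    convergence_diagnostics,
    fit_mtc,
    rank_probabilities,
    single_contrast,
)
from mtcsim.network import network_from_tables
from mtcsim.synthetic import GeneratorConfig, generate_skeleton


def _fake_posterior(k, n=4000, scale=0.1, seed=0, chains=2):
    rng = np.random.default_rng(seed)
    d = rng.normal(0.0, scale, size=(chains, n, k - 1))
    sigma = np.abs(rng.normal(0.1, 0.02, size=(chains, n)))
    return PosteriorSamples(
        treatments=[f"T{i:02d}" for i in range(1, k + 1)], d=d, sigma=sigma
    )


class TestFitOracles:
    def test_symmetric_single_trial_matches_wald(self, symmetric_trial, quick_mcmc):
        """Single 57/100 vs 57/100 trial with the common-effect model:
        posterior mean ~ 0 and posterior SD within 15% of the Wald SE
        sqrt(1/57 + 1/43 + 1/57 + 1/43)."""
        post = fit_mtc(symmetric_trial, MTCModelSpec(sigma_fixed=0.0), quick_mcmc)
        c = single_contrast(post, "A", "B")
        wald = np.sqrt(1 / 57 + 1 / 43 + 1 / 57 + 1 / 43)
        assert abs(c.log_or) < 0.05
        assert abs(c.se - wald) / wald < 0.15

    def test_asymmetric_single_trial_matches_wald(self, quick_mcmc):
        net = network_from_tables([("S1", [("A", 200, 80), ("B", 200, 120)])])
        post = fit_mtc(net, MTCModelSpec(sigma_fixed=0.0), quick_mcmc)
        c = single_contrast(post, "A", "B")
        wald_mean = np.log(120 * 120 / (80 * 80.0))
        wald_se = np.sqrt(2 / 80 + 2 / 120)
        assert c.log_or == pytest.approx(wald_mean, abs=0.05)
        assert abs(c.se - wald_se) / wald_se < 0.15

    def test_indirect_contrast_agrees_with_direct_sum(self):
        """A-B and B-C evidence only: the A-C estimate must equal the sum of
        the A-B and B-C contrasts (consistency equations)."""
        trials = []
        rng = np.random.default_rng(77)
        p = {"A": 0.45, "B": 0.55, "C": 0.65}
        for i in range(6):
            trials.append(
                (f"AB{i}", [("A", 500, int(rng.binomial(500, p["A"]))),
                            ("B", 500, int(rng.binomial(500, p["B"])))])
            )
            trials.append(
                (f"BC{i}", [("B", 500, int(rng.binomial(500, p["B"]))),
                            ("C", 500, int(rng.binomial(500, p["C"])))])
            )
        net = network_from_tables(trials, treatments=["A", "B", "C"])
        post = fit_mtc(net, MTCModelSpec(), MCMCConfig(chains=2, burn_in=1500,
                                                       draws=4000, seed=5))
        ab = single_contrast(post, "A", "B").log_or
        bc = single_contrast(post, "B", "C").log_or
        ac = single_contrast(post, "A", "C").log_or
        # the consistency equations make the indirect contrast the sum ...
        assert ac == pytest.approx(ab + bc, abs=1e-9)
        # ... and it recovers the planted A-C log odds ratio through the
        # indirect path alone (no A-C trials exist)
        logit = lambda q: np.log(q / (1 - q))
        assert ab == pytest.approx(logit(p["B"]) - logit(p["A"]), abs=0.2)
        assert ac == pytest.approx(logit(p["C"]) - logit(p["A"]), abs=0.25)

    def test_rejects_unfilled_or_invalid_networks(self, default_skeleton, quick_mcmc):
        with pytest.raises(ValueError, match="without responder"):
            fit_mtc(default_skeleton, MTCModelSpec(), quick_mcmc)


class TestContrasts:
    def test_twelve_treatments_give_66_contrasts(self):
        post = _fake_posterior(k=12)
        assert len(contrast_estimates(post)) == 66

    def test_two_treatments_give_one_contrast(self):
        post = _fake_posterior(k=2)
        cons = contrast_estimates(post)
        assert len(cons) == 1
        assert cons[0].pair == ("T01", "T02")

    def test_reversed_pair_is_negation(self):
        post = _fake_posterior(k=3, seed=4)
        fwd = single_contrast(post, "T01", "T03")
        rev = single_contrast(post, "T03", "T01")
        assert rev.log_or == pytest.approx(-fwd.log_or)
        assert rev.se == pytest.approx(fwd.se)
        assert rev.odds_ratio == pytest.approx(1.0 / fwd.odds_ratio)
        assert rev.significant == fwd.significant

    def test_estimate_invariants(self):
        for c in contrast_estimates(_fake_posterior(k=4, seed=9)):
            assert c.odds_ratio == pytest.approx(np.exp(c.log_or))
            assert c.ci_low < c.odds_ratio < c.ci_high
            assert c.significant == (c.ci_low > 1.0 or c.ci_high < 1.0)

    def test_credible_rule_close_to_normal_on_gaussian_draws(self):
        post = _fake_posterior(k=3, n=20000, seed=1)
        nrm = contrast_estimates(post, rule="normal")
        crd = contrast_estimates(post, rule="credible")
        for a, b in zip(nrm, crd):
            assert b.ci_low == pytest.approx(a.ci_low, rel=0.05)
            assert b.ci_high == pytest.approx(a.ci_high, rel=0.05)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 1.5])
    def test_alpha_bounds_enforced(self, alpha):
        with pytest.raises(ValueError):
            contrast_estimates(_fake_posterior(k=2), alpha=alpha)

    def test_contrast_table_layout(self):
        tab = contrast_table(contrast_estimates(_fake_posterior(k=3)))
        assert list(tab.columns) == [
            "pair", "logOR_mean", "logOR_sd", "OR", "lo95", "hi95", "significant"
        ]
        assert len(tab) == 3


class TestRankProbabilities:
    def test_rows_and_columns_sum_to_one(self):
        mat = rank_probabilities(_fake_posterior(k=5, seed=3))
        np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(mat.sum(axis=0), 1.0, atol=1e-12)

    def test_symmetric_null_network_ranks_uniformly(self):
        """Identical trials on every pair of 3 treatments: by symmetry each
        treatment is ranked first about 1/3 of the time."""
        trials = [
            ("AB", [("A", 400, 228), ("B", 400, 228)]),
            ("BC", [("B", 400, 228), ("C", 400, 228)]),
            ("AC", [("A", 400, 228), ("C", 400, 228)]),
        ]
        net = network_from_tables(trials, treatments=["A", "B", "C"])
        post = fit_mtc(net, MTCModelSpec(),
                       MCMCConfig(chains=2, burn_in=1500, draws=5000, seed=8))
        mat = rank_probabilities(post)
        np.testing.assert_allclose(mat[1], 1 / 3, atol=0.06)

    def test_planted_dominant_treatment_ranks_first(self):
        trials = [
            ("AB", [("A", 2000, 800), ("B", 2000, 1400)]),
            ("AC", [("A", 2000, 800), ("C", 2000, 810)]),
        ]
        net = network_from_tables(trials, treatments=["A", "B", "C"])
        post = fit_mtc(net, MTCModelSpec(sigma_fixed=0.0),
                       MCMCConfig(chains=2, burn_in=1000, draws=3000, seed=8))
        mat = rank_probabilities(post)
        assert mat.loc["B", 1] > 0.99


class TestDiagnostics:
    def test_single_chain_is_an_error(self):
        post = _fake_posterior(k=3)
        post = PosteriorSamples(post.treatments, post.d[:1], post.sigma[:1])
        with pytest.raises(ValueError, match="2 chains"):
            convergence_diagnostics(post)

    def test_identical_chains_reported_degenerate(self):
        base = _fake_posterior(k=3, chains=1)
        dup = PosteriorSamples(
            base.treatments,
            np.repeat(base.d, 2, axis=0),
            np.repeat(base.sigma, 2, axis=0),
        )
        report = convergence_diagnostics(dup)
        assert report.degenerate

    def test_well_mixed_fit_passes_psrf(self, tiny_network, quick_mcmc):
        post = fit_mtc(tiny_network, MTCModelSpec(), quick_mcmc)
        report = convergence_diagnostics(post)
        assert not report.degenerate
        assert report.max_psrf <= 1.05
        assert set(report.table["parameter"]) == {"d[B]", "sigma"}
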