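"""Trait-model likelihoods vs brute-force oracles; fitting and AICc."""

import numpy as np
import pytest

from _oracles import (bm_loglik_brute, eb_loglik_brute, ou_loglik_brute,
                      random_regime_map, random_tree)
from osteophylo.evomodels import (AlphaDiagnostics, ModelFitResult, _aicc,
                                  akaike_weights, alpha_significance,
                                  fit_model, loglik_bm, loglik_eb, loglik_ou)
from osteophylo.synth import TraitModel, simulate_traits, simulate_tree
from osteophylo.trees import Phylogeny, uniform_regime_map

STATES = ("generalist", "fossorial", "natatorial")


def _fixture(seed, n=6):
    rng = np.random.default_rng(seed)
    tree = random_tree(rng, n)
    rm = random_regime_map(rng, tree, STATES)
    x = rng.normal(0, 1, tree.n_tips)
    return rng, tree, rm, x


class TestLoglikBM:
    def test_two_tip_standard_normal(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        lnL = loglik_bm(tree, np.zeros(2), 1.0, 0.0)
        assert lnL == pytest.approx(-np.log(2 * np.pi), abs=1e-12)

    def test_equal_rates_collapse_to_single_rate(self, tree8_with_history):
        tree, _, rm = tree8_with_history
        x = np.linspace(-1, 1, tree.n_tips)
        sig = {s: 0.6 for s in rm.states}
        assert loglik_bm(tree, x, sig, 0.2, rm) == pytest.approx(
            loglik_bm(tree, x, 0.6, 0.2), abs=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_mvn(self, seed):
        rng, tree, rm, x = _fixture(seed)
        sig = {s: float(rng.uniform(0.3, 2.0)) for s in STATES}
        z0 = float(rng.normal())
        assert loglik_bm(tree, x, sig, z0, rm) == pytest.approx(
            bm_loglik_brute(tree, rm, x, sig, z0), abs=1e-8)

    def test_nonpositive_rate_rejected(self, tree28):
        with pytest.raises(ValueError):
            loglik_bm(tree28, np.zeros(28), -1.0, 0.0)


class TestLoglikOU:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_quadrature_oracle(self, seed):
        rng, tree, rm, x = _fixture(seed)
        alpha = float(rng.uniform(0.3, 4.0))
        sig = float(rng.uniform(0.3, 2.0))
        theta = {s: float(rng.normal(0, 2)) for s in STATES}
        assert loglik_ou(tree, x, alpha, sig, theta, rm) == pytest.approx(
            ou_loglik_brute(tree, rm, x, alpha, sig, theta), abs=1e-6)

    def test_vanishing_alpha_approaches_bm(self, tree8_with_history):
        tree, _, rm = tree8_with_history
        x = np.linspace(-1, 1, tree.n_tips)
        th = {s: 0.3 for s in rm.states}
        lnL_ou = loglik_ou(tree, x, 1e-9, 1.2, th, rm)
        lnL_bm = loglik_bm(tree, x, 1.2, 0.3)
        assert lnL_ou == pytest.approx(lnL_bm, abs=1e-6)

    def test_equal_optima_collapse_to_ou1(self, tree8_with_history):
        tree, _, rm = tree8_with_history
        x = np.linspace(-1, 1, tree.n_tips)
        th = {s: 0.5 for s in rm.states}
        one = uniform_regime_map(tree, rm.root_state)
        assert loglik_ou(tree, x, 2.0, 1.0, th, rm) == pytest.approx(
            loglik_ou(tree, x, 2.0, 1.0, 0.5, one), abs=1e-10)

    def test_nonpositive_alpha_rejected(self, tree28):
        with pytest.raises(ValueError, match="alpha"):
            loglik_ou(tree28, np.zeros(28), 0.0, 1.0, 0.0)


class TestLoglikEB:
    def test_zero_rate_is_bm1(self, tree28):
        x = np.linspace(-2, 2, 28)
        assert loglik_eb(tree28, x, 1.1, 0.4, 0.0) == pytest.approx(
            loglik_bm(tree28, x, 1.1, 0.4), abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_transform_oracle(self, seed):
        rng, tree, _, x = _fixture(seed)
        # burst decay expressed per unit tree height, as everywhere else;
        # deeper decay makes |lnL| explode and the comparison vacuous
        r = float(-rng.uniform(0.2, 3.0) / tree.height)
        sig = float(rng.uniform(0.3, 2.0))
        z0 = float(rng.normal())
        assert loglik_eb(tree, x, sig, z0, r) == pytest.approx(
            eb_loglik_brute(tree, x, sig, z0, r), abs=1e-8)

    def test_tip_variance_decreases_with_burst_strength(self, tree28):
        """Total tip variance sigma0^2 (1 - e^{rT})/|r| shrinks as r drops."""
        from osteophylo.evomodels import _eb_vcv
        v0 = np.diag(_eb_vcv(tree28, -1.0)).max()
        v1 = np.diag(_eb_vcv(tree28, -5.0)).max()
        assert v1 < v0

    def test_positive_rate_rejected(self, tree28):
        with pytest.raises(ValueError):
            loglik_eb(tree28, np.zeros(28), 1.0, 0.0, 0.5)


class TestFitModel:
    def test_aicc_arithmetic(self):
        assert _aicc(-10.0, 3, 28) == pytest.approx(27.0)

    def test_bm1_closed_form_recovery(self):
        tree = simulate_tree(64, seed=21)
        ests = [fit_model(tree, simulate_traits(tree, TraitModel("BM1"), seed=s),
                          "BM1").params["sigma2"] for s in range(30)]
        assert 0.8 < np.median(ests) < 1.2

    def test_nesting_ou_dominates_bm(self, tree28):
        x = simulate_traits(tree28, TraitModel("BM1"), seed=31)
        f_bm = fit_model(tree28, x, "BM1")
        f_ou = fit_model(tree28, x, "OU1")
        f_eb = fit_model(tree28, x, "EB")
        assert f_ou.lnL >= f_bm.lnL - 1e-6
        assert f_eb.lnL >= f_bm.lnL - 1e-6

    def test_nesting_multi_regime(self, tree8_with_history):
        tree, _, rm = tree8_with_history
        x = simulate_traits(tree, TraitModel("BM1"), seed=33)
        n_reg = len(rm.states)
        f1 = fit_model(tree, x, "BM1")
        fm = fit_model(tree, x, f"BM{n_reg}", regime_map=rm)
        assert fm.lnL >= f1.lnL - 1e-6
        o1 = fit_model(tree, x, "OU1")
        om = fit_model(tree, x, f"OU{n_reg}", regime_map=rm)
        assert om.lnL >= o1.lnL - 1e-5

    def test_parameter_counts(self, tree8_with_history):
        tree, _, rm = tree8_with_history
        x = np.linspace(-1, 1, tree.n_tips)
        assert fit_model(tree, x, "BM1").k == 2
        assert fit_model(tree, x, "OU1").k == 3
        assert fit_model(tree, x, "EB").k == 3
        n_reg = len(rm.states)
        assert fit_model(tree, x, f"BM{n_reg}", regime_map=rm).k == n_reg + 1
        assert fit_model(tree, x, f"OU{n_reg}", regime_map=rm).k == n_reg + 2

    def test_aicc_identity_on_emitted_fits(self, tree28):
        x = simulate_traits(tree28, TraitModel("BM1"), seed=35)
        for name in ("BM1", "OU1", "EB"):
            f = fit_model(tree28, x, name)
            assert f.aicc == pytest.approx(
                -2 * f.lnL + 2 * f.k + 2 * f.k * (f.k + 1) / (f.n - f.k - 1))

    def test_missing_regime_map_rejected(self, tree28):
        with pytest.raises(ValueError, match="regime map"):
            fit_model(tree28, np.zeros(28), "OU4")

    def test_profile_se_matches_full_hessian(self):
        """Profile-curvature SE agrees with the full numerical Hessian."""
        from osteophylo.evomodels import _ou_alpha_se
        tree = simulate_tree(32, seed=41)
        x = simulate_traits(tree, TraitModel("OU1", sigma2=1.0, alpha=4.0,
                                             theta=0.0), seed=42)
        f = fit_model(tree, x, "OU1")
        assert f.alpha_se is not None
        full = _ou_alpha_se(tree, x.reindex(tree.tip_labels).to_numpy(),
                            uniform_regime_map(tree, "all"),
                            f.params["alpha"], f.params["sigma2"],
                            f.params["theta"])
        assert full == pytest.approx(f.alpha_se, rel=0.05)


class TestAkaikeWeights:
    def test_two_unit_delta(self):
        w = akaike_weights(np.array([100.0, 102.0]))
        assert w[0] == pytest.approx(0.7311, abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)

    def test_equal_aicc_uniform(self):
        np.testing.assert_allclose(akaike_weights(np.full(5, 7.0)), 0.2)

    def test_normalization_random(self, rng):
        w = akaike_weights(rng.uniform(10, 50, size=7))
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_dict_interface(self):
        w = akaike_weights({"BM1": 10.0, "OU1": 12.0})
        assert w["BM1"] > w["OU1"]
        assert sum(w.values()) == pytest.approx(1.0)


class TestAlphaSignificance:
    def test_boundary_fit_never_significant(self):
        fit = ModelFitResult("OU1", 0.0, {"alpha": 1e-9}, 3, 28, 0.0,
                             alpha_at_bound=True, alpha_se=1e-12,
                             alpha_ci=(1e-9, 1.1e-9))
        assert not alpha_significance(fit).significant

    def test_missing_hessian_indeterminate(self):
        fit = ModelFitResult("OU1", 0.0, {"alpha": 2.0}, 3, 28, 0.0)
        d = alpha_significance(fit)
        assert d.indeterminate and not d.significant

    def test_clear_signal_flagged_significant(self):
        fit = ModelFitResult("OU4", 0.0, {"alpha": 8.0}, 6, 64, 0.0,
                             alpha_se=0.5, alpha_ci=(7.02, 8.98))
        d = alpha_significance(fit, tree_height=1.0)
        assert d.significant and not d.wide_ci

    def test_wide_interval_flagged(self):
        fit = ModelFitResult("OU1", 0.0, {"alpha": 5.0}, 3, 28, 0.0,
                             alpha_se=2.55, alpha_ci=(1e-5, 200.0))
        d = alpha_significance(fit)
        assert d.wide_ci

    def test_non_ou_rejected(self):
        fit = ModelFitResult("BM1", 0.0, {}, 2, 28, 0.0)
        with pytest.raises(ValueError):
            alpha_significance(fit)
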