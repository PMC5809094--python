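import numpy as np
import pytest
from scipy import stats

from phylocomp.interactions import InteractionTimeline
from phylocomp.models import (FAMILIES, FitResult, ModelParams, compare_models,
                              dd_unit_cov, dd_vcv, fit_model, fit_over_maps,
                              mc_moments, mc_unit_cov, model_loglik, ou_unit_cov,
                              ou_vcv, subgroup_loglik)
from phylocomp.simulate import simulate_traits
from phylocomp.synth import sim_tree
from phylocomp.tree import phylo_vcv, read_tree


class TestMCMoments:
    def test_s_zero_reduces_to_bm(self, tree6):
        tl = InteractionTimeline.full_sympatry(tree6)
        m, V = mc_moments(tree6, tl, 0.0, 2.0, 1.5)
        assert np.allclose(m, 1.5)
        assert np.allclose(V, 2.0 * phylo_vcv(tree6), atol=1e-10)

    def test_allopatry_ignores_s(self, tree6):
        tl = InteractionTimeline.full_allopatry(tree6)
        _, V = mc_moments(tree6, tl, -0.8, 1.0, 0.0)
        assert np.allclose(V, phylo_vcv(tree6), atol=1e-10)

    def test_two_tip_vs_independent_euler_ode(self):
        """Exact propagation matches a fine-grained Euler integration of
        the moment ODEs for 2 sympatric tips."""
        tree = read_tree("(A:1,B:1);")
        tl = InteractionTimeline.full_sympatry(tree)
        S, s2 = -0.5, 1.0
        _, V = mc_moments(tree, tl, S, s2, 0.0)
        v = c = 0.0
        dt = 1e-5
        for _ in range(100000):
            dv = 2 * (-S * v + S * c) + s2
            dc = 2 * (S * v - S * c)
            v, c = v + dv * dt, c + dc * dt
        assert V[0, 0] == pytest.approx(v, rel=1e-3)
        assert V[0, 1] == pytest.approx(c, rel=1e-3)

    def test_covariance_psd_and_symmetric(self, tree50, tree50_symp):
        for S in (-0.01, -0.1, -0.5):
            V = mc_unit_cov(tree50, tree50_symp, S)
            assert np.allclose(V, V.T)
            ev = np.linalg.eigvalsh(V)
            assert ev.min() > -1e-10 * max(ev.max(), 1.0)

    def test_include_self_convention(self, tree6):
        """Averaging the clique including self only rescales the repulsion;
        both conventions reduce to BM at S = 0."""
        tl = InteractionTimeline.full_sympatry(tree6)
        V0 = mc_unit_cov(tree6, tl, 0.0, include_self=True)
        assert np.allclose(V0, phylo_vcv(tree6), atol=1e-10)
        Va = mc_unit_cov(tree6, tl, -0.3, include_self=True)
        Vb = mc_unit_cov(tree6, tl, -0.3, include_self=False)
        assert not np.allclose(Va, Vb)

    def test_positive_s_rejected(self, tree6):
        tl = InteractionTimeline.full_sympatry(tree6)
        with pytest.raises(ValueError, match="S must be <= 0"):
            mc_unit_cov(tree6, tl, 0.5)


class TestDDVCV:
    def test_zero_slope_reduces_to_bm(self, tree6):
        tl = InteractionTimeline.full_sympatry(tree6)
        for form in ("lin", "exp"):
            V = dd_vcv(tree6, tl, 1.5, 0.0, form)
            assert np.allclose(V, 1.5 * phylo_vcv(tree6), atol=1e-12)

    def test_constant_n_exponential_closed_form(self):
        tree = read_tree("(A:1,B:1);")
        tl = InteractionTimeline.full_sympatry(tree)  # n == 2 throughout
        V = dd_vcv(tree, tl, 1.0, 0.3, "exp")
        assert np.allclose(V, np.exp(0.6) * phylo_vcv(tree), atol=1e-12)

    def test_three_tip_hand_integration(self, tree3):
        """n jumps 1 -> 2 -> 3 at the two branching events under full
        sympatry; piecewise integrals done by hand."""
        tl = InteractionTimeline.full_sympatry(tree3)
        b, s0 = 1.0, 1.0
        V = dd_vcv(tree3, tl, s0, b, "lin")
        # ages: root 2, cherry 1.  Interval [2,1]: 2 lineages alive, n=2,
        # rate 3; interval [1,0]: 3 lineages, n=3, rate 4.
        a, bb, c = tree3.tip_index("A"), tree3.tip_index("B"), tree3.tip_index("C")
        assert V[a, a] == pytest.approx(3.0 * 1 + 4.0 * 1)
        assert V[c, c] == pytest.approx(3.0 * 1 + 4.0 * 1)
        assert V[a, bb] == pytest.approx(3.0 * 1)  # shared path = first My
        assert V[a, c] == pytest.approx(0.0)

    def test_negative_linear_rate_rejected(self, tree3):
        tl = InteractionTimeline.full_sympatry(tree3)
        with pytest.raises(ValueError, match="negative DDlin rate"):
            dd_unit_cov(tree3, tl, -0.5, "lin")


class TestOUVCV:
    def test_alpha_zero_is_bm(self, tree6):
        assert np.allclose(ou_unit_cov(tree6, 0.0), phylo_vcv(tree6))

    def test_strong_attraction_stationary(self, tree6):
        a = 20.0 / tree6.root_age * 10  # alpha*T = 200
        m, V = ou_vcv(tree6, 1.0, a, theta=3.0, z0=-1.0)
        assert np.allclose(m, 3.0, atol=1e-6)
        assert np.allclose(V, np.eye(6) / (2 * a), atol=1e-8)

    def test_three_tip_direct_formula(self, tree3):
        s2, a = 1.3, 0.4
        _, V = ou_vcv(tree3, s2, a, theta=0.0, z0=0.0)
        T = tree3.root_age
        C = phylo_vcv(tree3)
        expect = s2 / (2 * a) * np.exp(-2 * a * (T - C)) * (1 - np.exp(-2 * a * C))
        assert np.allclose(V, expect, atol=1e-12)


class TestSubgroupLoglik:
    def test_univariate_case(self):
        ll = subgroup_loglik(np.array([1.2]), np.array([0.5]),
                             np.array([[2.0]]), np.array([0]))
        assert ll == pytest.approx(stats.norm.logpdf(1.2, 0.5, np.sqrt(2.0)))

    def test_full_set_matches_scipy(self, tree6, rng):
        V = phylo_vcv(tree6) * 1.7
        x = rng.normal(size=6)
        ll = subgroup_loglik(x, np.zeros(6), V, np.arange(6))
        want = stats.multivariate_normal(np.zeros(6), V).logpdf(x)
        assert ll == pytest.approx(want, abs=1e-9)

    def test_restriction_equals_marginalization(self, tree6, rng):
        V = phylo_vcv(tree6) + 0.2 * np.eye(6)
        x = rng.normal(size=6)
        focal = np.array([0, 2, 5])
        ll = subgroup_loglik(x, np.zeros(6), V, focal)
        want = stats.multivariate_normal(
            np.zeros(3), V[np.ix_(focal, focal)]).logpdf(x[focal])
        assert ll == pytest.approx(want, abs=1e-9)

    def test_missing_data_dropped(self, tree6):
        V = phylo_vcv(tree6)
        x = np.array([1.0, np.nan, 0.5, np.nan, -0.3, 0.1])
        ll = subgroup_loglik(x, np.zeros(6), V, np.arange(6))
        keep = np.array([0, 2, 4, 5])
        want = stats.multivariate_normal(
            np.zeros(4), V[np.ix_(keep, keep)]).logpdf(x[keep])
        assert ll == pytest.approx(want, abs=1e-9)

    def test_non_pd_reports_eigenvalue(self):
        V = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(ValueError, match="eigenvalue"):
            subgroup_loglik(np.array([0.0, 0.0]), np.zeros(2), V,
                            np.arange(2))


class TestBoundaryEquivalences:
    def test_all_competition_models_reduce_to_bm(self, study_tiny):
        tree = study_tiny.tree
        tl = study_tiny.timeline("diet2", study_tiny.modal_guild("diet2"), 0)
        x = study_tiny.traits.values["trait_08"]  # BM-generated
        z0, s2 = 0.3, 1.1
        ll_bm = model_loglik(tree, None, x, "BM",
                             ModelParams("BM", z0=z0, sigma2=s2))
        ll_mc = model_loglik(tree, tl, x, "MC",
                             ModelParams("MC", z0=z0, sigma2=s2, S=0.0))
        ll_dl = model_loglik(tree, tl, x, "DDlin",
                             ModelParams("DDlin", z0=z0, sigma0_2=s2, b=0.0))
        ll_de = model_loglik(tree, tl, x, "DDexp",
                             ModelParams("DDexp", z0=z0, sigma0_2=s2, r=0.0))
        ll_ou = model_loglik(tree, None, x, "OU",
                             ModelParams("OU", z0=z0, sigma2=s2, alpha=1e-12,
                                         theta=z0))
        assert ll_mc == pytest.approx(ll_bm, abs=1e-6)
        assert ll_dl == pytest.approx(ll_bm, abs=1e-6)
        assert ll_de == pytest.approx(ll_bm, abs=1e-6)
        assert ll_ou == pytest.approx(ll_bm, abs=1e-4)


class TestFitModel:
    def test_bm_rate_recovery(self):
        tree = sim_tree(0.3, 0.0, 100, seed=21)
        C = phylo_vcv(tree)
        L = np.linalg.cholesky(C)
        rng = np.random.default_rng(3)
        errs = []
        for _ in range(50):
            x = L @ rng.standard_normal(100) * np.sqrt(2.0)
            f = fit_model(tree, None, x, "BM")
            errs.append(f.params.sigma2 / 2.0)
        assert abs(np.median(errs) - 1.0) < 0.2

    def test_mc_on_allopatric_timeline_equals_bm(self, tree6, rng):
        tl = InteractionTimeline.full_allopatry(tree6)
        x = rng.normal(size=6)
        f_mc = fit_model(tree6, tl, x, "MC")
        f_bm = fit_model(tree6, tl, x, "BM")
        assert f_mc.loglik == pytest.approx(f_bm.loglik, abs=1e-4)

    def test_too_few_tips(self, tree3, rng):
        with pytest.raises(ValueError, match="at least"):
            fit_model(tree3, None, rng.normal(size=3), "OU")

    def test_restart_diagnostics_recorded(self, tree50, tree50_symp, rng):
        x = rng.normal(size=50)
        f = fit_model(tree50, tree50_symp, x, "DDexp")
        assert len(f.restarts) >= 3
        assert {"start", "fun", "success"} <= set(f.restarts[0])


def _fr(family, aicc, n=30):
    k = {"BM": 2, "OU": 3, "MC": 3, "DDlin": 3, "DDexp": 3}[family]
    lnL = -(aicc - 2 * k - 2 * k * (k + 1) / (n - k - 1)) / 2
    return FitResult(ModelParams(family, z0=0.0, sigma2=1.0, S=0.0 if family == "MC" else None,
                                 sigma0_2=1.0 if family.startswith("DD") else None),
                     lnL, k, n, aicc)


class TestCompareModels:
    def test_equal_aicc_gives_uniform_weights(self):
        fits = {f: _fr(f, 100.0) for f in FAMILIES}
        comp = compare_models(fits)
        assert np.allclose(list(comp.weights.values()), 0.2)
        assert comp.relative_support == pytest.approx(0.5)
        assert comp.best == "BM"  # tie broken toward the simpler family

    def test_vanishing_competition_weight(self):
        aiccs = {"BM": 10.0, "OU": 12.0, "MC": 200.0, "DDlin": 210.0,
                 "DDexp": 220.0}
        comp = compare_models({f: _fr(f, a) for f, a in aiccs.items()})
        assert comp.relative_support < 1e-10

    def test_hand_computed_rs(self):
        aiccs = {"BM": 100.0, "OU": 102.0, "MC": 98.0, "DDlin": 105.0,
                 "DDexp": 103.0}
        comp = compare_models({f: _fr(f, a) for f, a in aiccs.items()})
        d = {f: a - 98.0 for f, a in aiccs.items()}
        w = {f: np.exp(-v / 2) for f, v in d.items()}
        tot = sum(w.values())
        w = {f: v / tot for f, v in w.items()}
        rs = max(w["MC"], w["DDlin"], w["DDexp"]) / (
            max(w["BM"], w["OU"]) + max(w["MC"], w["DDlin"], w["DDexp"]))
        assert comp.relative_support == pytest.approx(rs, abs=1e-12)
        assert comp.best == "MC"
        assert sum(comp.weights.values()) == pytest.approx(1.0)

    def test_missing_family_group_errors(self):
        fits = {f: _fr(f, 100.0) for f in ("BM", "OU")}
        with pytest.raises(ValueError, match="family group"):
            compare_models(fits)

    def test_weights_sum_to_one_property(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            aiccs = dict(zip(FAMILIES, 100 + rng.normal(0, 5, 5)))
            comp = compare_models({f: _fr(f, a) for f, a in aiccs.items()})
            assert sum(comp.weights.values()) == pytest.approx(1.0)
            assert 0.0 <= comp.relative_support <= 1.0


class TestFitOverMaps:
    def test_identical_maps_zero_sd(self, study_tiny):
        tree = study_tiny.tree
        tl = study_tiny.timeline("diet2", study_tiny.modal_guild("diet2"), 0)
        x = study_tiny.traits.values["trait_01"]
        comps, summary = fit_over_maps(tree, [tl, tl], x)
        assert summary["sd_rs"] == pytest.approx(0.0, abs=1e-12)
        assert summary["n_converged_maps"] == 2

    def test_single_map_summary(self, study_tiny):
        tree = study_tiny.tree
        tl = study_tiny.timeline("diet2", study_tiny.modal_guild("diet2"), 0)
        x = study_tiny.traits.values["trait_02"]
        comps, summary = fit_over_maps(tree, [tl], x)
        assert summary["mean_rs"] == pytest.approx(comps[0].relative_support)
        assert summary["best_family"] == comps[0].best

    def test_mean_rs_is_arithmetic_mean(self, study_tiny):
        tree = study_tiny.tree
        tls = [study_tiny.timeline("diet2", study_tiny.modal_guild("diet2"), m) for m in range(3)]
        x = study_tiny.traits.values["trait_04"]
        comps, summary = fit_over_maps(tree, tls, x)
        rs = [c.relative_support for c in comps if c is not None]
        assert summary["mean_rs"] == pytest.approx(np.mean(rs))
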