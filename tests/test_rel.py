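"""Random-effects rate-distribution models and cross-dataset tests."""

import numpy as np
import pytest

from selcontrast.model import fit_global_model
from selcontrast.rel import (CONSTRAINT_DF, CONSTRAINTS, OmegaClassFit,
                             RateClass, RateDistribution, _CrossParam,
                             _dist_from_theta, _theta_from_dist,
                             cross_dataset_tests, fit_cross, fit_m1, fit_m2a,
                             fit_m3, fit_rel, lrt, site_class_posteriors)
from selcontrast.simulate import (ScenarioConfig, SiteOmegaSpec,
                                  default_params, make_differential_scenario,
                                  scale_to_mean_pairwise, simulate_alignment,
                                  simulate_tree)
from selcontrast.surface import OmegaProfile, SiteRateSurface


class TestLRT:
    def test_headline_strength_statistic(self):
        """Printed log-likelihoods of the equal-strength null reproduce the
        published chi-square statistic and significance."""
        r = lrt(-16765.49, -16749.63, 1)
        assert r.statistic == pytest.approx(31.72, abs=0.01)
        assert r.p_value < 1e-4

    def test_proportion_statistic_not_significant(self):
        r = lrt(-16750.60, -16749.63, 1)
        assert r.statistic == pytest.approx(1.94, abs=0.01)
        assert r.p_value == pytest.approx(0.1636, abs=0.001)

    def test_equal_likelihoods_give_p_one(self):
        r = lrt(-100.0, -100.0, 3)
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_inverted_likelihoods_warn(self):
        with pytest.warns(RuntimeWarning):
            lrt(-99.0, -100.0, 1)

    def test_df_must_be_positive(self):
        with pytest.raises(ValueError):
            lrt(-1.0, -1.0, 0)


class TestParameterization:
    def test_free_parameter_counts(self):
        expected = {"free": 20, "same_strength": 19, "same_proportion": 19,
                    "same_regime": 18, "shared_distributions": 10}
        for name, n in expected.items():
            assert _CrossParam(name).n_params == n

    def test_df_bookkeeping_matches_nesting(self):
        free = _CrossParam("free").n_params
        for name, df in CONSTRAINT_DF.items():
            assert free - _CrossParam(name).n_params == df

    def test_theta_roundtrip_preserves_distribution(self):
        for dist in (RateDistribution.physalis_like(),
                     RateDistribution.solanum_like()):
            back = _dist_from_theta(_theta_from_dist(dist))
            for a, b in zip(back.classes, dist.classes):
                assert a.dS == pytest.approx(b.dS, rel=1e-3)
                # a strictly-zero dN sits on the purifying-ratio boundary:
                # the logistic parameterization maps it to ~1e-5
                assert a.dN == pytest.approx(b.dN, rel=1e-3, abs=1e-4)
                assert a.prob == pytest.approx(b.prob, rel=1e-3)

    def test_structural_roles_enforced(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            theta = rng.uniform(-4, 1.5, size=10)
            d = _dist_from_theta(theta)
            pos, neu, p1, p2 = d.classes
            assert pos.dN > pos.dS
            assert neu.dN == pytest.approx(neu.dS)
            assert p1.dN < p1.dS and p2.dN < p2.dS
            assert sum(c.prob for c in d.classes) == pytest.approx(1.0, abs=1e-10)

    def test_constrained_unpack_honors_ties(self):
        d1 = RateDistribution.physalis_like()
        d2 = RateDistribution.solanum_like()
        p = _CrossParam("same_strength")
        u1, u2 = p.unpack(p.pack(d1, d2))
        assert u1.positive.omega == pytest.approx(u2.positive.omega)
        p = _CrossParam("same_proportion")
        u1, u2 = p.unpack(p.pack(d1, d2))
        assert u1.positive.prob == pytest.approx(u2.positive.prob)
        p = _CrossParam("same_regime")
        u1, u2 = p.unpack(p.pack(d1, d2))
        assert u1.positive.omega == pytest.approx(u2.positive.omega)
        assert u1.positive.prob == pytest.approx(u2.positive.prob)

    def test_unknown_constraint_rejected(self):
        with pytest.raises(ValueError):
            _CrossParam("bogus")


class TestRelFits:
    @pytest.fixture(scope="class")
    def surface(self, small_aln, small_tree, small_fit):
        return SiteRateSurface.from_global_fit(small_aln, small_fit)

    def test_identical_datasets_same_regime_lrt_near_zero(
            self, small_aln, small_tree, surface):
        free = fit_cross(small_aln, small_tree, small_aln, small_tree, "free",
                         surfaces=(surface, surface), seed=0)
        con = fit_cross(small_aln, small_tree, small_aln, small_tree,
                        "same_regime", surfaces=(surface, surface), seed=0,
                        init=(free.dist1, free.dist2))
        stat = -2.0 * (con.lnl - free.lnl)
        assert stat < 2.0

    def test_nesting_monotonicity(self, small_aln, small_tree, surface):
        free, tests = cross_dataset_tests(
            small_aln, small_tree, small_aln, small_tree,
            surfaces=(surface, surface), n_restarts=1, seed=1)
        for name, (fit, res) in tests.items():
            assert fit.lnl <= free.lnl + 1e-4, name
            assert res.statistic >= -1e-6

    def test_mismatched_length_rejected(self, small_aln, small_tree):
        other = simulate_alignment(small_tree, SiteOmegaSpec.constant(10, 1, 1),
                                   default_params(), seed=1)
        with pytest.raises(ValueError):
            fit_cross(small_aln, small_tree, other, small_tree, "free")

    def test_identical_sequences_boundary_handled(self, code):
        """Degenerate data: the positive-class weight walks to its boundary
        without the optimizer crashing."""
        import numpy as np
        from selcontrast.genetics import CodonAlignment
        tree = simulate_tree(4, "coalescent", 0.4, seed=3)
        states = np.tile(np.arange(25, dtype=np.int16), (4, 1))
        aln = CodonAlignment(tree.labels, states, code)
        gf = fit_global_model(aln, tree, nuc_model="HKY",
                              optimize_exchangeabilities=False)
        fit = fit_rel(aln, tree, global_fit=gf, n_restarts=1, seed=0)
        assert np.isfinite(fit.lnl)


class TestRecovery:
    def test_positive_class_recovery(self):
        """Data from a known 4-class distribution (48 taxa x 300 codons):
        median positive-class omega over 3 replicates within +/-25% of the
        generating 2.5 and median weight within +/-0.1 of 0.4.  The
        positive-class likelihood ridge is flat enough that a median over
        replicates is the appropriate point check."""
        gen = RateDistribution.from_arrays(
            [1.0, 1.0, 0.8, 1.2], [2.5, 1.0, 0.0, 0.24], [0.4, 0.3, 0.15, 0.15])
        ws, ps = [], []
        for seed in (1, 2, 3):
            tree = scale_to_mean_pairwise(
                simulate_tree(48, "coalescent", 1.0, seed=100 + seed), 1.0)
            rng = np.random.default_rng(200 + seed)
            spec, _ = SiteOmegaSpec.from_distribution(gen, 300, rng)
            aln = simulate_alignment(tree, spec, default_params(), seed=300 + seed)
            gf = fit_global_model(aln, tree, nuc_model="HKY")
            fit = fit_rel(aln, tree, global_fit=gf, seed=seed)
            ws.append(fit.distribution.positive.omega)
            ps.append(fit.distribution.positive.prob)
        assert 2.5 * 0.75 <= np.median(ws) <= 2.5 * 1.25
        assert abs(np.median(ps) - 0.4) <= 0.1


class TestOmegaClassModels:
    @pytest.fixture(scope="class")
    def profile(self, small_aln, small_fit):
        return OmegaProfile.from_global_fit(small_aln, small_fit)

    def test_single_class_reduces_to_global_fit(self, small_aln, small_fit,
                                                small_tree, profile):
        """n_classes=1 is the single-ratio model: its optimum must match an
        independent 1-D omega optimization with everything else frozen."""
        from scipy.optimize import minimize_scalar
        from selcontrast.model import PruningEngine

        m0 = fit_m3(small_aln, small_tree, n_classes=1, profile=profile)
        engine = PruningEngine(small_fit.tree, small_aln)
        fac = small_fit.factory

        def nll(lw):
            sp = fac.spectral(1.0, np.exp(lw))
            return -engine.loglikelihood(sp, small_fit.tree.lengths).sum()

        ref = minimize_scalar(nll, bounds=(np.log(1e-6), np.log(100)),
                              method="bounded", options={"xatol": 1e-8})
        assert m0.lnl == pytest.approx(-ref.fun, abs=1e-6)
        assert m0.omegas[0] == pytest.approx(np.exp(ref.x), rel=1e-3)

    def test_m_series_nesting(self, small_aln, small_tree, profile):
        m1 = fit_m1(small_aln, small_tree, profile=profile)
        m2a = fit_m2a(small_aln, small_tree, profile=profile, seed=0)
        m3 = fit_m3(small_aln, small_tree, profile=profile, seed=0)
        assert m2a.lnl >= m1.lnl - 1e-6
        assert m3.lnl >= m2a.lnl - 0.05  # both approximate the same surface

    def test_posteriors_sum_to_one(self, small_aln, small_tree, profile):
        m3 = fit_m3(small_aln, small_tree, profile=profile, seed=0)
        post, p_pos = site_class_posteriors(m3)
        assert np.abs(post.sum(axis=1) - 1.0).max() < 1e-10
        assert np.all((p_pos >= 0) & (p_pos <= 1))

    def test_single_class_posterior_is_one(self, small_aln, small_tree, profile):
        m0 = fit_m3(small_aln, small_tree, n_classes=1, profile=profile)
        post, _ = site_class_posteriors(m0)
        assert np.all(post == 1.0)

    def test_two_class_toy_matches_bayes_formula(self):
        """Hand-computed posterior for a synthetic two-class fit."""
        lk = np.log(np.array([[0.2, 0.01], [0.1, 0.4]]))  # (K=2, L=2)
        fit = OmegaClassFit("Mdisc2", np.array([0.5, 3.0]),
                            np.array([0.7, 0.3]), 0.0, lk)
        post, p_pos = site_class_posteriors(fit)
        expected0 = 0.7 * 0.2 / (0.7 * 0.2 + 0.3 * 0.1)
        assert post[0, 0] == pytest.approx(expected0, abs=1e-12)
        expected_pos1 = 0.3 * 0.4 / (0.7 * 0.01 + 0.3 * 0.4)
        assert p_pos[1] == pytest.approx(expected_pos1, abs=1e-12)
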