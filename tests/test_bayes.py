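"""Per-site omega posteriors, HPD intervals, and the ratio-of-omegas test."""

import numpy as np
import pytest
from scipy import stats

from selcontrast.bayes import (ChainConfig, PosteriorSamples, RatioResult,
                               SitePosteriorSet, call_differential_sites,
                               gelman_rubin, hpd, omega_ratio_test,
                               ratio_table, sample_site_omega)
from selcontrast.surface import OmegaProfile


def _lognormal_hpd_oracle(mu, sigma, mass=0.95):
    """Shortest interval of a lognormal by quantile search."""
    from scipy.optimize import minimize_scalar
    d = stats.lognorm(s=sigma, scale=np.exp(mu))

    def width(p_lo):
        return d.ppf(p_lo + mass) - d.ppf(p_lo)

    r = minimize_scalar(width, bounds=(1e-9, 1.0 - mass - 1e-9),
                        method="bounded")
    return d.ppf(r.x), d.ppf(r.x + mass)


class TestHPD:
    def test_uniform_grid_interval(self):
        s = np.linspace(1.0, 2.0, 101)
        lo, hi = hpd(s, mass=0.9)
        assert hi - lo == pytest.approx(0.9, abs=0.011)
        assert lo >= 1.0 and hi <= 2.0

    def test_constant_samples_degenerate(self):
        lo, hi = hpd(np.full(50, 3.0))
        assert lo == hi == 3.0

    def test_mass_one_spans_range(self):
        s = np.arange(30, dtype=float)
        assert hpd(s, mass=1.0) == (0.0, 29.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            hpd(np.ones(10))

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError):
            hpd(np.ones(30), mass=0.0)
        with pytest.raises(ValueError):
            hpd(np.ones(30), mass=1.5)

    def test_lognormal_matches_analytic_interval(self):
        """Sample HPD of a skewed distribution tracks the exact shortest
        interval; a skewed target distinguishes HPD from an equal-tail
        interval."""
        rng = np.random.default_rng(5)
        draws = rng.lognormal(0.0, 1.0, size=200_000)
        lo, hi = hpd(draws, mass=0.95)
        lo_ref, hi_ref = _lognormal_hpd_oracle(0.0, 1.0, 0.95)
        assert lo == pytest.approx(lo_ref, abs=0.02)
        assert hi == pytest.approx(hi_ref, rel=0.05)
        # and it is visibly different from the central interval
        et_lo, et_hi = stats.lognorm(s=1.0).ppf([0.025, 0.975])
        assert hi < et_hi
        assert (hi - lo) < (et_hi - et_lo)


class TestRatioResult:
    def test_exclusion_and_direction(self):
        r = RatioResult(1, 2.0, 1.2, 3.0)
        assert r.excludes_one and r.direction == 1
        r = RatioResult(1, 0.5, 0.2, 0.9)
        assert r.excludes_one and r.direction == -1
        r = RatioResult(1, 1.1, 0.8, 1.5)
        assert not r.excludes_one and r.direction == 0

    def test_bad_interval_rejected(self):
        with pytest.raises(ValueError):
            RatioResult(1, 1.0, 2.0, 1.0)

    def test_constant_posteriors_give_exact_ratio(self):
        s1 = PosteriorSamples(4, np.full(100, 2.0), 0.3)
        s2 = PosteriorSamples(4, np.full(100, 1.0), 0.3)
        r = omega_ratio_test(s1, s2, n_pairs=500, seed=0)
        assert r.geometric_mean == pytest.approx(2.0)
        assert (r.hpd_lower, r.hpd_upper) == (2.0, 2.0)
        assert r.excludes_one and r.direction == 1

    def test_geometric_mean_identity(self):
        """The summary is exp(mean log ratio) of the resampled pairs, exactly
        reproducible from the same seed."""
        rng = np.random.default_rng(11)
        s1 = PosteriorSamples(2, rng.lognormal(0.4, 0.3, 400), 0.3)
        s2 = PosteriorSamples(2, rng.lognormal(-0.1, 0.3, 400), 0.3)
        r = omega_ratio_test(s1, s2, n_pairs=2000, seed=7)
        pair_rng = np.random.default_rng(7)
        a = pair_rng.choice(s1.draws, size=2000, replace=True)
        b = pair_rng.choice(s2.draws, size=2000, replace=True)
        assert r.geometric_mean == pytest.approx(
            np.exp(np.mean(np.log(a / b))), abs=1e-12)

    def test_reciprocal_symmetry(self):
        rng = np.random.default_rng(3)
        s1 = PosteriorSamples(1, rng.lognormal(0.5, 0.4, 600), 0.3)
        s2 = PosteriorSamples(1, rng.lognormal(-0.3, 0.4, 600), 0.3)
        ab = omega_ratio_test(s1, s2, n_pairs=20_000, seed=5)
        ba = omega_ratio_test(s2, s1, n_pairs=20_000, seed=5)
        assert np.log(ab.geometric_mean) == pytest.approx(
            -np.log(ba.geometric_mean), abs=0.02)
        assert ab.direction == -ba.direction

    def test_site_mismatch_rejected(self):
        s1 = PosteriorSamples(1, np.ones(50) * 2, 0.3)
        s2 = PosteriorSamples(2, np.ones(50), 0.3)
        with pytest.raises(ValueError):
            omega_ratio_test(s1, s2)

    def test_empty_or_nonpositive_draws_rejected(self):
        with pytest.raises(ValueError):
            PosteriorSamples(1, np.array([]), 0.3)
        with pytest.raises(ValueError):
            PosteriorSamples(1, np.array([1.0, -2.0]), 0.3)


class TestSampler:
    @pytest.fixture(scope="class")
    def profile(self, small_aln, small_fit):
        return OmegaProfile.from_global_fit(small_aln, small_fit)

    @pytest.fixture(scope="class")
    def posterior(self, profile):
        return SitePosteriorSet(profile, ChainConfig.fast(seed=1))

    def test_chain_bookkeeping(self, posterior, small_aln):
        cfg = posterior.config
        n_kept = len(range(cfg.burn_in, cfg.iterations, cfg.thin))
        assert posterior.draws.shape == (n_kept, small_aln.n_codons)
        assert np.all(posterior.draws > 0)
        assert np.all((posterior.acceptance > 0) & (posterior.acceptance < 1))

    def test_site_extraction_and_p_positive(self, posterior):
        s = posterior.site(1)
        assert s.site == 1
        assert s.p_positive == pytest.approx(
            float(np.mean(posterior.draws[:, 0] > 1.0)))
        assert np.allclose(posterior.p_positive(),
                           (posterior.draws > 1.0).mean(axis=0))

    def test_flat_likelihood_recovers_prior(self, small_aln, small_fit,
                                            small_tree, code):
        """A fully missing column has likelihood 1 everywhere, so the
        posterior is the truncated 1/omega prior: flat in log omega."""
        from selcontrast.genetics import MISSING, CodonAlignment

        states = np.full((small_aln.n_taxa, 2), MISSING, dtype=np.int16)
        blank = CodonAlignment(small_aln.labels, states, code)
        prof = OmegaProfile.from_global_fit(blank, small_fit)
        post = SitePosteriorSet(prof, ChainConfig.fast(seed=2))
        x = np.log(post.draws[:, 0])
        from selcontrast.bayes import OMEGA_SUPPORT
        lo, hi = np.log(OMEGA_SUPPORT[0]), np.log(OMEGA_SUPPORT[1])
        u = stats.uniform(lo, hi - lo)
        assert abs(x.mean() - u.mean()) < 0.3
        assert abs(x.std() - u.std()) < 0.3
        # thirds of the log-range each hold roughly a third of the draws
        counts = np.histogram(x, bins=3, range=(lo, hi))[0] / x.size
        assert np.abs(counts - 1 / 3).max() < 0.1

    def test_two_chains_converge(self, profile):
        c1 = SitePosteriorSet(profile, ChainConfig.fast(seed=10))
        c2 = SitePosteriorSet(profile, ChainConfig.fast(seed=11))
        rhats = [gelman_rubin([c1.draws[:, i], c2.draws[:, i]])
                 for i in range(profile.L)]
        assert max(rhats) < 1.1

    def test_single_site_wrapper(self, small_aln, small_tree, small_fit,
                                 profile):
        s = sample_site_omega(small_aln, small_tree, small_fit, 3,
                              config=ChainConfig.fast(seed=1), profile=profile)
        assert s.site == 3
        assert len(s.draws) > 1000

    def test_bad_chain_config_rejected(self):
        with pytest.raises(ValueError):
            ChainConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            ChainConfig(thin=0)


class TestCalls:
    def _ratio(self, site, lo, hi):
        return RatioResult(site, np.sqrt(lo * hi), lo, hi)

    def test_screening_rule(self):
        ratios = [self._ratio(1, 1.3, 2.5),   # excludes 1, strong support
                  self._ratio(2, 1.3, 2.5),   # excludes 1, weak support
                  self._ratio(3, 0.7, 1.4)]   # does not exclude 1
        pb = (np.array([0.99, 0.5, 0.99]), np.array([0.1, 0.2, 0.99]))
        calls = call_differential_sites(ratios, pb)
        assert [c.called for c in calls] == [True, False, False]
        assert calls[0].direction == 1
        assert calls[1].direction == 0  # uncalled sites report no direction

    def test_eb_support_can_rescue_a_site(self):
        ratios = [self._ratio(1, 1.3, 2.5)]
        pb = (np.array([0.5]), np.array([0.5]))
        eb = (np.array([0.97]), np.array([0.1]))
        assert not call_differential_sites(ratios, pb)[0].called
        assert call_differential_sites(ratios, pb, eb)[0].called

    def test_calls_subset_of_exclusions(self):
        rng = np.random.default_rng(0)
        ratios, pbs = [], []
        for i in range(30):
            lo = rng.uniform(0.5, 1.2)
            ratios.append(self._ratio(i + 1, lo, lo + rng.uniform(0.1, 1.0)))
            pbs.append(rng.uniform(0, 1))
        pb = (np.array(pbs), np.array(pbs)[::-1].copy())
        for c in call_differential_sites(ratios, pb):
            if c.called:
                assert c.ratio.excludes_one

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            call_differential_sites([self._ratio(1, 1.2, 2.0)],
                                    (np.ones(2), np.ones(2)))

    def test_table_columns(self):
        ratios = [self._ratio(1, 1.3, 2.5)]
        pb = (np.array([0.99]), np.array([0.1]))
        tab = ratio_table(call_differential_sites(ratios, pb))
        assert set(tab.columns) >= {"site", "geometric_mean", "hpd_lower",
                                    "hpd_upper", "excludes_one", "called",
                                    "direction"}
        assert bool(tab.loc[0, "called"])
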