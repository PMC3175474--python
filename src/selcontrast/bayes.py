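"""Per-site Bayesian omega posteriors and the ratio-of-omegas test.

For each codon, an independent Metropolis–Hastings random walk targets the
posterior of the site's dN/dS ratio under the phylogenetic column
likelihood (global parameters frozen), with an improper 1/omega prior
truncated to [1e-3, 100].  In log-omega coordinates that prior is flat, so
the walk proposes Gaussian steps on x = log(omega) and accepts with the
likelihood ratio alone.

Differential selection between two allele sets is then assessed per codon
by resampling the two independent posteriors: draw pairs, form
r = omega_1/omega_2, and report the geometric mean exp(mean log r) and the
95% highest-posterior-density interval of r.  A site shows significantly
different selection when that HPD excludes 1; the final *call* additionally
requires at least one dataset to show posterior probability >= 0.95 of
positive selection (by the sampler itself or by the empirical-Bayes
site-class posterior), screening out sites that are merely differently
purifying.

Chains evaluate the column log-likelihood through the cached omega profile
of :mod:`selcontrast.surface`; that cache is what makes full-length chains
(hundreds of thousands of generations) affordable, and all sites advance
in lock-step as one vectorized walk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .surface import OmegaProfile

#: omega support of the sampler's uniform-in-log prior; symmetric about 1
#: in log space so that, absent data, P(omega > 1) = 0.5 and diffuse
#: posteriors are not dragged toward either selection regime
OMEGA_SUPPORT = (0.01, 100.0)


@dataclass(frozen=True)
class ChainConfig:
    """MCMC settings.

    Full-length defaults: 500,000 generations, every 100th sampled, 50,000
    burn-in.  ``fast()`` gives the scaled-down settings used by tests and
    simulation studies.
    """

    iterations: int = 500_000
    thin: int = 100
    burn_in: int = 50_000
    proposal_scale: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thinning interval must be >= 1")

    @classmethod
    def fast(cls, seed: int = 0) -> "ChainConfig":
        return cls(iterations=50_000, thin=10, burn_in=5_000, seed=seed)


@dataclass
class PosteriorSamples:
    """Post-burn-in omega draws for one codon."""

    site: int
    draws: np.ndarray
    acceptance_rate: float

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.size == 0:
            raise ValueError("posterior sample vector must be non-empty")
        if np.any(self.draws <= 0):
            raise ValueError("omega draws must be positive")

    @property
    def p_positive(self) -> float:
        """P(omega > 1) as the fraction of draws above 1."""
        return float(np.mean(self.draws > 1.0))


def _mh_all_sites(profile: OmegaProfile, config: ChainConfig) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized random-walk MH over all sites; returns (draws (n_kept, L),
    acceptance rates (L,))."""
    rng = np.random.default_rng(config.seed)
    L = profile.L
    lo, hi = np.log(OMEGA_SUPPORT[0]), np.log(OMEGA_SUPPORT[1])
    x = np.zeros(L)  # start at omega = 1
    lp = profile.loglik_sites_at(x)
    kept = []
    accepted = np.zeros(L)
    proposed = np.zeros(L)
    for it in range(config.iterations):
        step = rng.normal(0.0, config.proposal_scale, size=L)
        xn = x + step
        inside = (xn >= lo) & (xn <= hi)
        lpn = np.where(inside, profile.loglik_sites_at(xn), -np.inf)
        accept = np.log(rng.random(L)) < (lpn - lp)
        accept &= inside
        x = np.where(accept, xn, x)
        lp = np.where(accept, lpn, lp)
        proposed += 1
        accepted += accept
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            kept.append(x.copy())
    return np.exp(np.array(kept)), accepted / proposed


class SitePosteriorSet:
    """Posterior omega draws for every codon of one dataset (one chain)."""

    def __init__(self, profile: OmegaProfile, config: ChainConfig):
        draws, acc = _mh_all_sites(profile, config)
        self.draws = draws  # (n_kept, L)
        self.acceptance = acc
        self.config = config
        self.L = profile.L
        bad = (acc < 0.05) | (acc > 0.8)
        if np.any(bad):
            warnings.warn(
                f"{int(bad.sum())} site chains have acceptance rates outside "
                "[0.05, 0.8]; consider tuning proposal_scale", RuntimeWarning)

    def site(self, site: int) -> PosteriorSamples:
        return PosteriorSamples(site, self.draws[:, site - 1],
                                float(self.acceptance[site - 1]))

    def p_positive(self) -> np.ndarray:
        return (self.draws > 1.0).mean(axis=0)


def sample_site_omega(aln, tree, global_fit, site: int,
                      config: ChainConfig | None = None,
                      profile: OmegaProfile | None = None) -> PosteriorSamples:
    """Posterior omega draws for one codon (runs the vectorized walk and
    extracts the requested site; pass ``profile`` to amortize)."""
    config = config or ChainConfig.fast()
    if profile is None:
        profile = OmegaProfile.from_global_fit(aln, global_fit)
    return SitePosteriorSet(profile, config).site(site)


def gelman_rubin(chains: list[np.ndarray]) -> float:
    """Potential scale reduction factor across chains (on log omega)."""
    arr = np.log(np.asarray(chains, dtype=float))
    m, n = arr.shape
    means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W)) if W > 0 else 1.0


# ---------------------------------------------------------------------------
# HPD and the ratio test
# ---------------------------------------------------------------------------

def hpd(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws.

    Sorted-window construction: among all windows of ceil(mass*n)
    consecutive order statistics the narrowest wins; ties break toward the
    lowest start.
    """
    s = np.sort(np.asarray(samples, dtype=float))
    n = len(s)
    if n < 20:
        raise ValueError("need at least 20 samples for an HPD interval")
    if not 0.0 < mass <= 1.0:
        raise ValueError("mass must be in (0, 1]")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(s[0]), float(s[-1])
    widths = s[k - 1:] - s[: n - k + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + k - 1])


@dataclass
class RatioResult:
    """Posterior ratio omega_1/omega_2 summary for one codon."""

    site: int
    geometric_mean: float
    hpd_lower: float
    hpd_upper: float
    excludes_one: bool = field(init=False)
    direction: int = 0  # +1: dataset 1 larger; -1: dataset 2; 0: undecided

    def __post_init__(self):
        if self.hpd_lower > self.hpd_upper:
            raise ValueError("HPD lower bound above upper bound")
        self.excludes_one = self.hpd_lower > 1.0 or self.hpd_upper < 1.0
        if self.excludes_one:
            self.direction = 1 if self.hpd_lower > 1.0 else -1


def omega_ratio_test(samples1: PosteriorSamples, samples2: PosteriorSamples,
                     n_pairs: int = 10_000, seed: int = 0,
                     mass: float = 0.95) -> RatioResult:
    """Resample the two posteriors into ratio draws and summarize.

    Pairs are drawn independently with replacement (the chains are
    independent by construction); the geometric mean is exp(mean log ratio).
    """
    if samples1.site != samples2.site:
        raise ValueError("posterior samples come from different sites")
    rng = np.random.default_rng(seed)
    a = rng.choice(samples1.draws, size=n_pairs, replace=True)
    b = rng.choice(samples2.draws, size=n_pairs, replace=True)
    r = a / b
    gm = float(np.exp(np.mean(np.log(r))))
    # the HPD is taken on the log scale: a rate ratio is scale-free, and the
    # shortest-interval construction is not parameterization-invariant — in
    # raw space the right skew of the ratio pulls the interval leftward
    lo, hi = hpd(np.log(r), mass=mass)
    return RatioResult(samples1.site, gm, float(np.exp(lo)), float(np.exp(hi)))


# ---------------------------------------------------------------------------
# Differential-site calls
# ---------------------------------------------------------------------------

@dataclass
class SiteSelectionCall:
    """Screened differential-selection call for one codon."""

    site: int
    called: bool
    ratio: RatioResult
    support: dict  # posterior P(omega>1) per dataset per method

    @property
    def direction(self) -> int:
        return self.ratio.direction if self.called else 0


def call_differential_sites(ratios: list[RatioResult],
                            posteriors_bayes: tuple[np.ndarray, np.ndarray],
                            posteriors_eb: tuple[np.ndarray, np.ndarray] | None = None,
                            threshold: float = 0.95) -> list[SiteSelectionCall]:
    """Apply the screening rule to ratio results.

    A site is called iff its ratio HPD excludes 1 *and* at least one
    dataset shows P(omega > 1) >= ``threshold`` by either the sampler
    (``posteriors_bayes``) or the empirical-Bayes site-class posterior
    (``posteriors_eb``).  Inputs are per-site arrays indexed like the
    ratio list.
    """
    pb1, pb2 = posteriors_bayes
    pe1, pe2 = posteriors_eb if posteriors_eb is not None else (None, None)
    L = len(ratios)
    for arr in (pb1, pb2, pe1, pe2):
        if arr is not None and len(arr) != L:
            raise ValueError("posterior arrays must match the ratio list length")
    calls = []
    for i, r in enumerate(ratios):
        support = {"bayes_1": float(pb1[i]), "bayes_2": float(pb2[i])}
        if pe1 is not None:
            support["eb_1"] = float(pe1[i])
            support["eb_2"] = float(pe2[i])
        strong = max(support.values()) >= threshold
        calls.append(SiteSelectionCall(r.site, bool(r.excludes_one and strong),
                                       r, support))
    return calls


def ratio_table(calls: list[SiteSelectionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "site": c.site, "geometric_mean": c.ratio.geometric_mean,
            "hpd_lower": c.ratio.hpd_lower, "hpd_upper": c.ratio.hpd_upper,
            "excludes_one": c.ratio.excludes_one, "called": c.called,
            "direction": c.direction, **c.support,
        })
    return pd.DataFrame(rows)
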