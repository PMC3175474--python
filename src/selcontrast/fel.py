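"""Fixed-effects likelihood (FEL) per-site selection tests.

With global parameters (frequencies, exchangeabilities, branch lengths)
frozen at the dataset-level fit, dS and dN are estimated at each codon
directly by maximizing the single-column likelihood.  Three nested tests
are built on that machinery:

* ``fel_site_fit`` / ``fel_scan`` — the per-site positive-selection test:
  alternative (dS, dN) free versus null dN = dS (1 df).  The chi-square
  p-value is two-sided; a *positive-selection call* additionally requires
  dN-hat > dS-hat, which keeps empirical false-positive rates at or below
  nominal.
* ``fel_csp`` — compare selective pressures across two datasets at a
  homologous codon: alternative (dS1, dN1, dS2, dN2) free (4 parameters)
  versus null dN1/dS1 = dN2/dS2 (3 parameters), 1 df.
* ``fel_clade`` — foreground/background contrast on a tagged tree:
  null one (dS, dN) for all branches; alternative shared dS with separate
  dN for foreground (clade + stem) and background branches, 1 df.

``run_power_analysis`` is the simulation harness: replicate alignments are
generated from a per-site rate template, rescanned, and p-values tallied
into width-0.01 bins to estimate power and false-positive rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .genetics import MISSING, CodonAlignment
from .model import GlobalFit, PruningEngine, QFactory, fit_global_model
from .surface import SiteRateSurface
from .trees import TAG_BACKGROUND, TAG_CLADE, TAG_STEM, Phylogeny

RATE_FLOOR = 1e-6
RATE_CEIL = 10.0


@dataclass
class SiteFitResult:
    """Per-codon fixed-effects estimates and test outcome."""

    site: int  # 1-based codon position
    dS: float
    dN: float
    lnl_alt: float
    lnl_null: float
    statistic: float
    p_value: float
    test: str  # 'positive_selection' | 'csp' | 'clade'
    extra: dict = field(default_factory=dict)

    @property
    def omega(self) -> float:
        return self.dN / self.dS if self.dS > 0 else np.inf

    @property
    def positive_call(self) -> bool:
        """Positive-selection call: significant LRT *and* dN-hat > dS-hat."""
        return self.p_value <= 0.05 and self.dN > self.dS


def _column_loglik_factory(aln: CodonAlignment, fit: GlobalFit, site: int):
    """Exact single-column log-likelihood as a function of (dS, dN)."""
    engine = PruningEngine(fit.tree, aln)
    fac = fit.factory
    lengths = fit.tree.lengths
    sites = np.array([site - 1])

    def loglik(dS: float, dN: float) -> float:
        sp = fac.spectral(max(dS, RATE_FLOOR), max(dN, RATE_FLOOR))
        return float(engine.loglikelihood(sp, lengths, sites=sites)[0])

    return loglik


def _fit_column(loglik, invariant: bool):
    """Maximize a column likelihood: alternative free (dS,dN), null dN=dS."""
    if invariant:
        lnl = loglik(RATE_FLOOR, RATE_FLOOR)
        return (RATE_FLOOR, RATE_FLOOR, lnl, lnl)

    def nll_alt(x):
        return -loglik(np.exp(x[0]), np.exp(x[1]))

    lo, hi = np.log(RATE_FLOOR), np.log(RATE_CEIL)
    best = None
    for x0 in ([0.0, 0.0], [np.log(0.3), np.log(1.5)], [np.log(1.5), np.log(0.3)]):
        res = minimize(nll_alt, x0, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 300})
        if best is None or res.fun < best.fun:
            best = res
    dS, dN = np.clip(np.exp(best.x), RATE_FLOOR, RATE_CEIL)
    lnl_alt = -best.fun

    res0 = minimize_scalar(lambda lx: -loglik(np.exp(lx), np.exp(lx)),
                           bounds=(lo, hi), method="bounded",
                           options={"xatol": 1e-6})
    lnl_null = -res0.fun
    if lnl_null > lnl_alt:  # the null is nested: never let noise invert it
        lnl_alt = lnl_null
        dS = dN = float(np.exp(res0.x))
    return dS, dN, lnl_alt, lnl_null


def fel_site_fit(aln: CodonAlignment, tree: Phylogeny, global_fit: GlobalFit,
                 site: int) -> SiteFitResult:
    """Exact per-site FEL fit and positive-selection LRT at one codon."""
    col = aln.column(site)
    obs = col[col != MISSING]
    invariant = len(np.unique(obs)) <= 1
    loglik = _column_loglik_factory(aln, global_fit, site)
    dS, dN, lnl_alt, lnl_null = _fit_column(loglik, invariant)
    stat = max(2.0 * (lnl_alt - lnl_null), 0.0)
    p = float(chi2.sf(stat, 1)) if not invariant else 1.0
    return SiteFitResult(site, dS, dN, lnl_alt, lnl_null, stat, p,
                         "positive_selection")


_SURF_LO = 1e-4  # rate box shared by the surface-based alt and null fits,
_SURF_HI = 8.0   # so the nested optima live in the same feasible set


def _surface_site_fit(surface: SiteRateSurface, site: int) -> SiteFitResult:
    """Per-site FEL fit on the interpolated likelihood surface."""
    g = surface.grid
    s0, n0 = surface.grid_argmax(site)

    def nll_alt(x):
        s, n = np.clip(np.exp(x), _SURF_LO, _SURF_HI)
        return -surface.loglik_site(site, s, n)

    x0 = np.log([max(s0, 1e-3), max(n0, 1e-3)])
    res = minimize(nll_alt, x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 200})
    dS, dN = np.clip(np.exp(res.x), _SURF_LO, _SURF_HI)
    lnl_alt = -res.fun

    diag = surface.loglik_site(site, g, g)
    k0 = int(np.argmax(diag))
    res0 = minimize_scalar(
        lambda lx: -surface.loglik_site(site, np.exp(lx), np.exp(lx)),
        bounds=(np.log(_SURF_LO), np.log(_SURF_HI)), method="bounded",
        options={"xatol": 1e-6})
    lnl_null = max(-res0.fun, float(diag[k0]))
    if lnl_null > lnl_alt:
        lnl_alt = lnl_null
        dS = dN = float(np.exp(res0.x))
    stat = max(2.0 * (lnl_alt - lnl_null), 0.0)
    return SiteFitResult(site, float(dS), float(dN), float(lnl_alt),
                         float(lnl_null), stat, float(chi2.sf(stat, 1)),
                         "positive_selection")


def fel_scan(aln: CodonAlignment, tree: Phylogeny, global_fit: GlobalFit | None = None,
             surface: SiteRateSurface | None = None) -> list[SiteFitResult]:
    """FEL positive-selection test at every codon.

    All columns are priced on one shared (dS, dN) likelihood grid (a single
    pruning pass per grid knot covers every site), then each site's fit is
    refined continuously on the interpolated surface.
    """
    if aln.n_codons == 0:
        raise ValueError("empty alignment")
    if surface is None:
        if global_fit is None:
            global_fit = fit_global_model(aln, tree)
        surface = SiteRateSurface.from_global_fit(aln, global_fit)
    results = []
    for site in range(1, aln.n_codons + 1):
        col = aln.column(site)
        obs = col[col != MISSING]
        if len(np.unique(obs)) <= 1:
            lnl = surface.loglik_site(site, 1e-6, 1e-6)
            results.append(SiteFitResult(site, RATE_FLOOR, RATE_FLOOR,
                                         lnl, lnl, 0.0, 1.0,
                                         "positive_selection"))
        else:
            results.append(_surface_site_fit(surface, site))
    return results


def scan_table(results: list[SiteFitResult]) -> pd.DataFrame:
    """Tidy per-site table (1-based positions) with a BH-adjusted column."""
    df = pd.DataFrame([{
        "site": r.site, "dS": r.dS, "dN": r.dN, "dN_dS": r.omega,
        "lnL_alt": r.lnl_alt, "lnL_null": r.lnl_null,
        "LRT": r.statistic, "p": r.p_value, "test": r.test,
        **r.extra,
    } for r in results])
    if len(df):
        from statsmodels.stats.multitest import multipletests
        df["p_bh"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# FEL-CSP: compare selective pressures across datasets
# ---------------------------------------------------------------------------

def fel_csp(aln1: CodonAlignment, tree1: Phylogeny,
            aln2: CodonAlignment, tree2: Phylogeny,
            global_fits: tuple[GlobalFit, GlobalFit] | None = None,
            site: int | None = None,
            surfaces: tuple[SiteRateSurface, SiteRateSurface] | None = None
            ) -> list[SiteFitResult] | SiteFitResult:
    """Cross-dataset comparison of selective pressure at homologous codons.

    Null: one shared ratio, dN1/dS1 = dN2/dS2 (3 free parameters).
    Alternative: dS1, dN1, dS2, dN2 all free (4 parameters); 1 df.
    Returns one result (``site`` given) or a list over all codons.  Each
    result carries both datasets' point estimates so callers can screen
    significant sites whose estimates are not actually > 1.
    """
    if aln1.n_codons != aln2.n_codons:
        raise ValueError("datasets must share codon coordinates (equal L)")
    if surfaces is None:
        if global_fits is None:
            global_fits = (fit_global_model(aln1, tree1),
                           fit_global_model(aln2, tree2))
        surfaces = (SiteRateSurface.from_global_fit(aln1, global_fits[0]),
                    SiteRateSurface.from_global_fit(aln2, global_fits[1]))
    s1, s2 = surfaces
    sites = [site] if site is not None else list(range(1, aln1.n_codons + 1))
    out = []
    for s in sites:
        f1 = _surface_site_fit(s1, s)
        f2 = _surface_site_fit(s2, s)
        lnl_alt = f1.lnl_alt + f2.lnl_alt

        def null_profile(lw):
            w = np.exp(lw)
            tot = 0.0
            for surf in (s1, s2):
                r = minimize_scalar(
                    lambda lx: -surf.loglik_site(
                        s, np.clip(np.exp(lx), _SURF_LO, _SURF_HI),
                        np.clip(w * np.exp(lx), _SURF_LO, _SURF_HI)),
                    bounds=(np.log(_SURF_LO), np.log(_SURF_HI)),
                    method="bounded", options={"xatol": 1e-4})
                tot += -r.fun
            return -tot

        # ratio bounds span the full rate box so the null can always reach
        # the alternative optimum when the two datasets agree; the profile
        # in the shared ratio can be multimodal, so scan a coarse grid
        # before local refinement
        lw_lo, lw_hi = np.log(_SURF_LO / _SURF_HI), np.log(_SURF_HI / _SURF_LO)
        lw_grid = np.linspace(lw_lo, lw_hi, 31)
        prof = np.array([null_profile(lw) for lw in lw_grid])
        i = int(np.argmin(prof))
        r0 = minimize_scalar(null_profile,
                             bounds=(lw_grid[max(i - 1, 0)],
                                     lw_grid[min(i + 1, len(lw_grid) - 1)]),
                             method="bounded", options={"xatol": 1e-4})
        lnl_null = max(-r0.fun, -prof[i])
        shared_omega = float(np.exp(r0.x if -r0.fun >= -prof[i] else lw_grid[i]))
        lnl_null = min(lnl_null, lnl_alt)  # nesting guard
        stat = max(2.0 * (lnl_alt - lnl_null), 0.0)
        direction = 1 if (f1.omega > f2.omega) else (-1 if f2.omega > f1.omega else 0)
        out.append(SiteFitResult(
            s, f1.dS, f1.dN, lnl_alt, lnl_null, stat, float(chi2.sf(stat, 1)),
            "csp", extra={"dS2": f2.dS, "dN2": f2.dN,
                          "omega1": f1.omega, "omega2": f2.omega,
                          "shared_omega": shared_omega,
                          "direction": direction}))
    return out[0] if site is not None else out


# ---------------------------------------------------------------------------
# FEL-Clade: foreground/background contrast on a tagged tree
# ---------------------------------------------------------------------------

def fel_clade(aln: CodonAlignment, tree: Phylogeny, global_fit: GlobalFit,
              site: int) -> SiteFitResult:
    """Per-site foreground/background dN contrast (shared dS), 1 df.

    Requires every branch of ``tree`` to carry a compartment tag; the
    foreground is the clade plus its stem branch.  ``extra['direction']``
    reports which side has the larger dN-hat.
    """
    if tree.tags is None:
        raise ValueError("every branch must carry a compartment tag")
    engine = PruningEngine(tree, aln)
    fac = global_fit.factory
    lengths = tree.lengths
    sites = np.array([site - 1])
    fore = (tree.tags == TAG_CLADE) | (tree.tags == TAG_STEM)

    ts = np.where(np.arange(tree.n_nodes) == tree.root, 0.0, lengths)
    back = ~fore
    back[tree.root] = False
    n_states = fac.pi.size
    P = np.empty((tree.n_nodes, n_states, n_states))

    def loglik(dS, dN_fore, dN_back):
        sp_f = fac.spectral(max(dS, RATE_FLOOR), max(dN_fore, RATE_FLOOR))
        P[fore] = sp_f.transition_many(ts[fore])
        if dN_back == dN_fore:
            P[back] = sp_f.transition_many(ts[back])
        else:
            sp_b = fac.spectral(max(dS, RATE_FLOOR), max(dN_back, RATE_FLOOR))
            P[back] = sp_b.transition_many(ts[back])
        return float(engine.site_loglikelihoods(P, fac.pi, sites=sites)[0])

    col = aln.column(site)
    obs = col[col != MISSING]
    if len(np.unique(obs)) <= 1:
        lnl = loglik(RATE_FLOOR, RATE_FLOOR, RATE_FLOOR)
        return SiteFitResult(site, RATE_FLOOR, RATE_FLOOR, lnl, lnl, 0.0, 1.0,
                             "clade", extra={"dN_fore": RATE_FLOOR,
                                             "dN_back": RATE_FLOOR,
                                             "direction": "none"})

    def nll_null(x):
        return -loglik(np.exp(x[0]), np.exp(x[1]), np.exp(x[1]))

    best0 = None
    for x0 in ([0.0, 0.0], [np.log(0.5), np.log(1.5)]):
        r = minimize(nll_null, x0, method="Nelder-Mead",
                     options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 200})
        if best0 is None or r.fun < best0.fun:
            best0 = r
    lnl_null = -best0.fun
    dS0, dN0 = np.exp(best0.x)

    def nll_alt(x):
        return -loglik(np.exp(x[0]), np.exp(x[1]), np.exp(x[2]))

    best = None
    for x0 in ([best0.x[0], best0.x[1], best0.x[1]],
               [best0.x[0], best0.x[1] + 0.7, best0.x[1] - 0.7]):
        r = minimize(nll_alt, x0, method="Nelder-Mead",
                     options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 250})
        if best is None or r.fun < best.fun:
            best = r
    lnl_alt = max(-best.fun, lnl_null)
    dS, dNf, dNb = np.exp(best.x)
    stat = max(2.0 * (lnl_alt - lnl_null), 0.0)
    direction = "foreground" if dNf > dNb else ("background" if dNb > dNf else "none")
    return SiteFitResult(site, float(dS), float(max(dNf, dNb)), lnl_alt,
                         lnl_null, stat, float(chi2.sf(stat, 1)), "clade",
                         extra={"dN_fore": float(dNf), "dN_back": float(dNb),
                                "dS_null": float(dS0), "dN_null": float(dN0),
                                "direction": direction})


# ---------------------------------------------------------------------------
# Power / false-positive harness
# ---------------------------------------------------------------------------

@dataclass
class PowerReport:
    """Tallied outcome of the replicate simulation harness."""

    n_replicates: int
    n_sites: int  # per replicate
    alpha_grid: np.ndarray
    bin_counts: np.ndarray  # p-value histogram, 100 bins of width 0.01
    power: dict  # alpha -> fraction of truly positive sites called
    false_positive_rate: dict  # alpha -> fraction of null sites called
    false_positive_rate_neutral: dict  # denominator: strictly neutral sites only
    n_positive_sites: int
    n_null_sites: int
    master_seed: int
    notes: str = ""

    @property
    def total_sites(self) -> int:
        return self.n_replicates * self.n_sites


def run_power_analysis(template, tree: Phylogeny, params=None,
                       n_replicates: int = 100, alpha_grid=(0.01, 0.05, 0.1),
                       seed: int = 0, global_fit_mode: str = "fast",
                       grid=None) -> PowerReport:
    """Simulate replicates from a per-site rate template and re-scan with FEL.

    ``template`` is a :class:`~selcontrast.simulate.SiteOmegaSpec`; truly
    positive sites are those generated with dN > dS.  Each replicate draws
    a fresh alignment on ``tree``, refits the dataset-level scale and omega,
    and runs the FEL scan; positive-selection calls require p <= alpha and
    dN-hat > dS-hat.  Per-replicate seeds derive from ``seed`` by counter.
    """
    from .simulate import default_params, simulate_alignment

    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    params = params or default_params()
    rates = template.rates
    L = template.L
    truly_positive = rates[:, 1] > rates[:, 0] + 1e-12
    neutral = np.abs(rates[:, 1] - rates[:, 0]) <= 1e-12
    null_sites = ~truly_positive

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_replicates)
    bins = np.zeros(100, dtype=np.int64)
    pvals = np.empty((n_replicates, L))
    calls = np.empty((n_replicates, L), dtype=bool)
    for rep in range(n_replicates):
        rng = np.random.default_rng(child_seeds[rep])
        aln = simulate_alignment(tree, template, params, rng=rng)
        gf = fit_global_model(aln, tree, nuc_model="HKY",
                              optimize_exchangeabilities=(global_fit_mode != "fast"),
                              branch_mode="scale")
        surface = SiteRateSurface.from_global_fit(aln, gf, grid=grid)
        res = fel_scan(aln, tree, surface=surface)
        p = np.array([r.p_value for r in res])
        d = np.array([r.dN > r.dS for r in res])
        pvals[rep] = p
        calls[rep] = d
        bins += np.histogram(p, bins=np.linspace(0, 1, 101))[0]

    power = {}
    fpr = {}
    fpr_neutral = {}
    notes = ""
    for a in alpha_grid:
        sig = (pvals <= a) & calls
        if truly_positive.any():
            power[a] = float(sig[:, truly_positive].mean())
        else:
            power[a] = float("nan")
            notes = "no truly positive sites in template: power undefined"
        fpr[a] = float(sig[:, null_sites].mean()) if null_sites.any() else float("nan")
        fpr_neutral[a] = float(sig[:, neutral].mean()) if neutral.any() else float("nan")
    return PowerReport(
        n_replicates=n_replicates, n_sites=L, alpha_grid=np.asarray(alpha_grid),
        bin_counts=bins, power=power, false_positive_rate=fpr,
        false_positive_rate_neutral=fpr_neutral,
        n_positive_sites=int(truly_positive.sum()) * n_replicates,
        n_null_sites=int(null_sites.sum()) * n_replicates,
        master_seed=seed, notes=notes)
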