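"""Pairwise nucleotide diversity (NG86) and the terminal-branch dN-dS
regression contrast.

``pairwise_pi`` implements Nei–Gojobori (1986) counting: per codon,
synonymous site counts are the fraction of single-nucleotide changes that
preserve the amino acid (changes to stop codons count as non-synonymous so
that synonymous + non-synonymous sites always total 3 per codon);
differences between codons average over all substitution orderings,
skipping pathways through stop codons.  Per pair, pi is differences/sites,
averaged over all unordered pairs with pairwise deletion of missing
codons; a Jukes–Cantor correction is optional.

``terminal_branch_rates`` re-optimizes each terminal branch's synonymous
and non-synonymous rate multipliers with everything else frozen at the
global fit, converting to per-site rates via dS = alpha*t/3, dN = beta*t/3
(branch lengths are expected substitutions per codon at neutrality, and a
codon exposes three nucleotide sites, so the per-site conversion divides
by 3 regardless of the synonymous/non-synonymous opportunity split).

``dnds_regression`` contrasts two groups of terminal-branch (dS, dN)
points: per-group OLS slopes/intercepts, a pooled group-by-dS interaction
test for slope differences, and per-group quadratic checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.optimize import minimize

from .genetics import MISSING, CodonAlignment, GeneticCode, universal_code
from .model import GlobalFit, PruningEngine
from .trees import Phylogeny

# ---------------------------------------------------------------------------
# NG86 diversity
# ---------------------------------------------------------------------------


def _ng86_tables(code: GeneticCode):
    """Per-codon synonymous site counts and per-pair difference counts."""
    if hasattr(code, "_ng86"):
        return code._ng86
    n = code.n_states
    nucs = code.codon_nucs
    syn_sites = np.zeros(n)
    for i in range(n):
        aa = code.translate_state(i)
        s = 0.0
        for pos in range(3):
            for nuc in range(4):
                if nuc == nucs[i, pos]:
                    continue
                mut = nucs[i].copy()
                mut[pos] = nuc
                trip = "".join("ACGT"[x] for x in mut)
                if trip in code.state_of and code.codon_to_aa[trip] == aa:
                    s += 1.0 / 3.0
                # stop codons and non-synonymous changes both count toward
                # the non-synonymous opportunity (3 - s per codon)
        syn_sites[i] = s

    # pairwise differences, averaged over substitution orderings
    syn_diff = np.zeros((n, n))
    nonsyn_diff = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pos = [k for k in range(3) if nucs[i, k] != nucs[j, k]]
            paths = []
            for order in permutations(pos):
                cur = nucs[i].copy()
                sd = nd = 0.0
                ok = True
                for k in order:
                    aa_from = code.codon_to_aa["".join("ACGT"[x] for x in cur)]
                    cur[k] = nucs[j, k]
                    trip = "".join("ACGT"[x] for x in cur)
                    if trip not in code.state_of:
                        ok = False
                        break
                    if code.codon_to_aa[trip] == aa_from:
                        sd += 1
                    else:
                        nd += 1
                if ok:
                    paths.append((sd, nd))
            if not paths:  # every path crosses a stop: count all as nonsyn
                paths = [(0.0, float(len(pos)))]
            sd = float(np.mean([p[0] for p in paths]))
            nd = float(np.mean([p[1] for p in paths]))
            syn_diff[i, j] = syn_diff[j, i] = sd
            nonsyn_diff[i, j] = nonsyn_diff[j, i] = nd
    object.__setattr__(code, "_ng86", (syn_sites, syn_diff, nonsyn_diff))
    return code._ng86


@dataclass
class DiversityResult:
    """Average pairwise per-site diversity for one site class."""

    site_class: str  # 'syn' | 'nonsyn' | 'all'
    pi: float
    mean_sites: float  # average NG86 sites per pair for this class
    mean_diffs: float
    n_pairs: int
    jc_corrected: bool = False


def _jc(p: float) -> float:
    if p >= 0.75:
        return float("inf")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def pairwise_pi(aln: CodonAlignment, site_class: str = "all",
                jc_correction: bool = False) -> DiversityResult:
    """Average pairwise nucleotide diversity for a site class.

    ``site_class='syn'``/``'nonsyn'`` use NG86 site and difference counts;
    ``'all'`` is the plain per-nucleotide difference proportion.  Codons
    missing in either sequence of a pair are excluded for that pair.
    """
    if site_class not in ("syn", "nonsyn", "all"):
        raise ValueError("site_class must be 'syn', 'nonsyn' or 'all'")
    if aln.n_taxa < 2:
        raise ValueError("need at least two sequences")
    code = aln.code
    syn_sites, syn_diff, nonsyn_diff = _ng86_tables(code)
    st = aln.states
    n = aln.n_taxa
    dists, sites_used, diffs_used = [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            ok = (st[i] != MISSING) & (st[j] != MISSING)
            if not ok.any():
                continue
            a, b = st[i, ok].astype(int), st[j, ok].astype(int)
            if site_class == "all":
                sites = 3.0 * len(a)
                diffs = float((syn_diff[a, b] + nonsyn_diff[a, b]).sum())
            elif site_class == "syn":
                sites = float((syn_sites[a] + syn_sites[b]).sum() / 2.0)
                diffs = float(syn_diff[a, b].sum())
            else:
                sites = float((3.0 - (syn_sites[a] + syn_sites[b]) / 2.0).sum())
                diffs = float(nonsyn_diff[a, b].sum())
            p = diffs / sites if sites > 0 else 0.0
            dists.append(_jc(p) if jc_correction else p)
            sites_used.append(sites)
            diffs_used.append(diffs)
    if not dists:
        raise ValueError("no comparable codon pairs (all missing)")
    return DiversityResult(site_class, float(np.mean(dists)),
                           float(np.mean(sites_used)), float(np.mean(diffs_used)),
                           len(dists), jc_correction)


def diversity_table(aln: CodonAlignment, jc_correction: bool = False) -> pd.DataFrame:
    """Synonymous / non-synonymous / all-sites pi in one table."""
    rows = [pairwise_pi(aln, c, jc_correction) for c in ("syn", "nonsyn", "all")]
    return pd.DataFrame([{"class": r.site_class, "pi": r.pi,
                          "mean_sites": r.mean_sites, "n_pairs": r.n_pairs}
                         for r in rows])


# ---------------------------------------------------------------------------
# Terminal branch rates
# ---------------------------------------------------------------------------


@dataclass
class BranchRates:
    """Per-site substitution rates on one terminal branch."""

    taxon: str
    dN: float
    dS: float


def terminal_branch_rates(aln: CodonAlignment, tree: Phylogeny,
                          global_fit: GlobalFit) -> list[BranchRates]:
    """Per-terminal-branch (dS, dN): local re-optimization of each leaf
    branch's rate multipliers with all other parameters frozen."""
    fit_tree = global_fit.tree
    engine = PruningEngine(fit_tree, aln)
    fac = global_fit.factory
    base = fit_tree.lengths
    omega0 = global_fit.params.omega
    sp_rest = fac.spectral(1.0, omega0)
    ts = np.where(np.arange(fit_tree.n_nodes) == fit_tree.root, 0.0, base)
    P_base = sp_rest.transition_many(ts)

    out = []
    for leaf in range(fit_tree.n_leaves):
        t = base[leaf]
        if t <= 1e-9:
            out.append(BranchRates(fit_tree.labels[leaf], 0.0, 0.0))
            continue

        def nll(x):
            a, b = np.exp(x)
            P = P_base.copy()
            P[leaf] = fac.spectral(a, b).transition(t)
            return -engine.site_loglikelihoods(P, fac.pi).sum()

        best = None
        for x0 in ([0.0, 0.0], [np.log(0.5), np.log(1.5)]):
            r = minimize(nll, x0, method="Nelder-Mead",
                         options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 300})
            if best is None or r.fun < best.fun:
                best = r
        a, b = np.clip(np.exp(best.x), 0.0, 50.0)
        # branch length t is expected substitutions per codon at neutrality;
        # per-nucleotide-site rates divide the codon rate by 3
        out.append(BranchRates(fit_tree.labels[leaf],
                               dN=float(b * t / 3.0), dS=float(a * t / 3.0)))
    return out


# ---------------------------------------------------------------------------
# Regression contrast
# ---------------------------------------------------------------------------


@dataclass
class GroupRegression:
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    quadratic_p: float
    n: int


@dataclass
class RegressionContrast:
    """Two-group dN ~ dS comparison."""

    group1: GroupRegression
    group2: GroupRegression
    interaction_t: float
    interaction_p: float
    intercept_diff_p: float


def _branch_frame(rates: list[BranchRates] | np.ndarray) -> pd.DataFrame:
    if isinstance(rates, pd.DataFrame):
        return rates[["dS", "dN"]].copy()
    if isinstance(rates, (list, tuple)) and rates and isinstance(rates[0], BranchRates):
        return pd.DataFrame({"dS": [r.dS for r in rates],
                             "dN": [r.dN for r in rates]})
    arr = np.asarray(rates, dtype=float)
    return pd.DataFrame({"dS": arr[:, 0], "dN": arr[:, 1]})


def _group_fit(df: pd.DataFrame) -> GroupRegression:
    X = sm.add_constant(df["dS"])
    fit = sm.OLS(df["dN"], X).fit()
    Xq = sm.add_constant(pd.DataFrame({"dS": df["dS"], "dS2": df["dS"] ** 2}))
    fitq = sm.OLS(df["dN"], Xq).fit()
    return GroupRegression(
        slope=float(fit.params["dS"]), slope_se=float(fit.bse["dS"]),
        intercept=float(fit.params["const"]), intercept_se=float(fit.bse["const"]),
        quadratic_p=float(fitq.pvalues["dS2"]), n=len(df))


def dnds_regression(group1, group2) -> RegressionContrast:
    """OLS contrast of terminal-branch dN ~ dS between two allele sets.

    Accepts lists of :class:`BranchRates`, (dS, dN) arrays or DataFrames.
    The slope difference is tested by the group-by-dS interaction in a
    pooled model; quadratic curvature is tested per group.
    """
    d1, d2 = _branch_frame(group1), _branch_frame(group2)
    for d in (d1, d2):
        if len(d) < 3:
            raise ValueError("need at least 3 points per group")
        if np.allclose(d["dS"].values, d["dS"].values[0]):
            raise ValueError("degenerate dS variance in one group")
    g1, g2 = _group_fit(d1), _group_fit(d2)
    pooled = pd.concat([d1.assign(group=0), d2.assign(group=1)], ignore_index=True)
    inter = smf.ols("dN ~ dS * C(group)", data=pooled).fit()
    tname = [n for n in inter.params.index if n.startswith("dS:")][0]
    iname = [n for n in inter.params.index if n.startswith("C(group)")][0]
    return RegressionContrast(
        group1=g1, group2=g2,
        interaction_t=float(inter.tvalues[tname]),
        interaction_p=float(inter.pvalues[tname]),
        intercept_diff_p=float(inter.pvalues[iname]))
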