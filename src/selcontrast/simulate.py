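"""Synthetic trees and codon alignments with controlled selection regimes.

The generator evolves sense-codon states down a phylogeny under the codon
model of :mod:`selcontrast.model`, with per-site synonymous (dS) and
non-synonymous (dN) rate multipliers.  Because the state space contains
only sense codons, transitions into stop codons have rate zero by
construction and no rejection sampling is needed.

The reference scenario emulates two sets of S-RNase alleles: a younger,
recently re-diversified set (48 taxa, shallower trans-specific genealogy,
a positively selected site class with dN/dS around 2.7) and an older set
(49 taxa, deeper genealogy, positive class near 1.1).  All randomness is
driven by ``numpy.random.Generator`` seeded from an explicit master seed
(PCG64), so identical configs give identical outputs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import dendropy
from dendropy.simulate import treesim

import pandas as pd

from .genetics import CodonAlignment, GeneticCode, universal_code
from .model import CodonFrequencies, CodonModelParams, QFactory, hky_exchangeabilities
from .trees import Phylogeny

#: default nucleotide composition by codon position (moderately AT-rich,
#: typical of plant nuclear coding sequence)
DEFAULT_POS_NUC = np.array([
    [0.30, 0.18, 0.26, 0.26],
    [0.28, 0.22, 0.20, 0.30],
    [0.26, 0.20, 0.22, 0.32],
])


def default_params(code: GeneticCode | None = None,
                   kappa: float = 2.0) -> CodonModelParams:
    """Reference simulation parameters: HKY85 with ts/tv ratio ``kappa`` and
    F3x4 frequencies from :data:`DEFAULT_POS_NUC`."""
    code = code or universal_code()
    freqs = CodonFrequencies.f3x4(DEFAULT_POS_NUC, code)
    return CodonModelParams(hky_exchangeabilities(kappa), freqs)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, shape: str = "coalescent", depth: float = 1.0,
                  seed: int = 0, prefix: str = "t",
                  n_lineages: int | None = None) -> Phylogeny:
    """Random phylogeny with total branch length scaled to ``depth``.

    ``shape='coalescent'`` draws a Kingman coalescent genealogy (dendropy);
    ``shape='balanced'`` builds a symmetric bifurcating topology with equal
    branch lengths; ``shape='allelic'`` emulates a genealogy maintained by
    long-term balancing selection — ``n_lineages`` ancient lineages (long
    stems attached near the root) each carrying a shallow re-diversified
    coalescent subtree, so most leaf pairs are separated by two long stems
    and pairwise divergences are nearly uniform rather than
    coalescent-distributed.  Deterministic given ``seed``.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    labels = [f"{prefix}{i + 1}" for i in range(n_taxa)]
    if shape == "coalescent":
        tn = dendropy.TaxonNamespace(labels)
        dt = treesim.pure_kingman_tree(taxon_namespace=tn, pop_size=1,
                                       rng=random.Random(int(seed)))
        tree = Phylogeny.from_dendropy(dt)
    elif shape == "balanced":
        def nest(labs):
            if len(labs) == 1:
                return f"{labs[0]}:1"
            h = len(labs) // 2
            return f"({nest(labs[:h])},{nest(labs[h:])}):1"
        newick = f"({nest(labels[: n_taxa // 2])},{nest(labels[n_taxa // 2:])});"
        tree = Phylogeny.from_newick(newick)
    elif shape == "allelic":
        m = n_lineages if n_lineages is not None else n_taxa
        if not 2 <= m <= n_taxa:
            raise ValueError("n_lineages must be in [2, n_taxa]")
        rng = np.random.default_rng(seed)
        groups = np.array_split(np.asarray(labels, dtype=object),
                                m)
        # stems are long (unit scale with mild jitter); the radiation at the
        # base and the within-lineage subtrees are short relative to stems
        stem_parts = []
        for g, labs in enumerate(groups):
            stem = 1.0 * float(rng.uniform(0.85, 1.15))
            if len(labs) == 1:
                stem_parts.append(f"{labs[0]}:{stem:.6f}")
                continue
            tn = dendropy.TaxonNamespace(list(labs))
            sub = Phylogeny.from_dendropy(treesim.pure_kingman_tree(
                taxon_namespace=tn, pop_size=1,
                rng=random.Random(int(seed) + 7919 * (g + 1))))
            # shallow re-diversification: subtree total length 15% of stem
            sub = sub.scaled(0.15 * stem / sub.total_length())
            stem_parts.append(f"{sub.to_newick().rstrip(';')}:{stem:.6f}")
        # short random basal radiation joining the stems
        parts = list(stem_parts)
        while len(parts) > 2:
            i, j = sorted(rng.choice(len(parts), size=2, replace=False))
            b = parts.pop(j)
            a = parts.pop(i)
            parts.append(f"({a},{b}):{rng.uniform(0.005, 0.02):.6f}")
        newick = f"({parts[0]},{parts[1]});"
        tree = Phylogeny.from_newick(newick)
    else:
        raise ValueError(f"unknown tree shape {shape!r}")
    total = tree.total_length()
    return tree.scaled(depth / total)


def scale_to_mean_pairwise(tree: Phylogeny, target: float) -> Phylogeny:
    """Rescale so the mean patristic leaf-to-leaf distance equals ``target``."""
    return tree.scaled(target / tree.mean_pairwise_path())


# ---------------------------------------------------------------------------
# Site rate specifications
# ---------------------------------------------------------------------------

@dataclass
class SiteOmegaSpec:
    """Per-site (dS, dN) multipliers driving a simulation.

    ``rates`` has shape (L, 2) with columns (dS, dN); neutral sites have the
    two equal.
    """

    rates: np.ndarray

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 2 or self.rates.shape[1] != 2:
            raise ValueError("rates must be (L, 2) of (dS, dN)")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    @property
    def L(self) -> int:
        return self.rates.shape[0]

    @classmethod
    def constant(cls, L: int, dS: float = 1.0, dN: float = 1.0):
        return cls(np.tile([dS, dN], (L, 1)))

    @classmethod
    def from_distribution(cls, dist, L: int, rng: np.random.Generator):
        """Draw per-site classes from a :class:`~selcontrast.rel.RateDistribution`."""
        probs = np.array([c.prob for c in dist.classes])
        probs = probs / probs.sum()
        ks = rng.choice(len(probs), size=L, p=probs)
        rates = np.array([[dist.classes[k].dS, dist.classes[k].dN] for k in ks])
        return cls(rates), ks


def fel_template_rates(L: int = 131, neutral_fraction: float = 0.25,
                       flavor: str = "physalis", seed: int = 0,
                       rng: np.random.Generator | None = None) -> SiteOmegaSpec:
    """Per-site rate template emulating FEL point estimates with every site
    non-positively selected (dN <= dS) — the null template of the false
    positive analysis.

    A ``neutral_fraction`` of sites evolves strictly neutrally (dN = dS);
    the rest draw a purifying dN/dS and a synonymous rate whose spread
    mirrors the fitted rate-distribution of the corresponding allele set
    (``'physalis'`` or ``'solanum'``).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    if not 0.0 <= neutral_fraction <= 1.0:
        raise ValueError("neutral_fraction must be in [0, 1]")
    n_neutral = int(round(neutral_fraction * L))
    idx = rng.permutation(L)
    rates = np.empty((L, 2))
    # purifying site classes (dS, dN/dS weight) echoing the fitted mixtures
    if flavor == "physalis":
        classes = [(0.58, 0.0, 0.36), (1.49, 0.18, 0.64)]
    elif flavor == "solanum":
        classes = [(0.80, 0.50, 0.50), (0.93, 0.08, 0.50)]
    else:
        raise ValueError(f"unknown flavor {flavor!r}")
    probs = np.array([c[2] for c in classes])
    probs = probs / probs.sum()
    for pos, site in enumerate(idx):
        jitter = rng.lognormal(0.0, 0.25)
        if pos < n_neutral:
            s = jitter
            rates[site] = (s, s)
        else:
            k = rng.choice(len(classes), p=probs)
            dS0, ratio, _ = classes[k]
            s = dS0 * jitter
            rates[site] = (s, s * ratio)
    return SiteOmegaSpec(rates)


# ---------------------------------------------------------------------------
# Alignment simulation
# ---------------------------------------------------------------------------

def simulate_alignment(tree: Phylogeny, spec: SiteOmegaSpec,
                       params: CodonModelParams | None = None,
                       L: int | None = None, seed: int = 0,
                       rng: np.random.Generator | None = None) -> CodonAlignment:
    """Evolve codon states over ``tree`` with per-site (dS, dN) multipliers.

    Root codons are drawn from the model's equilibrium frequencies; each
    branch applies the transition matrix of the site's rate pair.
    """
    params = params or default_params()
    code = universal_code()
    if L is None:
        L = spec.L
    if spec.L != L:
        raise ValueError("spec must cover exactly L sites")
    if not tree.has_lengths:
        raise ValueError("tree must have branch lengths")
    rng = rng if rng is not None else np.random.default_rng(seed)
    fac = QFactory(params.exchangeabilities, params.freqs, code)
    pi = fac.pi
    S = len(pi)

    # group sites by identical (dS, dN) so each branch needs one P per group
    pairs, group = np.unique(spec.rates, axis=0, return_inverse=True)
    spectrals = [fac.spectral(a, b) for a, b in pairs]

    states = np.empty((tree.n_nodes, L), dtype=np.int16)
    states[tree.root] = rng.choice(S, size=L, p=pi)
    for nd in tree.postorder[::-1]:
        nd = int(nd)
        if nd == tree.root:
            continue
        t = tree.lengths[nd]
        parent_states = states[tree.parent[nd]]
        child = np.empty(L, dtype=np.int16)
        u = rng.random(L)
        for g, sp in enumerate(spectrals):
            sel = group == g
            if not np.any(sel):
                continue
            P = sp.transition(t)
            C = np.cumsum(P, axis=1)
            rows = C[parent_states[sel]]
            child[sel] = (rows < u[sel, None]).sum(axis=1)
        states[nd] = child
    leaf_states = states[: tree.n_leaves]
    return CodonAlignment(tree.labels, leaf_states, universal_code())


def simulate_branch_class_alignment(tree: Phylogeny, omega_by_tag: dict[int, float],
                                    L: int, params: CodonModelParams | None = None,
                                    seed: int = 0,
                                    rng: np.random.Generator | None = None
                                    ) -> CodonAlignment:
    """Evolve codons with branch-compartment-specific omega (dS = 1).

    ``tree.tags`` selects, per branch, the omega from ``omega_by_tag`` —
    the generating model of the clade/branch partition analyses.
    """
    if tree.tags is None:
        raise ValueError("tree must carry compartment tags")
    if not tree.has_lengths:
        raise ValueError("tree must have branch lengths")
    params = params or default_params()
    rng = rng if rng is not None else np.random.default_rng(seed)
    fac = QFactory(params.exchangeabilities, params.freqs)
    pi = fac.pi
    spectrals = {tag: fac.spectral(1.0, w) for tag, w in omega_by_tag.items()}
    states = np.empty((tree.n_nodes, L), dtype=np.int16)
    states[tree.root] = rng.choice(len(pi), size=L, p=pi)
    for nd in tree.postorder[::-1]:
        nd = int(nd)
        if nd == tree.root:
            continue
        sp = spectrals[int(tree.tags[nd])]
        P = sp.transition(tree.lengths[nd])
        C = np.cumsum(P, axis=1)
        u = rng.random(L)
        states[nd] = (C[states[tree.parent[nd]]] < u[:, None]).sum(axis=1)
    return CodonAlignment(tree.labels, states[: tree.n_leaves], universal_code())


# ---------------------------------------------------------------------------
# Reference differential scenario
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Conditions of a two-dataset differential-selection simulation.

    Defaults emulate the S-RNase study conditions: 48 vs 49 alleles, 131
    codons, deep trans-specific coalescent genealogies with mean pairwise
    path lengths chosen so synonymous diversity lands near 0.33 (younger
    set) and 0.48 (older set), and the fitted four-class rate distributions
    as generating truths (positive-class dN/dS 2.663 with weight 0.463
    versus 1.139 with weight 0.353).
    """

    n_taxa: tuple[int, int] = (48, 49)
    L: int = 131
    #: S-allele genealogies are shaped by long-term balancing selection:
    #: pairwise divergence is nearly uniform (within-species synonymous
    #: diversity matches the genus-wide value), so the default is the
    #: star-like 'allelic' shape rather than a Kingman coalescent
    tree_shape: str = "allelic"
    #: mean pairwise leaf-to-leaf path length per dataset (expected
    #: substitutions per codon under neutrality); the defaults were
    #: calibrated once so raw (uncorrected) NG86 synonymous diversity lands
    #: near 0.33 (set 1) and 0.48 (set 2) at the default sample sizes
    mean_pairwise: tuple[float, float] = (1.08, 2.05)
    dist1: "RateDistribution | None" = None
    dist2: "RateDistribution | None" = None
    share_proportions: bool = False
    kappa: float = 2.0
    seed: int = 0


@dataclass
class ScenarioData:
    """Two simulated datasets plus generating truth."""

    aln1: CodonAlignment
    tree1: Phylogeny
    aln2: CodonAlignment
    tree2: Phylogeny
    truth: pd.DataFrame  # per-site generating rates and differential flag
    config: ScenarioConfig = field(repr=False, default=None)


def _default_distributions():
    from .rel import RateDistribution  # local import to avoid a cycle
    return (RateDistribution.physalis_like(), RateDistribution.solanum_like())


def make_differential_scenario(config: ScenarioConfig | None = None) -> ScenarioData:
    """Simulate the two-dataset contrast with coupled per-site classes.

    Each site draws one uniform variate used against both distributions'
    cumulative class proportions, so classes with matching cumulative
    boundaries (always the positive class under ``share_proportions=True``,
    every class when the two proportion vectors coincide) are assigned to
    the same sites in both datasets, and a site is *truly differential*
    exactly when its generating rates differ across datasets.
    """
    config = config or ScenarioConfig()
    d1, d2 = config.dist1, config.dist2
    if d1 is None or d2 is None:
        dd1, dd2 = _default_distributions()
        d1 = d1 or dd1
        d2 = d2 or dd2
    ss = np.random.SeedSequence(config.seed)
    s_tree1, s_tree2, s_sites, s_aln1, s_aln2 = ss.spawn(5)
    params = default_params(kappa=config.kappa)

    tree1 = simulate_tree(config.n_taxa[0], config.tree_shape, depth=1.0,
                          seed=int(s_tree1.generate_state(1)[0] % 2**31), prefix="p")
    tree1 = scale_to_mean_pairwise(tree1, config.mean_pairwise[0])
    tree2 = simulate_tree(config.n_taxa[1], config.tree_shape, depth=1.0,
                          seed=int(s_tree2.generate_state(1)[0] % 2**31), prefix="s")
    tree2 = scale_to_mean_pairwise(tree2, config.mean_pairwise[1])

    rng_sites = np.random.default_rng(s_sites)
    u = rng_sites.random(config.L)
    p1 = np.array([c.prob for c in d1.classes])
    p1 = p1 / p1.sum()
    p2 = np.array([c.prob for c in d2.classes])
    p2 = p2 / p2.sum()
    if config.share_proportions:
        # tie only the positive-class proportion (the quantity the
        # same-proportion null constrains) at the midpoint; the remaining
        # classes keep their dataset-specific relative weights
        q = 0.5 * (p1[0] + p2[0])
        p1 = np.concatenate([[q], p1[1:] * (1.0 - q) / (1.0 - p1[0])])
        p2 = np.concatenate([[q], p2[1:] * (1.0 - q) / (1.0 - p2[0])])
    k1 = np.searchsorted(np.cumsum(p1), u, side="right").clip(max=len(p1) - 1)
    k2 = np.searchsorted(np.cumsum(p2), u, side="right").clip(max=len(p2) - 1)
    r1 = np.array([[d1.classes[k].dS, d1.classes[k].dN] for k in k1])
    r2 = np.array([[d2.classes[k].dS, d2.classes[k].dN] for k in k2])

    aln1 = simulate_alignment(tree1, SiteOmegaSpec(r1), params,
                              rng=np.random.default_rng(s_aln1))
    aln2 = simulate_alignment(tree2, SiteOmegaSpec(r2), params,
                              rng=np.random.default_rng(s_aln2))

    with np.errstate(divide="ignore", invalid="ignore"):
        w1 = np.where(r1[:, 0] > 0, r1[:, 1] / r1[:, 0], np.where(r1[:, 1] > 0, np.inf, 1.0))
        w2 = np.where(r2[:, 0] > 0, r2[:, 1] / r2[:, 0], np.where(r2[:, 1] > 0, np.inf, 1.0))
    truth = pd.DataFrame({
        "site": np.arange(1, config.L + 1),
        "class1": k1, "class2": k2,
        "dS1": r1[:, 0], "dN1": r1[:, 1],
        "dS2": r2[:, 0], "dN2": r2[:, 1],
        "omega1": w1, "omega2": w2,
        "differential": np.abs(w1 - w2) > 1e-6,
    })
    return ScenarioData(aln1, tree1, aln2, tree2, truth, config)
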