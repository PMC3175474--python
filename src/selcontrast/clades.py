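"""Lineage-specific dN/dS partition models with LRTs, AIC and profile CIs.

A phylogeny is compartmentalized into *background* branches, a designated
monophyletic *clade* subtree and the single *stem* branch subtending it.
Five nested models tie the compartment dN/dS ratios together:

  1. one global ratio for the whole tree;
  2. clade + background share a ratio, the stem has its own;
  3. clade + stem share a ratio, background has its own;
  4. clade has its own ratio, stem + background share;
  5. all three compartments free.

Models use the HKY85 nucleotide parameterization, branch lengths and
frequencies frozen at the dataset-level fit, and are compared by LRT
against model 1 and by AIC = 2k - 2 lnL where k counts the free dN/dS
parameters (shared nuisance parameters are identical across models, so
AIC differences are driven by the ratios alone; absolute AIC values are
not comparable across software with different bookkeeping).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .genetics import CodonAlignment
from .model import GlobalFit, PruningEngine, fit_global_model
from .trees import TAG_BACKGROUND, TAG_CLADE, TAG_STEM, Phylogeny

#: compartment-tying map: model id -> tag index -> free-parameter slot
#: (tags: 0 background, 1 clade, 2 stem)
MODEL_TIES = {
    1: {TAG_BACKGROUND: 0, TAG_CLADE: 0, TAG_STEM: 0},
    2: {TAG_BACKGROUND: 0, TAG_CLADE: 0, TAG_STEM: 1},
    3: {TAG_BACKGROUND: 0, TAG_CLADE: 1, TAG_STEM: 1},
    4: {TAG_BACKGROUND: 0, TAG_CLADE: 1, TAG_STEM: 0},
    5: {TAG_BACKGROUND: 0, TAG_CLADE: 1, TAG_STEM: 2},
}

OMEGA_LO, OMEGA_HI = 1e-4, 50.0
#: half the chi-square(1) 95% quantile: the profile-likelihood drop
PROFILE_DROP_95 = chi2.ppf(0.95, 1) / 2.0


@dataclass
class PartitionSpec:
    """A clade membership definition resolved against a tree."""

    clade_taxa: tuple[str, ...]
    include_stem: bool = True

    def resolve(self, tree: Phylogeny) -> np.ndarray:
        """Per-branch tags; raises if the taxa are not monophyletic."""
        taxa = set(self.clade_taxa)
        if not taxa:
            raise ValueError("clade must contain at least one taxon")
        mrca = tree.mrca(sorted(taxa))
        leaves = {tree.labels[i] for i in tree.subtree_leaves(mrca)}
        if leaves != taxa:
            extra = sorted(leaves - taxa)
            raise ValueError(
                f"clade is not monophyletic: MRCA also spans {extra}")
        tags = np.full(tree.n_nodes, TAG_BACKGROUND, dtype=np.int64)
        stack = list(tree.children[mrca])
        while stack:
            nd = stack.pop()
            tags[nd] = TAG_CLADE
            stack.extend(tree.children[nd])
        tags[mrca] = TAG_STEM if mrca != tree.root else TAG_BACKGROUND
        return tags

    def tag_tree(self, tree: Phylogeny) -> Phylogeny:
        return tree.with_tags(self.resolve(tree))


@dataclass
class CladeModelFit:
    """One fitted partition model."""

    model_id: int
    omegas: dict  # compartment name -> fitted dN/dS
    lnl: float
    n_free: int
    aic: float = field(init=False)
    profile_ci: dict = field(default_factory=dict)
    spec: PartitionSpec | None = field(default=None, repr=False)
    _context: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.aic = 2.0 * self.n_free - 2.0 * self.lnl


class _CladeLikelihood:
    """Whole-alignment likelihood with per-compartment omega."""

    def __init__(self, aln: CodonAlignment, tree: Phylogeny, fit: GlobalFit):
        if tree.tags is None:
            raise ValueError("tree must carry compartment tags (PartitionSpec)")
        self.engine = PruningEngine(tree, aln)
        self.factory = fit.factory
        self.tree = tree
        self.lengths = tree.lengths

    def loglik(self, omega_by_tag: dict[int, float],
               scale: float = 1.0) -> float:
        fac = self.factory
        ts = np.where(np.arange(self.tree.n_nodes) == self.tree.root,
                      0.0, self.lengths * scale)
        spectrals = {tag: fac.spectral(1.0, max(w, OMEGA_LO))
                     for tag, w in omega_by_tag.items()}
        P = np.empty((self.tree.n_nodes, fac.pi.size, fac.pi.size))
        for tag, sp in spectrals.items():
            sel = self.tree.tags == tag
            if np.any(sel):
                P[sel] = sp.transition_many(ts[sel])
        return float(self.engine.site_loglikelihoods(P, fac.pi).sum())


def _slots(model_id: int) -> tuple[dict, int]:
    ties = MODEL_TIES[model_id]
    n_free = len(set(ties.values()))
    return ties, n_free


def _fit_slots(lik: _CladeLikelihood, ties: dict, n_free: int,
               fixed: dict[int, float] | None = None,
               warm: tuple[dict, float] | None = None):
    """Maximize over the free omega slots plus one shared branch-scale
    nuisance parameter; ``fixed`` pins slots (profiling).

    The scale re-estimates total divergence jointly with the compartment
    omegas: the input branch lengths come from a single-omega fit whose
    compromise scale otherwise biases compartment rates.  It is identified
    by synonymous divergence (Q is neutral-normalized) and is shared by
    all five models, so AIC differences are unaffected.

    ``warm`` supplies (slot values, scale) to start from — profiling
    restarts from the MLE instead of from scratch.
    """
    fixed = fixed or {}
    free_slots = [s for s in sorted(set(ties.values())) if s not in fixed]

    def omega_by_tag(x):
        vals = dict(fixed)
        for s, v in zip(free_slots, np.exp(x[1:])):
            vals[s] = v
        return {tag: vals[slot] for tag, slot in ties.items()}

    def nll(x):
        return -lik.loglik(omega_by_tag(x), scale=float(np.exp(x[0])))

    dim = 1 + len(free_slots)
    lw, hw = np.log(OMEGA_LO), np.log(OMEGA_HI)
    bounds = [(-4.0, 4.0)] + [(lw, hw)] * len(free_slots)
    starts = []
    if warm is not None:
        wvals, wscale = warm
        starts.append(np.concatenate(
            [[np.log(wscale)],
             np.log([max(wvals.get(s, 1.0), OMEGA_LO) for s in free_slots])]))
    else:
        starts.append(np.zeros(dim))
        starts.append(np.concatenate(
            [[0.0], np.log(np.linspace(0.5, 2.0, len(free_slots)))]))
    best, x = None, None
    for start in starts:
        r = minimize(nll, np.clip(start, [b[0] for b in bounds],
                                  [b[1] for b in bounds]),
                     method="L-BFGS-B", bounds=bounds,
                     options={"ftol": 1e-10, "gtol": 1e-6, "maxiter": 200})
        if best is None or r.fun < best:
            best, x = r.fun, r.x
        if not free_slots:
            break
    vals = dict(fixed)
    for s, v in zip(free_slots, np.exp(np.atleast_1d(x)[1:])):
        vals[s] = float(v)
    return -best, vals, float(np.exp(x[0]))


_COMPARTMENT_NAMES = {TAG_BACKGROUND: "background", TAG_CLADE: "clade",
                      TAG_STEM: "stem"}


def fit_clade_model(aln: CodonAlignment, tree: Phylogeny, spec: PartitionSpec,
                    model_id: int, global_fit: GlobalFit | None = None,
                    compute_ci: bool = False) -> CladeModelFit:
    """Fit one of the five partition models (HKY85 nucleotide model)."""
    if model_id not in MODEL_TIES:
        raise ValueError("model_id must be in 1..5")
    if global_fit is None:
        global_fit = fit_global_model(aln, tree, nuc_model="HKY",
                                      optimize_exchangeabilities=True)
    tagged = spec.tag_tree(global_fit.tree)
    lik = _CladeLikelihood(aln, tagged, global_fit)
    ties, n_free = _slots(model_id)
    lnl, slot_vals, scale = _fit_slots(lik, ties, n_free)
    omegas = {_COMPARTMENT_NAMES[tag]: slot_vals[slot]
              for tag, slot in ties.items()}
    fit = CladeModelFit(model_id, omegas, lnl, n_free, spec=spec,
                        _context={"lik": lik, "ties": ties,
                                  "slot_vals": slot_vals, "scale": scale})
    if compute_ci:
        for name in set(omegas):
            fit.profile_ci[name] = profile_ci(fit, name)
    return fit


def profile_ci(fit: CladeModelFit, compartment: str,
               level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood CI for one compartment's dN/dS.

    Bisect for the omega values where the re-optimized log-likelihood drops
    by chi2_1(level)/2 from the maximum; bounds hitting the optimizer box
    are returned one-sided at the box edge.
    """
    ctx = fit._context
    if not ctx:
        raise ValueError("fit carries no likelihood context")
    lik, ties = ctx["lik"], ctx["ties"]
    tag = {v: k for k, v in _COMPARTMENT_NAMES.items()}[compartment]
    slot = ties[tag]
    mle = fit.omegas[compartment]
    if level <= 0.0:
        return (mle, mle)
    drop = chi2.ppf(level, 1) / 2.0
    mle_warm = (ctx["slot_vals"], ctx.get("scale", 1.0))

    target = fit.lnl - drop

    def search(direction: int) -> float:
        # chain warm starts: each bisection step restarts the nuisance
        # optimization from the previous step's solution, which is close
        warm = mle_warm

        def profile_lnl(w):
            nonlocal warm
            lnl, vals, scale = _fit_slots(lik, ties, fit.n_free,
                                          fixed={slot: w}, warm=warm)
            warm = (vals, scale)
            return lnl

        lo_edge = OMEGA_LO if direction < 0 else OMEGA_HI
        a, b = np.log(mle), np.log(lo_edge)
        if profile_lnl(lo_edge) > target:  # flat to the boundary
            return lo_edge
        warm = mle_warm
        for _ in range(30):
            m = 0.5 * (a + b)
            if profile_lnl(np.exp(m)) > target:
                a = m
            else:
                b = m
            if abs(b - a) < 5e-3:
                break
        return float(np.exp(0.5 * (a + b)))

    return (search(-1), search(+1))


def compare_clade_models(fits: list[CladeModelFit]) -> pd.DataFrame:
    """AIC ranking plus LRT of each model against the single-ratio model.

    All fits must share data and clade specification (model 1 included).
    """
    specs = {tuple(sorted(f.spec.clade_taxa)) if f.spec else None for f in fits}
    if len(specs) != 1:
        raise ValueError("fits mix different clade specifications")
    base = next((f for f in fits if f.model_id == 1), None)
    rows = []
    for f in fits:
        p = np.nan
        if base is not None and f.model_id != 1:
            df = f.n_free - base.n_free
            if df >= 1:
                stat = max(2.0 * (f.lnl - base.lnl), 0.0)
                p = float(chi2.sf(stat, df))
        rows.append({"model": f.model_id, "k": f.n_free, "lnL": f.lnl,
                     "AIC": f.aic, "p_vs_model1": p,
                     **{f"omega_{k}": v for k, v in sorted(f.omegas.items())}})
    return pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)
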