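"""Codon substitution model, pruning likelihood and global model fitting.

The substitution process follows the codon-model lineage of Muse–Gaut /
Nielsen–Yang: an instantaneous rate matrix over sense codons in which only
single-nucleotide exchanges have positive rate,

    q_ij = rho(a,b) * f_j * alpha   (synonymous i -> j)
    q_ij = rho(a,b) * f_j * beta    (non-synonymous i -> j)

where ``rho`` is a GTR (or HKY) nucleotide exchangeability for the changed
pair ``a -> b``, and ``f_j`` is the frequency factor of the target: the
position-specific target-nucleotide frequency under F3x4 (default) or the
target-codon frequency under F61.  Both choices are time reversible with
respect to the codon equilibrium frequencies.

``alpha`` carries the synonymous and ``beta`` the non-synonymous rate
multiplier, so ``omega = beta/alpha``.  The matrix is scaled once by the
mean rate at stationarity computed at ``alpha = beta = 1``; with that
convention branch lengths are expected substitutions per codon site under
neutrality and (alpha, beta) act directly as the per-site dS/dN rate
multipliers used by the random- and fixed-effects machinery downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import eigh, expm
from scipy.optimize import minimize, minimize_scalar

from .genetics import MISSING, CodonAlignment, GeneticCode, universal_code
from .trees import Phylogeny

# GTR exchangeability order (upper triangle of a 4x4 ACGT matrix)
EXCH_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
EXCH_NAMES = ["AC", "AG", "AT", "CG", "CT", "GT"]


def exch_matrix(rates) -> np.ndarray:
    """Symmetric 4x4 exchangeability matrix from 6 rates (GT conventionally 1)."""
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (6,) or np.any(rates <= 0):
        raise ValueError("need 6 positive exchangeabilities (AC,AG,AT,CG,CT,GT)")
    R = np.zeros((4, 4))
    for (a, b), r in zip(EXCH_PAIRS, rates):
        R[a, b] = R[b, a] = r
    return R


def hky_exchangeabilities(kappa: float) -> np.ndarray:
    """HKY85 as a GTR special case: transitions (AG, CT) get rate kappa."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])


@dataclass(frozen=True)
class CodonFrequencies:
    """Codon equilibrium frequencies with their generating convention."""

    mode: str  # 'F3x4' or 'F61'
    codon: np.ndarray  # (n_sense,) sums to 1
    pos_nuc: np.ndarray | None = None  # (3, 4) for F3x4

    def __post_init__(self):
        c = np.asarray(self.codon, dtype=float)
        if np.any(c < 0) or abs(c.sum() - 1.0) > 1e-10:
            raise ValueError("codon frequencies must be non-negative and sum to 1")

    @classmethod
    def f3x4(cls, pos_nuc, code: GeneticCode) -> "CodonFrequencies":
        pos_nuc = np.asarray(pos_nuc, dtype=float)
        if pos_nuc.shape != (3, 4):
            raise ValueError("pos_nuc must be (3, 4)")
        pos_nuc = pos_nuc / pos_nuc.sum(axis=1, keepdims=True)
        nucs = code.codon_nucs
        codon = pos_nuc[0, nucs[:, 0]] * pos_nuc[1, nucs[:, 1]] * pos_nuc[2, nucs[:, 2]]
        codon = codon / codon.sum()
        return cls("F3x4", codon, pos_nuc)

    @classmethod
    def f61(cls, codon) -> "CodonFrequencies":
        codon = np.asarray(codon, dtype=float)
        return cls("F61", codon / codon.sum())

    @classmethod
    def uniform(cls, code: GeneticCode) -> "CodonFrequencies":
        return cls.f3x4(np.full((3, 4), 0.25), code)

    @classmethod
    def from_alignment(cls, aln: CodonAlignment, mode: str = "F3x4",
                       pseudocount: float = 0.5) -> "CodonFrequencies":
        """Observed-count frequencies (position-specific nucleotides for F3x4)."""
        code = aln.code
        obs = aln.states[aln.states != MISSING]
        if obs.size == 0:
            raise ValueError("alignment has no observed codons")
        if mode == "F61":
            counts = np.bincount(obs, minlength=code.n_states) + pseudocount
            return cls.f61(counts)
        nucs = code.codon_nucs[obs]  # (n_obs, 3)
        pos_nuc = np.empty((3, 4))
        for k in range(3):
            pos_nuc[k] = np.bincount(nucs[:, k], minlength=4) + pseudocount
        return cls.f3x4(pos_nuc, code)


@dataclass(frozen=True)
class CodonModelParams:
    """Parameters of the codon substitution model.

    ``alpha`` houses the synonymous (dS) and ``beta`` the non-synonymous
    (dN) rate multiplier; ``omega = beta / alpha``.
    """

    exchangeabilities: np.ndarray  # 6 GTR rates, GT fixed to 1 by convention
    freqs: CodonFrequencies
    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self):
        ex = np.asarray(self.exchangeabilities, dtype=float)
        if ex.shape != (6,) or np.any(ex <= 0):
            raise ValueError("exchangeabilities must be 6 positive rates")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")

    @property
    def omega(self) -> float:
        return self.beta / self.alpha if self.alpha > 0 else np.inf

    def with_rates(self, alpha: float, beta: float) -> "CodonModelParams":
        return replace(self, alpha=alpha, beta=beta)


class QFactory:
    """Precomputed synonymous / non-synonymous parts of the rate matrix.

    ``Q(alpha, beta) = (alpha * S + beta * N) / C`` with diagonal set so rows
    sum to zero, where ``C`` is the stationary mean rate of ``S + N`` (the
    neutral matrix), fixed once so branch lengths keep a single scale while
    alpha/beta vary.
    """

    def __init__(self, exchangeabilities, freqs: CodonFrequencies,
                 code: GeneticCode | None = None):
        self.code = code or universal_code()
        self.freqs = freqs
        self.exch = np.asarray(exchangeabilities, dtype=float)
        R = exch_matrix(self.exch)
        n = self.code.n_states
        i, j, pos, a, b, syn = self.code.single_step_pairs()
        if freqs.mode == "F3x4":
            if freqs.pos_nuc is None:
                raise ValueError("F3x4 frequencies need pos_nuc")
            factor = freqs.pos_nuc[pos, b]
        else:
            factor = freqs.codon[j]
        rate = R[a, b] * factor
        S = np.zeros((n, n))
        N = np.zeros((n, n))
        S[i[syn], j[syn]] = rate[syn]
        N[i[~syn], j[~syn]] = rate[~syn]
        pi = freqs.codon
        neutral = S + N
        self.mean_rate_neutral = float(pi @ neutral.sum(axis=1))
        if self.mean_rate_neutral <= 0:
            raise ValueError("degenerate frequencies: zero neutral rate")
        self._S = S / self.mean_rate_neutral
        self._N = N / self.mean_rate_neutral
        self.pi = pi
        # fraction of neutral substitution flux that is synonymous
        self.syn_flux_fraction = float(pi @ S.sum(axis=1)) / self.mean_rate_neutral

    def rate_matrix(self, alpha: float = 1.0, beta: float = 1.0) -> np.ndarray:
        Q = alpha * self._S + beta * self._N
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def spectral(self, alpha: float = 1.0, beta: float = 1.0) -> "SpectralQ":
        return SpectralQ(self.rate_matrix(alpha, beta), self.pi)


class SpectralQ:
    """Eigendecomposition of a reversible rate matrix for fast P(t).

    Reversibility lets us symmetrize ``B = D^{1/2} Q D^{-1/2}`` (D = diag pi)
    and use a stable symmetric eigendecomposition; scaling-and-squaring
    (``scipy.linalg.expm``) is the fallback when frequencies are degenerate.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.Q = Q
        self.pi = pi
        d = np.sqrt(np.maximum(pi, 1e-300))
        B = (Q * d[:, None]) / d[None, :]
        asym = np.abs(B - B.T).max()
        if asym < 1e-8 * max(1.0, np.abs(B).max()):
            w, V = eigh((B + B.T) / 2)
            self._w = w
            self._left = V / d[:, None]      # D^{-1/2} V
            self._right = (V * d[:, None]).T  # V^T D^{1/2}
            self._ok = True
        else:
            self._ok = False

    def transition(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be non-negative")
        if not self._ok:
            return expm(self.Q * t)
        P = (self._left * np.exp(self._w * t)) @ self._right
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_many(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) for a vector of branch lengths, shape (n, S, S)."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValueError("branch lengths must be non-negative")
        if not self._ok:
            return np.stack([expm(self.Q * t) for t in ts])
        E = np.exp(np.multiply.outer(ts, self._w))  # (n, S)
        P = np.einsum("ik,nk,kj->nij", self._left, E, self._right, optimize=True)
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P


def build_rate_matrix(params: CodonModelParams, code: GeneticCode | None = None) -> np.ndarray:
    """Instantaneous rate matrix (rows sum to 0) for the given parameters."""
    fac = QFactory(params.exchangeabilities, params.freqs, code)
    return fac.rate_matrix(params.alpha, params.beta)


def transition_probabilities(Q: np.ndarray, t: float, pi: np.ndarray | None = None) -> np.ndarray:
    """P(t) = exp(Qt); uses the reversible spectral route when pi is given."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if pi is None:
        return expm(Q * t)
    return SpectralQ(Q, pi).transition(t)


class PruningEngine:
    """Felsenstein pruning over all alignment columns at once.

    The engine binds a tree and an alignment (leaf rows reordered to tree
    leaves) and evaluates per-site log-likelihoods for any stack of branch
    transition matrices, with per-node rescaling to avoid underflow.
    Missing leaf states contribute partial likelihood 1.
    """

    def __init__(self, tree: Phylogeny, aln: CodonAlignment):
        if sorted(tree.labels) != sorted(aln.labels):
            raise ValueError("tree leaf labels must match alignment labels")
        self.tree = tree
        self.code = aln.code
        order = [aln.labels.index(lab) for lab in tree.labels]
        self.leaf_states = aln.states[order]  # (n_leaves, L)
        self.L = aln.n_codons
        self.S = self.code.n_states

    def site_loglikelihoods(self, P: np.ndarray, root_pi: np.ndarray,
                            sites: np.ndarray | None = None) -> np.ndarray:
        """Per-site log-likelihood given transition matrices.

        Parameters
        ----------
        P :
            (n_nodes, S, S) array; ``P[i]`` is the matrix of the branch above
            node ``i`` (the root entry is ignored).
        root_pi :
            Root state distribution.
        sites :
            Optional 0-based column subset.
        """
        tree = self.tree
        S = self.S
        cols = self.leaf_states if sites is None else self.leaf_states[:, sites]
        L = cols.shape[1]
        partial = {}
        logscale = np.zeros(L)
        for nd in tree.postorder:
            nd = int(nd)
            if nd < tree.n_leaves:
                continue
            acc = np.ones((L, S))
            for ch in tree.children[nd]:
                if ch < tree.n_leaves:
                    states = cols[ch]
                    lik = np.ones((L, S))
                    obs = states != MISSING
                    if np.any(obs):
                        # P[i, s_obs] column gathered per site
                        lik[obs] = P[ch][:, states[obs]].T
                else:
                    lik = partial.pop(ch) @ P[ch].T
                acc *= lik
            m = acc.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            acc /= m[:, None]
            logscale += np.log(m)
            partial[nd] = acc
        root = partial.pop(tree.root)
        lik = root @ root_pi
        with np.errstate(divide="ignore"):
            return np.log(lik) + logscale

    def loglikelihood(self, spectral: SpectralQ, lengths: np.ndarray,
                      root_pi: np.ndarray | None = None,
                      sites: np.ndarray | None = None) -> np.ndarray:
        """Per-site log-likelihoods with one rate matrix shared by all branches."""
        ts = np.where(np.arange(self.tree.n_nodes) == self.tree.root, 0.0, lengths)
        P = spectral.transition_many(ts)
        pi = spectral.pi if root_pi is None else root_pi
        return self.site_loglikelihoods(P, pi, sites=sites)


def site_log_likelihood(column, tree: Phylogeny, params: CodonModelParams,
                        code: GeneticCode | None = None) -> float:
    """Log-likelihood of a single codon column (states in tree-label order)."""
    code = code or universal_code()
    column = np.asarray(column, dtype=np.int16).reshape(-1, 1)
    if column.shape[0] != tree.n_leaves:
        raise ValueError("column length must equal number of leaves")
    aln = CodonAlignment(tree.labels, column, code)
    engine = PruningEngine(tree, aln)
    fac = QFactory(params.exchangeabilities, params.freqs, code)
    sp = fac.spectral(params.alpha, params.beta)
    return float(engine.loglikelihood(sp, tree.lengths)[0])


# ---------------------------------------------------------------------------
# Global model fit
# ---------------------------------------------------------------------------

OMEGA_BOUNDS = (1e-6, 100.0)
BRANCH_FLOOR = 1e-9
BRANCH_CEIL = 20.0


@dataclass
class GlobalFit:
    """Result of the dataset-level model fit, reused read-only downstream."""

    params: CodonModelParams
    tree: Phylogeny  # with fitted branch lengths
    lnl: float
    n_evaluations: int = 0
    converged: bool = True
    details: dict = field(default_factory=dict)

    @property
    def factory(self) -> QFactory:
        return QFactory(self.params.exchangeabilities, self.params.freqs)


def _initial_lengths(tree: Phylogeny, aln: CodonAlignment) -> np.ndarray:
    """Crude starting lengths when the input Newick has none: split the mean
    pairwise codon p-distance uniformly over root-to-leaf path edges."""
    sub = aln.subset(tree.labels)
    st = sub.states
    n = st.shape[0]
    diffs, total = [], 0
    for i in range(min(n, 12)):
        for j in range(i + 1, min(n, 12)):
            ok = (st[i] != MISSING) & (st[j] != MISSING)
            if ok.sum():
                diffs.append((st[i, ok] != st[j, ok]).mean())
    d = float(np.mean(diffs)) if diffs else 0.1
    per_edge = max(d, 0.01) / max(np.log2(max(tree.n_leaves, 2)), 1.0)
    lengths = np.full(tree.n_nodes, per_edge)
    lengths[tree.root] = 0.0
    return lengths


def fit_global_model(aln: CodonAlignment, tree: Phylogeny, *,
                     nuc_model: str = "GTR", freq_mode: str = "F3x4",
                     optimize_exchangeabilities: bool = True,
                     branch_mode: str = "scale",
                     tol: float = 1e-6) -> GlobalFit:
    """Fit frequencies (closed form), exchangeabilities, global omega and
    branch lengths to an alignment/tree pair.

    ``branch_mode``:
      * ``'scale'`` (default) — keep the input tree's relative branch lengths
        and optimize a single tree-scale factor jointly with the substitution
        parameters;
      * ``'each'``  — additionally sweep every branch with 1-D optimization
        (used when the input Newick has no lengths);
      * ``'fixed'`` — hold the input lengths fixed.
    """
    if aln.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if aln.n_codons == 0:
        raise ValueError("empty alignment")
    freqs = CodonFrequencies.from_alignment(aln, mode=freq_mode)
    engine = PruningEngine(tree, aln)

    lengths = tree.lengths.copy()
    if not tree.has_lengths:
        lengths = _initial_lengths(tree, aln)
        if branch_mode == "fixed":
            branch_mode = "each"

    n_exch = 5 if (optimize_exchangeabilities and nuc_model == "GTR") else (
        1 if optimize_exchangeabilities else 0)

    evals = [0]

    def unpack(x):
        log_scale, log_omega = x[0], x[1]
        if n_exch == 5:
            ex = np.array([np.exp(v) for v in x[2:7]] + [1.0])
        elif n_exch == 1:
            kappa = np.exp(x[2])
            ex = hky_exchangeabilities(kappa)
        else:
            ex = hky_exchangeabilities(2.0) if nuc_model == "HKY" else np.ones(6)
        return np.exp(log_scale), np.exp(log_omega), ex

    def negloglik(x, lens):
        evals[0] += 1
        scale, omega, ex = unpack(x)
        fac = QFactory(ex, freqs, aln.code)
        sp = fac.spectral(1.0, omega)
        ll = engine.loglikelihood(sp, np.clip(lens * scale, BRANCH_FLOOR, BRANCH_CEIL))
        total = ll.sum()
        return 1e10 if not np.isfinite(total) else -total

    x0 = np.zeros(2 + n_exch)
    x0[1] = np.log(0.5)
    if branch_mode == "fixed":
        # scale pinned at 1: optimize the rest with the scale coordinate frozen
        bounds = [(0.0, 0.0), (np.log(OMEGA_BOUNDS[0]), np.log(OMEGA_BOUNDS[1]))]
    else:
        bounds = [(np.log(1e-8), np.log(1e3)),
                  (np.log(OMEGA_BOUNDS[0]), np.log(OMEGA_BOUNDS[1]))]
    bounds += [(np.log(1e-3), np.log(1e3))] * n_exch

    res = minimize(negloglik, x0, args=(lengths,), method="L-BFGS-B",
                   bounds=bounds, options={"ftol": tol, "maxiter": 200})
    x = res.x
    scale, omega, ex = unpack(x)
    lengths = np.clip(lengths * scale, BRANCH_FLOOR, BRANCH_CEIL)
    lengths[tree.root] = 0.0

    if branch_mode == "each":
        fac = QFactory(ex, freqs, aln.code)
        sp = fac.spectral(1.0, omega)

        def branch_nll(t, nd):
            lens = lengths.copy()
            lens[nd] = t
            return -engine.loglikelihood(sp, lens).sum()

        for _sweep in range(2):
            for nd in range(tree.n_nodes):
                if nd == tree.root:
                    continue
                r = minimize_scalar(branch_nll, args=(nd,),
                                    bounds=(BRANCH_FLOOR, BRANCH_CEIL),
                                    method="bounded",
                                    options={"xatol": 1e-4})
                lengths[nd] = float(r.x)
            # re-polish omega between sweeps
            r = minimize_scalar(
                lambda lw: negloglik(np.concatenate(([0.0], [lw], x[2:])), lengths),
                bounds=(np.log(OMEGA_BOUNDS[0]), np.log(OMEGA_BOUNDS[1])),
                method="bounded", options={"xatol": 1e-5})
            omega = float(np.exp(r.x))
            sp = QFactory(ex, freqs, aln.code).spectral(1.0, omega)

    params = CodonModelParams(ex, freqs, alpha=1.0, beta=omega)
    fac = QFactory(ex, freqs, aln.code)
    lnl = float(engine.loglikelihood(fac.spectral(1.0, omega), lengths).sum())
    if not np.isfinite(lnl):
        raise ValueError("global fit produced a non-finite likelihood")
    fitted = tree.with_lengths(lengths)
    return GlobalFit(params=params, tree=fitted, lnl=lnl,
                     n_evaluations=evals[0], converged=bool(res.success),
                     details={"scale": scale, "branch_mode": branch_mode,
                              "nuc_model": nuc_model})
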