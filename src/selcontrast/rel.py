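"""Random-effects (discrete rate-distribution) models and cross-dataset tests.

Sites are assigned to four latent (dS, dN) rate classes with structural
roles — two purifying (dN < dS), one neutral (dN = dS) and one positively
selected (dN > dS) — and the mixture likelihood integrates over class
membership:

    lnL = sum_sites log sum_k prob_k * L_site(dS_k, dN_k)

Fitting two allele sets jointly under nested constraints yields the four
cross-dataset hypothesis tests:

  a. ``same_strength``      — positive-class dN/dS equal across datasets (df 1)
  b. ``same_proportion``    — positive-class weight equal (df 1)
  c. ``same_regime``        — both constraints (df 2)
  d. ``shared_distributions`` — one distribution for both datasets (df 10)

each rejected against the free model by -2 dlnL on a chi-square with the
difference in free parameters.  Class roles are enforced by
reparameterization (purifying ratios through a logistic, the positive-class
excess through log(omega - 1)), not by post-hoc sorting, so parameter
counts are exact: 7 rate parameters + 3 mixing logits = 10 per
distribution with branch lengths held fixed at the global fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, logit, logsumexp
from scipy.stats import chi2

from .genetics import CodonAlignment
from .model import GlobalFit, fit_global_model
from .surface import OmegaProfile, SiteRateSurface
from .trees import Phylogeny

ROLES = ("positive", "neutral", "purifying", "purifying")
CONSTRAINTS = ("free", "same_strength", "same_proportion", "same_regime",
               "shared_distributions")
#: degrees of freedom of each constrained model against the free model
CONSTRAINT_DF = {"same_strength": 1, "same_proportion": 1,
                 "same_regime": 2, "shared_distributions": 10}


@dataclass(frozen=True)
class RateClass:
    """One discrete (dS, dN) class with its mixing proportion."""

    dS: float
    dN: float
    prob: float

    def __post_init__(self):
        if self.dS < 0 or self.dN < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("prob must lie in [0, 1]")

    @property
    def omega(self) -> float:
        if self.dS > 0:
            return self.dN / self.dS
        return np.inf if self.dN > 0 else 1.0


@dataclass
class RateDistribution:
    """Ordered four-class rate distribution: positive, neutral, 2x purifying."""

    classes: tuple[RateClass, ...]

    def __post_init__(self):
        if len(self.classes) != 4:
            raise ValueError("expected exactly 4 rate classes")
        probs = sum(c.prob for c in self.classes)
        if abs(probs - 1.0) > 1e-8:
            raise ValueError("class probabilities must sum to 1")

    @property
    def positive(self) -> RateClass:
        return self.classes[0]

    @property
    def neutral(self) -> RateClass:
        return self.classes[1]

    def mean_rate(self, syn_flux_fraction: float = 0.5) -> float:
        """Stationary mean substitution rate implied by the mixture."""
        return sum(
            c.prob * (syn_flux_fraction * c.dS + (1 - syn_flux_fraction) * c.dN)
            for c in self.classes
        )

    def normalized(self, syn_flux_fraction: float = 0.5) -> "RateDistribution":
        """Copy rescaled to mean substitution rate 1 (reporting convention)."""
        m = self.mean_rate(syn_flux_fraction)
        return RateDistribution(tuple(
            RateClass(c.dS / m, c.dN / m, c.prob) for c in self.classes))

    @classmethod
    def from_arrays(cls, dS, dN, prob) -> "RateDistribution":
        """Build from parallel arrays; proportions are renormalized to sum
        exactly to 1 (printed tables often round to three decimals)."""
        total = float(np.sum(prob))
        return cls(tuple(
            RateClass(s, n, p / total) for s, n, p in zip(dS, dN, prob)))

    # Reference distributions: the fitted free-model rate classes of the two
    # S-RNase allele sets (younger Physalis-like, older Solanum-like); used
    # as generating truths by the synthetic scenarios.
    @classmethod
    def physalis_like(cls) -> "RateDistribution":
        return cls.from_arrays([1.047, 0.814, 0.580, 1.487],
                               [2.788, 0.814, 0.000, 0.262],
                               [0.463, 0.311, 0.081, 0.144]).renormalized_probs()

    @classmethod
    def solanum_like(cls) -> "RateDistribution":
        return cls.from_arrays([0.942, 2.000, 0.800, 0.933],
                               [1.073, 2.000, 0.397, 0.077],
                               [0.353, 0.094, 0.274, 0.279]).renormalized_probs()

    def renormalized_probs(self) -> "RateDistribution":
        t = sum(c.prob for c in self.classes)
        return RateDistribution(tuple(
            RateClass(c.dS, c.dN, c.prob / t) for c in self.classes))


# ---------------------------------------------------------------------------
# Parameterization
# ---------------------------------------------------------------------------
# theta layout per distribution (10 free parameters):
#   0: log dS_pos            4: log dS_pur1        7..9: mixing logits vs the
#   1: log(omega_pos - 1)    5: logit ratio_pur1        positive class
#   2: log dS_neutral        6: log dS_pur2
#   3: logit ratio_pur1? (see below)
# concretely: [ls4, lw4m1, ls3, ls1, lr1, ls2, lr2, q1, q2, q3]

_LS_LO, _LS_HI = np.log(1e-3), np.log(6.0)
_LW_LO, _LW_HI = -9.0, np.log(7.0)
_Q_LO, _Q_HI = -12.0, 12.0

THETA_BOUNDS = [(_LS_LO, _LS_HI), (_LW_LO, _LW_HI), (_LS_LO, _LS_HI),
                (_LS_LO, _LS_HI), (_Q_LO, _Q_HI), (_LS_LO, _LS_HI),
                (_Q_LO, _Q_HI), (_Q_LO, _Q_HI), (_Q_LO, _Q_HI), (_Q_LO, _Q_HI)]


def _dist_from_theta(theta: np.ndarray) -> RateDistribution:
    ls4, lw, ls3, ls1, lr1, ls2, lr2, q1, q2, q3 = theta
    s4 = np.exp(ls4)
    w4 = 1.0 + np.exp(lw)
    s3 = np.exp(ls3)
    s1, r1 = np.exp(ls1), expit(lr1)
    s2, r2 = np.exp(ls2), expit(lr2)
    z = np.array([0.0, q1, q2, q3])
    ez = np.exp(z - z.max())
    probs = ez / ez.sum()
    return RateDistribution(tuple(
        RateClass(s, n, p) for (s, n), p in zip(
            [(s4, s4 * w4), (s3, s3), (s1, s1 * r1), (s2, s2 * r2)], probs)))


def _theta_from_dist(dist: RateDistribution) -> np.ndarray:
    c4, c3, c1, c2 = dist.classes
    w4 = max(c4.omega, 1.0 + 1e-4)

    def _lg(x):
        return np.log(np.clip(x, np.exp(_LS_LO), np.exp(_LS_HI)))

    def _ratio(c):
        return logit(np.clip(c.omega if np.isfinite(c.omega) else 0.5,
                             1e-5, 1 - 1e-5))

    p = np.clip([c.prob for c in dist.classes], 1e-6, None)
    q = np.log(p / p[0])
    return np.clip(np.array([
        _lg(c4.dS), np.log(np.clip(w4 - 1.0, np.exp(_LW_LO), np.exp(_LW_HI))),
        _lg(c3.dS), _lg(c1.dS), _ratio(c1), _lg(c2.dS), _ratio(c2),
        q[1], q[2], q[3],
    ]), [b[0] for b in THETA_BOUNDS], [b[1] for b in THETA_BOUNDS])


class _CrossParam:
    """Pack/unpack joint parameter vectors for each cross-dataset constraint."""

    def __init__(self, constraint: str):
        if constraint not in CONSTRAINTS:
            raise ValueError(f"unknown constraint {constraint!r}")
        self.constraint = constraint
        self.n_params = {"free": 20, "same_strength": 19, "same_proportion": 19,
                         "same_regime": 18, "shared_distributions": 10}[constraint]

    def bounds(self):
        if self.constraint == "shared_distributions":
            return THETA_BOUNDS
        if self.constraint == "free":
            return THETA_BOUNDS * 2
        if self.constraint == "same_strength":
            return [THETA_BOUNDS[1]] + _drop(THETA_BOUNDS, [1]) * 2
        if self.constraint == "same_proportion":
            return [(_Q_LO, _Q_HI)] + THETA_BOUNDS[:7] + [(_Q_LO, _Q_HI)] * 2 \
                + THETA_BOUNDS[:7] + [(_Q_LO, _Q_HI)] * 2
        # same_regime
        return [THETA_BOUNDS[1], (_Q_LO, _Q_HI)] + THETA_BOUNDS[:1] \
            + THETA_BOUNDS[2:7] + [(_Q_LO, _Q_HI)] * 2 \
            + THETA_BOUNDS[:1] + THETA_BOUNDS[2:7] + [(_Q_LO, _Q_HI)] * 2

    # -- proportion helpers ------------------------------------------------
    @staticmethod
    def _probs_to_shared(qp, q2, q3):
        """Mixing logits with the positive-class weight pinned to sigmoid(qp)."""
        p4 = expit(qp)
        z = np.array([0.0, q2, q3])
        ez = np.exp(z - z.max())
        rest = ez / ez.sum() * (1 - p4)
        return np.concatenate([[p4], rest])

    def unpack(self, x) -> tuple[RateDistribution, RateDistribution]:
        c = self.constraint
        if c == "shared_distributions":
            d = _dist_from_theta(np.asarray(x))
            return d, d
        if c == "free":
            return _dist_from_theta(x[:10]), _dist_from_theta(x[10:])
        if c == "same_strength":
            lw = x[0]
            t1 = np.concatenate([[x[1]], [lw], x[2:10]])
            t2 = np.concatenate([[x[10]], [lw], x[11:19]])
            return _dist_from_theta(t1), _dist_from_theta(t2)
        if c == "same_proportion":
            qp = x[0]
            d1 = self._dist_shared_prop(x[1:8], x[8:10], qp)
            d2 = self._dist_shared_prop(x[10:17], x[17:19], qp)
            return d1, d2
        # same_regime: shared lw (positive-class omega) and shared qp (weight)
        lw, qp = x[0], x[1]
        d1 = self._dist_shared_prop(
            np.concatenate([[x[2]], [lw], x[3:8]]), x[8:10], qp)
        d2 = self._dist_shared_prop(
            np.concatenate([[x[10]], [lw], x[11:16]]), x[16:18], qp)
        return d1, d2

    def _dist_shared_prop(self, rate7, q23, qp) -> RateDistribution:
        probs = self._probs_to_shared(qp, q23[0], q23[1])
        ls4, lw, ls3, ls1, lr1, ls2, lr2 = rate7
        s4 = np.exp(ls4)
        w4 = 1.0 + np.exp(lw)
        pairs = [(s4, s4 * w4), (np.exp(ls3), np.exp(ls3)),
                 (np.exp(ls1), np.exp(ls1) * expit(lr1)),
                 (np.exp(ls2), np.exp(ls2) * expit(lr2))]
        return RateDistribution(tuple(
            RateClass(s, n, p) for (s, n), p in zip(pairs, probs)))

    def pack(self, d1: RateDistribution, d2: RateDistribution) -> np.ndarray:
        t1, t2 = _theta_from_dist(d1), _theta_from_dist(d2)
        c = self.constraint
        if c == "free":
            return np.concatenate([t1, t2])
        if c == "shared_distributions":
            return t1
        if c == "same_strength":
            lw = 0.5 * (t1[1] + t2[1])
            return np.concatenate([[lw], _drop_vec(t1, [1]), _drop_vec(t2, [1])])

        def qp_of(d):
            p4 = np.clip(d.classes[0].prob, 1e-6, 1 - 1e-6)
            return logit(p4)

        def q23_of(d):
            p = np.clip([c_.prob for c_ in d.classes[1:]], 1e-9, None)
            return np.log(p[1] / p[0]), np.log(p[2] / p[0])

        qp = 0.5 * (qp_of(d1) + qp_of(d2))
        if c == "same_proportion":
            return np.concatenate([[qp], t1[:7], q23_of(d1), t2[:7], q23_of(d2)])
        lw = 0.5 * (t1[1] + t2[1])
        return np.concatenate([
            [lw, qp], [t1[0]], t1[2:7], q23_of(d1), [t2[0]], t2[2:7], q23_of(d2)])


def _drop(seq, idx):
    return [v for i, v in enumerate(seq) if i not in idx]


def _drop_vec(vec, idx):
    keep = [i for i in range(len(vec)) if i not in idx]
    return np.asarray(vec)[keep]


# ---------------------------------------------------------------------------
# Likelihood and fitting
# ---------------------------------------------------------------------------

def mixture_site_logliks(surface: SiteRateSurface, dist: RateDistribution) -> np.ndarray:
    """(K, L) matrix of per-class per-site log-likelihoods."""
    return surface.loglik_many([(c.dS, c.dN) for c in dist.classes])


def mixture_loglik(surface: SiteRateSurface, dist: RateDistribution) -> float:
    a = mixture_site_logliks(surface, dist)
    a = a + np.log([max(c.prob, 1e-300) for c in dist.classes])[:, None]
    m = a.max(axis=0)
    return float((m + np.log(np.exp(a - m).sum(axis=0))).sum())


@dataclass
class RelFit:
    """A fitted four-class rate distribution on one dataset."""

    distribution: RateDistribution
    lnl: float
    converged: bool
    restart_lnls: list = field(default_factory=list)
    surface: SiteRateSurface | None = field(default=None, repr=False)


@dataclass
class CrossDatasetFit:
    """Joint two-dataset fit under one of the nested constraints."""

    constraint: str
    dist1: RateDistribution
    dist2: RateDistribution
    lnl: float
    n_free_params: int
    converged: bool


@dataclass
class LRTResult:
    lnl_null: float
    lnl_alt: float
    df: int
    statistic: float = 0.0
    p_value: float = 1.0

    def __post_init__(self):
        self.statistic = -2.0 * (self.lnl_null - self.lnl_alt)
        if self.statistic < -1e-4:
            warnings.warn(
                f"alternative log-likelihood below null by {-self.statistic / 2:.4g}; "
                "optimizer may not have converged", RuntimeWarning)
        self.p_value = float(chi2.sf(max(self.statistic, 0.0), self.df))


def lrt(lnl_null: float, lnl_alt: float, df: int) -> LRTResult:
    """Likelihood-ratio test: -2(lnL0 - lnL1) against chi-square with ``df``."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return LRTResult(lnl_null, lnl_alt, df)


def _moment_init(surface: SiteRateSurface) -> RateDistribution:
    """Data-driven starting distribution from per-site grid maxima.

    Sites are bucketed by their grid-argmax dN/dS into the four role
    classes (positive, neutral, two purifying tiers split at the median
    purifying ratio); class rates are bucket means and weights are bucket
    frequencies.  Gives the optimizer a start inside the basin suggested by
    the per-site estimates, which matters because the mixture surface is
    multimodal in the positive/neutral split.
    """
    pts = np.array([surface.grid_argmax(i + 1) for i in range(surface.L)])
    dS, dN = np.clip(pts[:, 0], 1e-3, None), pts[:, 1]
    ratio = dN / dS
    pos = ratio > 1.25
    neu = (ratio > 0.8) & ~pos
    pur = ~pos & ~neu
    # a near-invariant-protein class (ratio ~ 0) is common and sits in its
    # own basin; bucket it separately when present
    zero = pur & (ratio < 0.05)
    if zero.sum() >= 2:
        med = 0.05
    else:
        med = np.median(ratio[pur]) if pur.any() else 0.3

    def bucket(mask, lo_ratio, hi_ratio, fallback):
        if mask.sum() < 2:
            return fallback
        s = float(np.clip(dS[mask].mean(), 0.05, 5.0))
        r = float(np.clip(np.mean(ratio[mask]), lo_ratio, hi_ratio))
        return s, s * r, max(mask.mean(), 0.02)

    c_pos = bucket(pos, 1.05, 6.0, (1.0, 2.0, 0.05))
    c_neu = bucket(neu, 1.0, 1.0, (1.0, 1.0, 0.1))
    c_p1 = bucket(pur & (ratio >= med), 0.0, 0.95, (0.8, 0.32, 0.1))
    c_p2 = bucket(pur & (ratio < med), 0.0, 0.95, (1.0, 0.08, 0.1))
    w = np.array([c_pos[2], c_neu[2], c_p1[2], c_p2[2]])
    w = w / w.sum()
    return RateDistribution.from_arrays(
        [c_pos[0], c_neu[0], c_p1[0], c_p2[0]],
        [c_pos[1], c_neu[1], c_p1[1], c_p2[1]], w)


def _with_positive(dist: RateDistribution, dS: float, dN: float,
                   prob: float) -> RateDistribution:
    """Copy of ``dist`` with the positive class replaced and the weight
    difference absorbed by the neutral class (clipped to stay valid)."""
    pos, neu, p1, p2 = dist.classes
    neu_p = max(neu.prob + pos.prob - prob, 1e-5)
    classes = (RateClass(dS, dN, prob), RateClass(neu.dS, neu.dN, neu_p),
               p1, p2)
    t = sum(c.prob for c in classes)
    return RateDistribution(tuple(
        RateClass(c.dS, c.dN, c.prob / t) for c in classes))


def _swap_positive_neutral(dist: RateDistribution,
                           target_w: float) -> RateDistribution:
    """Exchange the positive and neutral class roles of ``dist``.

    The positive slot takes over the neutral class's rate scale (ratio just
    above 1) with weight ``target_w``; the neutral slot takes the old
    positive class's rate scale and the leftover weight.  This is the other
    labeling of a fit whose large near-neutral class is really the weakly
    positive one.
    """
    pos, neu, p1, p2 = dist.classes
    new_neu_w = max(pos.prob + neu.prob - target_w, 1e-5)
    classes = (RateClass(neu.dS, neu.dS * 1.05, target_w),
               RateClass(pos.dS, pos.dS, new_neu_w), p1, p2)
    t = sum(c.prob for c in classes)
    return RateDistribution(tuple(
        RateClass(c.dS, c.dN, c.prob / t) for c in classes))


def _structured_inits(constraint: str, d1: RateDistribution,
                      d2: RateDistribution):
    """Initial points that cover the boundary optima of each constraint.

    Tied parameters can be satisfied at no likelihood cost by shrinking one
    dataset's positive-class weight to ~0 (ratio ties) or by parking a
    positive class at omega ~ 1 where it mimics the neutral class (weight
    ties).  Weight ties are additionally subject to label switching: when a
    dataset's weakly positive sites are absorbed by its fitted neutral
    class, the constrained optimum lives in the labeling where the positive
    slot holds that large near-neutral class instead.  Plain initialization
    from the free optimum often misses these basins, so each constrained
    fit also starts from explicit versions of them.
    """
    inits = [(d1, d2)]
    w1, w2 = d1.classes[0].omega, d2.classes[0].omega
    if constraint in ("same_strength", "same_regime"):
        # vacate one dataset's positive class at the other's tied ratio
        inits.append((d1, _with_positive(d2, d2.classes[1].dS,
                                         d2.classes[1].dS * w1, 1e-3)))
        inits.append((_with_positive(d1, d1.classes[1].dS,
                                     d1.classes[1].dS * w2, 1e-3), d2))
    if constraint in ("same_proportion", "same_regime"):
        # match weights with the smaller-weight dataset's positive class
        # mimicking neutrality at omega just above 1
        p1, p2 = d1.classes[0].prob, d2.classes[0].prob
        inits.append((d1, _with_positive(d2, d2.classes[1].dS,
                                         d2.classes[1].dS * 1.001, p1)))
        inits.append((_with_positive(d1, d1.classes[1].dS,
                                     d1.classes[1].dS * 1.001, p2), d2))
        # label-swapped variants matching the other dataset's weight
        inits.append((d1, _swap_positive_neutral(d2, p1)))
        inits.append((_swap_positive_neutral(d1, p2), d2))
    if constraint == "shared_distributions":
        inits.extend([(d2, d2), (d1, d1)])
    return inits


_DEFAULT_INIT = RateDistribution.from_arrays(
    [1.0, 1.0, 0.8, 1.2], [2.0, 1.0, 0.08, 0.45], [0.25, 0.25, 0.25, 0.25])
_STRONG_POSITIVE_INIT = RateDistribution.from_arrays(
    [1.0, 1.5, 0.8, 1.0], [3.0, 1.5, 0.1, 0.5], [0.4, 0.2, 0.2, 0.2])
_NO_POSITIVE_INIT = RateDistribution.from_arrays(
    [1.0, 1.3, 0.8, 1.0], [1.001, 1.3, 0.1, 0.5], [0.01, 0.39, 0.3, 0.3])
_ZERO_CLASS_INIT = RateDistribution.from_arrays(
    [1.0, 0.9, 0.6, 1.3], [2.2, 0.9, 0.0002, 0.35], [0.3, 0.3, 0.12, 0.28])


def _optimize(fun, x0, bounds, jitters, rng):
    best = None
    lnls = []
    starts = [np.asarray(x0)]
    for _ in range(jitters):
        starts.append(np.clip(
            np.asarray(x0) + rng.normal(0, 0.5, size=len(x0)),
            [b[0] for b in bounds], [b[1] for b in bounds]))
    for s in starts:
        res = minimize(fun, s, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-9, "maxiter": 500})
        lnls.append(-res.fun)
        if best is None or res.fun < best.fun:
            best = res
    return best, lnls


def fit_rel(aln: CodonAlignment, tree: Phylogeny,
            global_fit: GlobalFit | None = None,
            surface: SiteRateSurface | None = None,
            n_restarts: int = 3, seed: int = 0,
            init: RateDistribution | None = None) -> RelFit:
    """Maximum-likelihood four-class rate distribution for one dataset."""
    if surface is None:
        if global_fit is None:
            global_fit = fit_global_model(aln, tree)
        surface = SiteRateSurface.from_global_fit(aln, global_fit)
    rng = np.random.default_rng(seed)
    x0 = _theta_from_dist(init or _DEFAULT_INIT)

    def nll(theta):
        return -mixture_loglik(surface, _dist_from_theta(theta))

    best, lnls = _optimize(nll, x0, THETA_BOUNDS, max(n_restarts - 1, 0), rng)
    # the positive class's weight/rate trade-off is multimodal: also start
    # from the per-site-estimate moment init and from strong-positive and
    # no-positive configurations
    for alt in (_moment_init(surface), _STRONG_POSITIVE_INIT,
                _NO_POSITIVE_INIT, _ZERO_CLASS_INIT):
        cand, alt_lnls = _optimize(nll, _theta_from_dist(alt),
                                   THETA_BOUNDS, 0, rng)
        lnls.extend(alt_lnls)
        if cand.fun < best.fun:
            best = cand
    spread = max(lnls) - min(lnls)
    converged = bool(best.success)
    if not converged:
        warnings.warn("REL fit did not report convergence", RuntimeWarning)
    return RelFit(_dist_from_theta(best.x), -best.fun, converged,
                  restart_lnls=lnls, surface=surface)


def fit_cross(aln1: CodonAlignment, tree1: Phylogeny,
              aln2: CodonAlignment, tree2: Phylogeny,
              constraint: str = "free",
              surfaces: tuple[SiteRateSurface, SiteRateSurface] | None = None,
              global_fits=None, n_restarts: int = 2, seed: int = 0,
              init: tuple[RateDistribution, RateDistribution] | None = None
              ) -> CrossDatasetFit:
    """Joint fit of both datasets under a cross-dataset constraint.

    The free model is separable, so it is fitted per dataset; constrained
    models share the tied parameters and are initialized from the free
    optimum (when ``init`` supplies it) plus jittered restarts.
    """
    if aln1.n_codons != aln2.n_codons:
        raise ValueError("datasets must have the same number of codon columns")
    if surfaces is None:
        if global_fits is None:
            global_fits = (fit_global_model(aln1, tree1),
                           fit_global_model(aln2, tree2))
        surfaces = (SiteRateSurface.from_global_fit(aln1, global_fits[0]),
                    SiteRateSurface.from_global_fit(aln2, global_fits[1]))
    s1, s2 = surfaces
    param = _CrossParam(constraint)
    rng = np.random.default_rng(seed)

    if constraint == "free":
        f1 = fit_rel(aln1, tree1, surface=s1, n_restarts=n_restarts + 1,
                     seed=seed, init=init[0] if init else None)
        f2 = fit_rel(aln2, tree2, surface=s2, n_restarts=n_restarts + 1,
                     seed=seed + 1, init=init[1] if init else None)
        return CrossDatasetFit("free", f1.distribution, f2.distribution,
                               f1.lnl + f2.lnl, 20, f1.converged and f2.converged)

    x0 = param.pack(*(init or (_DEFAULT_INIT, _DEFAULT_INIT)))

    def nll(x):
        d1, d2 = param.unpack(x)
        return -(mixture_loglik(s1, d1) + mixture_loglik(s2, d2))

    best, _ = _optimize(nll, x0, param.bounds(), n_restarts, rng)
    d1, d2 = param.unpack(best.x)
    return CrossDatasetFit(constraint, d1, d2, -best.fun, param.n_params,
                           bool(best.success))


def cross_dataset_tests(aln1, tree1, aln2, tree2,
                        constraints=("same_strength", "same_proportion",
                                     "same_regime", "shared_distributions"),
                        global_fits=None, surfaces=None,
                        n_restarts: int = 2, seed: int = 0):
    """Free fit plus the requested nested tests; returns (free, dict of
    (fit, LRTResult)).

    After each constrained fit the free model is re-polished from the
    constrained optimum, so the reported statistics are never negative
    beyond optimizer tolerance.
    """
    if surfaces is None:
        if global_fits is None:
            global_fits = (fit_global_model(aln1, tree1),
                           fit_global_model(aln2, tree2))
        surfaces = (SiteRateSurface.from_global_fit(aln1, global_fits[0]),
                    SiteRateSurface.from_global_fit(aln2, global_fits[1]))
    free = fit_cross(aln1, tree1, aln2, tree2, "free", surfaces=surfaces,
                     n_restarts=n_restarts, seed=seed)
    results = {}
    for k, cname in enumerate(constraints):
        fit = None
        for j, pair in enumerate(_structured_inits(cname, free.dist1,
                                                   free.dist2)):
            cand = fit_cross(aln1, tree1, aln2, tree2, cname,
                             surfaces=surfaces,
                             n_restarts=n_restarts if j == 0 else 0,
                             seed=seed + 17 * (k + 1) + 1000 * j, init=pair)
            if fit is None or cand.lnl > fit.lnl:
                fit = cand
        if fit.lnl > free.lnl + 1e-7:
            refit = fit_cross(aln1, tree1, aln2, tree2, "free",
                              surfaces=surfaces, n_restarts=0, seed=seed,
                              init=(fit.dist1, fit.dist2))
            if refit.lnl > free.lnl:
                free = refit
        results[cname] = fit
    tests = {name: (fit, lrt(fit.lnl, free.lnl, CONSTRAINT_DF[name]))
             for name, fit in results.items()}
    return free, tests


# ---------------------------------------------------------------------------
# Omega-only site-class models (M0 / M1 / M2a / M3)
# ---------------------------------------------------------------------------

@dataclass
class OmegaClassFit:
    """Discrete-omega site-class fit (dS fixed at 1)."""

    model: str
    omegas: np.ndarray
    probs: np.ndarray
    lnl: float
    class_site_logliks: np.ndarray = field(repr=False)  # (K, L)
    converged: bool = True

    @property
    def n_free_params(self) -> int:
        return {"M0": 1, "M1": 1, "M2a": 3, "M3": 5}.get(self.model,
                                                         2 * len(self.omegas) - 1)


def _profile_for(aln, tree, global_fit, profile):
    if profile is None:
        if global_fit is None:
            global_fit = fit_global_model(aln, tree)
        profile = OmegaProfile.from_global_fit(aln, global_fit)
    return profile


def fit_m3(aln: CodonAlignment, tree: Phylogeny, n_classes: int = 3,
           global_fit: GlobalFit | None = None,
           profile: OmegaProfile | None = None,
           n_restarts: int = 3, seed: int = 0) -> OmegaClassFit:
    """General discrete omega-class model with ``n_classes`` free classes.

    ``n_classes=1`` reduces to the single-ratio model (M0) and is optimized
    on the exact likelihood so it matches the global fit identically.
    """
    profile = _profile_for(aln, tree, global_fit, profile)
    if n_classes == 1:
        res = minimize_scalar(lambda lw: -profile.exact_loglik(np.exp(lw)).sum(),
                              bounds=(np.log(1e-6), np.log(100.0)),
                              method="bounded", options={"xatol": 1e-8})
        w = float(np.exp(res.x))
        lk = profile.exact_loglik(w)[None, :]
        return OmegaClassFit("M0", np.array([w]), np.array([1.0]),
                             float(lk.sum()), lk)
    rng = np.random.default_rng(seed)
    lo, hi = profile.log_bounds
    K = n_classes

    def unpack(x):
        lw = np.sort(x[:K])
        z = np.concatenate([[0.0], x[K:]])
        ez = np.exp(z - z.max())
        probs = ez / ez.sum()
        return np.exp(lw), probs

    def nll(x):
        ws, probs = unpack(x)
        lk = np.stack([profile.loglik(w) for w in ws])
        return -logsumexp(lk + np.log(probs)[:, None], axis=0).sum()

    x0 = np.concatenate([np.linspace(np.log(0.05), np.log(2.5), K),
                         np.zeros(K - 1)])
    bounds = [(lo, hi)] * K + [(_Q_LO, _Q_HI)] * (K - 1)
    best, lnls = _optimize(nll, x0, bounds, max(n_restarts - 1, 0), rng)
    ws, probs = unpack(best.x)
    lk = np.stack([profile.loglik(w) for w in ws])
    return OmegaClassFit(f"M{K}" if K == 3 else f"Mdisc{K}", ws, probs,
                         -best.fun, lk, bool(best.success))


def fit_m1(aln, tree, global_fit=None, profile=None,
           zero_loglik: np.ndarray | None = None) -> OmegaClassFit:
    """Neutral null: site classes omega = 0 and omega = 1, free weight."""
    profile = _profile_for(aln, tree, global_fit, profile)
    l0 = profile.exact_loglik(1e-9) if zero_loglik is None else zero_loglik
    l1 = profile.exact_loglik(1.0)
    lk = np.stack([l0, l1])

    def nll(q):
        p0 = expit(q)
        return -logsumexp(lk + np.log([max(p0, 1e-300),
                                       max(1 - p0, 1e-300)])[:, None], axis=0).sum()

    res = minimize_scalar(nll, bounds=(_Q_LO, _Q_HI), method="bounded",
                          options={"xatol": 1e-8})
    p0 = float(expit(res.x))
    return OmegaClassFit("M1", np.array([0.0, 1.0]), np.array([p0, 1 - p0]),
                         -float(res.fun), lk)


def fit_m2a(aln, tree, global_fit=None, profile=None, n_restarts: int = 3,
            seed: int = 0) -> OmegaClassFit:
    """Selection model: omega in {0, 1, omega2 > 1} with free weights."""
    profile = _profile_for(aln, tree, global_fit, profile)
    l0 = profile.exact_loglik(1e-9)
    l1 = profile.exact_loglik(1.0)
    rng = np.random.default_rng(seed)
    lo, hi = profile.log_bounds

    def unpack(x):
        w2 = 1.0 + np.exp(x[0])
        z = np.array([0.0, x[1], x[2]])
        ez = np.exp(z - z.max())
        probs = ez / ez.sum()
        return w2, probs

    def nll(x):
        w2, probs = unpack(x)
        lk = np.stack([l0, l1, profile.loglik(w2)])
        return -logsumexp(lk + np.log(probs)[:, None], axis=0).sum()

    x0 = np.array([np.log(1.5), 0.0, -1.0])
    bounds = [(-9.0, np.log(np.exp(hi) - 1.0))] + [(_Q_LO, _Q_HI)] * 2
    best, _ = _optimize(nll, x0, bounds, max(n_restarts - 1, 0), rng)
    w2, probs = unpack(best.x)
    lk = np.stack([l0, l1, profile.loglik(w2)])
    return OmegaClassFit("M2a", np.array([0.0, 1.0, w2]), probs,
                         -best.fun, lk, bool(best.success))


# ---------------------------------------------------------------------------
# Empirical Bayes site posteriors
# ---------------------------------------------------------------------------

def site_class_posteriors(fit) -> tuple[np.ndarray, np.ndarray]:
    """Per-site posterior over classes and P(positive selection).

    Accepts an :class:`OmegaClassFit` (positive classes are those with
    omega > 1) or a :class:`RelFit` whose surface is attached (positive
    classes have dN > dS).  Returns ``(posterior (L, K), p_positive (L,))``.
    """
    if isinstance(fit, OmegaClassFit):
        lk = fit.class_site_logliks
        probs = fit.probs
        positive = fit.omegas > 1.0
    elif isinstance(fit, RelFit):
        if fit.surface is None:
            raise ValueError("RelFit must carry its likelihood surface")
        lk = mixture_site_logliks(fit.surface, fit.distribution)
        probs = np.array([c.prob for c in fit.distribution.classes])
        positive = np.array([c.dN > c.dS for c in fit.distribution.classes])
    else:
        raise TypeError(f"unsupported fit type {type(fit).__name__}")
    logpost = lk + np.log(np.clip(probs, 1e-300, None))[:, None]
    logpost -= logsumexp(logpost, axis=0, keepdims=True)
    post = np.exp(logpost).T  # (L, K)
    return post, post[:, positive].sum(axis=1)
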