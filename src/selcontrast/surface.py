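"""Cached per-site likelihood surfaces over (dS, dN) and over omega.

Every selection test in this package repeatedly needs the likelihood of a
codon column as a function of its synonymous and non-synonymous rate
multipliers, with the tree, branch lengths, frequencies and
exchangeabilities frozen at the global fit.  Evaluating that by pruning at
every optimizer step is wasteful: one pruning pass prices *all* columns at
a given rate pair.  The surface classes therefore run the pruning engine
over a fixed rate grid once and answer subsequent queries by cubic
interpolation.

Grids are square-root spaced in the rate so resolution concentrates near
zero where the likelihood curves sharply (and the grid includes rate 0
exactly, needed for the dN = 0 purifying class).  Because the null and
alternative of every likelihood-ratio test are optimized over the same
interpolated family, the tests remain properly nested.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline, RegularGridInterpolator

from .genetics import CodonAlignment
from .model import GlobalFit, PruningEngine, QFactory
from .trees import Phylogeny

#: default rate grid for (dS, dN) surfaces: 0..8, sqrt-spaced, 13 knots
DEFAULT_RATE_GRID = np.round(np.linspace(0.0, np.sqrt(8.0), 13) ** 2, 6)

#: default omega grid for the 1-D profile (dS = 1): log-spaced over the
#: truncated prior support [1e-3, 100]
DEFAULT_OMEGA_GRID = np.concatenate([[1e-3], np.geomspace(3e-3, 100.0, 29)])


class SiteRateSurface:
    """Per-site log-likelihood over a (dS, dN) grid with cubic interpolation.

    Parameters
    ----------
    aln, tree :
        Dataset; the tree must carry (fitted) branch lengths.
    factory :
        :class:`~selcontrast.model.QFactory` frozen at the global fit.
    grid :
        1-D array of rate values used for both axes (must include the range
        the optimizers will query; queries are clamped to it).
    """

    def __init__(self, aln: CodonAlignment, tree: Phylogeny, factory: QFactory,
                 grid: np.ndarray | None = None):
        self.grid = np.asarray(DEFAULT_RATE_GRID if grid is None else grid, float)
        if self.grid.ndim != 1 or len(self.grid) < 4:
            raise ValueError("grid must be a 1-D array with >= 4 knots")
        self.factory = factory
        self.engine = PruningEngine(tree, aln)
        self.lengths = tree.lengths
        self.L = aln.n_codons
        G = len(self.grid)
        values = np.empty((self.L, G, G))
        for i, a in enumerate(self.grid):
            for j, b in enumerate(self.grid):
                if a == 0.0 and b == 0.0:
                    # no substitutions at all: likelihood of the column being
                    # invariant; still well defined via the rate-0 matrix
                    sp = factory.spectral(1e-9, 1e-9)
                else:
                    sp = factory.spectral(a, b)
                values[:, i, j] = self.engine.loglikelihood(sp, self.lengths)
        # floor each site far below its maximum: rate pairs that implausible
        # never matter for the fits, and capping the dynamic range keeps the
        # cubic interpolant free of overshoot near hard corners (e.g. the
        # zero-rate corner of a variable column)
        floor = values.max(axis=(1, 2), keepdims=True) - 30.0
        np.maximum(values, floor, out=values)
        self.values = values
        u = np.sqrt(self.grid)
        self._interp = RegularGridInterpolator(
            (u, u), np.moveaxis(values, 0, -1), method="cubic",
            bounds_error=False, fill_value=None)
        self._u_max = u[-1]

    @classmethod
    def from_global_fit(cls, aln: CodonAlignment, fit: GlobalFit,
                        grid: np.ndarray | None = None) -> "SiteRateSurface":
        return cls(aln, fit.tree, fit.factory, grid=grid)

    def loglik(self, dS: float, dN: float) -> np.ndarray:
        """Interpolated per-site log-likelihood vector at one rate pair."""
        u = np.clip(np.sqrt([max(dS, 0.0), max(dN, 0.0)]), 0.0, self._u_max)
        return self._interp(u)[0]

    def loglik_many(self, rates: np.ndarray) -> np.ndarray:
        """Per-site log-likelihoods at a batch of rate pairs.

        ``rates`` is (K, 2) of (dS, dN); returns (K, L) in one interpolator
        call, which is much cheaper than K separate :meth:`loglik` calls.
        """
        u = np.clip(np.sqrt(np.clip(np.asarray(rates, float), 0.0, None)),
                    0.0, self._u_max)
        return self._interp(u)

    def loglik_site(self, site: int, dS, dN) -> np.ndarray | float:
        """Interpolated log-likelihood of 1-based ``site`` (vectorized in rates)."""
        dS = np.atleast_1d(np.asarray(dS, float))
        dN = np.atleast_1d(np.asarray(dN, float))
        u = np.clip(np.sqrt(np.clip(np.stack([dS, dN], axis=-1), 0.0, None)),
                    0.0, self._u_max)
        out = self._interp(u)[..., site - 1]
        return float(out[0]) if out.size == 1 else out

    def exact_loglik(self, dS: float, dN: float,
                     sites: np.ndarray | None = None) -> np.ndarray:
        """Non-interpolated per-site log-likelihood (one pruning pass)."""
        sp = self.factory.spectral(max(dS, 1e-9), max(dN, 1e-9))
        return self.engine.loglikelihood(sp, self.lengths, sites=sites)

    def grid_argmax(self, site: int) -> tuple[float, float]:
        """Grid knot (dS, dN) maximizing the site's tabulated log-likelihood."""
        v = self.values[site - 1]
        i, j = np.unravel_index(np.argmax(v), v.shape)
        return float(self.grid[i]), float(self.grid[j])


class OmegaProfile:
    """Per-site log-likelihood profile in omega with dS fixed to 1.

    Serves the omega-only site-class models (M0/M1/M2a/M3) and the per-site
    Bayesian sampler.  Alongside the cubic spline, a dense table on a log
    grid supports vectorized constant-time lookups inside MCMC loops.
    """

    def __init__(self, aln: CodonAlignment, tree: Phylogeny, factory: QFactory,
                 omegas: np.ndarray | None = None, dense: int = 1024):
        self.omegas = np.asarray(
            DEFAULT_OMEGA_GRID if omegas is None else omegas, float)
        if np.any(self.omegas <= 0):
            raise ValueError("omega grid must be positive (omega=0 handled via rate surface)")
        self.engine = PruningEngine(tree, aln)
        self.factory = factory
        self.lengths = tree.lengths
        self.L = aln.n_codons
        vals = np.empty((len(self.omegas), self.L))
        for k, w in enumerate(self.omegas):
            sp = factory.spectral(1.0, w)
            vals[k] = self.engine.loglikelihood(sp, self.lengths)
        self.x = np.log(self.omegas)
        self.values = vals  # (n_omega, L)
        self._spline = CubicSpline(self.x, vals, axis=0)
        self._xd = np.linspace(self.x[0], self.x[-1], dense)
        self._dense = self._spline(self._xd)  # (dense, L)
        self._dx = self._xd[1] - self._xd[0]

    @classmethod
    def from_global_fit(cls, aln: CodonAlignment, fit: GlobalFit,
                        omegas: np.ndarray | None = None) -> "OmegaProfile":
        return cls(aln, fit.tree, fit.factory, omegas=omegas)

    @property
    def log_bounds(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.x[-1])

    def loglik(self, omega: float) -> np.ndarray:
        """Per-site log-likelihood vector at one omega (spline)."""
        w = float(np.clip(omega, self.omegas[0], self.omegas[-1]))
        return self._spline(np.log(w))

    def loglik_sites_at(self, log_omega: np.ndarray) -> np.ndarray:
        """Dense-table lookup: per-site values at per-site log-omegas.

        ``log_omega`` has one entry per site; linear interpolation on the
        densified table.  This is the MCMC hot path.
        """
        x = np.clip(log_omega, self._xd[0], self._xd[-1])
        f = (x - self._xd[0]) / self._dx
        i0 = np.minimum(f.astype(np.int64), len(self._xd) - 2)
        w = f - i0
        cols = np.arange(self.L)
        return (1.0 - w) * self._dense[i0, cols] + w * self._dense[i0 + 1, cols]

    def exact_loglik(self, omega: float) -> np.ndarray:
        sp = self.factory.spectral(1.0, max(omega, 1e-9))
        return self.engine.loglikelihood(sp, self.lengths)
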