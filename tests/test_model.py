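"""Core codon model: rate matrix structure, transition probabilities,
pruning likelihood against brute-force enumeration, and the global fit."""

import numpy as np
import pytest

from selcontrast.genetics import MISSING, CodonAlignment, universal_code
from selcontrast.model import (CodonFrequencies, CodonModelParams, QFactory,
                               SpectralQ, build_rate_matrix, fit_global_model,
                               hky_exchangeabilities, site_log_likelihood,
                               transition_probabilities, PruningEngine)
from selcontrast.simulate import (SiteOmegaSpec, default_params,
                                  simulate_alignment, simulate_tree,
                                  scale_to_mean_pairwise)
from selcontrast.trees import Phylogeny


# ---------------------------------------------------------------------------
# Rate matrix
# ---------------------------------------------------------------------------

class TestRateMatrix:
    def test_beta_zero_kills_nonsynonymous_rates(self, params, code):
        Q = build_rate_matrix(params.with_rates(1.0, 0.0), code)
        i, j, _, _, _, syn = code.single_step_pairs()
        assert np.all(Q[i[~syn], j[~syn]] == 0.0)
        assert np.any(Q[i[syn], j[syn]] > 0.0)

    def test_neutral_rows_sum_to_zero(self, code):
        p = CodonModelParams(np.ones(6), CodonFrequencies.uniform(code))
        Q = build_rate_matrix(p, code)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_multi_nucleotide_changes_forbidden(self, params, code):
        Q = build_rate_matrix(params, code)
        nucs = code.codon_nucs
        ndiff = (nucs[:, None, :] != nucs[None, :, :]).sum(axis=2)
        off = ~np.eye(code.n_states, dtype=bool)
        assert np.all(Q[(ndiff > 1) & off] == 0.0)

    @pytest.mark.parametrize("mode", ["F3x4", "F61"])
    def test_detailed_balance(self, params, code, mode):
        if mode == "F61":
            rng = np.random.default_rng(0)
            freqs = CodonFrequencies.f61(rng.dirichlet(np.ones(61) * 5))
        else:
            freqs = params.freqs
        p = CodonModelParams(np.array([1.0, 2.2, 0.7, 1.1, 3.0, 1.0]), freqs,
                             alpha=0.8, beta=1.9)
        Q = build_rate_matrix(p, code)
        pi = p.freqs.codon
        flux = pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-10

    def test_neutral_scaling_normalizes_mean_rate(self, params, code):
        Q = build_rate_matrix(params.with_rates(1.0, 1.0), code)
        pi = params.freqs.codon
        assert abs(-(pi @ np.diag(Q)) - 1.0) < 1e-12

    def test_miniature_code_hand_computed(self):
        """Two-codon-state analogue: a 4-state chain with known entries.

        With uniform frequencies and alpha=beta the codon matrix restricted
        to a synonymous pair must equal exchangeability * frequency factor
        / neutral mean rate; checked on an explicit pair."""
        code = universal_code()
        freqs = CodonFrequencies.uniform(code)
        p = CodonModelParams(np.ones(6), freqs, alpha=2.0, beta=0.5)
        fac = QFactory(p.exchangeabilities, p.freqs, code)
        Q = fac.rate_matrix(2.0, 0.5)
        # GGU -> GGC is synonymous (Gly), single change at position 3
        i, j = code.state_of["GGT"], code.state_of["GGC"]
        expected = 1.0 * 0.25 * 2.0 / fac.mean_rate_neutral
        assert Q[i, j] == pytest.approx(expected, rel=1e-12)
        # GGU -> GCU is non-synonymous (Gly->Ala), position 2
        k = code.state_of["GCT"]
        expected_n = 1.0 * 0.25 * 0.5 / fac.mean_rate_neutral
        assert Q[i, k] == pytest.approx(expected_n, rel=1e-12)

    def test_invalid_parameters_rejected(self, code):
        with pytest.raises(ValueError):
            CodonModelParams(np.array([1, -1, 1, 1, 1, 1.0]),
                             CodonFrequencies.uniform(code))
        with pytest.raises(ValueError):
            CodonModelParams(np.ones(6), CodonFrequencies.uniform(code),
                             alpha=-0.1)
        with pytest.raises(ValueError):
            CodonFrequencies("F61", np.ones(61))  # does not sum to 1


# ---------------------------------------------------------------------------
# Transition probabilities
# ---------------------------------------------------------------------------

class TestTransitionProbabilities:
    def test_zero_time_is_identity(self, params, code):
        Q = build_rate_matrix(params, code)
        P = transition_probabilities(Q, 0.0, params.freqs.codon)
        assert np.abs(P - np.eye(61)).max() < 1e-10

    def test_rows_are_distributions(self, params, code):
        Q = build_rate_matrix(params, code)
        P = transition_probabilities(Q, 0.37, params.freqs.codon)
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-10
        assert P.min() >= 0.0

    def test_long_time_reaches_stationarity(self, params, code):
        Q = build_rate_matrix(params, code)
        P = transition_probabilities(Q, 400.0, params.freqs.codon)
        assert np.abs(P - params.freqs.codon[None, :]).max() < 1e-6

    def test_negative_time_rejected(self, params, code):
        Q = build_rate_matrix(params, code)
        with pytest.raises(ValueError):
            transition_probabilities(Q, -0.1)

    def test_two_state_closed_form(self):
        """Spectral exponentiation against the analytic two-state formula."""
        pi = np.array([0.3, 0.7])
        mu = 1.7
        Q = mu * np.array([[-pi[1], pi[1]], [pi[0], -pi[0]]])
        for t in (0.01, 0.5, 3.0):
            P = SpectralQ(Q, pi).transition(t)
            e = np.exp(-mu * t)
            expected = np.array([
                [pi[0] + pi[1] * e, pi[1] * (1 - e)],
                [pi[0] * (1 - e), pi[1] + pi[0] * e]])
            assert np.abs(P - expected).max() < 1e-12


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

def brute_force_column_loglik(column, tree, params, code):
    """Independent oracle: full enumeration of internal-node states via a
    single unoptimized einsum (one term per joint state assignment)."""
    fac = QFactory(params.exchangeabilities, params.freqs, code)
    sq = fac.spectral(params.alpha, params.beta)
    S = code.n_states
    axes = {}
    letters = iter("abcdefghijklmnop")
    for nd in range(tree.n_nodes):
        if nd >= tree.n_leaves:
            axes[nd] = next(letters)
    operands, subscripts = [], []
    for nd in range(tree.n_nodes):
        p = tree.parent[nd]
        if p < 0:
            continue
        P = sq.transition(tree.lengths[nd])
        if nd < tree.n_leaves:
            s = column[nd]
            vec = np.ones(S) if s == MISSING else P[:, s]
            operands.append(vec)
            subscripts.append(axes[p])
        else:
            operands.append(P)
            subscripts.append(axes[p] + axes[nd])
    operands.append(params.freqs.codon)
    subscripts.append(axes[tree.root])
    lik = np.einsum(",".join(subscripts) + "->", *operands, optimize=False)
    return np.log(lik)


class TestPruning:
    def test_single_leaf_column_gives_log_pi(self, params, code):
        tree = Phylogeny.from_newick("(A:0.1,B:0.2,C:0.3);")
        aln = CodonAlignment(["A", "B", "C"],
                             np.array([[5], [MISSING], [MISSING]], dtype=np.int16))
        ll = site_log_likelihood(aln.column(1), tree, params, code)
        # with B and C missing, the likelihood marginalizes to P(A = state 5)
        assert ll == pytest.approx(np.log(params.freqs.codon[5]), abs=1e-10)

    def test_all_missing_column_is_certain(self, params, code):
        tree = Phylogeny.from_newick("(A:0.1,(B:0.2,C:0.3):0.1);")
        col = np.array([MISSING] * 3, dtype=np.int16)
        assert site_log_likelihood(col, tree, params, code) == pytest.approx(0.0, abs=1e-12)

    def test_pruning_matches_brute_force_enumeration(self, params, code):
        """50 random instances with <= 4 taxa, tolerance 1e-8."""
        rng = np.random.default_rng(123)
        for rep in range(50):
            n = int(rng.integers(3, 5))
            tree = simulate_tree(n, "coalescent", float(rng.uniform(0.3, 3.0)),
                                 seed=int(rng.integers(0, 2**31)))
            column = rng.integers(0, 61, size=n).astype(np.int16)
            if rng.random() < 0.3:
                column[rng.integers(0, n)] = MISSING
            p = params.with_rates(float(rng.uniform(0.2, 2.0)),
                                  float(rng.uniform(0.0, 3.0)))
            ll = site_log_likelihood(column, tree, p, code)
            bf = brute_force_column_loglik(column, tree, p, code)
            assert ll == pytest.approx(bf, abs=1e-8)

    def test_likelihood_invariant_to_leaf_order(self, params, code, small_tree):
        rng = np.random.default_rng(5)
        aln = simulate_alignment(small_tree, SiteOmegaSpec.constant(10, 1, 1),
                                 default_params(), seed=3)
        perm = rng.permutation(aln.n_taxa)
        shuffled = CodonAlignment([aln.labels[i] for i in perm],
                                  aln.states[perm], code)
        fac = QFactory(params.exchangeabilities, params.freqs, code)
        sp = fac.spectral(1.0, 0.7)
        l1 = PruningEngine(small_tree, aln).loglikelihood(sp, small_tree.lengths)
        l2 = PruningEngine(small_tree, shuffled).loglikelihood(sp, small_tree.lengths)
        assert np.abs(l1 - l2).max() < 1e-8

    def test_likelihood_invariant_to_rerooting(self, params, code):
        """Time reversibility: rerooting along any branch keeps lnL."""
        tree = simulate_tree(6, "coalescent", 1.5, seed=11)
        aln = simulate_alignment(tree, SiteOmegaSpec.constant(8, 1, 1),
                                 default_params(), seed=2)
        fac = QFactory(params.exchangeabilities, params.freqs, code)
        sp = fac.spectral(0.9, 1.4)
        base = PruningEngine(tree, aln).loglikelihood(sp, tree.lengths).sum()
        dt = tree.to_dendropy()
        for edge in list(dt.preorder_edge_iter())[3:6]:
            if edge.head_node is dt.seed_node or edge.length is None:
                continue
            dt2 = dt.clone(depth=1)
            e2 = [e for e in dt2.preorder_edge_iter()
                  if e.length == edge.length][0]
            dt2.reroot_at_edge(e2, length1=e2.length / 2,
                               length2=e2.length / 2,
                               update_bipartitions=False)
            rerooted = Phylogeny.from_dendropy(dt2)
            ll = PruningEngine(rerooted, aln).loglikelihood(
                sp, rerooted.lengths).sum()
            assert ll == pytest.approx(base, abs=1e-7)

    def test_label_mismatch_raises(self, params, code, small_tree):
        aln = CodonAlignment(["x1", "x2", "x3"],
                             np.zeros((3, 2), dtype=np.int16))
        with pytest.raises(ValueError):
            PruningEngine(small_tree, aln)


# ---------------------------------------------------------------------------
# Global fit
# ---------------------------------------------------------------------------

class TestGlobalFit:
    def test_recovers_generating_omega(self):
        """omega = 0.5, 24 taxa x 150 codons: recovery within +/- 15%."""
        tree = scale_to_mean_pairwise(
            simulate_tree(24, "coalescent", 1.0, seed=21), 1.0)
        aln = simulate_alignment(tree, SiteOmegaSpec.constant(150, 1.0, 0.5),
                                 default_params(), seed=22)
        fit = fit_global_model(aln, tree, nuc_model="HKY")
        assert 0.5 * 0.85 <= fit.params.omega <= 0.5 * 1.15

    def test_refit_from_optimum_is_stable(self, small_aln, small_fit):
        refit = fit_global_model(small_aln, small_fit.tree, nuc_model="HKY")
        assert abs(refit.lnl - small_fit.lnl) < 1e-2
        assert refit.lnl >= small_fit.lnl - 1e-4

    def test_identical_sequences_collapse_branches(self, code):
        tree = Phylogeny.from_newick("(A:0.1,(B:0.1,C:0.1):0.1,D:0.1);")
        states = np.tile(np.arange(20, dtype=np.int16), (4, 1))
        aln = CodonAlignment(["A", "B", "C", "D"], states, code)
        fit = fit_global_model(aln, tree, nuc_model="HKY",
                               optimize_exchangeabilities=False)
        mask = np.arange(fit.tree.n_nodes) != fit.tree.root
        # effectively zero: under one expected substitution per 10^4 codons
        assert fit.tree.lengths[mask].max() < 1e-4

    def test_empty_alignment_rejected(self, small_tree, code):
        aln = CodonAlignment(small_tree.labels,
                             np.zeros((16, 0), dtype=np.int16), code)
        with pytest.raises(ValueError):
            fit_global_model(aln, small_tree)
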