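"""Likelihood engine tests, anchored by an exhaustive-enumeration oracle."""

from itertools import product

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from comphet import alphabet as ab
from comphet import phylo_model as pm
from comphet import simdata as sd
from comphet import tree as tr
from comphet.alignment import Alignment, from_sequences

from conftest import random_tree_with_lengths


def brute_force_loglik(aln, tree, model):
    """Sum over all internal-node state assignments, per site."""
    S = model.n_states
    rates = pm.discretize_gamma(model.alpha, model.n_rate_categories)
    nodes = tree.postorder()
    internals = [n for n in nodes if not n.is_leaf]
    leaf_row = {n.name: aln.taxa.index(n.name) for n in nodes if n.is_leaf}
    lookup = ab.partial_lookup(aln.alphabet)
    P = {}
    for n in nodes:
        if n is tree.root:
            continue
        Q = pm.build_rate_matrix(model.R, tree.comp_vectors[n.comp])
        P[id(n)] = [pm.transition_probabilities(Q, n.length, r) for r in rates]
    total = 0.0
    for site in range(aln.n_columns):
        site_l = 0.0
        for k in range(len(rates)):
            for assign in product(range(S), repeat=len(internals)):
                amap = {id(n): s for n, s in zip(internals, assign)}
                p = tree.comp_vectors[tree.root.comp][amap[id(tree.root)]]
                for n in nodes:
                    if n is tree.root:
                        continue
                    parent_state = amap[id(n.parent)]
                    if n.is_leaf:
                        pv = lookup[aln.matrix[leaf_row[n.name], site]]
                        p *= float(P[id(n)][k][parent_state] @ pv)
                    else:
                        p *= P[id(n)][k][parent_state, amap[id(n)]]
                site_l += p
        total += np.log(site_l / len(rates))
    return total


def random_simplex(n, rng):
    x = rng.dirichlet(np.ones(n) * 5.0)
    return x / x.sum()


class TestBuildRateMatrix:
    def test_jukes_cantor_limit(self):
        Q = pm.build_rate_matrix(pm.gtr_matrix(), np.full(4, 0.25))
        off = Q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0 / 3.0)
        assert np.allclose(np.diag(Q), -1.0)

    def test_rows_sum_to_zero(self, rng):
        for _ in range(5):
            pi = random_simplex(4, rng)
            Q = pm.build_rate_matrix(pm.gtr_matrix(rng.uniform(0.5, 2, 6)), pi)
            assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_detailed_balance(self, rng):
        pi = random_simplex(4, rng)
        Q = pm.build_rate_matrix(pm.gtr_matrix(rng.uniform(0.5, 2, 6)), pi)
        flux = pi[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_unit_mean_rate(self, rng):
        pi = random_simplex(4, rng)
        Q = pm.build_rate_matrix(pm.gtr_matrix(rng.uniform(0.5, 2, 6)), pi)
        assert -np.dot(pi, np.diag(Q)) == pytest.approx(1.0)

    def test_nonpositive_pi_rejected(self):
        with pytest.raises(ValueError):
            pm.build_rate_matrix(pm.gtr_matrix(), np.array([0.5, 0.5, 0.0, 0.0]))


class TestTransitionProbabilities:
    def test_t_zero_identity(self):
        Q = pm.build_rate_matrix(pm.gtr_matrix(), np.full(4, 0.25))
        assert np.allclose(pm.transition_probabilities(Q, 0.0), np.eye(4))

    def test_jc_closed_form(self):
        Q = pm.build_rate_matrix(pm.gtr_matrix(), np.full(4, 0.25))
        for t in (0.01, 0.1, 0.5, 1.0, 3.0):
            P = pm.transition_probabilities(Q, t)
            p_same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
            p_diff = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
            want = np.full((4, 4), p_diff)
            np.fill_diagonal(want, p_same)
            assert np.abs(P - want).max() <= 1e-10

    def test_rows_sum_to_one(self, rng):
        pi = random_simplex(4, rng)
        Q = pm.build_rate_matrix(pm.gtr_matrix(rng.uniform(0.5, 2, 6)), pi)
        P = pm.transition_probabilities(Q, 0.7, rate=1.3)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert (P >= 0).all()

    def test_long_branch_reaches_stationarity(self, rng):
        pi = random_simplex(4, rng)
        Q = pm.build_rate_matrix(pm.gtr_matrix(), pi)
        P = pm.transition_probabilities(Q, 500.0)
        assert np.allclose(P, np.tile(pi, (4, 1)), atol=1e-9)

    def test_invalid_t(self):
        Q = pm.build_rate_matrix(pm.gtr_matrix(), np.full(4, 0.25))
        with pytest.raises(ValueError):
            pm.transition_probabilities(Q, np.nan)


class TestDiscretizeGamma:
    def test_single_category(self):
        assert pm.discretize_gamma(0.7, 1).tolist() == [1.0]

    def test_exponential_quartiles_numeric_oracle(self):
        # alpha=1: unit-mean exponential; category means by numeric integration
        got = pm.discretize_gamma(1.0, 4)
        edges = gamma_dist.ppf([0, 0.25, 0.5, 0.75, 1.0], a=1.0, scale=1.0)
        want = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            val, _ = quad(lambda x: x * np.exp(-x), lo,
                          hi if np.isfinite(hi) else 50.0)
            want.append(4.0 * val)
        want = np.array(want) / np.mean(want)
        assert np.allclose(got, want, atol=1e-6)

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0, 2.7, 10.0])
    def test_mean_is_one(self, alpha):
        assert pm.discretize_gamma(alpha, 4).mean() == pytest.approx(1.0)

    def test_rates_increase(self):
        r = pm.discretize_gamma(0.4, 6)
        assert (np.diff(r) > 0).all()


class TestTreeLogLikelihood:
    def test_single_leaf_single_site(self):
        leaf = tr.Node("x", None)
        tree = tr.Tree(leaf, comp_vectors=[np.array([0.1, 0.2, 0.3, 0.4])])
        aln = from_sequences([("x", "G")], alphabet=ab.NUCLEOTIDE)
        model = pm.SubstitutionModel(R=pm.gtr_matrix(), alpha=1.0,
                                     n_rate_categories=1)
        res = pm.tree_log_likelihood(aln, tree, model)
        assert res.total == pytest.approx(np.log(0.3))

    @pytest.mark.parametrize("mode,seed", [("cv1", 0), ("ndch", 1),
                                           ("ndch2", 2)])
    def test_matches_enumeration_oracle(self, mode, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree_with_lengths("abcd", rng)
        nodes = tree.postorder()
        if mode == "cv1":
            tree.comp_vectors = [random_simplex(4, rng)]
        elif mode == "ndch":
            tree.comp_mode = tr.NDCH
            tree.comp_vectors = [random_simplex(4, rng) for _ in range(2)]
            for n in nodes:
                n.comp = int(rng.integers(2))
        else:
            tree.comp_mode = tr.NDCH2
            tree.comp_vectors = [random_simplex(4, rng) for _ in nodes]
            for i, n in enumerate(nodes):
                n.comp = i
        model = pm.SubstitutionModel(R=pm.gtr_matrix(rng.uniform(0.5, 2, 6)),
                                     alpha=0.8, n_rate_categories=3)
        aln = sd.simulate_matrix(tree, model, 30, rng, ab.NUCLEOTIDE)
        got = pm.tree_log_likelihood(aln, tree, model)
        want = brute_force_loglik(aln, tree, model)
        assert abs(got.total - want) <= 1e-8

    def test_oracle_with_ambiguity_and_gaps(self):
        rng = np.random.default_rng(3)
        tree = random_tree_with_lengths("abcd", rng)
        tree.comp_vectors = [random_simplex(4, rng)]
        model = pm.SubstitutionModel(R=pm.gtr_matrix(), alpha=1.0,
                                     n_rate_categories=2)
        aln = from_sequences(
            [("a", "ARGT-"), ("b", "?CGNN"), ("c", "ACYT-"), ("d", "WCGT?")],
            alphabet=ab.NUCLEOTIDE)
        got = pm.tree_log_likelihood(aln, tree, model)
        want = brute_force_loglik(aln, tree, model)
        assert abs(got.total - want) <= 1e-8

    def test_two_taxon_jc_closed_form(self):
        n, x, t = 40, 7, 0.35
        seq_a = "A" * n
        seq_b = "C" * x + "A" * (n - x)
        aln = from_sequences([("a", seq_a), ("b", seq_b)],
                             alphabet=ab.NUCLEOTIDE)
        root = tr.Node()
        root.add_child(tr.Node("a", t / 2))
        root.add_child(tr.Node("b", t / 2))
        tree = tr.Tree(root, comp_vectors=[np.full(4, 0.25)])
        model = pm.SubstitutionModel(R=pm.gtr_matrix(), alpha=1.0,
                                     n_rate_categories=1)
        got = pm.tree_log_likelihood(aln, tree, model).total
        p_same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
        p_diff = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
        want = n * np.log(0.25) + (n - x) * np.log(p_same) + x * np.log(p_diff)
        assert abs(got - want) <= 1e-10

    def test_per_site_sums_to_total(self, rng):
        tree, model, aln = _random_instance(rng)
        res = pm.tree_log_likelihood(aln, tree, model, per_site=True)
        assert res.per_site.shape == (aln.n_columns,)
        assert res.total == pytest.approx(res.per_site.sum(), abs=1e-8)

    def test_pattern_compression_invariance(self, rng):
        tree, model, aln = _random_instance(rng, n_sites=60)
        base = pm.tree_log_likelihood(aln, tree, model).total
        # duplicating every column doubles the log-likelihood exactly
        doubled = Alignment(taxa=list(aln.taxa),
                            matrix=np.hstack([aln.matrix, aln.matrix]),
                            alphabet=aln.alphabet)
        got = pm.tree_log_likelihood(doubled, tree, model).total
        assert got == pytest.approx(2 * base, abs=1e-9)

    def test_cv1_root_placement_invariance(self):
        rng = np.random.default_rng(9)
        pi = random_simplex(4, rng)
        a = tr.parse_newick("((a:0.2,b:0.3):0.1,c:0.4,d:0.25);")
        b = tr.parse_newick("((c:0.4,d:0.25):0.1,a:0.2,b:0.3);")
        model = pm.SubstitutionModel(R=pm.gtr_matrix(rng.uniform(0.5, 2, 6)),
                                     alpha=0.9)
        for t in (a, b):
            t.comp_vectors = [pi]
        aln = sd.simulate_matrix(a, model, 50, rng, ab.NUCLEOTIDE)
        la = pm.tree_log_likelihood(aln, a, model).total
        lb = pm.tree_log_likelihood(aln, b, model).total
        assert la == pytest.approx(lb, abs=1e-9)

    def test_fully_ambiguous_leaf_equals_pruned(self, rng):
        tree = random_tree_with_lengths("abcde", rng)
        tree.comp_vectors = [random_simplex(4, rng)]
        model = pm.SubstitutionModel(R=pm.gtr_matrix(), alpha=1.0)
        aln = sd.simulate_matrix(tree, model, 40, rng, ab.NUCLEOTIDE)
        idx = aln.taxa.index("e")
        aln.matrix[idx] = ab.MISSING
        full = pm.tree_log_likelihood(aln, tree, model).total
        pruned_tree = tree.prune_leaf("e")
        pruned_aln = Alignment(
            taxa=[t for t in aln.taxa if t != "e"],
            matrix=np.delete(aln.matrix, idx, axis=0),
            alphabet=aln.alphabet)
        pruned = pm.tree_log_likelihood(pruned_aln, pruned_tree, model).total
        assert abs(full - pruned) <= 1e-8

    def test_ndch2_missing_attachment_error(self, rng):
        tree = random_tree_with_lengths("abcd", rng)
        tree.comp_mode = tr.NDCH2
        tree.comp_vectors = [np.full(4, 0.25)]  # too few vectors
        for i, n in enumerate(tree.postorder()):
            n.comp = i
        aln = from_sequences([(t, "ACGT") for t in "abcd"],
                             alphabet=ab.NUCLEOTIDE)
        model = pm.SubstitutionModel(R=pm.gtr_matrix(), alpha=1.0)
        with pytest.raises(ValueError):
            pm.tree_log_likelihood(aln, tree, model)


def _random_instance(rng, n_sites=30):
    tree = random_tree_with_lengths("abcde", rng)
    tree.comp_vectors = [random_simplex(4, rng)]
    model = pm.SubstitutionModel(R=pm.gtr_matrix(rng.uniform(0.5, 2, 6)),
                                 alpha=1.2, n_rate_categories=4)
    aln = sd.simulate_matrix(tree, model, n_sites, rng, ab.NUCLEOTIDE)
    return tree, model, aln


class TestEmpiricalMatrices:
    @pytest.mark.parametrize("name", ["lg", "jtt"])
    def test_bundled_matrices_load(self, name):
        R, freqs = pm.load_paml_matrix(name)
        assert R.shape == (20, 20)
        assert np.allclose(R, R.T)
        assert (R >= 0).all()
        assert freqs.sum() == pytest.approx(1.0)

    def test_lg_known_value(self):
        # A<->R exchangeability of the LG matrix
        R, _ = pm.load_paml_matrix("lg")
        i, j = ab.AA_STATES.index("A"), ab.AA_STATES.index("R")
        assert R[i, j] == pytest.approx(0.425093, abs=1e-6)

    def test_amino_acid_likelihood_runs(self, rng):
        R, freqs = pm.load_paml_matrix("lg")
        tree = random_tree_with_lengths("abcd", rng)
        tree.comp_vectors = [freqs]
        model = pm.SubstitutionModel(R=R, alpha=1.0, name="LG")
        aln = sd.simulate_matrix(tree, model, 30, rng, ab.AMINO_ACID)
        res = pm.tree_log_likelihood(aln, tree, model)
        assert np.isfinite(res.total)

    def test_paml_reader_rejects_truncated(self, tmp_path):
        bad = tmp_path / "bad.dat"
        bad.write_text("0.1 0.2 0.3\n")
        with pytest.raises(ValueError, match="PAML"):
            pm.load_paml_matrix(str(bad))


class TestEmpiricalComposition:
    def test_counts_exclude_ambiguity(self):
        aln = from_sequences([("a", "AANN--"), ("b", "CC??RR")],
                             alphabet=ab.NUCLEOTIDE)
        pi = pm.empirical_composition(aln, pseudocount=0.0)
        assert pi[0] == pytest.approx(0.5)
        assert pi[1] == pytest.approx(0.5)
        assert pi[2] == pi[3] == 0.0
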