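import numpy as np
import pytest

from comphet import alphabet as ab
from comphet import phylo_model as pm
from comphet import simdata as sd
from comphet import tree as tr
from comphet.alignment import from_sequences


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_nt_alignment():
    return from_sequences(
        [("A", "ACGTAC"), ("B", "ACGTAA"), ("C", "ACGAAC"), ("D", "TCGTAC")],
        alphabet=ab.NUCLEOTIDE)


@pytest.fixture
def codon_alignment():
    return from_sequences(
        [("t1", "ATGGCTAAA"), ("t2", "ATGGCAAAG"), ("t3", "ATGGCGAAA")],
        alphabet=ab.NUCLEOTIDE, codon_structure=True)


@pytest.fixture
def jc_model():
    return pm.SubstitutionModel(R=pm.gtr_matrix(), alpha=1.0,
                                n_rate_categories=1)


def random_tree_with_lengths(taxa, rng, lo=0.05, hi=0.5):
    tree = tr.random_topology(list(taxa), rng)
    for node in tree.postorder():
        if node is not tree.root:
            node.length = float(rng.uniform(lo, hi))
    return tree


@pytest.fixture
def cv1_tree(rng):
    tree = random_tree_with_lengths("abcd", rng)
    tree.comp_vectors = [np.array([0.1, 0.2, 0.3, 0.4])]
    return tree


def simulate_cv1(taxa, n_sites, seed, pi=None, alpha=1.0, ncat=4,
                 exch=None, lo=0.05, hi=0.5):
    """Convenience: random CV1 tree + simulated alignment."""
    rng = np.random.default_rng(seed)
    tree = random_tree_with_lengths(taxa, rng, lo, hi)
    tree.comp_vectors = [np.asarray(pi if pi is not None else np.full(4, 0.25))]
    model = pm.SubstitutionModel(
        R=pm.gtr_matrix(exch), alpha=alpha, n_rate_categories=ncat)
    aln = sd.simulate_matrix(tree, model, n_sites, rng, ab.NUCLEOTIDE)
    return tree, model, aln
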