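"""Synthetic-data generation.

Sequences are evolved along a tree with the same branch/composition
convention as the likelihood engine (the branch into node ``v`` uses
``v``'s composition).  Three modes are supported:

* ``nucleotide`` / ``amino_acid`` — plain CTMC with discrete-gamma rates;
* ``codon`` — codons evolve under the nucleotide process with synonymous
  single-nucleotide changes accelerated by a multiplier ``omega_syn >= 1``,
  producing third-position saturation without a full codon model.

Scenario builders cover the structures the analyses are meant to stress:
lineage-specific compositions, convergent compositions on non-sister
lineages ("attraction" scenarios), and per-gene taxon dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from . import alphabet as ab
from .alignment import Alignment, GeneTable
from .msa_io import _codon_table, make_gene_table
from .phylo_model import (SubstitutionModel, _p_matrices, _reversible_eig,
                          discretize_gamma, gtr_matrix)
from .tree import CV1, NDCH, Node, Tree

MODES = ("nucleotide", "amino_acid", "codon")


@dataclass
class SimulationScenario:
    """Everything needed to simulate a multi-gene alignment."""

    tree: Tree
    model: SubstitutionModel
    mode: str = "nucleotide"
    gene_lengths: list = field(default_factory=lambda: [1000])
    dropout: float = 0.0
    omega_syn: float = 1.0
    genetic_code: int = 1
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.omega_syn < 1.0:
            raise ValueError("omega_syn must be >= 1")
        if self.mode == "codon" and any(n % 3 for n in self.gene_lengths):
            raise ValueError("codon-mode gene lengths must be divisible by 3")
        for v in self.tree.comp_vectors:
            v = np.asarray(v, dtype=float)
            if np.any(v <= 0) or abs(v.sum() - 1.0) > 1e-8:
                raise ValueError("composition vectors must be simplex points")

    @property
    def alphabet(self) -> str:
        return ab.AMINO_ACID if self.mode == "amino_acid" else ab.NUCLEOTIDE


# ---------------------------------------------------------------------------
# per-site CTMC simulation
# ---------------------------------------------------------------------------

def _sample_states(parent_states, cats, P, rng):
    """Child states given parent states and per-site rate categories."""
    child = np.empty_like(parent_states)
    ncat = P.shape[0]
    for k in range(ncat):
        in_cat = cats == k
        if not in_cat.any():
            continue
        for s in np.unique(parent_states[in_cat]):
            mask = in_cat & (parent_states == s)
            child[mask] = rng.choice(P.shape[1], size=mask.sum(), p=P[k, s])
    return child


def simulate_matrix(tree: Tree, model: SubstitutionModel, n_columns: int,
                    rng, alphabet: str) -> Alignment:
    """Simulate one alignment block (no codon structure, no dropout)."""
    states = ab.states_for(alphabet)
    rates = discretize_gamma(model.alpha, model.n_rate_categories)
    cats = rng.integers(model.n_rate_categories, size=n_columns)
    comp = [np.asarray(v, dtype=float) for v in tree.comp_vectors]
    node_states = {id(tree.root): rng.choice(
        len(states), size=n_columns, p=comp[tree.root.comp])}
    eig_cache: dict = {}
    for node in tree.preorder():
        for child in node.children:
            pi = comp[child.comp]
            key = pi.tobytes()
            if key not in eig_cache:
                eig_cache[key] = _reversible_eig(model.R, pi)
            P = _p_matrices(eig_cache[key], float(child.length), rates)
            P = P / P.sum(axis=2, keepdims=True)
            node_states[id(child)] = _sample_states(
                node_states[id(node)], cats, P, rng)
    leaves = tree.leaves()
    matrix = np.empty((len(leaves), n_columns), dtype="U1")
    taxa = []
    for i, leaf in enumerate(leaves):
        taxa.append(leaf.name)
        matrix[i] = np.array(list(states))[node_states[id(leaf)]]
    return Alignment(taxa=taxa, matrix=matrix, alphabet=alphabet)


# ---------------------------------------------------------------------------
# codon mode
# ---------------------------------------------------------------------------

def _codon_generator(R_nt, pi_nt, omega_syn, code):
    """Rate matrix over sense codons: nucleotide GTR rates with synonymous
    changes multiplied by omega_syn; scaled to mean rate 1 at the root
    codon distribution implied by pi_nt."""
    sense = sorted(code.forward_table)
    index = {c: i for i, c in enumerate(sense)}
    n = len(sense)
    nt_idx = {b: i for i, b in enumerate(ab.NT_STATES)}
    Q = np.zeros((n, n))
    for c1 in sense:
        for pos in range(3):
            for b in ab.NT_STATES:
                if b == c1[pos]:
                    continue
                c2 = c1[:pos] + b + c1[pos + 1:]
                if c2 not in index:
                    continue
                rate = R_nt[nt_idx[c1[pos]], nt_idx[b]] * pi_nt[nt_idx[b]]
                if code.forward_table[c1] == code.forward_table[c2]:
                    rate *= omega_syn
                Q[index[c1], index[c2]] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    root_dist = np.array([
        pi_nt[nt_idx[c[0]]] * pi_nt[nt_idx[c[1]]] * pi_nt[nt_idx[c[2]]]
        for c in sense])
    root_dist /= root_dist.sum()
    beta = -np.dot(root_dist, np.diag(Q))
    return sense, Q / beta, root_dist


def simulate_codon_matrix(tree: Tree, model: SubstitutionModel, n_codons: int,
                          rng, omega_syn: float = 1.0,
                          genetic_code: int = 1) -> Alignment:
    """Simulate a codon-structured nucleotide alignment (sense codons only)."""
    code = _codon_table(genetic_code)
    rates = discretize_gamma(model.alpha, model.n_rate_categories)
    cats = rng.integers(model.n_rate_categories, size=n_codons)
    comp = [np.asarray(v, dtype=float) for v in tree.comp_vectors]
    gen_cache: dict = {}

    def generator(pi):
        key = pi.tobytes()
        if key not in gen_cache:
            gen_cache[key] = _codon_generator(model.R, pi, omega_syn, code)
        return gen_cache[key]

    sense, _, root_dist = generator(comp[tree.root.comp])
    node_states = {id(tree.root): rng.choice(
        len(sense), size=n_codons, p=root_dist)}
    p_cache: dict = {}
    for node in tree.preorder():
        for child in node.children:
            pi = comp[child.comp]
            _, Q, _ = generator(pi)
            key = (pi.tobytes(), float(child.length))
            if key not in p_cache:
                P = np.stack([expm(Q * (child.length * r)) for r in rates])
                np.clip(P, 0.0, None, out=P)
                P /= P.sum(axis=2, keepdims=True)
                p_cache[key] = P
            node_states[id(child)] = _sample_states(
                node_states[id(node)], cats, p_cache[key], rng)
    leaves = tree.leaves()
    matrix = np.empty((len(leaves), 3 * n_codons), dtype="U1")
    taxa = []
    sense_arr = np.array([list(c) for c in sense])
    for i, leaf in enumerate(leaves):
        taxa.append(leaf.name)
        matrix[i] = sense_arr[node_states[id(leaf)]].reshape(-1)
    return Alignment(taxa=taxa, matrix=matrix, alphabet=ab.NUCLEOTIDE,
                     codon_structure=True)


# ---------------------------------------------------------------------------
# scenario execution
# ---------------------------------------------------------------------------

def simulate_alignment(scenario: SimulationScenario) -> GeneTable:
    """Simulate every gene of a scenario and apply per-gene taxon dropout.

    Deterministic given ``scenario.seed``: one RNG stream drives site
    categories, state evolution and the dropout mask.
    """
    rng = np.random.default_rng(scenario.seed)
    named = []
    width = len(str(len(scenario.gene_lengths)))
    for g, length in enumerate(scenario.gene_lengths):
        if scenario.mode == "codon":
            aln = simulate_codon_matrix(
                scenario.tree, scenario.model, length // 3, rng,
                omega_syn=scenario.omega_syn,
                genetic_code=scenario.genetic_code)
        else:
            aln = simulate_matrix(scenario.tree, scenario.model, length, rng,
                                  scenario.alphabet)
        if scenario.dropout > 0:
            drop = rng.random(aln.n_taxa) < scenario.dropout
            aln.matrix[drop] = ab.MISSING
        named.append((f"g{g + 1:0{width}d}", aln))
    return make_gene_table(named)


# ---------------------------------------------------------------------------
# scenario builders
# ---------------------------------------------------------------------------

def _group_clade(names, stem_length, tip_length, comp) -> Node:
    """Balanced-ish clade over ``names`` with every node assigned ``comp``."""
    nodes = [Node(n, tip_length, comp) for n in names]
    while len(nodes) > 1:
        joined = Node(length=tip_length, comp=comp)
        joined.add_child(nodes.pop(0))
        joined.add_child(nodes.pop(0))
        nodes.append(joined)
    top = nodes[0]
    top.length = stem_length
    top.comp = comp
    return top


def make_attraction_scenario(n_taxa_per_group: int = 2,
                             bias_strength: float = 0.8,
                             seed: int = 0,
                             n_sites: int = 5000,
                             n_genes: int = 1,
                             dropout: float = 0.0,
                             mode: str = "nucleotide",
                             omega_syn: float = 1.0,
                             alpha: float = 1.0,
                             stem_biased: float = 0.30,
                             stem_plain: float = 0.12,
                             inner_length: float = 0.025,
                             tip_length: float = 0.08,
                             tip_biased: float = 0.08) -> SimulationScenario:
    """Compositional-attraction scenario on a known 4-group topology.

    True unrooted topology is (A,B)|(C,D); groups A and C — which are NOT
    sisters — share a biased composition (convex combination of the base
    composition and a biased target with weight ``bias_strength``) and sit
    on long stems, so homogeneous-composition analyses are pulled toward
    the wrong A+C split.  The true and attractive splits are recorded in
    ``scenario.meta``.
    """
    if not (0.0 <= bias_strength <= 1.0):
        raise ValueError("bias_strength must be in [0, 1]")
    groups = {
        g: [f"{g}{i + 1}" for i in range(n_taxa_per_group)]
        for g in ("A", "B", "C", "D")
    }
    pi_base = np.array([0.27, 0.23, 0.23, 0.27])
    pi_target = np.array([0.60, 0.02, 0.36, 0.02])
    pi_biased = (1.0 - bias_strength) * pi_base + bias_strength * pi_target
    comp_vectors = [pi_base, pi_biased / pi_biased.sum()]
    BIASED, PLAIN = 1, 0
    root = Node(comp=PLAIN)
    ab_node = Node(length=inner_length, comp=PLAIN)
    ab_node.add_child(_group_clade(groups["A"], stem_biased, tip_biased, BIASED))
    ab_node.add_child(_group_clade(groups["B"], stem_plain, tip_length, PLAIN))
    root.add_child(ab_node)
    root.add_child(_group_clade(groups["C"], stem_biased, tip_biased, BIASED))
    root.add_child(_group_clade(groups["D"], stem_plain, tip_length, PLAIN))
    tree = Tree(root, comp_mode=NDCH if bias_strength > 0 else CV1,
                comp_vectors=comp_vectors)
    all_names = sorted(n for names in groups.values() for n in names)
    ref = all_names[0]
    full = frozenset(all_names)

    def canonical(side):
        side = frozenset(side)
        return full - side if ref in side else side

    model = SubstitutionModel(R=gtr_matrix(), alpha=alpha)
    base = n_sites // n_genes
    if mode == "codon":
        base -= base % 3
    lengths = [base] * n_genes
    if mode != "codon":
        lengths[-1] += n_sites - sum(lengths)
    return SimulationScenario(
        tree=tree, model=model, mode=mode, gene_lengths=lengths,
        omega_syn=omega_syn, dropout=dropout, seed=seed,
        meta={
            "groups": groups,
            "true_split": canonical(groups["A"] + groups["B"]),
            "attraction_split": canonical(groups["A"] + groups["C"]),
        })
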