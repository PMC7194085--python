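"""Gene-genealogy interrogation: constraint-topology enumeration, a
constrained maximum-likelihood search, the multiscale-RELL AU test, and the
per-gene monophyly screen.

The ML search is a deliberately simple hill-climb: random within-group
resolutions of the constraint topology from ``n_starts`` starting trees,
branch lengths optimized one at a time by bounded scalar minimization, the
gamma shape by the same means, and NNI rearrangements restricted to edges
inside groups (so group monophyly can never be broken).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .alignment import Alignment
from .phylo_model import (LikelihoodEvaluator, SubstitutionModel,
                          empirical_composition)
from .tree import Node, Tree

AU_KEEP_THRESHOLD = 0.05


@dataclass
class ConstraintTopology:
    """A resolved topology over named groups plus the group -> taxa map."""

    tree: Tree  # leaves are group names
    groups: dict

    def __post_init__(self):
        leaf_names = sorted(self.tree.leaf_names())
        if leaf_names != sorted(self.groups):
            raise ValueError("constraint leaves must match group names")

    def label(self) -> str:
        return self.tree.newick(precision=3)


@dataclass
class SiteLogLikMatrix:
    """topologies x sites per-site log-likelihoods at the constrained optima."""

    labels: list
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.labels):
            raise ValueError("matrix must be (n_topologies, n_sites)")
        if not np.isfinite(self.matrix).all():
            raise ValueError("site log-likelihoods must be finite")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("topology\t" + "\t".join(
                f"site{i + 1}" for i in range(self.matrix.shape[1])) + "\n")
            for label, row in zip(self.labels, self.matrix):
                fh.write(label + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "SiteLogLikMatrix":
        labels, rows = [], []
        with open(path) as fh:
            next(fh)
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                labels.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        return cls(labels=labels, matrix=np.array(rows))


@dataclass
class AUResult:
    p_values: np.ndarray          # per topology
    bp: np.ndarray                # (n_topologies, n_scales)
    d: np.ndarray                 # fitted signed distance
    ccurv: np.ndarray             # fitted curvature
    degenerate: np.ndarray        # bool flags where p was clamped
    scales: np.ndarray
    n_reps: int
    seed: int


# ---------------------------------------------------------------------------
# constraint enumeration
# ---------------------------------------------------------------------------

def _tree_on_three(names) -> Tree:
    root = Node()
    for n in names:
        root.add_child(Node(n, 1.0))
    return Tree(root)


def enumerate_group_topologies(groups: dict) -> list:
    """All resolved unrooted topologies over the group leaves.

    Built by sequential edge addition, so the count is the double factorial
    (2g-5)!! for g groups (15 for five groups).
    """
    names = list(groups)
    if len(names) < 3:
        raise ValueError("need at least 3 groups")
    trees = [_tree_on_three(names[:3])]
    for name in names[3:]:
        nxt = []
        for tree in trees:
            edges = [n for n in tree.postorder() if n is not tree.root]
            for i in range(len(edges)):
                t2 = tree.copy()
                target = [n for n in t2.postorder() if n is not t2.root][i]
                parent = target.parent
                mid = Node(length=1.0)
                parent.children[parent.children.index(target)] = mid
                mid.parent = parent
                mid.add_child(target)
                mid.add_child(Node(name, 1.0))
                nxt.append(t2)
        trees = nxt
    return [ConstraintTopology(tree=t, groups=dict(groups)) for t in trees]


# ---------------------------------------------------------------------------
# constrained ML search
# ---------------------------------------------------------------------------

def _random_resolved_clade(taxa, rng, branch_length) -> Node:
    nodes = [Node(t, branch_length) for t in taxa]
    rng.shuffle(nodes)
    while len(nodes) > 1:
        a, b = nodes.pop(), nodes.pop()
        join = Node(length=branch_length)
        join.add_child(a)
        join.add_child(b)
        nodes.insert(int(rng.integers(len(nodes) + 1)), join)
    return nodes[0]


def _expand_constraint(constraint: ConstraintTopology, rng,
                       branch_length=0.1) -> tuple:
    """Full-taxon tree from a constraint: each group leaf becomes a randomly
    resolved clade.  Returns (tree, set of node-ids inside groups)."""
    tree = constraint.tree.copy()
    inside: set = set()
    for leaf in list(tree.leaves()):
        taxa = constraint.groups[leaf.name]
        clade = _random_resolved_clade(list(taxa), rng, branch_length)
        clade.length = branch_length
        parent = leaf.parent
        parent.children[parent.children.index(leaf)] = clade
        clade.parent = parent
        stack = list(clade.children)
        while stack:
            n = stack.pop()
            inside.add(id(n))
            stack.extend(n.children)
    for node in tree.postorder():
        if node is not tree.root:
            node.length = branch_length
    return tree, inside


def _optimize_branches_and_alpha(evaluator, tree, model, estimate_alpha=True,
                                 tol=1e-4, max_cycles=10,
                                 branch_bounds=(1e-8, 20.0),
                                 alpha_bounds=(0.02, 50.0)):
    """Coordinate ascent: Brent per branch, then the gamma shape; cycles
    until the log-likelihood gain drops below ``tol``."""
    best = evaluator.log_likelihood(tree, model).total
    for _ in range(max_cycles):
        start = best
        for node in tree.postorder():
            if node is tree.root:
                continue

            def neg(t, node=node):
                node.length = t
                return -evaluator.log_likelihood(tree, model).total

            res = minimize_scalar(neg, bounds=branch_bounds, method="bounded",
                                  options={"xatol": 1e-6})
            node.length = float(res.x)
            best = -res.fun
        if estimate_alpha:
            def neg_alpha(a):
                return -evaluator.log_likelihood(
                    tree, SubstitutionModel(
                        R=model.R, alpha=a,
                        n_rate_categories=model.n_rate_categories)).total

            res = minimize_scalar(neg_alpha, bounds=alpha_bounds,
                                  method="bounded", options={"xatol": 1e-4})
            model = SubstitutionModel(R=model.R, alpha=float(res.x),
                                      n_rate_categories=model.n_rate_categories)
            best = -res.fun
        if best - start < tol:
            break
    return best, model


def _within_group_nni(evaluator, tree, model, inside, best):
    """First-improvement NNI restricted to edges whose child node lies
    strictly inside a group clade."""
    improved = True
    while improved:
        improved = False
        for v in tree.postorder():
            if v.is_leaf or v.parent is None or id(v) not in inside:
                continue
            p = v.parent
            siblings = [s for s in p.children if s is not v and id(s) in inside]
            for a in list(v.children):
                for c in siblings:
                    ia, ic = v.children.index(a), p.children.index(c)
                    v.children[ia], p.children[ic] = c, a
                    a.parent, c.parent = p, v
                    cand = evaluator.log_likelihood(tree, model).total
                    if cand > best + 1e-9:
                        best = cand
                        improved = True
                    else:
                        v.children[ia], p.children[ic] = a, c
                        a.parent, c.parent = v, p
            if improved:
                break
    return best


def constrained_ml_search(gene_aln: Alignment, constraint: ConstraintTopology,
                          model: SubstitutionModel, n_starts: int = 20,
                          seed: int = 0, estimate_alpha: bool = True):
    """Best tree compatible with the constraint, by multi-start hill-climb.

    Returns ``(tree, log_likelihood, per_site_log_likelihood)``.  The tree
    uses CV1 with the gene's empirical composition (the +Fest convention).
    """
    group_taxa = [t for taxa in constraint.groups.values() for t in taxa]
    uncovered = set(gene_aln.taxa) - set(group_taxa)
    if uncovered:
        raise ValueError(f"taxa missing from every group: {sorted(uncovered)}")
    rng = np.random.default_rng(seed)
    evaluator = LikelihoodEvaluator(gene_aln)
    pi = empirical_composition(gene_aln)
    best_tuple = None
    for _ in range(max(n_starts, 1)):
        tree, inside = _expand_constraint(constraint, rng)
        tree.comp_vectors = [pi]
        for n in tree.postorder():
            n.comp = 0
        score, fitted = _optimize_branches_and_alpha(
            evaluator, tree, model, estimate_alpha=estimate_alpha)
        if inside:
            new = _within_group_nni(evaluator, tree, fitted, inside, score)
            if new > score:
                score, fitted = _optimize_branches_and_alpha(
                    evaluator, tree, fitted, estimate_alpha=estimate_alpha)
        if best_tuple is None or score > best_tuple[0]:
            best_tuple = (score, tree, fitted)
    score, tree, fitted = best_tuple
    per_site = evaluator.log_likelihood(tree, fitted, per_site=True).per_site
    return tree, score, per_site


# ---------------------------------------------------------------------------
# AU test (multiscale RELL bootstrap)
# ---------------------------------------------------------------------------

DEFAULT_SCALES = np.arange(0.5, 1.41, 0.1)


def au_test(m: SiteLogLikMatrix, scales=None, n_reps: int = 1000,
            seed: int = 0) -> AUResult:
    """Approximately-unbiased p-values from multiscale RELL resampling.

    For each scale ``r`` the site columns are resampled with replacement to
    ``round(r * n_sites)`` columns ``n_reps`` times; each topology is scored
    by its resampled log-likelihood sum and the per-topology best-count
    proportion BP(r) recorded.  Signed distance ``d`` and curvature ``c``
    are fitted by weighted least squares on probit-transformed BP against
    (sqrt(r), 1/sqrt(r)); ``p = 1 - Phi(d - c)``.  Topologies whose BP is
    degenerate (all 0 or all 1) get a clamped p with a flag.
    """
    if len(m.labels) < 2:
        raise ValueError("AU test needs at least 2 topologies")
    if n_reps < 100:
        raise ValueError("n_reps < 100 gives an unstable AU fit")
    scales = DEFAULT_SCALES if scales is None else np.asarray(scales, float)
    rng = np.random.default_rng(seed)
    T, n_sites = m.matrix.shape
    bp = np.zeros((T, len(scales)))
    site_mat = m.matrix.T  # (sites, T)
    for si, r in enumerate(scales):
        n_draw = max(int(round(r * n_sites)), 1)
        counts = rng.multinomial(n_draw, np.full(n_sites, 1.0 / n_sites),
                                 size=n_reps)
        scores = counts @ site_mat  # (reps, T)
        # ties share the best-count fractionally (order-invariant)
        is_best = scores == scores.max(axis=1, keepdims=True)
        bp[:, si] = (is_best / is_best.sum(axis=1, keepdims=True)).sum(axis=0) \
            / n_reps
    p = np.zeros(T)
    d = np.zeros(T)
    cc = np.zeros(T)
    degenerate = np.zeros(T, dtype=bool)
    for t in range(T):
        usable = (bp[t] > 0) & (bp[t] < 1)
        if usable.sum() < 2:
            degenerate[t] = True
            # clamp by the raw-scale proportion
            raw = bp[t, np.argmin(np.abs(scales - 1.0))]
            p[t] = 1.0 if raw >= 0.5 else 0.0
            continue
        r = scales[usable]
        bpv = bp[t, usable]
        z = norm.ppf(1.0 - bpv)
        X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
        w = n_reps * norm.pdf(z) ** 2 / (bpv * (1.0 - bpv))
        WX = X * w[:, None]
        beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        d[t], cc[t] = beta
        p[t] = float(1.0 - norm.cdf(d[t] - cc[t]))
    return AUResult(p_values=p, bp=bp, d=d, ccurv=cc, degenerate=degenerate,
                    scales=scales, n_reps=n_reps, seed=seed)


def monophyly_screen(au_results: dict, alpha: float = AU_KEEP_THRESHOLD) -> dict:
    """Per-gene keep/flag decision from AU p-values over all constraints.

    ``au_results`` maps gene name -> vector of per-topology p-values (or an
    :class:`AUResult`).  A gene is kept iff at least one constraint topology
    reaches ``p >= alpha`` (the 'equal or greater' rule); otherwise it is
    flagged aberrant.
    """
    decisions = {}
    for gene, res in au_results.items():
        pvals = res.p_values if isinstance(res, AUResult) else np.asarray(res)
        decisions[gene] = "keep" if np.max(pvals) >= alpha else "flag"
    return decisions
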