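"""Metropolis-Hastings sampler over topology, branch lengths, model
parameters and composition vectors, plus convergence diagnostics and
majority-rule consensus trees.

Move set (one randomly chosen proposal per iteration): NNI on internal
edges; single-branch-length multiplier; gamma-shape multiplier on the log
scale; Dirichlet proposals centered at the current value for
exchangeabilities and composition vectors; an NDCH node-reassignment move;
and a log-scale random walk on the NDCH2 concentration ``c``.  Composition
and exchangeability supports are truncated at a floor of 1e-6 per entry
(proposals below the floor are rejected), which keeps densities finite at
every reachable state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .alignment import Alignment
from .phylo_model import (LikelihoodEvaluator, SubstitutionModel,
                          empirical_composition)
from .tree import CV1, NDCH, NDCH2, Tree, build_from_splits, random_topology


@dataclass
class PriorConfig:
    """Priors for every sampled block.

    Branch lengths are iid exponential; the topology prior is uniform;
    exchangeabilities and CV1/NDCH compositions get flat Dirichlets; NDCH2
    node compositions are ``Dirichlet(c * empirical)`` with the
    concentration ``c`` itself sampled under an exponential hyperprior
    (mean ``ndch2_c_mean``) unless pinned via ``fix_c``.
    """

    branch_length_mean: float = 0.1
    alpha_max: float = 50.0
    ndch2_c_mean: float = 100.0
    fix_c: float | None = None
    comp_floor: float = 1e-6

    def __post_init__(self):
        if self.branch_length_mean <= 0 or self.alpha_max <= 0 \
                or self.ndch2_c_mean <= 0 or self.comp_floor <= 0:
            raise ValueError("prior hyperparameters must be strictly positive")


@dataclass
class ModelSpec:
    """What to sample: composition mode and which blocks are estimated."""

    comp_mode: str = CV1
    n_comp_vectors: int = 1           # used by NDCH
    fixed_R: np.ndarray | None = None  # e.g. an empirical amino-acid matrix
    n_rate_categories: int = 4
    estimate_alpha: bool = True
    estimate_exchangeabilities: bool = True
    fixed_topology: Tree | None = None

    def __post_init__(self):
        if self.comp_mode not in (CV1, NDCH, NDCH2):
            raise ValueError(f"unknown composition mode {self.comp_mode!r}")
        if self.comp_mode == NDCH and self.n_comp_vectors < 1:
            raise ValueError("NDCH needs at least one composition vector")
        if self.fixed_R is not None:
            self.estimate_exchangeabilities = False


@dataclass
class Sample:
    iteration: int
    tree: Tree
    splits: frozenset
    alpha: float
    exchangeabilities: np.ndarray
    c: float
    log_likelihood: float
    log_prior: float


@dataclass
class ChainTrace:
    taxa: list
    comp_mode: str
    samples: list
    sample_interval: int
    seed: int
    acceptance: dict  # move -> (accepted, proposed)
    model_spec: "ModelSpec | None" = None

    def post_burnin(self, burnin_fraction: float = 0.25) -> list:
        if not (0.0 <= burnin_fraction < 1.0):
            raise ValueError("burnin_fraction must be in [0, 1)")
        start = int(len(self.samples) * burnin_fraction)
        return self.samples[start:]

    def acceptance_rates(self) -> dict:
        return {move: (acc / prop if prop else 0.0)
                for move, (acc, prop) in self.acceptance.items()}

    def write_tsv(self, params_path, trees_path) -> None:
        """Human-readable export: scalar parameters as TSV plus a newick
        file with one sampled tree per line (lossy: per-node compositions
        stay in the JSON-lines format written by :meth:`save`)."""
        with open(params_path, "w") as fh:
            n_exch = len(self.samples[0].exchangeabilities) if self.samples \
                else 0
            cols = ["iteration", "log_likelihood", "log_prior", "alpha", "c"]
            cols += [f"exch{i + 1}" for i in range(n_exch)]
            fh.write("\t".join(cols) + "\n")
            for s in self.samples:
                row = [str(s.iteration), f"{s.log_likelihood:.6f}",
                       f"{s.log_prior:.6f}", f"{s.alpha:.6f}", f"{s.c:.6f}"]
                row += [f"{v:.6f}" for v in s.exchangeabilities]
                fh.write("\t".join(row) + "\n")
        with open(trees_path, "w") as fh:
            for s in self.samples:
                fh.write(s.tree.newick() + "\n")

    # -- persistence (JSON-lines: one header record, then one per sample) --
    def save(self, path) -> None:
        import json
        with open(path, "w") as fh:
            header = {
                "taxa": self.taxa, "comp_mode": self.comp_mode,
                "sample_interval": self.sample_interval, "seed": self.seed,
                "acceptance": {m: list(v) for m, v in self.acceptance.items()},
            }
            if self.model_spec is not None:
                ms = self.model_spec
                header["model_spec"] = {
                    "comp_mode": ms.comp_mode,
                    "n_comp_vectors": ms.n_comp_vectors,
                    "fixed_R": None if ms.fixed_R is None else ms.fixed_R.tolist(),
                    "n_rate_categories": ms.n_rate_categories,
                    "estimate_alpha": ms.estimate_alpha,
                    "estimate_exchangeabilities": ms.estimate_exchangeabilities,
                }
            fh.write(json.dumps(header) + "\n")
            for s in self.samples:
                rec = {
                    "iteration": s.iteration,
                    "newick": s.tree.newick(precision=10),
                    "comp_vectors": [np.asarray(v).tolist()
                                     for v in s.tree.comp_vectors],
                    "node_comp": [n.comp for n in s.tree.postorder()],
                    "alpha": s.alpha,
                    "exch": s.exchangeabilities.tolist(),
                    "c": s.c,
                    "log_likelihood": s.log_likelihood,
                    "log_prior": s.log_prior,
                }
                fh.write(json.dumps(rec) + "\n")

    @classmethod
    def load(cls, path) -> "ChainTrace":
        import json

        from .tree import parse_newick
        with open(path) as fh:
            header = json.loads(fh.readline())
            spec = None
            if "model_spec" in header:
                ms = header["model_spec"]
                spec = ModelSpec(
                    comp_mode=ms["comp_mode"],
                    n_comp_vectors=ms["n_comp_vectors"],
                    fixed_R=None if ms["fixed_R"] is None
                    else np.asarray(ms["fixed_R"]),
                    n_rate_categories=ms["n_rate_categories"],
                    estimate_alpha=ms["estimate_alpha"],
                    estimate_exchangeabilities=ms["estimate_exchangeabilities"])
            samples = []
            taxa_sorted = sorted(header["taxa"])
            for line in fh:
                rec = json.loads(line)
                tree = parse_newick(rec["newick"])
                tree.comp_mode = header["comp_mode"]
                tree.comp_vectors = [np.asarray(v) for v in rec["comp_vectors"]]
                for node, comp in zip(tree.postorder(), rec["node_comp"]):
                    node.comp = comp
                samples.append(Sample(
                    iteration=rec["iteration"], tree=tree,
                    splits=tree.splits(taxa_sorted),
                    alpha=rec["alpha"],
                    exchangeabilities=np.asarray(rec["exch"]),
                    c=rec["c"],
                    log_likelihood=rec["log_likelihood"],
                    log_prior=rec["log_prior"]))
        return cls(taxa=header["taxa"], comp_mode=header["comp_mode"],
                   samples=samples, sample_interval=header["sample_interval"],
                   seed=header["seed"],
                   acceptance={m: tuple(v)
                               for m, v in header["acceptance"].items()},
                   model_spec=spec)


@dataclass
class ConvergenceReport:
    asdsf: float | None = None
    marginal_likelihoods: list = field(default_factory=list)
    acceptance_rates: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    return float(gammaln(alpha.sum()) - gammaln(alpha).sum()
                 + ((alpha - 1.0) * np.log(x)).sum())


def ndch2_log_prior(compositions, empirical_comp, c: float) -> float:
    """Sum over nodes of log Dirichlet(pi_v | c * empirical)."""
    if c <= 0:
        raise ValueError("concentration c must be positive")
    emp = np.asarray(empirical_comp, dtype=float)
    total = 0.0
    for pi in compositions:
        pi = np.asarray(pi, dtype=float)
        if np.any(pi <= 0):
            warnings.warn("composition on the simplex boundary: prior is -inf",
                          stacklevel=2)
            return -np.inf
        total += _dirichlet_logpdf(pi, c * emp)
    return total


def _log_prior(tree: Tree, alpha: float, c: float, spec: ModelSpec,
               prior: PriorConfig, empirical: np.ndarray) -> float:
    lp = 0.0
    mean = prior.branch_length_mean
    for node in tree.postorder():
        if node is tree.root:
            continue
        lp += -node.length / mean - np.log(mean)
    if not (0 < alpha <= prior.alpha_max):
        return -np.inf
    if spec.comp_mode == NDCH2:
        lp += ndch2_log_prior(tree.comp_vectors, empirical, c)
        if prior.fix_c is None:
            lp += -c / prior.ndch2_c_mean - np.log(prior.ndch2_c_mean)
    else:
        # flat Dirichlet normalizers: density Gamma(S) on the S-simplex
        lp += len(tree.comp_vectors) * float(gammaln(len(empirical)))
    if spec.estimate_exchangeabilities:
        S = len(empirical)
        lp += float(gammaln(S * (S - 1) // 2))
    lp -= np.log(prior.alpha_max)  # uniform alpha density
    if spec.fixed_topology is None:
        n = sum(1 for nd in tree.postorder() if nd.is_leaf)
        lp -= _log_n_unrooted_topologies(n)
    return lp


def _log_n_unrooted_topologies(n_leaves: int) -> float:
    """log (2n-5)!! — the number of resolved unrooted labeled topologies."""
    if n_leaves < 4:
        return 0.0
    return float(np.sum(np.log(np.arange(3, 2 * n_leaves - 4, 2))))


# ---------------------------------------------------------------------------
# proposals
# ---------------------------------------------------------------------------

def _propose_nni(tree: Tree, rng) -> tuple | None:
    """In-place NNI; returns an undo closure, or None if no eligible edge."""
    candidates = [n for n in tree.postorder()
                  if not n.is_leaf and n.parent is not None
                  and len(n.parent.children) >= 2]
    candidates = [n for n in candidates
                  if len([s for s in n.parent.children if s is not n]) >= 1]
    if not candidates:
        return None
    v = candidates[rng.integers(len(candidates))]
    p = v.parent
    a = v.children[rng.integers(len(v.children))]
    siblings = [s for s in p.children if s is not v]
    c = siblings[rng.integers(len(siblings))]
    ia, ic = v.children.index(a), p.children.index(c)
    v.children[ia], p.children[ic] = c, a
    a.parent, c.parent = p, v

    def undo():
        v.children[ia], p.children[ic] = a, c
        a.parent, c.parent = v, p

    return undo


def _propose_spr(tree: Tree, rng):
    """Subtree prune-and-regraft with a uniform regraft split fraction.

    Only subtrees whose parent is not the root are pruned, so the root keeps
    its degree and the proposal stays within the trifurcating-root
    representation.  Returns ``(undo, log_hastings)`` or None; the Hastings
    term is the Jacobian |u0 / (p0 + c0)| of the deterministic
    merge-and-split of branch lengths (choice probabilities cancel).
    """
    candidates = [n for n in tree.postorder()
                  if n.parent is not None and n.parent.parent is not None]
    if not candidates:
        return None
    v = candidates[rng.integers(len(candidates))]
    p = v.parent
    grand = p.parent
    c = next(ch for ch in p.children if ch is not v)
    # detach: suture p away, c absorbs p's length
    p0, c0 = p.length, c.length
    grand.children[grand.children.index(p)] = c
    c.parent = grand
    c.length = p0 + c0
    # forbid targets inside the pruned subtree
    banned = set()
    stack = [v]
    while stack:
        n = stack.pop()
        banned.add(id(n))
        stack.extend(n.children)
    targets = [n for n in tree.postorder()
               if n.parent is not None and id(n) not in banned]
    u = targets[rng.integers(len(targets))]
    w = rng.random()
    u0 = u.length
    up = u.parent
    p.children = []
    up.children[up.children.index(u)] = p
    p.parent = up
    p.length = w * u0
    p.add_child(u)
    u.length = (1.0 - w) * u0
    p.add_child(v)  # v keeps its own length

    def undo():
        # reverse regraft
        up.children[up.children.index(p)] = u
        u.parent = up
        u.length = u0
        # reverse detach
        grand.children[grand.children.index(c)] = p
        p.parent = grand
        p.children = [c, v]
        c.parent = p
        p.length, c.length = p0, c0
        v.parent = p

    log_h = np.log(u0 / (p0 + c0))
    return undo, log_h


def _centered_dirichlet(x: np.ndarray, rng, concentration: float):
    """Propose x' ~ Dir(kappa*x); returns (x', log Hastings ratio)."""
    kappa = concentration
    alpha_fwd = kappa * x
    proposal = rng.dirichlet(alpha_fwd)
    if np.any(proposal <= 0):
        return None
    alpha_rev = kappa * proposal
    log_h = (_dirichlet_logpdf(x, alpha_rev)
             - _dirichlet_logpdf(proposal, alpha_fwd))
    return proposal, log_h


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def _initial_state(aln, spec: ModelSpec, prior: PriorConfig, rng):
    empirical = empirical_composition(aln)
    if spec.fixed_topology is not None:
        tree = spec.fixed_topology.copy()
    else:
        tree = random_topology(aln.taxa, rng,
                               branch_length=prior.branch_length_mean)
    tree.comp_mode = spec.comp_mode
    nodes = tree.postorder()
    if spec.comp_mode == CV1:
        tree.comp_vectors = [empirical.copy()]
        for n in nodes:
            n.comp = 0
    elif spec.comp_mode == NDCH:
        tree.comp_vectors = [empirical.copy()
                             for _ in range(spec.n_comp_vectors)]
        for n in nodes:
            n.comp = int(rng.integers(spec.n_comp_vectors))
    else:  # NDCH2
        tree.comp_vectors = [empirical.copy() for _ in nodes]
        for i, n in enumerate(nodes):
            n.comp = i
    return tree, empirical


def run_chain(aln: Alignment, model_spec: ModelSpec, prior: PriorConfig,
              n_iterations: int, sample_interval: int = 10, seed: int = 0,
              likelihood_off: bool = False,
              tuning: dict | None = None,
              anneal_fraction: float = 0.2,
              anneal_start_power: float = 0.3) -> ChainTrace:
    """Run one MCMC chain; deterministic given ``seed``.

    ``likelihood_off`` replaces the likelihood with a constant so the chain
    samples the prior (used for prior-moment validation).

    During the first ``anneal_fraction`` of the iterations the likelihood is
    raised to a power ramping from ``anneal_start_power`` to 1, which helps
    the chain escape local topology/composition basins; samples from that
    window are not from the exact posterior, so the burn-in discarded
    downstream must cover at least the annealing window (defaults do).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    tune = {"branch": 1.0, "alpha": 0.6, "c": 0.8,
            "kappa_comp": 300.0, "kappa_exch": 300.0}
    tune.update(tuning or {})

    tree, empirical = _initial_state(aln, model_spec, prior, rng)
    n_states = len(empirical)
    n_pairs = n_states * (n_states - 1) // 2
    exch = np.full(n_pairs, 1.0 / n_pairs)
    alpha = 1.0
    c = prior.fix_c if prior.fix_c is not None else prior.ndch2_c_mean

    def build_model():
        if model_spec.fixed_R is not None:
            R = model_spec.fixed_R
        else:
            R = np.zeros((n_states, n_states))
            iu = np.triu_indices(n_states, k=1)
            R[iu] = exch
            R = R + R.T
        return SubstitutionModel(R=R, alpha=alpha,
                                 n_rate_categories=model_spec.n_rate_categories)

    evaluator = None if likelihood_off else LikelihoodEvaluator(aln)

    def loglik():
        if evaluator is None:
            return 0.0
        return evaluator.log_likelihood(tree, build_model()).total

    def logprior():
        return _log_prior(tree, alpha, c, model_spec, prior, empirical)

    cur_ll, cur_lp = loglik(), logprior()
    if not np.isfinite(cur_ll):
        raise RuntimeError(
            "log-likelihood is not finite at the initial state; "
            "check the alignment and model specification")

    n_branches = max(len(tree.postorder()) - 1, 1)
    move_weights = {"branch": max(n_branches // 2, 2),
                    "comp": max(len(tree.comp_vectors) // 2, 2)}
    if model_spec.fixed_topology is None and len(aln.taxa) >= 4:
        move_weights["nni"] = 3
        move_weights["spr"] = 2
    if model_spec.estimate_alpha:
        move_weights["alpha"] = 1
    if model_spec.estimate_exchangeabilities:
        move_weights["exch"] = 1
    if model_spec.comp_mode == NDCH and model_spec.n_comp_vectors > 1:
        move_weights["reassign"] = 2
    if model_spec.comp_mode == NDCH2 and prior.fix_c is None:
        move_weights["c"] = 1
    moves = list(move_weights)
    move_p = np.array([move_weights[m] for m in moves], dtype=float)
    move_p /= move_p.sum()
    acceptance = {m: [0, 0] for m in moves}

    nonroot = lambda: [n for n in tree.postorder() if n is not tree.root]
    samples: list = []
    taxa_sorted = sorted(aln.taxa)

    anneal_until = int(anneal_fraction * n_iterations)

    for it in range(1, n_iterations + 1):
        if it <= anneal_until and anneal_until > 0:
            power = (anneal_start_power
                     + (1.0 - anneal_start_power) * it / anneal_until)
        else:
            power = 1.0
        move = moves[rng.choice(len(moves), p=move_p)]
        acceptance[move][1] += 1
        log_h = 0.0
        undo = None
        ok = True

        if move == "nni":
            undo = _propose_nni(tree, rng)
            ok = undo is not None
        elif move == "spr":
            res = _propose_spr(tree, rng)
            ok = res is not None
            if ok:
                undo, log_h = res
        elif move == "branch":
            node = nonroot()[rng.integers(len(nonroot()))]
            old = node.length
            node.length = old * np.exp(tune["branch"] * (rng.random() - 0.5))
            log_h = np.log(node.length / old)
            undo = lambda n=node, o=old: setattr(n, "length", o)
        elif move == "alpha":
            old = alpha
            alpha = old * np.exp(tune["alpha"] * (rng.random() - 0.5))
            log_h = np.log(alpha / old)

            def undo(o=old):
                nonlocal alpha
                alpha = o
        elif move == "exch":
            res = _centered_dirichlet(exch, rng, tune["kappa_exch"])
            ok = res is not None and np.all(res[0] >= prior.comp_floor)
            if ok:
                old = exch
                exch, log_h = res

                def undo(o=old):
                    nonlocal exch
                    exch = o
        elif move == "comp":
            idx = int(rng.integers(len(tree.comp_vectors)))
            res = _centered_dirichlet(tree.comp_vectors[idx], rng,
                                      tune["kappa_comp"])
            ok = res is not None and np.all(res[0] >= prior.comp_floor)
            if ok:
                old = tree.comp_vectors[idx]
                tree.comp_vectors[idx], log_h = res

                def undo(i=idx, o=old):
                    tree.comp_vectors[i] = o
        elif move == "reassign":
            node = tree.postorder()[rng.integers(len(tree.postorder()))]
            old = node.comp
            node.comp = int(rng.integers(len(tree.comp_vectors)))
            undo = lambda n=node, o=old: setattr(n, "comp", o)
        elif move == "c":
            old = c
            c = old * np.exp(tune["c"] * (rng.random() - 0.5))
            log_h = np.log(c / old)

            def undo(o=old):
                nonlocal c
                c = o

        if ok:
            new_lp = logprior()
            new_ll = loglik() if np.isfinite(new_lp) else -np.inf
            log_ratio = (power * new_ll + new_lp) - (power * cur_ll + cur_lp) \
                + log_h
            if np.log(rng.random()) < log_ratio:
                cur_ll, cur_lp = new_ll, new_lp
                acceptance[move][0] += 1
            elif undo is not None:
                undo()

        if it % sample_interval == 0:
            snap = tree.copy()
            samples.append(Sample(
                iteration=it, tree=snap, splits=snap.splits(taxa_sorted),
                alpha=alpha, exchangeabilities=exch.copy(), c=c,
                log_likelihood=cur_ll, log_prior=cur_lp))

    return ChainTrace(taxa=list(aln.taxa), comp_mode=model_spec.comp_mode,
                      samples=samples, sample_interval=sample_interval,
                      seed=seed,
                      acceptance={m: tuple(v) for m, v in acceptance.items()},
                      model_spec=model_spec)


# ---------------------------------------------------------------------------
# diagnostics and consensus
# ---------------------------------------------------------------------------

def split_frequencies(samples) -> dict:
    counts: dict = {}
    for s in samples:
        for split in s.splits:
            counts[split] = counts.get(split, 0) + 1
    n = max(len(samples), 1)
    return {split: cnt / n for split, cnt in counts.items()}


def asdsf(trace_a: ChainTrace, trace_b: ChainTrace,
          burnin_fraction: float = 0.25, min_freq: float = 0.1) -> float:
    """Average standard deviation of split frequencies between two runs.

    Splits with support >= ``min_freq`` in at least one run enter the
    average; with no qualifying split the value is defined as 0.
    """
    if sorted(trace_a.taxa) != sorted(trace_b.taxa):
        raise ValueError("traces are over different taxon sets")
    fa = split_frequencies(trace_a.post_burnin(burnin_fraction))
    fb = split_frequencies(trace_b.post_burnin(burnin_fraction))
    qualifying = {s for s, f in fa.items() if f >= min_freq}
    qualifying |= {s for s, f in fb.items() if f >= min_freq}
    if not qualifying:
        warnings.warn("no splits above min_freq; ASDSF defined as 0",
                      stacklevel=2)
        return 0.0
    sds = [np.std([fa.get(s, 0.0), fb.get(s, 0.0)], ddof=1)
           for s in qualifying]
    return float(np.mean(sds))


def majority_rule_consensus(traces, burnin_fraction: float = 0.25,
                            cutoff: float = 0.5):
    """Majority-rule consensus of pooled post-burn-in samples.

    Returns ``(tree, support)`` where support maps each retained canonical
    split to its pooled frequency (the posterior probability).  Splits at
    exactly the cutoff are excluded (strict ``>`` rule).
    """
    pooled = []
    for t in traces:
        pooled.extend(t.post_burnin(burnin_fraction))
    if not pooled:
        raise ValueError("no post-burn-in samples")
    freqs = split_frequencies(pooled)
    majority = {s: f for s, f in freqs.items() if f > cutoff}
    taxa = sorted(traces[0].taxa)
    return build_from_splits(taxa, majority)


def check_convergence(report: ConvergenceReport, asdsf_max: float = 0.01,
                      marglik_max_diff: float = 10.0):
    """Convergence rule: ASDSF below threshold AND per-run marginal
    likelihoods within ``marglik_max_diff`` (natural-log units)."""
    reasons = []
    if report.asdsf is not None and not (report.asdsf < asdsf_max):
        reasons.append(f"ASDSF {report.asdsf:.4f} >= {asdsf_max}")
    ml = report.marginal_likelihoods
    if len(ml) >= 2:
        spread = max(ml) - min(ml)
        if not (spread < marglik_max_diff):
            reasons.append(
                f"marginal likelihood spread {spread:.2f} >= {marglik_max_diff}")
    return (not reasons), reasons
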