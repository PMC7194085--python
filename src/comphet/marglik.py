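"""Marginal-likelihood estimation from posterior samples.

The estimator is a stabilized harmonic-mean (Gelfand-Dey) scheme: a
*working prior* ``g`` is fitted to the post-burn-in draws (independent
parametric surrogates per parameter block — Dirichlet for simplex blocks,
gamma for positive scalars), and

    1/Z = E_posterior[ g(theta) / (L(theta) pi(theta)) ]

is averaged over the draws.  Topology is handled by conditioning on the
modal sampled topology and dividing by its posterior mass.  The
Monte-Carlo standard error comes from a nonparametric bootstrap over
draws.  The method tag records this choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .mcmc import ChainTrace, _dirichlet_logpdf
from .tree import NDCH2

METHOD_TAG = "working-prior-harmonic-mean"


@dataclass
class MarglikResult:
    log_marginal: float
    se: float
    method: str
    n_draws: int

    def __post_init__(self):
        if not np.isfinite(self.log_marginal):
            raise ValueError("marginal-likelihood estimate is not finite")
        if self.se < 0:
            raise ValueError("standard error must be nonnegative")


# ---------------------------------------------------------------------------
# working-prior surrogates
# ---------------------------------------------------------------------------

def fit_dirichlet(draws: np.ndarray) -> np.ndarray:
    """Moment-matched Dirichlet concentration for (n_draws, S) simplex draws."""
    m = draws.mean(axis=0)
    v = draws.var(axis=0)
    if np.any(v <= 0):
        raise ValueError("degenerate simplex block (zero variance)")
    s = np.mean(m * (1.0 - m) / v - 1.0)
    s = max(s, 1e-3)
    return np.maximum(s * m, 1e-3)


def fit_gamma(draws: np.ndarray) -> tuple:
    """Moment-matched (shape, scale) for positive scalar draws."""
    m, v = draws.mean(), draws.var()
    if v <= 0:
        raise ValueError("degenerate scalar block (zero variance)")
    return m * m / v, v / m


def _gamma_logpdf(x, shape, scale):
    return ((shape - 1.0) * np.log(x) - x / scale
            - gammaln(shape) - shape * np.log(scale))


def gelfand_dey_log_marginal(log_likelihood, log_prior, log_working) -> float:
    """log Z from draws via the working-prior harmonic-mean identity."""
    ll = np.asarray(log_likelihood, dtype=float)
    lp = np.asarray(log_prior, dtype=float)
    lg = np.asarray(log_working, dtype=float)
    if not (len(ll) == len(lp) == len(lg)) or len(ll) == 0:
        raise ValueError("mismatched or empty draw vectors")
    terms = lg - ll - lp
    return float(np.log(len(ll)) - logsumexp(terms))


# ---------------------------------------------------------------------------
# trace-based estimation
# ---------------------------------------------------------------------------

def _branch_key_lengths(sample):
    """Branch lengths keyed by the leaf set below each node (stable across
    draws that share a topology)."""
    tree = sample.tree
    below: dict = {}
    out = []
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(
                *(below[id(c)] for c in node.children))
        if node is not tree.root:
            out.append((below[id(node)], node.length))
    out.sort(key=lambda kv: (len(kv[0]), sorted(kv[0])))
    return np.array([v for _, v in out])


def _comp_blocks(sample) -> np.ndarray:
    """Per-node composition vectors ordered by a canonical clade key, so the
    working prior matches nodes consistently across same-topology draws."""
    tree = sample.tree
    below: dict = {}
    keyed = []
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(
                *(below[id(c)] for c in node.children))
        keyed.append((below[id(node)],
                      np.asarray(tree.comp_vectors[node.comp], dtype=float)))
    keyed.sort(key=lambda kv: (len(kv[0]), sorted(kv[0])))
    return np.stack([v for _, v in keyed])


def estimate_marginal_likelihood(trace: ChainTrace,
                                 burnin_fraction: float = 0.25,
                                 seed: int = 0,
                                 n_bootstrap: int = 200) -> MarglikResult:
    """Marginal likelihood of the sampled model from one chain trace.

    Conditions on the modal topology (its posterior mass re-inflates the
    estimate), fits the working prior per parameter block, and reports a
    bootstrap standard error.  Deterministic given ``seed``.
    """
    draws = trace.post_burnin(burnin_fraction)
    if len(draws) < 10:
        raise ValueError("need at least 10 post-burn-in draws")
    topologies = [s.splits for s in draws]
    unique, counts = np.unique(
        np.array([hash(t) for t in topologies]), return_counts=True)
    modal_hash = unique[np.argmax(counts)]
    modal_idx = np.array([hash(t) == modal_hash for t in topologies])
    modal = [s for s, keep in zip(draws, modal_idx) if keep]
    p_modal = len(modal) / len(draws)

    # parameter blocks on the modal-topology draws
    blocks = []
    branch = np.stack([_branch_key_lengths(s) for s in modal])
    for j in range(branch.shape[1]):
        blocks.append(("gamma", branch[:, j]))
    alphas = np.array([s.alpha for s in modal])
    if alphas.var() > 0:
        blocks.append(("gamma", alphas))
    exch = np.stack([s.exchangeabilities for s in modal])
    if exch.var(axis=0).max() > 0:
        blocks.append(("dirichlet", exch))
    if trace.comp_mode == NDCH2:
        comps = np.stack([_comp_blocks(s) for s in modal])  # (n, nodes, S)
    else:
        comps = np.stack([
            np.stack([np.asarray(v, dtype=float) for v in s.tree.comp_vectors])
            for s in modal])
    n_comp = comps.shape[1]
    for j in range(n_comp):
        blocks.append(("dirichlet", comps[:, j, :]))
    cs = np.array([s.c for s in modal])
    if trace.comp_mode == NDCH2 and cs.var() > 0:
        blocks.append(("gamma", cs))

    log_g = np.zeros(len(modal))
    for kind, data in blocks:
        if kind == "gamma":
            shape, scale = fit_gamma(data)
            log_g += _gamma_logpdf(data, shape, scale)
        else:
            conc = fit_dirichlet(data)
            log_g += np.array([_dirichlet_logpdf(x, conc) for x in data])

    ll = np.array([s.log_likelihood for s in modal])
    lp = np.array([s.log_prior for s in modal])
    terms = log_g - ll - lp
    logZ = float(np.log(len(modal)) - logsumexp(terms) - np.log(p_modal))

    rng = np.random.default_rng(seed)
    n_all = len(draws)
    boots = []
    for _ in range(n_bootstrap):
        pick = rng.integers(n_all, size=n_all)
        in_modal = modal_idx[pick]
        if not in_modal.any():
            continue
        p_b = in_modal.mean()
        # map picked draw indices to positions within the modal subset
        modal_positions = np.cumsum(modal_idx) - 1
        sel = modal_positions[pick[in_modal]]
        boots.append(np.log(len(sel)) - logsumexp(terms[sel]) - np.log(p_b))
    se = float(np.std(boots, ddof=1)) if len(boots) > 1 else 0.0
    return MarglikResult(log_marginal=logZ, se=se, method=METHOD_TAG,
                         n_draws=len(draws))
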