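"""Likelihood engine: GTR-style rate matrices, discrete-gamma rates, and
Felsenstein pruning with per-node composition vectors (CV1 / NDCH / NDCH2).

Conventions
-----------
* The branch leading into node ``v`` uses the rate matrix built from ``v``'s
  composition vector; the root's vector weights the root partials.
* Every branch's Q is rescaled to one expected substitution per unit branch
  length under its own composition, so branch lengths keep their usual
  interpretation across composition regimes.
* Gamma rate categories are equiprobable category means (k=4 by default),
  renormalized to mean exactly 1.
* Ambiguity, gap and missing symbols contribute leaf partials of 1 over
  their expansion sets; degenerate-recoded data therefore need no special
  alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import special
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from . import alphabet as ab
from .alignment import Alignment
from .tree import NDCH2, Tree


@dataclass
class SubstitutionModel:
    """Symmetric exchangeabilities + gamma shape.

    ``R`` is an S x S symmetric nonnegative matrix with zero diagonal
    (S = 4 for nucleotides, 20 for amino acids); one entry is fixed by the
    normalization applied in :func:`build_rate_matrix`, so only relative
    values matter.
    """

    R: np.ndarray
    alpha: float = 1.0
    n_rate_categories: int = 4
    name: str = "GTR"

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 2 or self.R.shape[0] != self.R.shape[1]:
            raise ValueError("R must be square")
        if not np.allclose(self.R, self.R.T):
            raise ValueError("R must be symmetric")
        if np.any(np.diag(self.R) != 0):
            raise ValueError("R must have zero diagonal")
        if np.any(self.R < 0):
            raise ValueError("R entries must be nonnegative")
        if not (self.alpha > 0):
            raise ValueError("gamma shape must be positive")
        if self.n_rate_categories < 1:
            raise ValueError("need at least one rate category")

    @property
    def n_states(self) -> int:
        return self.R.shape[0]


def gtr_matrix(rates=None) -> np.ndarray:
    """4x4 symmetric exchangeability matrix from the 6 upper-triangle rates
    (order AC, AG, AT, CG, CT, GT).  Defaults to all-equal (JC-like)."""
    if rates is None:
        rates = np.ones(6)
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (6,):
        raise ValueError("expected 6 exchangeability rates")
    R = np.zeros((4, 4))
    iu = np.triu_indices(4, k=1)
    R[iu] = rates
    return R + R.T


def upper_triangle(R: np.ndarray) -> np.ndarray:
    return R[np.triu_indices(R.shape[0], k=1)]


def build_rate_matrix(R: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Q with Q_ij = R_ij * pi_j, rows summing to zero, scaled so the
    expected substitution rate at stationarity is 1."""
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0):
        raise ValueError("composition entries must be positive")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("composition must sum to 1")
    Q = np.asarray(R, dtype=float) * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    beta = -np.dot(pi, np.diag(Q))
    if beta <= 0:
        raise ValueError("degenerate rate matrix (no substitutions)")
    return Q / beta


def transition_probabilities(Q: np.ndarray, t: float, rate: float = 1.0) -> np.ndarray:
    """P = exp(Q * t * rate) via the matrix exponential."""
    if not np.isfinite(t) or t < 0:
        raise ValueError(f"invalid branch length {t!r}")
    if rate <= 0:
        raise ValueError("rate must be positive")
    return expm(Q * (t * rate))


def discretize_gamma(alpha: float, k: int = 4) -> np.ndarray:
    """k equiprobable category rates (category means), renormalized to mean 1."""
    if not (alpha > 0):
        raise ValueError("alpha must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    cached = _GAMMA_CACHE.get((alpha, k))
    if cached is not None:
        return cached
    if k == 1:
        return np.ones(1)
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], bounds, [np.inf]])
    # mean of Gamma(alpha, rate=alpha) over [b0,b1] times k, via the
    # regularized incomplete gamma with shape alpha+1
    upper = np.where(np.isinf(edges[1:]), 1.0,
                     special.gammainc(alpha + 1.0, alpha * edges[1:]))
    lower = special.gammainc(alpha + 1.0, alpha * edges[:-1])
    rates = k * (upper - lower)
    rates = rates / rates.mean()
    if len(_GAMMA_CACHE) > 4096:
        _GAMMA_CACHE.clear()
    _GAMMA_CACHE[(alpha, k)] = rates
    return rates


_GAMMA_CACHE: dict = {}


@dataclass
class SiteLikelihoodResult:
    total: float
    per_site: np.ndarray | None = None


# ---------------------------------------------------------------------------
# pruning engine
# ---------------------------------------------------------------------------

def _reversible_eig(R: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of the scaled reversible Q for fast P(t)."""
    Q = build_rate_matrix(R, pi)
    sq = np.sqrt(pi)
    A = (Q * sq[:, None]) / sq[None, :]
    w, U = np.linalg.eigh((A + A.T) / 2.0)
    left = U / sq[:, None]       # D^{-1/2} U
    right = U.T * sq[None, :]    # U^T D^{1/2}
    return w, left, right


def _p_matrices(eig, t: float, rates: np.ndarray) -> np.ndarray:
    """(ncat, S, S) transition matrices from a cached eigendecomposition."""
    w, left, right = eig
    ew = np.exp(rates[:, None] * (w * t)[None, :])   # (ncat, S)
    P = np.einsum("ij,kj,jl->kil", left, ew, right)
    np.maximum(P, 0.0, out=P)
    return P


class LikelihoodEvaluator:
    """Pruning likelihood over unique site patterns for one alignment.

    The evaluator pre-compresses the alignment and caches per-composition
    eigendecompositions, so repeated calls during MCMC pay only for the
    pruning pass.
    """

    _SCALE_FLOOR = 1e-80
    _SCALE_EVERY = 8  # children processed between underflow checks

    def __init__(self, aln: Alignment):
        self.aln = aln
        self.n_states = len(ab.states_for(aln.alphabet))
        cols = aln.matrix.T
        patterns, inverse, counts = np.unique(
            cols, axis=0, return_inverse=True, return_counts=True)
        self.patterns = patterns              # (npat, ntaxa)
        self.pattern_index = inverse.ravel()  # site -> pattern
        self.weights = counts.astype(float)
        self.n_patterns = patterns.shape[0]
        lookup = ab.partial_lookup(aln.alphabet)
        self.leaf_partials = {}
        for i, taxon in enumerate(aln.taxa):
            lp = np.empty((self.n_patterns, self.n_states))
            for p in range(self.n_patterns):
                lp[p] = lookup[patterns[p, i]]
            self.leaf_partials[taxon] = lp
        self._eig_cache: dict = {}

    def _eig_for(self, R: np.ndarray, pi: np.ndarray):
        key = (R.tobytes(), pi.tobytes())
        eig = self._eig_cache.get(key)
        if eig is None:
            if len(self._eig_cache) > 4096:
                self._eig_cache.clear()
            eig = self._eig_cache[key] = _reversible_eig(R, pi)
        return eig

    def log_likelihood(self, tree: Tree, model: SubstitutionModel,
                       per_site: bool = False) -> SiteLikelihoodResult:
        if model.n_states != self.n_states:
            raise ValueError("model state count does not match alignment alphabet")
        comp_vectors = tree.comp_vectors
        if not comp_vectors:
            raise ValueError("tree carries no composition vectors")
        rates = discretize_gamma(model.alpha, model.n_rate_categories)
        ncat = model.n_rate_categories
        npat, S = self.n_patterns, self.n_states
        logscale = np.zeros(npat)
        partial: dict = {}
        since_scaled = 0
        for node in tree.postorder():
            if node.is_leaf:
                try:
                    lp = self.leaf_partials[node.name]
                except KeyError:
                    raise ValueError(f"leaf {node.name!r} not in alignment") from None
                partial[id(node)] = np.broadcast_to(lp, (ncat, npat, S))
                continue
            acc = np.ones((ncat, npat, S))
            for child in node.children:
                if child.comp >= len(comp_vectors):
                    raise ValueError(
                        f"node has unattached composition index {child.comp} "
                        f"(mode {tree.comp_mode})")
                pi = np.asarray(comp_vectors[child.comp], dtype=float)
                eig = self._eig_for(model.R, pi)
                P = _p_matrices(eig, float(child.length), rates)
                child_part = partial.pop(id(child))
                acc *= child_part @ P.transpose(0, 2, 1)
            # rescaling is only needed on deep trees; check periodically
            since_scaled += len(node.children)
            if since_scaled >= self._SCALE_EVERY:
                since_scaled = 0
                m = acc.max(axis=(0, 2))
                low = (m > 0) & (m < self._SCALE_FLOOR)
                if low.any():
                    acc[:, low, :] /= m[low][None, :, None]
                    logscale[low] += np.log(m[low])
            partial[id(node)] = acc
        if tree.root.comp >= len(comp_vectors):
            raise ValueError("root has no attached composition vector")
        pi_root = np.asarray(comp_vectors[tree.root.comp], dtype=float)
        root_part = partial[id(tree.root)]
        site_l = (root_part @ pi_root).mean(axis=0)   # (npat,)
        with np.errstate(divide="ignore"):
            pattern_lnl = np.log(site_l) + logscale
        total = float(np.dot(self.weights, pattern_lnl))
        result = SiteLikelihoodResult(total=total)
        if per_site:
            result.per_site = pattern_lnl[self.pattern_index]
        return result


def tree_log_likelihood(aln: Alignment, tree: Tree, model: SubstitutionModel,
                        per_site: bool = False) -> SiteLikelihoodResult:
    """One-shot pruning likelihood (see :class:`LikelihoodEvaluator`)."""
    _check_attachments(tree)
    return LikelihoodEvaluator(aln).log_likelihood(tree, model, per_site=per_site)


def _check_attachments(tree: Tree) -> None:
    n = len(tree.comp_vectors)
    for node in tree.postorder():
        if node.comp is None or node.comp >= n:
            raise ValueError(
                f"node without attached composition (mode {tree.comp_mode})")
        pi = np.asarray(tree.comp_vectors[node.comp], dtype=float)
        if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-6:
            raise ValueError("composition vector must be a positive simplex point")
    if tree.comp_mode == NDCH2:
        seen = [node.comp for node in tree.postorder()]
        if len(set(seen)) != len(seen):
            raise ValueError("NDCH2 requires a distinct vector per node")


# ---------------------------------------------------------------------------
# empirical amino-acid matrices (PAML .dat format)
# ---------------------------------------------------------------------------

#: PAML files list states in this order (differs from our internal order).
PAML_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"


def load_paml_matrix(source) -> tuple:
    """Read a PAML-format empirical amino-acid rate file.

    Returns ``(R, freqs)`` where ``R`` is the 20x20 symmetric exchangeability
    matrix and ``freqs`` the bundled equilibrium frequencies, both in the
    package state order.  ``source`` is a path or a name of a bundled matrix
    (``lg``, ``jtt``).
    """
    if isinstance(source, str) and "/" not in source and not source.endswith(".dat"):
        ref = resources.files("comphet.data") / f"{source.lower()}.dat"
        text = ref.read_text()
    else:
        with open(source) as fh:
            text = fh.read()
    numbers = []
    for line in text.splitlines():
        line = line.split("#")[0]
        for tok in line.split():
            try:
                numbers.append(float(tok))
            except ValueError:
                break  # comment text after the numbers
    need = 190 + 20
    if len(numbers) < need:
        raise ValueError("not a PAML rate file: expected 190 rates + 20 frequencies")
    rates, freqs = numbers[:190], np.array(numbers[190:210])
    R = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            R[i, j] = R[j, i] = rates[k]
            k += 1
    if np.any(R < 0) or np.any(freqs <= 0):
        raise ValueError("PAML matrix contains negative rates or frequencies")
    freqs = freqs / freqs.sum()
    # PAML order happens to match the internal order; keep the permutation
    # explicit in case either changes.
    perm = [PAML_AA_ORDER.index(a) for a in ab.AA_STATES]
    R = R[np.ix_(perm, perm)]
    freqs = freqs[perm]
    return R, freqs


def empirical_composition(aln: Alignment, pseudocount: float = 0.5) -> np.ndarray:
    """Empirical state frequencies; ambiguity/gap/missing symbols excluded."""
    states = ab.states_for(aln.alphabet)
    counts = np.array([(aln.matrix == s).sum() for s in states], dtype=float)
    counts += pseudocount
    return counts / counts.sum()
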