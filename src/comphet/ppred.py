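"""X² composition-homogeneity statistic and posterior predictive test.

The tail-area probability is the fraction of posterior-predictive
replicates whose X² is greater than or equal to the observed value (ties
count toward the tail, making the test conservative); values at or above
0.05 are read as "the composition model fits".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import alphabet as ab
from .alignment import Alignment
from .mcmc import ChainTrace
from .phylo_model import SubstitutionModel
from .simdata import simulate_matrix

FIT_THRESHOLD = 0.05


@dataclass
class X2Result:
    observed: float
    simulated: np.ndarray
    p_value: float
    n_draws: int
    seed: int

    @property
    def model_fits(self) -> bool:
        return self.p_value >= FIT_THRESHOLD


def _state_counts(aln: Alignment) -> np.ndarray:
    """Per-taxon counts of unambiguous states; everything else is excluded."""
    states = ab.states_for(aln.alphabet)
    counts = np.zeros((aln.n_taxa, len(states)))
    for j, s in enumerate(states):
        counts[:, j] = (aln.matrix == s).sum(axis=1)
    return counts


def x2_statistic(aln: Alignment) -> float:
    """Chi-square statistic of composition homogeneity across taxa.

    ``X² = sum_t sum_s (O_ts - E_ts)² / E_ts`` with expected counts
    ``E_ts = (taxon t's counted sites) * (global state frequency)``.
    Gaps, missing symbols and ambiguity codes do not enter the counts; a
    state absent from the whole alignment is dropped with a warning.
    """
    if aln.n_taxa < 2:
        raise ValueError("X² needs at least 2 taxa")
    O = _state_counts(aln)
    totals = O.sum(axis=1, keepdims=True)
    global_counts = O.sum(axis=0)
    if (global_counts == 0).any():
        warnings.warn("states with zero global frequency dropped from X²",
                      stacklevel=2)
        keep = global_counts > 0
        O = O[:, keep]
        global_counts = global_counts[keep]
    freq = global_counts / global_counts.sum()
    E = totals * freq[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(E > 0, (O - E) ** 2 / np.where(E > 0, E, 1.0), 0.0)
    return float(terms.sum())


def _apply_observed_mask(replicate: Alignment, observed: Alignment) -> Alignment:
    """Copy every non-counted observed cell (gap/missing/ambiguity) into the
    replicate so both sides of the comparison exclude the same cells."""
    states = set(ab.states_for(observed.alphabet))
    obs = observed.matrix
    masked = ~np.isin(obs, list(states))
    rep = replicate.matrix.copy()
    rep[masked] = obs[masked]
    return Alignment(taxa=list(observed.taxa), matrix=rep,
                     alphabet=observed.alphabet,
                     gene_bounds=list(observed.gene_bounds))


def posterior_predictive_pvalue(trace: ChainTrace, aln: Alignment,
                                n_draws: int = 100, seed: int = 0,
                                burnin_fraction: float = 0.25) -> X2Result:
    """Posterior predictive p-value for the X² homogeneity statistic.

    For each of ``n_draws`` evenly spaced post-burn-in samples a replicate
    alignment of identical dimensions is simulated under the drawn tree and
    parameters, the observed missing/ambiguity mask is re-applied, and X²
    is computed; ``p`` is the fraction of replicates with X² >= observed.
    """
    samples = trace.post_burnin(burnin_fraction)
    if n_draws > len(samples):
        raise ValueError(
            f"n_draws={n_draws} exceeds {len(samples)} post-burn-in samples")
    if sorted(trace.taxa) != sorted(aln.taxa):
        raise ValueError("trace and alignment taxa differ")
    rng = np.random.default_rng(seed)
    observed = x2_statistic(aln)
    picks = np.linspace(0, len(samples) - 1, n_draws).round().astype(int)
    spec = trace.model_spec
    ncat = spec.n_rate_categories if spec is not None else 4
    simulated = np.empty(n_draws)
    for i, idx in enumerate(picks):
        s = samples[idx]
        if spec is not None and spec.fixed_R is not None:
            R = spec.fixed_R
        else:
            S = len(s.tree.comp_vectors[0])
            R = np.zeros((S, S))
            iu = np.triu_indices(S, k=1)
            R[iu] = s.exchangeabilities
            R = R + R.T
        model = SubstitutionModel(R=R, alpha=s.alpha, n_rate_categories=ncat)
        replicate = simulate_matrix(s.tree, model, aln.n_columns, rng,
                                    aln.alphabet)
        # align replicate rows to the observed taxon order
        order = [replicate.taxa.index(t) for t in aln.taxa]
        replicate = Alignment(taxa=list(aln.taxa),
                              matrix=replicate.matrix[order],
                              alphabet=aln.alphabet)
        replicate = _apply_observed_mask(replicate, aln)
        simulated[i] = x2_statistic(replicate)
    p = float((simulated >= observed).sum() / n_draws)
    return X2Result(observed=observed, simulated=simulated, p_value=p,
                    n_draws=n_draws, seed=seed)
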