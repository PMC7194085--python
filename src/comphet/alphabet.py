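"""Character-state alphabets and ambiguity expansion.

Nucleotide states are ordered A, C, G, T; amino acids follow the common
one-letter ordering A R N D C Q E G H I L K M F P S T W Y V.  Ambiguity
symbols (IUPAC codes, ``X``, gap ``-`` and missing ``?``) expand to sets of
base states; the likelihood engine turns these into leaf partials of ones
over the expansion set, so ambiguous and missing characters are handled
uniformly.
"""

from __future__ import annotations

import numpy as np

NUCLEOTIDE = "nucleotide"
DEGENERATE_NUCLEOTIDE = "degenerate_nucleotide"
AMINO_ACID = "amino_acid"

ALPHABETS = (NUCLEOTIDE, DEGENERATE_NUCLEOTIDE, AMINO_ACID)

GAP = "-"
MISSING = "?"

NT_STATES = "ACGT"

#: IUPAC nucleotide codes mapped to their expansion over the 4 base states.
IUPAC_NT: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    GAP: "ACGT", MISSING: "ACGT",
}

#: Exact inverse of IUPAC_NT restricted to non-empty subsets of {A,C,G,T}.
NT_SET_TO_SYMBOL: dict[frozenset, str] = {
    frozenset(exp): sym
    for sym, exp in IUPAC_NT.items()
    if sym not in (GAP, MISSING)
}

AA_STATES = "ARNDCQEGHILKMFPSTWYV"

AA_AMBIGUITY: dict[str, str] = {
    "B": "ND", "Z": "QE", "J": "IL", "X": AA_STATES,
    GAP: AA_STATES, MISSING: AA_STATES,
}


def states_for(alphabet: str) -> str:
    """Base (unambiguous) state string for an alphabet name."""
    if alphabet in (NUCLEOTIDE, DEGENERATE_NUCLEOTIDE):
        return NT_STATES
    if alphabet == AMINO_ACID:
        return AA_STATES
    raise ValueError(f"unknown alphabet {alphabet!r}")


def expansion_map(alphabet: str) -> dict[str, str]:
    """Symbol -> string of base states the symbol may represent."""
    if alphabet in (NUCLEOTIDE, DEGENERATE_NUCLEOTIDE):
        return IUPAC_NT
    if alphabet == AMINO_ACID:
        out = {a: a for a in AA_STATES}
        out.update(AA_AMBIGUITY)
        return out
    raise ValueError(f"unknown alphabet {alphabet!r}")


def valid_symbols(alphabet: str) -> frozenset:
    return frozenset(expansion_map(alphabet))


def nt_symbol_for_set(states: frozenset | set | str) -> str:
    """Minimal IUPAC code whose expansion equals the given nucleotide set."""
    key = frozenset(states)
    try:
        return NT_SET_TO_SYMBOL[key]
    except KeyError:
        raise ValueError(f"no IUPAC symbol for state set {sorted(key)}") from None


def partial_lookup(alphabet: str) -> dict[str, np.ndarray]:
    """Symbol -> 0/1 leaf-partial vector over the base states."""
    states = states_for(alphabet)
    idx = {s: i for i, s in enumerate(states)}
    table = {}
    for sym, exp in expansion_map(alphabet).items():
        v = np.zeros(len(states))
        for s in exp:
            v[idx[s]] = 1.0
        table[sym] = v
    return table
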