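"""Codon-degenerate recoding.

Codons are replaced by IUPAC-ambiguity patterns so that synonymous point
substitutions become invisible to a nucleotide likelihood: all codons of a
synonymous family that is connected by single-nucleotide synonymous changes
receive one shared pattern covering the whole family.

The dialect implemented here merges the Leucine TTR/CTN and Arginine
AGR/CGN families (they are single-substitution connected through TTA<->CTA
and AGA<->CGA), giving YTN for all Leu codons and MGN for all Arg codons,
and keeps Serine's TCN and AGY families separate (no single synonymous
substitution connects them).  ``dump_table`` makes the full mapping
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from . import alphabet as ab
from .alignment import Alignment
from .msa_io import _codon_table

BASES = "ACGT"


@dataclass(frozen=True)
class DegeneracyTable:
    """codon -> 3-symbol IUPAC pattern; stop codons map to themselves."""

    genetic_code: int
    patterns: dict  # codon -> pattern

    def pattern(self, codon: str) -> str:
        return self.patterns[codon]

    def expansions(self, pattern: str) -> set:
        return {"".join(p) for p in product(*(ab.IUPAC_NT[c] for c in pattern))}


def _synonymous_families(code) -> list:
    """Partition sense codons of one amino acid into families connected by
    single-nucleotide synonymous substitutions (union-find)."""
    by_aa: dict = {}
    for codon, aa in code.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    families = []
    for codons in by_aa.values():
        parent = {c: c for c in codons}

        def find(c):
            while parent[c] != c:
                parent[c] = parent[parent[c]]
                c = parent[c]
            return c

        for c1 in codons:
            for c2 in codons:
                if sum(a != b for a, b in zip(c1, c2)) == 1:
                    parent[find(c1)] = find(c2)
        groups: dict = {}
        for c in codons:
            groups.setdefault(find(c), []).append(c)
        families.extend(groups.values())
    return families


def build_degeneracy_table(genetic_code: int = 1) -> DegeneracyTable:
    """Derive the codon -> degenerate-pattern map from a genetic code.

    Every family's pattern takes, per codon position, the exact IUPAC code
    for the set of nucleotides observed at that position within the family;
    all codons of a family share the same pattern.
    """
    code = _codon_table(genetic_code)
    patterns = {}
    for family in _synonymous_families(code):
        pattern = "".join(
            ab.nt_symbol_for_set({codon[pos] for codon in family})
            for pos in range(3)
        )
        for codon in family:
            patterns[codon] = pattern
    for stop in code.stop_codons:
        patterns[stop] = stop
    return DegeneracyTable(genetic_code=genetic_code, patterns=patterns)


def _recode_codon(codon: str, table: DegeneracyTable, code) -> str:
    if codon == ab.GAP * 3 or ab.MISSING in codon or ab.GAP in codon:
        return codon  # gaps / missing pass through untouched
    if codon in table.patterns and codon not in code.stop_codons:
        return table.patterns[codon]
    # ambiguous codon: union the patterns of all compatible sense expansions
    expansions = [
        "".join(p) for p in product(*(ab.IUPAC_NT[c] for c in codon))
    ]
    sense = [c for c in expansions if c in code.forward_table]
    if not sense:
        raise ValueError(f"codon {codon!r} has no sense expansion")
    out = []
    for pos in range(3):
        states: set = set()
        for c in sense:
            states |= set(ab.IUPAC_NT[table.patterns[c][pos]])
        out.append(ab.nt_symbol_for_set(states))
    return "".join(out)


def degen_recode(aln: Alignment, table: DegeneracyTable | None = None) -> Alignment:
    """Recode a codon-structured nucleotide alignment to degenerate patterns.

    Idempotent; gaps and missing data pass through; column count is
    unchanged.  The result keeps codon structure and is flagged with the
    ``degenerate_nucleotide`` alphabet.
    """
    if aln.alphabet == ab.AMINO_ACID:
        raise ValueError("cannot degenerate-recode amino-acid data")
    if not aln.codon_structure or aln.n_columns % 3:
        raise ValueError("degen recoding requires a codon-structured alignment")
    if table is None:
        table = build_degeneracy_table()
    code = _codon_table(table.genetic_code)
    out = np.empty_like(aln.matrix)
    cache: dict = {}
    for i in range(aln.n_taxa):
        row = aln.row(i)
        for j in range(aln.n_columns // 3):
            codon = row[3 * j: 3 * j + 3]
            rec = cache.get(codon)
            if rec is None:
                rec = cache[codon] = _recode_codon(codon, table, code)
            out[i, 3 * j: 3 * j + 3] = list(rec)
    return Alignment(taxa=list(aln.taxa), matrix=out,
                     alphabet=ab.DEGENERATE_NUCLEOTIDE,
                     gene_bounds=list(aln.gene_bounds), codon_structure=True)


def dump_table(table: DegeneracyTable) -> str:
    """TSV text of the codon -> pattern map (sorted), for inspection."""
    code = _codon_table(table.genetic_code)
    lines = ["codon\tamino_acid\tpattern"]
    for codon in sorted(table.patterns):
        aa = code.forward_table.get(codon, "*")
        lines.append(f"{codon}\t{aa}\t{table.patterns[codon]}")
    return "\n".join(lines) + "\n"
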