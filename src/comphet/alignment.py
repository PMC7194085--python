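"""Core alignment containers: :class:`Alignment` and :class:`GeneTable`.

Coordinates are 0-based half-open internally; error messages use 1-based
positions.  The gap symbol is ``-`` and the missing symbol ``?``; both are
fully ambiguous for the likelihood engine but are kept distinct in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import alphabet as ab


class AlignmentError(ValueError):
    """Malformed alignment input (ragged rows, bad structure)."""


class AlphabetError(AlignmentError):
    """A symbol outside the declared alphabet."""


@dataclass
class Alignment:
    """A taxa x columns character matrix with optional per-gene partitions.

    Parameters
    ----------
    taxa:
        Ordered taxon names (unique).
    matrix:
        ``(n_taxa, n_columns)`` array of single characters (dtype ``U1``).
    alphabet:
        One of ``nucleotide``, ``degenerate_nucleotide``, ``amino_acid``.
    gene_bounds:
        ``(gene_name, start, end)`` half-open column intervals partitioning
        ``[0, n_columns)``.  A single implicit gene is created when omitted.
    codon_structure:
        Whether nucleotide columns are organized in reading-frame triplets.
    """

    taxa: list
    matrix: np.ndarray
    alphabet: str
    gene_bounds: list = field(default_factory=list)
    codon_structure: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype="U1")
        if self.matrix.ndim != 2:
            raise AlignmentError("matrix must be 2-dimensional")
        if len(self.taxa) != self.matrix.shape[0]:
            raise AlignmentError(
                f"{len(self.taxa)} taxa but {self.matrix.shape[0]} matrix rows"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon names")
        if not self.gene_bounds:
            self.gene_bounds = [("gene1", 0, self.n_columns)]
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, taxon: str) -> str:
        return "".join(self.matrix[self.taxa.index(taxon)])

    def row(self, i: int) -> str:
        return "".join(self.matrix[i])

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        valid = ab.valid_symbols(self.alphabet)
        present = set(np.unique(self.matrix)) if self.matrix.size else set()
        bad = present - valid
        if bad:
            sym = sorted(bad)[0]
            rows, cols = np.nonzero(self.matrix == sym)
            raise AlphabetError(
                f"symbol {sym!r} not in alphabet {self.alphabet!r} "
                f"(taxon {self.taxa[rows[0]]!r}, column {cols[0] + 1})"
            )
        if self.codon_structure:
            if self.alphabet == ab.AMINO_ACID:
                raise AlignmentError("codon structure on amino-acid data")
            if self.n_columns % 3:
                raise AlignmentError(
                    f"codon structure requires columns divisible by 3, got {self.n_columns}"
                )
            for name, start, end in self.gene_bounds:
                if (end - start) % 3:
                    raise AlignmentError(f"gene {name!r} length not divisible by 3")
        pos = 0
        for name, start, end in self.gene_bounds:
            if start != pos or end < start:
                raise AlignmentError("gene_bounds do not partition the columns")
            pos = end
        if pos != self.n_columns:
            raise AlignmentError("gene_bounds do not cover all columns")

    # -- convenience -----------------------------------------------------
    def occupancy(self) -> np.ndarray:
        """Per-column fraction of taxa with a non-gap, non-missing symbol."""
        observed = (self.matrix != ab.GAP) & (self.matrix != ab.MISSING)
        return observed.mean(axis=0)

    def gene(self, name: str) -> "Alignment":
        for gname, start, end in self.gene_bounds:
            if gname == name:
                return Alignment(
                    taxa=list(self.taxa),
                    matrix=self.matrix[:, start:end].copy(),
                    alphabet=self.alphabet,
                    gene_bounds=[(gname, 0, end - start)],
                    codon_structure=self.codon_structure,
                )
        raise KeyError(name)

    def take_columns(self, cols, gene_bounds=None) -> "Alignment":
        cols = np.asarray(cols, dtype=int)
        if gene_bounds is None:
            gene_bounds = _recompute_bounds(self.gene_bounds, cols)
        return Alignment(
            taxa=list(self.taxa),
            matrix=self.matrix[:, cols],
            alphabet=self.alphabet,
            gene_bounds=gene_bounds,
            codon_structure=self.codon_structure,
        )

    def copy(self) -> "Alignment":
        return Alignment(
            taxa=list(self.taxa),
            matrix=self.matrix.copy(),
            alphabet=self.alphabet,
            gene_bounds=list(self.gene_bounds),
            codon_structure=self.codon_structure,
        )


def _recompute_bounds(bounds, kept_cols):
    kept = np.asarray(kept_cols)
    out = []
    pos = 0
    for name, start, end in bounds:
        n_kept = int(((kept >= start) & (kept < end)).sum())
        if n_kept:
            out.append((name, pos, pos + n_kept))
            pos += n_kept
    return out


def from_sequences(pairs, alphabet: str, codon_structure: bool = False,
                   gene_bounds=None) -> Alignment:
    """Build an Alignment from ``(name, sequence)`` pairs, checking row lengths."""
    taxa = [name for name, _ in pairs]
    seqs = [seq for _, seq in pairs]
    if not seqs:
        raise AlignmentError("no sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise AlignmentError(f"ragged rows: lengths {sorted(lengths)}")
    matrix = np.array([list(s.upper()) for s in seqs], dtype="U1")
    return Alignment(taxa=taxa, matrix=matrix, alphabet=alphabet,
                     codon_structure=codon_structure,
                     gene_bounds=list(gene_bounds) if gene_bounds else [])


@dataclass
class GeneTable:
    """Per-gene alignments over a shared taxon universe.

    Every per-gene alignment carries a row for every taxon in ``taxa``; a
    taxon absent from a gene has an all-``?`` row, and the presence flag for
    that (gene, taxon) cell is False.
    """

    taxa: list
    genes: list  # list of (gene_name, Alignment)

    def __post_init__(self):
        names = [n for n, _ in self.genes]
        if len(set(names)) != len(names):
            raise AlignmentError("duplicate gene names")
        for name, aln in self.genes:
            if aln.taxa != self.taxa:
                raise AlignmentError(f"gene {name!r} taxa differ from table universe")

    @property
    def gene_names(self) -> list:
        return [n for n, _ in self.genes]

    def gene(self, name: str) -> Alignment:
        for n, a in self.genes:
            if n == name:
                return a
        raise KeyError(name)

    def gene_lengths(self) -> dict:
        return {n: a.n_columns for n, a in self.genes}

    def presence(self) -> dict:
        """(gene, taxon) -> True iff the row is not entirely missing."""
        out = {}
        for name, aln in self.genes:
            all_missing = (aln.matrix == ab.MISSING).all(axis=1)
            for i, taxon in enumerate(self.taxa):
                out[(name, taxon)] = not bool(all_missing[i])
        return out

    def missing_fraction(self) -> float:
        pres = self.presence()
        if not pres:
            return 0.0
        return sum(1 for v in pres.values() if not v) / len(pres)
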