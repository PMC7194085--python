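"""Reading, writing, filtering, concatenating and translating alignments.

File I/O is delegated to Biopython (FASTA, relaxed PHYLIP, NEXUS); the
curation operations implement the occupancy / gene-length / required-group
filters and in-frame translation used by the pipeline.
"""

from __future__ import annotations

import warnings
from itertools import product

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

from . import alphabet as ab
from .alignment import Alignment, AlignmentError, GeneTable, from_sequences

FORMATS = {"fasta": "fasta", "phylip": "phylip-relaxed", "nexus": "nexus"}


class TranslationError(ValueError):
    """Stop codon or untranslatable codon encountered."""


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_alignment(path, fmt="fasta", alphabet=ab.NUCLEOTIDE,
                   codon_structure=False) -> Alignment:
    """Read one alignment file.

    ``fmt`` is one of ``fasta``, ``phylip`` (relaxed) or ``nexus``.  Taxon
    order is preserved from the file.  Ragged rows raise
    :class:`AlignmentError`; symbols outside the declared alphabet raise
    :class:`AlphabetError` naming the offending taxon and column.
    """
    if fmt not in FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; choose from {sorted(FORMATS)}")
    if fmt == "fasta":
        # parse record-wise so ragged input yields our error, not Biopython's
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"no sequences in {path}")
        pairs = [(r.id, str(r.seq)) for r in records]
    else:
        try:
            msa = AlignIO.read(str(path), FORMATS[fmt])
        except ValueError as exc:
            raise AlignmentError(f"cannot parse {path} as {fmt}: {exc}") from exc
        pairs = [(r.id, str(r.seq)) for r in msa]
    return from_sequences(pairs, alphabet=alphabet, codon_structure=codon_structure)


def write_alignment(aln: Alignment, path, fmt="fasta") -> None:
    if fmt not in FORMATS:
        raise ValueError(f"unsupported format {fmt!r}")
    mol = "protein" if aln.alphabet == ab.AMINO_ACID else "DNA"
    records = [
        SeqRecord(Seq(aln.row(i)), id=taxon, description="",
                  annotations={"molecule_type": mol})
        for i, taxon in enumerate(aln.taxa)
    ]
    AlignIO.write(MultipleSeqAlignment(records), str(path), FORMATS[fmt])


def read_gene_table(manifest: dict, fmt="fasta", alphabet=ab.NUCLEOTIDE,
                    codon_structure=False) -> GeneTable:
    """Build a GeneTable from a ``gene name -> file path`` manifest.

    The taxon universe is the union over genes, ordered by first appearance;
    rows for taxa absent from a gene are filled with the missing symbol.
    """
    per_gene = []
    universe: list = []
    for gene_name, path in manifest.items():
        aln = read_alignment(path, fmt=fmt, alphabet=alphabet,
                             codon_structure=codon_structure)
        for t in aln.taxa:
            if t not in universe:
                universe.append(t)
        per_gene.append((gene_name, aln))
    genes = []
    for gene_name, aln in per_gene:
        genes.append((gene_name, _expand_to_universe(aln, universe, gene_name)))
    return GeneTable(taxa=universe, genes=genes)


def _expand_to_universe(aln: Alignment, universe, gene_name) -> Alignment:
    matrix = np.full((len(universe), aln.n_columns), ab.MISSING, dtype="U1")
    for i, taxon in enumerate(aln.taxa):
        matrix[universe.index(taxon)] = aln.matrix[i]
    return Alignment(taxa=list(universe), matrix=matrix, alphabet=aln.alphabet,
                     gene_bounds=[(gene_name, 0, aln.n_columns)],
                     codon_structure=aln.codon_structure)


def make_gene_table(named_alignments) -> GeneTable:
    """GeneTable from ``(gene_name, Alignment)`` pairs with differing taxa."""
    universe: list = []
    for _, aln in named_alignments:
        for t in aln.taxa:
            if t not in universe:
                universe.append(t)
    genes = [(name, _expand_to_universe(aln, universe, name))
             for name, aln in named_alignments]
    return GeneTable(taxa=universe, genes=genes)


# ---------------------------------------------------------------------------
# curation filters
# ---------------------------------------------------------------------------

def filter_low_occupancy_columns(aln: Alignment, min_occupancy: float,
                                 per_codon: bool | None = None) -> Alignment:
    """Drop columns whose taxon occupancy falls below ``min_occupancy``.

    Occupancy of a column is the fraction of taxa with a non-gap,
    non-missing symbol; columns at exactly the threshold are kept.  For
    codon-structured data the filter operates on whole codons (a triple is
    dropped when its mean occupancy is below threshold) so the reading
    frame is preserved; set ``per_codon=False`` to force per-column mode.
    """
    if not (0 < min_occupancy <= 1):
        raise ValueError("min_occupancy must be in (0, 1]")
    occ = aln.occupancy()
    if per_codon is None:
        per_codon = aln.codon_structure
    if per_codon:
        if aln.n_columns % 3:
            raise AlignmentError("per-codon filtering requires columns divisible by 3")
        codon_occ = occ.reshape(-1, 3).mean(axis=1)
        keep_codons = codon_occ >= min_occupancy
        keep = np.repeat(keep_codons, 3)
    else:
        keep = occ >= min_occupancy
    if not keep.any():
        raise AlignmentError("all columns filtered by occupancy threshold")
    return aln.take_columns(np.nonzero(keep)[0])


def filter_genes(table: GeneTable, min_len_bp: int = 0,
                 required_groups: dict | None = None) -> GeneTable:
    """Retain genes of length >= ``min_len_bp`` with every required group present.

    ``required_groups`` maps a group name to its taxa; a gene passes the
    group rule if at least one taxon of every group has a non-missing
    sequence for that gene.
    """
    if min_len_bp < 0:
        raise ValueError("min_len_bp must be >= 0")
    presence = table.presence()
    kept = []
    for name, aln in table.genes:
        if aln.n_columns < min_len_bp:
            continue
        ok = True
        for group_name, group_taxa in (required_groups or {}).items():
            if not any(presence.get((name, t), False) for t in group_taxa):
                ok = False
                break
        if ok:
            kept.append((name, aln))
    if not kept:
        warnings.warn("all genes removed by filter_genes", stacklevel=2)
    return GeneTable(taxa=list(table.taxa), genes=kept)


def concatenate(table: GeneTable) -> Alignment:
    """Concatenate a GeneTable into one partitioned alignment.

    Columns are the sum of gene lengths; rows for taxa absent from a gene
    carry the missing symbol (the table stores them that way already).  The
    fraction of absent gene x taxon cells is available from
    ``table.missing_fraction()``.
    """
    if not table.genes:
        raise AlignmentError("empty gene table")
    alphabets = {aln.alphabet for _, aln in table.genes}
    if len(alphabets) > 1:
        raise AlignmentError(f"mixed alphabets in gene table: {sorted(alphabets)}")
    codon = all(aln.codon_structure for _, aln in table.genes)
    blocks = [aln.matrix for _, aln in table.genes]
    bounds = []
    pos = 0
    for name, aln in table.genes:
        bounds.append((name, pos, pos + aln.n_columns))
        pos += aln.n_columns
    return Alignment(taxa=list(table.taxa), matrix=np.hstack(blocks),
                     alphabet=alphabets.pop(), gene_bounds=bounds,
                     codon_structure=codon)


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

def _codon_table(genetic_code: int):
    return CodonTable.unambiguous_dna_by_id[genetic_code]


def translate_codon(codon: str, code) -> str:
    """Translate one codon; returns an amino acid, 'X', '-', '?' or raises.

    Gap codons (``---``) map to gap; codons containing the missing symbol or
    a partial gap map to missing.  IUPAC-ambiguous codons are expanded; if
    the sense expansions encode more than one amino acid the result is
    ``X``.  A codon with no sense expansion (a stop) raises
    :class:`TranslationError`.
    """
    if codon == ab.GAP * 3:
        return ab.GAP
    if ab.MISSING in codon or ab.GAP in codon:
        return ab.MISSING
    aas = set()
    stops = 0
    for expansion in product(*(ab.IUPAC_NT[c] for c in codon)):
        cdn = "".join(expansion)
        if cdn in code.stop_codons:
            stops += 1
        else:
            aas.add(code.forward_table[cdn])
    if not aas:
        raise TranslationError(f"stop codon {codon}")
    if len(aas) > 1:
        return "X"
    return aas.pop()


def translate(aln: Alignment, genetic_code: int = 1) -> Alignment:
    """Translate an in-frame codon alignment to amino acids.

    Output columns = nucleotide columns / 3; gene bounds are carried over at
    one third of their nucleotide coordinates.  Any codon whose expansions
    all encode stop raises :class:`TranslationError` naming the taxon, gene
    and 1-based codon position.
    """
    if aln.alphabet == ab.AMINO_ACID:
        raise AlignmentError("alignment is already amino acid")
    if not aln.codon_structure or aln.n_columns % 3:
        raise AlignmentError("translation requires a codon-structured alignment")
    code = _codon_table(genetic_code)
    n_codons = aln.n_columns // 3
    out = np.empty((aln.n_taxa, n_codons), dtype="U1")
    for i, taxon in enumerate(aln.taxa):
        row = aln.row(i)
        for j in range(n_codons):
            codon = row[3 * j: 3 * j + 3]
            try:
                out[i, j] = translate_codon(codon, code)
            except TranslationError:
                gene = next(g for g, s, e in aln.gene_bounds if s <= 3 * j < e)
                raise TranslationError(
                    f"stop codon {codon} in taxon {taxon!r}, gene {gene!r}, "
                    f"codon position {j + 1}"
                ) from None
    bounds = [(name, start // 3, end // 3) for name, start, end in aln.gene_bounds]
    return Alignment(taxa=list(aln.taxa), matrix=out, alphabet=ab.AMINO_ACID,
                     gene_bounds=bounds)


def translate_table(table: GeneTable, genetic_code: int = 1) -> GeneTable:
    genes = [(name, translate(aln, genetic_code)) for name, aln in table.genes]
    return GeneTable(taxa=list(table.taxa), genes=genes)
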