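"""Alignment container, FASTA I/O, codon translation, 4-fold-degenerate site
extraction, supermatrix concatenation, and the alignment-trimming filter.

Amino-acid state order follows the PAML convention (ARNDCQEGHILKMFPSTWYV),
which is also the order used by the packaged WAG/JTT matrix files.
Internally all coordinates are 0-based half-open; user-facing tables are
written 1-based and say so in their headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

from .errors import (
    AlignmentFormatError,
    AlphabetError,
    DuplicateTaxonError,
    MissingTaxonError,
)

log = logging.getLogger(__name__)

AA_STATES = "ARNDCQEGHILKMFPSTWYV"
DNA_STATES = "ACGT"
GAP = "-"

#: dinucleotide prefixes of the eight four-fold degenerate codon families
FOURFOLD_PREFIXES = frozenset(
    {"GC", "CG", "GG", "CT", "CC", "TC", "AC", "GT"}
)

_AA_ALLOWED = frozenset(AA_STATES) | {GAP, "X"}
_DNA_ALLOWED = frozenset(DNA_STATES) | {GAP, "N"}
_CODON_CHARS = frozenset(DNA_STATES) | {GAP, "N"}

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = frozenset(standard_dna_table.stop_codons)


@dataclass
class Alignment:
    """A taxa-by-columns character matrix over one alphabet.

    ``columns`` is a 2-D numpy array of unicode symbols: single characters
    for ``aa``/``dna``, codon triplets for ``codon``.
    """

    taxon_ids: list[str]
    columns: np.ndarray
    alphabet_tag: str  # "aa" | "dna" | "codon"
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.alphabet_tag not in ("aa", "dna", "codon"):
            raise ValueError(f"unknown alphabet tag {self.alphabet_tag!r}")
        self.columns = np.asarray(self.columns)
        if self.columns.ndim != 2:
            raise AlignmentFormatError("columns must be a 2-D matrix")
        if len(self.taxon_ids) != self.columns.shape[0]:
            raise AlignmentFormatError(
                f"{len(self.taxon_ids)} taxon ids for "
                f"{self.columns.shape[0]} rows"
            )
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            dupes = sorted(
                t for t in set(self.taxon_ids) if self.taxon_ids.count(t) > 1
            )
            raise DuplicateTaxonError(f"duplicate taxon ids: {dupes}")

    @property
    def n_taxa(self) -> int:
        return self.columns.shape[0]

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        try:
            return self.columns[self.taxon_ids.index(taxon)]
        except ValueError:
            raise MissingTaxonError(f"taxon {taxon!r} not in alignment") from None

    def sequence(self, taxon: str) -> str:
        return "".join(self.row(taxon))

    def reorder(self, taxa: Sequence[str]) -> "Alignment":
        """Return a copy with rows permuted to the given taxon order."""
        idx = []
        for t in taxa:
            if t not in self.taxon_ids:
                raise MissingTaxonError(f"taxon {t!r} not in alignment")
            idx.append(self.taxon_ids.index(t))
        return Alignment(
            list(taxa), self.columns[idx].copy(), self.alphabet_tag, self.gene_id
        )


def _validate_symbols(taxon: str, seq: str, alphabet_tag: str) -> None:
    allowed = _AA_ALLOWED if alphabet_tag == "aa" else _DNA_ALLOWED
    if alphabet_tag == "codon":
        allowed = _CODON_CHARS
    for pos, ch in enumerate(seq):
        if ch not in allowed:
            raise AlphabetError(
                f"symbol {ch!r} at position {pos + 1} of {taxon!r} is outside "
                f"the {alphabet_tag} alphabet"
            )


def read_fasta(path: str | Path, alphabet_tag: str, gene_id: str = "") -> Alignment:
    """Read an aligned multi-FASTA file into an :class:`Alignment`.

    Symbols are uppercased.  For amino-acid data a single terminal ``*``
    (stop) is stripped; internal ``*`` raises.  Records must all have the
    same length; for codon data the length must be divisible by 3.
    """
    path = Path(path)
    taxa: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in taxa:
            raise DuplicateTaxonError(f"duplicate taxon id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if alphabet_tag == "aa":
            if seq.endswith("*"):
                seq = seq[:-1]
            if "*" in seq:
                raise AlphabetError(
                    f"internal stop symbol '*' in record {rec.id!r}"
                )
        _validate_symbols(rec.id, seq, alphabet_tag)
        taxa.append(rec.id)
        seqs.append(seq)
    if not taxa:
        raise AlignmentFormatError(f"no FASTA records in {path}")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentFormatError(
            f"records in {path} have unequal lengths {sorted(lengths)}"
        )
    (length,) = lengths
    if alphabet_tag == "codon":
        if length % 3 != 0:
            raise AlignmentFormatError(
                f"codon alignment length {length} not divisible by 3"
            )
        mat = np.array(
            [[s[i : i + 3] for i in range(0, length, 3)] for s in seqs],
            dtype="U3",
        )
    else:
        mat = np.array([list(s) for s in seqs], dtype="U1")
    if not gene_id:
        gene_id = path.stem
    return Alignment(taxa, mat, alphabet_tag, gene_id)


def write_fasta(aln: Alignment, path: str | Path, wrap: int = 60) -> None:
    """Write an alignment as (wrapped) multi-FASTA."""
    with open(path, "w") as fh:
        for taxon in aln.taxon_ids:
            fh.write(f">{taxon}\n")
            seq = aln.sequence(taxon)
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def write_phylip(aln: Alignment, path: str | Path) -> None:
    """Write relaxed (long-name) sequential PHYLIP, for interoperability."""
    seqs = [aln.sequence(t) for t in aln.taxon_ids]
    with open(path, "w") as fh:
        fh.write(f" {aln.n_taxa} {len(seqs[0])}\n")
        for taxon, seq in zip(aln.taxon_ids, seqs):
            fh.write(f"{taxon}  {seq}\n")


def translate_codons(aln: Alignment, internal_stop: str = "error") -> Alignment:
    """Translate a codon alignment with the standard genetic code.

    Codons containing gap characters or ``N`` translate to ``X``, except the
    whole-codon gap ``---`` which maps to ``-``.  An internal stop codon
    raises by default; with ``internal_stop="X"`` it translates to ``X``.
    """
    if aln.alphabet_tag != "codon":
        raise AlignmentFormatError("translate_codons requires a codon alignment")
    if internal_stop not in ("error", "X"):
        raise ValueError("internal_stop must be 'error' or 'X'")
    out = np.empty(aln.columns.shape, dtype="U1")
    for i in range(aln.n_taxa):
        for j in range(aln.n_columns):
            codon = aln.columns[i, j]
            if codon == "---":
                out[i, j] = GAP
            elif GAP in codon or "N" in codon:
                out[i, j] = "X"
            elif codon in _STOP_CODONS:
                if internal_stop == "error":
                    raise AlphabetError(
                        f"internal stop codon {codon} at codon {j + 1} of "
                        f"{aln.taxon_ids[i]!r}"
                    )
                out[i, j] = "X"
            else:
                out[i, j] = _CODON_TABLE[codon]
    return Alignment(list(aln.taxon_ids), out, "aa", aln.gene_id)


@dataclass
class FourDSiteSet:
    """Third positions of codon columns that are four-fold degenerate in
    every taxon (identical unambiguous dinucleotide prefix across taxa,
    prefix in one of the eight 4-fold families, no gaps/ambiguity)."""

    gene_id: str
    taxon_ids: list[str]
    site_indices: list[int] = field(default_factory=list)  # 0-based codon idx
    third_position_matrix: np.ndarray = field(
        default_factory=lambda: np.empty((0, 0), dtype="U1")
    )

    @property
    def n_sites(self) -> int:
        return self.third_position_matrix.shape[1]


def extract_4d_sites(aln: Alignment) -> FourDSiteSet:
    """Extract strictly cross-taxon four-fold degenerate third positions.

    A codon column is retained when all taxa share the same unambiguous
    first+second codon positions, that prefix belongs to a four-fold
    degenerate family, and no taxon has a gap or ``N`` anywhere in the codon.
    """
    if aln.alphabet_tag != "codon":
        raise AlignmentFormatError("extract_4d_sites requires a codon alignment")
    kept: list[int] = []
    thirds: list[list[str]] = []
    for j in range(aln.n_columns):
        col = aln.columns[:, j]
        prefixes = {c[:2] for c in col}
        if len(prefixes) != 1:
            continue
        (prefix,) = prefixes
        if prefix not in FOURFOLD_PREFIXES:
            continue
        third = [c[2] for c in col]
        if any(ch not in DNA_STATES for ch in third):
            continue
        kept.append(j)
        thirds.append(third)
    if kept:
        mat = np.array(thirds, dtype="U1").T  # taxa x sites
    else:
        mat = np.empty((aln.n_taxa, 0), dtype="U1")
    return FourDSiteSet(aln.gene_id, list(aln.taxon_ids), kept, mat)


def concatenate_supermatrix(
    sets: Iterable[FourDSiteSet],
    taxa: Sequence[str],
    gap_fill: bool = False,
) -> Alignment:
    """Concatenate per-gene 4D-site matrices into one nucleotide supermatrix.

    By default every gene must cover every requested taxon (the single-copy
    ortholog contract); with ``gap_fill=True`` a missing taxon's row is
    filled with gaps instead.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("no 4D site sets to concatenate")
    blocks: list[np.ndarray] = []
    for s in sets:
        block = np.full((len(taxa), s.n_sites), GAP, dtype="U1")
        for i, t in enumerate(taxa):
            if t in s.taxon_ids:
                block[i] = s.third_position_matrix[s.taxon_ids.index(t)]
            elif not gap_fill:
                raise MissingTaxonError(
                    f"gene {s.gene_id!r} lacks taxon {t!r} (strict mode)"
                )
        blocks.append(block)
    return Alignment(list(taxa), np.hstack(blocks), "dna", "supermatrix")


def _is_gap(sym: str) -> bool:
    return set(sym) == {GAP}


def _is_ambiguous(sym: str, alphabet_tag: str) -> bool:
    if alphabet_tag == "aa":
        return sym == "X"
    if alphabet_tag == "dna":
        return sym == "N"
    # codon: N anywhere, or a partial gap, counts as ambiguous
    return "N" in sym or (GAP in sym and sym != "---")


def trim_alignment(
    aln: Alignment,
    max_gap_fraction: float = 0.5,
    drop_ambiguous: bool = True,
) -> tuple[Alignment, list[int]]:
    """Column filter standing in for heuristic alignment cleaning.

    Removes a column when its gap fraction exceeds ``max_gap_fraction``, or
    (if ``drop_ambiguous``) when any ambiguity symbol is present.  In codon
    alignments whole codon columns are removed.  Returns the trimmed
    alignment and the mapping from new to original column indices (0-based).
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    keep: list[int] = []
    for j in range(aln.n_columns):
        col = aln.columns[:, j]
        gap_frac = sum(_is_gap(c) for c in col) / aln.n_taxa
        if gap_frac > max_gap_fraction:
            continue
        if drop_ambiguous and any(
            _is_ambiguous(c, aln.alphabet_tag) for c in col
        ):
            continue
        keep.append(j)
    if not keep:
        log.warning(
            "trim_alignment removed every column of gene %r", aln.gene_id
        )
        empty = np.empty((aln.n_taxa, 0), dtype=aln.columns.dtype)
        return Alignment(list(aln.taxon_ids), empty, aln.alphabet_tag, aln.gene_id), []
    return (
        Alignment(
            list(aln.taxon_ids),
            aln.columns[:, keep].copy(),
            aln.alphabet_tag,
            aln.gene_id,
        ),
        keep,
    )
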