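"""Codon and protein alignment containers, cleaning, and identity statistics.

Alignments are read from FASTA with Biopython.  ``CodonAlignment`` is the
unit on which every selection statistic operates: an in-frame, gap-aware
matrix of codons with stop codons and ambiguity columns removed by
:func:`clean_codon_alignment`.  All alignment coordinates reported by this
module are 1-based, matching residue-style numbering (e.g. "site 98").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

from .codons import GAP_CODON, NUCLEOTIDES, STOP_CODONS, translate_codon

_VALID_NT = set(NUCLEOTIDES) | {"-"}


@dataclass
class Alignment:
    """A generic character alignment (one row per taxon)."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = {t for t in self.taxa if self.taxa.count(t) > 1}
            raise ValueError(f"duplicate taxon labels: {sorted(dupes)}")
        if self.rows:
            n = len(self.rows[0])
            for label, row in zip(self.taxa, self.rows):
                if len(row) != n:
                    raise ValueError(
                        f"ragged alignment: record {label!r} has length "
                        f"{len(row)}, expected {n}"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        """Column ``j`` (0-based) as a string over taxa."""
        return "".join(row[j] for row in self.rows)


@dataclass
class CodonAlignment(Alignment):
    """In-frame codon alignment; rows are nucleotide strings, length % 3 == 0."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.rows and len(self.rows[0]) % 3 != 0:
            raise ValueError(
                f"alignment length {len(self.rows[0])} is not a multiple of 3"
            )

    @property
    def n_sites(self) -> int:
        """Number of codon columns."""
        return self.n_columns // 3

    def codon(self, taxon_idx: int, site: int) -> str:
        """Codon of taxon ``taxon_idx`` at 0-based codon column ``site``."""
        return self.rows[taxon_idx][3 * site: 3 * site + 3]

    def codon_column(self, site: int) -> list[str]:
        return [self.codon(i, site) for i in range(self.n_taxa)]


@dataclass
class RemovalLog:
    """Columns removed by cleaning: 1-based codon-column indices + reasons."""

    entries: list[tuple[int, str]] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("column\treason\n")
            for col, reason in self.entries:
                fh.write(f"{col}\t{reason}\n")


def read_alignment(
    path: str | Path, kind: Literal["nucleotide", "protein"] = "nucleotide"
) -> CodonAlignment | Alignment:
    """Read an aligned FASTA file.

    ``kind='nucleotide'`` returns a :class:`CodonAlignment` (length must be
    divisible by 3); ``kind='protein'`` returns a plain :class:`Alignment`.
    Label order of the file is preserved.  Ragged records or an empty file
    raise ``ValueError``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    taxa = [r.id for r in records]
    rows = [str(r.seq).upper() for r in records]
    n = len(rows[0])
    for i, (label, row) in enumerate(zip(taxa, rows), start=1):
        if len(row) != n:
            raise ValueError(
                f"ragged alignment: record {i} ({label!r}) has length "
                f"{len(row)}, expected {n}"
            )
    if kind == "protein":
        return Alignment(taxa, rows)
    return CodonAlignment(taxa, rows)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for label, row in zip(aln.taxa, aln.rows):
            fh.write(f">{label}\n{row}\n")


def clean_codon_alignment(
    aln: CodonAlignment,
) -> tuple[CodonAlignment, RemovalLog]:
    """Remove codon columns containing stop codons or ambiguous bases.

    A column is dropped if any taxon's codon is a stop codon, or contains
    a character outside ACGT that does not form the full gap codon
    ``---``.  Whole columns (never taxa) are removed, so the taxon set
    stays concordant with the species tree.  Returns the cleaned
    alignment and a :class:`RemovalLog` with 1-based column indices.
    """
    keep: list[int] = []
    log = RemovalLog()
    for site in range(aln.n_sites):
        reason = None
        for codon in aln.codon_column(site):
            if codon in STOP_CODONS:
                reason = "stop_codon"
                break
            if codon != GAP_CODON and any(ch not in _VALID_NT for ch in codon):
                reason = "ambiguous_base"
                break
            if codon != GAP_CODON and "-" in codon:
                reason = "partial_gap_codon"
                break
        if reason is None:
            keep.append(site)
        else:
            log.entries.append((site + 1, reason))
    if not keep:
        raise ValueError("cleaning removed every codon column")
    new_rows = [
        "".join(row[3 * s: 3 * s + 3] for s in keep) for row in aln.rows
    ]
    return CodonAlignment(list(aln.taxa), new_rows), log


def percent_identity(
    aln: Alignment,
    gap_policy: Literal[
        "exclude_gap_columns", "count_gap_columns"
    ] = "exclude_gap_columns",
) -> float:
    """Fraction of columns in which every sequence carries the same residue.

    With the default ``exclude_gap_columns`` policy, columns containing any
    gap are excluded from the denominator; ``count_gap_columns`` keeps them
    (a gap never matches a residue, and an all-gap column is not identical).
    The statistic is invariant to sequence order.
    """
    if aln.n_taxa < 2:
        raise ValueError("percent identity requires at least 2 sequences")
    counted = identical = 0
    for j in range(aln.n_columns):
        col = aln.column(j)
        has_gap = "-" in col
        if has_gap and gap_policy == "exclude_gap_columns":
            continue
        counted += 1
        if not has_gap and len(set(col)) == 1:
            identical += 1
    if counted == 0:
        raise ValueError("no columns counted under the chosen gap policy")
    return identical / counted


def translate(aln: CodonAlignment) -> Alignment:
    """Translate a cleaned codon alignment; gap codons map to '-'.

    Protein column k corresponds to codon column k.  A residual stop codon
    means the cleaning contract was violated and raises ``ValueError``.
    """
    prot_rows = []
    for label, row in zip(aln.taxa, aln.rows):
        aas = []
        for site in range(aln.n_sites):
            codon = row[3 * site: 3 * site + 3]
            if codon in STOP_CODONS:
                raise ValueError(
                    f"stop codon {codon} at codon column {site + 1} in "
                    f"{label!r}: alignment was not cleaned"
                )
            aas.append(translate_codon(codon))
        prot_rows.append("".join(aas))
    return Alignment(list(aln.taxa), prot_rows)
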