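"""Transcript-space coordinate model for selenoprotein mRNAs.

Everything downstream works in transcript coordinates: 0-based, half-open,
one reference sequence per transcript (5'UTR | CDS | 3'UTR).  No genome
coordinates appear anywhere in the package; footprint alignments are expected
in transcriptome space.  The UGA/Sec codon of a selenoprotein is identified by
its codon index within the CDS (codon 0 is the start codon).

The module also provides exon-layout arithmetic (insertions, exon skipping,
RT-PCR amplicon sizes, frame preservation) used to reason about coding edits
such as the SECISBP2 exon-13 lesion modeled by the shipped synthetic fixture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
SEC_CODON = "TGA"


class AnnotationError(ValueError):
    """Inconsistent transcript annotation or edit arithmetic."""


def normalize_sequence(sequence: str) -> str:
    """Uppercase a nucleotide string and convert RNA U to DNA T."""
    return sequence.upper().replace("U", "T")


@dataclass(frozen=True)
class TranscriptAnnotation:
    """Coordinate model of one mRNA.

    ``cds_start`` is the first nt of the start codon, ``cds_end`` the first nt
    past the stop codon (half-open).  ``sec_codon_indices`` are 0-based codon
    indices within the CDS of in-frame UGA codons read as selenocysteine; the
    terminal stop codon is never a Sec codon.
    """

    transcript_id: str
    gene: str
    length: int
    cds_start: int
    cds_end: int
    sec_codon_indices: tuple[int, ...] = ()
    is_selenoprotein: bool | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= self.length):
            raise AnnotationError(
                f"{self.transcript_id}: CDS window [{self.cds_start}, "
                f"{self.cds_end}) out of range for length {self.length}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise AnnotationError(
                f"{self.transcript_id}: CDS length not divisible by 3"
            )
        if self.n_codons < 2:
            raise AnnotationError(f"{self.transcript_id}: CDS shorter than 2 codons")
        object.__setattr__(self, "sec_codon_indices",
                           tuple(sorted(int(i) for i in self.sec_codon_indices)))
        for idx in self.sec_codon_indices:
            if not 0 < idx < self.n_codons - 1:
                raise AnnotationError(
                    f"{self.transcript_id}: Sec codon index {idx} not strictly "
                    f"inside the CDS (terminator can never be a Sec codon)"
                )
        if self.is_selenoprotein is None:
            object.__setattr__(self, "is_selenoprotein",
                               len(self.sec_codon_indices) > 0)
        if self.sequence is not None:
            seq = normalize_sequence(self.sequence)
            object.__setattr__(self, "sequence", seq)
            if len(seq) != self.length:
                raise AnnotationError(
                    f"{self.transcript_id}: sequence length {len(seq)} != "
                    f"annotated length {self.length}"
                )
            for idx in self.sec_codon_indices:
                if self.codon(idx) != SEC_CODON:
                    raise AnnotationError(
                        f"{self.transcript_id}: codon {idx} is "
                        f"{self.codon(idx)}, expected {SEC_CODON}"
                    )

    @property
    def n_codons(self) -> int:
        """Number of codons in the CDS, stop codon included."""
        return (self.cds_end - self.cds_start) // 3

    @property
    def last_sense_codon(self) -> int:
        """Codon index of the last sense codon (the one before the stop)."""
        return self.n_codons - 2

    def codon(self, index: int) -> str:
        """Return the codon at CDS codon ``index`` (requires sequence)."""
        if self.sequence is None:
            raise AnnotationError(f"{self.transcript_id}: no sequence attached")
        start = self.cds_start + 3 * index
        return self.sequence[start:start + 3]


def locate_sec_codons(sequence: str, cds_start: int, cds_end: int) -> list[int]:
    """Find candidate UGA/Sec codons in a CDS.

    Returns the 0-based codon indices of every in-frame TGA strictly before
    the terminal codon, in ascending order.  The terminal stop codon is
    excluded even when it reads TGA, because a terminator is by definition not
    re-coded.
    """
    seq = normalize_sequence(sequence)
    if not (0 <= cds_start < cds_end <= len(seq)):
        raise AnnotationError("CDS window out of sequence bounds")
    if (cds_end - cds_start) % 3 != 0:
        raise AnnotationError("CDS length not divisible by 3")
    n_codons = (cds_end - cds_start) // 3
    hits = []
    for idx in range(n_codons - 1):  # terminal codon excluded
        if seq[cds_start + 3 * idx: cds_start + 3 * idx + 3] == SEC_CODON:
            hits.append(idx)
    return hits


# ---------------------------------------------------------------------------
# Annotation / FASTA I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["transcript_id", "gene", "length", "cds_start", "cds_end",
                "is_selenoprotein", "sec_codons"]


def write_annotation_tsv(annotations: Iterable[TranscriptAnnotation],
                         path: str | Path) -> None:
    rows = []
    for ann in annotations:
        rows.append({
            "transcript_id": ann.transcript_id,
            "gene": ann.gene,
            "length": ann.length,
            "cds_start": ann.cds_start,
            "cds_end": ann.cds_end,
            "is_selenoprotein": int(bool(ann.is_selenoprotein)),
            "sec_codons": ",".join(str(i) for i in ann.sec_codon_indices),
        })
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | Path,
                        fasta: str | Path | None = None,
                        ) -> dict[str, TranscriptAnnotation]:
    """Read a transcript annotation table, optionally attaching sequences.

    When ``fasta`` is given, sequences are attached and Sec codons are
    discovered with :func:`locate_sec_codons` for any transcript whose
    ``sec_codons`` field is empty but flagged as a selenoprotein.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sec_codons": str})
    sequences = read_fasta(fasta) if fasta is not None else {}
    annotations: dict[str, TranscriptAnnotation] = {}
    for row in df.itertuples(index=False):
        sec_raw = getattr(row, "sec_codons", "") or ""
        sec = tuple(int(x) for x in str(sec_raw).split(",") if x != "" and x != "nan")
        seq = sequences.get(row.transcript_id)
        if not sec and seq is not None:
            sec = tuple(locate_sec_codons(seq, row.cds_start, row.cds_end))
        annotations[row.transcript_id] = TranscriptAnnotation(
            transcript_id=row.transcript_id,
            gene=row.gene,
            length=int(row.length),
            cds_start=int(row.cds_start),
            cds_end=int(row.cds_end),
            sec_codon_indices=sec,
            is_selenoprotein=bool(row.is_selenoprotein),
            sequence=seq,
        )
    return annotations


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read transcript sequences, normalized to uppercase DNA."""
    return {rec.id: normalize_sequence(str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Exon-layout arithmetic (insertions, skipping, amplicons, frame checks)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExonLayout:
    """Ordered exon segments with a primer pair defining an amplicon.

    Exon segments are ``(exon_id, length_nt)`` pairs laid out left to right;
    primer positions are 0-based offsets into the concatenated layout, and the
    amplicon is the half-open span ``[primer_left, primer_right)``.
    """

    exons: tuple[tuple[str, int], ...]
    primer_left: int
    primer_right: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons",
                           tuple((str(e), int(n)) for e, n in self.exons))
        if any(n <= 0 for _, n in self.exons):
            raise AnnotationError("exon segment lengths must be positive")
        total = self.total_length
        if not (0 <= self.primer_left < self.primer_right <= total):
            raise AnnotationError("primers must define a non-empty span "
                                  "within the layout")

    @property
    def total_length(self) -> int:
        return sum(n for _, n in self.exons)

    def exon_bounds(self, exon_id: str) -> tuple[int, int]:
        """Concatenated-coordinate bounds of all segments with ``exon_id``."""
        pos, start, end = 0, None, None
        for eid, n in self.exons:
            if eid == exon_id:
                if start is None:
                    start = pos
                end = pos + n
            pos += n
        if start is None:
            raise AnnotationError(f"unknown exon id {exon_id!r}")
        return start, end


@dataclass(frozen=True)
class Insert:
    """Insert ``length`` nt into ``exon``.

    With ``new_id=None`` the host exon is enlarged (the inserted material
    becomes part of the exon, so a later skip of that exon removes it too,
    as happens when a mutated exon is skipped by the spliceosome).  With a
    ``new_id`` the insertion becomes its own segment inside the host exon and
    can be skipped independently.
    """
    length: int
    exon: str
    offset: int | None = None  # position within the exon; default: midpoint
    new_id: str | None = None


@dataclass(frozen=True)
class Skip:
    """Remove every segment carrying ``exon`` from the layout."""
    exon: str


Edit = Insert | Skip


def apply_edits(layout: ExonLayout, edits: Sequence[Edit]) -> ExonLayout:
    """Apply edits left to right, tracking primer positions."""
    current = layout
    for edit in edits:
        if isinstance(edit, Insert):
            current = _apply_insert(current, edit)
        elif isinstance(edit, Skip):
            current = _apply_skip(current, edit)
        else:
            raise AnnotationError(f"unknown edit type {type(edit).__name__}")
    return current


def _apply_insert(layout: ExonLayout, edit: Insert) -> ExonLayout:
    if edit.length <= 0:
        raise AnnotationError("insertion length must be positive")
    start, end = layout.exon_bounds(edit.exon)
    offset = (end - start) // 2 if edit.offset is None else edit.offset
    if not 0 <= offset <= end - start:
        raise AnnotationError("insertion offset outside exon")
    pos = start + offset
    exons: list[tuple[str, int]] = []
    cursor = 0
    done = False
    for eid, n in layout.exons:
        if not done and eid == edit.exon and cursor <= pos <= cursor + n:
            if edit.new_id is None:
                exons.append((eid, n + edit.length))
            else:
                left = pos - cursor
                if left:
                    exons.append((eid, left))
                exons.append((edit.new_id, edit.length))
                if n - left:
                    exons.append((eid, n - left))
            done = True
        else:
            exons.append((eid, n))
        cursor += n
    pl = layout.primer_left + (edit.length if layout.primer_left >= pos else 0)
    pr = layout.primer_right + (edit.length if layout.primer_right >= pos else 0)
    return ExonLayout(tuple(exons), pl, pr)


def _apply_skip(layout: ExonLayout, edit: Skip) -> ExonLayout:
    start, end = layout.exon_bounds(edit.exon)  # raises on unknown exon
    exons: list[tuple[str, int]] = []
    pl, pr = layout.primer_left, layout.primer_right
    cursor = 0
    for eid, n in layout.exons:
        if eid == edit.exon:
            if cursor <= pl < cursor + n or cursor < pr <= cursor + n:
                raise AnnotationError(
                    f"cannot skip exon {edit.exon!r}: it contains a primer, "
                    f"the amplicon is undefined"
                )
            if pl >= cursor + n:
                pl -= n
            if pr >= cursor + n:
                pr -= n
        else:
            exons.append((eid, n))
        cursor += n
    return ExonLayout(tuple(exons), pl, pr)


def amplicon_length(layout: ExonLayout, edits: Sequence[Edit] = ()) -> int:
    """RT-PCR amplicon size after applying ``edits`` to ``layout``."""
    edited = apply_edits(layout, edits)
    return edited.primer_right - edited.primer_left


def net_length_change(layout: ExonLayout, edits: Sequence[Edit]) -> int:
    """Net nt change of the transcript (not the amplicon) under ``edits``."""
    return apply_edits(layout, edits).total_length - layout.total_length


def check_in_frame(edits: Sequence[Edit], layout: ExonLayout) -> bool:
    """True iff the edits change the coding length by a multiple of 3."""
    return net_length_change(layout, edits) % 3 == 0


def secisbp2_exon12_14_layout() -> ExonLayout:
    """Synthetic exon-12/13/14 layout for SECISBP2 edit arithmetic.

    A three-exon stand-in (not real exon sequences or true exon lengths) with
    primers placed in exons 12 and 14 so that the control amplicon is 335 nt.
    Exon 13 is 24 nt (8 codons), so skipping it yields a 311-nt in-frame
    product, while a 181-nt insertion into exon 13 yields 516 nt out of frame.
    """
    return ExonLayout(
        exons=(("E12", 160), ("E13", 24), ("E14", 200)),
        primer_left=10,
        primer_right=345,
    )
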