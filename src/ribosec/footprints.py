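"""Footprint ingestion, length-class filtering, P/A-site assignment, RPM.

A ribosome-protected fragment (RPF) is summarized by its transcript, the
transcript coordinate of its 5'-most aligned nucleotide and its read length.
Two length classes carry ribosome-state information: big footprints of
28-29 nt (bRPF) come from ribosomes with an occupied A-site, small footprints
of 20-21 nt (sRPF) from ribosomes with an empty A-site.  The first nucleotide
of the P-site codon sits a fixed offset downstream of the footprint 5' end
(12 nt by default for all four retained lengths, so the A-site codon starts
15 nt from the 5' end).

Reading frame is reported relative to the annotated CDS as -1 / 0 / +1, where
frame -1 denotes a P-site residue of 2 mod 3 (equivalently +2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import pysam

from .annotation import TranscriptAnnotation

logger = logging.getLogger(__name__)

SRPF_LENGTHS = (20, 21)
BRPF_LENGTHS = (28, 29)
RETAINED_LENGTHS = SRPF_LENGTHS + BRPF_LENGTHS

#: Default 5'-end -> P-site offset, applied to every retained read length.
DEFAULT_OFFSETS: dict[int, int] = {length: 12 for length in RETAINED_LENGTHS}

#: A-site codon starts one codon (3 nt) past the P-site codon.
ASITE_SHIFT_NT = 3

#: Frame label from (psite_nt - cds_start) mod 3.
FRAME_FROM_RESIDUE = {0: 0, 1: 1, 2: -1}

MIN_READ_LENGTH = 15
MAX_READ_LENGTH = 45


class ConfigurationError(ValueError):
    """Missing or inconsistent pipeline configuration."""


@dataclass(frozen=True)
class Footprint:
    """One aligned ribosome-protected fragment in transcript space."""
    transcript_id: str
    five_prime: int          # transcript coordinate of 5'-most aligned nt
    read_length: int
    sample_id: str = "sample"


def size_class(read_length: int) -> str:
    """Classify a read length as ``sRPF`` (20-21), ``bRPF`` (28-29) or ``other``."""
    if read_length in SRPF_LENGTHS:
        return "sRPF"
    if read_length in BRPF_LENGTHS:
        return "bRPF"
    return "other"


@dataclass(frozen=True)
class SiteAssignment:
    """Derived P-site/A-site codon, frame and length class of one footprint.

    ``psite_codon``/``asite_codon``/``frame`` are ``None`` when the P-site
    falls outside the annotated CDS (or, for the A-site, past the last codon).
    """
    footprint: Footprint
    size_class: str
    in_cds: bool
    psite_nt: int
    psite_codon: int | None
    asite_codon: int | None
    frame: int | None


# ---------------------------------------------------------------------------
# Alignment ingestion
# ---------------------------------------------------------------------------

def read_alignments(path: str | Path,
                    annotations: Mapping[str, TranscriptAnnotation],
                    min_mapq: int = 10,
                    primary_only: bool = True,
                    unknown_reference: str = "error",
                    sample_id: str | None = None,
                    stats: dict | None = None) -> Iterator[Footprint]:
    """Stream footprints from a transcriptome-space SAM/BAM file.

    Unmapped and (with ``primary_only``) secondary records are dropped, as are
    records below ``min_mapq`` — the usual "unique primary high-quality"
    filter.  Records on reference sequences absent from ``annotations`` are
    skipped with a warning when ``unknown_reference='skip'`` and raise
    otherwise.  Drop counts are accumulated into ``stats`` when given and
    logged at the end of iteration.
    """
    if unknown_reference not in ("error", "skip"):
        raise ConfigurationError("unknown_reference must be 'error' or 'skip'")
    counts = stats if stats is not None else {}
    for key in ("total", "kept", "unmapped", "secondary", "low_mapq",
                "unknown_reference", "bad_length", "soft_clipped"):
        counts.setdefault(key, 0)
    label = sample_id if sample_id is not None else Path(path).stem
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as handle:
        for rec in handle:
            counts["total"] += 1
            if rec.is_unmapped:
                counts["unmapped"] += 1
                continue
            if primary_only and (rec.is_secondary or rec.is_supplementary):
                counts["secondary"] += 1
                continue
            if rec.mapping_quality < min_mapq:
                counts["low_mapq"] += 1
                continue
            ref = rec.reference_name
            if ref not in annotations:
                counts["unknown_reference"] += 1
                if unknown_reference == "error":
                    raise ConfigurationError(
                        f"alignment reference {ref!r} not in annotation set")
                logger.warning("skipping read on unknown reference %r", ref)
                continue
            cig = rec.cigartuples
            if cig and cig[0][0] == pysam.CSOFT_CLIP:
                # end-to-end alignments should not be clipped; the 5' end is
                # taken as the first aligned nt regardless
                counts["soft_clipped"] += 1
                logger.warning("5' soft clip on %s; using first aligned nt",
                               rec.query_name)
            read_length = rec.query_length or rec.infer_query_length() or 0
            if not MIN_READ_LENGTH <= read_length <= MAX_READ_LENGTH:
                counts["bad_length"] += 1
                continue
            counts["kept"] += 1
            yield Footprint(transcript_id=ref,
                            five_prime=rec.reference_start,
                            read_length=read_length,
                            sample_id=label)
    logger.info("read_alignments(%s): kept %d of %d records (%s)",
                path, counts["kept"], counts["total"],
                {k: v for k, v in counts.items()
                 if k not in ("total", "kept") and v})


def load_alignments(path: str | Path,
                    annotations: Mapping[str, TranscriptAnnotation],
                    **kwargs) -> tuple[list[Footprint], dict]:
    """Materialize :func:`read_alignments`, returning footprints and stats."""
    stats: dict = {}
    fps = list(read_alignments(path, annotations, stats=stats, **kwargs))
    return fps, stats


def filter_by_length(footprints: Iterable[Footprint]) -> list[Footprint]:
    """Retain only the informative length classes (20+21 and 28+29 nt)."""
    return [fp for fp in footprints if fp.read_length in RETAINED_LENGTHS]


# ---------------------------------------------------------------------------
# Site assignment
# ---------------------------------------------------------------------------

def assign_sites(footprint: Footprint,
                 offsets: Mapping[int, int],
                 annotation: TranscriptAnnotation) -> SiteAssignment:
    """Assign P-site/A-site codon and frame to a single footprint."""
    if footprint.read_length not in offsets:
        raise ConfigurationError(
            f"no P-site offset configured for read length "
            f"{footprint.read_length}")
    offset = offsets[footprint.read_length]
    psite_nt = footprint.five_prime + offset
    in_cds = annotation.cds_start <= psite_nt < annotation.cds_end
    if in_cds:
        residue = (psite_nt - annotation.cds_start) % 3
        codon = (psite_nt - annotation.cds_start) // 3
        asite = codon + 1 if codon + 1 <= annotation.n_codons - 1 else None
        frame = FRAME_FROM_RESIDUE[residue]
    else:
        codon = asite = frame = None
    return SiteAssignment(footprint=footprint,
                          size_class=size_class(footprint.read_length),
                          in_cds=in_cds, psite_nt=psite_nt,
                          psite_codon=codon, asite_codon=asite, frame=frame)


_RAW_COLUMNS = ["transcript_id", "five_prime", "read_length", "sample_id"]


def footprint_frame(footprints: Iterable[Footprint]) -> pd.DataFrame:
    """Tabulate footprints into the raw columns used by the bulk pipeline."""
    return pd.DataFrame(
        [(fp.transcript_id, fp.five_prime, fp.read_length, fp.sample_id)
         for fp in footprints],
        columns=_RAW_COLUMNS,
    )


def assignment_table(footprints: Iterable[Footprint] | pd.DataFrame,
                     annotations: Mapping[str, TranscriptAnnotation],
                     offsets: Mapping[int, int] | None = None) -> pd.DataFrame:
    """Vectorized site assignment for many footprints.

    Returns one row per footprint with columns ``transcript_id, gene,
    sample_id, read_length, size_class, five_prime, psite_nt, in_cds,
    psite_codon, asite_codon, frame``.  Codon and frame columns are NaN for
    footprints whose P-site falls outside the CDS; such footprints are
    excluded from codon-level metrics but retained here so the caller can
    decide the RPM denominator.
    """
    offsets = dict(DEFAULT_OFFSETS if offsets is None else offsets)
    if isinstance(footprints, pd.DataFrame):
        df = footprints.loc[:, _RAW_COLUMNS].copy()
    else:
        df = footprint_frame(footprints)
    lengths = set(df["read_length"].unique())
    missing = lengths - set(offsets)
    if missing:
        raise ConfigurationError(
            f"no P-site offset configured for read lengths {sorted(missing)}")
    unknown = set(df["transcript_id"].unique()) - set(annotations)
    if unknown:
        raise ConfigurationError(
            f"transcripts missing from annotation set: {sorted(unknown)[:5]}")

    df["size_class"] = df["read_length"].map(size_class)
    df["gene"] = df["transcript_id"].map(
        {t: a.gene for t, a in annotations.items()})
    offset_col = df["read_length"].map(offsets)
    df["psite_nt"] = df["five_prime"] + offset_col

    cds_start = df["transcript_id"].map(
        {t: a.cds_start for t, a in annotations.items()})
    cds_end = df["transcript_id"].map(
        {t: a.cds_end for t, a in annotations.items()})
    rel = df["psite_nt"] - cds_start
    df["in_cds"] = (df["psite_nt"] >= cds_start) & (df["psite_nt"] < cds_end)

    codon = np.floor_divide(rel.to_numpy(), 3).astype(float)
    residue = np.mod(rel.to_numpy(), 3)
    frame = np.where(residue == 2, -1, residue).astype(float)
    n_codons = (cds_end - cds_start).to_numpy() // 3
    asite = codon + 1
    asite[asite > n_codons - 1] = np.nan

    out = ~df["in_cds"].to_numpy()
    codon[out] = np.nan
    frame[out] = np.nan
    asite[out] = np.nan
    df["psite_codon"] = codon
    df["asite_codon"] = asite
    df["frame"] = frame
    return df[["transcript_id", "gene", "sample_id", "read_length",
               "size_class", "five_prime", "psite_nt", "in_cds",
               "psite_codon", "asite_codon", "frame"]]


# ---------------------------------------------------------------------------
# Normalization and coverage profiles
# ---------------------------------------------------------------------------

def mapped_totals(assignments: pd.DataFrame) -> pd.Series:
    """Per-sample RPM denominator: length-filtered reads with an in-CDS P-site.

    Whether UTR-mapped footprints should count toward the library size is not
    settled; this package counts only in-CDS P-sites, and that choice is
    recorded in output metadata by the CLI.
    """
    in_cds = assignments[assignments["in_cds"]]
    return in_cds.groupby("sample_id").size()


def rpm_normalize(count: float, total_mapped: float) -> float:
    """Reads-per-million: ``count * 1e6 / total_mapped``."""
    if total_mapped <= 0:
        raise ValueError("RPM undefined: total mapped reads must be > 0")
    return count * 1e6 / total_mapped


@dataclass
class CoverageProfile:
    """Per-nt RPM along one transcript, with its cumulative sum."""
    transcript_id: str
    label: str
    rpm: np.ndarray
    cumulative: np.ndarray
    sec_positions_nt: tuple[int, ...] = ()

    def plot(self, ax=None):
        """Plot the profile with its cumulative sum; UGA/Sec marked by 'x'."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(len(self.rpm))
        ax.plot(x, self.rpm, lw=0.8, label=self.label)
        for pos in self.sec_positions_nt:
            ax.plot([pos], [self.rpm[pos]], "x", color="black")
        twin = ax.twinx()
        twin.plot(x, self.cumulative, lw=0.8, ls="--", alpha=0.6)
        ax.set_xlabel("transcript position (nt)")
        ax.set_ylabel("RPM")
        twin.set_ylabel("cumulative RPM")
        return ax


def coverage_profile(assignments: pd.DataFrame,
                     annotation: TranscriptAnnotation,
                     sample_ids: Iterable[str],
                     totals: Mapping[str, float] | None = None,
                     label: str | None = None) -> CoverageProfile:
    """Mean per-nt P-site RPM profile over the replicates of one condition.

    Each replicate is normalized by its own mapped-read total (in-CDS reads
    by default) before averaging, as when plotting condition means.
    """
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise ValueError("at least one replicate is required")
    if totals is None:
        totals = mapped_totals(assignments).to_dict()
    sub = assignments[(assignments["transcript_id"] == annotation.transcript_id)
                      & assignments["in_cds"]]
    profiles = np.zeros((len(sample_ids), annotation.length))
    for i, sample in enumerate(sample_ids):
        counts = np.bincount(
            sub.loc[sub["sample_id"] == sample, "psite_nt"].astype(int),
            minlength=annotation.length)[:annotation.length]
        profiles[i] = counts * 1e6 / float(totals[sample])
    rpm = profiles.mean(axis=0)
    sec_nt = tuple(annotation.cds_start + 3 * i
                   for i in annotation.sec_codon_indices)
    return CoverageProfile(transcript_id=annotation.transcript_id,
                           label=label or "+".join(sample_ids),
                           rpm=rpm, cumulative=np.cumsum(rpm),
                           sec_positions_nt=sec_nt)
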