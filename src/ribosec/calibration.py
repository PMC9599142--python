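"""Start-codon metagene calibration of the 5'-end -> P-site offset.

When a ribosome initiates, its P-site sits on the start codon, so footprints
from initiating ribosomes have their 5' end a fixed distance upstream of the
annotated CDS start.  For each retained read length this module histograms
``cds_start - five_prime`` over a search window and takes the modal value as
the P-site offset for that length.  Elongating ribosomes on early codons
contribute satellite peaks 3 nt apart; the initiation peak dominates because
start codons carry excess ribosome density in real (and simulated) data.

Calibration is per length class, integer-valued, with ties broken toward the
smaller offset (the more conservative 5' placement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .annotation import TranscriptAnnotation
from .footprints import Footprint, RETAINED_LENGTHS, footprint_frame

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = (9, 14)
DEFAULT_OFFSET = 12
DEFAULT_MIN_FOOTPRINTS = 500


class CalibrationError(ValueError):
    """Not enough start-proximal footprints to calibrate an offset."""


@dataclass
class OffsetTable:
    """Per-read-length P-site offsets with metagene diagnostics.

    ``histograms`` holds the start-codon metagene counts (rows: read length,
    columns: candidate offset).  ``fallback_lengths`` lists lengths that had
    fewer than the required start-proximal footprints and were assigned the
    default offset instead of a measured one.
    """

    offsets: dict[int, int]
    histograms: pd.DataFrame | None = None
    fallback_lengths: tuple[int, ...] = ()

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"offsets": {int(k): int(v)
                                        for k, v in self.offsets.items()},
                            "fallback_lengths": [int(x) for x in
                                                 self.fallback_lengths]},
                           fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "OffsetTable":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(offsets={int(k): int(v)
                            for k, v in data["offsets"].items()},
                   fallback_lengths=tuple(data.get("fallback_lengths", ())))


def calibrate_psite_offset(footprints: Iterable[Footprint] | pd.DataFrame,
                           annotations: Mapping[str, TranscriptAnnotation],
                           window: tuple[int, int] = DEFAULT_WINDOW,
                           min_footprints: int = DEFAULT_MIN_FOOTPRINTS,
                           lengths: Iterable[int] = RETAINED_LENGTHS,
                           ) -> OffsetTable:
    """Determine the 5'-end -> P-site offset per read length.

    For each read length, counts footprints whose 5' end lies exactly ``d``
    nt upstream of an annotated start codon for every ``d`` in ``window``
    (inclusive), and returns the argmax.  A length with fewer than
    ``min_footprints`` start-proximal footprints falls back to the default
    offset of 12 nt and is flagged; if every length falls back, a
    :class:`CalibrationError` is raised instead.
    """
    lengths = sorted(set(int(x) for x in lengths))
    lo, hi = window
    if not 0 < lo <= hi:
        raise ValueError("invalid search window")
    if isinstance(footprints, pd.DataFrame):
        df = footprints
    else:
        df = footprint_frame(footprints)
    if df.empty:
        raise CalibrationError(
            "no footprints supplied; fall back to the default offset "
            f"{DEFAULT_OFFSET}")
    cds_start = df["transcript_id"].map(
        {t: a.cds_start for t, a in annotations.items()})
    d = cds_start - df["five_prime"]
    near = df.assign(d=d)
    near = near[(near["d"] >= lo) & (near["d"] <= hi)
                & near["read_length"].isin(lengths)]

    index = pd.Index(range(lo, hi + 1), name="offset")
    hist = (near.groupby(["read_length", "d"]).size()
            .unstack(fill_value=0)
            .reindex(index=lengths, columns=index, fill_value=0))

    offsets: dict[int, int] = {}
    fallback: list[int] = []
    for length in lengths:
        row = hist.loc[length]
        total = int(row.sum())
        if total < min_footprints:
            logger.warning(
                "read length %d: only %d start-proximal footprints "
                "(< %d); falling back to default offset %d",
                length, total, min_footprints, DEFAULT_OFFSET)
            offsets[length] = DEFAULT_OFFSET
            fallback.append(length)
            continue
        # idxmax scans ascending offsets, so ties resolve to the smaller one
        offsets[length] = int(row.idxmax())
    if len(fallback) == len(lengths):
        raise CalibrationError(
            "insufficient start-proximal footprints for every read length; "
            f"fall back to the default offset {DEFAULT_OFFSET}")
    return OffsetTable(offsets=offsets, histograms=hist,
                       fallback_lengths=tuple(fallback))
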