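"""Reading-frame composition around real and imaginary UGA/Sec codons.

Post-UGA frameshifting shows up as a drop of the frame-0 fraction among
footprints 3' of the UGA/Sec codon while the 5' side stays at the technical
baseline (incomplete 5' nuclease trimming puts a minority of footprints into
frames +1/-1 on both sides).  Frames are anchored at the P-site, pooled over
both footprint size classes.

The transcriptome-wide specificity control places an imaginary UGA at the
center codon of every non-selenoprotein transcript and compares the frame
composition of the two halves; under no frameshifting the two sides agree.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import TranscriptAnnotation

logger = logging.getLogger(__name__)

SIDES = ("5prime", "3prime")
#: Minimum footprints on a side for the fractions to be reported.
DEFAULT_MIN_COUNT = 20


class FramesError(ValueError):
    pass


def _fractions(frames: pd.Series, min_count: int) -> dict:
    n = int(len(frames))
    if n == 0 or n < min_count:
        if n:
            logger.debug("side with %d < %d footprints: fractions withheld",
                         n, min_count)
        return {"f_minus1": float("nan"), "f_0": float("nan"),
                "f_plus1": float("nan"), "n": n}
    return {"f_minus1": float((frames == -1).sum()) / n,
            "f_0": float((frames == 0).sum()) / n,
            "f_plus1": float((frames == 1).sum()) / n,
            "n": n}


def frame_fractions(assignments: pd.DataFrame,
                    annotation: TranscriptAnnotation,
                    pivot_codon: int,
                    side: str,
                    min_count: int = 0) -> dict:
    """Frame fractions among P-sites strictly on one side of a pivot codon.

    Footprints whose P-site codon equals the pivot are excluded from both
    sides.  Returns ``{"f_minus1", "f_0", "f_plus1", "n"}``; fractions are
    NaN when no (or fewer than ``min_count``) footprints fall on the side.
    """
    if side not in SIDES:
        raise FramesError(f"side must be one of {SIDES}")
    if not 0 <= pivot_codon <= annotation.n_codons - 1:
        raise FramesError("pivot codon outside the CDS")
    sub = assignments[
        (assignments["transcript_id"] == annotation.transcript_id)
        & assignments["in_cds"]]
    if side == "5prime":
        sel = sub["psite_codon"] < pivot_codon
    else:
        sel = sub["psite_codon"] > pivot_codon
    return _fractions(sub.loc[sel, "frame"], min_count)


def frame_table(assignments: pd.DataFrame,
                annotations: Mapping[str, TranscriptAnnotation],
                groups: Mapping[str, str] | None = None,
                min_count: int = DEFAULT_MIN_COUNT,
                pooled_label: str = "ALL") -> pd.DataFrame:
    """Per-gene and pooled frame fractions 5'/3' of each UGA/Sec codon.

    ``groups`` maps sample_id -> group label (e.g. condition); samples of a
    group are pooled.  The pooled row concatenates footprints over all
    selenoprotein genes, weighting each gene by its footprint count.
    Returns tidy rows ``(gene, group, side, f_minus1, f_0, f_plus1, n)``.
    """
    df = assignments[assignments["in_cds"]].copy()
    if groups is None:
        groups = {s: s for s in df["sample_id"].unique()}
    df["group"] = df["sample_id"].map(groups)
    rows = []
    for group, gdf in df.groupby("group"):
        pooled = {side: [] for side in SIDES}
        for ann in annotations.values():
            if not ann.sec_codon_indices:
                continue
            sub = gdf[gdf["transcript_id"] == ann.transcript_id]
            for uga in ann.sec_codon_indices:
                for side in SIDES:
                    sel = (sub["psite_codon"] < uga if side == "5prime"
                           else sub["psite_codon"] > uga)
                    frames = sub.loc[sel, "frame"]
                    pooled[side].append(frames)
                    rows.append({"gene": ann.gene, "group": group,
                                 "uga_index": uga, "side": side,
                                 **_fractions(frames, min_count)})
        for side in SIDES:
            frames = (pd.concat(pooled[side]) if pooled[side]
                      else pd.Series(dtype=float))
            rows.append({"gene": pooled_label, "group": group,
                         "uga_index": -1, "side": side,
                         **_fractions(frames, min_count)})
    return pd.DataFrame(rows)


def imaginary_uga_control(assignments: pd.DataFrame,
                          annotations: Mapping[str, TranscriptAnnotation],
                          exclude: Iterable[str] = (),
                          groups: Mapping[str, str] | None = None,
                          min_count: int = DEFAULT_MIN_COUNT,
                          ) -> pd.DataFrame:
    """Frame fractions around an imaginary center UGA on non-selenoproteins.

    Every transcript flagged as a selenoprotein, or whose gene appears in
    ``exclude``, is left out (and counted in the log).  For each remaining
    transcript the pivot is codon ``floor(n_codons / 2)`` of its CDS; frame
    fractions of the 5' and 3' halves are pooled over all transcripts.
    """
    exclude = set(exclude)
    df = assignments[assignments["in_cds"]].copy()
    if groups is None:
        groups = {s: s for s in df["sample_id"].unique()}
    df["group"] = df["sample_id"].map(groups)
    included, excluded = [], []
    pivots: dict[str, int] = {}
    for ann in annotations.values():
        if ann.is_selenoprotein or ann.gene in exclude \
                or ann.transcript_id in exclude:
            excluded.append(ann.transcript_id)
            continue
        included.append(ann.transcript_id)
        pivots[ann.transcript_id] = ann.n_codons // 2
    logger.info("imaginary-UGA control: %d transcripts pooled, %d excluded",
                len(included), len(excluded))
    if not included:
        raise FramesError("no non-selenoprotein transcripts to pool")
    df = df[df["transcript_id"].isin(included)]
    pivot_col = df["transcript_id"].map(pivots)
    rows = []
    for group, gdf in df.groupby("group"):
        piv = pivot_col.loc[gdf.index]
        for side in SIDES:
            sel = (gdf["psite_codon"] < piv if side == "5prime"
                   else gdf["psite_codon"] > piv)
            rows.append({"gene": "ALL_NONSEL", "group": group,
                         "uga_index": -1, "side": side,
                         **_fractions(gdf.loc[sel, "frame"], min_count)})
    return pd.DataFrame(rows)


def center_pivot(annotation: TranscriptAnnotation) -> int:
    """Imaginary-UGA pivot: floor of half the CDS codon count."""
    return annotation.n_codons // 2


def frameshift_contrast(table: pd.DataFrame,
                        ctl_group: str,
                        mut_group: str,
                        threshold: float = -0.15) -> pd.DataFrame:
    """Per-gene frameshift call from a :func:`frame_table` output.

    For each gene and condition, ``delta = f_0(3') - f_0(5')``; the gene is
    flagged as frameshifting when ``delta_mut - delta_ctl`` falls below
    ``threshold`` (a loss of in-frame footprints specific to the mutant and
    to the 3' side).  NaN fractions propagate to NaN deltas and an
    unflagged gene.
    """
    wide = table.pivot_table(index=["gene", "uga_index"],
                             columns=["group", "side"], values="f_0",
                             aggfunc="first")
    rows = []
    for (gene, uga), row in wide.iterrows():
        deltas = {}
        for group in (ctl_group, mut_group):
            try:
                deltas[group] = float(row[(group, "3prime")]
                                      - row[(group, "5prime")])
            except KeyError:
                deltas[group] = float("nan")
        diff = deltas[mut_group] - deltas[ctl_group]
        rows.append({"gene": gene, "uga_index": uga,
                     "delta_ctl": deltas[ctl_group],
                     "delta_mut": deltas[mut_group],
                     "difference": diff,
                     "frameshift_flag": bool(np.isfinite(diff)
                                             and diff < threshold)})
    return pd.DataFrame(rows)
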