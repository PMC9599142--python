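"""Per-gene recoding readouts: URE, dURE, 3'RPM, pUGA, A-site occupancies.

All metrics are computed from pooled sRPF+bRPF P-site assignments unless a
size class is requested explicitly.  Regions around a UGA/Sec codon at codon
index ``u`` are, in codon units:

* 5' region: codons ``1 .. u-1`` (start codon excluded),
* the UGA codon itself (belongs to neither region),
* 3' region: codons ``u+1 .. last sense codon``.

Readouts
--------
URE (UGA redefinition efficiency)
    ribosome density 3' of the UGA divided by density 5' of it, densities in
    reads per codon.  dURE = URE(mut) / URE(ctl); both are invariant to
    global rescaling of a sample's counts, hence to library size and to mRNA
    abundance.
3'RPM
    footprints strictly 3' of the UGA per million mapped reads; integrates
    readthrough and mRNA abundance, and can be divided by mRNA abundance
    (counts-per-million from a 3'-RNA-Seq table) to isolate readthrough.
pUGA
    RPM of footprints whose P-site codon is the UGA — a direct readout of
    successful Sec elongation, defined for every selenoprotein including
    those with the UGA close to the C-terminus; both size classes pooled.
A-site UGA occupancy
    RPM of bRPF (occupied A-site) or sRPF (empty A-site) whose A-site codon
    is the UGA; contrasts tRNA selection against stalling with an empty
    A-site.

Transcripts with several UGA/Sec codons are handled per UGA, with each UGA's
5'/3' regions bounded by its neighboring UGAs; rows carry a ``multi_sec``
flag because most cell models express only single-Sec genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .annotation import TranscriptAnnotation
from .footprints import rpm_normalize, mapped_totals

logger = logging.getLogger(__name__)

#: A UGA qualifies as "internal" (far from the termination codon) when its
#: 3' region has at least this many codons; URE and 3'RPM panels are
#: restricted to internal UGAs, pUGA never is.
DEFAULT_MIN_THREE_PRIME_CODONS = 30


class MetricsError(ValueError):
    pass


def sec_regions(annotation: TranscriptAnnotation,
                uga_index: int | None = None,
                trim: int = 0) -> tuple[range, int, range]:
    """Codon ranges ``(five_prime, uga, three_prime)`` around one UGA.

    For multi-Sec transcripts the regions are bounded by the neighboring
    UGA/Sec codons.  ``trim`` removes that many codons from the outer ends of
    both regions (initiation/termination ramps); 0 by default.
    """
    if not annotation.sec_codon_indices:
        raise MetricsError(f"{annotation.transcript_id} has no UGA/Sec codon")
    secs = annotation.sec_codon_indices
    if uga_index is None:
        if len(secs) > 1:
            raise MetricsError(
                f"{annotation.transcript_id} has {len(secs)} UGA/Sec codons; "
                "pass uga_index")
        uga_index = secs[0]
    if uga_index not in secs:
        raise MetricsError(f"codon {uga_index} is not an annotated UGA/Sec")
    pos = secs.index(uga_index)
    lo = secs[pos - 1] + 1 if pos > 0 else 1          # start codon excluded
    hi = secs[pos + 1] - 1 if pos + 1 < len(secs) else annotation.last_sense_codon
    five = range(lo + trim, uga_index)
    three = range(uga_index + 1, hi + 1 - trim)
    return five, uga_index, three


def _gene_assignments(assignments: pd.DataFrame,
                      annotation: TranscriptAnnotation) -> pd.DataFrame:
    sub = assignments[(assignments["transcript_id"] == annotation.transcript_id)
                      & assignments["in_cds"]]
    return sub


def region_counts(assignments: pd.DataFrame,
                  annotation: TranscriptAnnotation,
                  uga_index: int | None = None,
                  trim: int = 0) -> dict:
    """Pooled P-site counts in the 5' region, on the UGA, and 3' of it."""
    five, uga, three = sec_regions(annotation, uga_index, trim)
    codons = _gene_assignments(assignments, annotation)["psite_codon"]
    return {
        "counts_5prime": int(((codons >= five.start)
                              & (codons < five.stop)).sum()),
        "counts_uga": int((codons == uga).sum()),
        "counts_3prime": int(((codons >= three.start)
                              & (codons < three.stop)).sum()),
        "len_5prime": len(five),
        "len_3prime": len(three),
    }


def ure_from_counts(counts_5prime: int, counts_3prime: int,
                    len_5prime: int, len_3prime: int) -> float:
    """URE from raw region counts; NaN when the 5' density is undefined/zero."""
    if len_5prime <= 0 or len_3prime <= 0 or counts_5prime == 0:
        return float("nan")
    return (counts_3prime / len_3prime) / (counts_5prime / len_5prime)


def ure(assignments: pd.DataFrame,
        annotation: TranscriptAnnotation,
        uga_index: int | None = None,
        trim: int = 0) -> float:
    """UGA redefinition efficiency: 3' density over 5' density."""
    rc = region_counts(assignments, annotation, uga_index, trim)
    return ure_from_counts(rc["counts_5prime"], rc["counts_3prime"],
                           rc["len_5prime"], rc["len_3prime"])


def delta_ure(ure_mut: float, ure_ctl: float) -> float:
    """URE(mut) / URE(ctl); NaN (never infinity) when the control is 0/NaN."""
    if not np.isfinite(ure_mut) or not np.isfinite(ure_ctl) or ure_ctl == 0:
        return float("nan")
    return ure_mut / ure_ctl


def three_prime_rpm(assignments: pd.DataFrame,
                    annotation: TranscriptAnnotation,
                    total_mapped: float,
                    uga_index: int | None = None,
                    trim: int = 0) -> float:
    """RPM of P-site assignments strictly 3' of the UGA codon."""
    rc = region_counts(assignments, annotation, uga_index, trim)
    if rc["len_3prime"] == 0:
        logger.warning("%s: zero-length 3' region (UGA adjacent to stop)",
                       annotation.transcript_id)
    return rpm_normalize(rc["counts_3prime"], total_mapped)


def three_prime_rpm_per_mrna(three_prime_rpm_value: float,
                             mrna_abundance: float) -> float:
    """3'RPM divided by mRNA abundance (CPM); NaN at zero abundance."""
    if not np.isfinite(mrna_abundance) or mrna_abundance <= 0:
        return float("nan")
    return three_prime_rpm_value / mrna_abundance


def puga(assignments: pd.DataFrame,
         annotation: TranscriptAnnotation,
         total_mapped: float,
         uga_index: int | None = None) -> float:
    """RPM of pooled-size footprints whose P-site codon is the UGA/Sec."""
    _, uga, _ = sec_regions(annotation, uga_index)
    codons = _gene_assignments(assignments, annotation)["psite_codon"]
    return rpm_normalize(int((codons == uga).sum()), total_mapped)


def asite_uga_occupancy(assignments: pd.DataFrame,
                        annotation: TranscriptAnnotation,
                        total_mapped: float,
                        size_class: str,
                        uga_index: int | None = None) -> float:
    """RPM of footprints of one size class with the UGA/Sec in the A-site.

    ``size_class='bRPF'`` counts ribosomes that have selected a tRNA at the
    UGA, ``'sRPF'`` ribosomes stalled with an empty A-site.
    """
    if size_class not in ("sRPF", "bRPF"):
        raise MetricsError("size_class must be 'sRPF' or 'bRPF'")
    _, uga, _ = sec_regions(annotation, uga_index)
    sub = _gene_assignments(assignments, annotation)
    count = int(((sub["asite_codon"] == uga)
                 & (sub["size_class"] == size_class)).sum())
    return rpm_normalize(count, total_mapped)


def correlate(metric_x: Sequence[float], metric_y: Sequence[float],
              log: bool = True, min_n: int = 3) -> float:
    """Pearson R across genes, on log10 values by default.

    Gene pairs with a non-finite (or, under log, non-positive) value are
    dropped; fewer than ``min_n`` remaining pairs yields NaN.
    """
    x = np.asarray(metric_x, dtype=float)
    y = np.asarray(metric_y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if log:
        keep &= (x > 0) & (y > 0)
    x, y = x[keep], y[keep]
    if len(x) < min_n:
        return float("nan")
    if log:
        x, y = np.log10(x), np.log10(y)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Recoding table and condition contrasts
# ---------------------------------------------------------------------------

def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per column of a gene x sample count table."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise MetricsError("mRNA count table has a sample with zero counts")
    return counts * 1e6 / totals


def read_mrna_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample count table (TSV, first column = gene)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def recoding_table(assignments: pd.DataFrame,
                   annotations: Mapping[str, TranscriptAnnotation],
                   mrna_cpm: pd.DataFrame | None = None,
                   totals: Mapping[str, float] | None = None,
                   min_three_prime_codons: int = DEFAULT_MIN_THREE_PRIME_CODONS,
                   trim: int = 0) -> pd.DataFrame:
    """Per (gene, sample, UGA) metric table over all selenoproteins.

    ``mrna_cpm`` is a gene x sample table of mRNA abundances in CPM; when
    given, ``three_prime_rpm_per_mrna`` is filled in.  ``internal_uga`` marks
    UGAs whose 3' region has at least ``min_three_prime_codons`` codons;
    URE/3'RPM panels conventionally restrict to those genes while pUGA is
    meaningful for all.
    """
    if totals is None:
        totals = mapped_totals(assignments).to_dict()
    rows = []
    samples = sorted(assignments["sample_id"].unique())
    for ann in annotations.values():
        if not ann.sec_codon_indices:
            continue
        multi = len(ann.sec_codon_indices) > 1
        for uga in ann.sec_codon_indices:
            for sample in samples:
                sub = assignments[assignments["sample_id"] == sample]
                total = float(totals[sample])
                rc = region_counts(sub, ann, uga, trim)
                t3 = three_prime_rpm(sub, ann, total, uga, trim)
                row = {
                    "gene": ann.gene,
                    "transcript_id": ann.transcript_id,
                    "sample_id": sample,
                    "uga_index": uga,
                    "multi_sec": multi,
                    "internal_uga": rc["len_3prime"] >= min_three_prime_codons,
                    **rc,
                    "ure": ure_from_counts(rc["counts_5prime"],
                                           rc["counts_3prime"],
                                           rc["len_5prime"],
                                           rc["len_3prime"]),
                    "three_prime_rpm": t3,
                    "puga_rpm": puga(sub, ann, total, uga),
                    "asite_uga_rpm_b": asite_uga_occupancy(sub, ann, total,
                                                           "bRPF", uga),
                    "asite_uga_rpm_s": asite_uga_occupancy(sub, ann, total,
                                                           "sRPF", uga),
                }
                if mrna_cpm is not None and ann.gene in mrna_cpm.index:
                    ab = float(mrna_cpm.loc[ann.gene, sample])
                    row["mrna_abundance"] = ab
                    row["three_prime_rpm_per_mrna"] = \
                        three_prime_rpm_per_mrna(t3, ab)
                else:
                    row["mrna_abundance"] = float("nan")
                    row["three_prime_rpm_per_mrna"] = float("nan")
                rows.append(row)
    return pd.DataFrame(rows)


def compare_conditions(recoding: pd.DataFrame,
                       conditions: Mapping[str, str],
                       metric: str,
                       contrast: tuple[str, str] = ("mut", "ctl"),
                       ) -> pd.DataFrame:
    """Per-gene condition contrast of one metric with BH-adjusted q values.

    ``conditions`` maps sample_id -> condition label.  Per gene (and UGA), a
    two-sided Welch t-test compares per-replicate metric values between the
    two conditions; p values are Benjamini-Hochberg adjusted across genes.
    With a single replicate in either condition only the fold change is
    reported and p/q are NaN.  The URE metric additionally yields
    ``delta_ure`` = mean URE(mut) / mean URE(ctl).
    """
    mut_label, ctl_label = contrast
    df = recoding.copy()
    df["condition"] = df["sample_id"].map(conditions)
    rows = []
    for (gene, uga), grp in df.groupby(["gene", "uga_index"]):
        mut = grp.loc[grp["condition"] == mut_label, metric].astype(float)
        ctl = grp.loc[grp["condition"] == ctl_label, metric].astype(float)
        mut, ctl = mut[np.isfinite(mut)], ctl[np.isfinite(ctl)]
        mean_mut = float(mut.mean()) if len(mut) else float("nan")
        mean_ctl = float(ctl.mean()) if len(ctl) else float("nan")
        fold = (mean_mut / mean_ctl
                if np.isfinite(mean_ctl) and mean_ctl != 0 else float("nan"))
        if len(mut) >= 2 and len(ctl) >= 2:
            values = np.concatenate([mut, ctl])
            if np.allclose(values, values[0]):
                p = 1.0  # no signal at all
            else:
                p = float(sps.ttest_ind(mut, ctl, equal_var=False).pvalue)
        else:
            p = float("nan")
        row = {"gene": gene, "uga_index": uga,
               f"mean_{mut_label}": mean_mut, f"mean_{ctl_label}": mean_ctl,
               "fold_change": fold, "p_value": p,
               "n_mut": len(mut), "n_ctl": len(ctl)}
        if metric == "ure":
            row["delta_ure"] = delta_ure(mean_mut, mean_ctl)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q_value"] = float("nan")
    ok = out["p_value"].notna()
    if ok.any():
        out.loc[ok, "q_value"] = multipletests(
            out.loc[ok, "p_value"], method="fdr_bh")[1]
    return out
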