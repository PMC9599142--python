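"""Synthetic transcriptomes and footprint experiments with ground truth.

The generative model follows the decision tree of a ribosome reaching a
UGA/Sec codon: with probability ``readthrough`` (r) it incorporates Sec and
elongates into the 3' part of the CDS; otherwise it terminates and leaves no
footprints 3' of the UGA.  Termination can entail mRNA surveillance, modeled
statically as an ``nmd_depletion`` factor scaling the whole transcript's
footprint density and mRNA abundance.  Ribosomes dwelling at the UGA with an
empty A-site (no Sec-tRNA recruited) produce extra small footprints (sRPF)
in proportion to ``stall_weight``, while ribosomes that have selected the
tRNA produce big footprints (bRPF) with the UGA in the A-site in proportion
to r.  A ribosome that continues past the UGA may shift permanently into the
+1 or -1 register with probabilities ``f_plus1``/``f_minus1``.

Footprint geometry: the 5' end is cut ``offset`` nt upstream of the P-site
codon, with probability ``jitter`` mis-cut by +-1 nt; big footprints are
28-29 nt, small ones 20-21 nt; away from the UGA a fraction
``empty_a_frac`` of elongating ribosomes is captured with an empty A-site
(sRPF).  Start codons carry ``init_peak_weight``-fold excess density, the
initiation peak that anchors offset calibration.  Misreading by near-cognate
tRNAs is observationally identical to readthrough in footprint space and is
not modeled separately; drop-off/no-Go decay leaves no distinct footprint
signature and is subsumed in 1 - r.

Every emitted footprint is bookkept, so simulator truth and output agree
exactly and every downstream metric can be tested by parameter recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam
import yaml

from .annotation import (SEC_CODON, STOP_CODONS, TranscriptAnnotation,
                         write_annotation_tsv, write_fasta)
from .footprints import Footprint, assignment_table, size_class

logger = logging.getLogger(__name__)

_BASES = "ACGT"
#: All 61 sense codons; using only these for random CDS positions guarantees
#: no spurious in-frame UGA (or other stop) ever appears.
SENSE_CODONS = tuple(a + b + c
                     for a in _BASES for b in _BASES for c in _BASES
                     if a + b + c not in STOP_CODONS)


class SimulationError(ValueError):
    pass


def _check_prob(name: str, value: float) -> None:
    if not 0 <= value <= 1:
        raise SimulationError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class GeneParams:
    """Per-gene generative parameters.

    ``n_codons`` counts CDS codons including start and stop;
    ``sec_codon_index`` is the UGA/Sec codon index (None for a
    non-selenoprotein).  ``base_density`` is the expected number of
    footprints per codon 5' of the UGA; ``mrna_level`` the expected mRNA
    count before NMD depletion.
    """
    name: str
    n_codons: int
    sec_codon_index: int | None = None
    utr5_len: int = 30
    utr3_len: int = 30
    base_density: float = 2.0
    readthrough: float = 1.0
    stall_weight: float = 0.0
    nmd_depletion: float = 1.0
    f_plus1: float = 0.0
    f_minus1: float = 0.0
    mrna_level: float = 100.0

    def __post_init__(self) -> None:
        if self.n_codons < 3:
            raise SimulationError(f"{self.name}: need at least 3 codons")
        for prob in ("readthrough", "f_plus1", "f_minus1"):
            _check_prob(f"{self.name}.{prob}", getattr(self, prob))
        if self.f_plus1 + self.f_minus1 > 1:
            raise SimulationError(
                f"{self.name}: f_plus1 + f_minus1 must be <= 1")
        if not 0 < self.nmd_depletion <= 1:
            raise SimulationError(f"{self.name}: nmd_depletion in (0, 1]")
        if self.base_density < 0 or self.stall_weight < 0:
            raise SimulationError(f"{self.name}: densities must be >= 0")
        if self.sec_codon_index is not None and not (
                0 < self.sec_codon_index < self.n_codons - 1):
            raise SimulationError(
                f"{self.name}: sec_codon_index {self.sec_codon_index} out of "
                f"range for {self.n_codons} codons")


@dataclass(frozen=True)
class SimParams:
    """Global simulation parameters plus the gene roster."""
    genes: tuple[GeneParams, ...]
    b_lengths: tuple[int, ...] = (28, 29)
    s_lengths: tuple[int, ...] = (20, 21)
    empty_a_frac: float = 0.15
    jitter: float = 0.0
    offset: int = 12
    init_peak_weight: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if not self.genes:
            raise SimulationError("at least one gene is required")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise SimulationError("gene names must be unique")
        _check_prob("empty_a_frac", self.empty_a_frac)
        _check_prob("jitter", self.jitter)
        if self.offset <= 0:
            raise SimulationError("offset must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimParams":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        genes = tuple(GeneParams(**g) for g in data.pop("genes"))
        for key in ("b_lengths", "s_lengths"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(genes=genes, **data)


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

def simulate_transcriptome(params: SimParams,
                           rng: np.random.Generator | None = None,
                           ) -> tuple[dict[str, TranscriptAnnotation],
                                      dict[str, str]]:
    """Random transcript sequences and annotations for the gene roster.

    Each CDS starts with ATG, ends with TAA, and draws internal codons from
    the 61 sense codons, so the only in-frame UGA is the one placed at the
    requested Sec codon index.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    annotations: dict[str, TranscriptAnnotation] = {}
    sequences: dict[str, str] = {}
    for g in params.genes:
        codons = ["ATG"] + [SENSE_CODONS[i] for i in
                            rng.integers(0, len(SENSE_CODONS),
                                         size=g.n_codons - 2)] + ["TAA"]
        if g.sec_codon_index is not None:
            codons[g.sec_codon_index] = SEC_CODON
        utr5 = "".join(_BASES[i] for i in rng.integers(0, 4, size=g.utr5_len))
        utr3 = "".join(_BASES[i] for i in rng.integers(0, 4, size=g.utr3_len))
        seq = utr5 + "".join(codons) + utr3
        ann = TranscriptAnnotation(
            transcript_id=g.name, gene=g.name, length=len(seq),
            cds_start=g.utr5_len, cds_end=g.utr5_len + 3 * g.n_codons,
            sec_codon_indices=(() if g.sec_codon_index is None
                               else (g.sec_codon_index,)),
            sequence=seq)
        annotations[g.name] = ann
        sequences[g.name] = seq
    return annotations, sequences


# ---------------------------------------------------------------------------
# Footprints
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """One simulated footprint library with per-footprint ground truth.

    ``table`` has one row per emitted footprint: transcript, true P-site
    codon, true frame, ribosome kind (``elong``, ``puga``, ``wait_b``,
    ``wait_s``), region relative to the UGA (``five``/``uga``/``three``, or
    ``cds`` for genes without one), size class, read length and 5' end.
    """
    params: SimParams
    annotations: dict[str, TranscriptAnnotation]
    sequences: dict[str, str]
    sample_id: str
    table: pd.DataFrame
    dropped: dict[str, int]

    def __len__(self) -> int:
        return len(self.table)

    def raw_frame(self) -> pd.DataFrame:
        """Raw footprint columns for :func:`ribosec.footprints.assignment_table`."""
        out = self.table[["transcript_id", "five_prime", "read_length"]].copy()
        out["sample_id"] = self.sample_id
        return out

    def footprints(self) -> list[Footprint]:
        return [Footprint(t, int(f), int(l), self.sample_id)
                for t, f, l in zip(self.table["transcript_id"],
                                   self.table["five_prime"],
                                   self.table["read_length"])]

    def truth_summary(self) -> pd.DataFrame:
        """Exact counts by gene, region, ribosome kind, size class and frame."""
        return (self.table
                .groupby(["gene", "region", "kind", "size_class", "frame"])
                .size().rename("count").reset_index())

    def write_sam(self, path: str | Path) -> None:
        """Write the library as unspliced all-match SAM records, MAPQ 255."""
        header = {"HD": {"VN": "1.6", "SO": "unsorted"},
                  "SQ": [{"SN": tid, "LN": ann.length}
                         for tid, ann in self.annotations.items()]}
        tid_index = {tid: i for i, tid in enumerate(self.annotations)}
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for i, row in enumerate(self.table.itertuples(index=False)):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = f"{self.sample_id}.{i}"
                rec.flag = 0
                rec.reference_id = tid_index[row.transcript_id]
                rec.reference_start = int(row.five_prime)
                rec.mapping_quality = 255
                rec.cigartuples = [(pysam.CMATCH, int(row.read_length))]
                seq = self.sequences[row.transcript_id]
                rec.query_sequence = seq[int(row.five_prime):
                                         int(row.five_prime)
                                         + int(row.read_length)]
                out.write(rec)


def simulate_footprints(annotations: Mapping[str, TranscriptAnnotation],
                        params: SimParams,
                        rng: np.random.Generator | None = None,
                        sample_id: str = "sim",
                        sequences: Mapping[str, str] | None = None,
                        ) -> SimResult:
    """Draw one footprint library under the generative model.

    Per-codon footprint counts are Poisson around the effective density
    ``base_density * nmd_depletion`` (times ``readthrough`` at and 3' of the
    UGA, times ``init_peak_weight`` on the start codon); UGA-proximal
    ribosome states and frameshifts are drawn per footprint as described in
    the module docstring.  Footprints that would protrude beyond the
    transcript ends are dropped and counted per gene in ``dropped``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if sequences is None:
        sequences = {t: a.sequence for t, a in annotations.items()
                     if a.sequence is not None}
    genes = {g.name: g for g in params.genes}
    missing = set(genes) - set(annotations)
    if missing:
        raise SimulationError(f"genes without annotation: {sorted(missing)}")
    b_lengths = np.asarray(params.b_lengths)
    s_lengths = np.asarray(params.s_lengths)
    pieces = []
    dropped: dict[str, int] = {}
    for name, g in genes.items():
        ann = annotations[name]
        d_eff = g.base_density * g.nmd_depletion
        n_sense = ann.n_codons - 1
        u = g.sec_codon_index
        lam = np.full(n_sense, d_eff)
        lam[0] *= params.init_peak_weight
        if u is not None:
            lam[u:] = d_eff * g.readthrough
        counts = rng.poisson(lam)
        codons = np.repeat(np.arange(n_sense), counts)
        kind = np.full(len(codons), "elong", dtype=object)
        if u is not None:
            kind[codons == u] = "puga"
            n_wait_b = rng.poisson(d_eff * g.readthrough)
            n_wait_s = rng.poisson(d_eff * g.stall_weight)
            codons = np.concatenate([
                codons, np.full(n_wait_b + n_wait_s, u - 1)])
            kind = np.concatenate([
                kind, np.array(["wait_b"] * n_wait_b + ["wait_s"] * n_wait_s,
                               dtype=object)])
        n = len(codons)
        state_b = rng.random(n) < (1 - params.empty_a_frac)
        state_b[kind == "wait_b"] = True
        state_b[kind == "wait_s"] = False
        # permanent register change for ribosomes that continued past the UGA
        adj = np.zeros(n, dtype=np.int64)
        if u is not None and (g.f_plus1 > 0 or g.f_minus1 > 0):
            three = codons > u
            draw = rng.random(n)
            adj[three & (draw < g.f_plus1)] = 1           # frame +1
            adj[three & (draw >= g.f_plus1)
                & (draw < g.f_plus1 + g.f_minus1)] = 2    # frame -1
        frame = np.where(adj == 2, -1, adj)
        psite_nt = ann.cds_start + 3 * codons + adj
        jit = np.zeros(n, dtype=np.int64)
        if params.jitter > 0:
            jmask = rng.random(n) < params.jitter
            jit[jmask] = rng.choice([-1, 1], size=int(jmask.sum()))
        five_prime = psite_nt - params.offset + jit
        length = np.where(state_b,
                          rng.choice(b_lengths, size=n),
                          rng.choice(s_lengths, size=n))
        ok = (five_prime >= 0) & (five_prime + length <= ann.length)
        dropped[name] = int((~ok).sum())
        if u is None:
            region = np.full(n, "cds", dtype=object)
        else:
            region = np.where(codons < u, "five",
                              np.where(codons == u, "uga", "three"))
        pieces.append(pd.DataFrame({
            "transcript_id": name,
            "gene": name,
            "psite_codon": codons[ok],
            "frame": frame[ok],
            "kind": kind[ok],
            "region": region[ok],
            "size_class": np.where(state_b[ok], "bRPF", "sRPF"),
            "read_length": length[ok],
            "five_prime": five_prime[ok],
        }))
    table = pd.concat(pieces, ignore_index=True)
    total_drop = sum(dropped.values())
    if total_drop:
        logger.info("dropped %d footprints protruding past transcript ends",
                    total_drop)
    return SimResult(params=params, annotations=dict(annotations),
                     sequences=dict(sequences), sample_id=sample_id,
                     table=table, dropped=dropped)


# ---------------------------------------------------------------------------
# Ready-made two-condition archetype panel
# ---------------------------------------------------------------------------

def _panel_gene_params() -> dict[str, list[GeneParams]]:
    """Gene roster spanning the selenoprotein archetypes, per condition.

    Archetypes (``*L`` = "-like", all synthetic): NMD-sensitive genes losing
    both mRNA and footprints in the mutant (GPX1L, SELWL), NMD-resistant
    genes losing readthrough but not mRNA (GPX4L, SEPHS2L), stall-prone
    genes whose empty-A-site occupancy rises (SELHL, SELOL), frameshift-prone
    genes (SELWL strongly, SELFL moderately, with a mild control-condition
    rate in SELWL), near-C-terminal UGA genes where URE is not reportable
    but pUGA is (TXNRD1L, MSRB1L), an insensitive gene (MSRB1L), and four
    non-selenoprotein housekeeping genes (HK1-4) for the imaginary-UGA
    control.
    """
    # the housekeeping background carries most of the library, as the
    # non-selenoprotein transcriptome does in a real experiment, keeping
    # RPM denominators stable across conditions
    base = [
        GeneParams("HK1", 400, None, base_density=100.0, mrna_level=300),
        GeneParams("HK2", 300, None, base_density=90.0, mrna_level=200),
        GeneParams("HK3", 250, None, base_density=120.0, mrna_level=250),
        GeneParams("HK4", 200, None, base_density=70.0, mrna_level=150),
        GeneParams("GPX1L", 203, 49, base_density=60.0, mrna_level=400,
                   readthrough=0.85),
        GeneParams("GPX4L", 170, 46, base_density=50.0, mrna_level=250,
                   readthrough=0.85),
        GeneParams("SELWL", 88, 13, base_density=60.0, mrna_level=300,
                   readthrough=0.80, f_plus1=0.08),
        GeneParams("SELFL", 134, 60, base_density=40.0, mrna_level=200,
                   readthrough=0.80, f_plus1=0.02),
        GeneParams("TXNRD1L", 200, 197, base_density=40.0, mrna_level=220,
                   readthrough=0.90),
        GeneParams("SELHL", 122, 44, base_density=40.0, mrna_level=180,
                   readthrough=0.85, stall_weight=0.5),
        GeneParams("SELOL", 150, 100, base_density=40.0, mrna_level=160,
                   readthrough=0.85, stall_weight=0.5),
        GeneParams("SEPHS2L", 120, 60, base_density=40.0, mrna_level=240,
                   readthrough=0.85),
        GeneParams("MSRB1L", 117, 95, base_density=40.0, mrna_level=140,
                   readthrough=0.85),
    ]
    mut_overrides: dict[str, dict] = {
        "GPX1L": dict(readthrough=0.10, nmd_depletion=0.25),
        "GPX4L": dict(readthrough=0.25),
        "SELWL": dict(readthrough=0.30, f_plus1=0.55, nmd_depletion=0.50),
        "SELFL": dict(readthrough=0.35, f_plus1=0.30, nmd_depletion=0.80),
        "TXNRD1L": dict(readthrough=0.85),
        "SELHL": dict(readthrough=0.30, stall_weight=1.0),
        "SELOL": dict(readthrough=0.35, stall_weight=1.0),
        "SEPHS2L": dict(readthrough=0.20),
        "MSRB1L": dict(readthrough=0.80),
    }
    mut = [replace(g, **mut_overrides.get(g.name, {})) for g in base]
    return {"ctl": base, "mut": mut}


@dataclass
class PanelResult:
    """Two-condition, two-replicate archetype dataset with ground truth."""
    annotations: dict[str, TranscriptAnnotation]
    sequences: dict[str, str]
    sim_results: dict[tuple[str, int], SimResult]
    sample_sheet: pd.DataFrame
    mrna_counts: pd.DataFrame
    gene_params: dict[str, list[GeneParams]]
    seed: int

    @property
    def conditions(self) -> dict[str, str]:
        """sample_id -> condition map."""
        return dict(zip(self.sample_sheet["sample_id"],
                        self.sample_sheet["condition"]))

    def assignment_table(self, offsets: Mapping[int, int] | None = None
                         ) -> pd.DataFrame:
        frames = []
        for (cond, rep), res in self.sim_results.items():
            raw = res.raw_frame()
            frames.append(raw)
        raw = pd.concat(frames, ignore_index=True)
        return assignment_table(raw, self.annotations, offsets)

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for cond, genes in self.gene_params.items():
            for g in genes:
                rows.append({"condition": cond, **g.__dict__})
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, outdir / "transcripts.fa")
        write_annotation_tsv(self.annotations.values(),
                             outdir / "annotation.tsv")
        for (cond, rep), res in self.sim_results.items():
            res.write_sam(outdir / f"{cond}_rep{rep}.sam")
        self.sample_sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t",
                                 index=False)
        self.mrna_counts.to_csv(outdir / "mrna_counts.tsv", sep="\t")
        self.truth_table().to_csv(outdir / "truth.tsv", sep="\t", index=False)


def make_archetype_panel(seed: int = 0,
                          n_replicates: int = 2,
                          jitter: float = 0.10,
                          density_scale: float = 1.0) -> PanelResult:
    """Simulate the two-condition archetype panel with distinct replicate seeds.

    Returns annotations, sequences, one :class:`SimResult` per (condition,
    replicate), a sample sheet, a matched 3'-RNA-Seq-style mRNA count table
    (Poisson around ``mrna_level * nmd_depletion``), and the exact generative
    parameters as the truth table.
    """
    roster = _panel_gene_params()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 + 2 * n_replicates * len(roster))
    rng_tx = np.random.default_rng(children[0])
    rng_mrna = np.random.default_rng(children[1])

    def scaled(genes: list[GeneParams]) -> tuple[GeneParams, ...]:
        return tuple(replace(g, base_density=g.base_density * density_scale)
                     for g in genes)

    params_by_cond = {
        cond: SimParams(genes=scaled(genes), jitter=jitter, seed=seed)
        for cond, genes in roster.items()}
    annotations, sequences = simulate_transcriptome(
        params_by_cond["ctl"], rng_tx)

    sim_results: dict[tuple[str, int], SimResult] = {}
    sheet_rows = []
    mrna_cols = {}
    child_idx = 2
    for cond, params in params_by_cond.items():
        for rep in range(1, n_replicates + 1):
            sample = f"{cond}_rep{rep}"
            rng = np.random.default_rng(children[child_idx])
            child_idx += 1
            sim_results[(cond, rep)] = simulate_footprints(
                annotations, params, rng, sample_id=sample,
                sequences=sequences)
            sheet_rows.append({"sample_id": sample, "condition": cond,
                               "replicate": rep})
            mrna_cols[sample] = rng_mrna.poisson(
                [g.mrna_level * g.nmd_depletion for g in params.genes])
    gene_names = [g.name for g in params_by_cond["ctl"].genes]
    mrna_counts = pd.DataFrame(mrna_cols, index=pd.Index(gene_names,
                                                         name="gene"))
    return PanelResult(annotations=annotations, sequences=sequences,
                       sim_results=sim_results,
                       sample_sheet=pd.DataFrame(sheet_rows),
                       mrna_counts=mrna_counts,
                       gene_params=roster, seed=seed)
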