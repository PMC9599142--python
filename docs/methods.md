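# Methods

## Coordinate model

All analysis is in transcript space: 0-based, half-open coordinates on one
reference sequence per transcript (5′UTR | CDS | 3′UTR). Genome coordinates,
splice graphs and isoform handling are out of scope; the reader consumes
alignments made end-to-end against a transcriptome, filtered to unique
primary records above a MAPQ threshold (default 10). Sequences are
normalized to uppercase DNA (U→T) on read. The UGA/Sec codon is the codon
index within the CDS; codon 0 is the start codon and the terminal stop codon
is never a Sec codon, so `locate_sec_codons` scans in-frame TGAs strictly
before the terminator.

## Footprint geometry and site assignment

Read lengths 20+21 nt (sRPF, empty A-site) and 28+29 nt (bRPF, occupied
A-site) are retained; everything else is discarded after ingestion. The
P-site codon starts `offset` nt downstream of the footprint 5′ end — 12 nt
by default for all four lengths, with per-length overrides from calibration
— and the A-site codon is exactly one codon (3 nt) further, i.e. 15 nt from
the 5′ end at the default offset. Reading frame is the P-site residue mod 3,
labelled 0/+1/−1 with −1 ≡ residue 2; this makes the frame label a bijection
of residues. Footprints whose P-site falls outside the CDS are kept in the
assignment table but flagged, and are excluded from codon metrics.

**RPM denominator.** Reads-per-million uses, per sample, the number of
length-filtered, quality-filtered footprints whose P-site lies in any CDS.
Whether UTR-mapped footprints should count is genuinely ambiguous; the
in-CDS choice matches the counting universe used for the metrics themselves
and is recorded in the CLI's output metadata.

**Soft clips.** End-to-end alignments should not be clipped; if a 5′ soft
clip occurs, the 5′ end is taken as the first aligned nucleotide and a
warning is emitted.

## Offset calibration

For each read length, the calibrator histograms `cds_start − five_prime`
over a search window (default 9–14 nt, within the plausible range for these
chemistries) and takes the argmax; ties break toward the smaller offset (the
more conservative 5′ placement). Initiating ribosomes put their P-site on
the start codon, so the true offset is the dominant peak; elongating
ribosomes on codons 1, 2, … contribute satellite peaks 3 nt apart, which is
why the method relies on start codons carrying excess density (they do, in
real metagenes, and the simulator reproduces this with `init_peak_weight`).
A length class with fewer than 500 start-proximal footprints (configurable)
is assigned the default 12-nt offset and flagged rather than calibrated; if
every class is that sparse, calibration raises. Calibration is per length
class, integer-valued; no sub-nucleotide or weighted-centroid offsets, no
3′-end anchoring, no per-transcript offsets.

## Metric definitions and conventions

Regions around a UGA at codon *u*: 5′ region = codons 1..*u*−1 (start codon
excluded), 3′ region = *u*+1..last sense codon; the UGA belongs to neither.
Densities are reads per codon (URE is identical under per-nt densities since
region lengths cancel). URE is NaN — never infinity — when the 5′ region has
zero reads or a region has zero length; ΔURE likewise when the control URE
is 0 or undefined. An optional `trim` removes codons from the outer region
ends to avoid initiation/termination ramps; default 0.

"Far from the termination codon" is operationalized as: a UGA qualifies as
*internal* when its 3′ region has ≥ 30 codons (configurable). URE/3′RPM
panels conventionally restrict to internal UGAs; pUGA is reported for all.

mRNA abundance is counts-per-million from a 3′-RNA-Seq count table;
differential-expression-style normalization (dispersion modeling, shrinkage)
is deliberately out of scope.

Multi-Sec transcripts get one metric row per UGA, with regions bounded by
the neighboring UGAs; rows carry a `multi_sec` flag since typical cell
models express single-Sec genes and the per-UGA treatment is an extension.

Correlations across genes (e.g. pUGA vs 3′RPM) are Pearson on log10 values,
dropping non-positive entries; fewer than 3 genes gives NaN. Condition
contrasts use a two-sided Welch t-test on per-replicate metric values with
Benjamini–Hochberg correction across genes. With N = 2 replicates this is
reported but underpowered — the q values are flags, not hard filters — and
with a single replicate only the fold change is reported.

## Frame analysis

Frame fractions are computed from P-site frames (offsets are defined to the
P-site, so it is the natural anchor), pooling both size classes, among
footprints strictly 5′ or strictly 3′ of the pivot codon; footprints on the
pivot are excluded from both sides. A side with fewer than 20 footprints
(QC floor) reports its count but withholds fractions. Pooled rows
concatenate footprints across genes, i.e. genes are weighted by footprint
count. The imaginary-UGA control uses pivot = ⌊CDS codons / 2⌋ on every
transcript not flagged as a selenoprotein (plus any explicit exclusions).
The frameshift call per gene is Δ = f₀(3′) − f₀(5′) per condition;
a gene is flagged when Δ(mut) − Δ(ctl) < −0.15 by default (a
mutant-specific, 3′-specific loss of ≥15 percentage points of in-frame
footprints; configurable).

## Generative model of the simulator

Each gene draws per-codon footprint counts as Poisson around an effective
density `base_density × nmd_depletion` (NMD is a static depletion factor —
only its abundance consequence is observable in this data type). The start
codon carries `init_peak_weight`-fold density (default 5, a realistic
initiation peak and the anchor for calibration). At the UGA: a fraction
`readthrough` (r) of ribosomes elongates through (producing the pUGA mass
and the 3′ plateau at r times the 5′ density); ribosomes that selected the
tRNA dwell with the UGA in the A-site in proportion to r (bRPF), stalled
empty-A-site ribosomes in proportion to `stall_weight` (sRPF). Termination
and no-Go decay leave no distinct footprint and are subsumed in 1 − r;
misreading by near-cognate tRNAs is observationally identical to readthrough
in footprint space and is not modeled separately. A continuing ribosome
shifts permanently into +1/−1 with probabilities `f_plus1`/`f_minus1` at the
UGA passage, changing the P-site register for all 3′ positions. Away from
the UGA a fraction `empty_a_frac` (default 0.15; not an empirically anchored
value — real sRPF/bRPF ratios at ordinary codons are a free parameter) of
elongating footprints is captured as sRPF.

Footprint 5′ ends are cut `offset` nt (default 12) upstream of the P-site,
mis-cut by ±1 nt with probability `jitter` — this is the sole source of
off-frame footprints outside genuine frameshifting, mirroring incomplete
nuclease digestion. Lengths are drawn uniformly within the class (28/29 or
20/21). Footprints protruding past transcript ends are dropped and counted.
CDS sequences draw internal codons from the 61 sense codons, so no spurious
in-frame UGA can occur; output SAM is unspliced all-match, MAPQ 255, one
reference per transcript. Every emitted record is bookkept per gene, region,
ribosome kind, size class and frame, so truth and output agree exactly.

**What the simulator does not emulate:** sequencing errors, ligation and
nuclease sequence biases, ribosome collisions/queueing, codon-specific dwell
times, kinetic NMD, drop-off signatures, multi-isoform ambiguity. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated model, not robustness to every artifact of real libraries.

## The archetype panel

`make_archetype_panel` emits a 13-gene, two-condition (ctl/mut), two-
replicate dataset spanning the characteristic selenoprotein behaviors:
NMD-sensitive genes losing both mRNA and footprints in the mutant (GPX1L,
SELWL), NMD-resistant genes losing readthrough only (GPX4L, SEPHS2L),
stall-prone genes whose empty-A-site occupancy rises (SELHL, SELOL),
frameshift-prone genes (SELWL strongly with a mild control-condition rate,
SELFL moderately), near-C-terminal-UGA genes where URE is not reportable but
pUGA is (TXNRD1L, MSRB1L), and four non-selenoprotein housekeeping genes.
Two composition choices matter: the housekeeping background carries ~70% of
each library, as the non-selenoprotein transcriptome does in a real
experiment, which keeps RPM denominators stable across conditions; and
per-gene densities are set so selenoprotein genes receive tens of
UGA-proximal footprints per library, since per-gene statements are
meaningless at single-digit counts. Each replicate uses an independent
spawned seed; a fixed panel seed reproduces every file byte-identically.
Matching mRNA counts are Poisson around `mrna_level × nmd_depletion`.

## Problem sizes used in validation

Recovery experiments use 15–20 genes of 70–150 codons at per-codon densities
of 40–100 (libraries of roughly 5×10⁴–2.5×10⁵ footprints): readthrough is
recovered from pooled pUGA count ratios against a matched r = 1 library
(within ±0.05 over r ∈ {0, 0.25, 0.5, 0.75, 1}), the +1 frameshift
probability from pooled 3′ frame fractions (within ±0.03 over
f ∈ {0.1, 0.3, 0.5, 0.7}), and the stall-weight doubling from sRPF A-site
occupancy (±10%; this experiment sets `empty_a_frac` = 0 so the doubling is
not diluted by background empty-A capture — with background present the
measured occupancy is signal plus a constant floor). The imaginary-UGA null
uses 10⁵ footprints and bounds the 5′/3′ frame-0 difference below one
percentage point. Offset recovery uses ≥10⁴ footprints with 10% jitter and
holds for true offsets across the search window.

## Numerical and degenerate-input conventions

Undefined ratios are NaN, never ±inf; RPM with a zero denominator raises.
Calibration ties break toward smaller offsets. A UGA adjacent to the stop
codon yields a zero-length 3′ region: its 3′RPM is reported over whatever
codons exist (with a warning) and its URE is NaN. Identical replicate values
across both conditions give p = 1 by convention (a Welch test is undefined
at zero variance). Assignment-table codon/frame columns are floats with NaN
for out-of-CDS footprints; counts are exact integers throughout.
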