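# Methods

`editscan` re-implements, as a tested library and CLI, the analysis of a
targeted amplicon-resequencing study of A-to-I RNA recoding: barcoded
single-end amplicon reads are demultiplexed, trimmed, aligned to their
amplicon, piled up into per-site base counts, converted to editing levels,
filtered, and compared between a disease (AD) and control (NDC) cohort;
clustered sites are additionally phased per read into isoform abundances,
and editing-enzyme expression is quantified from qPCR CT values by ΔΔCT.
Because the original patient RNA is not available, a synthetic-data
generator plays the role of the sequencer; everything downstream of the
FASTQ is the analysis proper.

## Panel model

A panel is a set of editing sites, each tied to one amplicon insert (primers
included) and a 0-based offset into it. All inserts and offsets are stored
in transcript orientation, so the editable base is always `A` and an edited
read base is always `G`; genome strand is metadata only. Genomic positions
are 1-based, matching `Chr1:160302244`-style site labels. Clusters group
sites that share an amplicon and sit close enough to be covered — and hence
phased — by single reads.

The shipped fixture panel contains the five-site HTR2C cluster (sites A, B,
C′, C, D spanning 13 nt, placed in the codons of amino acids 157/159/161)
plus eight single-site amplicons with plausible gene labels. Its sequences
are deterministic pseudo-random stand-ins, not the real transcripts; the
HTR2C codon context (`ATA`·…·`AAT`·…·`ATA`) is real in the sense that it
reproduces the known recoding outcomes (unedited INI, fully edited VGV,
24 distinct isoforms from 32 mRNA states).

## Synthetic reads

Each (sample, amplicon) pair is one reaction cell. A simulated read is
`barcode(10 nt) + CS1 + insert + revcomp(CS2)`, in transcript orientation —
a deliberate simplification of the two-step fusion-PCR construct that keeps
the barcode at a fixed, known location.

* **Between-sample variability.** The editing level of sample *s* at a site
  is drawn from Beta(μκ, (1−μ)κ); disease samples use μ+δ (clipped).
  Defaults μ = 0.268, δ = −0.05, κ = 200 place the two cohorts at the
  reported hippocampal global means (26.8% vs 21.8%) with a between-sample
  SD of ≈3%, matching the reported ±3.5–4.5% spread. Per-read editing is
  Bernoulli given the sample level, so counts are beta-binomial across
  samples — the minimal model that makes the per-site t-test non-trivial.
* **Clustered sites.** A cluster may carry an explicit joint distribution
  over its 2^k on/off states (optionally jittered per sample by a Dirichlet
  with concentration 200). `htr2c_cluster_probs()` plants the observed
  isoform pattern: 45% unedited (INI) transcripts in controls vs 58% in
  disease, compensated by depletion of the edited VDV/VGV forms.
  Independent per-site Bernoulli editing is the default when no joint model
  is given; it cannot express this isoform-level effect, which is the point
  of the phasing analysis.
* **Errors.** Substitutions are uniform over the three alternative bases at
  rate 10⁻³/base. Indels occur only in homopolymer runs ≥ 2 nt (±1 base,
  probability 5·10⁻⁴ per run per read), mimicking flow-sequencing chemistry
  and exercising the aligner's gap handling. Qualities are Phred+33,
  N(32, 4) clipped to [20, 41], with a 5% fraction replaced by Q2–19 to
  exercise the pileup filter. No per-read error profile was published for
  the original runs; these defaults are stated, not inferred.
* **Depth.** 1000 reads per cell by default; exact when
  `depth_dispersion=0` and the mean is integral, gamma-Poisson otherwise.
* **Determinism.** All draws flow from one `numpy` Generator seeded by
  `config.seed`; identical configs give byte-identical FASTQ.

## Demultiplexing and trimming

Reads are assigned by their leading 10 nt against the sample sheet, exact
by default (`max_mismatch=0`); any positive radius first verifies that all
barcode pairs are > 2·radius apart, making assignment unambiguous.
Shipped sample sheets use barcodes at pairwise Hamming distance ≥ 3.
CS1/revcomp(CS2) are removed from the read ends by mismatch-tolerant
(≤10%), indel-free comparison; qualities are trimmed in register, reads
< 20 nt are dropped, and reads with no adapter match pass through flagged.

## Alignment and pileup

Reads are aligned only against the panel's inserts with a banded affine
semi-global dynamic program (read consumed in full, free end-gaps on the
amplicon): match +1, mismatch −3, gap open −3, gap extend −1. These
penalties mirror common short-read-mapper defaults for small-indel data;
the score floor (reject below half the read length) plays the role of a
mapping-quality threshold. The band half-width is
`band + |len(ref) − len(read)|//2 + 1` around the length-centered diagonal
(`band=16` by default, far above the simulated indel counts); scores are
verified against an unbanded full dynamic program in the test suite.
Traceback tie-breaks prefer aligned pairs, giving deterministic,
5′-shifted gap placement in homopolymers. Candidate amplicons are
preselected by exact 20-mer seeds sampled every 10 nt (exhaustive fallback
when nothing seeds); a score tie between the two best amplicons rejects
the read as multi-mapping, the small-panel analogue of discarding
multiply-aligned reads.

The pileup counts, per (sample, site), the read bases aligned to the site
column with base quality ≥ 20; columns deleted in a read contribute
nothing — one plausible convention where mpileup-style tools differ.

## Editing levels, filters, statistics

The editing level is nG/(nG+nA); C/T bases are noise and excluded from the
ratio. Cells with no A/G evidence are missing, never 0 — conflating them
would bias group means downward. The coverage filter (≥ 500 total
quality-filtered reads) applies to nA+nC+nG+nT; "coverage" could also be
read as A+G depth, so the threshold column is configurable. Sites are
retained, per tissue, only with ≥ 5 passing samples in each group.

Per-site differences use a two-sided two-sample t-test — Welch by default
(cohort sizes are unequal and the original report does not specify the
variant), Student by flag — with Benjamini–Hochberg correction at FDR 0.1
over the testable sites of one tissue; untestable sites (< 2 values in a
group) are excluded before correction. The global signal is each sample's
mean level over retained sites, compared between groups the same way.

## Isoform phasing

A read is phased over a cluster iff every cluster site is covered by an
aligned, non-deleted base with Q ≥ 20 that is A or G; anything else rejects
the read from phasing entirely (no partial imputation — the joint
distribution must not be biased by per-site fill-in). State counts per
sample give the variant spectrum; all 2^k states are retained in the output
(unobserved at abundance 0) and abundances sum to 1 exactly. The codon
model substitutes G at each edited site's codon position and translates
with the standard genetic code; the HTR2C map (A→157.1, B→157.3, C′→159.1,
C→159.2, D→161.1) is the unique assignment consistent with the known
single-edit substitutions I157→V/M, N159→S/D/G, I161→V.

Group comparison of abundances is a fixed-effects two-way ANOVA
(group × variant) with type-II sums of squares — appropriate for the
unbalanced cohorts; the SS type is a design choice here, unstated in the
original analysis — plus per-variant Welch contrasts as post-hoc tests.

## qPCR

CT triplicates are averaged (an optional rule drops the replicate farthest
from the median when the range exceeds a configurable number of cycles;
off by default). ΔCT = CT(target) − CT(SDHA); ΔΔCT subtracts the mean ΔCT
of the control samples of the same tissue; relative expression is
2^(−ΔΔCT), i.e. amplification efficiency is fixed at 2.0 (classical ΔΔCT;
efficiency correction is out of scope). Group comparison is a two-sided
Mann–Whitney U test: exact when both groups have ≤ 8 tie-free values,
normal approximation with tie correction otherwise.

## Validation strategy and problem sizes

The study's per-site tables depend on unavailable patient RNA, so the test
suite validates closed-form claims and statistical behaviour instead:

* combinatorics: 32 mRNA variants / 24 protein isoforms for HTR2C; a full
  48 × 48 design is exactly 2304 reaction cells;
* oracle equivalence: banded aligner vs unbanded dynamic program (1000
  error-injected reads), BH vs literal step-up enumeration (1000 random
  p-vectors), t/ANOVA/MW statistics vs hand formulas and exhaustive
  rank-assignment enumeration;
* parameter recovery: a full-pipeline run (10 amplicons × 48 samples at
  ~1000× with the default error model, ≈480k reads) keeps the planted
  level inside the estimate's 99% Clopper–Pearson interval for ≥95% of
  cells, and detects the planted hypo-editing;
* calibration: under δ = 0 (1000 level-resolution replicates × 20 sites)
  the t-test rejects at 5% within [0.03, 0.07] and the mean BH-significant
  fraction stays ≤ 0.1; with δ = −0.05 at n = 28/20 over 66 sites the
  global test detects hypo-editing at p < 0.05 in ≥ 90/100 replicates;
* ΔΔCT: a planted 2-fold change at CT noise SD 0.2, n = 10/10, is
  recovered within [1.7, 2.3] in ≥ 90/100 replicates.

Replicate counts and panel sizes for these checks were fixed once as the
smallest designs whose Monte-Carlo error is comfortably below the margins
being tested. Calibration and power checks run at the level of simulated
editing levels (the same Beta model the read generator uses) rather than
re-sequencing hundreds of millions of reads; the single full-pipeline run
above ties the read level to the level-resolution results.

## What the generator does not model

PCR amplification bias and chimeric reads; sample-level correlation of
editing across sites (each site's level is drawn independently, so the
global test is better powered here than on real data, where samples act as
repeated measures); cell-type composition shifts; SNP contamination at
panel sites (sites are pre-validated by construction); the three amplicons
the original study failed to amplify. Passing tests therefore demonstrate
correctness of the computations and calibration under the stated model,
not performance on post-mortem brain RNA.

## Known limitations

* The banded aligner assumes reads are near-full-length amplicon copies;
  fragments starting far from the insert ends need a wider `band`.
* Multi-mapping is defined as an exact top-two score tie on the panel —
  reasonable for dozens of well-separated amplicons, but panels with
  near-duplicate inserts deserve a score-margin rule instead.
* The exact Mann–Whitney branch requires tie-free data; tied small samples
  fall back to the corrected normal approximation.
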