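# Methods

## Coordinate model

All analysis happens in transcript space: 0-based, half-open offsets along
the mature transcript, with `[0, cds_start)` the 5′UTR,
`[cds_start, cds_end)` the CDS (stop codon included, matching BED
thick-interval practice) and `[cds_end, length)` the 3′UTR. BED12 input is
converted by summing block lengths up to the thick boundaries (both
strands supported); GTF (1-based, closed) is converted on read, taking the
coding interval as the union of `CDS` and `stop_codon` features. A CDS
whose length is not a multiple of 3 is kept but flagged. Gene-level values
use one canonical transcript per gene — the longest CDS, ties broken by
transcript id — since isoform-aware quantification is out of scope.

## Quantification

Reads shorter than 20 nt are removed. Each RPF is collapsed to its P-site,
inferred as the 5′ end plus a fixed offset (default 12 nt for every
length, overridable per length); 12 nt is the standard plus-strand offset
for ~30-nt mammalian footprints. Reads whose P-site falls off the
transcript are excluded from positional statistics. Library size for
RPKM/FPKM is the number of length-filtered reads assigned to any
transcript in that library, computed per sample. Translation efficiency is
the ratio of CDS-restricted Ribo-seq RPKM to whole-transcript RNA-seq
FPKM and is undefined (propagated as NaN, never an exception) below an
mRNA floor of FPKM ≥ 1; the floor guards against unstable ratios at low
expression. Replicates are quantified independently; condition values are
replicate means — with two replicates per arm, heavier per-gene modelling
is not attempted.

## Differential classification

At each level (mRNA FPKM, ribosome-footprint RPKM, TE) genes are
partitioned by the log2 ratio of condition means: up at ≥ +1, down at
≤ −1 (2-fold), unchanged otherwise. A pseudocount of 0.5 is added to both
condition means at the count-derived levels; the TE level uses the raw TE
ratio so that log2 ΔTE equals log2(ribo fold-change) − log2(RNA
fold-change) exactly. Genes below the floor in both conditions (TE:
undefined in either condition) are reported as *not assessed*, never
silently folded into "unchanged". No per-gene significance test gates the
calls (n = 2); an optional two-sample t-test on log values is available
for volcano-style output only.

Because RPKM is a relative measure, strong asymmetric translational
effects shift the library composition: when a subset of genes gains many
footprints, every other gene's RPKM falls slightly. This is visible in
simulations as a small negative baseline in log2 ΔTE and a surplus of
"down" calls at the footprint level. It is a property of the normalization
shared with the emulated analysis, not corrected for.

## 5′UTR index and group analyses

The 5′UTR index of a transcript is its 5′UTR RPF count over its total RPF
count; only transcripts with at least one 5′UTR read are analysed
(condition-level counts are replicate sums). The index change
(treatment − control, computed for transcripts passing the selection in
both conditions) is compared across TE classes with a one-way ANOVA.
Separately, transcripts are split at the median *control* index into
equal high_UTR / low_UTR halves — ordering by (index, transcript id), the
lower ⌈n/2⌉ records to low_UTR, so ties at the median fall to low_UTR
deterministically and group sizes differ by at most one — and log2 ΔTE is
compared between halves with a classical equal-variance t-test (Welch and
Mann–Whitney available by flag). When all values are identical the test
is degenerate: statistic and p-value are NaN with an explicit flag.

## uORF detection and shift scoring

A uORF is any AUG with position < cds_start (U and T equivalent), paired
with the first in-frame stop codon found scanning the whole transcript; a
uORF with no stop, or whose stop lies past cds_start, is flagged as
CDS-overlapping — the configuration that represses main-ORF translation
under delayed reinitiation. Only AUG starts are considered (near-cognate
starts are out of scope). The Kozak context is the classical two-position
rule — purine at −3 and G at +4 (first base after the AUG) — giving
strong / adequate / weak; a flank that runs off the sequence counts as
unsatisfied. Cap distance is the uAUG offset itself.

The shift score uses a pseudocount of 1 in both conditions,
`log2[(n_cds+1)/(n_utr5+1)]_treat − log2[(n_cds+1)/(n_utr5+1)]_ctrl`,
keeping ratios finite at zero 5′UTR counts and making the score exactly
antisymmetric under condition swap.

## Enrichment

Over-representation only: upper-tail hypergeometric P(X ≥ k) for a query
of n genes against a set with K members in a universe of N, BH-adjusted
across sets. The default universe is the genes with defined TE. No
ontology data ships with the package; gene sets are user-supplied GMT.

## Synthetic data generator

The generator emulates a two-arm (optionally three-arm) design: control,
treatment, and an optional reversal arm in which every effect size is
scaled by 1 − r (default r = 0.9) toward control. Defaults describe the
emulated study at desk scale: 1,000 genes, 2 conditions × 2 replicates,
2 × 10⁶ reads per library, NB dispersion 0.1.

*Architecture.* Lognormal region lengths (medians ≈ 180 nt 5′UTR,
≈ 1.1 kb CDS, ≈ 400 nt 3′UTR, with floors 60/300/60 nt), CDS forced to a
whole number of codons beginning AUG, free of internal in-frame stops and
ending with a stop. 20% of genes carry a planted uORF: an AUG written into
the 5′UTR with a requested Kozak class (40/30/30 strong/adequate/weak),
closed by an in-frame stop inside the UTR when room allows and left
CDS-overlapping otherwise. uORF genes have their basal TE multiplied by a
Kozak-dependent repression factor (0.5 / 0.7 / 0.85), encoding that
stronger uAUG context represses the main ORF more.

*Effects.* Disjoint gene sets: 10% TE-up and 10% TE-down at ±2 log2, 2%
RNA-up and 2% RNA-down at ±2 log2, and 10% occupancy-shift genes whose
5′UTR RPF occupancy moves 0.40 → 0.10 under treatment (other uORF genes
sit at 0.25 in both arms; background genes at 0.055, with 0.027 in the
3′UTR). Because expected CDS footprints are abundance × TE × CDS length ×
p_cds, the occupancy shift raises the measurable CDS-density TE of shift
genes by log2(0.873/0.573) ≈ 0.61 — the uORF-bypass signature — and the
truth table records this effective TE per condition.

*Counts.* Each biological replicate draws one gamma factor per gene
(shape 1/α, mean 1), shared between the RNA and RPF libraries of that
replicate because both are sequenced from the same lysate; reads are then
allocated by a single multinomial, so marginal gene counts are negative
binomial with dispersion α while each library totals exactly the
configured size. Sharing the factor makes TE estimates benefit from the
biological pairing, as in the real assay; library-specific noise enters
through the multinomial. RPF placement: region by the gene's occupancies,
frame 0 with probability 0.75 inside the CDS (frames 1 and 2 equal),
position uniform within the region, read length from {28…32} with mode
30; RNA reads are 50 nt, uniform over the transcript. Read starts are
clipped to the transcript; with ≥ 60 nt UTR floors and a 12 nt offset the
clipping never moves a P-site across a region boundary.

What the generator does **not** emulate: sequence-level reads (alignments
are emitted directly, so aligner bias, mismatches and multi-mapping are
absent), UMI/duplicate structure, nucleotide-resolution pause sites,
codon-level dwell times, GC bias, and isoform mixtures (one transcript
per gene). Passing recovery tests therefore validates the statistical
pipeline downstream of alignment, not the read-processing upstream of it.

*Determinism.* All randomness flows from one seed through spawned
`numpy` SeedSequences; the same config reproduces FASTA, alignments and
truth byte-for-byte.

## Problem sizes and numerical choices

The validation suite simulates at the default study scale (1,000 genes,
2M reads/library) for parameter recovery — Spearman(true, estimated TE),
classification sensitivity and null false-call rate — and at 500 genes ×
100k reads (≈ 200 RPFs/transcript) for shift-score ranking. The
directional high_UTR vs low_UTR ΔTE t-test is evaluated in a scenario
where the occupancy shift is the only translational effect: with the ±2
log2 TE effect sets present, their variance (per-group sd ≈ 0.9)
legitimately swamps the ≈ 0.12 mean signal of 100 shift genes and a
mean-based test is uninformative about the mechanism; the medians-ordering
check is still made under the all-effects default. Null calibration uses
1,000 replicate two-sample t-tests (n = 1,000 per group) against U(0,1)
and 500 random ORA queries for BH false-discovery control.

Ties and degenerate inputs are handled deterministically throughout:
median ties go to low_UTR; identical-value group comparisons are flagged
rather than erroring; zero-read transcripts are skipped with a log
notice; zero usable reads raise an explicit error instead of returning
NaN percentages.

## Known limitations

- Fold-change classification without a significance gate will over-call
  at shallow depth; the defaults assume ≥ 1M reads/library.
- P-site offsets are fixed per length, not learned from metagene
  periodicity.
- RPKM composition effects (above) are not corrected; comparisons between
  very asymmetric libraries inherit them.
- The uORF scanner reports all upstream AUGs; it does not model
  reinitiation efficiency or ribosome queueing, and near-cognate starts
  are excluded.
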