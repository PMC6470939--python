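# Methods

`xylomir` re-implements, as a tested pipeline, the bioinformatic core of a
xylem-sap small-RNA study design: three sRNA libraries (untreated 0 h `C0`,
untreated 1 h `C1`, Cd-treated 1 h `Cd1`) are processed into unique tags,
classified into miRNA classes with hairpin-structure support, tested for
Cd-responsive differential expression with exact 2x2 tests, scanned against a
transcriptome under two complementarity schemes, and the intersected target
sites are validated against degradome 5'-end tag libraries.  A synthetic-study
generator with full ground truth makes every stage testable without any
external download.

## Read processing

Reads are 3'-adapter trimmed (full adapter anywhere, or an adapter prefix of
at least `min_overlap` = 6 nt reaching the read end; mismatch rate <= 0.1;
inserts < 15 nt are discarded as dimers/junk), collapsed to unique tags with
per-library counts, and filtered: exact substring matches to a contaminant
reference set (either strand) emulate rRNA/tRNA/snRNA/snoRNA removal;
low-complexity tags are removed when a single base or a 2-periodic dinucleotide
pattern covers >= 80% of the tag; tags outside 18-30 nt are dropped.  The
stage keeps an exact per-library ledger (`reads_in == kept + no_adapter +
too_short + contaminant + low_complexity + out_of_range`).  Normalization is
reads-per-million of the post-filter library total.

Tag-to-reference matching replaces BLAST with a bounded-edit matcher: 5'/3'
end shifts up to 2 nt per side (extensions must be templated by the
precursor context) and at most one internal substitution; matches minimize
(substitutions, total shift) with ties broken by reference class (own species
before other monocots) then id.  Variant names follow the isomiR convention
`id[_L+-n][_R+-n][_kssPPXY]` and reconstruct the tag exactly.

## Hairpin folding (model SLF-1) and precursor evaluation

Candidate precursors are folded under a fixed, enumeration-testable
single-stem-loop model rather than a full nearest-neighbour thermodynamic
model: pair energies GC/CG -3.0, AT/TA -2.0, GT/TG -1.0; +3.0 for closing
the terminal loop (>= 3 nt); +0.5 per unpaired nucleotide interior to the
stem; dangling ends are free.  The minimum-energy structure over all stem
placements is found by an O(n^2) dynamic program (exact integer half-unit
arithmetic; ties resolved toward more pairs, then the lexicographically
smallest pair list) and is checked against direct O(n^4) recursion on short
sequences in the tests.  The folding backend is a pluggable callable, so a
thermodynamic folder can be substituted; everything shipped uses SLF-1.

MFE statistics follow the plant pre-miRNA literature: AMFE = -MFE/length x
100 and MFEI = AMFE / GC%, with the customary MFEI >= 0.85 confidence
threshold.

Each genome-mapped tag is evaluated in three windows (tag +- 120 nt; tag at
the window 5' end with 240 nt downstream; tag at the 3' end with 240 nt
upstream), because the mature may derive from either hairpin arm and the
spec's flank is one-sided in the worst case.  A window passes when the model
MFE <= -18, MFEI >= 0.85, and the mature/star duplex criteria hold; the best
passing window (lowest MFE) is reported.

**Duplex criteria are judged on a direct duplex alignment, not on the global
fold.**  Under SLF-1 the +0.5/nt bulge penalty is mild enough that a ~260-nt
window of *random* sequence folds into a long window-spanning bulged stem
(model MFE around -150 to -230); the global minimum-energy structure of a
window containing a genuine hairpin therefore often routes through flank
sequence and leaves the mature partially unpaired, and the MFE/MFEI
thresholds alone do not discriminate at this window size.  The duplex
criteria are instead evaluated on the best antiparallel alignment of the
mature against every non-overlapping candidate star segment in the window
(<= 2 bulged nucleotides per strand, >= 3 nt loop gap): mismatched mature
positions and bulged nucleotides on either strand count toward the unpaired
tally (<= 4 by default), and no bulge may exceed 2 nt — the standard plant
miRNA/miRNA* duplex convention.  `mature_on_one_arm` is true when such a
star partner exists; the arm (5p/3p) is the mature's side of that duplex.

## miRNA annotation

Tags of 20-22 nt are classified with a strict priority: (1) variant match to
an own-species mature -> `known`; (2) exact hit on the arm of an own
precursor opposite its annotated mature -> `novel_arm` (named
`PRECURSOR-p5/p3`); (3) variant match to an other-monocot mature or
precursor arm whose precursor is locatable in the own genome -> `homolog`;
(4) genome-mapped tags whose window passes the precursor evaluation ->
`novel_pc`, named `PC-{5p|3p}-{serial}_{total raw count}` with serials
assigned in genome-position order so runs are reproducible.  Every tag
receives exactly one class or one drop reason (partition checked in tests).

The high-confidence filter keeps records with normalized count >= 10 in at
least one library (inclusive, which is what makes a table containing rows
whose best library holds exactly 10 reads self-consistent), MFEI >= 0.85
with passing structure for records that carry an evaluation, and raw reads
in >= 2 libraries.  Significance selection keeps records whose minimum
pairwise-comparison p-value is <= 0.05.

## Differential expression

With one library per condition there is no replicate dispersion to estimate;
each tag is tested on the raw-count 2x2 table `[[count_a, total_a - count_a],
[count_b, total_b - count_b]]`.  Fisher's exact test (two-sided, summing
hypergeometric probabilities no larger than the observed table's, computed in
log space) is used unless all four expected counts are >= 5, in which case
the Pearson chi-squared test (1 df, no continuity correction by default)
applies.  Fold changes are computed on normalized counts, with a 0.5
pseudocount applied only to zero sides.  A tag is called up/down when
p <= 0.05 and |log2FC| >= 1.  No multiple-testing correction is applied by
default (an optional Benjamini-Hochberg flag is a config knob); regulated
lists de-duplicate miRNAs reported at several loci.

**Null calibration** is run in the generator's Poisson limit (dispersion ->
0): the exact tests model sampling noise only, so their type-I rate is
meaningful exactly when the generative null matches that sampling model.
Under the default negative-binomial dispersion of 0.1 the per-tag variance
inflation raises the positive rate to ~15% at moderate abundances — that is
a statement about unmodelled biological variability in single-replicate
designs, not about the tests, and is a known limitation of this (and the
emulated) design.

## Target prediction

Scheme A ("expectation") scores the antiparallel miRNA/site duplex with
mismatch 1.0, G:U 0.5 and gap 2.0, doubled over the seed (miRNA positions
2-13), cutoff 5.0; up to two transcript-side insertions are allowed, never
opposite miRNA positions 10-11.  Gaps are transcript insertions only: a `-`
column in the pairing string is an extra target nucleotide charged at the
next miRNA position, which keeps the expectation exactly recomputable from
the pairing string (checked as an invariant).  The scan is a vectorized DP
over all window starts, validated against brute-force enumeration of all
gapped alignments.  Scheme B ("penalty") is gapless with mismatch 1.0 and
G:U 0.5 doubled over positions 2-17, cutoff 2.5.  Predicted inhibition is
`Cleavage` iff miRNA positions 9-11 are perfectly paired, else
`Translation`.  The consensus keeps (miRNA, transcript) pairs found by both
schemes with >= 50% site overlap; gene roll-up uses a transcript->gene map
or the `_Tnn` suffix rule.  A site-openness proxy (fold the site +- 17 nt
free and with the site blocked from pairing; report the non-negative energy
difference) stands in for target-accessibility energies, which are out of
scope.

The pipeline scans **all annotated miRNAs** by default (`targets_from: all`).
Gating on per-comparison significance, as the emulated study did, interacts
badly with single-replicate noise (a fold-change-1 miRNA is "significant
somewhere" only by chance), so the gate is available as a config option
(`significant`, `high_confidence`) rather than the default.

## Degradome evidence

The expected cleavage position is the transcript position pairing miRNA
position 10, obtained by walking the pairing columns from `site_end`; gaps
opposite positions 10-11 make it undefined.  Each predicted site is assigned
the standard five-tier T-plot category per library (0 unique maximum, 1 tied
maximum, 2 above the median of occupied positions, 3 at/below it, 4 a
single tag), best category within +-1 nt of the expected position; the
`deg` statistic counts libraries with category <= 2.  Categories 0-3 are
scale-invariant; category 4 depends on the raw value 1 by definition.

## Synthetic-study generator

The generator plants everything the pipeline is supposed to find:

* **Genome**: random chromosomes with non-overlapping hairpin loci (arm
  55-90 nt with GC drawn in [40%, 65%], loop 6-12 nt, 0-3 arm mispairs
  planted >= 5 nt apart and clear of the mature/star duplex so planted
  hairpins deterministically satisfy the duplex criteria); the mature
  20-22-mer lies fully within one arm; background regions that happen to
  contain a mature are re-drawn, so each mature occurs only at its truth
  locus.
* **Libraries**: per-miRNA counts are negative binomial with mean
  `baseline x depth / 1e6` (baseline in RPM) times the planted Cd fold
  change in `Cd1`; dispersion 0.1 by default, 0 = Poisson.  Cd-responsive
  miRNAs are planted at moderate fixed baselines (400-2000 RPM; two 8x up,
  two 1/8 down, one mild 2x) while flat miRNAs carry the bulk of the
  planted mass — normalization against the library total is only
  fold-change-faithful when the changing tags do not dominate the total,
  which also matches the abundance regime of real Cd-responsive xylem
  miRNAs.  ~20% of reads are background: random 18-30-mers and fragments
  of a bundled synthetic contaminant set, 20-24-nt dominated.  Reads carry
  a 3' adapter (default, a standard small-RNA kit sequence; configurable).
  3'-end isomiRs (genome-templated R+1, trimmed R-1) are planted at 5%
  each; 5' variants are off by default since 3' heterogeneity dominates
  real isomiR spectra and 5' shifts would move the expected cleavage site.
* **Transcriptome**: each planted site is the reverse complement of its
  miRNA with plan-specified edits (mismatch, G:U — relocated to the nearest
  wobble-capable base when needed — or 1-2-nt transcript-side bulge); the
  default plan is gapless so both schemes can recover every planted site.
  Truth records the realized pairing and its expectation score.
* **Degradome**: per targeted transcript, `peak_fraction` (default 0.8) of
  the tags fall exactly at the planted cleavage position, the rest uniform;
  `peak_fraction = 0` is the no-signal control.

Everything is byte-reproducible from one integer seed.  The generator does
**not** model sequencing errors, quality-score variation, paralogous miRNA
families, or overdispersion between biological replicates; passing tests
therefore demonstrate correctness of the algorithms under the stated
sampling model, not robustness to artefacts absent from that model.

## Problem sizes and numerical choices

The bundled end-to-end fixture uses 10 hairpins on a 100-kb chromosome,
three libraries of 1e6 reads, 60 transcripts carrying 50 planted target
sites, and three degradome libraries of 3e4 tags at peak fraction 0.8 —
large enough that planted effects dominate sampling noise (an 8x fold
change at >= 400 RPM is flagged with ~0.999 probability per miRNA) while a
full run stays under two minutes on one core.  Unit tests use smaller
seeds/sizes of the same generator.  All folding and scoring arithmetic is
integer-exact (half-unit energies, doubled scores), so oracle comparisons
are exact rather than tolerance-based; Fisher p-values are compared to
integer enumeration at 1e-7 relative tolerance (the log-space tie rule).

## Known limitations

* SLF-1 is not a thermodynamic model; its MFE/MFEI thresholds pass nearly
  any A/C/G/T window of this size (see above), so hairpin specificity rests
  on the duplex criteria.  Real-data use should plug in a thermodynamic
  folder via the backend hook.
* Exact 2x2 tests on single libraries understate biological variability;
  calls should be read as "inconsistent with sampling noise", not
  replicated differential expression.
* The keyword-based functional bins are a deterministic stand-in for GO /
  pathway enrichment services and only as good as the annotation text.
* Degradome support uses exact transcript coordinates; transcript-isoform
  mismatches between the degradome and target transcriptomes are not
  reconciled.
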