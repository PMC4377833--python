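# Methods

## Model and procedure

`msiamp` calls microsatellite instability from amplicon deep-sequencing
reads without genome alignment. The underlying model is that a two-stage
amplicon PCR yields primer-terminal products whose length varies only
through the embedded repeat tract, so the amplicon length distribution of
a locus is a direct readout of its allele-length distribution (convolved
with PCR stutter), and the distribution's mode is the maximally amplified
allele. Instability is a shift of that mode between tumour and comparator.

Pipeline stages and their contracts:

1. **Merging.** Read 1 and the reverse complement of read 2 are scanned
   over every relative offset; the offset maximising the number of
   matching bases is accepted if the overlap is ≥ `min_overlap` (default
   15 bp) and its mismatch fraction ≤ `max_mismatch_fraction` (default
   0.1). Ties break toward the longer overlap, then the smaller offset.
   The merged sequence spans from the start of read 1 to the end of
   reverse-complemented read 2 — the inferred amplicon — which trims
   adapter read-through on both sides (the normal case here, since the
   panel's amplicons are shorter than the read length). In the overlap the
   higher-Phred base wins and the merged quality is the per-base maximum.
   Mates that cannot be merged are counted and dropped; unmerged-read
   rescue is out of scope.
2. **Quality filter.** A merged read is kept iff its mean Phred score is
   ≥ `quality_threshold` (default 30). "Read quality" is interpreted as
   the arithmetic mean of per-base scores — the standard whole-read
   reading of a Q30 cut — and the boundary case (mean exactly 30.0) is
   kept. No recalibration is applied.
3. **Binning.** A read belongs to locus L iff L's forward primer matches
   its 5′ end and the reverse complement of L's reverse primer matches its
   3′ end, anchored, with ≤ `max_flank_mismatches` substitutions per flank
   (default 0, at most 2 recommended). Both orientations are tried. Reads
   matching no locus, or more than one, are UNASSIGNED — ambiguity is
   discarded, not arbitrated, and counted in the run log. Flank indels are
   deliberately not tolerated: an indel inside a primer would shift the
   apparent amplicon length, corrupting the one coordinate the method
   depends on.
4. **Length coordinate.** Lengths are measured on the full merged amplicon
   including both primers. The tumour–comparator deviation Δ is invariant
   to this convention; absolute lengths reported by other pipelines that
   trim primers or count only the repeat tract differ by a constant and
   must not be compared numerically.
5. **Locus call.** Δ = |mode(tumour) − mode(comparator)|; unstable iff
   Δ ≥ 2 bp for mononucleotide loci or Δ ≥ 4 bp for dinucleotide loci
   (`mono_cutoff_bp`, `di_cutoff_bp`; inclusive cut-offs). The looser
   dinucleotide cut-off absorbs single-unit stutter, which at 2 bp per
   unit would otherwise trip a 2 bp rule. Modal ties break toward the
   length closest to the comparator mode (biasing against false
   instability), else toward the shorter length — deterministic, and
   conservative in the same direction as the choice of strict cut-offs.
6. **Overall status.** MSI-H iff ≥ `msi_high_min_unstable` (default 2)
   informative loci are unstable, MSI-L for an unstable count between 1
   and the threshold, MSS for none. The threshold is an absolute count
   rather than a fraction: for the five-locus panel the two coincide
   (2/5 = 40%), and the count is what a two-locus tumour-only panel
   actually uses.

### Depth floor and NO_CALL

`min_reads_per_locus` (default 100) introduces an explicit
insufficient-data outcome: if either side of a comparison has fewer
assigned reads, the locus is NO_CALL and excluded from the overall
denominator; a sample with no informative locus is INDETERMINATE. Deep
amplicon runs (≈5000× per locus) never hit this floor; degraded FFPE
samples and desk-scale simulations can.

### Paired vs tumour-only mode

With a matched normal, the comparator is the normal's own length
distribution. Without one, only loci carrying an explicit
`reference_modal_length` in the panel are called — in the default panel
the quasimonomorphic mononucleotide markers BAT25 (123 bp) and BAT26
(121 bp), whose normal length is nearly invariant across individuals.
Loci without an explicit reference are skipped rather than silently
compared against the reference amplicon length, because a polymorphic
locus has no meaningful fixed comparator. How reference lengths should be
set for other panels is a per-laboratory calibration decision.

## Evaluation statistics

Marker performance is reported as confusion counts with
sensitivity = 100·TP/(TP+FN) and specificity = 100·TN/(TN+FP), and exact
two-sided binomial (Clopper–Pearson) confidence intervals computed from
beta quantiles: lower = B(α/2; k, n−k+1), upper = B(1−α/2; k+1, n−k),
with lower = 0 at k = 0 and upper = 100 at k = n (where the lower bound
reduces to 100·(α/2)^(1/n)). The exact family was fixed because every
interval printed in the source cohort tables matches it and neither
Wilson nor Wald intervals do. Percentages are rounded half-up to one
decimal for display; raw floats are kept internally. Two comparisons are
provided: locus-vs-locus (truth = the capillary PCR call for the same
locus; undefined for loci the capillary panel lacked, which raise a
not-comparable error) and locus-vs-overall (truth = the sample's overall
PCR status being MSI-H; rows poolable across cohorts). One caveat is
recorded here deliberately: the published per-series text quotes a
sensitivity CI lower bound (83.2) that arithmetically corresponds to the
pooled n = 20, not the paired series' n = 17 (exact bound 80.5); the
package reproduces the pooled computation, which is self-consistent.

## Synthetic data

The simulator defines the study conditions for all read-level tests,
since no sequencing data are deposited for the original cohorts.

- **Alleles.** Each locus gets a reference allele flank5 + unit×count +
  flank3 whose assembled amplicon starts with the forward primer, ends
  with the reverse-complemented reverse primer and has exactly the
  reference amplicon length. Default repeat counts: BAT25 25×A, BAT26
  26×A, BAT34c4 24×A, D18S55 13×CA, D5S346 12×CA — tract sizes typical of
  these markers, centred between the primers with fixed pseudo-random
  filler keyed on the locus name (stable across processes). Tumour shifts
  are expressed in repeat units: 1 bp per unit at mono loci, 2 bp at di
  loci.
- **Stutter.** With probability `stutter_prob` (default 0.02 per
  molecule) the repeat count slips by k units, k geometric with parameter
  `stutter_geometric_p` (default 0.7), contraction with probability 0.8 —
  the standard polymerase-slippage picture for short tandem repeats, with
  all parameters configurable since no quantitative stutter model is
  published for this assay.
- **Errors and qualities.** I.i.d. substitutions at
  `substitution_error_rate` (default 0.002/bp). Per-base Phred scores are
  normal (mean 36, sd 3), truncated to [2, 41], with the mean tapering by
  0.05 Phred per cycle beyond cycle 100 — echoing the late-cycle quality
  decline of real MiSeq runs, and enough to exercise the Q30 filter
  without dominating it.
- **Reads.** 2×150 bp; each mate reads through the amplicon into a fixed
  synthetic adapter (distinct sequences per side, so mates never
  spuriously overlap in adapter). `fraction_offtarget` (default 0.01)
  random-sequence pairs exercise the merge-failure and UNASSIGNED paths.
- **Depth.** Default 5000 molecules per locus, the order of the real
  assay; tests and the acceptance script use 30–2000 per locus, which the
  depth floor and the modal statistic tolerate comfortably.
- **Determinism.** All randomness flows from one seed through
  `numpy.random.default_rng`; identical configuration and seed give
  byte-identical FASTQ.

What the simulator does **not** model: FFPE artefacts (deamination),
locus-specific stutter spectra, quality-by-sequence-context effects,
sample-index chemistry, and allelic dropout. Passing simulation tests
therefore demonstrates the pipeline's correctness — conservation,
round-trip recovery, cut-off behaviour — not the assay's clinical
performance on real tissue; the latter is represented by the packaged
published call matrices.

## Numerical and degenerate-input choices

- Merge scoring maximises matching bases (not overlap length); with ties
  broken toward longer overlap then smaller offset the result is unique
  and order-independent.
- Empty length distributions raise on `modal_length` but yield NO_CALL
  through `call_locus`; a zero-depth locus is therefore reportable, not an
  error.
- Group ordering (descending count, then ascending length, then sequence)
  makes all TSV outputs byte-stable across runs.
- Panel validation rejects duplicate locus names and any primer that is a
  substring of another locus's primer, which would make flank lookup
  ambiguous.
- Batch mode isolates per-row failures: a missing file fails that row's
  entry in the cohort table and the batch continues.

## Known limitations

- Only the global mode is compared. A heterozygous dinucleotide locus with
  two normal alleles is summarised by one modal length; allele-aware
  deconvolution (and stutter correction) is explicitly out of scope.
- Substitution-only flank matching drops reads with primer-region indels;
  at default settings it also drops reads with any primer-region
  substitution unless `max_flank_mismatches` is raised.
- Tumour purity is not modelled: a minor unstable clone that does not
  displace the mode is invisible to a modal-shift rule.
- The CLI is single-process; at five loci and benchtop depths this is
  ample.
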