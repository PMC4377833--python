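# msiamp

Alignment-free microsatellite-instability (MSI) calling from amplicon
deep-sequencing reads.

## The problem

Microsatellites are short tandem repeats — runs of mono- or dinucleotide
units — that expand or contract when the mismatch-repair machinery fails.
In colorectal cancer, instability at a small panel of well-characterised
loci (BAT25, BAT26, BAT34c4, D18S55, D5S346) identifies mismatch-repair
deficiency, flags patients for Lynch-syndrome work-up and predicts poor
response to 5-FU chemotherapy. The classical assay sizes fluorescent PCR
products on a capillary analyser; `msiamp` implements the deep-resequencing
alternative: sequence only the marker amplicons at thousands-fold depth on
a benchtop instrument and read the repeat length digitally, molecule by
molecule, with no genome alignment.

The package is for laboratory bioinformaticians and method developers: it
provides the complete pipeline as an importable library and a thin CLI,
the published 44-case and 6-case evaluation cohorts as data, and a seeded
read simulator so every stage is testable without sequencing data.

## Method

For each sample the pipeline:

1. **Merges** each mate pair into a single amplicon sequence by exhaustive
   overlap scan (amplicons of 121–147 bp are fully spanned by 2×150 bp
   reads; read-through into adapter is trimmed), and discards merged reads
   with mean Phred quality < Q30.
2. **Bins** reads to loci by matching the forward primer at the 5′ end and
   the reverse-complemented reverse primer at the 3′ end against a lookup
   table — alignment-free, substitution-only, both orientations tried.
3. Builds the per-locus **length distribution** *n(ℓ)* — read count per
   amplicon length — and takes the **modal length**
   ℓ* = argmax<sub>ℓ</sub> *n(ℓ)*.
4. **Calls** locus instability from the modal-length deviation
   Δ = |ℓ*<sub>tumour</sub> − ℓ*<sub>comparator</sub>|: unstable iff
   Δ ≥ 2 bp (mononucleotide) or Δ ≥ 4 bp (dinucleotide). The comparator is
   the matched normal, or a fixed panel reference for quasimonomorphic
   markers in tumour-only mode.
5. **Classifies** the sample: MSI-H with ≥ 2 unstable loci, MSI-L with
   exactly 1, MSS with none; loci under a depth floor are NO_CALL and
   excluded.

Marker performance is summarised as sensitivity/specificity with exact
(Clopper–Pearson) 95% confidence intervals from beta quantiles.

## Worked example

```sh
python examples/call_simulated_sample.py
```

simulates a tumour/normal pair (500 reads per locus, 2% stutter, 0.2%
substitution errors) in which the tumour contracts BAT25 and BAT26 by 3 bp
and D18S55 by 3 repeat units, then runs the full pipeline:

```
locus       tumour  normal  delta  cutoff  status
BAT25          120     123      3       2  unstable
BAT26          118     121      3       2  unstable
BAT34c4        130     130      0       2  stable
D18S55         141     147      6       4  unstable
D5S346         124     124      0       4  stable

overall: MSI-H (3/5 loci unstable)
```

Each row compares the tumour's modal amplicon length against the matched
normal's; three loci deviate at or beyond their cut-off, so the sample is
called MSI-High. `examples/evaluate_published_series.py` reclassifies the
packaged cohorts (17 MSI-H / 1 MSI-L / 26 MSS in the paired series, 3
MSI-H / 3 MSS in the tumour-only series) and scores every marker;
`examples/tumour_only_mode.py` shows reference-based calling without a
normal.

The same operations are available from the shell:

```sh
msiamp simulate --out sim --depth 500 --shift BAT25=-3 --shift BAT26=-3
msiamp run --tumour-r1 sim/tumour_R1.fastq --tumour-r2 sim/tumour_R2.fastq \
           --normal-r1 sim/normal_R1.fastq --normal-r2 sim/normal_R2.fastq \
           --out results
msiamp evaluate --out evaluation.tsv
msiamp batch --sample-sheet sheet.tsv --out results
```

## Layout

- `src/msiamp/` — `panel`, `preprocess`, `binning`, `classify`,
  `evaluate`, `simulate`, `pipeline`, `cli`, plus packaged data
  (default panel, call-matrix fixtures)
- `examples/` — narrative scripts, one per capability
- `tests/` — unit, property and end-to-end suites
- `docs/methods.md` — model, parameters, simulator scope and limitations
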