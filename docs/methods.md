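# Methods

## Model and assumptions

Telomeric DNA in vertebrates is (TTAGGG)n on the G strand and (CCCTAA)n
on the C strand. Each C-strand six-base block carries three non-CpG
cytosines (site1 and site2 in CpC context, site3 in CpT context, indexed
5′→3′ on the C strand). The method assumes:

1. **Directional library.** Read 1 reports the bisulfite-converted
   original strand; read 2 its complement. Converted C-strand runs
   therefore match `[CT][CT][CT]TAA` in the forward file and
   `TTA[AG][AG][AG]` in the reverse file, with the reverse-file 'G' at
   block positions 4–6 mapping back to site3, site2, site1.
2. **Telomeres are unmethylated**, so a cytosine read as 'C' reflects
   either conversion failure or rare, random non-CpG methylation. The
   measured unconverted ratio (UCR) is the sum of the two; they cannot be
   distinguished from converted reads and are never reported separately.
3. **Independent Bernoulli failures.** With per-site unconverted
   probability p, the fractions of blocks with exactly 1, 2 and 3
   unconverted cytosines are binomial: R1 = 3p(1−p)², R2 = 3p²(1−p),
   R3 = p³. The fit of observed R2/R3 to the values predicted from the
   R1-derived estimate is the model check; strong excess N3 indicates a
   non-random cause.

Each FASTQ file is processed independently; mates are never paired,
because the scan needs no pairing. The forward file carries the primary
estimate and the reverse file is reported as a diagnostic: in real
libraries reverse reads always run from the telomere inward and can pick
up spurious blocks at read ends, biasing their UCR slightly upward.

## Scanner

A read's telomeric run is its single longest stretch of complete six-base
blocks at any phase offset (0–5); partial blocks at run edges are
discarded so that block-class tallies are well defined. The
implementation sweeps the six phases with O(length) set-membership tests;
the test suite holds it against an exhaustive every-start sliding-window
oracle. Both the C-strand and G-strand pattern are searched; the longer
run decides the strand, and ties go to the C strand so conversion
information is never lost. A fully unconverted run (`CCCTAA` blocks in
the forward file) is by construction a C-strand N3 run, never a G-strand
run — collapsing it into the G-strand class would erase the contamination
signal.

`min_blocks` (default 8) is the threshold for calling a read telomeric.
Counts of reads by run length fall steeply and flatten by n ≈ 8, and in
the human genome virtually all (TTAGGG)₇⁺ repeats are (sub)telomeric, so
8 blocks cleanly separates telomeric reads from chance matches: a random
6-mer matches the forward C-strand pattern with probability 8/4⁶ ≈ 1/512,
so ~25% of random 150 bp reads contain a 1-block run but essentially none
reach 8. The run-length distribution diagnostic always scans at threshold
1 (over 1..`max_distribution_n`, default 30) precisely to expose that
plateau.

Whether a read with several disjoint runs should contribute more than its
longest run is genuinely open; the longest-run policy was chosen because
it makes "a read with n repeated blocks" unambiguous. At the working
threshold the choice is immaterial (two disjoint ≥8-block runs in a
150 bp read barely fit), but at threshold 1 it makes equal-length
tie-breaking visible: the scanner takes the earliest maximal run, which
on reverse-complemented input mirrors to the *last* one, so forward and
reverse tallies are only guaranteed identical at the working threshold.

One documented ambiguity: the two pattern spellings in circulation for
the forward search ("N is A or G" vs "N represents G or C") are both
inconsistent with what bisulfite chemistry can produce; the patterns
implemented here are the ones chemistry forces (see table above).

## Estimator

* Per-site UCR: unconverted count at that site divided by total C-strand
  blocks, per file. An empty tally is an error distinct from UCR = 0.
* Overall UCR: invert R1 = 3p(1−p)² on p ∈ [0, 1/3], where the cubic is
  strictly increasing with maximum 4/9. The root is found by bracketed
  root finding (Brent) to 1e−12 absolute tolerance; endpoints are handled
  exactly. An observed R1 above 4/9 is reported as a model-inconsistency
  error rather than clamped. R1 is used because the N1 class outnumbers
  N2/N3 by orders of magnitude at realistic p.
* Reported alongside: conversion efficiency 1 − UCR, observed and
  predicted R2/R3. Binomial proportion standard errors are available on
  per-site UCRs (`SiteUCR.standard_error`) as an extension; no interval
  has an external reference value.
* Samples with fewer than 100 C-strand blocks are flagged
  "insufficient telomeric reads": a UCR on a tiny denominator is noise.
  The threshold is a heuristic, not a fitted value.

## Contamination call

Reads carrying at least `cluster_min` N3 blocks (default 2) are "N3-rich".
If N3-rich reads hold at least `concentration_min` (default 0.5) of all
N3 blocks, the verdict is `suspected_contamination`; if N3 blocks exist
but are scattered below those thresholds, `dispersed`; with no N3 blocks,
`none`. The thresholds are heuristics expressing "clustered vs dispersed"
and are CLI-configurable; at realistic p (~0.005) a random process puts
~1 N3 block per 8 million blocks in any one read, so even a trace of
untreated DNA (whole reads of 24–25 N3 blocks) dominates the
concentration statistic immediately.

## Synthetic data generator

`simulate_sample` emulates what a directional WGBS library does to
telomeric DNA: C-strand read 1 is a run of blocks whose three sites
independently stay 'C' with probability `p_site[k]`; G-strand read 1 is a
(TTAGGG)n run; contaminated reads are fully unconverted (CCCTAA)n runs;
background reads are uniform random sequence; read 2 is always the exact
reverse complement of read 1. Phase jitter shifts the run start by 0–5
bases, padding edges with partial blocks so the complete-block count in
the truth ledger stays exact. Defaults (chosen once as the study
conditions): read length 150, `p_site` = 0.004 at all three sites —
placing the UCR under the 0.5% level of a sound library and ~1.2% of
blocks in classes N1–N3 — G-strand fraction 0.7 of telomeric reads (PCR
GC bias favours the 50%-GC G strand; the imbalance is emulated, not
modelled), telomeric fraction 0.001, no contamination, no sequencing
error. A uniform substitution error rate is available (default 0) for
robustness studies.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: quality-score structure (qualities are constant
placeholders), adapters, subtelomeric junction sequence, the mechanism
that inflates reverse-file UCRs in real libraries (its cause — spurious
blocks at read ends — is not specified precisely enough to simulate), and
any dependence of conversion efficiency on position or sequence context.
Background reads do contain chance 1–2 block runs at the expected
combinatorial rate, as real non-telomeric reads would; the truth ledger
marks them non-telomeric, and they are invisible at the working
threshold.

## Numerical and interface choices

* Root finding: `scipy.optimize.brentq` on the guaranteed bracket
  [0, 1/3], xtol = 1e−12.
* Coordinates are 0-based half-open internally; the report contains only
  counts and ratios.
* The TSV report (one row per sample × file, fractions at 6 decimals) was
  chosen over free text for machine readability; a one-line human summary
  per file goes to standard error. Re-running on identical input is
  byte-identical, and the generator writes gzip members with a zeroed
  timestamp so fixed seeds give byte-identical FASTQ files.
* Degenerate inputs: an empty FASTQ yields a report with zero counts and
  a "no reads" status; zero telomeric blocks yield `nan` model fields and
  an "insufficient" status, never a crash or a silent zero.
* Telomeric repeat spellings live in one module-level table
  (`telomere_scan`), so adapting the scanner to a species with a
  different repeat unit is a one-table change; no fuzzy matching is
  attempted.

## Problem sizes

The acceptance script and heavy tests use 20 replicates of 50,000
C-strand telomeric 150 bp reads (~1.2 M blocks each) for parameter
recovery at p = 0.005, a 200,000-read mixed sample for the headline
estimate, 20,000-read samples for the contamination checks, 1,000 random
sequences (length ≤ 60) for scanner/oracle agreement, and a 100-point
grid for the inversion identity — sizes at which binomial sampling error
is far smaller than the effects being checked.

## Known limitations

* The UCR conflates conversion failure with genuine non-CpG methylation;
  only their sum is identifiable here.
* Telomeres may not convert exactly like bulk genomic DNA; the estimate
  is a baseline, not a per-locus guarantee.
* Single-end or non-directional (PBAT-style) libraries are out of scope:
  the per-file dialects assume directionality.
* The contamination verdict is a screen, not a quantification of
  contaminating mass.
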