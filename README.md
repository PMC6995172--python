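# teloqc

Alignment-free bisulfite-conversion quality control for whole-genome
bisulfite sequencing (WGBS), using telomeric repeats as a native spike-in.

## The problem

WGBS infers DNA methylation from C/T status after bisulfite treatment,
which converts unmethylated cytosines to uracil (read as T). Incomplete
conversion produces false methylation calls, so every run needs an
estimate of its conversion efficiency. Common approaches either align
reads to the genome and read off non-CpG methylation (slow, and confounded
by real non-CpG methylation and C/T SNPs) or add an exogenous spike-in
(extra wet-lab work, and the spike may not convert like genomic DNA).

Vertebrate telomeres offer a shortcut. The telomeric C strand is a long
(CCCTAA)n run carrying three non-CpG cytosines per six-base block (two in
CpC context, one in CpT; numbered site1–site3, 5′→3′), and telomeric DNA
is essentially unmethylated. Telomeric reads are trivially recognizable
in raw FASTQ — no reference, no alignment — so the fraction of those
cytosines still read as 'C' (the **unconverted ratio, UCR**) measures
conversion failure plus the (tiny, random) non-CpG methylation rate.
The two components are not separately identifiable and are reported as
one number.

## The model

In a directional paired-end library, converted C-strand telomeric reads
appear in the forward file as blocks matching `[CT][CT][CT]TAA` and in
the reverse file as their reverse complement `TTA[AG][AG][AG]`;
cytosine-free G-strand reads appear as `TTAGGG` / `CCCTAA` runs. A read
is telomeric if its longest run of complete blocks has at least
`min_blocks` blocks (default 8). Each C-strand block is classified by its
number of unconverted cytosines into classes N0–N3.

Treating per-site conversion failure as independent Bernoulli(p) trials,
the block-class fractions R1–R3 are binomial:

    R1 = 3 p (1 − p)²,   R2 = 3 p² (1 − p),   R3 = p³

p (the UCR) is estimated by inverting the R1 equation on its identifiable
branch p ∈ [0, 1/3] (R1 rests on by far the largest class); R2 and R3
predicted from the estimate are reported next to their observed values as
a goodness-of-fit check. Per-site UCRs are reported alongside.

N3 blocks separate two failure modes: a random per-site process scatters
them one per read, while untreated (unconverted) genomic DNA contamination
concentrates them in a few fully unconverted reads. A dispersion heuristic
on the N3 blocks flags suspected contamination.

## Worked example

Simulate a paired sample (100,000 read pairs, 1% telomeric, per-site
unconverted probability 0.004) and analyze it:

```
teloqc simulate --n-reads 100000 --telomeric-fraction 0.01 \
    --g-strand-fraction 0.7 --p-site 0.004 0.004 0.004 \
    --seed 7 --out-prefix demo
teloqc run --fastq1 demo_1.fastq.gz --fastq2 demo_2.fastq.gz \
    --label demo --out demo_report.tsv
```

The run logs, per file:

```
[teloqc] demo/fastq1: 962/100000 telomeric reads, 7251 C-strand blocks, conversion efficiency 0.9958, contamination: none [ok]
```

and the TSV report contains (forward-file row, abridged):

| column | value | meaning |
|---|---|---|
| telomeric_ratio | 0.009620 | 962 of 100,000 reads carry a telomeric run |
| total_blocks / n0 / n1 | 7251 / 7160 / 91 | block classes: 91 blocks have one unconverted cytosine |
| ucr_site1/2/3 | 0.005103 / 0.002758 / 0.004689 | per-site unconverted ratios |
| ucr_hat | 0.004219 | UCR from inverting R1 — recovers the simulated 0.004 within binomial error |
| conversion_efficiency | 0.995781 | 1 − UCR |
| r2_obs / r2_exp | 0.000000 / 0.000053 | model check: at this depth ~0.4 N2 blocks are expected |
| contamination_verdict | none | no N3 blocks at all |

The reverse-file row is reported for diagnostics; the forward file
carries the primary estimate. Batch mode takes a manifest TSV of
`label<TAB>fastq1<TAB>fastq2` via `teloqc run --manifest`.

The library API mirrors the CLI: `stream_reads`, `scan_read`,
`classify_block`, `tally_blocks`, `site_ucr`, `fit_binomial`,
`ucr_from_r1`, `assess_contamination`, `analyze_sample`, `write_report`,
and `simulate_sample` for synthetic data with a truth ledger.

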