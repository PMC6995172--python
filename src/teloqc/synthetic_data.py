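"""Synthetic directional paired-end WGBS reads with a truth ledger.

The generator emulates what a bisulfite library does to telomeric DNA:

* C-strand fragments: read 1 is a run of six-base blocks in which each of
  the three non-CpG cytosines independently stays 'C' (conversion failure
  or methylation) with its per-site probability, otherwise reads 'T';
  read 2 is the exact reverse complement.
* G-strand fragments: read 1 is (TTAGGG)n — no cytosines, so conversion
  leaves it untouched; read 2 is its reverse complement (CCCTAA)n.
* Contamination: untreated genomic DNA escapes conversion entirely, so a
  contaminated telomeric read is a fully unconverted (CCCTAA)n run — all
  its blocks are N3 and cluster in few reads, unlike the dispersed N3
  blocks a random per-site process produces.
* Background: uniform random sequence standing in for the rest of the
  genome. Chance matches of one or two repeat blocks occur in it at the
  expected combinatorial rate, as they do in real data; runs long enough
  to pass the working threshold essentially never do.

No sequencing-error model is applied by default; an optional uniform
substitution rate is available for robustness studies. Quality strings
are constant placeholders. With a fixed seed, output files are
byte-identical across runs (gzip members are written with a zeroed
timestamp).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

__all__ = ["SimulationConfig", "ReadTruth", "SimulationTruth", "simulate_sample"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = np.array(list("ACGT"))
_QUAL_CHAR = "I"
BLOCK = 6

TRUTH_COLUMNS = (
    "read_id",
    "kind",
    "strand",
    "offset",
    "block_count",
    "n0",
    "n1",
    "n2",
    "n3",
    "site1_unconverted",
    "site2_unconverted",
    "site3_unconverted",
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated sample.

    Defaults describe a clean, well-converted human WGBS library: a
    per-site unconverted probability of 0.004 (under the 0.5% level seen
    in sound libraries, and placing ~1.2% of blocks in the N1-N3 classes),
    G-strand telomeric reads outnumbering C-strand ones (PCR GC bias
    favours the 50%-GC G strand), no contamination, and 150 bp reads.
    """

    n_reads: int = 100_000
    read_length: int = 150
    telomeric_fraction: float = 0.001
    g_strand_fraction: float = 0.7
    p_site: Tuple[float, float, float] = (0.004, 0.004, 0.004)
    contamination_fraction: float = 0.0
    phase_jitter: bool = True
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("telomeric_fraction", "g_strand_fraction",
                     "contamination_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(not 0.0 <= p <= 1.0 for p in self.p_site):
            raise ValueError(f"p_site entries must be in [0, 1], got {self.p_site}")
        if self.g_strand_fraction + self.contamination_fraction > 1.0:
            raise ValueError(
                "g_strand_fraction + contamination_fraction must not exceed 1"
            )
        if self.n_reads < 0 or self.read_length < BLOCK:
            raise ValueError("need n_reads >= 0 and read_length >= 6")


@dataclass(frozen=True)
class ReadTruth:
    """Generator bookkeeping for one read pair (block counts refer to
    complete blocks of read 1; read 2 mirrors them exactly)."""

    read_id: str
    kind: str  # c_strand | g_strand | contamination | background
    strand: str  # c_strand | g_strand | none
    offset: int  # phase offset of the first complete block in read 1
    block_count: int
    n_by_class: Tuple[int, int, int, int]
    site_unconverted: Tuple[int, int, int]


@dataclass
class SimulationTruth:
    """Per-read labels plus their aggregate tallies."""

    config: SimulationConfig
    reads: List[ReadTruth] = field(default_factory=list)

    @property
    def aggregate(self) -> Dict[str, int]:
        agg = {
            "telomeric_reads": 0,
            "c_strand_reads": 0,
            "g_strand_reads": 0,
            "contamination_reads": 0,
            "total_blocks": 0,
            "n0": 0,
            "n1": 0,
            "n2": 0,
            "n3": 0,
            "site1_unconverted": 0,
            "site2_unconverted": 0,
            "site3_unconverted": 0,
        }
        for r in self.reads:
            if r.kind == "background":
                continue
            agg["telomeric_reads"] += 1
            if r.strand == "g_strand":
                agg["g_strand_reads"] += 1
                continue
            agg["c_strand_reads"] += 1
            if r.kind == "contamination":
                agg["contamination_reads"] += 1
            agg["total_blocks"] += r.block_count
            for k in range(4):
                agg[f"n{k}"] += r.n_by_class[k]
            for i in range(3):
                agg[f"site{i + 1}_unconverted"] += r.site_unconverted[i]
        return agg


def _c_strand_read(
    length: int, offset: int, p_site: Tuple[float, float, float], rng: np.random.Generator
) -> Tuple[str, int, Tuple[int, int, int, int], Tuple[int, int, int]]:
    """Converted C-strand read 1: blocks [C/T][C/T][C/T]TAA from ``offset``.

    Returns (sequence, block_count, N-class counts, per-site unconverted
    counts) over the complete blocks only; jitter pads the edges with the
    tail/head of adjacent blocks so no extra complete block can form.
    """
    n_blocks = (length - offset) // BLOCK
    draws = rng.random((n_blocks, 3)) < np.asarray(p_site)
    blocks = ["".join("C" if u else "T" for u in row) + "TAA" for row in draws]
    body = "".join(blocks)
    head = "TTTTAA"[-offset:] if offset else ""  # tail of a preceding block
    tail_len = length - offset - n_blocks * BLOCK
    tail = "TTTTAA"[:tail_len]  # head of a following block, never complete
    seq = head + body + tail
    counts = np.bincount(draws.sum(axis=1), minlength=4)
    per_site = draws.sum(axis=0)
    return (
        seq,
        n_blocks,
        (int(counts[0]), int(counts[1]), int(counts[2]), int(counts[3])),
        (int(per_site[0]), int(per_site[1]), int(per_site[2])),
    )


def _repeat_read(unit: str, length: int, offset: int) -> Tuple[str, int]:
    """Read 1 made of ``unit`` repeats with a phase offset; returns the
    sequence and its complete-block count."""
    n_blocks = (length - offset) // BLOCK
    head = unit[-offset:] if offset else ""
    tail_len = length - offset - n_blocks * BLOCK
    seq = head + unit * n_blocks + unit[:tail_len]
    return seq, n_blocks


def _background_read(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        arr[hit] = _BASES[rng.integers(0, 4, size=int(hit.sum()))]
    return "".join(arr)


def _open_deterministic_gzip(path: Path):
    raw = open(path, "wb")
    return gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)


def simulate_sample(
    config: SimulationConfig, out_prefix: Union[str, Path]
) -> SimulationTruth:
    """Write ``<prefix>_1.fastq.gz``, ``<prefix>_2.fastq.gz`` and
    ``<prefix>_truth.tsv``; return the truth ledger.

    Read 2 is always the exact reverse complement of read 1, so scanning
    the reverse file with its own block dialect must reproduce the forward
    tallies exactly.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    truth = SimulationTruth(config=config)
    qual = _QUAL_CHAR * config.read_length

    p_telo = config.telomeric_fraction
    p_g = config.g_strand_fraction
    p_contam = config.contamination_fraction

    f1 = _open_deterministic_gzip(out_prefix.parent / (out_prefix.name + "_1.fastq.gz"))
    f2 = _open_deterministic_gzip(out_prefix.parent / (out_prefix.name + "_2.fastq.gz"))
    try:
        for i in range(config.n_reads):
            read_id = f"sim_{i:07d}"
            offset = 0
            if rng.random() < p_telo:
                offset = int(rng.integers(0, BLOCK)) if config.phase_jitter else 0
                u = rng.random()
                if u < p_g:
                    seq, nb = _repeat_read("TTAGGG", config.read_length, offset)
                    rec = ReadTruth(read_id, "g_strand", "g_strand", offset, nb,
                                    (0, 0, 0, 0), (0, 0, 0))
                elif u < p_g + p_contam:
                    seq, nb = _repeat_read("CCCTAA", config.read_length, offset)
                    rec = ReadTruth(read_id, "contamination", "c_strand", offset, nb,
                                    (0, 0, 0, nb), (nb, nb, nb))
                else:
                    seq, nb, classes, sites = _c_strand_read(
                        config.read_length, offset, config.p_site, rng
                    )
                    rec = ReadTruth(read_id, "c_strand", "c_strand", offset, nb,
                                    classes, sites)
            else:
                seq = _background_read(config.read_length, rng)
                rec = ReadTruth(read_id, "background", "none", 0, 0,
                                (0, 0, 0, 0), (0, 0, 0))
            seq = _apply_errors(seq, config.error_rate, rng)
            mate2 = reverse_complement(seq)
            f1.write(f"@{read_id}/1\n{seq}\n+\n{qual}\n".encode())
            f2.write(f"@{read_id}/2\n{mate2}\n+\n{qual}\n".encode())
            truth.reads.append(rec)
    finally:
        f1.close()
        f2.close()

    truth_path = out_prefix.parent / (out_prefix.name + "_truth.tsv")
    with open(truth_path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for r in truth.reads:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        r.read_id, r.kind, r.strand, r.offset, r.block_count,
                        *r.n_by_class, *r.site_unconverted,
                    )
                )
                + "\n"
            )
    return truth
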