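"""Detection and classification of telomeric repeat runs in reads.

Vertebrate telomeres are (TTAGGG)n on the G strand and (CCCTAA)n on the
C strand. In a directional bisulfite library the C strand carries three
non-CpG cytosines per six-base repeat (two CpC sites and one CpT site,
numbered 5'->3' on the C strand as site1, site2, site3); after conversion
each of those cytosines reads as 'C' (unconverted) or 'T' (converted).

Per file, two block patterns apply:

==========  ==================  ============
file        C-strand block      G-strand block
==========  ==================  ============
FASTQ1      [CT][CT][CT]TAA     TTAGGG
FASTQ2      TTA[AG][AG][AG]     CCCTAA
==========  ==================  ============

FASTQ2 reads are the reverse complement of the converted C strand, so an
unconverted cytosine appears as a 'G' in block positions 4-6, mapping back
(by reverse complement) to site3, site2, site1 respectively.

A read's telomeric run is its single longest stretch of complete six-base
blocks at any phase offset; partial blocks at the run edges are ignored.
A fully unconverted run (CCCTAA blocks in FASTQ1, TTAGGG in FASTQ2) is a
C-strand run of N3 blocks, never a G-strand run — this is what lets
untreated-DNA contamination be seen at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import product
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

import pandas as pd

from .fastq_io import ReadRecord

__all__ = [
    "SourceFile",
    "Strand",
    "Site",
    "ScanParams",
    "BlockObservation",
    "TelomereMatch",
    "classify_block",
    "scan_read",
    "block_count_distribution",
    "telomeric_read_ratio",
]


class SourceFile(str, Enum):
    FASTQ1 = "fastq1"
    FASTQ2 = "fastq2"


class Strand(str, Enum):
    C_STRAND = "c_strand"
    G_STRAND = "g_strand"


class Site(str, Enum):
    """The three non-CpG cytosines of one C-strand repeat, 5'->3'."""

    SITE1 = "site1"  # CpC
    SITE2 = "site2"  # CpC
    SITE3 = "site3"  # CpT


BLOCK_SIZE = 6

# All valid C-strand block spellings per file dialect.
_C_BLOCKS_FASTQ1: FrozenSet[str] = frozenset(
    "".join(b) + "TAA" for b in product("CT", repeat=3)
)
_C_BLOCKS_FASTQ2: FrozenSet[str] = frozenset(
    "TTA" + "".join(b) for b in product("AG", repeat=3)
)
_G_BLOCK = {SourceFile.FASTQ1: "TTAGGG", SourceFile.FASTQ2: "CCCTAA"}
_C_BLOCKS = {SourceFile.FASTQ1: _C_BLOCKS_FASTQ1, SourceFile.FASTQ2: _C_BLOCKS_FASTQ2}

# (block position, unconverted base, site) per dialect.
_SITE_MAP: Dict[SourceFile, Tuple[Tuple[int, str, Site], ...]] = {
    SourceFile.FASTQ1: (
        (0, "C", Site.SITE1),
        (1, "C", Site.SITE2),
        (2, "C", Site.SITE3),
    ),
    SourceFile.FASTQ2: (
        (3, "G", Site.SITE3),
        (4, "G", Site.SITE2),
        (5, "G", Site.SITE1),
    ),
}


@dataclass(frozen=True)
class ScanParams:
    """Scanner settings.

    min_blocks:
        Minimal number of complete repeat blocks for a read to count as
        telomeric. The default of 8 sits past the point where the count of
        matching reads stops falling with run length, so shorter chance
        matches in non-telomeric sequence are excluded.
    max_distribution_n:
        Largest run length tracked by the block-count diagnostic.
    """

    min_blocks: int = 8
    max_distribution_n: int = 30

    def __post_init__(self) -> None:
        if self.min_blocks < 1:
            raise ValueError("min_blocks must be >= 1")
        if self.max_distribution_n < 1:
            raise ValueError("max_distribution_n must be >= 1")


@dataclass(frozen=True)
class BlockObservation:
    """One six-base C-strand block and its unconverted cytosines."""

    block_sequence: str
    unconverted_count: int
    unconverted_sites: FrozenSet[Site]


@dataclass(frozen=True)
class TelomereMatch:
    """The longest telomeric repeat run found in one read."""

    read_id: str
    source_file: SourceFile
    strand_origin: Strand
    run_start: int  # 0-based offset of the first complete block
    block_count: int
    blocks: Tuple[BlockObservation, ...] = field(default_factory=tuple)

    @property
    def n3_count(self) -> int:
        return sum(1 for b in self.blocks if b.unconverted_count == 3)


def classify_block(block_sequence: str, source_file: SourceFile) -> BlockObservation:
    """Classify one C-strand block by its unconverted cytosines.

    Raises ValueError if the block does not match the dialect's C-strand
    pattern.
    """
    if block_sequence not in _C_BLOCKS[source_file]:
        raise ValueError(
            f"{block_sequence!r} is not a {source_file.value} C-strand block"
        )
    sites = frozenset(
        site
        for pos, base, site in _SITE_MAP[source_file]
        if block_sequence[pos] == base
    )
    return BlockObservation(block_sequence, len(sites), sites)


def _longest_run(sequence: str, blocks: FrozenSet[str]) -> Tuple[int, int]:
    """Longest run of consecutive complete blocks at any phase offset.

    Returns (start, block_count); (0, 0) when no block matches. Ties are
    broken toward the smaller start offset.
    """
    n = len(sequence)
    best_start, best_len = 0, 0
    for phase in range(min(BLOCK_SIZE, n)):
        run = 0
        for pos in range(phase, n - BLOCK_SIZE + 1, BLOCK_SIZE):
            if sequence[pos : pos + BLOCK_SIZE] in blocks:
                run += 1
            else:
                run = 0
                continue
            if run > best_len or (
                run == best_len and pos - (run - 1) * BLOCK_SIZE < best_start
            ):
                best_len = run
                best_start = pos - (run - 1) * BLOCK_SIZE
    return best_start, best_len


def scan_read(
    read: ReadRecord,
    source_file: SourceFile,
    params: ScanParams = ScanParams(),
) -> Optional[TelomereMatch]:
    """Find the longest telomeric run in a read, or None.

    Both the C-strand and the G-strand pattern of the file's dialect are
    searched; the longer run wins, with ties resolved toward the C strand
    so that conversion information is never discarded. Runs shorter than
    ``params.min_blocks`` are rejected.
    """
    c_start, c_len = _longest_run(read.sequence, _C_BLOCKS[source_file])
    g_start, g_len = _longest_run(
        read.sequence, frozenset((_G_BLOCK[source_file],))
    )
    if c_len >= g_len:
        strand, start, length = Strand.C_STRAND, c_start, c_len
    else:
        strand, start, length = Strand.G_STRAND, g_start, g_len
    if length < params.min_blocks:
        return None
    if strand is Strand.C_STRAND:
        blocks = tuple(
            classify_block(
                read.sequence[pos : pos + BLOCK_SIZE], source_file
            )
            for pos in range(start, start + length * BLOCK_SIZE, BLOCK_SIZE)
        )
    else:
        blocks = ()
    return TelomereMatch(read.read_id, source_file, strand, start, length, blocks)


def block_count_distribution(
    matches: Iterable[TelomereMatch],
    params: ScanParams = ScanParams(),
) -> pd.DataFrame:
    """Tabulate reads by telomeric run length.

    Returns a DataFrame indexed by (source_file, strand_origin) with one
    column per run length n in 1..max_distribution_n; cell value is the
    number of reads whose longest run has exactly n blocks. Matches longer
    than max_distribution_n are not tabulated. The diagnostic is meant to
    be fed matches scanned with min_blocks = 1.
    """
    ns = range(1, params.max_distribution_n + 1)
    index = pd.MultiIndex.from_product(
        [[f.value for f in SourceFile], [s.value for s in Strand]],
        names=["source_file", "strand_origin"],
    )
    table = pd.DataFrame(0, index=index, columns=list(ns), dtype=int)
    for m in matches:
        if 1 <= m.block_count <= params.max_distribution_n:
            table.loc[(m.source_file.value, m.strand_origin.value), m.block_count] += 1
    return table


def telomeric_read_ratio(n_telomeric: int, n_total: int) -> float:
    """Fraction of reads in a file that carry a telomeric run."""
    if n_total == 0:
        raise ZeroDivisionError("no reads: telomeric read ratio is undefined")
    if n_telomeric > n_total or n_telomeric < 0:
        raise ValueError("need 0 <= n_telomeric <= n_total")
    return n_telomeric / n_total
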