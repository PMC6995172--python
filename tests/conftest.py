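"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's phase-sweep scanner:
the run finder enumerates every (start, length) window, and the reverse-
file block classifier works by literal reverse complementation. They are
slow but obviously correct, which is the point.
"""

from __future__ import annotations

import gzip
from itertools import product
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import pytest

from teloqc.telomere_scan import Site, SourceFile, Strand

C_BLOCKS = {
    SourceFile.FASTQ1: frozenset("".join(b) + "TAA" for b in product("CT", repeat=3)),
    SourceFile.FASTQ2: frozenset("TTA" + "".join(b) for b in product("AG", repeat=3)),
}
G_BLOCK = {SourceFile.FASTQ1: "TTAGGG", SourceFile.FASTQ2: "CCCTAA"}

_RC = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def oracle_longest_run(seq: str, blocks: FrozenSet[str]) -> Tuple[int, int]:
    """Exhaustive sliding-window run finder: try every start, extend block
    by block. Returns (start, block_count); first maximum wins."""
    best_start, best_len = 0, 0
    for start in range(len(seq)):
        count = 0
        while (
            start + (count + 1) * 6 <= len(seq)
            and seq[start + count * 6 : start + (count + 1) * 6] in blocks
        ):
            count += 1
        if count > best_len:
            best_start, best_len = start, count
    return best_start, best_len


def oracle_scan(
    seq: str, source_file: SourceFile
) -> Optional[Tuple[Strand, int, int]]:
    """Strand choice replicated on top of the exhaustive run finder:
    longer run wins, ties go to the C strand. Returns
    (strand, start, block_count) or None when nothing matches."""
    c_start, c_len = oracle_longest_run(seq, C_BLOCKS[source_file])
    g_start, g_len = oracle_longest_run(seq, frozenset((G_BLOCK[source_file],)))
    if c_len == 0 and g_len == 0:
        return None
    if c_len >= g_len:
        return Strand.C_STRAND, c_start, c_len
    return Strand.G_STRAND, g_start, g_len


def oracle_classify_fastq2(block: str) -> FrozenSet[Site]:
    """Classify a reverse-file block by literally reverse-complementing it
    into C-strand orientation and reading off the 'C' positions."""
    fwd = rc(block)
    assert fwd in C_BLOCKS[SourceFile.FASTQ1]
    sites = []
    for pos, site in ((0, Site.SITE1), (1, Site.SITE2), (2, Site.SITE3)):
        if fwd[pos] == "C":
            sites.append(site)
    return frozenset(sites)


def write_fastq(
    path: Path, records: Sequence[Tuple[str, str, str]], compress: bool = False
) -> Path:
    """Write (id, seq, qual) triples as a FASTQ file."""
    text = "".join(f"@{rid}\n{seq}\n+\n{qual}\n" for rid, seq, qual in records)
    if compress:
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        path.write_text(text)
    return path


@pytest.fixture
def fastq_writer():
    return write_fastq


@pytest.fixture(scope="session")
def mixed_sample(tmp_path_factory):
    """A small paired simulated sample with every read category present,
    plus its truth ledger."""
    from teloqc.synthetic_data import SimulationConfig, simulate_sample

    prefix = tmp_path_factory.mktemp("sim") / "mixed"
    config = SimulationConfig(
        n_reads=3000,
        read_length=150,
        telomeric_fraction=0.1,
        g_strand_fraction=0.5,
        p_site=(0.02, 0.02, 0.02),
        contamination_fraction=0.01,
        phase_jitter=True,
        seed=42,
    )
    truth = simulate_sample(config, prefix)
    return {
        "prefix": prefix,
        "fastq1": prefix.parent / "mixed_1.fastq.gz",
        "fastq2": prefix.parent / "mixed_2.fastq.gz",
        "truth_tsv": prefix.parent / "mixed_truth.tsv",
        "truth": truth,
        "config": config,
    }
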