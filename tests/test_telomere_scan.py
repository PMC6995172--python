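"""Repeat-run detection and block classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teloqc.fastq_io import ReadRecord
from teloqc.telomere_scan import (
    ScanParams,
    Site,
    SourceFile,
    Strand,
    block_count_distribution,
    classify_block,
    scan_read,
    telomeric_read_ratio,
)

from conftest import C_BLOCKS, oracle_classify_fastq2, oracle_scan

P1 = ScanParams(min_blocks=1)


def read(seq: str) -> ReadRecord:
    return ReadRecord("r", seq, "I" * len(seq))


class TestClassifyBlock:
    def test_all_fastq1_variants(self):
        # site_k unconverted exactly when block position k-1 is 'C'
        for block in C_BLOCKS[SourceFile.FASTQ1]:
            obs = classify_block(block, SourceFile.FASTQ1)
            expected = frozenset(
                s for s, pos in ((Site.SITE1, 0), (Site.SITE2, 1), (Site.SITE3, 2))
                if block[pos] == "C"
            )
            assert obs.unconverted_sites == expected
            assert obs.unconverted_count == len(expected)

    def test_all_fastq2_variants_match_reverse_complement_oracle(self):
        for block in C_BLOCKS[SourceFile.FASTQ2]:
            obs = classify_block(block, SourceFile.FASTQ2)
            assert obs.unconverted_sites == oracle_classify_fastq2(block)

    @pytest.mark.parametrize(
        "block, source, count, sites",
        [
            ("TTTTAA", SourceFile.FASTQ1, 0, frozenset()),
            ("TCTTAA", SourceFile.FASTQ1, 1, frozenset({Site.SITE2})),
            ("CCCTAA", SourceFile.FASTQ1, 3,
             frozenset({Site.SITE1, Site.SITE2, Site.SITE3})),
            ("TTAAGA", SourceFile.FASTQ2, 1, frozenset({Site.SITE2})),
        ],
    )
    def test_known_blocks(self, block, source, count, sites):
        obs = classify_block(block, source)
        assert obs.unconverted_count == count
        assert obs.unconverted_sites == sites

    def test_nonmatching_block_rejected(self):
        with pytest.raises(ValueError):
            classify_block("TTAGGG", SourceFile.FASTQ1)


class TestScanRead:
    def test_fully_telomeric_converted_read(self):
        m = scan_read(read("TTTTAA" * 25), SourceFile.FASTQ1)
        assert m is not None
        assert m.strand_origin is Strand.C_STRAND
        assert m.block_count == 25
        assert all(b.unconverted_count == 0 for b in m.blocks)

    def test_run_below_min_blocks_is_rejected(self):
        seq = "G" * 50 + "TTTTAA" * 7 + "G" * 50
        assert scan_read(read(seq), SourceFile.FASTQ1, ScanParams(min_blocks=8)) is None
        m = scan_read(read(seq), SourceFile.FASTQ1, ScanParams(min_blocks=7))
        assert m is not None and m.block_count == 7

    def test_fully_unconverted_run_is_c_strand_not_g_strand(self):
        # the contamination signature: all-N3 C-strand runs
        m1 = scan_read(read("CCCTAA" * 10), SourceFile.FASTQ1)
        assert m1.strand_origin is Strand.C_STRAND and m1.n3_count == 10
        m2 = scan_read(read("TTAGGG" * 10), SourceFile.FASTQ2)
        assert m2.strand_origin is Strand.C_STRAND and m2.n3_count == 10

    def test_g_strand_run_detected(self):
        m = scan_read(read("TTAGGG" * 12), SourceFile.FASTQ1)
        assert m.strand_origin is Strand.G_STRAND
        assert m.block_count == 12 and m.blocks == ()

    def test_phase_offset_runs_found(self):
        seq = "AA" + "TTCTAA" * 9 + "GGGC"
        m = scan_read(read(seq), SourceFile.FASTQ1)
        assert m.run_start == 2 and m.block_count == 9
        assert all(b.unconverted_sites == {Site.SITE3} for b in m.blocks)

    def test_random_reads_do_not_match_at_default_threshold(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=100))
            assert scan_read(read(seq), SourceFile.FASTQ1) is None

    def test_unconverted_site_sum_matches_class_counts(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            blocks = [
                "".join(rng.choice(["C", "T"], size=3)) + "TAA" for _ in range(12)
            ]
            m = scan_read(read("".join(blocks)), SourceFile.FASTQ1)
            by_class = [sum(1 for b in m.blocks if b.unconverted_count == k)
                        for k in range(4)]
            assert sum(b.unconverted_count for b in m.blocks) == (
                by_class[1] + 2 * by_class[2] + 3 * by_class[3]
            )


@st.composite
def telomere_like_sequences(draw):
    """Sequences biased to contain runs: random flanks around spliced
    blocks from either dialect, or plain random sequence."""
    kind = draw(st.integers(0, 2))
    if kind == 0:
        return draw(st.text(alphabet="ACGT", min_size=0, max_size=60))
    source = SourceFile.FASTQ1 if kind == 1 else SourceFile.FASTQ2
    pool = sorted(C_BLOCKS[source]) + [
        {"fastq1": "TTAGGG", "fastq2": "CCCTAA"}[source.value]
    ]
    blocks = draw(st.lists(st.sampled_from(pool), min_size=0, max_size=8))
    prefix = draw(st.text(alphabet="ACGT", min_size=0, max_size=8))
    suffix = draw(st.text(alphabet="ACGT", min_size=0, max_size=8))
    return (prefix + "".join(blocks) + suffix)[:60]


@settings(max_examples=300, derandomize=True, deadline=None)
@given(seq=telomere_like_sequences(), source=st.sampled_from(list(SourceFile)))
def test_scan_equals_exhaustive_window_oracle(seq, source):
    expected = oracle_scan(seq, source)
    m = scan_read(read(seq) if seq else ReadRecord("r", "", ""), source, P1)
    if expected is None:
        assert m is None
    else:
        strand, start, length = expected
        assert m is not None
        assert (m.strand_origin, m.run_start, m.block_count) == (strand, start, length)


def test_reverse_complement_scan_gives_identical_site_classification():
    """A forward C-strand read and its reverse complement (scanned under
    the reverse dialect) must report the same per-site calls."""
    from conftest import rc

    rng = np.random.default_rng(3)
    for _ in range(30):
        blocks = ["".join(rng.choice(["C", "T"], size=3)) + "TAA" for _ in range(10)]
        fwd = "".join(blocks)
        m1 = scan_read(read(fwd), SourceFile.FASTQ1)
        m2 = scan_read(read(rc(fwd)), SourceFile.FASTQ2)
        sites1 = [b.unconverted_sites for b in m1.blocks]
        sites2 = [b.unconverted_sites for b in reversed(m2.blocks)]
        assert sites1 == sites2


class TestDistributionAndRatio:
    def test_empty_matches_give_zero_table(self):
        table = block_count_distribution([], P1)
        assert (table.to_numpy() == 0).all()
        assert table.shape == (4, 30)

    def test_single_match_lands_in_its_cell(self):
        m = scan_read(read("TTAGGG" * 25), SourceFile.FASTQ1, P1)
        table = block_count_distribution([m], P1)
        assert table.loc[("fastq1", "g_strand"), 25] == 1
        assert table.to_numpy().sum() == 1

    def test_rows_sum_to_telomeric_read_counts(self):
        rng = np.random.default_rng(5)
        matches = []
        for i in range(40):
            n = int(rng.integers(1, 26))
            matches.append(scan_read(read("TTTTAA" * n), SourceFile.FASTQ1, P1))
        table = block_count_distribution(matches, P1)
        assert table.loc[("fastq1", "c_strand")].sum() == 40

    def test_ratio(self):
        assert telomeric_read_ratio(0, 1000) == 0.0
        assert telomeric_read_ratio(5, 1000) == pytest.approx(0.005)
        with pytest.raises(ZeroDivisionError):
            telomeric_read_ratio(0, 0)
        with pytest.raises(ValueError):
            telomeric_read_ratio(5, 4)
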