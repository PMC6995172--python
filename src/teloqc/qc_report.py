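"""Per-sample QC assembly: contamination call, report record, TSV writer.

The N3 (fully unconverted) block class separates two very different
causes. Enzymatic non-CpG methylation and conversion failure act per
cytosine, so the rare N3 blocks they produce are scattered one per read;
untreated genomic DNA, by contrast, contributes whole unconverted reads,
so its N3 blocks concentrate in a few reads. The contamination verdict
is a heuristic on that dispersion: if reads carrying at least
``cluster_min`` N3 blocks hold at least ``concentration_min`` of all N3
blocks, contamination is suspected; otherwise the N3 blocks are called
dispersed. Both thresholds are configurable.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import pandas as pd

from .conversion_model import (
    BinomialFit,
    BlockTally,
    SiteUCR,
    fit_binomial,
    site_ucr,
    tally_blocks,
)
from .fastq_io import Mate, stream_reads
from .telomere_scan import (
    ScanParams,
    SourceFile,
    Strand,
    TelomereMatch,
    block_count_distribution,
    scan_read,
    telomeric_read_ratio,
)

__all__ = [
    "Verdict",
    "ContaminationAssessment",
    "FileResult",
    "SampleReport",
    "assess_contamination",
    "analyze_sample",
    "write_report",
]

logger = logging.getLogger("teloqc")

# Below this many C-strand blocks the UCR is dominated by counting noise.
MIN_BLOCKS_FOR_ESTIMATE = 100

REPORT_COLUMNS = [
    "sample", "file", "total_reads", "telomeric_reads", "c_strand_reads",
    "g_strand_reads", "telomeric_ratio", "total_blocks", "n0", "n1", "n2",
    "n3", "ucr_site1", "ucr_site2", "ucr_site3", "ucr_hat",
    "conversion_efficiency", "r2_obs", "r2_exp", "r3_obs", "r3_exp",
    "contamination_verdict",
]


class Verdict(str, Enum):
    NONE = "none"
    DISPERSED = "dispersed"
    SUSPECTED_CONTAMINATION = "suspected_contamination"


@dataclass(frozen=True)
class ContaminationAssessment:
    n3_total: int
    n3_rich_reads: int
    n3_in_rich_reads: int
    verdict: Verdict


@dataclass
class FileResult:
    """Everything measured from one FASTQ file."""

    source_file: SourceFile
    path: str
    total_reads: int
    telomeric_reads: int
    c_strand_reads: int
    g_strand_reads: int
    ratio: Optional[float]
    distribution: pd.DataFrame
    tally: BlockTally
    ucr: Optional[SiteUCR]
    fit: Optional[BinomialFit]
    contamination: ContaminationAssessment
    status: str  # "ok" | "insufficient telomeric reads" | "no reads"


@dataclass
class SampleReport:
    label: str
    params: ScanParams
    cluster_min: int
    concentration_min: float
    files: List[FileResult]


def assess_contamination(
    matches: Iterable[TelomereMatch],
    cluster_min: int = 2,
    concentration_min: float = 0.5,
) -> ContaminationAssessment:
    """Call contamination from how N3 blocks distribute across reads.

    ``matches`` should be the C-strand matches of one file.
    """
    per_read_n3 = [m.n3_count for m in matches if m.strand_origin is Strand.C_STRAND]
    n3_total = sum(per_read_n3)
    rich = [c for c in per_read_n3 if c >= cluster_min]
    n3_in_rich = sum(rich)
    if n3_total == 0:
        verdict = Verdict.NONE
    elif n3_in_rich >= concentration_min * n3_total:
        verdict = Verdict.SUSPECTED_CONTAMINATION
    else:
        verdict = Verdict.DISPERSED
    return ContaminationAssessment(n3_total, len(rich), n3_in_rich, verdict)


def _analyze_file(
    path: Union[str, Path],
    source_file: SourceFile,
    params: ScanParams,
    cluster_min: int,
    concentration_min: float,
) -> FileResult:
    """Single pass over one file: scan at threshold 1, keep the run-length
    distribution for every match, and apply ``params.min_blocks`` when
    deciding which reads count as telomeric."""
    scan_all = ScanParams(min_blocks=1, max_distribution_n=params.max_distribution_n)
    mate = Mate.MATE1 if source_file is SourceFile.FASTQ1 else Mate.MATE2
    all_matches: List[TelomereMatch] = []
    kept: List[TelomereMatch] = []
    total_reads = 0
    for read in stream_reads(path, mate):
        total_reads += 1
        m = scan_read(read, source_file, scan_all)
        if m is None:
            continue
        all_matches.append(m)
        if m.block_count >= params.min_blocks:
            kept.append(m)

    distribution = block_count_distribution(all_matches, params)
    c_matches = [m for m in kept if m.strand_origin is Strand.C_STRAND]
    g_count = sum(1 for m in kept if m.strand_origin is Strand.G_STRAND)
    tally = tally_blocks(c_matches, source_file)
    contamination = assess_contamination(c_matches, cluster_min, concentration_min)

    if total_reads == 0:
        status = "no reads"
    elif tally.total_blocks < MIN_BLOCKS_FOR_ESTIMATE:
        status = "insufficient telomeric reads"
    else:
        status = "ok"
    ucr = site_ucr(tally) if tally.total_blocks > 0 else None
    fit = fit_binomial(tally) if tally.total_blocks > 0 else None
    ratio = telomeric_read_ratio(len(kept), total_reads) if total_reads else None
    if status != "ok":
        logger.warning("%s: %s (%d blocks)", path, status, tally.total_blocks)
    return FileResult(
        source_file=source_file,
        path=str(path),
        total_reads=total_reads,
        telomeric_reads=len(kept),
        c_strand_reads=len(c_matches),
        g_strand_reads=g_count,
        ratio=ratio,
        distribution=distribution,
        tally=tally,
        ucr=ucr,
        fit=fit,
        contamination=contamination,
        status=status,
    )


def analyze_sample(
    fastq1: Union[str, Path],
    fastq2: Optional[Union[str, Path]] = None,
    params: ScanParams = ScanParams(),
    label: str = "sample",
    cluster_min: int = 2,
    concentration_min: float = 0.5,
) -> SampleReport:
    """Run the full pipeline on one sample.

    Each file is processed independently (scan -> tally -> per-site UCR ->
    binomial fit -> contamination call). The forward file carries the
    primary estimate; reverse-file results are diagnostics. A sample with
    no telomeric reads yields a report flagged as insufficient, not an
    error.
    """
    files = [_analyze_file(fastq1, SourceFile.FASTQ1, params,
                           cluster_min, concentration_min)]
    if fastq2 is not None:
        files.append(_analyze_file(fastq2, SourceFile.FASTQ2, params,
                                   cluster_min, concentration_min))
    return SampleReport(label, params, cluster_min, concentration_min, files)


def _fmt(x: Optional[float]) -> str:
    return "nan" if x is None else f"{x:.6f}"


def report_rows(report: SampleReport) -> List[Dict[str, object]]:
    rows: List[Dict[str, object]] = []
    for fr in report.files:
        ucr = fr.ucr
        fit = fr.fit
        rows.append({
            "sample": report.label,
            "file": fr.source_file.value,
            "total_reads": fr.total_reads,
            "telomeric_reads": fr.telomeric_reads,
            "c_strand_reads": fr.c_strand_reads,
            "g_strand_reads": fr.g_strand_reads,
            "telomeric_ratio": _fmt(fr.ratio),
            "total_blocks": fr.tally.total_blocks,
            "n0": fr.tally.n0,
            "n1": fr.tally.n1,
            "n2": fr.tally.n2,
            "n3": fr.tally.n3,
            "ucr_site1": _fmt(ucr.ucr_site1 if ucr else None),
            "ucr_site2": _fmt(ucr.ucr_site2 if ucr else None),
            "ucr_site3": _fmt(ucr.ucr_site3 if ucr else None),
            "ucr_hat": _fmt(fit.ucr_hat if fit else None),
            "conversion_efficiency": _fmt(fit.conversion_efficiency if fit else None),
            "r2_obs": _fmt(fit.r2_obs if fit else None),
            "r2_exp": _fmt(fit.r2_exp if fit else None),
            "r3_obs": _fmt(fit.r3_obs if fit else None),
            "r3_exp": _fmt(fit.r3_exp if fit else None),
            "contamination_verdict": fr.contamination.verdict.value,
        })
    return rows


def write_report(reports: Sequence[SampleReport], out: Union[str, Path]) -> None:
    """Write one TSV row per (sample, file), samples in input order."""
    if not reports:
        raise ValueError("need at least one sample report")
    rows: List[Dict[str, object]] = []
    for rep in reports:
        rows.extend(report_rows(rep))
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    frame.to_csv(out, sep="\t", index=False, lineterminator="\n")
    for rep in reports:
        for fr in rep.files:
            eff = fr.fit.conversion_efficiency if fr.fit else float("nan")
            print(
                f"[teloqc] {rep.label}/{fr.source_file.value}: "
                f"{fr.telomeric_reads}/{fr.total_reads} telomeric reads, "
                f"{fr.tally.total_blocks} C-strand blocks, "
                f"conversion efficiency {eff:.4f}, "
                f"contamination: {fr.contamination.verdict.value} [{fr.status}]",
                file=sys.stderr,
            )
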