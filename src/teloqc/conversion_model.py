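"""Binomial model of conversion failure at telomeric non-CpG cytosines.

Each six-base C-strand telomeric block carries three non-CpG cytosines.
Treating the unconverted state of each cytosine as an independent
Bernoulli trial with probability p (the unconverted ratio, UCR), the
fraction of blocks with exactly k unconverted cytosines is binomial:

    R1 = 3 p (1-p)^2        (N1 blocks)
    R2 = 3 p^2 (1-p)        (N2 blocks)
    R3 = p^3                (N3 blocks)

The UCR is estimated by inverting the R1 equation, which rests on by far
the largest block class; R2 and R3 predicted from that estimate are then
compared with their observed fractions as a goodness-of-fit check. The
UCR is the sum of the bisulfite false-conversion rate and the true
non-CpG methylation rate; the two components cannot be separated from
converted reads alone and are never reported separately here.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Dict, Iterable, Tuple

from scipy.optimize import brentq

from .telomere_scan import Site, SourceFile, Strand, TelomereMatch

__all__ = [
    "BlockTally",
    "SiteUCR",
    "BinomialFit",
    "tally_blocks",
    "site_ucr",
    "expected_block_fractions",
    "ucr_from_r1",
    "fit_binomial",
]

# Maximum of 3p(1-p)^2 on [0, 1/3]; observed R1 above this is inconsistent
# with the model's identifiable branch.
R1_MAX = 4.0 / 9.0


class NoTelomericBlocksError(ValueError):
    """Raised when a UCR is requested from an empty tally."""


@dataclass(frozen=True)
class BlockTally:
    """Aggregate block counts for one file's C-strand matches."""

    source_file: SourceFile
    total_blocks: int
    n0: int
    n1: int
    n2: int
    n3: int
    site_unconverted: Dict[Site, int]

    def __post_init__(self) -> None:
        if self.n0 + self.n1 + self.n2 + self.n3 != self.total_blocks:
            raise ValueError("N0..N3 must sum to total_blocks")
        if sum(self.site_unconverted.values()) != self.n1 + 2 * self.n2 + 3 * self.n3:
            raise ValueError("site counts must sum to N1 + 2*N2 + 3*N3")


@dataclass(frozen=True)
class SiteUCR:
    """Per-site unconverted ratios with binomial standard errors."""

    ucr_site1: float
    ucr_site2: float
    ucr_site3: float
    denominator: int

    def standard_error(self, site_index: int) -> float:
        p = (self.ucr_site1, self.ucr_site2, self.ucr_site3)[site_index - 1]
        return sqrt(p * (1.0 - p) / self.denominator)


@dataclass(frozen=True)
class BinomialFit:
    """Observed block-class fractions and the model fit derived from R1."""

    r1_obs: float
    r2_obs: float
    r3_obs: float
    ucr_hat: float
    r2_exp: float
    r3_exp: float

    @property
    def conversion_efficiency(self) -> float:
        return 1.0 - self.ucr_hat


def tally_blocks(
    matches: Iterable[TelomereMatch], source_file: SourceFile
) -> BlockTally:
    """Count every block of every C-strand match of one file exactly once.

    Matches from other files or from the G strand are ignored; an empty
    input yields a zero tally.
    """
    n_by_class = [0, 0, 0, 0]
    site_counts: Dict[Site, int] = {s: 0 for s in Site}
    for m in matches:
        if m.source_file is not source_file or m.strand_origin is not Strand.C_STRAND:
            continue
        for block in m.blocks:
            n_by_class[block.unconverted_count] += 1
            for site in block.unconverted_sites:
                site_counts[site] += 1
    return BlockTally(
        source_file=source_file,
        total_blocks=sum(n_by_class),
        n0=n_by_class[0],
        n1=n_by_class[1],
        n2=n_by_class[2],
        n3=n_by_class[3],
        site_unconverted=site_counts,
    )


def site_ucr(tally: BlockTally) -> SiteUCR:
    """Per-site UCR: unconverted count over total blocks, per site."""
    if tally.total_blocks == 0:
        raise NoTelomericBlocksError(
            "no telomeric blocks: per-site UCR is undefined (not zero)"
        )
    n = tally.total_blocks
    return SiteUCR(
        ucr_site1=tally.site_unconverted[Site.SITE1] / n,
        ucr_site2=tally.site_unconverted[Site.SITE2] / n,
        ucr_site3=tally.site_unconverted[Site.SITE3] / n,
        denominator=n,
    )


def expected_block_fractions(ucr: float) -> Tuple[float, float, float]:
    """Binomial block-class fractions (R1, R2, R3) at a given UCR."""
    if not 0.0 <= ucr <= 1.0:
        raise ValueError(f"UCR must be in [0, 1], got {ucr}")
    q = 1.0 - ucr
    return 3.0 * ucr * q * q, 3.0 * ucr * ucr * q, ucr**3


def ucr_from_r1(r1_obs: float) -> float:
    """Invert R1 = 3 p (1-p)^2 for p on the identifiable branch [0, 1/3].

    The cubic is strictly increasing on [0, 1/3] with maximum 4/9, so the
    root is unique; it is bracketed and found to 1e-12 absolute tolerance.
    """
    if r1_obs < 0.0:
        raise ValueError(f"R1 must be non-negative, got {r1_obs}")
    if r1_obs > R1_MAX:
        raise ValueError(
            f"R1 = {r1_obs} exceeds the model maximum 4/9; "
            "observed data are inconsistent with the binomial model"
        )
    if r1_obs == 0.0:
        return 0.0
    if r1_obs == R1_MAX:
        return 1.0 / 3.0
    return float(
        brentq(
            lambda p: 3.0 * p * (1.0 - p) ** 2 - r1_obs,
            0.0,
            1.0 / 3.0,
            xtol=1e-12,
        )
    )


def fit_binomial(tally: BlockTally) -> BinomialFit:
    """Estimate the UCR from R1 and predict R2/R3 under the model."""
    if tally.total_blocks == 0:
        raise NoTelomericBlocksError("no telomeric blocks: cannot fit model")
    n = tally.total_blocks
    r1_obs = tally.n1 / n
    r2_obs = tally.n2 / n
    r3_obs = tally.n3 / n
    ucr_hat = ucr_from_r1(r1_obs)
    _, r2_exp, r3_exp = expected_block_fractions(ucr_hat)
    return BinomialFit(r1_obs, r2_obs, r3_obs, ucr_hat, r2_exp, r3_exp)
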