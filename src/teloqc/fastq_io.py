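"""Streaming FASTQ input.

Reads are consumed one file at a time; forward and reverse files of a
paired-end run are never joined, because the downstream repeat scan needs
no mate information. Gzip compression is detected from the file's magic
bytes, not from its extension. Quality strings are carried through but
never used for filtering.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from enum import Enum
from itertools import islice
from pathlib import Path
from typing import IO, Iterator, Union

__all__ = ["Mate", "ReadRecord", "stream_reads"]

_VALID_BASES = frozenset("ACGTN")
_GZIP_MAGIC = b"\x1f\x8b"


class Mate(str, Enum):
    """Which mate of a paired-end run a file holds."""

    MATE1 = "mate1"
    MATE2 = "mate2"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read.

    ``sequence`` is uppercase DNA over {A, C, G, T, N} and has the same
    length as ``quality``.
    """

    read_id: str
    sequence: str
    quality: str
    mate: Mate = Mate.UNKNOWN

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)}"
            )
        if not _VALID_BASES.issuperset(self.sequence):
            bad = sorted(set(self.sequence) - _VALID_BASES)
            raise ValueError(f"read {self.read_id!r}: invalid bases {bad}")


class FastqFormatError(ValueError):
    """Raised when a FASTQ record is structurally malformed."""


def _open_maybe_gzip(path: Union[str, Path]) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def stream_reads(
    path: Union[str, Path], mate: Mate = Mate.UNKNOWN
) -> Iterator[ReadRecord]:
    """Yield :class:`ReadRecord` objects from a FASTQ file in file order.

    Parameters
    ----------
    path:
        FASTQ file, plain text or gzip-compressed (sniffed by magic bytes).
    mate:
        Mate label attached to every record; purely informational.

    Raises
    ------
    FastqFormatError
        On a malformed record (length mismatch, missing ``@`` header),
        naming the 1-based record index. An empty file yields nothing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    n_seen = 0
    with _open_maybe_gzip(path) as handle:
        while True:
            # strictly 4-line records: header, sequence, separator, quality
            group = [line.rstrip("\n") for line in islice(handle, 4)]
            if not group:
                break
            n_seen += 1
            if len(group) < 4:
                raise FastqFormatError(
                    f"{path}: malformed FASTQ record {n_seen}: truncated record"
                )
            header, seq, sep, qual = group
            if not header.startswith("@"):
                raise FastqFormatError(
                    f"{path}: malformed FASTQ record {n_seen}: "
                    f"header does not start with '@' ({header[:20]!r})"
                )
            if not sep.startswith("+"):
                raise FastqFormatError(
                    f"{path}: malformed FASTQ record {n_seen}: "
                    "separator line does not start with '+'"
                )
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"{path}: malformed FASTQ record {n_seen}: sequence length "
                    f"{len(seq)} != quality length {len(qual)}"
                )
            seq = seq.upper()
            if not _VALID_BASES.issuperset(seq):
                bad = sorted(set(seq) - _VALID_BASES)
                raise FastqFormatError(
                    f"{path}: malformed FASTQ record {n_seen} "
                    f"contains invalid bases {bad}"
                )
            read_id = header[1:].split(None, 1)[0] if len(header) > 1 else ""
            yield ReadRecord(read_id, seq, qual, mate)
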