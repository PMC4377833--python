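"""FASTQ reading and writing (Phred+33, plain or gzip-compressed).

Thin wrappers around Biopython's FASTQ parser that yield the package's
:class:`~msiamp.preprocess.ReadPair` records from paired R1/R2 files and
write merged or simulated reads back out.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .preprocess import MergedRead, ReadPair

__all__ = ["FastqError", "read_pairs", "write_reads", "open_text"]


class FastqError(ValueError):
    """Malformed or mismatched FASTQ input."""


def open_text(path: str | Path, mode: str = "rt") -> TextIO:
    """Open a possibly gzip-compressed text file by extension."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _records(path: str | Path) -> Iterator[SeqRecord]:
    with open_text(path) as handle:
        yield from SeqIO.parse(handle, "fastq")


def read_pairs(r1_path: str | Path, r2_path: str | Path
               ) -> Iterator[ReadPair]:
    """Iterate mate pairs from two parallel FASTQ files.

    Raises :class:`FastqError` on truncated records or unequal pair counts.
    """
    it1, it2 = _records(r1_path), _records(r2_path)
    while True:
        try:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
        except ValueError as exc:  # Biopython: truncated/malformed record
            raise FastqError(f"malformed FASTQ record: {exc}") from exc
        if rec1 is None and rec2 is None:
            return
        if rec1 is None or rec2 is None:
            raise FastqError(
                f"unequal read counts in {r1_path} and {r2_path}")
        yield ReadPair(
            id=rec1.id,
            seq1=str(rec1.seq).upper(),
            qual1=tuple(rec1.letter_annotations["phred_quality"]),
            seq2=str(rec2.seq).upper(),
            qual2=tuple(rec2.letter_annotations["phred_quality"]),
        )


def write_reads(reads: Iterable[MergedRead | tuple[str, str, Iterable[int]]],
                path: str | Path) -> int:
    """Write reads as 4-line FASTQ records; returns the number written.

    Accepts :class:`MergedRead` objects or ``(id, seq, quals)`` tuples.
    """
    n = 0
    with open_text(path, "wt") as handle:
        for read in reads:
            if isinstance(read, MergedRead):
                rid, seq, quals = read.id, read.seq, read.qual
            else:
                rid, seq, quals = read
            rec = SeqRecord(Seq(seq), id=rid, description="")
            rec.letter_annotations["phred_quality"] = list(quals)
            SeqIO.write(rec, handle, "fastq")
            n += 1
    return n
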