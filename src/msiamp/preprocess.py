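"""Paired-end read merging and whole-read quality filtering.

Amplicons in the default panel are 121–147 bp while MiSeq v2 reads are
2 × 150 bp, so the two mates of a pair overlap across the entire amplicon
and read through into adapter on both sides. Merging reconstructs the
amplicon by exhaustively scanning every relative offset between read 1 and
the reverse complement of read 2, keeping the offset that maximises the
number of matching bases subject to a minimum overlap and a maximum
mismatch fraction, and trimming the merged sequence to the inferred
amplicon (read-1 start through reverse-complemented-read-2 end). Within the
overlap the base with the higher Phred score wins and the merged quality is
the maximum of the two.

Merged reads whose mean Phred quality falls below the configured threshold
(default Q30, an expected error rate below 1/1000) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import reverse_complement

__all__ = [
    "ReadPair",
    "MergedRead",
    "PreprocessConfig",
    "MergeFailure",
    "merge_pair",
    "quality_filter",
]

_ENCODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _ENCODE[_b] = _i


@dataclass(frozen=True)
class PreprocessConfig:
    """Merge and filter parameters.

    min_overlap
        Smallest mate overlap (bp) accepted as evidence the pair spans one
        molecule.
    max_mismatch_fraction
        Largest tolerated fraction of mismatching bases within the overlap.
    quality_threshold
        Mean-Phred cutoff below which a merged read is discarded.
    """

    min_overlap: int = 15
    max_mismatch_fraction: float = 0.1
    quality_threshold: float = 30.0

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0.0 <= self.max_mismatch_fraction <= 1.0:
            raise ValueError("max_mismatch_fraction must be in [0, 1]")
        if self.quality_threshold < 0:
            raise ValueError("quality_threshold must be >= 0")


@dataclass(frozen=True)
class ReadPair:
    id: str
    seq1: str
    qual1: tuple[int, ...]
    seq2: str
    qual2: tuple[int, ...]

    def __post_init__(self) -> None:
        for seq, qual, mate in ((self.seq1, self.qual1, 1),
                                (self.seq2, self.qual2, 2)):
            if len(seq) != len(qual):
                raise ValueError(
                    f"read {self.id!r} mate {mate}: sequence length "
                    f"{len(seq)} != quality length {len(qual)}")
            if qual and not (0 <= min(qual) and max(qual) <= 60):
                raise ValueError(
                    f"read {self.id!r} mate {mate}: Phred scores must lie "
                    f"in [0, 60]")


@dataclass(frozen=True)
class MergedRead:
    id: str
    seq: str
    qual: tuple[int, ...]
    mean_quality: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError("sequence and quality lengths differ")
        if self.mean_quality is None:
            object.__setattr__(
                self, "mean_quality",
                float(np.mean(self.qual)) if self.qual else 0.0)


@dataclass(frozen=True)
class MergeFailure:
    """Returned when no acceptable overlap exists; a value, not an error."""

    id: str
    reason: str = "no acceptable overlap"


def _match_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Matching-base count at every offset of ``b`` relative to ``a``.

    Entry ``o + len(b) - 1`` is the number of positions i with
    ``a[i] == b[i - o]`` and the base not N. Computed as the sum over the
    four base channels of the full cross-correlation of indicator vectors.
    """
    total = np.zeros(len(a) + len(b) - 1, dtype=np.int64)
    for code in range(4):  # N (code 4) never matches
        ia = (a == code).astype(np.float64)
        ib = (b == code).astype(np.float64)
        total += np.rint(np.convolve(ia, ib[::-1])).astype(np.int64)
    return total


def merge_pair(pair: ReadPair, cfg: PreprocessConfig | None = None
               ) -> MergedRead | MergeFailure:
    """Merge one mate pair into a single amplicon sequence.

    Returns a :class:`MergeFailure` when no offset satisfies the overlap
    and mismatch bounds. The merged sequence spans from the start of read 1
    to the end of reverse-complemented read 2 (the inferred amplicon);
    adapter read-through outside that span is trimmed.
    """
    cfg = cfg or PreprocessConfig()
    seq2rc = reverse_complement(pair.seq2)
    qual2rc = pair.qual2[::-1]
    n1, n2 = len(pair.seq1), len(seq2rc)
    if min(n1, n2) < cfg.min_overlap:
        return MergeFailure(pair.id, "reads shorter than min_overlap")

    a = _ENCODE[np.frombuffer(pair.seq1.encode(), dtype=np.uint8)]
    b = _ENCODE[np.frombuffer(seq2rc.encode(), dtype=np.uint8)]
    counts = _match_counts(a, b)

    # offset o = position of seq2rc[0] in read-1 coordinates
    offsets = np.arange(-(n2 - 1), n1)
    starts = np.maximum(0, offsets)
    ends = np.minimum(n1, offsets + n2)
    overlaps = ends - starts
    mismatches = overlaps - counts
    ok = (overlaps >= cfg.min_overlap) & (
        mismatches <= cfg.max_mismatch_fraction * overlaps)
    if not ok.any():
        return MergeFailure(pair.id)

    idx = np.flatnonzero(ok)
    # maximise matches; ties -> longer overlap -> smaller offset
    order = np.lexsort((offsets[idx], -overlaps[idx], -counts[idx]))
    best = idx[order[0]]
    o = int(offsets[best])

    length = o + n2  # inferred amplicon: [0, o + n2) in read-1 coordinates
    if length < 1:
        return MergeFailure(pair.id)
    seq = []
    qual = []
    for i in range(length):
        in1 = i < n1
        in2 = o <= i < o + n2
        if in1 and in2:
            q1, q2 = pair.qual1[i], qual2rc[i - o]
            seq.append(pair.seq1[i] if q1 >= q2 else seq2rc[i - o])
            qual.append(max(q1, q2))
        elif in1:
            seq.append(pair.seq1[i])
            qual.append(pair.qual1[i])
        else:
            seq.append(seq2rc[i - o])
            qual.append(qual2rc[i - o])
    return MergedRead(id=pair.id, seq="".join(seq), qual=tuple(qual))


def quality_filter(read: MergedRead, cfg: PreprocessConfig | None = None
                   ) -> bool:
    """True iff the read's mean Phred quality is at or above the threshold."""
    cfg = cfg or PreprocessConfig()
    return read.mean_quality >= cfg.quality_threshold
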