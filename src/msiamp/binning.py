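"""Alignment-free read binning by flanking-primer lookup.

Each merged read is assigned to a panel locus when the locus's forward
primer matches the read's 5' end and the reverse complement of its reverse
primer matches the 3' end (substitution-only, anchored, configurable
mismatch allowance; the reverse-complemented read is also tried). Because
the two-stage amplicon PCR makes every genuine product primer-terminal,
no genome alignment is needed. Assigned reads are collapsed into groups of
identical sequences with counts, from which per-locus read-count histograms
over amplicon length are built — the quantity the instability call is made
on. Lengths are measured on the full merged amplicon, primers included;
length *deviation* between tumour and normal is invariant to that choice.
"""

from __future__ import annotations

import enum
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .panel import Panel, reverse_complement
from .preprocess import MergedRead

__all__ = [
    "Orientation",
    "Assignment",
    "UNASSIGNED",
    "LookupTable",
    "AmpliconGroup",
    "LengthDistribution",
    "build_lookup",
    "assign_read",
    "group_reads",
    "length_distribution",
    "bin_reads",
]


class Orientation(enum.Enum):
    FORWARD = "+"
    REVERSE = "-"


@dataclass(frozen=True)
class Assignment:
    """Outcome of matching one read against the lookup table."""

    locus_name: str | None
    orientation: Orientation | None = None

    @property
    def assigned(self) -> bool:
        return self.locus_name is not None


UNASSIGNED = Assignment(locus_name=None)


@dataclass(frozen=True)
class LookupTable:
    """Per-locus flank keys: forward primer and reverse-complemented
    reverse primer, as they appear on a merged forward-orientation read."""

    forward_keys: Mapping[str, str]
    reverse_keys: Mapping[str, str]

    @property
    def locus_names(self) -> list[str]:
        return list(self.forward_keys)


@dataclass(frozen=True)
class AmpliconGroup:
    locus_name: str
    seq: str
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")

    @property
    def length_bp(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class LengthDistribution:
    """Read-count histogram over amplicon length for one locus."""

    locus_name: str
    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("all histogram counts must be >= 1")

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    def __bool__(self) -> bool:
        return bool(self.counts)


def build_lookup(panel: Panel) -> LookupTable:
    """Build the flank lookup table for a panel."""
    return LookupTable(
        forward_keys={loc.name: loc.forward_primer for loc in panel},
        reverse_keys={loc.name: reverse_complement(loc.reverse_primer)
                      for loc in panel},
    )


def _mismatches_within(a: str, b: str, limit: int) -> bool:
    if a == b:
        return True
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return False
    return True


def _flanks_match(seq: str, fwd: str, rev: str, limit: int) -> bool:
    if len(seq) < len(fwd) + len(rev):
        return False
    return (_mismatches_within(seq[:len(fwd)], fwd, limit)
            and _mismatches_within(seq[-len(rev):], rev, limit))


def assign_read(read: MergedRead | str, table: LookupTable,
                max_flank_mismatches: int = 0) -> Assignment:
    """Assign a merged read to a locus by anchored flank matching.

    Both orientations are tried; a read matching no locus — or more than
    one — is UNASSIGNED (ambiguity is discarded rather than arbitrated).
    Only substitutions are tolerated in the flanks: a flank indel would
    corrupt the amplicon-length estimate, so such reads fail to match.
    """
    seq = read if isinstance(read, str) else read.seq
    hits: list[Assignment] = []
    seq_rc: str | None = None
    for name in table.forward_keys:
        fwd, rev = table.forward_keys[name], table.reverse_keys[name]
        if _flanks_match(seq, fwd, rev, max_flank_mismatches):
            hits.append(Assignment(name, Orientation.FORWARD))
            continue
        if seq_rc is None:
            seq_rc = reverse_complement(seq)
        if _flanks_match(seq_rc, fwd, rev, max_flank_mismatches):
            hits.append(Assignment(name, Orientation.REVERSE))
    if len(hits) == 1:
        return hits[0]
    return UNASSIGNED


def group_reads(assigned: Iterable[tuple[str, str]]
                ) -> list[AmpliconGroup]:
    """Collapse (locus_name, sequence) pairs into identical-read groups.

    Groups are sorted by locus name, then descending read count, then
    ascending length, then sequence (for full determinism).
    """
    tally: Counter[tuple[str, str]] = Counter()
    for locus_name, seq in assigned:
        tally[(locus_name, seq)] += 1
    groups = [AmpliconGroup(locus_name=k[0], seq=k[1], read_count=n)
              for k, n in tally.items()]
    groups.sort(key=lambda g: (g.locus_name, -g.read_count,
                               g.length_bp, g.seq))
    return groups


def length_distribution(groups: Sequence[AmpliconGroup], locus: str
                        ) -> LengthDistribution:
    """Histogram of read counts over amplicon length for one locus."""
    counts: Counter[int] = Counter()
    for g in groups:
        if g.locus_name != locus:
            raise ValueError(
                f"group for locus {g.locus_name!r} passed to "
                f"length_distribution({locus!r})")
        counts[g.length_bp] += g.read_count
    return LengthDistribution(locus_name=locus, counts=dict(counts))


def bin_reads(reads: Iterable[MergedRead], table: LookupTable,
              max_flank_mismatches: int = 0
              ) -> tuple[dict[str, LengthDistribution], dict[str, int], int]:
    """Assign, group and histogram a stream of merged reads.

    Returns per-locus length distributions, per-locus assigned-read counts,
    and the number of unassigned reads. Reads are conserved:
    ``sum(assigned.values()) + unassigned == number of input reads``.
    """
    per_locus: dict[str, list[tuple[str, str]]] = defaultdict(list)
    unassigned = 0
    for read in reads:
        hit = assign_read(read, table, max_flank_mismatches)
        if hit.assigned:
            seq = read.seq if hit.orientation is Orientation.FORWARD \
                else reverse_complement(read.seq)
            per_locus[hit.locus_name].append((hit.locus_name, seq))
        else:
            unassigned += 1
    distributions = {
        name: length_distribution(group_reads(pairs), name)
        for name, pairs in per_locus.items()
    }
    assigned_counts = {name: d.total_reads
                       for name, d in distributions.items()}
    return distributions, assigned_counts, unassigned
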