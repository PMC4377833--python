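"""Instability calling from modal amplicon lengths.

A locus's modal length is the amplicon length with the highest read count —
the maximally amplified allele in that tissue. A locus is unstable when the
tumour's modal length deviates from the comparator (matched normal tissue,
or a fixed panel reference in tumour-only mode) by at least 2 bp for
mononucleotide repeats or 4 bp for dinucleotide repeats; the looser
dinucleotide cut-off absorbs the single-repeat-unit stutter these loci
show. A sample is MSI-H with two or more unstable loci, MSI-L with exactly
one, MSS with none. Loci with insufficient depth on either side are NO_CALL
and excluded from the denominator; a sample with no informative locus is
INDETERMINATE.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .binning import LengthDistribution
from .panel import LocusDefinition, RepeatClass

__all__ = [
    "ClassifyConfig",
    "LocusStatus",
    "ComparatorSource",
    "OverallStatus",
    "LocusCall",
    "SampleResult",
    "modal_length",
    "call_locus",
    "overall_status",
]


class LocusStatus(enum.Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    NO_CALL = "no_call"


class ComparatorSource(enum.Enum):
    MATCHED_NORMAL = "matched_normal"
    PANEL_REFERENCE = "panel_reference"


class OverallStatus(enum.Enum):
    MSS = "MSS"
    MSI_L = "MSI-L"
    MSI_H = "MSI-H"
    INDETERMINATE = "Indeterminate"


@dataclass(frozen=True)
class ClassifyConfig:
    """Instability cut-offs and depth requirements.

    mono_cutoff_bp / di_cutoff_bp
        Minimum modal-length deviation (bp, inclusive) calling a
        mononucleotide / dinucleotide locus unstable.
    min_reads_per_locus
        Depth below which a side is uninformative and the locus is NO_CALL.
    msi_high_min_unstable
        Unstable-locus count at or above which a sample is MSI-H.
    """

    mono_cutoff_bp: int = 2
    di_cutoff_bp: int = 4
    min_reads_per_locus: int = 100
    msi_high_min_unstable: int = 2

    def __post_init__(self) -> None:
        if self.mono_cutoff_bp < 1 or self.di_cutoff_bp < 1:
            raise ValueError("cut-offs must be >= 1")
        if self.min_reads_per_locus < 0:
            raise ValueError("min_reads_per_locus must be >= 0")

    def cutoff_for(self, locus: LocusDefinition) -> int:
        if locus.repeat_class is RepeatClass.MONONUCLEOTIDE:
            return self.mono_cutoff_bp
        if locus.repeat_class is RepeatClass.DINUCLEOTIDE:
            return self.di_cutoff_bp
        raise ValueError(f"unknown repeat class {locus.repeat_class!r}")


@dataclass(frozen=True)
class LocusCall:
    locus_name: str
    status: LocusStatus
    tumour_modal_length: int | None = None
    comparator_modal_length: int | None = None
    comparator_source: ComparatorSource | None = None
    cutoff_bp: int | None = None

    @property
    def delta_bp(self) -> int | None:
        if (self.tumour_modal_length is None
                or self.comparator_modal_length is None):
            return None
        return abs(self.tumour_modal_length - self.comparator_modal_length)


@dataclass(frozen=True)
class SampleResult:
    sample_id: str
    calls: tuple[LocusCall, ...]
    overall: OverallStatus
    n_unstable: int = field(init=False)
    n_informative: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "n_unstable",
            sum(c.status is LocusStatus.UNSTABLE for c in self.calls))
        object.__setattr__(
            self, "n_informative",
            sum(c.status is not LocusStatus.NO_CALL for c in self.calls))


def modal_length(dist: LengthDistribution,
                 comparator_mode: int | None = None) -> int:
    """Length carrying the maximum read count.

    Ties (equal read counts) break toward the length closest to the
    comparator mode when one is supplied — conservative toward a STABLE
    call — and otherwise toward the shorter length.
    """
    if not dist.counts:
        raise ValueError(
            f"empty length distribution for locus {dist.locus_name!r}")
    if comparator_mode is None:
        return max(dist.counts, key=lambda L: (dist.counts[L], -L))
    return max(dist.counts,
               key=lambda L: (dist.counts[L], -abs(L - comparator_mode), -L))


def call_locus(tumour: LengthDistribution,
               comparator: LengthDistribution | int,
               locus: LocusDefinition,
               cfg: ClassifyConfig | None = None) -> LocusCall:
    """Call one locus stable/unstable from modal-length deviation.

    ``comparator`` is the matched normal's length distribution (paired
    mode) or a fixed reference modal length in bp (tumour-only mode).
    """
    cfg = cfg or ClassifyConfig()
    cutoff = cfg.cutoff_for(locus)

    if isinstance(comparator, LengthDistribution):
        source = ComparatorSource.MATCHED_NORMAL
        comp_deep = comparator.total_reads >= cfg.min_reads_per_locus
        comp_mode = modal_length(comparator) if comparator.counts else None
    else:
        source = ComparatorSource.PANEL_REFERENCE
        comp_deep = True
        comp_mode = int(comparator)

    if tumour.total_reads < cfg.min_reads_per_locus or not comp_deep:
        tum_mode = (modal_length(tumour, comp_mode)
                    if tumour.counts else None)
        return LocusCall(locus_name=locus.name, status=LocusStatus.NO_CALL,
                         tumour_modal_length=tum_mode,
                         comparator_modal_length=comp_mode,
                         comparator_source=source, cutoff_bp=cutoff)

    tum_mode = modal_length(tumour, comp_mode)
    delta = abs(tum_mode - comp_mode)
    status = (LocusStatus.UNSTABLE if delta >= cutoff
              else LocusStatus.STABLE)
    return LocusCall(locus_name=locus.name, status=status,
                     tumour_modal_length=tum_mode,
                     comparator_modal_length=comp_mode,
                     comparator_source=source, cutoff_bp=cutoff)


def overall_status(calls: Iterable[LocusCall],
                   cfg: ClassifyConfig | None = None,
                   sample_id: str = "") -> SampleResult:
    """Combine locus calls into an overall MSI status.

    MSI-H with ``msi_high_min_unstable`` (default 2) or more unstable loci,
    MSI-L with exactly one, MSS with none; INDETERMINATE when no locus is
    informative. NO_CALL loci never count toward instability.
    """
    cfg = cfg or ClassifyConfig()
    calls = tuple(calls)
    informative = [c for c in calls if c.status is not LocusStatus.NO_CALL]
    n_unstable = sum(c.status is LocusStatus.UNSTABLE for c in informative)
    if not informative:
        overall = OverallStatus.INDETERMINATE
    elif n_unstable >= cfg.msi_high_min_unstable:
        overall = OverallStatus.MSI_H
    elif n_unstable >= 1:  # below the MSI-H threshold; == 1 at defaults
        overall = OverallStatus.MSI_L
    else:
        overall = OverallStatus.MSS
    return SampleResult(sample_id=sample_id, calls=calls, overall=overall)


def calls_from_flags(flags: Sequence[bool],
                     locus_names: Sequence[str] | None = None
                     ) -> tuple[LocusCall, ...]:
    """Build bare stable/unstable calls from booleans (True = unstable).

    Used when reclassifying published per-locus call matrices, where the
    underlying length distributions are not available.
    """
    names = locus_names or [f"locus{i + 1}" for i in range(len(flags))]
    return tuple(
        LocusCall(locus_name=name,
                  status=LocusStatus.UNSTABLE if f else LocusStatus.STABLE)
        for name, f in zip(names, flags))
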