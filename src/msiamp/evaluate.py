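"""Performance statistics for MSI marker panels.

Confusion matrices of per-locus NGS calls against a truth column — either
the capillary multiplex-PCR call for the same locus, or the sample's
overall MSI status — with sensitivity, specificity and exact two-sided
(Clopper–Pearson) 95% binomial confidence intervals. Two published call
matrices ship with the package as TSV fixtures: a 44-case colorectal
series with matched normals over five markers, and a 6-case tumour-only
series over BAT25/BAT26.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy.stats import beta

from .classify import (ClassifyConfig, OverallStatus, calls_from_flags,
                       overall_status)

__all__ = [
    "CallMatrix",
    "ConfusionSummary",
    "CohortSummary",
    "clopper_pearson",
    "locus_vs_locus",
    "locus_vs_overall",
    "cohort_summary",
    "load_call_matrix",
    "series1_matrix",
    "series2_matrix",
    "round_half_up",
]

_STATUS = {"High": OverallStatus.MSI_H, "Low": OverallStatus.MSI_L,
           "Stable": OverallStatus.MSS}
_CALL = {"+": True, "-": False}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up, for displaying percentages as printed."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def clopper_pearson(successes: int, trials: int,
                    confidence: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval, in percent.

    Beta-quantile form: lower = B(alpha/2; k, n-k+1), upper =
    B(1-alpha/2; k+1, n-k), with the conventional boundary values 0 at
    k = 0 and 100 at k = n (where the lower bound reduces to
    100 * (alpha/2)^(1/n)).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    alpha = 1.0 - confidence
    lo = 0.0 if successes == 0 else float(
        beta.ppf(alpha / 2, successes, trials - successes + 1))
    hi = 1.0 if successes == trials else float(
        beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return 100.0 * lo, 100.0 * hi


@dataclass(frozen=True)
class ConfusionSummary:
    """Binary confusion counts with exact-interval sensitivity/specificity.

    ``sensitivity``/``specificity`` are percentages, ``None`` when the
    corresponding denominator is zero (not applicable).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    confidence: float = 0.95

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float | None:
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else None

    @property
    def specificity(self) -> float | None:
        neg = self.tn + self.fp
        return 100.0 * self.tn / neg if neg else None

    @property
    def sens_ci(self) -> tuple[float, float] | None:
        pos = self.tp + self.fn
        return clopper_pearson(self.tp, pos, self.confidence) if pos else None

    @property
    def spec_ci(self) -> tuple[float, float] | None:
        neg = self.tn + self.fp
        return clopper_pearson(self.tn, neg, self.confidence) if neg else None


class NotComparableError(ValueError):
    """The requested locus has no truth calls in the matrix."""


@dataclass(frozen=True)
class CallMatrix:
    """Per-case, per-locus paired stable/unstable calls plus overall
    statuses from two methods (``ngs`` prediction, ``pcr`` truth).

    ``pcr`` locus calls may be ``None`` where the comparator assay did not
    include the locus.
    """

    name: str
    cases: tuple[str, ...]
    loci: tuple[str, ...]
    ngs: dict[str, tuple[bool, ...]]
    pcr: dict[str, tuple[bool | None, ...]]
    ngs_status: tuple[OverallStatus, ...]
    pcr_status: tuple[OverallStatus, ...]

    def __len__(self) -> int:
        return len(self.cases)


def load_call_matrix(path: str | Path, name: str | None = None) -> CallMatrix:
    """Read a call matrix from TSV.

    Expected columns: ``case``, one ``<locus>_ngs`` (+/-) and one
    ``<locus>_pcr`` (+/-/NA) per locus, and ``ngs_status``/``pcr_status``
    in {High, Low, Stable}.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    loci = tuple(c[:-4] for c in df.columns if c.endswith("_ngs")
                 and c != "ngs_status")
    ngs = {loc: tuple(_CALL[v] for v in df[f"{loc}_ngs"]) for loc in loci}
    pcr = {loc: tuple(None if v == "NA" else _CALL[v]
                      for v in df[f"{loc}_pcr"]) for loc in loci}
    return CallMatrix(
        name=name or Path(path).stem,
        cases=tuple(df["case"]),
        loci=loci,
        ngs=ngs,
        pcr=pcr,
        ngs_status=tuple(_STATUS[s] for s in df["ngs_status"]),
        pcr_status=tuple(_STATUS[s] for s in df["pcr_status"]),
    )


def _packaged_matrix(filename: str, name: str) -> CallMatrix:
    ref = resources.files("msiamp.data") / filename
    with resources.as_file(ref) as path:
        return load_call_matrix(path, name=name)


def series1_matrix() -> CallMatrix:
    """The packaged 44-case paired tumour/normal series (five markers)."""
    return _packaged_matrix("series1_calls.tsv", "series1")


def series2_matrix() -> CallMatrix:
    """The packaged 6-case tumour-only series (BAT25/BAT26)."""
    return _packaged_matrix("series2_calls.tsv", "series2")


def locus_vs_locus(matrix: CallMatrix, locus: str) -> ConfusionSummary:
    """Confusion of NGS locus calls against the same locus's PCR calls.

    Truth = the multiplex-PCR call; positives = unstable.
    """
    if locus not in matrix.loci:
        raise KeyError(f"locus {locus!r} not in matrix {matrix.name!r}")
    pcr = matrix.pcr[locus]
    if any(v is None for v in pcr):
        raise NotComparableError(
            f"locus {locus!r} has no multiplex-PCR calls in matrix "
            f"{matrix.name!r}; locus-vs-locus comparison is not possible")
    return _confusion(matrix.ngs[locus], pcr)


def locus_vs_overall(matrices: CallMatrix | Sequence[CallMatrix],
                     locus: str) -> ConfusionSummary:
    """Confusion of NGS locus calls against overall MSI-H status.

    Truth = (the sample's PCR overall status is MSI-H); prediction = (the
    NGS call at ``locus`` is unstable). Rows are pooled across the supplied
    matrices, so quasimonomorphic markers present in several series can be
    scored over all cases at once.
    """
    if isinstance(matrices, CallMatrix):
        matrices = [matrices]
    pred: list[bool] = []
    truth: list[bool] = []
    for m in matrices:
        if locus not in m.loci:
            raise KeyError(f"locus {locus!r} not in matrix {m.name!r}")
        pred.extend(m.ngs[locus])
        truth.extend(s is OverallStatus.MSI_H for s in m.pcr_status)
    return _confusion(pred, truth)


def _confusion(pred: Sequence[bool], truth: Sequence[bool]
               ) -> ConfusionSummary:
    tp = sum(p and t for p, t in zip(pred, truth))
    fp = sum(p and not t for p, t in zip(pred, truth))
    tn = sum(not p and not t for p, t in zip(pred, truth))
    fn = sum(not p and t for p, t in zip(pred, truth))
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class CohortSummary:
    """Overall statuses recomputed from per-locus NGS calls."""

    counts: dict[OverallStatus, int]
    recomputed: tuple[OverallStatus, ...]
    discrepancies: tuple[str, ...]  # cases where recomputed != printed


def cohort_summary(matrix: CallMatrix,
                   cfg: ClassifyConfig | None = None) -> CohortSummary:
    """Reclassify every case from its per-locus NGS calls.

    Applies the standard combination rule (>=2 unstable loci MSI-H, 1
    MSI-L, 0 MSS) to each row and cross-checks the matrix's own overall
    NGS status column, reporting any case where the two disagree.
    """
    cfg = cfg or ClassifyConfig()
    recomputed: list[OverallStatus] = []
    discrepancies: list[str] = []
    for i, case in enumerate(matrix.cases):
        flags = [matrix.ngs[loc][i] for loc in matrix.loci]
        result = overall_status(calls_from_flags(flags, matrix.loci), cfg,
                                sample_id=str(case))
        recomputed.append(result.overall)
        if result.overall is not matrix.ngs_status[i]:
            discrepancies.append(str(case))
    counts = {s: recomputed.count(s)
              for s in (OverallStatus.MSS, OverallStatus.MSI_L,
                        OverallStatus.MSI_H)}
    return CohortSummary(counts=counts, recomputed=tuple(recomputed),
                         discrepancies=tuple(discrepancies))


def evaluation_report(matrices: dict[str, CallMatrix]) -> pd.DataFrame:
    """One row per (comparison, locus): counts, sensitivity, specificity
    and 95% CIs, percentages rounded half-up to 1 decimal for display."""
    rows = []

    def add(comparison: str, locus: str, cs: ConfusionSummary) -> None:
        def r(x):
            return None if x is None else round_half_up(x)
        rows.append({
            "comparison": comparison, "locus": locus,
            "tp": cs.tp, "fp": cs.fp, "tn": cs.tn, "fn": cs.fn,
            "sens": r(cs.sensitivity),
            "sens_ci_lo": r(cs.sens_ci[0]) if cs.sens_ci else None,
            "sens_ci_hi": r(cs.sens_ci[1]) if cs.sens_ci else None,
            "spec": r(cs.specificity),
            "spec_ci_lo": r(cs.spec_ci[0]) if cs.spec_ci else None,
            "spec_ci_hi": r(cs.spec_ci[1]) if cs.spec_ci else None,
        })

    for mname, matrix in matrices.items():
        for locus in matrix.loci:
            try:
                add(f"{mname}:ngs-vs-pcr", locus,
                    locus_vs_locus(matrix, locus))
            except NotComparableError:
                pass
            add(f"{mname}:locus-vs-overall", locus,
                locus_vs_overall(matrix, locus))
    pooled_loci = set.intersection(*(set(m.loci) for m in matrices.values())) \
        if len(matrices) > 1 else set()
    for locus in sorted(pooled_loci):
        add("pooled:locus-vs-overall", locus,
            locus_vs_overall(list(matrices.values()), locus))
    return pd.DataFrame(rows)
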