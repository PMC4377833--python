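"""Synthetic paired-end amplicon reads for microsatellite panels.

Emulates MiSeq-style 2 x 150 bp amplicon sequencing over a marker panel:
each locus gets a defined allele (flanks + repeat tract), each sequenced
molecule may slip by whole repeat units (PCR stutter, geometric slip size,
biased toward contraction as polymerase slippage on short tandem repeats
is), then acquires i.i.d. substitution errors. Molecules are emitted as
mate pairs that read through the short amplicon into synthetic adapter,
with per-base Phred qualities drawn from a truncated normal whose mean
tapers after cycle 100 — mimicking the late-cycle quality decline of real
runs — plus a configurable fraction of random off-target pairs. A truth
table records every locus's true modal amplicon length so downstream
modules can be checked end to end.

Output is deterministic given the seed: identical configuration and seed
produce byte-identical FASTQ.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from .fastq import open_text
from .panel import LocusDefinition, Panel, RepeatClass, reverse_complement

__all__ = [
    "AlleleSpec",
    "SimulationConfig",
    "SimulatedSample",
    "TruthEntry",
    "allele_for_locus",
    "simulate_molecule",
    "simulate_sample",
    "write_sample",
]

# Synthetic read-through adapters appended past each amplicon end; fixed,
# distinct sequences so the two mates never spuriously overlap in adapter.
_ADAPTER_R1 = "CTGTCTCTTATACACATCTCCGAGCCCACGAGACTAAGGCGAATCTCGTATGCCGTCTTC"
_ADAPTER_R2 = "CTGTCTCTTATACACATCTGACGCTGCCGACGAGCGATCTAGTGTAGATCTCGGTGGTCG"

_DEFAULT_REPEAT_COUNTS = {
    "BAT25": 25, "BAT26": 26, "BAT34c4": 24, "D18S55": 13, "D5S346": 12,
}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class AlleleSpec:
    """A concrete allele: 5' flank + repeat_unit x repeat_count + 3' flank.

    For the reference allele the assembled amplicon starts with the locus's
    forward primer, ends with the reverse complement of its reverse primer
    and has exactly the reference amplicon length.
    """

    locus_name: str
    repeat_unit: str
    repeat_count: int
    flank5: str
    flank3: str

    @property
    def amplicon(self) -> str:
        return (self.flank5 + self.repeat_unit * self.repeat_count
                + self.flank3)

    def with_shift(self, shift_units: int) -> "AlleleSpec":
        """Allele shifted by whole repeat units (negative = contraction)."""
        new_count = self.repeat_count + shift_units
        if new_count < 1:
            raise ValueError(
                f"shift {shift_units} empties the repeat tract of "
                f"{self.locus_name!r}")
        return replace(self, repeat_count=new_count)


def _filler(name: str, tag: str, n: int) -> str:
    """Deterministic pseudo-random flank filler, stable across processes."""
    seed = zlib.crc32(f"{name}/{tag}".encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(seed)
    return rng.choice(_BASES, size=n).tobytes().decode()


def allele_for_locus(locus: LocusDefinition,
                     repeat_unit: str | None = None,
                     repeat_count: int | None = None) -> AlleleSpec:
    """Construct a reference allele consistent with the locus definition.

    The repeat tract sits centrally between the primers; flank filler is a
    fixed pseudo-random sequence keyed on the locus name, so alleles are
    identical across runs and processes.
    """
    if repeat_unit is None:
        repeat_unit = ("A" if locus.repeat_class is RepeatClass.MONONUCLEOTIDE
                       else "CA")
    if repeat_count is None:
        repeat_count = _DEFAULT_REPEAT_COUNTS.get(
            locus.name,
            20 if locus.repeat_class is RepeatClass.MONONUCLEOTIDE else 12)
        repeat_count = min(repeat_count,
                           locus.core_length // len(repeat_unit))
    tract = len(repeat_unit) * repeat_count
    spare = locus.core_length - tract
    if spare < 0:
        raise ValueError(
            f"repeat tract ({tract} bp) exceeds the amplicon interior "
            f"({locus.core_length} bp) of {locus.name!r}")
    left = spare // 2
    right = spare - left
    return AlleleSpec(
        locus_name=locus.name,
        repeat_unit=repeat_unit,
        repeat_count=repeat_count,
        flank5=locus.forward_primer + _filler(locus.name, "L", left),
        flank3=(_filler(locus.name, "R", right)
                + reverse_complement(locus.reverse_primer)),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated tumour/normal pair.

    shifts
        Tumour length shift per locus, in repeat units (signed; one unit is
        1 bp at mononucleotide loci, 2 bp at dinucleotide loci). Missing
        loci default to 0.
    depth_per_locus
        Molecules sequenced per locus, matching the ~5000x coverage of a
        deep amplicon resequencing run.
    stutter_prob / stutter_geometric_p / stutter_deletion_bias
        Per-molecule slippage probability, geometric slip-size parameter
        and probability that a slip is a contraction.
    """

    panel: Panel
    shifts: dict[str, int] = field(default_factory=dict)
    alleles: dict[str, AlleleSpec] = field(default_factory=dict)
    depth_per_locus: int = 5000
    stutter_prob: float = 0.02
    stutter_geometric_p: float = 0.7
    stutter_deletion_bias: float = 0.8
    substitution_error_rate: float = 0.002
    read_length: int = 150
    quality_mean: float = 36.0
    quality_sd: float = 3.0
    quality_taper_start: int = 100
    quality_taper_slope: float = 0.05
    fraction_offtarget: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.stutter_prob, self.stutter_geometric_p,
                  self.stutter_deletion_bias, self.substitution_error_rate,
                  self.fraction_offtarget):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.depth_per_locus < 0:
            raise ValueError("depth_per_locus must be >= 0")
        for name in self.shifts:
            if name not in self.panel:
                raise ValueError(f"shift given for unknown locus {name!r}")

    def allele(self, locus_name: str) -> AlleleSpec:
        if locus_name in self.alleles:
            return self.alleles[locus_name]
        return allele_for_locus(self.panel[locus_name])


@dataclass(frozen=True)
class TruthEntry:
    locus_name: str
    role: str
    true_modal_length: int
    shift_units: int
    shift_bp: int


@dataclass
class SimulatedSample:
    role: str
    records: list[tuple[str, str, tuple[int, ...], str, tuple[int, ...]]]
    truth: dict[str, TruthEntry]


def simulate_molecule(allele: AlleleSpec, cfg: SimulationConfig,
                      rng: np.random.Generator) -> str:
    """One sequenced molecule: stutter slippage, then substitution errors."""
    count = allele.repeat_count
    if cfg.stutter_prob > 0 and rng.random() < cfg.stutter_prob:
        k = rng.geometric(cfg.stutter_geometric_p)
        if rng.random() < cfg.stutter_deletion_bias:
            count = max(1, count - k)
        else:
            count = count + k
    seq = (allele.flank5 + allele.repeat_unit * count + allele.flank3)
    if cfg.substitution_error_rate > 0:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        hits = np.flatnonzero(rng.random(arr.size)
                              < cfg.substitution_error_rate)
        for i in hits:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = rng.choice(choices)
        seq = arr.tobytes().decode()
    return seq


def _qualities(n: int, cfg: SimulationConfig,
               rng: np.random.Generator) -> tuple[int, ...]:
    cycles = np.arange(n)
    taper = cfg.quality_taper_slope * np.maximum(
        0, cycles - cfg.quality_taper_start)
    q = rng.normal(cfg.quality_mean - taper, cfg.quality_sd)
    return tuple(int(v) for v in np.clip(np.rint(q), 2, 41))


def _pad(seq: str, adapter: str, n: int) -> str:
    out = seq
    while len(out) < n:
        out += adapter
    return out[:n]


def _read_pair_for(amplicon: str, cfg: SimulationConfig,
                   rng: np.random.Generator
                   ) -> tuple[str, tuple[int, ...], str, tuple[int, ...]]:
    r1 = _pad(amplicon, _ADAPTER_R1, cfg.read_length)
    r2 = _pad(reverse_complement(amplicon), _ADAPTER_R2, cfg.read_length)
    return (r1, _qualities(len(r1), cfg, rng),
            r2, _qualities(len(r2), cfg, rng))


def simulate_sample(cfg: SimulationConfig, role: str,
                    rng: np.random.Generator | None = None
                    ) -> SimulatedSample:
    """Simulate one sample (``"tumour"`` applies the configured shifts,
    ``"normal"`` sequences the reference alleles).

    Returns the mate pairs in a deterministic pseudo-random order plus the
    per-locus truth table of true modal amplicon lengths.
    """
    if role not in ("tumour", "normal"):
        raise ValueError(f"role must be 'tumour' or 'normal', got {role!r}")
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 1 if role == "tumour" else 0])

    records = []
    truth: dict[str, TruthEntry] = {}
    for locus in cfg.panel:
        base = cfg.allele(locus.name)
        shift = cfg.shifts.get(locus.name, 0) if role == "tumour" else 0
        allele = base.with_shift(shift) if shift else base
        unit_bp = len(base.repeat_unit)
        truth[locus.name] = TruthEntry(
            locus_name=locus.name, role=role,
            true_modal_length=len(allele.amplicon),
            shift_units=shift, shift_bp=shift * unit_bp)
        for i in range(cfg.depth_per_locus):
            mol = simulate_molecule(allele, cfg, rng)
            r1, q1, r2, q2 = _read_pair_for(mol, cfg, rng)
            records.append((f"{role}:{locus.name}:{i}", r1, q1, r2, q2))

    n_off = int(round(cfg.fraction_offtarget * len(records)))
    for i in range(n_off):
        s1 = rng.choice(_BASES, size=cfg.read_length).tobytes().decode()
        s2 = rng.choice(_BASES, size=cfg.read_length).tobytes().decode()
        records.append((f"{role}:offtarget:{i}",
                        s1, _qualities(cfg.read_length, cfg, rng),
                        s2, _qualities(cfg.read_length, cfg, rng)))

    order = rng.permutation(len(records))
    records = [records[int(j)] for j in order]
    return SimulatedSample(role=role, records=records, truth=truth)


def write_sample(sample: SimulatedSample,
                 r1_path: str | Path, r2_path: str | Path,
                 truth_path: str | Path | None = None) -> None:
    """Write a simulated sample as paired FASTQ(.gz) plus optional truth TSV."""
    with open_text(r1_path, "wt") as h1, open_text(r2_path, "wt") as h2:
        for rid, s1, q1, s2, q2 in sample.records:
            h1.write(_fastq_record(rid, s1, q1))
            h2.write(_fastq_record(rid, s2, q2))
    if truth_path is not None:
        lines = ["locus\trole\ttrue_modal_length\tconfigured_shift"]
        for t in sample.truth.values():
            lines.append(f"{t.locus_name}\t{t.role}\t{t.true_modal_length}"
                         f"\t{t.shift_units}")
        Path(truth_path).write_text("\n".join(lines) + "\n")


def _fastq_record(rid: str, seq: str, qual: Iterable[int]) -> str:
    qstr = "".join(chr(q + 33) for q in qual)
    return f"@{rid}\n{seq}\n+\n{qstr}\n"
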