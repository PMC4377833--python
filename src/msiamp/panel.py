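"""MSI marker panel definitions.

A panel is an ordered set of microsatellite loci, each described by the two
PCR primers that flank its repeat tract, the repeat-unit class
(mononucleotide or dinucleotide — the class sets the instability cut-off),
and the reference amplicon length in base pairs. The default panel ships
with the package and covers the five classical colorectal MSI markers
BAT25, BAT26, BAT34c4, D18S55 and D5S346.

Genomic coordinates are carried as opaque provenance labels only; the
calling method is alignment-free and never uses them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "RepeatClass",
    "LocusDefinition",
    "Panel",
    "PanelError",
    "reverse_complement",
    "load_panel",
    "write_panel",
    "default_panel",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_DNA = frozenset("ACGT")
_DNA_N = frozenset("ACGTN")


class PanelError(ValueError):
    """Malformed or invalid panel configuration."""


class RepeatClass(enum.Enum):
    MONONUCLEOTIDE = "mono"
    DINUCLEOTIDE = "di"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    if not set(seq) <= _DNA_N:
        bad = sorted(set(seq) - _DNA_N)
        raise ValueError(f"non-nucleotide character(s) in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LocusDefinition:
    """One MSI marker: flanking primers, repeat class, reference length.

    ``reference_modal_length`` is the fixed comparator used in tumour-only
    mode (no matched normal). It is meaningful only for quasimonomorphic
    markers such as BAT25 and BAT26, whose normal allele length is nearly
    invariant across individuals; loci without an explicit value are
    excluded from tumour-only runs rather than silently compared against
    the reference amplicon length.
    """

    name: str
    repeat_class: RepeatClass
    forward_primer: str
    reverse_primer: str
    reference_amplicon_length: int
    chromosome_label: str = ""
    coordinates_label: str = ""
    reference_modal_length: int | None = None

    def __post_init__(self) -> None:
        for label, primer in (("forward", self.forward_primer),
                              ("reverse", self.reverse_primer)):
            if not primer or not set(primer) <= _DNA:
                raise PanelError(
                    f"locus {self.name!r}: {label} primer must be a non-empty "
                    f"string over A/C/G/T, got {primer!r}")
        min_len = len(self.forward_primer) + len(self.reverse_primer)
        if self.reference_amplicon_length <= min_len:
            raise PanelError(
                f"locus {self.name!r}: reference_amplicon_length "
                f"{self.reference_amplicon_length} must exceed the combined "
                f"primer length {min_len}")
    @property
    def effective_reference_length(self) -> int:
        """Comparator length: explicit modal reference, else amplicon length."""
        if self.reference_modal_length is not None:
            return self.reference_modal_length
        return self.reference_amplicon_length

    @property
    def core_length(self) -> int:
        """Length of the amplicon interior between the two primers."""
        return (self.reference_amplicon_length
                - len(self.forward_primer) - len(self.reverse_primer))


@dataclass
class Panel:
    """An ordered collection of loci with unique names and distinct primers."""

    loci: list[LocusDefinition]
    name: str = "panel"
    _by_name: dict[str, LocusDefinition] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise PanelError(f"duplicate locus name(s): {dup}")
        primers = [(loc.name, p)
                   for loc in self.loci
                   for p in (loc.forward_primer, loc.reverse_primer)]
        for name_a, a in primers:
            for name_b, b in primers:
                if name_a != name_b and a in b:
                    raise PanelError(
                        f"primer of locus {name_a!r} is a substring of a "
                        f"primer of locus {name_b!r}; flank lookup would be "
                        f"ambiguous")
        self._by_name = {loc.name: loc for loc in self.loci}

    def __iter__(self):
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    def __getitem__(self, name: str) -> LocusDefinition:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]


_REQUIRED_FIELDS = ("name", "repeat_class", "forward_primer",
                    "reverse_primer", "reference_amplicon_length")


def _locus_from_mapping(raw: dict) -> LocusDefinition:
    missing = [f for f in _REQUIRED_FIELDS if f not in raw]
    if missing:
        raise PanelError(
            f"locus entry {raw.get('name', '<unnamed>')!r}: missing required "
            f"field(s) {missing}")
    try:
        repeat_class = RepeatClass(raw["repeat_class"])
    except ValueError as exc:
        raise PanelError(
            f"locus {raw['name']!r}: repeat_class must be one of "
            f"{[c.value for c in RepeatClass]}, got {raw['repeat_class']!r}"
        ) from exc
    return LocusDefinition(
        name=str(raw["name"]),
        repeat_class=repeat_class,
        forward_primer=str(raw["forward_primer"]).upper(),
        reverse_primer=str(raw["reverse_primer"]).upper(),
        reference_amplicon_length=int(raw["reference_amplicon_length"]),
        chromosome_label=str(raw.get("chromosome_label", "")),
        coordinates_label=str(raw.get("coordinates_label", "")),
        reference_modal_length=(int(raw["reference_modal_length"])
                                if raw.get("reference_modal_length") is not None
                                else None),
    )


def load_panel(path: str | Path) -> Panel:
    """Read a panel from a YAML configuration file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise PanelError(f"cannot parse panel file {path}: {exc}") from exc
    if not isinstance(raw, dict) or "loci" not in raw:
        raise PanelError(f"panel file {path} must contain a 'loci' list")
    loci = [_locus_from_mapping(entry) for entry in raw["loci"]]
    return Panel(loci=loci, name=str(raw.get("name", path.stem)))


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel to YAML; ``load_panel`` round-trips it field-for-field."""
    doc = {
        "name": panel.name,
        "loci": [
            {
                "name": loc.name,
                "chromosome_label": loc.chromosome_label,
                "coordinates_label": loc.coordinates_label,
                "repeat_class": loc.repeat_class.value,
                "forward_primer": loc.forward_primer,
                "reverse_primer": loc.reverse_primer,
                "reference_amplicon_length": loc.reference_amplicon_length,
                "reference_modal_length": loc.reference_modal_length,
            }
            for loc in panel
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def default_panel() -> Panel:
    """The packaged five-marker colorectal MSI panel."""
    ref = resources.files("msiamp.data") / "default_panel.yaml"
    with resources.as_file(ref) as path:
        return load_panel(path)
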