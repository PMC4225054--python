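"""Declarative reward-gene risk panels.

A panel is an ordered list of markers.  Each marker declares its gene, an
identifier (rsID or conventional name), a class (SNP, VNTR, or a length
polymorphism such as 5-HTTLPR S/L), whether it sits on an autosome or the
X chromosome, the universe of allele labels it can take, and which of those
labels count as *risk* alleles.  VNTR markers may instead declare risk as a
repeat-count predicate (``repeats >= k``), which is resolved against the
allele universe at load time.

Three panels ship with the package:

``gars9``
    The nine-gene study panel (DRD2, DRD3, DRD4, MAOA, COMT, DAT1,
    5-HTTLPR, OPRM1, GABRB3).  With its single X-linked marker
    (MAOA-uVNTR) it exposes 18 countable allele slots for females and 17
    for males.
``gars10``
    gars9 plus DRD1 (risk allele 48G).
``extended``
    gars10 plus the two 5-HT2A receptor SNPs (T102C, -1438G/A).

Allele labels are case-insensitive and stored uppercase.
"""

from __future__ import annotations

import enum
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

import yaml

from .errors import PanelError

__all__ = [
    "MarkerClass",
    "ChromosomeClass",
    "Sex",
    "MarkerDefinition",
    "PanelDefinition",
    "load_panel",
    "builtin_panel",
    "builtin_panel_names",
    "dump_panel",
    "countable_alleles",
]

BUILTIN_PANELS = ("gars9", "gars10", "extended")

_REPEAT_RE = re.compile(r"^(\d+)R$")


class MarkerClass(str, enum.Enum):
    SNP = "SNP"
    VNTR = "VNTR"
    LENGTH_POLYMORPHISM = "LENGTH_POLYMORPHISM"


class ChromosomeClass(str, enum.Enum):
    AUTOSOMAL = "AUTOSOMAL"
    X_LINKED = "X_LINKED"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"
    UNKNOWN = "UNKNOWN"


def _norm_allele(label: object) -> str:
    return str(label).strip().upper()


def repeat_count(label: str) -> int | None:
    """Repeat count of a VNTR allele label like ``9R``, or None."""
    m = _REPEAT_RE.match(label)
    return int(m.group(1)) if m else None


@dataclass(frozen=True)
class MarkerDefinition:
    """One polymorphic marker and its risk-allele declaration.

    ``allele_universe`` is ordered as declared; the first non-risk member
    (or the explicit ``baseline``) is the canonical non-risk label used
    when the simulator collapses a multi-allelic VNTR to risk vs non-risk.
    ``risk_min_repeats`` records a repeat-count predicate; when present,
    ``risk_alleles`` holds the labels of the universe satisfying it.
    """

    gene_symbol: str
    marker_id: str
    marker_class: MarkerClass
    chromosome_class: ChromosomeClass
    allele_universe: tuple[str, ...]
    risk_alleles: frozenset[str]
    risk_min_repeats: int | None = None
    baseline: str | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if not self.allele_universe:
            raise PanelError(f"marker {self.marker_id}: empty allele universe")
        if len(set(self.allele_universe)) != len(self.allele_universe):
            raise PanelError(f"marker {self.marker_id}: duplicate allele labels")
        if not self.risk_alleles:
            raise PanelError(f"marker {self.marker_id}: no risk alleles")
        extra = self.risk_alleles - set(self.allele_universe)
        if extra:
            raise PanelError(
                f"marker {self.marker_id}: risk allele(s) {sorted(extra)} "
                "outside allele universe"
            )
        if self.risk_min_repeats is not None:
            bad = [a for a in self.allele_universe if repeat_count(a) is None]
            if bad:
                raise PanelError(
                    f"marker {self.marker_id}: repeat predicate not evaluable "
                    f"on allele(s) {bad}"
                )
        if self.baseline is not None and self.baseline not in self.allele_universe:
            raise PanelError(
                f"marker {self.marker_id}: baseline {self.baseline!r} outside "
                "allele universe"
            )
        if self.baseline is not None and self.baseline in self.risk_alleles:
            raise PanelError(
                f"marker {self.marker_id}: baseline {self.baseline!r} is a risk allele"
            )

    @property
    def is_x_linked(self) -> bool:
        return self.chromosome_class is ChromosomeClass.X_LINKED

    def is_risk(self, allele: str) -> bool:
        return _norm_allele(allele) in self.risk_alleles

    def non_risk_baseline(self) -> str:
        """Canonical non-risk allele label for risk/non-risk collapsing."""
        if self.baseline is not None:
            return self.baseline
        for a in self.allele_universe:
            if a not in self.risk_alleles:
                return a
        raise PanelError(
            f"marker {self.marker_id}: every allele is a risk allele; "
            "no non-risk baseline exists"
        )


@dataclass(frozen=True)
class PanelDefinition:
    """Named, versioned, ordered collection of markers."""

    name: str
    version: str
    markers: tuple[MarkerDefinition, ...]
    _by_id: Mapping[str, MarkerDefinition] = field(
        init=False, repr=False, compare=False, default=None  # type: ignore[assignment]
    )

    def __post_init__(self) -> None:
        if not self.markers:
            raise PanelError(f"panel {self.name!r}: must declare at least one marker")
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelError(f"panel {self.name!r}: duplicate marker ids {dupes}")
        object.__setattr__(self, "_by_id", {m.marker_id: m for m in self.markers})

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._by_id

    def marker(self, marker_id: str) -> MarkerDefinition:
        try:
            return self._by_id[marker_id]
        except KeyError:
            raise PanelError(
                f"panel {self.name!r} has no marker {marker_id!r}"
            ) from None

    @property
    def marker_ids(self) -> tuple[str, ...]:
        return tuple(m.marker_id for m in self.markers)

    @property
    def x_linked_markers(self) -> tuple[MarkerDefinition, ...]:
        return tuple(m for m in self.markers if m.is_x_linked)


def countable_alleles(panel: PanelDefinition, sex: Sex | str) -> int:
    """Total allele slots the panel exposes for a subject of the given sex.

    Autosomal markers contribute 2 slots each; X-linked markers contribute
    2 for females, 1 for hemizygous males.  For the nine-gene panel this is
    the familiar 18 (F) / 17 (M).

    Raises
    ------
    PanelError
        If the panel contains an X-linked marker and sex is UNKNOWN.
    """
    sex = Sex(sex)
    n_x = len(panel.x_linked_markers)
    if n_x and sex is Sex.UNKNOWN:
        raise PanelError(
            f"panel {panel.name!r} contains X-linked marker(s) "
            f"{[m.marker_id for m in panel.x_linked_markers]}; "
            "supply sex F or M to count allele slots"
        )
    n_auto = len(panel) - n_x
    per_x = 2 if sex is Sex.F else 1
    return 2 * n_auto + per_x * n_x


def _parse_marker(raw: Mapping, index: int) -> MarkerDefinition:
    if not isinstance(raw, Mapping):
        raise PanelError(f"marker #{index + 1}: expected a mapping, got {type(raw).__name__}")
    ident = raw.get("id", f"#{index + 1}")
    required = ("gene", "id", "class", "chrom", "alleles", "risk")
    missing = [k for k in required if k not in raw]
    if missing:
        raise PanelError(f"marker {ident}: missing required key(s) {missing}")
    try:
        mclass = MarkerClass(str(raw["class"]).upper())
    except ValueError:
        raise PanelError(
            f"marker {ident}: unknown class {raw['class']!r} "
            f"(expected one of {[c.value for c in MarkerClass]})"
        ) from None
    try:
        chrom = ChromosomeClass(str(raw["chrom"]).upper())
    except ValueError:
        raise PanelError(
            f"marker {ident}: unknown chromosome class {raw['chrom']!r} "
            f"(expected one of {[c.value for c in ChromosomeClass]})"
        ) from None
    if not isinstance(raw["alleles"], (list, tuple)):
        raise PanelError(f"marker {ident}: 'alleles' must be a list")
    universe = tuple(_norm_allele(a) for a in raw["alleles"])

    risk_spec = raw["risk"]
    min_repeats: int | None = None
    if isinstance(risk_spec, Mapping):
        if set(risk_spec) != {"min_repeats"}:
            raise PanelError(
                f"marker {ident}: risk predicate must be {{min_repeats: k}}, "
                f"got {dict(risk_spec)!r}"
            )
        min_repeats = int(risk_spec["min_repeats"])
        bad = [a for a in universe if repeat_count(a) is None]
        if bad:
            raise PanelError(
                f"marker {ident}: repeat predicate not evaluable on "
                f"allele(s) {bad}"
            )
        risk = frozenset(
            a for a in universe
            if (rc := repeat_count(a)) is not None and rc >= min_repeats
        )
        if not risk:
            raise PanelError(
                f"marker {ident}: no allele in the universe satisfies "
                f"repeats >= {min_repeats}"
            )
    elif isinstance(risk_spec, (list, tuple)):
        risk = frozenset(_norm_allele(a) for a in risk_spec)
    else:
        raise PanelError(
            f"marker {ident}: 'risk' must be a list of alleles or "
            "{min_repeats: k}"
        )

    baseline = raw.get("baseline")
    return MarkerDefinition(
        gene_symbol=str(raw["gene"]),
        marker_id=str(raw["id"]),
        marker_class=mclass,
        chromosome_class=chrom,
        allele_universe=universe,
        risk_alleles=risk,
        risk_min_repeats=min_repeats,
        baseline=_norm_allele(baseline) if baseline is not None else None,
        note=str(raw.get("note", "")),
    )


def load_panel(source: Union[str, Path, io.TextIOBase, Mapping]) -> PanelDefinition:
    """Load and validate a panel from YAML (path, text, open file, or dict).

    A bare builtin name (``gars9``, ``gars10``, ``extended``) is resolved
    to the corresponding packaged panel.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        if isinstance(source, (str, Path)):
            text_candidate = str(source)
            if text_candidate in BUILTIN_PANELS:
                return builtin_panel(text_candidate)
            p = Path(source)
            if p.exists():
                text = p.read_text()
            elif isinstance(source, str) and "\n" in source:
                text = source
            else:
                raise PanelError(f"panel source {source!r}: no such file or builtin panel")
        else:
            text = source.read()
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise PanelError(f"panel document does not parse: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise PanelError("panel document must be a mapping with keys name/version/markers")
    for key in ("name", "markers"):
        if key not in doc:
            raise PanelError(f"panel document missing required key {key!r}")
    raw_markers = doc["markers"]
    if not isinstance(raw_markers, (list, tuple)) or not raw_markers:
        raise PanelError(f"panel {doc['name']!r}: 'markers' must be a nonempty list")
    markers = tuple(_parse_marker(m, i) for i, m in enumerate(raw_markers))
    return PanelDefinition(
        name=str(doc["name"]),
        version=str(doc.get("version", "0")),
        markers=markers,
    )


def builtin_panel(name: str) -> PanelDefinition:
    """Load one of the packaged panels by name."""
    if name not in BUILTIN_PANELS:
        raise PanelError(
            f"unknown builtin panel {name!r}; available: {list(BUILTIN_PANELS)}"
        )
    text = resources.files("garscore").joinpath("panels", f"{name}.yaml").read_text()
    return load_panel(yaml.safe_load(text))


def builtin_panel_names() -> tuple[str, ...]:
    return BUILTIN_PANELS


def dump_panel(panel: PanelDefinition) -> str:
    """Serialize a panel to the YAML dialect :func:`load_panel` accepts.

    Round-trips: ``load_panel(dump_panel(p)) == p``.
    """
    markers = []
    for m in panel.markers:
        risk: object
        if m.risk_min_repeats is not None:
            risk = {"min_repeats": m.risk_min_repeats}
        else:
            # preserve universe order for a stable round-trip
            risk = [a for a in m.allele_universe if a in m.risk_alleles]
        entry = {
            "gene": m.gene_symbol,
            "id": m.marker_id,
            "class": m.marker_class.value,
            "chrom": m.chromosome_class.value,
            "alleles": list(m.allele_universe),
            "risk": risk,
        }
        if m.baseline is not None:
            entry["baseline"] = m.baseline
        if m.note:
            entry["note"] = m.note
        markers.append(entry)
    doc = {"name": panel.name, "version": panel.version, "markers": markers}
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)
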