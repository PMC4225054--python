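"""Genotype I/O: canonical delimited tables and a SNP-only VCF subset.

The canonical exchange format is a tab-delimited genotype table::

    subject_id  sex  rs1800497  DRD4-exon3-VNTR  MAOA-uVNTR ...
    S1          F    A1/A2      4R/7R            3R/4R
    S2          M    A2/A2      4R/4R            4R

Diploid calls are written ``X/Y`` (order non-semantic), hemizygous male
X-linked calls as a single allele ``X``, missing as ``.`` or ``./.``.

VCF input is supported for SNP-class markers only: the panel's VNTR and
length polymorphisms (DAT1, DRD4, MAOA-uVNTR, 5-HTTLPR, GABRB3) have no
faithful VCF representation, so those markers are left MISSING with a
logged notice.  Sites are matched by the VCF ID field (rsID), never by
position, and REF/ALT base calls are translated to panel labels through an
explicit rsID map; no strand flipping is attempted.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Optional, Sequence

from .errors import GarsError, GenotypeValidationError
from .panel import ChromosomeClass, MarkerClass, PanelDefinition, Sex, _norm_allele

if TYPE_CHECKING:  # pragma: no cover
    from .scoring import ScoreResult

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeCall",
    "SubjectGenotype",
    "CohortTable",
    "read_genotype_table",
    "read_vcf_subset",
    "write_genotype_table",
    "write_scores",
    "DEFAULT_RSID_MAP",
]

MISSING_TOKENS = {".", "./.", "", "NA"}

#: REF/ALT -> panel-label translation for the builtin SNP markers.
DEFAULT_RSID_MAP: Mapping[str, Mapping[str, str]] = {
    "rs1800497": {"ref": "A2", "alt": "A1"},   # DRD2 Taq I
    "rs6280": {"ref": "T", "alt": "C"},        # DRD3 Ser9Gly
    "rs4680": {"ref": "A", "alt": "G"},        # COMT Val158Met (G=Val)
    "rs1799971": {"ref": "A", "alt": "G"},     # OPRM1 A118G
    "rs4532": {"ref": "48A", "alt": "48G"},    # DRD1 -48A/G
    "rs6313": {"ref": "C", "alt": "T"},        # HTR2A T102C (risk C is REF)
    "rs6311": {"ref": "G", "alt": "A"},        # HTR2A -1438G/A
}


@dataclass(frozen=True)
class GenotypeCall:
    """An unordered call of 1-2 allele labels, or MISSING (empty)."""

    alleles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @classmethod
    def missing(cls) -> "GenotypeCall":
        return cls(())

    @property
    def is_missing(self) -> bool:
        return not self.alleles

    @property
    def ploidy(self) -> int:
        return len(self.alleles)

    def __str__(self) -> str:
        return "/".join(self.alleles) if self.alleles else "."


@dataclass(frozen=True)
class SubjectGenotype:
    """Per-subject allele calls keyed by marker id, plus sex."""

    subject_id: str
    sex: Sex
    calls: Mapping[str, GenotypeCall]

    def call(self, marker_id: str) -> GenotypeCall:
        return self.calls.get(marker_id, GenotypeCall.missing())


@dataclass
class CohortTable:
    """An ordered cohort of subjects validated against one panel."""

    panel: PanelDefinition
    subjects: list[SubjectGenotype]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GenotypeValidationError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)


def _validate_call(
    marker, alleles: Sequence[str], sex: Sex, subject_id: str
) -> GenotypeCall:
    """Normalize and validate raw allele labels for one marker."""
    labels = [_norm_allele(a) for a in alleles]
    for lab in labels:
        if lab not in marker.allele_universe:
            raise GenotypeValidationError(
                f"subject {subject_id!r}, marker {marker.marker_id}: allele "
                f"{lab!r} not in universe {list(marker.allele_universe)}"
            )
    if marker.chromosome_class is ChromosomeClass.X_LINKED and sex is Sex.M:
        if len(labels) == 2:
            if labels[0] != labels[1]:
                raise GenotypeValidationError(
                    f"subject {subject_id!r}, marker {marker.marker_id}: male "
                    f"with two distinct X-linked alleles {labels}"
                )
            # common genotyping-export artifact: "4R/4R" for a hemizygote
            logger.warning(
                "subject %r, marker %s: male X-linked call %s collapsed to "
                "hemizygous %s",
                subject_id, marker.marker_id, "/".join(labels), labels[0],
            )
            labels = labels[:1]
        if len(labels) != 1:
            raise GenotypeValidationError(
                f"subject {subject_id!r}, marker {marker.marker_id}: male "
                f"X-linked call must hold exactly 1 allele, got {len(labels)}"
            )
    else:
        if len(labels) != 2:
            raise GenotypeValidationError(
                f"subject {subject_id!r}, marker {marker.marker_id}: expected "
                f"a diploid call, got {len(labels)} allele(s)"
            )
    return GenotypeCall(tuple(labels))


def _parse_sex(token: str, subject_id: str) -> Sex:
    t = token.strip().upper()
    aliases = {"F": Sex.F, "FEMALE": Sex.F, "M": Sex.M, "MALE": Sex.M,
               "U": Sex.UNKNOWN, "UNKNOWN": Sex.UNKNOWN, ".": Sex.UNKNOWN}
    if t not in aliases:
        raise GenotypeValidationError(
            f"subject {subject_id!r}: unrecognized sex {token!r} (use F/M/UNKNOWN)"
        )
    return aliases[t]


def read_genotype_table(path: str | Path, panel: PanelDefinition) -> CohortTable:
    """Read the canonical tab-delimited genotype table against a panel.

    Header must start ``subject_id<TAB>sex`` followed by one column per
    marker id.  Unknown columns are reported and ignored; panel markers
    absent from the header are MISSING for every subject.  Per-marker call
    rates are logged.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise GenotypeValidationError(f"{path}: empty genotype table") from None
        header = [h.strip() for h in header]
        if header[:2] != ["subject_id", "sex"]:
            raise GenotypeValidationError(
                f"{path}: first two columns must be subject_id, sex "
                f"(got {header[:2]})"
            )
        marker_cols: dict[str, int] = {}
        unknown: list[str] = []
        for idx, name in enumerate(header[2:], start=2):
            if name in panel:
                marker_cols[name] = idx
            else:
                unknown.append(name)
        if unknown:
            logger.warning(
                "%s: ignoring %d column(s) not in panel %r: %s",
                path, len(unknown), panel.name, unknown,
            )
        subjects: list[SubjectGenotype] = []
        n_called: dict[str, int] = {mid: 0 for mid in marker_cols}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise GenotypeValidationError(
                    f"{path}:{lineno}: row has fewer than 2 columns"
                )
            subject_id = row[0].strip()
            sex = _parse_sex(row[1], subject_id)
            calls: dict[str, GenotypeCall] = {}
            for mid, idx in marker_cols.items():
                token = row[idx].strip() if idx < len(row) else "."
                if token in MISSING_TOKENS:
                    calls[mid] = GenotypeCall.missing()
                    continue
                alleles = token.split("/") if "/" in token else [token]
                calls[mid] = _validate_call(panel.marker(mid), alleles, sex, subject_id)
                n_called[mid] += 1
            subjects.append(SubjectGenotype(subject_id, sex, calls))
    for mid in marker_cols:
        rate = n_called[mid] / len(subjects) if subjects else 0.0
        logger.info("%s: marker %s call rate %.3f", path, mid, rate)
    return CohortTable(
        panel=panel,
        subjects=subjects,
        provenance=f"genotype table {path} ({len(subjects)} subjects)",
    )


def read_vcf_subset(
    path: str | Path,
    panel: PanelDefinition,
    rsid_map: Optional[Mapping[str, Mapping[str, str]]] = None,
    sexes: Optional[Mapping[str, Sex | str]] = None,
) -> CohortTable:
    """Populate SNP-class panel markers from a VCF (GT fields, matched by rsID).

    ``rsid_map`` maps each rsID to ``{"ref": <panel label>, "alt": <panel
    label>}``; the packaged :data:`DEFAULT_RSID_MAP` covers the builtin SNP
    markers.  VNTR and length-polymorphism markers are left MISSING.
    ``sexes`` optionally supplies per-sample sex (default UNKNOWN).
    """
    from cyvcf2 import VCF  # deferred: htslib import is relatively heavy

    path = Path(path)
    if rsid_map is None:
        rsid_map = DEFAULT_RSID_MAP
    snp_markers = {
        m.marker_id: m for m in panel if m.marker_class is MarkerClass.SNP
    }
    skipped = [m.marker_id for m in panel if m.marker_class is not MarkerClass.SNP]
    if skipped:
        logger.info(
            "%s: non-SNP marker(s) %s cannot be read from VCF; left MISSING",
            path, skipped,
        )
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise GarsError(f"{path}: malformed or unreadable VCF: {exc}") from exc
    samples = list(vcf.samples)
    sex_of = {
        s: Sex(sexes[s]) if sexes and s in sexes else Sex.UNKNOWN for s in samples
    }
    calls: dict[str, dict[str, GenotypeCall]] = {s: {} for s in samples}
    n_sites = 0
    for var in vcf:
        rsid = var.ID
        if rsid is None or rsid not in rsid_map or rsid not in snp_markers:
            continue
        marker = snp_markers[rsid]
        mapping = rsid_map[rsid]
        if len(var.ALT) > 1:
            logger.warning(
                "%s: multi-allelic site %s not covered by rsid map; calls MISSING",
                path, rsid,
            )
            for s in samples:
                calls[s][rsid] = GenotypeCall.missing()
            continue
        n_sites += 1
        label_of = {0: _norm_allele(mapping["ref"]), 1: _norm_allele(mapping["alt"])}
        for s_idx, gt in enumerate(var.genotypes):
            sample = samples[s_idx]
            allele_idx = [g for g in gt[:-1] if g is not None and g >= 0]
            if not allele_idx:
                calls[sample][rsid] = GenotypeCall.missing()
                continue
            labels = [label_of[g] for g in allele_idx]
            calls[sample][rsid] = _validate_call(
                marker, labels, sex_of[sample], sample
            )
    if n_sites == 0:
        logger.warning("%s: VCF contains none of the panel's rsIDs; all calls MISSING", path)
    subjects = [
        SubjectGenotype(
            subject_id=s,
            sex=sex_of[s],
            calls={
                mid: calls[s].get(mid, GenotypeCall.missing())
                for mid in panel.marker_ids
            },
        )
        for s in samples
    ]
    return CohortTable(
        panel=panel,
        subjects=subjects,
        provenance=f"VCF {path} ({len(subjects)} samples, {n_sites} panel sites)",
    )


def write_genotype_table(path: str | Path, cohort: CohortTable) -> None:
    """Write a cohort back to the canonical tab-delimited format."""
    path = Path(path)
    panel = cohort.panel
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["subject_id", "sex"] + list(panel.marker_ids))
        for subj in cohort:
            writer.writerow(
                [subj.subject_id, subj.sex.value]
                + [str(subj.call(mid)) for mid in panel.marker_ids]
            )
    logger.info("%s: wrote %d subjects, %d markers", path, len(cohort), len(panel))


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero at the given decimal place (41.15 -> 41.2)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def write_scores(path: str | Path, results: "Sequence[ScoreResult]") -> None:
    """Write score results as TSV with a fixed column order.

    Columns: subject_id, sex, risk_alleles, countable_alleles, percentage
    (one decimal, half-up), severity, call_rate (three decimals).
    """
    if not results:
        raise GarsError("write_scores: no results to write")
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["subject_id", "sex", "risk_alleles", "countable_alleles",
             "percentage", "severity", "call_rate"]
        )
        for r in results:
            writer.writerow(
                [r.subject_id, r.sex.value, r.risk_alleles_carried,
                 r.countable_alleles, f"{round_half_up(r.percentage, 1):.1f}",
                 r.severity.value, f"{r.call_rate:.3f}"]
            )
    logger.info("%s: wrote %d score rows", path, len(results))
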