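"""The GARS computation: risk-allele counting, percentage, severity bands.

The score is an unweighted count.  For each non-missing marker every
allele in the call that belongs to the marker's risk set adds 1 to the
numerator; the denominator is the number of allele slots actually called
(2 per autosomal marker, 2 per X-linked marker for females, 1 for males).
Missing markers are excluded from both numerator and denominator — calling
them non-risk would bias the percentage downward — and the call rate is
reported alongside so consumers can filter low-coverage subjects.

The percentage 100 x carried / countable is stratified into the printed
severity bands after rounding half-up to the nearest integer percent:
LOW 1-36, MODERATE 37-50, HIGH 51-100.  An exact 0 % is reported as its
own ZERO band because the printed low band starts at 1 %; pass
``zero_as_low=True`` to collapse it into LOW.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import GarsError, GenotypeValidationError, UnscorableError
from .genotype_io import CohortTable, SubjectGenotype, round_half_up
from .panel import PanelDefinition, Sex, countable_alleles

__all__ = [
    "Severity",
    "ScoreResult",
    "CohortSummary",
    "count_risk_alleles",
    "gars_percentage",
    "stratify_severity",
    "score_subject",
    "score_cohort",
    "summarize_cohort",
]


class Severity(str, enum.Enum):
    ZERO = "ZERO"
    LOW = "LOW"
    MODERATE = "MODERATE"
    HIGH = "HIGH"


@dataclass(frozen=True)
class ScoreResult:
    subject_id: str
    sex: Sex
    risk_alleles_carried: int
    countable_alleles: int
    percentage: float
    severity: Severity
    call_rate: float


@dataclass(frozen=True)
class CohortSummary:
    n_subjects: int
    band_fractions: Mapping[Severity, float]
    mean_percentage: float
    median_percentage: float


def count_risk_alleles(
    subject: SubjectGenotype, panel: PanelDefinition
) -> tuple[int, int, float]:
    """Count (carried, countable, call_rate) for one subject.

    ``carried`` is the number of called alleles in the risk set, ``countable``
    the number of called allele slots, and ``call_rate`` the fraction of the
    subject's full sex-specific slot count that was called.
    """
    carried = 0
    countable = 0
    full = 0
    for marker in panel:
        slots = 1 if (marker.is_x_linked and subject.sex is Sex.M) else 2
        call = subject.call(marker.marker_id)
        if call.is_missing:
            # sex UNKNOWN with a missing X call: treat the marker as diploid
            # for the call-rate denominator only (its slots were never called)
            full += slots
            continue
        if marker.is_x_linked and subject.sex is Sex.UNKNOWN:
            raise GenotypeValidationError(
                f"subject {subject.subject_id!r}: X-linked marker "
                f"{marker.marker_id} is called but sex is UNKNOWN; supply sex"
            )
        if call.ploidy != slots:
            raise GenotypeValidationError(
                f"subject {subject.subject_id!r}, marker {marker.marker_id}: "
                f"call has {call.ploidy} allele(s), expected {slots}"
            )
        full += slots
        countable += slots
        carried += sum(1 for a in call.alleles if marker.is_risk(a))
    call_rate = countable / full if full else 0.0
    return carried, countable, call_rate


def gars_percentage(carried: int, countable: int) -> float:
    """Risk-allele percentage 100 x carried / countable."""
    if countable <= 0:
        raise UnscorableError(
            "subject has no countable alleles (all panel markers missing)"
        )
    if not 0 <= carried <= countable:
        raise GarsError(f"carried={carried} outside [0, countable={countable}]")
    return 100.0 * carried / countable


def stratify_severity(percentage: float, zero_as_low: bool = False) -> Severity:
    """Map a percentage onto the printed severity bands.

    The percentage is rounded half-up to an integer p, then
    ZERO if p = 0 (unless ``zero_as_low``), LOW for 1-36,
    MODERATE for 37-50, HIGH for 51-100.
    """
    if not 0.0 <= percentage <= 100.0:
        raise GarsError(f"percentage {percentage} outside [0, 100]")
    p = int(round_half_up(percentage, 0))
    if p == 0:
        return Severity.LOW if zero_as_low else Severity.ZERO
    if p <= 36:
        return Severity.LOW
    if p <= 50:
        return Severity.MODERATE
    return Severity.HIGH


def score_subject(
    subject: SubjectGenotype,
    panel: PanelDefinition,
    zero_as_low: bool = False,
) -> ScoreResult:
    carried, countable, call_rate = count_risk_alleles(subject, panel)
    pct = gars_percentage(carried, countable)
    return ScoreResult(
        subject_id=subject.subject_id,
        sex=subject.sex,
        risk_alleles_carried=carried,
        countable_alleles=countable,
        percentage=pct,
        severity=stratify_severity(pct, zero_as_low=zero_as_low),
        call_rate=call_rate,
    )


def score_cohort(
    cohort: CohortTable, zero_as_low: bool = False
) -> list[ScoreResult]:
    """Score every subject in a cohort against its panel."""
    return [score_subject(s, cohort.panel, zero_as_low=zero_as_low) for s in cohort]


def summarize_cohort(results: Sequence[ScoreResult]) -> CohortSummary:
    """Severity-band fractions and mean/median percentage for a cohort."""
    if not results:
        raise GarsError("summarize_cohort: empty result list")
    n = len(results)
    fractions = {
        band: sum(1 for r in results if r.severity is band) / n
        for band in Severity
        if any(r.severity is band for r in results)
    }
    pcts = [r.percentage for r in results]
    return CohortSummary(
        n_subjects=n,
        band_fractions=fractions,
        mean_percentage=statistics.fmean(pcts),
        median_percentage=statistics.median(pcts),
    )
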