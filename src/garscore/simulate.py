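"""Synthetic genotype-cohort simulator.

Cohorts are drawn under the null model the scorer and association module
assume: Hardy-Weinberg equilibrium at every marker and linkage equilibrium
between markers.  Autosomal genotypes are two independent draws at the
risk-allele frequency; at an X-linked marker males draw one allele and
females two.  Multi-allelic VNTR universes collapse to risk vs one
canonical non-risk label unless a full per-allele frequency vector is
supplied.  Missingness is applied independently per call.

Reproducibility contract: one root seed; every (population, marker)
pair gets its own deterministic substream (keyed by CRC-32 of the names,
not by position), so adding or removing a marker never perturbs the draws
of the others.  Identical seed + config therefore yields byte-identical
genotype tables.

Frequency presets back-solved from published DRD2 Taq1 A1 carrier rates
under HWE (carrier = 1 - (1 - q)^2):

=================  ============  ==================
preset             carrier rate  A1 frequency q
=================  ============  ==================
``super_control``  3 %           0.01511
``screened_control``  26 %       0.13982
``rds_family``     78 %          0.53096
=================  ============  ==================

Super controls are screened to exclude *all* reward-deficiency behaviors,
not merely the index addiction, which is what drops the carrier rate from
~26 % to ~3 %.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np

from .errors import SimulationError
from .genotype_io import CohortTable, GenotypeCall, SubjectGenotype
from .panel import MarkerDefinition, PanelDefinition, Sex, repeat_count

__all__ = [
    "PopulationConfig",
    "SimulationConfig",
    "generate_cohort",
    "carrier_rate",
    "carrier_to_frequency",
    "frequency_to_carrier",
    "preset_frequencies",
    "DEFAULT_RISK_FREQUENCIES",
    "PRESET_CARRIER_RATES",
]

FrequencySpec = Union[float, Mapping[str, float]]

#: Default per-marker risk-allele frequencies (builtin marker ids), chosen
#: as round literature-typical values for populations of European ancestry.
DEFAULT_RISK_FREQUENCIES: Mapping[str, float] = {
    "rs1800497": 0.20,        # DRD2 Taq1 A1
    "rs6280": 0.35,           # DRD3 Ser9Gly C
    "DRD4-exon3-VNTR": 0.20,  # long (>=7R)
    "MAOA-uVNTR": 0.60,       # 4R
    "rs4680": 0.50,           # COMT Val (G)
    "DAT1-3UTR-VNTR": 0.25,   # 9R
    "5-HTTLPR": 0.45,         # S
    "rs1799971": 0.15,        # OPRM1 118G
    "GABRB3-CA-repeat": 0.25, # 181
    "rs4532": 0.40,           # DRD1 48G
    "rs6313": 0.55,           # HTR2A 102C
    "rs6311": 0.45,           # HTR2A -1438A
}

#: DRD2 Taq1 A1 carrier rates behind the shipped presets.
PRESET_CARRIER_RATES: Mapping[str, float] = {
    "super_control": 0.03,
    "screened_control": 0.26,
    "rds_family": 0.78,
}


def carrier_to_frequency(carrier_rate: float) -> float:
    """Back-solve the allele frequency q from a carrier rate under HWE.

    carrier = 1 - (1 - q)^2  =>  q = 1 - sqrt(1 - carrier).
    """
    if not 0.0 <= carrier_rate <= 1.0:
        raise SimulationError(f"carrier rate {carrier_rate} outside [0, 1]")
    return 1.0 - math.sqrt(1.0 - carrier_rate)


def frequency_to_carrier(q: float) -> float:
    """Carrier rate 1 - (1 - q)^2 implied by allele frequency q under HWE."""
    if not 0.0 <= q <= 1.0:
        raise SimulationError(f"allele frequency {q} outside [0, 1]")
    return 1.0 - (1.0 - q) ** 2


def preset_frequencies(
    name: str, panel: PanelDefinition | None = None
) -> dict[str, float]:
    """Per-marker frequencies for a named preset population.

    The DRD2 frequency is back-solved from the preset's carrier rate;
    every other marker keeps its default frequency.  With ``panel`` given,
    the result is restricted to that panel's markers.
    """
    if name not in PRESET_CARRIER_RATES:
        raise SimulationError(
            f"unknown preset {name!r}; available: {sorted(PRESET_CARRIER_RATES)}"
        )
    freqs = dict(DEFAULT_RISK_FREQUENCIES)
    freqs["rs1800497"] = carrier_to_frequency(PRESET_CARRIER_RATES[name])
    if panel is not None:
        freqs = {mid: f for mid, f in freqs.items() if mid in panel.marker_ids}
    return freqs


@dataclass(frozen=True)
class PopulationConfig:
    """Sample size and per-marker frequencies for one simulated population.

    A frequency may be a scalar (risk-allele frequency; the marker is
    collapsed to risk vs its non-risk baseline label) or a full mapping
    allele label -> frequency summing to 1.
    """

    n: int
    frequencies: Mapping[str, FrequencySpec]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SimulationError(f"population size n={self.n} must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    panel: PanelDefinition
    populations: Mapping[str, PopulationConfig]
    female_fraction: float = 0.5
    missingness: Union[float, Mapping[str, float]] = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations:
            raise SimulationError("at least one population is required")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise SimulationError(
                f"female_fraction {self.female_fraction} outside [0, 1]"
            )

    def missing_rate(self, marker_id: str) -> float:
        if isinstance(self.missingness, Mapping):
            rate = float(self.missingness.get(marker_id, 0.0))
        else:
            rate = float(self.missingness)
        if not 0.0 <= rate <= 1.0:
            raise SimulationError(
                f"missingness {rate} for marker {marker_id} outside [0, 1]"
            )
        return rate


def _stream(seed: int, pop: str, marker_id: str, purpose: int) -> np.random.Generator:
    """Deterministic substream keyed by names, stable under panel edits."""
    key = (
        seed,
        zlib.crc32(pop.encode()),
        zlib.crc32(marker_id.encode()),
        purpose,
    )
    return np.random.default_rng(np.random.SeedSequence(entropy=key))


def _marker_labels(
    marker: MarkerDefinition, spec: FrequencySpec
) -> tuple[list[str], np.ndarray]:
    """Resolve a frequency spec to (labels, probabilities)."""
    if isinstance(spec, Mapping):
        labels = [str(k).upper() for k in spec]
        probs = np.asarray([float(v) for v in spec.values()], dtype=float)
        unknown = set(labels) - set(marker.allele_universe)
        if unknown:
            raise SimulationError(
                f"marker {marker.marker_id}: frequency vector names allele(s) "
                f"{sorted(unknown)} outside the universe"
            )
        if np.any(probs < 0) or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise SimulationError(
                f"marker {marker.marker_id}: frequency vector must be "
                f"nonnegative and sum to 1 (got sum {probs.sum():.6g})"
            )
        return labels, probs
    q = float(spec)
    if not 0.0 <= q <= 1.0:
        raise SimulationError(
            f"marker {marker.marker_id}: risk frequency {q} outside [0, 1]"
        )
    if marker.risk_min_repeats is not None:
        # representative long allele: the shortest satisfying the predicate
        risk_label = min(marker.risk_alleles, key=repeat_count)
    else:
        risk_label = next(
            a for a in marker.allele_universe if a in marker.risk_alleles
        )
    return [risk_label, marker.non_risk_baseline()], np.asarray([q, 1.0 - q])


def generate_cohort(config: SimulationConfig) -> dict[str, CohortTable]:
    """Draw one cohort per configured population; reproducible given seed."""
    panel = config.panel
    out: dict[str, CohortTable] = {}
    for pop_name in config.populations:
        pop = config.populations[pop_name]
        missing_markers = set(pop.frequencies) - set(panel.marker_ids)
        if missing_markers:
            raise SimulationError(
                f"population {pop_name!r}: frequency given for unknown "
                f"marker(s) {sorted(missing_markers)}"
            )
        n = pop.n
        sex_rng = _stream(config.seed, pop_name, "__sex__", 0)
        is_female = sex_rng.random(n) < config.female_fraction
        sexes = np.where(is_female, Sex.F.value, Sex.M.value)

        # allele labels drawn per marker into an (n, 2) array; column 1 is
        # ignored for hemizygous males
        calls_by_marker: dict[str, list[GenotypeCall]] = {}
        for marker in panel:
            mid = marker.marker_id
            if mid not in pop.frequencies:
                calls_by_marker[mid] = [GenotypeCall.missing()] * n
                continue
            labels, probs = _marker_labels(marker, pop.frequencies[mid])
            geno_rng = _stream(config.seed, pop_name, mid, 1)
            idx = geno_rng.choice(len(labels), size=(n, 2), p=probs)
            miss_rng = _stream(config.seed, pop_name, mid, 2)
            missing = miss_rng.random(n) < config.missing_rate(mid)
            calls: list[GenotypeCall] = []
            for i in range(n):
                if missing[i]:
                    calls.append(GenotypeCall.missing())
                elif marker.is_x_linked and not is_female[i]:
                    calls.append(GenotypeCall((labels[idx[i, 0]],)))
                else:
                    calls.append(
                        GenotypeCall((labels[idx[i, 0]], labels[idx[i, 1]]))
                    )
            calls_by_marker[mid] = calls

        width = len(str(n))
        subjects = [
            SubjectGenotype(
                subject_id=f"{pop_name}-{i + 1:0{width}d}",
                sex=Sex(sexes[i]),
                calls={mid: calls_by_marker[mid][i] for mid in panel.marker_ids},
            )
            for i in range(n)
        ]
        out[pop_name] = CohortTable(
            panel=panel,
            subjects=subjects,
            provenance=(
                f"simulated population {pop_name!r} (n={n}, "
                f"seed={config.seed}, HWE + linkage equilibrium; frequencies "
                "back-solved from carrier rates where presets are used)"
            ),
        )
    return out


def carrier_rate(cohort: CohortTable, marker_id: str) -> float:
    """Fraction of non-missing subjects carrying >= 1 risk allele."""
    marker = cohort.panel.marker(marker_id)
    n_called = 0
    n_carrier = 0
    for subj in cohort:
        call = subj.call(marker_id)
        if call.is_missing:
            continue
        n_called += 1
        if any(marker.is_risk(a) for a in call.alleles):
            n_carrier += 1
    if n_called == 0:
        raise SimulationError(
            f"marker {marker_id}: no non-missing calls in cohort"
        )
    return n_carrier / n_called
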