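import pytest

from garscore import (
    GenotypeCall,
    PanelDefinition,
    Sex,
    SubjectGenotype,
    builtin_panel,
)
from garscore.panel import (
    ChromosomeClass,
    MarkerClass,
    MarkerDefinition,
)


@pytest.fixture(scope="session")
def gars9():
    return builtin_panel("gars9")


@pytest.fixture(scope="session")
def gars10():
    return builtin_panel("gars10")


def snp(marker_id, risk="A1", non_risk="A2", gene="GENE", chrom="AUTOSOMAL"):
    """Minimal biallelic marker for constructed test panels."""
    return MarkerDefinition(
        gene_symbol=gene,
        marker_id=marker_id,
        marker_class=MarkerClass.SNP,
        chromosome_class=ChromosomeClass(chrom),
        allele_universe=(non_risk, risk),
        risk_alleles=frozenset({risk}),
    )


def mini_panel(*markers, name="mini"):
    return PanelDefinition(name=name, version="0", markers=tuple(markers))


def non_risk_calls(panel):
    """Homozygous (or hemizygous) non-risk call at every marker."""
    calls = {}
    for m in panel:
        base = m.non_risk_baseline()
        n = 2 if not m.is_x_linked else 2  # female default
        calls[m.marker_id] = GenotypeCall((base,) * n)
    return calls


def make_subject(panel, sex=Sex.F, subject_id="S1", **overrides):
    """Subject with non-risk defaults; override per marker with allele tuples.

    A value of None marks the marker MISSING.
    """
    sex = Sex(sex)
    calls = {}
    for m in panel:
        base = m.non_risk_baseline()
        ploidy = 1 if (m.is_x_linked and sex is Sex.M) else 2
        calls[m.marker_id] = GenotypeCall((base,) * ploidy)
    for mid, alleles in overrides.items():
        if alleles is None:
            calls[mid] = GenotypeCall.missing()
        else:
            calls[mid] = GenotypeCall(tuple(alleles))
    return SubjectGenotype(subject_id=subject_id, sex=sex, calls=calls)
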