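import itertools

import pytest
from hypothesis import given, settings, strategies as st

from garscore import (
    GarsError,
    GenotypeCall,
    GenotypeValidationError,
    Severity,
    Sex,
    SubjectGenotype,
    UnscorableError,
    count_risk_alleles,
    gars_percentage,
    score_cohort,
    score_subject,
    stratify_severity,
    summarize_cohort,
)
from garscore.panel import (
    ChromosomeClass,
    MarkerClass,
    MarkerDefinition,
)

from conftest import make_subject, mini_panel, snp


class TestCountRiskAlleles:
    def test_female_all_non_risk_scores_zero_of_18(self, gars9):
        subj = make_subject(gars9, Sex.F)
        assert count_risk_alleles(subj, gars9) == (0, 18, 1.0)

    def test_female_homozygous_taq1a1_carries_two(self, gars9):
        subj = make_subject(gars9, Sex.F, rs1800497=("A1", "A1"))
        assert count_risk_alleles(subj, gars9) == (2, 18, 1.0)

    def test_male_hemizygous_4r_plus_dat1_het_carries_two_of_17(self, gars9):
        subj = make_subject(
            gars9, Sex.M, **{"MAOA-uVNTR": ("4R",), "DAT1-3UTR-VNTR": ("9R", "10R")}
        )
        assert count_risk_alleles(subj, gars9) == (2, 17, 1.0)

    def test_missing_marker_shrinks_denominator(self, gars9):
        subj = make_subject(gars9, Sex.F, rs1800497=None)
        carried, countable, call_rate = count_risk_alleles(subj, gars9)
        assert (carried, countable) == (0, 16)
        assert call_rate == pytest.approx(16 / 18)

    def test_drd4_long_alleles_count_via_predicate(self, gars9):
        subj = make_subject(gars9, Sex.F, **{"DRD4-exon3-VNTR": ("7R", "8R")})
        assert count_risk_alleles(subj, gars9)[0] == 2
        subj = make_subject(gars9, Sex.F, **{"DRD4-exon3-VNTR": ("4R", "6R")})
        assert count_risk_alleles(subj, gars9)[0] == 0

    def test_unknown_sex_with_called_x_marker_rejected(self, gars9):
        subj = make_subject(gars9, Sex.F, subject_id="SU")
        subj = SubjectGenotype("SU", Sex.UNKNOWN, subj.calls)
        with pytest.raises(GenotypeValidationError, match="sex is UNKNOWN"):
            count_risk_alleles(subj, gars9)

    def test_all_markers_missing_is_unscorable(self, gars9):
        subj = make_subject(
            gars9, Sex.F, **{mid: None for mid in gars9.marker_ids}
        )
        carried, countable, _ = count_risk_alleles(subj, gars9)
        assert (carried, countable) == (0, 0)
        with pytest.raises(UnscorableError):
            gars_percentage(carried, countable)


class TestGarsPercentage:
    @pytest.mark.parametrize(
        "carried,countable,expected",
        [(7, 17, 100 * 7 / 17), (0, 18, 0.0), (18, 18, 100.0)],
    )
    def test_direct_arithmetic(self, carried, countable, expected):
        assert gars_percentage(carried, countable) == pytest.approx(
            expected, abs=1e-9
        )

    def test_carried_above_countable_rejected(self):
        with pytest.raises(GarsError):
            gars_percentage(19, 18)


class TestStratifySeverity:
    @pytest.mark.parametrize(
        "pct,band",
        [
            (0, Severity.ZERO),
            (1, Severity.LOW),
            (36, Severity.LOW),
            (37, Severity.MODERATE),
            (50, Severity.MODERATE),
            (51, Severity.HIGH),
            (100, Severity.HIGH),
            (100 * 7 / 17, Severity.MODERATE),  # 41.18 rounds to 41
            (36.4, Severity.LOW),
            (36.5, Severity.MODERATE),  # half-up
            (0.4, Severity.ZERO),
            (0.5, Severity.LOW),
        ],
    )
    def test_printed_bands(self, pct, band):
        assert stratify_severity(pct) is band

    def test_zero_as_low_collapses_the_zero_band(self):
        assert stratify_severity(0.0, zero_as_low=True) is Severity.LOW

    @pytest.mark.parametrize("pct", [-0.1, 100.1])
    def test_out_of_range_rejected(self, pct):
        with pytest.raises(GarsError, match="outside"):
            stratify_severity(pct)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=100.0, allow_nan=False))
    def test_every_percentage_maps_to_exactly_one_band(self, pct):
        assert stratify_severity(pct) in set(Severity)


class TestInvariants:
    def x_vntr(self):
        return MarkerDefinition(
            gene_symbol="MAOA", marker_id="xm",
            marker_class=MarkerClass.VNTR,
            chromosome_class=ChromosomeClass.X_LINKED,
            allele_universe=("3R", "4R"), risk_alleles=frozenset({"4R"}),
        )

    def test_adding_a_risk_allele_never_decreases_percentage(self, gars9):
        base = make_subject(gars9, Sex.F)
        order = list(Severity)
        prev_pct, prev_band = -1.0, 0
        # flip one non-risk allele to risk at a time, marker by marker
        flipped = {}
        for m in gars9:
            risk = sorted(m.risk_alleles)[0]
            flipped[m.marker_id] = (risk, m.non_risk_baseline())
            subj = make_subject(gars9, Sex.F, **flipped)
            res = score_subject(subj, gars9)
            assert res.percentage >= prev_pct
            assert order.index(res.severity) >= prev_band
            prev_pct, prev_band = res.percentage, order.index(res.severity)

    @pytest.mark.parametrize(
        "auto_call,x_call",
        [(("A2", "A2"), ("3R",)), (("A1", "A1"), ("4R",))],
        ids=["all-non-risk", "all-risk"],
    )
    def test_sex_symmetry_at_homozygous_x(self, auto_call, x_call):
        """Male hemizygous vs female homozygous for the same X allele.

        Percentages coincide exactly when the X allele's risk status agrees
        with the autosomal risk fraction — i.e. for subjects uniformly
        risk or uniformly non-risk; a mediant (r+x)/(n+1) otherwise sits
        strictly between the two sex-specific denominators.
        """
        panel = mini_panel(snp("a1"), snp("a2"), self.x_vntr())
        male = make_subject(panel, Sex.M, subject_id="m", a1=auto_call,
                            a2=auto_call, xm=x_call)
        female = make_subject(panel, Sex.F, subject_id="f", a1=auto_call,
                              a2=auto_call, xm=x_call * 2)
        pm = score_subject(male, panel)
        pf = score_subject(female, panel)
        assert pm.percentage == pytest.approx(pf.percentage)

    def test_scorer_matches_exhaustive_enumeration_small_panels(self):
        """Brute-force oracle over every genotype combination, both sexes."""
        panel = mini_panel(
            snp("s"),
            MarkerDefinition(
                gene_symbol="V", marker_id="v",
                marker_class=MarkerClass.VNTR,
                chromosome_class=ChromosomeClass.AUTOSOMAL,
                allele_universe=("4R", "7R", "9R"),
                risk_alleles=frozenset({"7R", "9R"}), risk_min_repeats=7,
            ),
            self.x_vntr(),
        )
        risk_sets = {"s": {"A1"}, "v": {"7R", "9R"}, "xm": {"4R"}}
        for sex in (Sex.F, Sex.M):
            per_marker = []
            for m in panel:
                k = 1 if (m.is_x_linked and sex is Sex.M) else 2
                per_marker.append([
                    tuple(c) for c in
                    itertools.combinations_with_replacement(m.allele_universe, k)
                ])
            for combo in itertools.product(*per_marker):
                calls = {
                    m.marker_id: GenotypeCall(c)
                    for m, c in zip(panel.markers, combo)
                }
                subj = SubjectGenotype("s", sex, calls)
                expected = sum(
                    sum(a in risk_sets[m.marker_id] for a in c)
                    for m, c in zip(panel.markers, combo)
                )
                carried, countable, _ = count_risk_alleles(subj, panel)
                assert carried == expected
                assert countable == (6 if sex is Sex.F else 5)


class TestSummarize:
    def make_results(self, pcts):
        from garscore.scoring import ScoreResult
        return [
            ScoreResult(
                subject_id=f"S{i}", sex=Sex.F, risk_alleles_carried=0,
                countable_alleles=18, percentage=p,
                severity=stratify_severity(p), call_rate=1.0,
            )
            for i, p in enumerate(pcts)
        ]

    def test_two_low_two_high(self):
        s = summarize_cohort(self.make_results([10, 20, 60, 70]))
        assert s.band_fractions == {Severity.LOW: 0.5, Severity.HIGH: 0.5}
        assert s.n_subjects == 4

    def test_single_moderate_subject(self):
        s = summarize_cohort(self.make_results([40]))
        assert s.band_fractions == {Severity.MODERATE: 1.0}
        assert s.mean_percentage == 40 and s.median_percentage == 40

    def test_empty_rejected(self):
        with pytest.raises(GarsError, match="empty"):
            summarize_cohort([])

    def test_simulated_cohort_fractions_sum_to_one(self, gars9):
        from garscore import (
            PopulationConfig, SimulationConfig, generate_cohort,
            preset_frequencies,
        )
        cfg = SimulationConfig(
            panel=gars9,
            populations={"p": PopulationConfig(
                n=100, frequencies=preset_frequencies("screened_control", gars9)
            )},
            seed=5,
        )
        cohort = generate_cohort(cfg)["p"]
        s = summarize_cohort(score_cohort(cohort))
        assert sum(s.band_fractions.values()) == pytest.approx(1.0)
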