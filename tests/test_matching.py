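"""Allele reconciliation, dosages, additive scores, Mendelian calls."""

import math

import pytest
from hypothesis import given, strategies as st

from sportsrisk.genotype_io import GenotypeCall, GenotypeProfile
from sportsrisk.matching import (
    ExclusionReason,
    MendelianStatus,
    additive_score,
    call_sickle_cell_trait,
    match_variant,
)
from sportsrisk.panel import Panel, complement_variant
from tests.test_panel import make_variant

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def profile_with(*calls: GenotypeCall, build="GRCh37") -> GenotypeProfile:
    return GenotypeProfile("t", {c.rsid: c for c in calls}, build=build)


def call(rsid, genotype, chrom="1", position=1):
    return GenotypeCall(rsid, chrom, position,
                        tuple(sorted(genotype)) if genotype else (),
                        is_snp=all(a in "ACGT" for a in genotype))


class TestMatchVariant:
    def test_homozygous_effect_allele_dosage_two(self):
        v = make_variant(effect_allele="G", other_allele="T")
        m = match_variant(profile_with(call("rs1000", "GG")), v)
        assert m.dosage == 2 and not m.strand_flipped and not m.excluded

    def test_heterozygote_dosage_one(self):
        v = make_variant(effect_allele="G", other_allele="T")
        m = match_variant(profile_with(call("rs1000", "GT")), v)
        assert m.dosage == 1

    def test_irreconcilable_alleles_are_mismatch(self):
        # A/G call vs G/T panel: neither reading nor its complement fits
        v = make_variant(effect_allele="G", other_allele="T")
        m = match_variant(profile_with(call("rs1000", "AG")), v)
        assert m.excluded_reason is ExclusionReason.allele_mismatch

    def test_fully_complementary_call_is_flip_not_mismatch(self):
        # A/C call vs G/T panel alleles is the complement-strand reading
        v = make_variant(effect_allele="G", other_allele="T")
        m = match_variant(profile_with(call("rs1000", "AC")), v)
        assert m.dosage == 1 and m.strand_flipped

    def test_complement_call_flags_strand_flip(self):
        # call CC against G/A panel alleles: C is the complement of G
        v = make_variant(effect_allele="G", other_allele="A")
        m = match_variant(profile_with(call("rs1000", "CC")), v)
        assert m.dosage == 2 and m.strand_flipped

    def test_palindromic_site_excluded_by_default(self):
        v = make_variant(effect_allele="A", other_allele="T")
        m = match_variant(profile_with(call("rs1000", "AT")), v)
        assert m.excluded_reason is ExclusionReason.ambiguous_site
        assert m.ambiguous

    def test_palindromic_site_counted_when_strand_trusted(self):
        v = make_variant(effect_allele="A", other_allele="T")
        m = match_variant(profile_with(call("rs1000", "AT")), v,
                          trust_strand=True)
        assert m.dosage == 1 and m.ambiguous

    def test_absent_and_nocall_are_missing(self):
        v = make_variant()
        assert match_variant(profile_with(), v).excluded_reason \
            is ExclusionReason.missing_call
        m = match_variant(profile_with(call("rs1000", "")), v)
        assert m.excluded_reason is ExclusionReason.missing_call

    def test_indel_call_excluded_as_non_snp(self):
        v = make_variant()
        m = match_variant(profile_with(call("rs1000", "DD")), v)
        assert m.excluded_reason is ExclusionReason.non_snp

    def test_hemizygous_counts_single_allele(self):
        v = make_variant(chrom="X", effect_allele="A", other_allele="G")
        m = match_variant(profile_with(call("rs1000", "A", chrom="X")), v)
        assert m.dosage == 1

    @given(st.sampled_from(["AC", "AG", "CT", "GT"]),
           st.integers(min_value=0, max_value=2))
    def test_dosages_of_both_alleles_sum_to_two(self, pair, dosage):
        ea, oa = pair[0], pair[1]
        geno = ea * dosage + oa * (2 - dosage)
        v = make_variant(effect_allele=ea, other_allele=oa)
        w = make_variant(effect_allele=oa, other_allele=ea)
        p = profile_with(call("rs1000", geno))
        assert match_variant(p, v).dosage + match_variant(p, w).dosage == 2

    @given(st.sampled_from(["AC", "AG", "CT", "GT"]),
           st.integers(min_value=0, max_value=2))
    def test_strand_flip_invariance(self, pair, dosage):
        ea, oa = pair[0], pair[1]
        geno = ea * dosage + oa * (2 - dosage)
        v = make_variant(effect_allele=ea, other_allele=oa)
        p = profile_with(call("rs1000", geno))
        direct = match_variant(p, v)
        flipped = match_variant(p, complement_variant(v))
        assert direct.dosage == flipped.dosage == dosage
        assert flipped.strand_flipped and not direct.strand_flipped


def three_locus_panel(weights=(0.1, 0.2, 0.3)):
    pairs = [("A", "G"), ("C", "T"), ("G", "T")]
    variants = tuple(
        make_variant(rsid=f"rs{i+1}", effect_allele=ea, other_allele=oa,
                     weight=w, category="osteoarthritis")
        for i, (w, (ea, oa)) in enumerate(zip(weights, pairs))
    )
    return Panel(variants=variants)


def profile_for(panel, dosages, **kwargs):
    calls = []
    for v, d in zip(panel, dosages):
        geno = v.effect_allele * d + v.other_allele * (2 - d)
        calls.append(call(v.rsid, geno, chrom=v.chrom, position=v.position))
    return profile_with(*calls, **kwargs)


class TestAdditiveScore:
    def test_hand_computed_weighted_sum(self):
        panel = three_locus_panel()
        profile = profile_for(panel, [2, 1, 0])
        s = additive_score(profile, panel, "osteoarthritis")
        assert s.raw_score == pytest.approx(0.1 * 2 + 0.2 * 1 + 0.3 * 0)
        assert s.risk_allele_count == 3
        assert s.n_matched == 3 and s.coverage == 1.0 and not s.rescaled

    def test_all_seven_oa_heterozygotes_count_seven(self, fixture_panel):
        oa = fixture_panel.category("osteoarthritis")
        assert len(oa) == 7
        calls = [call(v.rsid, v.effect_allele + v.other_allele) for v in oa]
        s = additive_score(profile_with(*calls), fixture_panel,
                           "osteoarthritis")
        assert s.risk_allele_count == 7
        assert s.raw_score == pytest.approx(sum(v.weight for v in oa))

    def test_no_matching_calls_scores_zero(self):
        panel = three_locus_panel()
        s = additive_score(profile_with(), panel, "osteoarthritis",
                           rescale=False)
        assert s.raw_score == 0.0 and s.coverage == 0.0
        assert s.insufficient_coverage

    def test_rescaling_restores_full_panel_scale(self):
        panel = three_locus_panel(weights=(0.1, 0.2, 0.3))
        profile = profile_for(panel, [1, 1, 1])
        full = additive_score(profile, panel, "osteoarthritis")
        partial_calls = [profile.get("rs1"), profile.get("rs2")]
        partial = additive_score(profile_with(*partial_calls), panel,
                                 "osteoarthritis")
        assert partial.rescaled
        # matched score 0.3 scaled by 0.6/0.3 = full-panel score 0.6
        assert partial.raw_score == pytest.approx(full.raw_score)
        assert partial.insufficient_coverage  # 2/3 < 0.9 floor

    def test_zero_weight_locus_never_changes_score(self):
        with_zero = three_locus_panel(weights=(0.1, 0.0, 0.3))
        profile = profile_for(with_zero, [2, 2, 1])
        s = additive_score(profile, with_zero, "osteoarthritis",
                           rescale=False)
        assert s.raw_score == pytest.approx(0.1 * 2 + 0.3 * 1)

    def test_risk_allele_count_bounded_by_twice_matches(self, fixture_panel):
        profiles = profile_with()  # empty: bound trivially holds
        for category in ("ACL_rupture", "osteoarthritis"):
            s = additive_score(profiles, fixture_panel, category,
                               rescale=False)
            assert s.risk_allele_count <= 2 * s.n_matched

    def test_strand_flip_invariance_of_score(self):
        panel = three_locus_panel()
        flipped = Panel(variants=tuple(complement_variant(v) for v in panel))
        profile = profile_for(panel, [2, 1, 2])
        a = additive_score(profile, panel, "osteoarthritis")
        b = additive_score(profile, flipped, "osteoarthritis")
        assert a.raw_score == pytest.approx(b.raw_score)
        assert a.risk_allele_count == b.risk_allele_count

    def test_unknown_category_raises(self, fixture_panel):
        with pytest.raises(Exception):
            additive_score(profile_with(), fixture_panel, "elbow")

    def test_combined_subset_uses_63_loci(self, fixture_panel):
        s = additive_score(profile_with(), fixture_panel,
                           "bone_mineral_density", combined_subset=True,
                           rescale=False)
        assert s.n_panel == 63


class TestSickleCellTrait:
    def sct_variant(self, fixture_panel):
        return fixture_panel.get("rs334")

    @pytest.mark.parametrize("genotype, status", [
        ("TT", MendelianStatus.negative),
        ("AT", MendelianStatus.trait_carrier),
        ("AA", MendelianStatus.homozygous_variant),
        ("", MendelianStatus.no_call),
    ])
    def test_carrier_states(self, fixture_panel, genotype, status):
        v = self.sct_variant(fixture_panel)
        p = profile_with(call("rs334", genotype, chrom="11"))
        assert call_sickle_cell_trait(p, v).status is status

    def test_absent_rs334_is_no_call(self, fixture_panel):
        v = self.sct_variant(fixture_panel)
        result = call_sickle_cell_trait(profile_with(), v)
        assert result.status is MendelianStatus.no_call

    def test_rejects_additive_variant(self):
        with pytest.raises(ValueError, match="Mendelian"):
            call_sickle_cell_trait(profile_with(), make_variant())
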