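"""Allele harmonization, risk-allele dosages, additive scores, Mendelian calls.

Matching reconciles an individual's unphased forward-strand calls against
a panel variant's effect/other alleles.  If the call's alleles are a
subset of the panel alleles the dosage is counted directly; if they are a
subset of the strand complements, the call is complemented first and
flagged as strand-flipped.  Palindromic panel sites (A/T or C/G), where
the two readings are indistinguishable, are excluded by default; a flag
permits trusting same-strand reporting.  All failure modes are typed
exclusions, never exceptions.

An additive category score is S = sum_i w_i * x_i over the non-excluded
loci, with x_i the effect-allele dosage (0/1/2 diploid, 0/1 hemizygous)
and w_i the per-allele weight (ln OR or beta).  When some loci are
missing, the score can be rescaled by the ratio of total to matched
weight so it stays on the full-panel scale; below a coverage floor the
score is flagged as insufficient.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .genotype_io import GenotypeProfile
from .panel import Panel, PanelVariant

__all__ = [
    "ExclusionReason",
    "MatchedDosage",
    "CategoryScore",
    "MendelianResult",
    "MendelianStatus",
    "match_variant",
    "additive_score",
    "call_sickle_cell_trait",
]

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Combined-score coverage below which a score is flagged insufficient.
DEFAULT_COVERAGE_FLOOR = 0.9


class ExclusionReason(str, enum.Enum):
    none = "none"
    missing_call = "missing_call"
    allele_mismatch = "allele_mismatch"
    ambiguous_site = "ambiguous_site"
    non_snp = "non_snp"


class MendelianStatus(str, enum.Enum):
    negative = "negative"
    trait_carrier = "trait_carrier"
    homozygous_variant = "homozygous_variant"
    no_call = "no_call"


@dataclass(frozen=True)
class MatchedDosage:
    """Effect-allele dosage for one panel variant, or a typed exclusion."""

    rsid: str
    dosage: int | None
    strand_flipped: bool = False
    ambiguous: bool = False
    excluded_reason: ExclusionReason = ExclusionReason.none

    @property
    def excluded(self) -> bool:
        return self.excluded_reason is not ExclusionReason.none

    def __post_init__(self) -> None:
        if (self.dosage is None) != self.excluded:
            raise ValueError("dosage must be present iff not excluded")


@dataclass(frozen=True)
class CategoryScore:
    """Additive score for one category: S = sum(w_i * x_i) over matched loci."""

    category: str
    raw_score: float
    risk_allele_count: int
    n_matched: int
    n_panel: int
    rescaled: bool = False
    insufficient_coverage: bool = False

    @property
    def coverage(self) -> float:
        return self.n_matched / self.n_panel if self.n_panel else 0.0


@dataclass(frozen=True)
class MendelianResult:
    """Carrier status derived solely from the Mendelian variant's genotype."""

    rsid: str
    status: MendelianStatus


def _exclude(rsid: str, reason: ExclusionReason, *,
             ambiguous: bool = False) -> MatchedDosage:
    return MatchedDosage(rsid=rsid, dosage=None, ambiguous=ambiguous,
                         excluded_reason=reason)


def match_variant(profile: GenotypeProfile, variant: PanelVariant,
                  trust_strand: bool = False) -> MatchedDosage:
    """Reconcile one profile call against one panel variant.

    Parameters
    ----------
    trust_strand:
        Count dosage at palindromic (A/T, C/G) panel sites instead of
        excluding them.  Only safe when profile and panel are known to
        report the same strand; strand flips are undetectable at such
        sites.
    """
    if variant.is_palindromic and not trust_strand:
        return _exclude(variant.rsid, ExclusionReason.ambiguous_site,
                        ambiguous=True)
    call = profile.get(variant.rsid)
    if call is None or call.is_missing:
        return _exclude(variant.rsid, ExclusionReason.missing_call,
                        ambiguous=variant.is_palindromic)
    if not call.is_snp:
        return _exclude(variant.rsid, ExclusionReason.non_snp,
                        ambiguous=variant.is_palindromic)
    panel_alleles = {variant.effect_allele, variant.other_allele}
    observed = set(call.alleles)
    if observed <= panel_alleles:
        return MatchedDosage(rsid=variant.rsid,
                             dosage=call.dosage_of(variant.effect_allele),
                             ambiguous=variant.is_palindromic)
    if {_COMP[a] for a in observed} <= panel_alleles:
        flipped = _COMP[variant.effect_allele]
        return MatchedDosage(rsid=variant.rsid,
                             dosage=call.dosage_of(flipped),
                             strand_flipped=True)
    return _exclude(variant.rsid, ExclusionReason.allele_mismatch)


def additive_score(profile: GenotypeProfile, panel: Panel, category: str,
                   combined_subset: bool = False, rescale: bool = True,
                   coverage_floor: float = DEFAULT_COVERAGE_FLOOR,
                   trust_strand: bool = False) -> CategoryScore:
    """Additive risk score for one panel category.

    Sums effect-allele dosage times weight over the loci that matched;
    excluded loci (missing, mismatched, ambiguous, non-SNP) do not
    contribute.  With ``rescale`` (default), an incomplete score is
    multiplied by total-weight / matched-weight so it remains comparable
    to the full-panel reference distribution, and scores with coverage
    below ``coverage_floor`` are flagged ``insufficient_coverage``.

    ``combined_subset`` restricts to the combined-score subset
    (bone-mineral-density loci with ``in_combined_score``).
    """
    if combined_subset:
        variants = [v for v in panel.combined_score_subset()
                    if v.category == category]
    else:
        variants = [v for v in panel.category(category)
                    if v.effect_model == "additive"]
    if not variants:
        raise ValueError(f"no additive panel loci in category {category!r}")

    score = 0.0
    risk_alleles = 0
    matched_weight = 0.0
    total_weight = sum(abs(v.weight) for v in variants)
    n_matched = 0
    for v in variants:
        m = match_variant(profile, v, trust_strand=trust_strand)
        if m.excluded:
            continue
        n_matched += 1
        score += v.weight * m.dosage
        risk_alleles += m.dosage
        matched_weight += abs(v.weight)

    rescaled = False
    if rescale and 0 < n_matched < len(variants) and matched_weight > 0:
        score *= total_weight / matched_weight
        rescaled = True
    coverage = n_matched / len(variants)
    return CategoryScore(
        category=category,
        raw_score=score if n_matched else 0.0,
        risk_allele_count=risk_alleles,
        n_matched=n_matched,
        n_panel=len(variants),
        rescaled=rescaled,
        insufficient_coverage=coverage < coverage_floor,
    )


def call_sickle_cell_trait(profile: GenotypeProfile,
                           variant: PanelVariant) -> MendelianResult:
    """Mendelian carrier call at the hemoglobin-S locus (rs334).

    Zero copies of the variant allele is negative, one is the trait
    carrier state, two is homozygous for the variant; a missing or
    unmatchable call yields no_call.  The site is A/T palindromic, so the
    forward-strand reading is trusted: a strand flip at rs334 is
    undetectable from alleles alone and DTC exports report the forward
    strand.
    """
    if variant.effect_model != "mendelian":
        raise ValueError(
            f"{variant.rsid}: Mendelian call requested for {variant.effect_model} variant"
        )
    m = match_variant(profile, variant, trust_strand=True)
    if m.excluded:
        return MendelianResult(rsid=variant.rsid, status=MendelianStatus.no_call)
    status = {
        0: MendelianStatus.negative,
        1: MendelianStatus.trait_carrier,
        2: MendelianStatus.homozygous_variant,
    }[m.dosage]
    return MendelianResult(rsid=variant.rsid, status=status)
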