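"""Per-athlete risk reports: one four-tier assessment per panel category.

Assembles the outputs of matching, scoring, Mendelian calling and
calibration into a summary with one color-coded tier per category —
decreased (green), average (black), slightly increased (yellow),
increased (red) — plus drill-down annotations: published bin odds for
the combined bone-mineral-density score, named-SNP findings, and static
prevention notes per category.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass

from .calibration import (
    BinScheme,
    RiskTier,
    TIER_COLORS,
    assign_bin,
    assign_tier,
    single_variant_tier,
)
from .genotype_io import GenotypeProfile
from .matching import (
    CategoryScore,
    MendelianResult,
    MendelianStatus,
    additive_score,
    call_sickle_cell_trait,
    match_variant,
)
from .panel import Panel

__all__ = [
    "AthleteReport",
    "BuildMismatchError",
    "CategoryAssessment",
    "PREVENTION_NOTES",
    "assess_athlete",
    "render_report",
]

# Static per-category prevention annotations — content, not computation.
PREVENTION_NOTES = {
    "ACL_rupture": ("prevention: dynamic warm-up with landing/cutting form, "
                    "core and hamstring strengthening"),
    "achilles_tendon": ("prevention: gastrocnemius/soleus eccentric "
                        "strengthening, calf and Achilles stretching, "
                        "softer running surfaces"),
    "bone_mineral_density": ("prevention: monitor bone health, adequate "
                             "calcium and vitamin D intake, graded "
                             "loading progression"),
    "osteoarthritis": ("prevention: protect joints from injury; joint "
                       "injuries accelerate osteoarthritis onset"),
    "vitamin_mineral": ("prevention: dietary review and micronutrient "
                        "monitoring for flagged deficiencies"),
    "sickle_cell_trait": ("NCAA guidance for carriers: slow and gradual "
                          "conditioning, adequate rest between repetitions, "
                          "stop activity on symptoms, optimal hydration, "
                          "no exercise during acute illness, prompt "
                          "medical care when in distress"),
}


class BuildMismatchError(ValueError):
    """Profile and panel genome-build labels disagree."""


@dataclass(frozen=True)
class CategoryAssessment:
    """Tier, score and annotations for one category of one athlete."""

    category: str
    tier: RiskTier
    score: CategoryScore | MendelianResult | None
    bin: int | None = None
    annotations: tuple[str, ...] = ()
    coverage_warning: bool = False

    @property
    def color(self) -> str:
        return TIER_COLORS[self.tier]


@dataclass(frozen=True)
class AthleteReport:
    """One athlete's six-category risk summary."""

    individual_id: str
    assessments: tuple[CategoryAssessment, ...]
    panel_version: str = ""
    calibration_version: str = ""

    def assessment(self, category: str) -> CategoryAssessment:
        for a in self.assessments:
            if a.category == category:
                return a
        raise KeyError(category)


def _assess_combined(profile: GenotypeProfile, panel: Panel,
                     scheme: BinScheme) -> CategoryAssessment:
    score = additive_score(profile, panel, "bone_mineral_density",
                           combined_subset=True)
    notes = [PREVENTION_NOTES["bone_mineral_density"]]
    if score.n_matched == 0:
        return CategoryAssessment(
            category="bone_mineral_density", tier=RiskTier.average,
            score=score, annotations=tuple(notes), coverage_warning=True,
        )
    b = assign_bin(score.raw_score, scheme)
    tier = assign_tier(score.raw_score, scheme)
    if b in scheme.bin_annotations:
        notes.insert(0, scheme.bin_annotations[b])
    return CategoryAssessment(
        category="bone_mineral_density", tier=tier, score=score, bin=b,
        annotations=tuple(notes),
        coverage_warning=score.insufficient_coverage,
    )


def _assess_additive(profile: GenotypeProfile, panel: Panel,
                     category: str) -> CategoryAssessment:
    score = additive_score(profile, panel, category)
    notes = [PREVENTION_NOTES.get(category, "")]
    if score.n_matched == 0:
        return CategoryAssessment(
            category=category, tier=RiskTier.average, score=score,
            annotations=tuple(n for n in notes if n), coverage_warning=True,
        )
    # category tier: strongest per-variant finding; all-protective -> decreased
    tier = RiskTier.average
    tiers = []
    for v in panel.category(category):
        if v.effect_model != "additive":
            continue
        m = match_variant(profile, v)
        t = single_variant_tier(v, m)
        tiers.append(t)
        if t is RiskTier.increased and v.odds_ratio is not None:
            notes.insert(0, f"{v.rsid}: OR {v.odds_ratio:g}, "
                            f"dosage {m.dosage} of risk allele "
                            f"{v.effect_allele}")
    risky = [t for t in tiers if t > RiskTier.average]
    if risky:
        tier = max(risky)
    elif tiers and any(t is RiskTier.decreased for t in tiers):
        tier = RiskTier.decreased
    return CategoryAssessment(
        category=category, tier=tier, score=score,
        annotations=tuple(n for n in notes if n),
        coverage_warning=score.insufficient_coverage,
    )


def _assess_mendelian(profile: GenotypeProfile, panel: Panel,
                      category: str) -> CategoryAssessment:
    variants = [v for v in panel.category(category)
                if v.effect_model == "mendelian"]
    v = variants[0]
    result = call_sickle_cell_trait(profile, v)
    notes = []
    if result.status in (MendelianStatus.trait_carrier,
                         MendelianStatus.homozygous_variant):
        tier = RiskTier.increased
        notes.append(f"{v.rsid}: {result.status.value}")
        notes.append(PREVENTION_NOTES["sickle_cell_trait"])
    elif result.status is MendelianStatus.no_call:
        tier = RiskTier.average
        notes.append(f"{v.rsid}: no call; carrier status undetermined")
    else:
        tier = RiskTier.average
        notes.append(f"{v.rsid}: {result.status.value}")
    return CategoryAssessment(
        category=category, tier=tier, score=result,
        annotations=tuple(notes),
        coverage_warning=result.status is MendelianStatus.no_call,
    )


def assess_athlete(profile: GenotypeProfile, panel: Panel,
                   scheme: BinScheme, panel_version: str = "",
                   calibration_version: str = "") -> AthleteReport:
    """Full six-category assessment of one athlete.

    The combined bone-mineral-density score is placed in its population
    bin by ``scheme`` and mapped to a tier; other additive categories
    are tiered per-variant by effect size and dosage; the sickle-cell
    category uses the Mendelian carrier call.  Deterministic given its
    inputs.  Refuses mismatched genome builds.
    """
    if profile.build != panel.build:
        raise BuildMismatchError(
            f"profile build {profile.build!r} != panel build {panel.build!r}"
        )
    assessments = []
    for category in panel.categories:
        variants = panel.category(category)
        if all(v.effect_model == "mendelian" for v in variants):
            assessments.append(_assess_mendelian(profile, panel, category))
        elif category == "bone_mineral_density":
            assessments.append(_assess_combined(profile, panel, scheme))
        else:
            assessments.append(_assess_additive(profile, panel, category))
    return AthleteReport(
        individual_id=profile.individual_id,
        assessments=tuple(assessments),
        panel_version=panel_version,
        calibration_version=calibration_version,
    )


def _render_tsv(report: AthleteReport) -> str:
    lines = ["individual_id\tcategory\ttier\tcolor\tbin\tcoverage_warning\tannotations"]
    for a in report.assessments:
        lines.append("\t".join([
            report.individual_id, a.category, a.tier.name, a.color,
            "" if a.bin is None else str(a.bin),
            "1" if a.coverage_warning else "0",
            " | ".join(a.annotations),
        ]))
    return "\n".join(lines) + "\n"


def _render_text(report: AthleteReport) -> str:
    lines = [f"Genetic risk summary for {report.individual_id}", "=" * 40]
    for a in report.assessments:
        bin_part = f" (population bin {a.bin})" if a.bin is not None else ""
        lines.append(f"{a.category}: {a.tier.name} [{a.color}]{bin_part}")
        for note in a.annotations:
            lines.append(f"    - {note}")
    return "\n".join(lines) + "\n"


def _render_html(report: AthleteReport) -> str:
    rows = []
    for a in report.assessments:
        notes = "; ".join(_html.escape(n) for n in a.annotations)
        rows.append(
            f"<tr><td>{_html.escape(a.category)}</td>"
            f"<td style=\"color:{a.color}\">{a.tier.name}</td>"
            f"<td>{notes}</td></tr>"
        )
    body = "\n".join(rows)
    return (
        "<html><head><title>Genetic risk summary: "
        f"{_html.escape(report.individual_id)}</title></head><body>\n"
        f"<h1>{_html.escape(report.individual_id)}</h1>\n"
        "<table>\n<tr><th>category</th><th>tier</th><th>notes</th></tr>\n"
        f"{body}\n</table>\n</body></html>\n"
    )


def render_report(report: AthleteReport, format: str = "tsv") -> str:
    """Render a report as ``tsv`` (one row per category), ``text`` or ``html``.

    Rendering is pure: the same report always yields identical bytes.
    """
    renderers = {"tsv": _render_tsv, "text": _render_text, "html": _render_html}
    if format not in renderers:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(renderers)}")
    return renderers[format](report)
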