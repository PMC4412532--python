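"""Regenerate the bundled fixture panel (src/sportsrisk/data/fixture_panel.tsv).

The fixture reproduces the published panel composition — 124 SNPs across
six categories (ACL 4, Achilles 6, BMD 67, osteoarthritis 7,
vitamin/mineral 39, sickle cell trait 1), 63 BMD SNPs in the combined
score, 11 SNPs previously used in sports genetics — but all rsIDs,
weights and allele frequencies other than rs1800012 and rs334 are
synthetic placeholders drawn with a fixed seed.  Run from the repo root:

    python scripts/build_fixture_panel.py
"""

from __future__ import annotations

import math
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sportsrisk.panel import Panel, PanelVariant, write_panel  # noqa: E402

SEED = 2015
OUT = Path(__file__).resolve().parents[1] / "src" / "sportsrisk" / "data" / "fixture_panel.tsv"

# non-palindromic allele pairs only, so default matching never excludes
# a fixture site for strand ambiguity
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]

COMMENTS = [
    "sportsrisk fixture panel — SYNTHETIC except rs1800012 and rs334.",
    "Category counts reproduce the published literature-review summary:",
    "  ACL_rupture 4, achilles_tendon 6, bone_mineral_density 67,",
    "  osteoarthritis 7, vitamin_mineral 39, sickle_cell_trait 1 (total 124).",
    "The source text gives both 66 and 67 for the BMD count; 67 is used here",
    "so the category counts sum to the printed total of 124.",
    "Vitamin/mineral sub-rows print 41 assignments over 39 unique SNPs; two",
    "folate-pathway variants are dual-labelled b_vitamins;homocysteine.",
    "63 BMD variants carry in_combined_score=1 (the combined genetic score).",
    f"Synthetic weights/frequencies drawn with numpy default_rng({SEED}).",
]


def _rsid(rng: np.random.Generator, taken: set[str]) -> str:
    while True:
        rid = f"rs{int(rng.integers(10_000_000, 99_999_999))}"
        if rid not in taken:
            taken.add(rid)
            return rid


def build_fixture_panel(seed: int = SEED) -> Panel:
    rng = np.random.default_rng(seed)
    taken = {"rs1800012", "rs334"}
    chrom_cycle = [str(c) for c in range(1, 23)]
    variants: list[PanelVariant] = []

    def synth(category: str, subcategory: str, *, odds_ratio: float | None,
              weight: float, previously_used: bool, evidence: str,
              study: str, source: str, in_combined: bool = False,
              rsid: str | None = None,
              freq_range: tuple[float, float] = (0.10, 0.90)) -> None:
        ea, oa = _ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))]
        if rng.random() < 0.5:
            ea, oa = oa, ea
        variants.append(PanelVariant(
            rsid=rsid or _rsid(rng, taken),
            chrom=chrom_cycle[len(variants) % len(chrom_cycle)],
            position=int(rng.integers(1_000_000, 200_000_000)),
            effect_allele=ea,
            other_allele=oa,
            weight=round(weight, 6),
            odds_ratio=None if odds_ratio is None else round(odds_ratio, 4),
            effect_model="additive",
            category=category,
            subcategory=subcategory,
            allele_freq=round(float(rng.uniform(*freq_range)), 3),
            in_combined_score=in_combined,
            previously_used=previously_used,
            evidence_level=evidence,
            study_type=study,
            source=source,
        ))

    # ACL rupture: 4 candidate-gene SNPs, allelic ORs spanning 2.4-50
    for odds, gene in zip((2.4, 4.2, 8.5, 50.0),
                          ("COL1A1", "COL5A1", "COL12A1", "MMP12")):
        synth("ACL_rupture", "", odds_ratio=odds, weight=math.log(odds),
              previously_used=True, evidence="weak", study="candidate_gene",
              source=f"acl_{gene.lower()}", freq_range=(0.05, 0.30))

    # Achilles tendon: rs1800012 (COL1A1, OR 11, risk allele G) + 5 synthetic
    variants.append(PanelVariant(
        rsid="rs1800012", chrom="17", position=50_200_388,
        effect_allele="G", other_allele="T", weight=round(math.log(11.0), 6),
        odds_ratio=11.0, effect_model="additive", category="achilles_tendon",
        subcategory="", allele_freq=0.82, in_combined_score=False,
        previously_used=True, evidence_level="weak",
        study_type="candidate_gene", source="achilles_col1a1",
    ))
    for i, odds in enumerate((2.3, 3.0, 2.6, 4.8, 2.1)):
        synth("achilles_tendon", "", odds_ratio=odds, weight=math.log(odds),
              previously_used=True, evidence="weak", study="candidate_gene",
              source=f"achilles_syn{i+1}", freq_range=(0.05, 0.30))

    # BMD: 67 GWAS SNPs; the first 63 form the combined genetic score
    for i in range(67):
        odds = float(rng.uniform(1.02, 1.17))
        synth("bone_mineral_density", "", odds_ratio=odds,
              weight=math.log(odds), previously_used=False,
              evidence="strong", study="GWAS",
              source="bmd_meta" if i < 63 else "bmd_followup",
              in_combined=i < 63)

    # Osteoarthritis: 7 GWAS SNPs, allelic ORs 1.1-1.2 (small, additive)
    for i in range(7):
        odds = float(rng.uniform(1.10, 1.20))
        synth("osteoarthritis", "", odds_ratio=odds, weight=math.log(odds),
              previously_used=False, evidence="strong", study="GWAS",
              source=f"oa_gwas{i+1}")

    # Vitamin/mineral: 39 unique SNPs, beta weights (quantitative), OR absent.
    # Sub-rows sum to 41 via two dual-labelled folate-pathway variants.
    vm_rows = [
        ("iron", 8, "moderate"), ("vitamin_E", 3, "moderate"),
        ("vitamin_D", 6, "moderate"), ("calcium", 2, "strong"),
        ("magnesium", 4, "moderate"), ("b_vitamins", 5, "moderate"),
        ("homocysteine", 6, "moderate"),
        ("b_vitamins;homocysteine", 2, "moderate"),
        ("phytosterols", 3, "moderate"),
    ]
    for sub, n, evidence in vm_rows:
        for i in range(n):
            synth("vitamin_mineral", sub, odds_ratio=None,
                  weight=float(rng.uniform(0.03, 0.15)),
                  previously_used=False, evidence=evidence, study="GWAS",
                  source=f"vm_{sub.replace(';', '_')}{i+1}")

    # Sickle cell trait: rs334, Mendelian carrier call (HbS allele A,
    # forward strand; site is A/T palindromic, handled by the Mendelian path)
    variants.append(PanelVariant(
        rsid="rs334", chrom="11", position=5_248_232,
        effect_allele="A", other_allele="T", weight=0.0, odds_ratio=None,
        effect_model="mendelian", category="sickle_cell_trait",
        subcategory="", allele_freq=0.02, in_combined_score=False,
        previously_used=True, evidence_level="strong",
        study_type="candidate_gene", source="sct_hbb",
    ))

    return Panel(variants=tuple(variants), build="GRCh37")


if __name__ == "__main__":
    panel = build_fixture_panel()
    OUT.parent.mkdir(parents=True, exist_ok=True)
    write_panel(panel, OUT, comments=COMMENTS)
    print(f"wrote {len(panel)} variants to {OUT}")
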