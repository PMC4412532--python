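"""Injury-SNP panel: schema, validation, effect-size classification.

A panel is a curated table of SNPs associated with sports-injury risk,
grouped into six categories (ACL rupture, Achilles tendon injury, low bone
mineral density, osteoarthritis, vitamin/mineral deficiencies, sickle cell
trait).  Each variant carries an effect allele, a per-allele weight on the
score scale (ln OR for binary outcomes, beta for quantitative traits), a
population effect-allele frequency, and literature metadata (evidence
level, study type, whether the SNP had previously been used in sports
genetics).

The bundled fixture panel reproduces the published category composition
(124 SNPs; 67 bone-mineral-density SNPs of which 63 enter the combined
score; 113 SNPs new to sports genetics).  Only rs1800012 (COL1A1, Achilles
tendon rupture, OR = 11, risk allele G) and rs334 (hemoglobin S, sickle
cell trait) carry literature-stated semantics; the remaining entries are
synthetic placeholders with seeded weights and frequencies.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "CATEGORIES",
    "EffectSize",
    "Panel",
    "PanelError",
    "PanelVariant",
    "classify_effect_size",
    "fixture_panel_path",
    "load_fixture_panel",
    "load_panel",
    "panel_summary",
    "write_panel",
]

CATEGORIES = (
    "ACL_rupture",
    "achilles_tendon",
    "bone_mineral_density",
    "osteoarthritis",
    "vitamin_mineral",
    "sickle_cell_trait",
)

EFFECT_MODELS = ("additive", "mendelian")
EVIDENCE_LEVELS = ("weak", "moderate", "strong")
STUDY_TYPES = ("candidate_gene", "GWAS")
_BASES = frozenset("ACGT")
_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X", "Y", "MT"])

#: Panel TSV column order; booleans serialize as 0/1, absent OR as "NA".
PANEL_COLUMNS = (
    "rsid", "chrom", "position", "effect_allele", "other_allele",
    "weight", "odds_ratio", "effect_model", "category", "subcategory",
    "allele_freq", "in_combined_score", "previously_used",
    "evidence_level", "study_type", "source",
)


class PanelError(ValueError):
    """Raised when a panel file or variant violates the schema."""


class EffectSize(enum.IntEnum):
    """Ordered effect-size class derived from an allelic odds ratio."""

    small = 1
    medium = 2
    large = 3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class PanelVariant:
    """One injury-associated SNP with its effect and literature metadata."""

    rsid: str
    chrom: str
    position: int
    effect_allele: str
    other_allele: str
    weight: float
    odds_ratio: float | None
    effect_model: str
    category: str
    subcategory: str
    allele_freq: float
    in_combined_score: bool
    previously_used: bool
    evidence_level: str
    study_type: str
    source: str

    def validate(self) -> None:
        """Check single-variant invariants; raise :class:`PanelError`."""
        if not self.rsid.startswith("rs") or not self.rsid[2:].isdigit():
            raise PanelError(f"malformed rsid {self.rsid!r}")
        if self.chrom not in _CHROMS:
            raise PanelError(f"{self.rsid}: unknown chromosome {self.chrom!r}")
        if self.position < 1:
            raise PanelError(f"{self.rsid}: non-positive position")
        if self.effect_allele not in _BASES or self.other_allele not in _BASES:
            raise PanelError(f"{self.rsid}: alleles must be A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise PanelError(f"{self.rsid}: effect and other allele identical")
        if not math.isfinite(self.weight):
            raise PanelError(f"{self.rsid}: non-finite weight")
        if self.odds_ratio is not None and self.odds_ratio <= 0:
            raise PanelError(f"{self.rsid}: odds ratio must be positive")
        if self.effect_model not in EFFECT_MODELS:
            raise PanelError(f"{self.rsid}: unknown effect model {self.effect_model!r}")
        if self.category not in CATEGORIES:
            raise PanelError(f"{self.rsid}: unknown category {self.category!r}")
        if self.effect_model == "mendelian" and self.category != "sickle_cell_trait":
            raise PanelError(f"{self.rsid}: mendelian model outside sickle_cell_trait")
        if self.effect_model == "additive" and not 0.0 < self.allele_freq < 1.0:
            raise PanelError(f"{self.rsid}: allele_freq must lie in (0,1)")
        if self.in_combined_score and self.category != "bone_mineral_density":
            raise PanelError(f"{self.rsid}: combined-score flag outside bone_mineral_density")
        if self.evidence_level not in EVIDENCE_LEVELS:
            raise PanelError(f"{self.rsid}: unknown evidence level {self.evidence_level!r}")
        if self.study_type not in STUDY_TYPES:
            raise PanelError(f"{self.rsid}: unknown study type {self.study_type!r}")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T or C/G sites, where strand cannot be resolved."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class Panel:
    """Ordered collection of panel variants plus the genome-build label."""

    variants: tuple[PanelVariant, ...]
    build: str = "GRCh37"
    _index: dict[str, PanelVariant] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        index: dict[str, PanelVariant] = {}
        for v in self.variants:
            if v.rsid in index:
                raise PanelError(f"duplicate rsid {v.rsid}")
            index[v.rsid] = v
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def get(self, rsid: str) -> PanelVariant | None:
        return self._index.get(rsid)

    def category(self, category: str) -> tuple[PanelVariant, ...]:
        """Variants of one category, in panel order."""
        if category not in CATEGORIES:
            raise PanelError(f"unknown category {category!r}")
        return tuple(v for v in self.variants if v.category == category)

    def combined_score_subset(self) -> tuple[PanelVariant, ...]:
        """The BMD subset entering the combined genetic score."""
        return tuple(v for v in self.variants if v.in_combined_score)

    @property
    def categories(self) -> tuple[str, ...]:
        present = {v.category for v in self.variants}
        return tuple(c for c in CATEGORIES if c in present)


def classify_effect_size(odds_ratio: float) -> EffectSize:
    """Classify an allelic odds ratio as small, medium or large.

    Thresholds: OR in [1.0, 1.3] is small, (1.3, 2.0] medium, above 2.0
    large.  Protective odds ratios (below 1) are classified by magnitude,
    i.e. 1/OR, so that e.g. 0.38 maps the same as 2.63.

    Parameters
    ----------
    odds_ratio : float
        Allelic odds ratio; must be positive.
    """
    if not math.isfinite(odds_ratio) or odds_ratio <= 0:
        raise ValueError(f"odds ratio must be positive and finite, got {odds_ratio}")
    magnitude = odds_ratio if odds_ratio >= 1.0 else 1.0 / odds_ratio
    if magnitude <= 1.3:
        return EffectSize.small
    if magnitude <= 2.0:
        return EffectSize.medium
    return EffectSize.large


def _parse_row(fields: Mapping[str, str], line_no: int) -> PanelVariant:
    def fail(msg: str) -> PanelError:
        return PanelError(f"line {line_no}: {msg}")

    try:
        odds = fields["odds_ratio"]
        variant = PanelVariant(
            rsid=fields["rsid"],
            chrom=fields["chrom"],
            position=int(fields["position"]),
            effect_allele=fields["effect_allele"],
            other_allele=fields["other_allele"],
            weight=float(fields["weight"]),
            odds_ratio=None if odds in ("NA", "") else float(odds),
            effect_model=fields["effect_model"],
            category=fields["category"],
            subcategory=fields["subcategory"],
            allele_freq=float(fields["allele_freq"]),
            in_combined_score=fields["in_combined_score"] == "1",
            previously_used=fields["previously_used"] == "1",
            evidence_level=fields["evidence_level"],
            study_type=fields["study_type"],
            source=fields["source"],
        )
    except (KeyError, ValueError) as exc:
        if isinstance(exc, PanelError):
            raise fail(str(exc)) from None
        raise fail(f"unparseable field ({exc})") from None
    try:
        variant.validate()
    except PanelError as exc:
        raise fail(str(exc)) from None
    return variant


def load_panel(path: str | Path, build: str = "GRCh37") -> Panel:
    """Load and validate a tab-separated panel file.

    The file must carry a header row with the canonical column names;
    lines starting with ``#`` are comments.  Row order is preserved.

    Raises
    ------
    PanelError
        On a missing/invalid header, a malformed row (with its line
        number), or a duplicate rsid (named in the message).
    """
    path = Path(path)
    header: list[str] | None = None
    variants: list[PanelVariant] = []
    with path.open("r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                missing = set(PANEL_COLUMNS) - set(header)
                if missing:
                    raise PanelError(
                        f"{path}: header missing columns {sorted(missing)}"
                    )
                continue
            if len(parts) != len(header):
                raise PanelError(
                    f"line {line_no}: expected {len(header)} fields, got {len(parts)}"
                )
            variants.append(_parse_row(dict(zip(header, parts)), line_no))
    if header is None:
        raise PanelError(f"{path}: no header row found")
    return Panel(variants=tuple(variants), build=build)


def write_panel(panel: Panel, path: str | Path,
                comments: Iterable[str] = ()) -> None:
    """Serialize a panel back to the tab-separated dialect.

    Round-trips through :func:`load_panel` to an equal panel.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for v in panel:
            odds = "NA" if v.odds_ratio is None else format(v.odds_ratio, "g")
            fh.write("\t".join([
                v.rsid, v.chrom, str(v.position), v.effect_allele,
                v.other_allele, repr(v.weight), odds, v.effect_model,
                v.category, v.subcategory, repr(v.allele_freq),
                "1" if v.in_combined_score else "0",
                "1" if v.previously_used else "0",
                v.evidence_level, v.study_type, v.source,
            ]) + "\n")


def panel_summary(panel: Panel) -> dict:
    """Per-category counts plus novelty statistics.

    Returns a dict with ``category_counts`` (category -> variant count),
    ``subcategory_counts`` (split on ';' for dual-labelled variants, so
    sub-counts may sum above the category count), ``total``,
    ``n_not_previously_used`` and ``pct_not_previously_used`` (rounded to
    the nearest integer percent).
    """
    cat_counts = {c: 0 for c in panel.categories}
    sub_counts: dict[str, int] = {}
    n_new = 0
    for v in panel:
        cat_counts[v.category] += 1
        if v.subcategory:
            for sub in v.subcategory.split(";"):
                sub_counts[sub] = sub_counts.get(sub, 0) + 1
        if not v.previously_used:
            n_new += 1
    total = len(panel)
    pct = round(100.0 * n_new / total) if total else 0
    return {
        "category_counts": cat_counts,
        "subcategory_counts": sub_counts,
        "total": total,
        "n_not_previously_used": n_new,
        "pct_not_previously_used": pct,
        "n_combined_score": len(panel.combined_score_subset()),
    }


def fixture_panel_path() -> Path:
    """Path to the bundled fixture panel TSV."""
    return Path(resources.files("sportsrisk.data") / "fixture_panel.tsv")


def load_fixture_panel() -> Panel:
    """Load the bundled 124-SNP fixture panel."""
    return load_panel(fixture_panel_path())


def complement_variant(variant: PanelVariant) -> PanelVariant:
    """The same variant reported on the opposite strand (test helper)."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    return replace(
        variant,
        effect_allele=comp[variant.effect_allele],
        other_allele=comp[variant.other_allele],
    )
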