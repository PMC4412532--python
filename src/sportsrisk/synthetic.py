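"""Synthetic genotype cohorts with the statistical structure the pipeline assumes.

Generates per-individual raw genotype files by drawing unphased diploid
genotypes at every panel locus from Hardy-Weinberg equilibrium at the
panel's effect-allele frequencies, independently across loci and
individuals (no linkage disequilibrium — the same independence the
calibration model assumes).  Selected individuals can be overridden with
deterministic extreme profiles: heterozygous at every locus of a
category, maximum or minimum risk, or a sickle-cell-trait carrier.

Also ships the pilot-cohort table: 14 triathletes (9 male, 5 female),
10 of 14 injured in the season before consultation (71%) and 4 of the
12 with follow-up data injured in the season after (33%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import GenotypeCall, GenotypeProfile, write_raw_genotypes
from .panel import CATEGORIES, Panel

__all__ = [
    "CohortSpec",
    "InjectedProfile",
    "cohort_injury_summary",
    "pilot_cohort",
    "simulate_profiles",
    "table1_cohort",
    "write_cohort",
]

PROFILE_KINDS = ("all_heterozygous", "max_risk", "min_risk", "sct_carrier")


@dataclass(frozen=True)
class InjectedProfile:
    """A deterministic override for one simulated individual."""

    individual_id: str
    category: str
    kind: str  # one of PROFILE_KINDS

    def __post_init__(self) -> None:
        if self.kind not in PROFILE_KINDS:
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Size, seed, composition and overrides for a simulated cohort."""

    n_individuals: int
    seed: int
    sex_ratio: float = 0.5  # fraction male
    injected: tuple[InjectedProfile, ...] = ()
    id_prefix: str = "athlete"

    def __post_init__(self) -> None:
        ids = [inj.individual_id for inj in self.injected]
        if len(ids) != len(set(ids)):
            raise ValueError("injected individual ids must be unique")
        if self.n_individuals < len(self.injected):
            raise ValueError("more injected profiles than individuals")

    def individual_ids(self) -> list[str]:
        width = len(str(max(self.n_individuals, 1)))
        return [f"{self.id_prefix}_{i+1:0{width}d}"
                for i in range(self.n_individuals)]


def _dosage_to_call(variant, dosage: int) -> GenotypeCall:
    alleles = tuple(sorted(
        [variant.effect_allele] * dosage
        + [variant.other_allele] * (2 - dosage)
    ))
    return GenotypeCall(rsid=variant.rsid, chrom=variant.chrom,
                        position=variant.position, alleles=alleles)


def _apply_injection(panel: Panel, calls: dict[str, GenotypeCall],
                     inj: InjectedProfile) -> None:
    targets = panel.category(inj.category)
    if not targets:
        raise ValueError(f"injected category {inj.category!r} absent from panel")
    dosage = {"all_heterozygous": 1, "max_risk": 2, "min_risk": 0,
              "sct_carrier": 1}[inj.kind]
    for v in targets:
        calls[v.rsid] = _dosage_to_call(v, dosage)


def simulate_profiles(panel: Panel, spec: CohortSpec) -> list[GenotypeProfile]:
    """Simulate one genotype profile per individual under HWE.

    Dosages at each panel locus are Binomial(2, allele_freq) draws —
    the HWE genotype distribution — independent across loci and
    individuals; injected profiles override the drawn calls at their
    category's loci.  Reproducible: the same spec and seed give
    identical profiles.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = np.array([v.allele_freq for v in panel])
    injections = {inj.individual_id: inj for inj in spec.injected}
    profiles: list[GenotypeProfile] = []
    for individual_id in spec.individual_ids():
        dosages = rng.binomial(2, freqs)
        calls = {
            v.rsid: _dosage_to_call(v, int(d))
            for v, d in zip(panel, dosages)
        }
        if individual_id in injections:
            _apply_injection(panel, calls, injections[individual_id])
        profiles.append(GenotypeProfile(individual_id=individual_id,
                                        calls=calls, build=panel.build))
    return profiles


def write_cohort(profiles: list[GenotypeProfile], out_dir: str | Path) -> list[Path]:
    """Write one raw genotype file per profile; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in profiles:
        path = out_dir / f"{p.individual_id}.txt"
        write_raw_genotypes(p, path)
        paths.append(path)
    return paths


def pilot_cohort(panel: Panel, seed: int = 2015) -> list[GenotypeProfile]:
    """Simulate 14 profiles mirroring the pilot cohort's genetic findings.

    One athlete is heterozygous at every osteoarthritis locus, and every
    athlete is sickle-cell-trait negative (the Mendelian locus is forced
    to homozygous normal), matching the observed cohort.  Individual ids
    align with :func:`table1_cohort`.
    """
    spec = CohortSpec(
        n_individuals=14, seed=seed,
        injected=(InjectedProfile("athlete_01", "osteoarthritis",
                                  "all_heterozygous"),),
    )
    profiles = simulate_profiles(panel, spec)
    sct = [v for v in panel if v.effect_model == "mendelian"]
    negatives = []
    for p in profiles:
        calls = dict(p.calls)
        for v in sct:
            calls[v.rsid] = _dosage_to_call(v, 0)
        negatives.append(GenotypeProfile(individual_id=p.individual_id,
                                         calls=calls, build=p.build))
    return negatives


def table1_cohort() -> pd.DataFrame:
    """The pilot cohort table: 14 athletes with per-season injury status.

    Marginals: 9 male / 5 female; 10 of 14 injured in season 1 (6 male,
    4 female); season-2 status known for 12 of 14 (one male and one
    female unknown), of whom 4 were injured.  ``season2_injured`` uses
    pandas NA for the two athletes without follow-up data.
    """
    rows = []
    # 9 males: 6 injured season 1; one without season-2 data; 2 injured s2
    s1_male = [True] * 6 + [False] * 3
    s2_male = [True, True, False, False, False, False, False, False, pd.NA]
    for i in range(9):
        rows.append((f"athlete_{i+1:02d}", "M", s1_male[i], s2_male[i]))
    # 5 females: 4 injured season 1; one without season-2 data; 2 injured s2
    s1_female = [True] * 4 + [False]
    s2_female = [True, True, False, False, pd.NA]
    for i in range(5):
        rows.append((f"athlete_{i+10:02d}", "F", s1_female[i], s2_female[i]))
    return pd.DataFrame(
        rows, columns=["individual_id", "sex", "season1_injured", "season2_injured"]
    ).astype({"season2_injured": "boolean"})


def cohort_injury_summary(table: pd.DataFrame) -> dict:
    """Per-season injury proportions over individuals with known status.

    Returns counts, percentages rounded to one decimal, and
    display-rounded integer percentages, per season and per sex.
    """
    if table.empty:
        raise ValueError("empty cohort table")
    out: dict = {"n_individuals": int(len(table))}
    for season in ("season1_injured", "season2_injured"):
        col = table[season]
        known = col.notna()
        n_known = int(known.sum())
        n_injured = int(col[known].astype(bool).sum())
        pct = 100.0 * n_injured / n_known if n_known else float("nan")
        key = season.replace("_injured", "")
        out[key] = {
            "n_known": n_known,
            "n_injured": n_injured,
            "pct_injured": round(pct, 1),
            "pct_display": round(pct),
        }
        if "sex" in table.columns:
            by_sex = {}
            for sex, grp in table.groupby("sex"):
                gk = grp[season].notna()
                gn = int(gk.sum())
                gi = int(grp[season][gk].astype(bool).sum())
                by_sex[sex] = {
                    "n_known": gn, "n_injured": gi,
                    "pct_injured": round(100.0 * gi / gn, 1) if gn else float("nan"),
                }
            out[key]["by_sex"] = by_sex
    return out
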