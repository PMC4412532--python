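"""Reference-population score distributions, quantile bins, risk tiers.

The population distribution of an additive score S = sum_i w_i * x_i is
computed under Hardy-Weinberg equilibrium: at each locus the
effect-allele dosage x_i is 0/1/2 with probabilities
((1-p_i)^2, 2 p_i (1-p_i), p_i^2), independent across loci (no linkage
disequilibrium).  The exact distribution is a dynamic-programming
convolution of the per-locus dosage-weight distributions on a fixed
score grid; a seeded Monte-Carlo sampler provides an independent
empirical cross-check.

Scores are banded into population-quantile bins (default quintiles,
matching the five risk categories of the combined bone-mineral-density
score, whose outer bins carry published odds: osteoporosis OR 1.56 /
fracture OR 1.60 at the top, 0.38 / 0.54 at the bottom) and bins map
onto the four color-coded report tiers: decreased (green), average
(black), slightly increased (yellow), increased (red).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .matching import MatchedDosage
from .panel import EffectSize, PanelVariant, classify_effect_size

__all__ = [
    "BinScheme",
    "DEFAULT_QUANTILES",
    "RiskTier",
    "ScoreDistribution",
    "TIER_COLORS",
    "assign_bin",
    "assign_tier",
    "derive_bins",
    "exact_score_distribution",
    "mc_score_distribution",
    "single_variant_tier",
]

DEFAULT_GRID_STEP = 0.01
DEFAULT_QUANTILES = (0.2, 0.4, 0.6, 0.8)
DEFAULT_MC_SEED = 2015

#: Published odds carried as annotations on the outer combined-score bins.
TOP_BIN_ODDS = {"osteoporosis_or": 1.56, "fracture_or": 1.60}
BOTTOM_BIN_ODDS = {"osteoporosis_or": 0.38, "fracture_or": 0.54}


class RiskTier(enum.IntEnum):
    """Four-level report tier; order reflects increasing risk."""

    decreased = 1
    average = 2
    slightly_increased = 3
    increased = 4


TIER_COLORS = {
    RiskTier.decreased: "green",
    RiskTier.average: "black",
    RiskTier.slightly_increased: "yellow",
    RiskTier.increased: "red",
}
COLOR_TIERS = {color: tier for tier, color in TIER_COLORS.items()}


@dataclass(frozen=True)
class ScoreDistribution:
    """Probability mass function of a category score on an ascending grid."""

    support: np.ndarray
    pmf: np.ndarray
    method: str  # "exact" | "monte_carlo"
    n_samples: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=float)
        pmf = np.asarray(self.pmf, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "pmf", pmf)
        if support.shape != pmf.shape or support.ndim != 1:
            raise ValueError("support and pmf must be 1-D of equal length")
        if support.size and np.any(np.diff(support) <= 0):
            raise ValueError("support must be strictly ascending")
        if np.any(pmf < 0) or abs(pmf.sum() - 1.0) > 1e-9:
            raise ValueError("pmf must be non-negative and sum to 1")

    @property
    def cdf(self) -> np.ndarray:
        return np.cumsum(self.pmf)

    def mean(self) -> float:
        return float(np.dot(self.support, self.pmf))

    def quantile(self, q: float) -> float:
        """Smallest support value with CDF >= q (deterministic on ties)."""
        if not 0.0 < q < 1.0:
            raise ValueError("quantile level must lie in (0,1)")
        idx = int(np.searchsorted(self.cdf, q - 1e-12, side="left"))
        return float(self.support[min(idx, self.support.size - 1)])

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write(f"# method: {self.method}\n")
            if self.n_samples is not None:
                fh.write(f"# n_samples: {self.n_samples}\n")
            if self.seed is not None:
                fh.write(f"# seed: {self.seed}\n")
            fh.write("score\tprobability\n")
            for s, p in zip(self.support, self.pmf):
                fh.write(f"{float(s)!r}\t{float(p)!r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreDistribution":
        path = Path(path)
        meta: dict[str, str] = {}
        support: list[float] = []
        pmf: list[float] = []
        with path.open("r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, value = line[1:].partition(":")
                    meta[key.strip()] = value.strip()
                    continue
                if not line or line.startswith("score\t"):
                    continue
                s, p = line.split("\t")
                support.append(float(s))
                pmf.append(float(p))
        return cls(
            support=np.array(support), pmf=np.array(pmf),
            method=meta.get("method", "exact"),
            n_samples=int(meta["n_samples"]) if "n_samples" in meta else None,
            seed=int(meta["seed"]) if "seed" in meta else None,
        )


def _hwe_probs(p: float) -> np.ndarray:
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])


def _to_distribution(idx_pmf: dict[int, float], grid_step: float,
                     **kwargs) -> ScoreDistribution:
    items = sorted(idx_pmf.items())
    support = np.array([i * grid_step for i, _ in items])
    pmf = np.array([p for _, p in items])
    pmf = pmf / pmf.sum()
    return ScoreDistribution(support=support, pmf=pmf, **kwargs)


def exact_score_distribution(variants: Sequence[PanelVariant],
                             grid_step: float = DEFAULT_GRID_STEP,
                             ) -> ScoreDistribution:
    """Exact HWE distribution of an additive score by grid convolution.

    Each locus contributes dosage 0/1/2 with HWE probabilities at its
    effect-allele frequency, scaled by its weight; scores are snapped to
    a grid of width ``grid_step`` and convolved locus by locus.  With no
    loci the distribution is a point mass at zero.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    # pmf over grid indices; dict convolution keeps the support sparse
    acc: dict[int, float] = {0: 1.0}
    for v in variants:
        probs = _hwe_probs(v.allele_freq)
        offsets = [round(k * v.weight / grid_step) for k in range(3)]
        nxt: dict[int, float] = {}
        for idx, mass in acc.items():
            for off, pr in zip(offsets, probs):
                if pr == 0.0:
                    continue
                key = idx + off
                nxt[key] = nxt.get(key, 0.0) + mass * pr
        acc = nxt
    return _to_distribution(acc, grid_step, method="exact")


def mc_score_distribution(variants: Sequence[PanelVariant],
                          n_samples: int = 100_000,
                          seed: int = DEFAULT_MC_SEED,
                          grid_step: float = DEFAULT_GRID_STEP,
                          ) -> ScoreDistribution:
    """Monte-Carlo HWE score distribution (seeded, reproducible).

    Dosages are drawn as Binomial(2, p_i) per locus per individual —
    exactly the HWE genotype distribution — and the weighted sums are
    binned on the same grid as the exact method.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    rng = np.random.default_rng(seed)
    weights = np.array([v.weight for v in variants])
    freqs = np.array([v.allele_freq for v in variants])
    if weights.size == 0:
        return ScoreDistribution(support=np.array([0.0]), pmf=np.array([1.0]),
                                 method="monte_carlo", n_samples=n_samples,
                                 seed=seed)
    dosages = rng.binomial(2, freqs, size=(n_samples, freqs.size))
    grid_idx = np.round(dosages * (weights / grid_step)).sum(axis=1)
    grid_idx = np.rint(grid_idx).astype(np.int64)
    uniq, counts = np.unique(grid_idx, return_counts=True)
    return _to_distribution(
        dict(zip(uniq.tolist(), (counts / n_samples).tolist())), grid_step,
        method="monte_carlo", n_samples=n_samples, seed=seed,
    )


@dataclass(frozen=True)
class BinScheme:
    """Ascending score cutpoints defining population-quantile bins.

    ``edges`` are the distribution's quantile values at ``quantiles``;
    bin b (1-based) is [edges[b-2], edges[b-1]) with bin 1 open below
    and the last bin closed above.  ``bin_annotations`` carries per-bin
    labels such as the published outer-bin odds.
    """

    edges: tuple[float, ...]
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES
    bin_annotations: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.quantiles):
            raise ValueError("one edge per quantile required")
        if any(b <= a for a, b in zip(self.quantiles, self.quantiles[1:])):
            raise ValueError("quantiles must be strictly ascending")
        if any(b < a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be non-decreasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write("bin\tlower_quantile\tlower_edge\tannotation\n")
            for b in range(1, self.n_bins + 1):
                lo_q = "" if b == 1 else repr(self.quantiles[b - 2])
                lo_e = "" if b == 1 else repr(self.edges[b - 2])
                fh.write(f"{b}\t{lo_q}\t{lo_e}\t{self.bin_annotations.get(b, '')}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BinScheme":
        quantiles: list[float] = []
        edges: list[float] = []
        annotations: dict[int, str] = {}
        with Path(path).open("r", encoding="utf-8") as fh:
            next(fh)  # header
            for line in fh:
                b, lo_q, lo_e, note = line.rstrip("\n").split("\t")
                if lo_q:
                    quantiles.append(float(lo_q))
                    edges.append(float(lo_e))
                if note:
                    annotations[int(b)] = note
        return cls(edges=tuple(edges), quantiles=tuple(quantiles),
                   bin_annotations=annotations)


def _default_annotations(n_bins: int) -> dict[int, str]:
    if n_bins != 5:
        return {}
    top = TOP_BIN_ODDS
    bot = BOTTOM_BIN_ODDS
    return {
        1: (f"lowest population quintile: osteoporosis OR {bot['osteoporosis_or']}, "
            f"fracture OR {bot['fracture_or']}"),
        5: (f"highest population quintile: osteoporosis OR {top['osteoporosis_or']}, "
            f"fracture OR {top['fracture_or']}"),
    }


def derive_bins(dist: ScoreDistribution,
                quantiles: Iterable[float] = DEFAULT_QUANTILES,
                annotations: dict[int, str] | None = None) -> BinScheme:
    """Quantile bin edges for a score distribution.

    Default quantiles (0.2, 0.4, 0.6, 0.8) give the five population
    quintile bins; for a 5-bin scheme the outer bins are annotated with
    the published combined-score odds unless annotations are supplied.
    """
    quantiles = tuple(quantiles)
    if not quantiles or any(not 0 < q < 1 for q in quantiles):
        raise ValueError("quantiles must lie strictly within (0,1)")
    if any(b <= a for a, b in zip(quantiles, quantiles[1:])):
        raise ValueError("quantiles must be strictly ascending")
    edges = tuple(dist.quantile(q) for q in quantiles)
    if annotations is None:
        annotations = _default_annotations(len(edges) + 1)
    return BinScheme(edges=edges, quantiles=quantiles,
                     bin_annotations=dict(annotations))


def assign_bin(score: float, scheme: BinScheme) -> int:
    """1-based bin for a score: bins are [lower, upper), last closed above."""
    for i, edge in enumerate(scheme.edges):
        if score < edge:
            return i + 1
    return scheme.n_bins


def assign_tier(score: float, scheme: BinScheme) -> RiskTier:
    """Map a score's population bin to the four-level report tier.

    For the default five-bin scheme: bin 1 is decreased, bins 2-3
    average, bin 4 slightly increased, bin 5 increased.  Other bin
    counts map by the same proportions (bottom bin decreased, top bin
    increased, second-from-top slightly increased when there are at
    least four bins).
    """
    b = assign_bin(score, scheme)
    n = scheme.n_bins
    if n == 1:
        return RiskTier.average
    if b == 1:
        return RiskTier.decreased
    if b == n:
        return RiskTier.increased
    if n >= 4 and b == n - 1:
        return RiskTier.slightly_increased
    return RiskTier.average


def single_variant_tier(variant: PanelVariant, match: MatchedDosage) -> RiskTier:
    """Tier contribution of a single matched variant, by effect size and dosage.

    Risk-oriented variants (OR >= 1): any copy of a large-effect allele
    is increased risk; a heterozygote at a medium-effect locus is
    slightly increased, a homozygote increased; small effects stay
    average.  Protective variants (OR < 1): carrying the allele lowers
    the tier to decreased.  Variants without an odds ratio (beta-scale)
    and excluded matches contribute average.
    """
    if match.excluded or variant.odds_ratio is None:
        return RiskTier.average
    size = classify_effect_size(variant.odds_ratio)
    d = match.dosage
    if variant.odds_ratio < 1.0:
        return RiskTier.decreased if d >= 1 else RiskTier.average
    if size is EffectSize.large and d >= 1:
        return RiskTier.increased
    if size is EffectSize.medium:
        if d == 2:
            return RiskTier.increased
        if d == 1:
            return RiskTier.slightly_increased
    return RiskTier.average
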