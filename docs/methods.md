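# Methods

## Problem and model

`sportsrisk` assesses an athlete's genetic predisposition to six
sports-injury categories — ACL rupture, Achilles tendon injury, low bone
mineral density (a stress-fracture risk factor), osteoarthritis,
vitamin/mineral deficiencies, and sickle cell trait — from a
direct-to-consumer (DTC) raw genotype export and a curated SNP panel.

Each additive category carries a polygenic score

    S = Σᵢ wᵢ·xᵢ

where xᵢ ∈ {0, 1, 2} is the athlete's dosage of the effect allele at
locus *i* and wᵢ is the per-allele weight: the natural log of the allelic
odds ratio for binary outcomes, the regression β for quantitative traits
(vitamin/mineral biomarkers). The two scales are never mixed within one
score. Sickle cell trait is the single Mendelian category: carrier status
follows directly from the rs334 genotype (0 variant alleles = negative,
1 = trait carrier, 2 = homozygous variant).

The combined bone-mineral-density score sums the 63-SNP subset flagged
`in_combined_score` and is interpreted against the score's population
distribution: five quintile bins whose outer bins carry the published
clinical odds (top quintile: osteoporosis OR 1.56, fracture OR 1.60;
bottom quintile: 0.38 and 0.54).

## Allele harmonization

DTC exports report unphased forward-strand genotypes. Matching a call
against a panel variant proceeds in order:

1. call alleles ⊆ {effect, other} → direct dosage;
2. call alleles ⊆ strand complements of {effect, other} → dosage on the
   complemented alleles, flagged `strand_flipped`;
3. otherwise → typed exclusion (`allele_mismatch`).

Missing calls (`--` or absent rsid) and indel codes (I/D) are typed
exclusions as well; no failure mode raises inside scoring. Palindromic
panel sites (A/T, C/G) are excluded by default because a strand flip
there is undetectable from alleles alone; `trust_strand=True` opts into
same-strand reporting. The Mendelian rs334 site is itself A/T
palindromic, so the carrier call trusts the forward-strand convention —
the documented exception, stated in its docstring.

A fully complementary call (e.g. A/C against a G/T panel site) is
treated as a strand flip, consistent with standard PRS harmonization
practice, even though one could also read it as a mismatch; the flip
reading is the only one under which harmonization is invariant to the
reporting strand (property-tested).

## Missing-locus handling

With incomplete coverage the raw score is rescaled by
Σ|w| (all loci) / Σ|w| (matched loci), keeping it on the full-panel scale
of the reference distribution; scores with coverage below 0.9 (default
floor) are flagged `insufficient_coverage` and surfaced as a coverage
warning in reports. Rescaling can be disabled. Hemizygous calls count
the single allele once (dosage 0/1); all bundled panel loci are
autosomal, so this path is exercised only by unit tests.

## Population calibration

The reference distribution of an additive score assumes Hardy–Weinberg
equilibrium at each locus — genotype probabilities
((1−p)², 2p(1−p), p²) at effect-allele frequency p — and independence
across loci (no linkage disequilibrium), the standard PRS reference
assumption. Two routes:

- **exact**: dynamic-programming convolution of per-locus dosage-weight
  distributions. Scores are snapped to a grid (default step 0.01 on the
  weight scale), which bounds the support (~10³ points for 63 loci) and
  makes quantiles deterministic. Grid snapping moves each locus
  contribution by at most step/2, so the distribution mean matches the
  analytic Σ wᵢ·2pᵢ within n·step/2·2 (observed error ~10⁻³).
- **monte_carlo**: Binomial(2, p) dosage draws per locus (identical to
  HWE), seeded (default seed 2015, always recorded in the output), used
  as an independent cross-check of the exact route; its quantiles agree
  with exact within 3 sampling standard errors at 10⁵ draws.

Quantile convention: the smallest support value whose CDF reaches q
(deterministic on discrete ties). Bins are half-open [lower, upper) with
the last bin closed above; a degenerate point-mass distribution
collapses all edges and maps every score at the mass point to the top
bin. Default quantiles (0.2, 0.4, 0.6, 0.8) give quintiles; the bin
count is configurable because the original five population categories
may not have been exact quintiles.

## Tier mapping

Reports use four color-coded tiers: decreased (green), average (black),
slightly increased (yellow), increased (red). The five population bins
map to tiers by this package's convention (the source material does not
specify one): bin 1 → decreased, bins 2–3 → average, bin 4 → slightly
increased, bin 5 → increased. Categories scored per-variant (few-SNP
candidate-gene panels) tier by effect size and dosage: any copy of a
large-effect (OR > 2) risk allele → increased; heterozygous at a
medium-effect locus → slightly increased, homozygous → increased;
protective alleles (OR < 1) carried with no risk findings → decreased;
otherwise average. Effect-size classes follow the odds-ratio rule
small = [1.0, 1.3], medium = (1.3, 2.0], large = (2.0, ∞), with the
shared boundary values resolved downward for determinism and protective
ORs classified by magnitude 1/OR.

## Fixture panel

The bundled panel reproduces the published review's composition — 124
SNPs: ACL 4, Achilles 6, BMD 67 (63 in the combined score),
osteoarthritis 7, vitamin/mineral 39, sickle cell trait 1 — with 113
SNPs (91%) not previously used in sports genetics (the 11 previously
used being the ACL, Achilles and SCT variants). Two source statements
disagree on the BMD count (66 vs 67); 67 is used so category counts sum
to the printed 124. The vitamin/mineral sub-rows print 41 assignments
over 39 SNPs; two folate-pathway variants are dual-labelled
`b_vitamins;homocysteine`, the only consistent reading.

Only rs1800012 (COL1A1; Achilles rupture OR 11, risk allele G, G
frequency 0.82) and rs334 (hemoglobin S; forward-strand alleles T/A,
variant allele A) carry literature semantics. Every other rsID, weight
and frequency is a seeded synthetic placeholder
(`scripts/build_fixture_panel.py`, seed 2015): BMD ORs U(1.02, 1.17),
OA ORs U(1.10, 1.20), vitamin/mineral β U(0.03, 0.15), frequencies
U(0.10, 0.90) except large-effect candidate-gene risk alleles at
U(0.05, 0.30) (large-effect risk alleles at high frequency are
implausible under selection). Synthetic sites use only non-palindromic
allele pairs so default matching covers the whole panel.

## Synthetic cohorts

The generator draws unphased genotypes per locus from HWE at the panel
frequencies, independent across loci and individuals — matching the
calibration model exactly, which is both its purpose and its limitation:
it emulates no linkage disequilibrium, no ancestry structure, no
genotyping error or missingness, and no genotype–injury association
(injury labels are fixture attributes, not modeled outcomes). Passing
tests therefore demonstrate pipeline correctness under the model's own
assumptions, not robustness to real-data artifacts. Injected profiles
override draws deterministically: `all_heterozygous`, `max_risk`,
`min_risk` (dosage 1/2/0 at every category locus) and `sct_carrier`
(heterozygous rs334). Same spec and seed give byte-identical files.

The pilot cohort helper simulates 14 athletes mirroring the study's
genetic findings — every athlete sickle-cell-trait negative (forced,
since at carrier frequency 0.02 a random 14-person cohort would contain
a carrier ~43% of the time) and one athlete heterozygous at all seven
osteoarthritis loci. The companion cohort table fixes the injury
marginals: 9 male/5 female; 10/14 injured in season 1; season-2 status
known for 12, of whom 4 injured; proportions are computed over known
statuses only (71.4% → 71%, 33.3% → 33%). The published per-sex
season-2 percentages cannot all be consistent with a denominator of 12,
so only the overall marginals are encoded.

## Problem sizes and numerical choices

The default test and acceptance runs use the full 124-SNP panel, the
63-locus exact convolution (≈10³ support points, < 1 s), Monte-Carlo
cross-checks at 10⁵ draws, and simulated cohorts of up to 10⁴
individuals for HWE frequency checks — sizes chosen to exercise every
code path at full panel scale while completing in seconds. Exact-pmf
normalization tolerance is 10⁻⁹; KS agreement between simulated cohorts
and the exact distribution is tested at loose α (0.001) because the
discrete grid makes the KS statistic conservative.

## Known limitations

- Panel weights/frequencies are placeholders; real use requires a curated
  panel file in the documented TSV schema.
- Single frequency column: no ancestry-specific reference distributions.
- No genome-build liftover; profile and panel build labels must match.
- No imputation; uncovered loci reduce coverage rather than being
  inferred.
- VCF ingestion is an extension point (the TSV dialect is the only
  implemented reader).
- The pre/post-consultation injury comparison is descriptive counting;
  the package deliberately fits no genotype→injury model.
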