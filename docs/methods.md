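# Methods

This note records the statistical model behind `dtmr`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that a maintainer would otherwise have
to reverse-engineer.

## Study design

The package implements a four-step drug-target Mendelian randomization (MR)
workflow over GWAS summary statistics.  Step 1–2: two-sample MR of a
protein exposure (cis-pQTL instruments) on disease and risk-factor
outcomes, each analysis paired with Bayesian colocalization and extended by
phenome-wide single-variant scans.  Step 3: validation by genetic mimicry
(concordance of common-variant and protein-truncating-variant effect
profiles over a metabolite panel) and by functional-variant-restricted MR.
Step 4: meta-analysis of protein-truncating-variant (PTV) carrier studies.

## Estimators

**Wald ratio.**  θ̂ = β_Y/β_X, se = se_Y/|β_X|.  The SE is first order and
ignores exposure-side uncertainty; this is standard practice and
conservative for instruments that pass genome-wide significance, where the
exposure z-score is large.  β_X = 0 is a hard error, not a NaN.

**IVW.**  Fixed-effect: θ̂ = Σβ_Xβ_Y/se_Y² / Σβ_X²/se_Y², identical to
SE-weighted zero-intercept regression (asserted against a generic
least-squares solve in the tests).  Heterogeneity is Cochran's
Q = Σw_i(θ_i − θ̂)² with w_i = β_X,i²/se_Y,i².  Random effects use
multiplicative overdispersion — the fixed SE scaled by
max(1, √(Q/(k−1))) — rather than an additive τ²; this is the two-sample MR
convention and guarantees the random-effects SE never falls below fixed.
A single instrument under the random model falls back to fixed with a
warning.

**GLS-IVW.**  With covariance Ω_ij = se_Y,i · se_Y,j · r_ij from signed LD:
θ̂ = (XᵀΩ⁻¹X)⁻¹XᵀΩ⁻¹Y, se = √((XᵀΩ⁻¹X)⁻¹).  Exposure effects are treated
as fixed (outcome-SE-only covariance), the standard correlated-instrument
weighting.  The condition number of Ω is computed on every call; above 1e8
the fit aborts with advice to clump at a stricter r², since a
near-singular Ω means near-duplicate instruments.  A generalized Q
(residual quadratic form in Ω⁻¹) is reported with k−1 degrees of freedom.

**Effect translation.**  `rescale_log_or` multiplies a log-OR result by an
exposure dose (e.g. converting an OR per mmol/L TG into the OR for an
achieved TG reduction); it composes multiplicatively.  `orient_to_lowering`
negates estimates so results read per unit of *lowered* exposure, matching
how protein-lowering therapies are discussed.

**Confidence intervals and multiplicity.**  When an analysis family
carries a Bonferroni divisor m, CIs are reported at level 1 − 0.05/m and a
row passes at p ≤ 0.05/m.  The shipped families are: primary disease
5×3 + 5×4 + 5 = 40; risk factors 15×3 = 45; imaging 11×3 = 33; blood
chemistry 43×3 = 129; phenome-wide 694×3 = 2082; and an uncorrected family
(m = 1) for safety outcomes where a false negative is costlier than a
false positive.

## Instrument selection

Cis selection keeps variants inside the gene footprint padded by 2.5 kb
with exposure p ≤ 5×10⁻⁸, then clumps greedily: accept the smallest-p
variant, discard everything with r² ≥ 0.10 against an accepted index,
repeat.  Ties in p break by ascending position then lexicographic id, so
selection is a pure function of the data.  The r² threshold is read as the
*removal* condition — retained pairs satisfy r² < 0.10 — because its
purpose is protecting the GLS covariance from multicollinearity.  The
greedy output equals the lexicographically-first maximal independent set
under the p ordering; the tests verify this against exhaustive subset
enumeration.  Genome-wide mode (positive-control polygenic exposures) uses
r² < 0.001 plus a 500 kb positional window between accepted index variants
on the same chromosome.

The functional-variant filter retains, at a relaxed p ≤ 0.01, variants in
UTR/splice/truncating classes and missense variants with SIFT
"deleterious" or PolyPhen "probably/possibly damaging".  PolyPhen's
vocabulary has no "likely damaging" label, so the accepted set
{probably_damaging, possibly_damaging} is a documented judgement call.
PTV flagging requires a stop-gain, frameshift or essential-splice
consequence and effect-allele frequency below 0.05.

## Harmonization

Outcome records are aligned to the exposure's effect allele: swapped
alleles negate β and complement the allele frequency; non-palindromic
strand flips are resolved by complementation; palindromic (A/T, C/G)
variants with exposure EAF within 0.5 ± 0.08 are dropped as ambiguous (the
window is a package default; the upstream sources are pre-harmonized, so
no published rule exists to copy).  Harmonization is involutive —
re-harmonizing aligned pairs changes nothing — and this is property-tested.
Multi-allelic sites (duplicate ids) are rejected at parse time.

## Colocalization

Per-variant Wakefield log approximate Bayes factors,
log ABF = ½(log(1−K) + Kz²) with K = W/(W + se²), are combined under the
single-causal-variant assumption: H1 and H2 sum each trait's ABFs, H4 sums
the products over the shared variant, H3 sums products over distinct
variants (computed as the full product sum minus the diagonal, in log
space throughout).  Priors default to p1 = p2 = 1e-4 and p12 = 1e-5, and
the effect-prior variance to W = 0.15² for quantitative traits and 0.2²
(log-OR) for binary ones — the field-standard defaults, configurable per
call.  Posteriors are renormalized and asserted to sum to 1 within 1e-9.
No multi-signal (conditioning/masking) extension is attempted.

## PTV meta-analysis and mimicry

Carrier 2×2 tables give Woolf log-ORs with the Haldane–Anscombe 0.5
correction when a cell is zero (a zero margin is an error).  Fixed-effect
IVW pooling runs per truncating allele or per mmol/L TG; the per-TG scale
divides each study's log-OR and SE by its |TG effect|, substituting the
pooled IVW TG estimate for studies lacking one.  Denominator uncertainty
is ignored (first-order) — the pooled per-TG SE is conditional on the TG
effects, which is the standard simplification and is stated here
prominently.  The absolute value is used with the orientation tracked
separately, so protective alleles with negative TG effects do not flip
sign spuriously.  An I² = max(0, (Q−df)/Q) is reported alongside Q as a
convenience.  A `sequencing_only` filter (default on) drops
array-genotyped studies before pooling, because rare-variant genotype
error on arrays biases toward the null.

Mimicry divides the PTV (collapsing) effect vector by its 1-s.d. TG effect
to put both profiles on a comparable scale, then fits OLS with intercept
and reports R².  R² is invariant to common rescaling of both vectors;
three traits is the minimum accepted.

## The synthetic-data generator

`simulate_region` emulates a cis region at the summary level.  LD is AR(1)
(r_ij = ρ^|i−j|, default ρ = 0.6) or two independent AR(1) blocks for the
distinct-signal colocalization scenario.  One causal variant carries a
per-allele protein effect (default 0.3 s.d.); marginal effects of the
other variants are the causal effect propagated through LD on the
standardized-genotype scale and de-standardized by each variant's own
allele frequency.  The binary outcome acts through the exposure: every
variant's true outcome log-OR is θ times its true exposure effect, which
is exactly the no-horizontal-pleiotropy identifying assumption of MR, and
is recorded in a truth sidecar for recovery tests.  Sampling noise is
multivariate normal with per-variant SEs from the analytic approximation
se = sd/√(2·n·maf(1−maf)) (divided by √(cf(1−cf)) for a binary outcome
with case fraction cf) and correlation equal to the LD matrix — the
within-cohort correlation of summary-statistic noise that the GLS
estimator exists to handle.  Exposure and outcome samples are independent
(two-sample design; no overlap knob).  Default sample sizes (3.5×10⁴
exposure, 10⁶ outcome, 16% cases) mirror the scale of a large pQTL
discovery cohort feeding a CAD-sized case-control meta-analysis.

Binary outcomes are simulated directly on the log-OR scale with Gaussian
noise rather than via individual-level logistic draws: two-sample MR
consumes only summary data, and the summary-level route keeps every oracle
analytic.  What the generator deliberately does *not* emulate: real allele
frequency spectra and LD panels, sample overlap between exposure and
outcome, horizontal pleiotropy, population stratification, and
platform-specific epitope artefacts (a platform-replicate helper adds
unstructured between-assay noise only).  Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to those real-data pathologies.

`simulate_ptv_study` draws binomial case counts for heterozygous carriers
(odds multiplied by the per-allele OR over a 10% baseline risk) and a TG
mean difference around the configured shift (default −0.81 mmol/L, the
magnitude typical of truncating alleles in these lipase-pathway genes);
studies with an expected cell below 1 carry a warning flag.
`simulate_metabolite_panel` draws per-trait latent effects (scale
0.25 s.d.) bivariate-normal with the configured concordance ρ and adds
0.01 s.d. measurement noise — small relative to the latent scale, as
collapsing estimates over ~180k participants are precise — so the
observed R² concentrates near ρ² (e.g. ρ = 0.91 → R² ≈ 0.83, the
high-concordance regime; the panel default is 167 traits).

## Numerical and design choices

- LD matrices store signed r; clumping squares it.  Non-PSD inputs are
  repaired by eigenvalue clipping at 1e-8 followed by diagonal
  renormalization, so the GLS covariance is always invertible; asymmetry
  beyond 1e-8 or |r| > 1 + 1e-8 is an input error, not repaired.
- Coordinates are 1-based.  Delimiters are auto-detected between tab and
  comma on input; output is always tab.  Numeric round-trip is preserved
  to 12 significant digits.
- P-values are clipped into (0, 1] at the smallest positive float rather
  than underflowing to 0.
- Selection that finds nothing returns a typed empty instrument set
  ("Zero SNPs"), not an exception, so report tables can show the row.
- Phenotypes missing the instrument variant are reported "not testable"
  rather than p = 1.
- The pipeline derives every stage seed from the master seed by hashing
  the stage label, so stages are independently reproducible and a config +
  seed reproduces `results.json` byte for byte.
- The verification experiments (`dtmr.experiments`) use 500 replicates for
  recovery/coverage, 2000 for type-I error, 200 per colocalization
  scenario and 1000 clumping instances — sizes at which Monte-Carlo error
  is small relative to the property bands being checked.

## Known limitations

- No MR-Egger, weighted-median or other pleiotropy-robust estimators; the
  workflow's pleiotropy control is instrument design (cis windows,
  functional filters) plus colocalization.
- The GLS weighting ignores exposure-side uncertainty, which costs a
  little CI coverage (a percentage point or two at realistic pQTL sample
  sizes) — visible in the recovery experiments and inherent to the
  first-order convention.
- Per-TG meta-analysis SEs ignore denominator uncertainty.
- Multi-allelic sites are rejected rather than decomposed.
- Colocalization assumes at most one causal variant per trait per region.
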