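# Methods

## Model and assumptions

Two-sample MR takes per-SNP association estimates from two independent
GWAS: β̂ₓⱼ ± σₓⱼ for the exposure and β̂ᵧⱼ ± σᵧⱼ for the outcome. The
working model is

  β̂ᵧⱼ = θ β̂ₓⱼ + αⱼ + εⱼ,  εⱼ ~ N(0, σᵧⱼ²)

with causal effect θ (log-OR per SD of the exposure for binary
outcomes) and pleiotropic effect αⱼ. The standard instrumental-variable
assumptions are: relevance (β̂ₓⱼ ≠ 0, enforced by genome-wide
significance), independence from confounders, and exclusion restriction
(αⱼ = 0). Additional two-sample assumptions: non-overlapping samples
(so σₓ and σᵧ errors are independent — this is what the first-order
Wald SE and the mediation delta method rely on), a common underlying
population, and linearity/homogeneity of the SNP effects. Sensitivity
estimators relax exclusion: IVW-RE tolerates balanced pleiotropy, the
weighted median tolerates up to 50% of weight on invalid instruments,
and MR-Egger allows directional pleiotropy if it is independent of
instrument strength (InSIDE).

## Estimators

- **Wald ratio**: θ̂ⱼ = β̂ᵧⱼ/β̂ₓⱼ, SE σᵧⱼ/|β̂ₓⱼ| (first order); an
  optional second-order term adds β̂ᵧⱼ²σₓⱼ²/β̂ₓⱼ⁴.
- **IVW, multiplicative random effects**: weighted least squares of β̂ᵧ
  on β̂ₓ through the origin, weights wⱼ = 1/σᵧⱼ². The fixed-effect SE
  1/√(Σwⱼβ̂ₓⱼ²) is inflated by √(max(1, Q/(L−1))) where Q is Cochran's
  statistic; under-dispersion is never allowed to shrink the SE below
  fixed-effect. p-values are normal. I² = max(0, (Q−df)/Q)·100 with
  bands low (≤25), moderate (25–50), high (≥50).
- **Weighted median**: interpolated weighted median of the per-SNP Wald
  ratios, weights 1/SE(θ̂ⱼ)²; SE from a seeded parametric bootstrap
  (default 1000 replicates) redrawing β̂ₓ and β̂ᵧ from their reported SEs.
- **MR-Egger**: weighted regression with intercept after orienting all
  β̂ₓⱼ ≥ 0; t(L−2) inference; residual overdispersion multiplies both
  SEs, floored at 1.
- **MVMR**: no-intercept weighted least squares of β̂ᵧ on the matrix of
  exposure betas over the union of the exposures' instruments (or the
  first exposure's set for mediation step 2), same overdispersion floor,
  normal p-values. The design is rejected if its condition number
  exceeds 10⁸.
- **Mediation (two-step)**: α from IVW of exposure→mediator on the
  exposure's instruments; β_m from MVMR of (mediator, exposure)→outcome
  on the mediator's instruments. Indirect = α·β_m with delta SE
  √(α²SE(β_m)² + β_m²SE(α)²); mediated proportion = indirect/total·100
  with a delta-method ratio CI. Proportions outside [0, 100]% are
  reported and flagged, never clamped.

## Harmonization

Outcome records are re-expressed on the exposure's effect allele:
identical allele pairs are kept; reversed pairs get β negated and
EAF reflected; strand complements (and complement-plus-swap) are
recognized for non-palindromic SNPs. Palindromic SNPs (A/T, C/G) are
oriented by EAF concordance — both studies' effect-allele frequencies
must fall on the same side of 0.5 — and excluded as ambiguous when the
exposure MAF exceeds 0.42 (strictly; 0.42 itself is retained) or EAF is
missing or exactly 0.5. Instruments associated with the outcome at
genome-wide significance are excluded. Missing outcome SNPs may be
replaced by LD proxies with r² > 0.60, choosing the maximum r² and
breaking ties lexicographically; proxy alleles are remapped through the
proxy's allele correspondence.

## Instrument strength and power

Per-SNP variance explained uses the standardized identity
R² = z²/(z² + N); F = R²(N−2)/(1−R²). Study power for a binary outcome
with total N, case fraction K, instrument R² and true odds ratio OR is

  power = Φ(z − z_{1−α/2}) + Φ(−z − z_{1−α/2}),  z = |ln OR|·√(N·R²·K(1−K))

two-sided at α = 0.05 by default.

## Defaults and rationale

| Parameter | Default | Rationale |
|---|---|---|
| instrument p-threshold | 5×10⁻⁸ | genome-wide significance convention |
| outcome-association exclusion | 5×10⁻⁸ | removes instruments plausibly acting outcome-first |
| palindromic MAF threshold | 0.42 | EAF orientation unreliable near 0.5 |
| proxy r² minimum | 0.60 | common proxy-lookup floor |
| family-wise α / family size | 0.05 / 5 | Bonferroni over the five primary outcomes (threshold 0.01); a 4-outcome family gives 0.0125, conventionally printed as 0.013 but compared at full precision |
| bootstrap replicates | 1000 | weighted-median SE stable to ~2% |
| overdispersion floor | 1 | multiplicative random-effects convention; SEs never shrink below fixed-effect |

## Synthetic-data generator

`mrpipe.synthetic_data` draws per-SNP true effects γⱼ ~ N(0.02, 0.005²)
(per-SNP F in the tens at N = 400 000), EAFs uniform in MAF 0.05–0.5,
and asymptotic standardized SEs se = 1/√(2f(1−f)N), multiplied by
1/√(K(1−K)) for binary outcomes (K = 0.10 by default). Observed betas
add mean-zero noise at the reported SE; pleiotropy is injected into a
configurable fraction of instruments with configurable mean
(directional) and SD (balanced). Allele-orientation corruption —
effect/other swaps (30%), strand flips (10%), palindromic pairs
(15%) — changes only the representation, never the implied association,
and the truth record keeps the uncorrupted orientation. The mediation
generator adds a mediator-only instrument block and three independent
samples. Defaults are study conditions fixed once in the dataclass; the
generator covers common-variant, independent-instrument settings only
(no LD between instruments, no sample overlap, no winner's curse).

## Numerical choices

Regressions are delegated to `statsmodels` WLS; unscaled coefficient
SEs are taken from the normalized covariance so the overdispersion floor
can be applied explicitly. p-values are clipped away from zero at the
smallest positive double. Summary-statistic I/O round-trips exactly:
writing uses `%.17g` and reading uses round-trip float parsing.

## Limitations

- Inference is asymptotic (normal/t); very small instrument counts rely
  on the Wald-ratio fallback.
- The weighted-median bootstrap is parametric, not resampling-based.
- MVMR assumes the exposure betas are measured precisely enough to
  ignore regression dilution (no SE-weighting of the design matrix).
- The generator does not model LD, sample overlap, or selection
  (winner's curse), so calibration results apply to independent-SNP
  settings.
- The mediated-proportion CI is a delta-method approximation that can be
  poor when the total effect is near zero; such cases are flagged.
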