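# Methods

## Familial-aggregation meta-analysis

Each published study contributes one log relative risk (logRR) with its
standard error; where only 2×2 counts are available, `rr_from_counts` applies
`RR = (a/(a+c))/(b/(b+d))` with the delta-method variance
`1/a − 1/(a+c) + 1/b − 1/(b+d)`. Studies with an empty `a` or `b` cell have
no finite logRR and are excluded by default (the published pooled analyses
likewise dropped the one zero-proband study); a 0.5 continuity correction is
available but opt-in, because it biases small studies toward the null.

Pooling is inverse-variance on the log scale. The random-effects model uses
the DerSimonian–Laird moment estimator of the between-study variance τ²; the
heterogeneity block (Q, df, I², τ²) is always computed from the fixed-effect
weights, so common- and random-effects reports agree on heterogeneity.
Confidence intervals are Wald intervals with z = 1.96 on the log scale, no
Hartung–Knapp adjustment — this is the combination that reproduces the
published pooled values, and it is what the packaged fixtures are checked
against. I² is truncated at 0 and reported as a percentage.

The packaged study table stores, per study row, the printed RR, logRR, SE and
CI. Three printed rows are internally inconsistent; for these the fixture
stores the (logRR, SE) pair that reproduces the row's own printed CI:
the myositis rows (logRR recomputed as ln RR — one printed logRR is a clear
sign/magnitude typo), one sibling row whose printed SE disagrees with its CI
(SE 0.713 recovered from the CI half-width), and one MS row whose logRR and
SE columns are evidently transposed. Pooling groupings are explicit study
lists in `poolings.yaml`, not inferred: overlapping national registry cohorts
(Sweden, Taiwan) are de-duplicated by keeping the study with more probands,
which selects one of the two Taiwanese lupus registry analyses and the
dedicated 2016 systemic-sclerosis study. The published systemic-sclerosis
pooled RR of 2.65 is not reproducible from any subset of the printed rows
(our pooling of the two retained studies gives 2.51); the package reports its
own value and the test suite asserts the discrepancy rather than the printed
number.

Small-study diagnostics: Egger's test is OLS of θ/SE on 1/SE with a t-test on
the intercept (n − 2 df); Begg's test is Kendall's τ-b between
variance-standardized deviations from the common-effect pooled value and the
study variances, with the normal-approximation p. Because every deviation is
measured from the same pooled mean, the full-null rejection rate of Begg's
test sits slightly below nominal — the test is conservative, which the suite
asserts instead of uniformity. Cohen's κ is computed from marginal
frequencies with the convention κ = 1 when both raters are constant and equal
(chance agreement p_e = 1).

## Summary-statistic harmonization

All downstream code consumes one canonical representation: GRCh38 records
with columns chrom/pos/effect_allele/other_allele/beta/se/p/n plus z = β/SE,
sorted and unique on the variant key. Rows failing validity (SE ≤ 0, p
outside (0,1], identical alleles) are dropped with a counted warning;
duplicate keys are a hard error, since silent de-duplication would hide
upstream merge bugs. Pairwise alignment intersects on position (not rsID —
identifier coverage differs across resources), flips the sign of z₂ where the
effect/other coding is swapped (including after strand complementation), and
drops strand-ambiguous A/T and C/G variants: without allele frequencies their
orientation cannot be determined. Genome-build liftover is out of scope;
inputs must already be GRCh38.

## Locus architecture

Genome-wide significance is strict: p < 5×10⁻⁸. Each significant variant is
expanded to a ±250 kb window (floored at position 1) and intersecting or
end-to-start touching windows are merged — with integer coordinates adjacency
is a measure-zero distinction and merging is the conservative reading. The
merge is a sort-and-sweep verified against a per-base coverage-union oracle.
The HLA region is the half-open chr6 [25,000,000, 34,000,000) on GRCh38; any
nonempty intersection classifies a locus as HLA.

Cross-disease overlap is evaluated in union-locus space: all diseases' loci
merged into non-overlapping union loci, a presence bit per disease, and
Jaccard = shared/either over those bits. Evaluating in union space (rather
than raw per-disease intervals) means one physical region counts once per
pair even when the two diseases' raw loci fragment differently. The Jaccard
of a pair with no loci at all is defined as 0.

## LD score regression

The univariate regression is χ²ⱼ on ℓⱼ with heteroskedasticity-motivated
weights 1/(1 + N h² ℓⱼ/M)², iterated twice from an unweighted first pass; h²
= slope·M/N. The bivariate regression is z₁ⱼz₂ⱼ on ℓⱼ with the analogous
variance approximation in the weights; the intercept is never constrained,
because sample overlap (shared controls) must be absorbable there. Standard
errors are a contiguous-block jackknife, 200 blocks by default (configurable);
for rg the per-block delete values of all three slopes (covariance and the
two heritabilities) are combined, so the rg SE reflects correlated noise in
numerator and denominator. The p-value for rg uses the normal approximation
on rg/SE. Heritability estimates are clipped to [0,1] only at reporting time;
rg is reported outside [−1,1] with a warning rather than truncated. Variants
in the HLA window are excluded from the regressions by default (the published
correlations exclude it too), with `exclude_hla=False` available. A minimum
of 200 regression variants and non-constant LD scores are enforced.

## PLACO pleiotropy

Calibration uses variants that are approximately null in *both* traits
(p > 10⁻⁴ jointly — the AND rule keeps genuinely associated variants out of
the covariance estimate): VarZ per trait, CorZ across traits. Adjustment
rescales by √VarZ first, then whitens with the symmetric inverse square root
of the 2×2 correlation matrix — the symmetric root makes the transform
invariant under trait swap. |CorZ| ≥ 0.999 is rejected as collinear.

The product-normal tail P(|XY| ≥ t) is computed from the Bessel density
K₀(|x|)/π via adaptive quadrature of the exponentially scaled k0e with the
e^(−t) factor applied analytically, keeping absolute accuracy through the
deep tail (checked to |t| = 50). The composite-null p-value is the
intersection–union bound max(p₀, p₁, p₂): p₀ the product-normal tail, p₁ and
p₂ the marginal two-sided p-values of the *other* trait's adjusted score —
each term is exactly the tail probability under one sub-null, so the max is
level-α under all three. This construction is deliberately simple and
provably conservative; simulation shows type-I error at or below nominal
under both the both-null and single-trait-associated sub-nulls, and spiked
truly-pleiotropic variants dominate equally strong single-trait variants.

## Synthetic data

The familial generator draws per-study effects θᵢ ~ Normal(μ, τ²), control
counts Binomial(n, baseline) and case counts Binomial(n, baseline·e^θ);
defaults emulate registry-scale cohorts (800/5,000/8,500 cases, controls ×10,
baseline 0.2%). It refuses parameter combinations implying a case rate above
1. Note that with τ² > 0 and only three studies the DerSimonian–Laird CI
undercovers (≈84% at τ² = 0.05 in our simulations) — a known small-k
property, so the coverage guarantee in the tests is stated for τ² = 0
(97% observed).

The GWAS generator simulates z-scores directly at the summary level from a
per-variant multivariate normal with Var(z_k) = 1 + N_k h_k² ℓⱼ/M and
Cov(z_k, z_l) = ρs_kl + √(N_kN_l) rg_kl √(h_k²h_l²) ℓⱼ/M — exactly the
moment structure the LDSC regressions invert, so parameter recovery is a
genuine end-to-end check. LD scores are 1 + Gamma(1.5, 6) (mean ≈ 10,
right-skewed, minimum 1). Variants sit on an even 100 kb grid over
chromosomes 1–22 so that chromosome 6 spans the HLA window; alleles alternate
A/G and C/T (never palindromic, so pairwise alignment keeps every variant).
Spikes overwrite the drawn z with a fixed large value in every trait, inside
the HLA window or at listed positions. What the generator does *not* emulate:
realistic LD block structure (LD scores are exchangeable draws, not spatially
correlated), allele-frequency spectra, ancestry structure, or case/control
imbalance — so passing recovery tests demonstrate correctness of the
estimators under their own model assumptions, not robustness to real-data
violations of them.

Default scales for the recovery suite: M = 20,000 variants, N = 50,000,
h² = 0.3 — small enough that a full simulate-fit cycle runs in well under a
second while leaving jackknife SEs a few percent. All generators are
seed-deterministic and emit a JSON truth sidecar.

## Pipeline

Stages communicate only via files (TSV/BED/JSON), so any stage can be re-run
standalone from prior outputs; a failed stage aborts its dependents but
independent stages complete, and the run log records the package version,
seed and a config hash. Outputs are plain text throughout. Plotting is left
to downstream tools: every figure-shaped result (forest table, Jaccard
matrices, Manhattan-ready PLACO scans, presence matrix) is exported as a
table instead.

## Known limitations

- The τ² estimator is DerSimonian–Laird only; REML/Paule–Mandel and
  Hartung–Knapp CIs are not implemented (they would not reproduce the
  published values, which is this package's calibration anchor).
- Locus definition is purely positional; no LD-aware clumping or conditional
  analysis.
- LDSC here regresses on *supplied* LD scores; computing LD scores from a
  reference panel is out of scope, as are partitioned heritability and
  functional annotations.
- PLACO's intersection–union p-value is conservative relative to approaches
  that model the product distribution under estimated non-unit variances;
  power comparisons across PLACO variants are out of scope.
- The pleiotropy scan does not colocalize: a significant pleiotropic variant
  indicates shared signal, not a shared causal variant.
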