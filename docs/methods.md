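# Methods

This note documents the statistical models behind `crosspop`, the choices
made where the methodology is genuinely open, and what the synthetic-data
tests do and do not demonstrate about real data.

## Setting and notation

Two GWAS of the same phenotype: a large *discovery* cohort (subscript 2;
European-ancestry role, sample size N₂) and a smaller *target* cohort
(subscript 1; East Asian-ancestry role, N₁). For SNP j we observe marginal
per-allele effects β̂ⱼₖ with standard errors sⱼₖ, z = β̂/s and two-sided
P = 2Ψ(−|z|). Reference panels of a few hundred genotyped individuals per
population supply the variant map, allele frequencies, LD and Fst.

## Harmonization

QC follows the conventional five steps, in order: drop all copies of
duplicated rs ids; keep biallelic single-base variants; require rs labels;
require presence in the reference panel with a matching (possibly
order-swapped) allele pair; keep MAF > 0.01 (panel-backfilled when the
file lacks frequencies). Pairing intersects the populations on rs id and
aligns population 1 to population 2's effect allele, negating β and
complementing the effect-allele frequency where the pair is order-swapped.
Palindromic (A/T, C/G) SNPs are strand-ambiguous; they are retained only
when both populations' MAF < 0.4 (configurable, `palindromic_maf_max`),
the conventional safeguard. Coordinates are 1-based; the MHC exclusion
(chr6:28.5–33.5 Mb, bounds inclusive) is applied before heritability-type
analyses and before transFDR classification, because the region's
long-range LD violates the approximate independence transFDR assumes.

## Index-SNP selection

Greedy P-ordered clumping on panel genotypes, PLINK-convention: candidates
with p < 5×10⁻⁸ are visited in ascending P (ties broken by lower
(chromosome, position) for cross-platform determinism); a candidate is
discarded if it lies within 1 Mb of an already-accepted index SNP on the
same chromosome with squared Pearson dosage correlation > 0.01. Distance
is measured index-to-candidate. The clumping is validated against an
exhaustive-pair reference implementation.

## Winner's-curse correction

Index SNPs are selected because |z| exceeded c = Ψ⁻¹(1 − α/2) ≈ 5.4513
(α = 5×10⁻⁸) in the same data used to estimate their effects, so
β̂ | selection is biased away from zero. Under β̂ ~ N(β, s²) truncated to
|β̂/s| > c,

    E[β̂ | selected] = β + s·[φ(β/s − c) − φ(−β/s − c)]
                          / [Ψ(β/s − c) + Ψ(−β/s − c)],

which is also the score equation of the truncated-normal likelihood. The
corrector inverts this identity per SNP by a dense grid search (10,001
points) over the 95% CI of β̂, using a single pooled s (the mean SE of the
index set) inside the model, ties broken toward smaller |β| (more
conservative shrinkage). The corrected SE keeps the marginal z unchanged:
se(β) = β/z.

**Known limitation.** For observations just above the threshold the
estimating equation has no root inside the search window (the conditional
mean exceeds β̂ for every in-window β); the solution then sits near the
window's lower edge, giving a systematic *negative* per-SNP overshoot of
up to ~2 SE units near |z| ≈ c. Averaged over a polygenic spectrum of
selected SNPs the corrected effects still reduce the mean selection bias
several-fold (≥ 5× in the package's acceptance simulations, which use
normal true effects with sd(z_true) = 2.5 so that selected SNPs' true z
spans roughly 4–8), but per-SNP corrected values near the threshold should
be treated as conservative lower bounds in magnitude.

## Sample-size standardization

To stop the N₁ ≪ N₂ gap masquerading as population specificity, target
SEs are replaced by the frequency-based approximation evaluated at the
*discovery* sample size:

    continuous:  se ≈ √(1/(N·f·(1−f)))
    binary:      se ≈ √((N₁ + N₀)/(2·N₁·N₀·f·(1−f)))

with the effect held fixed and z/P recomputed. These are the forms used at
the analysis stage; note the continuous form omits the diploid factor 2 —
it is an approximation inherited from the method, applied identically to
real and synthetic inputs, so downstream comparisons are internally
consistent (it scales all target z by the same √2-type constant).

## transFDR

The trans-ethnic FDR of an index SNP is the posterior probability that it
is null in the target population given observed significance in both
populations. Conditioning on discovery significance is implemented by
restricting the empirical-Bayes fit to the discovery-significant index set
(the analysis set *is* the conditioning event). Within that set the
quantity is the Efron two-group local FDR of the standardized target z.

Because the hypothesis is two-sided, the model is fit on magnitudes:
null density f₀(|z|) = 2φ(|z|) (theoretical half-normal), marginal f̂
estimated by Poisson-GLM smoothing of |z| histogram counts (120
equal-width bins, cubic B-spline basis with 7 df, uniform internal knots),
π₀ by Storey's λ = 0.5 estimator on the two-sided P values (capped at 1),
and fdr(|z|) = π̂₀·f₀/f̂ clipped to [0,1] and made monotone non-increasing
in |z| by isotonic regression. Fitting on |z| rather than signed z makes
the transFDR invariant to the sign of z (as a two-sided quantity should
be) and avoids unstable density estimation in sparse signed tails.
A theoretical rather than empirical null is used deliberately: index-SNP
sets are small and signal-enriched, so central matching would be badly
biased. Sets with fewer than 30 SNPs skip density estimation and use BH
q-values on the conditioned set as a conservative surrogate.

Declaration threshold 0.05. Calibration on synthetic index sets (half
shared at near-complete power, half target-null) shows the procedure is
conservative: empirical FDR ≈ 0.01% at the 5% threshold, and on pure-null
sets essentially nothing is declared. The histogram-spline density cannot
track the steep null→alternative transition of the fdr curve (it falls
from ~0.9 to ~0.1 within about one z unit) to better than ~0.1–0.25
absolute at realistic set sizes; outside that narrow transition the fitted
fdr tracks the Bayes oracle to within 0.05. This matters for interpreting
individual fdr values near the decision boundary, not for the group
classification, which the calibration results cover.

## Heterogeneity and group characterization

Within each group (significant / non-significant) the marginal
trans-ethnic correlation r_m of effect estimates is disattenuated for
estimation noise under a measurement-error model:

    r_m = S₁₂ / √((S₁² − mean(s₁²))·(S₂² − mean(s₂²))),

clipped to [−1,1]; if a noise-corrected variance is non-positive (small,
noise-dominated groups) the raw Pearson correlation is used with a
warning. Per-SNP heterogeneity contrasts the unadjusted target effect with
the bias-reduced discovery effect:

    u = (β̂₁ − β̂₂) / √(s₁² + s₂² − 2·r_m·s₁·s₂),

two-sided normal P, BH within phenotype and group, heterogeneous if
FDR < 0.05. The r_m term treats the two estimators as correlated; with
truly independent sampling noise this makes the test anti-conservative in
high-r_m groups — a property of the method itself, visible in synthetic
runs as a substantial "heterogeneous" share even for perfectly shared
effects, and consistent with the high heterogeneity fractions the approach
reports on real data. Group contrasts of heterogeneous counts use Pearson
chi-square without continuity correction.

Direction concordance classifies nonzero effect pairs by sign quadrant
(++, +−, −+, −−); exact zeros are reported separately.

## Population-genetic metrics

LD scores: for each focal SNP, the sum over same-chromosome SNPs within
±10 Mb (self included) of the bias-adjusted squared correlation
r̃² = r² − (1 − r²)/(n − 2); flanking SNPs must pass MAF > 0.01 and HWE
P > 10⁻⁵ (chi-square, 1 df — adequate at n ≈ 500). Cross-population CVs
use the two-value form (|a − b|/√2)/mean(a,b) (n−1 SD over mean); MAF is
folded first. Fst per SNP is Hudson's estimator with sampling correction
(configurable to Weir–Cockerham-style uses downstream); slightly negative
values are legitimate and not clamped. Group comparisons: two-sided
Mann–Whitney U (normal approximation, tie-corrected) per phenotype;
across phenotypes each contributes the binary indicator
mean(significant) < mean(non-significant) and an exact binomial sign test
against 0.5 is reported — the pragmatic reading of a "paired McNemar on
group averages", which is not otherwise well defined; a literal McNemar
chi-square on the discordant-pair construction is available behind
`literal_mcnemar` for transparency.

## Phenotype-level tests

Heritability difference: u = (ĥ²₁ − ĥ²₂)/√(se₁² + se₂² − 2ρ̂g·se₁·se₂),
treating ρ̂g as the correlation between the two heritability estimators as
the formula is written, with two-sided normal P. ρg = 0 and ρg = 1 tests
are two-sided normal tests on (ρ̂g − ρ₀)/se; two-sided is the declared
convention because, with the bundled 31-phenotype table, it yields 16/30
BH rejections of ρg = 1 (53.3%) where one-sided would give 19. BH is the
standard step-up procedure (validated against statsmodels); h²/ρg
estimation itself (LD-score regression, trans-ethnic-correlation software)
is upstream and consumed as a table. The heritability CV per phenotype
uses the two-value n−1 convention above; since that convention is a
choice, only the sign of its association with ρ̂g is treated as
meaningful.

## Synthetic-data generator

`generate_panels` draws ancestral frequencies Uniform(0.05, 0.5),
diverges them by Balding–Nichols with parameter F (so E[Fst] ≈ F), and
builds haplotypes from block-shared latent Gaussians: SNPs within a block
share a factor giving within-block squared dosage correlations of roughly
the requested level (the threshold construction attenuates the latent
correlation slightly). Default panel sizes 504/503 individuals mirror the
reference-cohort role.

`generate_paired_sumstats` draws causal standardized effects from a
bivariate normal with correlation ρg and variances h²ₖ/m_causal, converts
to per-allele scale by dividing by √(2f(1−f)), and adds estimation noise
with the exact sampling SE 1/√(2·N·f·(1−f)) (case/control form for binary
traits), which is also reported as the record's SE — so z = β/se, P and
the polygenic identity E[χ²] = 1 + N·h²/m hold exactly in expectation.
Winner's curse arises naturally from selecting at P < 5×10⁻⁸. Defaults
(h²₁ = 0.08, h²₂ = 0.13, N₁ = 100k, N₂ = 500k, ρg = 0.75, 1% causal)
reflect typical values for the phenotypes this pipeline targets: target
cohorts several-fold smaller, moderate polygenic heritability, strong but
incomplete trans-ethnic sharing.

**What the synthetic tests do not show.** The generator has no realistic
genome-wide LD map (block-uniform LD only), no summary-statistic/panel
mismatch, no imputation error, no within-population stratification, and
binary traits are emulated at the summary level rather than via a
liability threshold. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated model, not robustness to those
real-data complications.

## Numerical choices

- Truncation-model ratio: evaluated with scipy's survival functions; where
  the denominator underflows (|z| far beyond any realistic value) the bias
  term is zero by construction and β is returned unchanged.
- Grid solver: 10,001 points over β̂ ± 1.96s; agreement with a Brent
  root-finder is within one grid step wherever an interior root exists.
- Local FDR: bins fixed at 120; spline df 7; both configurable. Degenerate
  inputs (constant z, < 30 SNPs) fall back to fdr ≡ 1 or BH q-values with
  a warning rather than failing.
- P values are clamped at 10⁻³⁰⁰ before BH to guard floating-point
  underflow to zero.
- All randomness flows from a single seed through stage-name-hashed
  substreams (`crc32(stage)` mixed into a `SeedSequence`), so stage-level
  reruns and full-pipeline reruns are bit-reproducible.
- Problem sizes in the acceptance simulations (6,000 selected SNPs for the
  bias-reduction check; 50 replicates of 400-SNP index sets for FDR
  calibration; 5,000 SNPs for correlation recovery) were chosen so that
  Monte-Carlo error is small relative to the properties being asserted.
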