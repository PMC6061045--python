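# Methods

This note documents the statistical model behind each pipeline stage, the
parameters that matter, the design choices made where the recipe left the
design open, what the synthetic-data generator does and does not emulate,
and the package's known limitations.

## The two-step mouse screen

**Step 1 — strain-differential selection.** Non-transgenic animals from
three inbred strains (one of low AD susceptibility; defaults DBA, B6, SJL
with 4 arrays each) are compared per probe with the classical
pooled-variance two-tailed Student *t* test. The phrase "differential in
the resistant strain compared with the other two" admits three readings,
all implemented:

* `either` (default): summary *p* = min of the two pairwise comparisons —
  a probe counts if it differs from *either* susceptible strain;
* `both`: the max — it must differ from both;
* `pooled`: one comparison against the susceptible strains pooled.

The default follows the "or" phrasing of the source screen. Zero pooled
variance with equal means yields *p* = 1 by convention. The FDR reported at
a cutoff α is the expected-false-positives estimator *m*·α/*k* (capped at
1, undefined when *k* = 0); the exact estimator behind the original
screen's printed FDR is not described, so no attempt is made to match it.
A gene is a candidate when **any** of its probes passes (probes collapse
to genes by the mapping table; the unit-of-selection question — probes vs
genes — is resolved this way).

**Step 2 — amyloid correlation.** In the transgenic cohort (default
*n* = 28 animals) each gene's expression is correlated with the per-animal
amyloid-β level. The correlation type is not stated in the source recipe;
**Pearson** is used because the (r, n = 28) → p mapping then reproduces all
five published per-gene correlation p-values at printed precision (one row
differs by one unit in the sixth decimal, attributable to the published r
being rounded to four decimals). The two-tailed *p* uses
*t* = *r*√((*n*−2)/(1−*r*²)) with *n*−2 df; a 10,000-permutation oracle
agrees within Monte-Carlo error. Probe→gene collapse keeps the
smallest-*p* probe (ties: larger |r|, then lexicographic probe id).

## Per-SNP association and inflation

The association model is logistic regression with additive allele-dosage
coding and age + sex covariates, Wald two-tailed *p* on the dosage
coefficient (the original test statistic is unstated; this is the standard
covariate-adjusted choice). Age is standardized and sex coded 0/1 before
fitting; missing dosages are dropped per SNP (complete-case). Monomorphic
SNPs and (quasi-)separated fits are reported as missing with a reason
rather than silently dropped.

λ is the median of the per-SNP 1-df χ² statistics divided by the exact
χ²₁ median 0.454936… (printed as 0.4549 elsewhere; the exact value makes
"all p = 0.5 ⇒ λ = 1" hold identically). QQ coordinates are
−log₁₀((i−0.5)/n) vs −log₁₀ p₍ᵢ₎.

## Gene-based statistics (extended Simes)

SNP-to-gene assignment: inside [start − 3 kb, end + 3 kb] on the gene's
chromosome, plus LD proxies with *r*² **strictly** > 0.8 to any in-region
SNP. Proxy candidates are searched within ±1 Mb of the flanked region — an
implementation bound (typical LD range is far shorter) since the source
recipe sets none. Genes with no assigned SNP are flagged and excluded
downstream.

The gene p-value is P = min_j Me·p₍ⱼ₎/Me(j) over ascending-sorted SNP
p-values (ties broken by genomic position then SNP id, for
reproducibility). Me = M − Σ_{λ>1}(λ−1) from the eigenvalues of the
p-value correlation matrix; negative eigenvalues of the approximate
(possibly non-PSD) matrix are truncated at zero, Me is clamped to [1, M],
and the partial Me(j) sequence is made monotone non-decreasing (it is in
exact arithmetic). The p-value correlation is approximated from genotype
correlation r by the published 6th-degree polynomial (coefficients 0.2982,
−0.0127, 0.0588, 0.0099, 0.6281, −0.0009), evaluated at |r| so the
function is even, clipped to [0, 1], and pinned to exactly 1 at |r| = 1 so
duplicated SNPs collapse to min-p exactly (the raw polynomial gives 0.9814
at 1). An f(r) = r² fallback is selectable. Both are validated against a
Monte-Carlo bivariate-normal oracle; the limiting cases (identity LD ⇒
Simes, unit LD ⇒ min p) hold exactly, and the permutation-calibrated
type-I error at 0.05 under AR-1 LD (adjacent r = 0.8, 10 SNPs) is ~0.05.

## Integration

One-tailed z-scores are obtained as z = Φ⁻¹(1 − p/2) — **both** two-tailed
inputs are halved before inversion. This convention is adopted because it
is the only one that reproduces all five published combined p-values to 3
significant figures from the published input pairs. Z_C = (Z_MEXP +
Z_HGWAS)/√2 without weights; the combined one-tailed p is doubled and
capped at 1. The mouse direction (sign of r) is annotation only and never
flips z — consistent with the published table, where positively and
negatively correlated genes combine identically.

Because both z's are folded (non-negative), the combined p is **not**
uniform under the null: with independent uniform inputs the rejection rate
at nominal 0.05 is ≈ 0.096 (folded-normal-sum closed form, confirmed by
simulation in `calibration.stouffer_null_calibration`). This
anti-conservatism is reported, not corrected — fidelity to the recipe
takes precedence, and the Bonferroni-style threshold 0.05/n/2 governs the
actual calls. Ortholog joining is case-insensitive on symbols; when
several mouse genes map to one human gene the smallest-p mouse partner is
kept and flagged `multi_ortholog`. The threshold denominator defaults to
the number of genes with both p-values.

z-scores are capped at the quantile of p = 10⁻³⁰⁰ (z ≈ 37.04) with a
logged warning when an input p underflows the inversion.

## Validation stage

Reference normalization is a plain ratio on linear scale or 2^−ΔCt on the
qPCR cycle scale; group comparison is the pooled-variance two-tailed t
test (case minus control sign convention); FDR control is
Benjamini–Hochberg ("FDR < 0.05" named no procedure; BH is the standard
deterministic step-up choice). The family is the set of genes in the
validation run. Direction concordance (a "Down" gene being lower in the
disease group) is recorded per gene as a boolean report, not asserted.

## Synthetic data: what it emulates

One root seed feeds named substreams per stage, so stages regenerate
independently and identical configurations are bit-identical.

* **Strain expression**: gene baselines ~ N(8, 1) log-intensity, i.i.d.
  Gaussian noise (σ = 1). Planted genes are shifted in the
  low-susceptibility strain only, by `strain_shift_sd` noise-SDs (default
  6; the screen is meant to retain strongly strain-differential genes, and
  at 6 SD the default 4-per-strain design has ~0.97 power at p < 0.001 by
  the noncentral-t oracle). A "Down" gene (negatively amyloid-correlated)
  is shifted *up* in the resistant strain, mirroring the motivating
  biology.
* **Transgenic cohort**: amyloid is log-normal (exp(N(log 50, 0.5²)),
  ELISA-like positive and right-skewed; the distribution is a design
  choice, not an inference). Causal-gene expression is baseline +
  β·amyloid + noise with β set from the *population* SDs so the population
  correlation equals the configured signed effect (default magnitude 0.7);
  the sample correlation at n = 28 is attenuated slightly (mean ≈ −0.67
  for a −0.7 target), as expected for finite samples.
* **Genotypes**: haplotypes from a latent-Gaussian threshold model, AR-1
  within LD blocks, independent across blocks; dosage = sum of two
  haplotypes. `within_block_rho` is the target **allelic** correlation of
  adjacent SNPs: the latent coefficient is found per adjacent pair by
  inverting the tetrachoric relation (bisection on the bivariate-normal
  orthant probability via Owen's T), because a latent correlation used
  directly badly under-delivers allelic r² after thresholding (latent 0.95
  at MAF 0.3 yields allelic r² ≈ 0.62, not > 0.8). MAFs are uniform on
  (0.05, 0.5]; one gene spans each block (blocks 2 Mb apart, SNPs 1 kb
  apart).
* **Phenotypes**: logit P(case) = b₀ + Σ log(OR)·dosage + 0.02·(age−70) +
  0.25·sex, with b₀ bisected so the expected case fraction matches the
  target (±0.02 realized at n = 2,000); causal SNPs default to the middle
  SNP of each causal gene's block, per-allele OR 1.5.

**Not emulated**: demographic population structure (so λ calibration
checks the statistic, not confounding control), genotyping error and
imputation, probe-level microarray artifacts, batch effects,
between-block LD, and realistic gene length / SNP density variation.
Passing tests therefore show the *statistics* behave as designed, not that
the pipeline is robust to those real-data complications.

## Problem sizes in the standard runs

Null GWAS calibration uses 50,000 LD-free SNPs × 1,000 individuals
(LD-free so the median-λ acceptance band [0.97, 1.03] reflects
calibration rather than block-dependence noise). Extended-Simes
calibration uses one 10-SNP gene at adjacent allelic r = 0.8 with 10,000
phenotype permutations, scored by the vectorized 1-df trend test (the
no-covariate score test of the same logistic model) and the batched GATES
implementation (verified identical to the scalar one). End-to-end recovery
runs 50 replicate studies at the default 200-gene configuration.

## Known limitations

* The GATES polynomial is an approximation fitted for two-tailed p-value
  correlation; outside |r| ≤ 1 it is undefined and near |r| = 1 it is
  pinned to 1 (see above).
* The inverse-normal combination's null anti-conservatism (above) means
  combined p-values should be interpreted through the study-wide
  threshold, not as calibrated tail probabilities.
* Per-SNP logistic fits are per-column statsmodels fits; at hundreds of
  thousands of SNPs a specialized batched solver would be preferable.
* The 3-noise-SD / 4-animals-per-strain screen configuration sometimes
  quoted for this design has only ~0.4 (either) to ~0.6 (pooled) power at
  p < 0.001 by the noncentral-t oracle; recovery claims at that effect
  size are checked against the oracle, not against a fixed rate.
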