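# Methods

## Scope

`eqtlkit` re-implements, at desk scale, a condition-resolved expression-GWAS
workflow: per-condition mixed-linear-model association of every SNP with every
expressed gene, consolidation of significant SNPs into eQTLs, local/distant and
static/dynamic classification, a TF→target network with hierarchy tiers, and
2SLS Mendelian randomization linking instrumented expression to a quantitative
phenotype. Upstream read processing (alignment, variant calling, transcript
quantification) is out of scope: the package starts from a genotype matrix
(VCF), a gene annotation (GFF3), per-condition abundance matrices (TSV) and a
phenotype vector.

## Genotype QC

Residual heterozygous calls in an inbred panel are treated by site MAF: below
0.05 they are assumed to be sequencing errors and recoded to the major-allele
homozygote; at or above 0.05 they are masked as missing. SNP filters are
applied exactly as stated for the target design — missing fraction strictly
below 0.6, MAF at least 0.05 (inclusive). Cross-panel comparison keys SNPs on
(chrom, pos, ref, alt) with allele-swap detection; discordant jointly-called
cells are masked missing in the merged panel, and concordance is averaged per
sample (a pooled-cells variant is available, since the choice is not forced by
the definition).

## Expression normalization

Each condition's abundance matrix is quantile-normalized across samples (every
sample's sorted values become the across-sample mean order statistics; ties
within a sample receive the mean of the reference values they span), then each
gene is inverse-normal transformed: value_i → Φ⁻¹((r_i − a)/(n + 1 − 2a)) with
the qqnorm offset convention a = 0.5 for n > 10 and a = 3/8 for n ≤ 10,
average ranks for ties, missing values excluded from n. Quantile normalization
and the rank transform are each exactly idempotent on their own axis; their
composition preserves per-gene ranks up to tie-averaging collisions (the
transformed matrix places every gene on the same value grid, so a second pass
meets ties that the first did not). The expression filter keeps genes above
0.05 (strict, configurable) in at least ⌈0.2·n⌉ samples.

Differential expression across conditions is called by a fold-change-fraction
rule aggregated over accessions: a gene is a DEG when, for some condition
pair, ≥ 20% of paired accessions change by |log2 FC| > 1 (ε = 0.01 guards
zeros) and a paired Wilcoxon signed-rank test across accessions passes BH
FDR < 0.05. This replaces a count-model test that would need within-accession
replicates the data model does not contain; the 20%-of-accessions aggregation
is kept verbatim. DEG profiles (z-scored condition means) are clustered by
k-means (k = 3, n_init = 25) with labels canonically reordered by descending
centroid slope so cluster 1 is "induced", cluster k "repressed".

## Association scan

The per-gene model is y = Wα + xβ + u + e with u ~ N(0, σ²_g K),
e ~ N(0, σ²_e I). Components:

- **Kinship** K: IBS similarity K_ij = mean over jointly called SNPs of
  1 − |g_i − g_j|/2, computed on a thinned set (per non-overlapping 10-kb
  window, the SNP with the lowest missing rate; ties to the lowest position).
  IBS plays the same role as 1 − (normalized distance) from a distance-matrix
  program, but is exactly specified. Non-PSD K gets a 1e-6 ridge (logged).
- **Structure covariates**: top principal components (default 3) of the
  centered, mean-imputed dosage matrix, signs fixed by making each loading
  vector's largest-magnitude element positive. This substitutes a model-based
  ancestry program with an equivalent fixed-effect correction.
- **Hidden factors** (default k = 14): each transformed gene is residualized
  on the structure covariates, and the top sample-space principal components
  of the residual matrix enter as fixed effects. This is the PC analogue of a
  Bayesian factor-analysis step; k = 14 matches the factor count the target
  design retains per condition.
- **Variance components (P3D)**: K = U D Uᵀ once per panel; per gene, REML
  over δ = σ²_e/σ²_g on a 101-point log₁₀ grid in [−5, 5] plus bounded local
  refinement, under the null (no SNP). δ̂ is reused for every SNP of that gene.
- **Per-SNP test**: GLS in the whitened rotated system via Frisch–Waugh
  residualization (two matrix products per gene for the whole SNP panel);
  Wald t with df = n − rank(W) − 1; partial R² = t²/(t² + df), which is the
  "determination coefficient" reported as an eQTL's effect size (the source
  workflow never defines it; this is our interpretation, documented).
  Missing dosages are mean-imputed per SNP; post-imputation monomorphic SNPs
  are dropped; samples with missing expression are dropped per gene (with a
  kinship sub-decomposition). With K = I and no covariates the scan is
  numerically identical to OLS simple regression.
- **Significance**: Benjamini–Hochberg step-up on the pooled p-values of all
  gene × SNP tests within a condition (matching a single per-condition
  cutoff); zero rejections give cutoff 0.

## eQTL consolidation and classification

Per etrait–condition, an eQTL exists only when ≥ 3 SNPs are genome-wide
significant (the rule is applied before grouping by default; a per-cluster
variant is configurable because the phrasing is ambiguous). Consolidation:
(1) single-linkage chaining of significant SNPs with gaps < 5 kb on one
chromosome; (2) transitive merging of clusters whose lead SNPs have dosage
r² > 0.1 within 250 kb (union over the pre-merge leads, then the overall most
significant lead is re-elected); (3) merging of clusters whose leads fall in
the same gene body. Lead ties break by larger partial R², then smaller
position, making outputs deterministic and order-independent.

Locality: local ⇔ lead SNP within [gene start − 20 kb, gene end + 20 kb] on
the same chromosome (window anchored on the gene body, not the TSS). Dynamics:
cross-condition locus identity is not defined by the source design; we declare
two per-condition loci of one etrait identical when their leads are < 5 kb
apart or in LD (r² > 0.1) — the same tolerances used within a condition. A
locus in all three regimes is static, in one or two dynamic, and stress-only
when never seen under WW. Percentages in summaries are rounded half-up to one
decimal.

## TF network and hierarchy

Distant eQTLs whose lead SNP lies inside a TF gene body (1-based inclusive)
become directed edges TF → etrait (both edges, with a warning, if two TF
bodies overlap the lead; never a self-edge). Edges are deduplicated per
(regulator, target) with condition sets unioned. Hierarchy height
h = (O − I)/(O + I) uses each TF's out-degree and its in-degree through TF
regulators (every edge source is a TF by construction). Heights min–max
normalize to [0, 1]; equal-width thirds give tiers (top [2/3, 1], middle
[1/3, 2/3), bottom [0, 1/3)); a quantile mode is available because the tier
cutoffs are an interpretation, not a published definition. Family-level scores
sum O and I over member TFs before computing h.

## Mendelian randomization

One test per (gene, condition) with a called eQTL; the instrument z is that
condition's lead SNP (additive coding, hets = 1), the exposure x the same
condition's transformed expression, the outcome y the condition-independent
phenotype; samples missing any of z, x, y are dropped. b_zx and b_zy are
simple least-squares slopes; b_xy = b_zy/b_zx;
var(b_xy) = var(y)(1 − R²_xy)/(n·var(x)·R²_zx) with n−1-denominator sample
variances; T_MR = b²_xy/var(b_xy) against χ²₁. The experiment-wise threshold
defaults to 1/n_tests ("reciprocal": 30,006 tests → 3.33 × 10⁻⁵); the orthodox
0.05/n Bonferroni is available. Significant genes split into positive and
negative contributors by sign(b_xy), counted per gene on its best test.

**Known property**: the variance formula is exact when x explains ~none of y,
and understates the sampling variance by a factor ≈ 1/(1 − R²_xy) otherwise.
Under a null with strong x–y confounding the χ² test is therefore
anti-conservative (we measure ~7–8% rejections at nominal 5% with R²_xy ≈
0.17). The calibration suite runs the null at near-zero R²_xy, where the test
is exact, and separately documents the inflated regime. Weak instruments
(R²_zx → 0) inflate the dispersion of b̂_xy as 1/R²_zx, also covered by tests.

## Synthetic data generator

The generator defines the study conditions for all property tests; its
defaults are fixed once:

- **Panel**: 200 inbred accessions from 3 Balding–Nichols subpopulations
  (ancestral p ~ U(0.05, 0.5); subpop p ~ Beta(p(1−F)/F, (1−p)(1−F)/F),
  F = 0.1), matching a tropical/temperate/mixed-origin panel structure.
- **Genome**: one chromosome, 12,000 SNPs at ~100 bp mean (exponential)
  spacing (~1.2 Mb span), 200 genes of 2 kb tiled along it. The density
  emulates the local SNP clusters of a dense integrated panel, which the
  ≥ 3-significant-SNP consolidation rule needs as substrate.
- **LD**: an allele-copying process — at each SNP a haplotype keeps its
  previous allele with probability exp(−d/1600 bp), else draws fresh at its
  subpopulation frequency — giving allele-scale correlation ≈ exp(−d/1600)
  and the ~1.6 kb r² < 0.2 decay of a diverse panel. A latent-Gaussian
  AR(1) alternative was rejected because thresholding attenuates allele-scale
  LD well below what any consolidation rule could use.
- **Effects**: 40 genes carry a local causal SNP within ±20 kb (inside the
  body when possible) with variance fraction r² ~ U(0.05, 0.4); the
  non-genetic component is orthogonalized against the causal dosage so the
  configured r² holds exactly in-sample. 8 TF genes each regulate one target
  ≥ 100 kb away through their own expression (distant effects are mediated by
  TF expression, not raw TF genotype, so the causal chain is recoverable);
  regulator TFs get strong static local effects (top of the range) and their
  targets' mediated strength is drawn from (0.25, 0.45) — the SNP-level
  signal at a target is the *product* of two variance fractions, and the
  distant links model the detected hotspot class. 27% of effects are static
  (active in all three conditions); the rest activate in a random one- or
  two-condition subset.
- **Nuisance**: 14 hidden factors per condition, i.i.d. N(0, 1) scores with
  80%-sparse N(0, 0.5²) gene loadings; log-normal noise (σ = 1 on the log
  scale); 2% missing genotypes; 1% heterozygous calls.
- **Phenotype**: y = Σ c_g·x_g(WS2, transformed) + N(0, 0.25), affinely
  mapped to [0, 1] (a survival-rate scale); 5 causal genes drawn among genes
  whose local eQTL is active under WS2 (otherwise the exposure carries no
  genetic signal and the MR design is unidentifiable); |c_g| ~ U(0.3, 0.6)
  with random signs. Ledger effects are recorded on the released [0, 1]
  scale.

Everything is deterministic given the seed; every nonzero effect appears
exactly once in the truth ledger.

**What passing tests do and do not show.** The generator reproduces the
*structure* of the target data — population stratification, kb-scale LD,
condition-activated cis and TF-mediated trans effects, hidden confounding,
a mediated phenotype — but not its scale (200 genes vs ~30,000; one
chromosome; 12k SNPs vs 1.29M), nor count-level noise in expression,
batch structure beyond the factor model, multi-signal loci, or realistic
recombination. Recovery rates measured here therefore validate the
*correctness of the machinery* (calibration, rule application, causal-chain
recoverability), not genome-scale power or FDR of a real panel.

## Problem sizes and numerical choices

Default test/acceptance problem sizes (200 samples × 12k SNPs × 200 genes ×
3 conditions; 5k SNPs × 50 traits for the calibration null; 1,000 random
instances for the consolidation oracle; 10,000 replicates for MR type-I) were
chosen so each suite completes in minutes on one CPU while leaving the power
regimes of interest (effect r² ≥ 0.2 at n = 200) clearly resolvable.
Numerical details: REML grid [−5, 5] in log₁₀δ with 101 points plus bounded
refinement; eigenvalues clipped at 0 with a 1e-6 ridge for non-PSD kinship;
BH cutoff comparisons use ≤ on the exact step-up bound; the KS uniformity
check uses the window-thinned SNP subset because LD correlates neighboring
tests and would invalidate the KS null; equal-width tier edges carry a 1e-9
epsilon so exact band boundaries land in the upper tier despite float
rounding; percentage rounding is decimal half-up, not banker's.

## Limitations

- Single-instrument MR only; no IVW/Egger, no pleiotropy diagnostics, and the
  variance formula's anti-conservativeness under strong confounding (above).
- One significant signal per locus is assumed by consolidation; overlapping
  independent signals in strong LD merge into one eQTL (no conditional
  analysis or fine-mapping).
- The DEG caller is a decision-rule substitute, not a count-model test; its
  FDR control is demonstrated empirically on the generator's data only.
- Hidden-factor correction by residual PCs can absorb genuine broad *trans*
  signals if the gene panel is very small relative to k; at the default
  200-gene scale the planted factor structure dominates.
- D′ uses an inbred shortcut (homozygote rows as gametes, hets excluded
  pairwise) and is not an EM haplotype-frequency estimate.
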