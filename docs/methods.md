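# Methods

This note records the models, parameter choices and numerical decisions
behind `depotgene`, and what the synthetic-data generators do and do
not emulate.

## Local adiposity traits

The three "adj" traits are ordinary least-squares residuals of a depot
volume on {1, age, age², BMI, height}, fitted separately per sex; rows
with any missing covariate are dropped from that sex's fit rather than
imputed.  Depot ratios are elementwise quotients of the raw volumes
with no residualization.  All nine traits are rank-based
inverse-normal transformed before association testing, using
Φ⁻¹((rank − c)/(n − 2c + 1)) with offset c = 0.5 and average ranks for
ties — the transform commonly used in biobank-scale GWAS.  A design is
rejected as degenerate when any per-sex design matrix is rank
deficient (for example, constant BMI within a sex).

The collider diagnostic asks, for each lead SNP of an adjusted trait,
whether the unadjusted depot effect is strictly larger in magnitude
than the BMI effect on the same effect allele.  Ties are classified
discordant: "stronger" is read as a strict inequality.

## Association core

The association engine is covariate-adjusted least squares.  The study
this emulates used a linear mixed model to absorb relatedness and
structure; with unrelated synthetic individuals the fixed-effect model
is the statistically equivalent desk-scale engine, and it is
implemented via Frisch-Waugh-Lovell projection so a scan is two matrix
products per chunk.  Missing dosages are mean-imputed per variant;
variants monomorphic after imputation are skipped and logged; fits
with residual variance ≤ 1e−12 of the trait scale are flagged
degenerate.  P-values come from the two-sided t distribution with
n − p − 2 degrees of freedom.

Hard-call Hardy-Weinberg testing uses the exact conditional test
(summing, over heterozygote counts of matching parity, the
probabilities no larger than the observed configuration).  It is
computed from log-factorials with renormalisation so the far tail is
meaningful against the 1e−15 exclusion threshold; a chi-square
approximation would not be trustworthy there.

LD clumping follows the greedy PLINK semantics exactly: take the
lowest-p unassigned variant with p < p1 as a lead; assign every
unassigned variant with p < p2, within the window and with r² above
the threshold, to it; repeat.  Ties in p are broken by (CHR, BP)
ascending so output is deterministic.  Missing LD entries are treated
as r² = 0 with a one-time warning, since a complete empirical panel
cannot be assumed.  Novelty is strict: a lead is novel only when its
maximum r² with every catalog SNP is < 0.1; exactly 0.1 is "known";
leads absent from the LD lookup are "indeterminate", never novel.

λ_GC is the median of the 1-df chi-square quantiles of the p-values
divided by 0.4549 (the null median).  Bonferroni thresholds are
sequential divisions of α, reported unrounded together with a
2-significant-figure display value.  Replication concordance uses the
two-sided exact binomial p against 0.5, min(1, 2·P(X ≥ max(k, n−k)));
pairs with a zero effect in either source are excluded.

## Sex heterogeneity

The dimorphism statistic is
t = (β_m − β_f) / √(se_m² + se_f² − 2 r se_m se_f), where r is the
Spearman rank correlation between male and female effect sizes over
all shared, allele-aligned SNPs of the trait (not a pruned subset, and
not per locus).  The statistic is referred to the standard normal: at
biobank sample sizes the t/normal distinction is immaterial, and this
matches common practice in sex-stratified GWAS tooling.  Note a known,
mild conservatism: r is a Spearman coefficient plugged into a slot
that formally expects the Pearson correlation of the estimates; for
bivariate-normal noise Spearman underestimates Pearson slightly
((6/π)·asin(ρ/2) ≈ 0.96ρ), so the null rejection rate at α = 0.05
sits near 0.047 rather than exactly 0.050.  The package implements the
method as published rather than "correcting" it.

Locus classes follow the three-stratum rule: `combined` when genome-wide
significant in the sex-combined scan, `male_only` when significant in
males but in neither females nor combined (symmetrically
`female_only`), `other` otherwise.

## bNMF clustering

The clustering input is built from lead SNPs and a panel of trait
summary statistics: keep leads nominally associated (p < 0.05) with
the primary trait; LD-prune at r² = 0.1 keeping the lower primary p;
form z = β/se per trait and rescale by √(median N / N_trait); flip
each variant's sign vector so its primary-trait effect is positive;
drop traits with no |z| above the Bonferroni normal quantile for
0.05/n_variants; among trait pairs with |Pearson corr| > 0.85 on the
signed columns keep the trait with the lower minimum p; split each
signed column into non-negative (pos, neg) halves.  The primary trait
defines selection and orientation but is not itself a clustering
column, mirroring how a dedicated cardiometabolic panel is used.
Variants with a primary effect of exactly zero are dropped (their
orientation is undefined); missing variant-trait entries are an error —
panels must be complete.

The factorization minimises

F = ½‖Xᵀ − WH‖²_F + Σ_k (½‖w_k‖² + ½‖h_k‖² + b)/λ_k + C Σ_k log λ_k,

with C = (2M + N)/2 + a + 1 — the negative log posterior under
half-normal priors on W (2M × K) and H (K × N) whose per-component
scales λ_k carry inverse-gamma(a, b) hyperpriors.  Defaults: K₀ = 20
initial components, shape a = 10, and scale b matched to the data,
b = √(mean X²)·(a − 1)/K₀, so the prior mean relevance sits near a
per-component share of the data energy.  Updates alternate monotone
multiplicative (majorise-minimise) steps in W and H with the
closed-form λ update; components whose share of the total energy
√(‖w_k‖²‖h_k‖²) falls below 1e−8 are pruned, which is how ARD selects
K.  Convergence requires the active component count to be stable and
the relative objective change to be below 1e−7 across a 100-iteration
window (objective checked every 10 iterations); a single-step check is
not used because slowly dying components masquerade as plateaus.  The
iteration cap is 10,000.

The procedure is restarted (default 100 times, child seed = master
seed + restart index, bit-reproducible), the modal K across restarts
is reported with its frequency, and the reported solution is the
lowest-objective restart at the modal K.  Because the ARD penalty
biases the retained factors toward zero, the selected solution is
polished with unpenalized multiplicative updates before reporting;
this removes the shrinkage bias (and makes exactly factorizable input
reconstruct to machine precision) without touching model selection.
Objective values are comparable within stretches of constant K;
pruning removes a component's penalty terms and re-bases the trace.

## Rare-variant burden

Per-call filter (a call is set missing): DP ≤ 10 or DP ≥ 200; hom-ref
with GQ ≤ 20 or alt-allele balance > 0.1; het with balance < 0.2 or
PL(ref) < 20; hom-alt with balance < 0.9 or PL(ref) < 20; any missing
quality field.  Variant filter: exclusion-region overlap, exact HWE
p < 1e−15, call rate < 90%, or monomorphic after call filtering.

Masks are pLoF (high-confidence predicted loss of function, weight 1)
and pLoF+missense, where damaging-missense variants in gene G carry
w = min(1, √(f_L(1−f_L)/(f_M(1−f_M)))) with f_L, f_M the cumulative
allele frequencies of the gene's qualifying pLoF and missense
variants; w = 1 when the gene has no high-confidence pLoF variants.
Rarity (MAF < 0.1%) and the cumulative frequencies are computed in the
analysis cohort after call-level QC; variants monomorphic in the
cohort are excluded from the mask (they carry no carriers and would be
removed by variant QC).  An individual's gene score is the weighted
dosage sum over qualifying variants (het = 1, hom-alt = 2), capped at
one; missing calls contribute zero but the sample is retained, since
excluding such samples would bias carrier counts.  The burden test is
least-squares regression of the INT phenotype on the score plus
covariates, restricted to genes with ≥ 10 carriers before multiplicity
accounting; exome-wide and study-wide thresholds are attached to the
result table.

## Polygenic-score evaluation

Scores are weighted dosage sums with allele alignment (dosage flipped
to 2 − d when the weight's effect allele is the genotype's other
allele; unresolvable pairs skipped and counted).  Scores are
residualized on genetic PCs before any percentile operation; note that
swapping a weight row's alleles while negating its weight changes each
individual's score by the same constant (−2w), so all percentile- and
tail-based results are unchanged.  Tail enrichment builds the 2×2
table of phenotype-tail × score-tail membership with strictly-beyond
empirical (type-7) quantile tails, reports OR = ad/bc with the Woolf
log-normal 95% CI, and applies the Haldane 0.5 correction to zero
cells.  The 2×2 is deliberately unadjusted; covariate-adjusted
alternatives live in the extreme-percentile regressions, which fit
linear (continuous outcomes) or logistic (binary outcomes) models of
each outcome on top-5% and bottom-5% score indicators plus covariates.

## Synthetic data: what it does and does not emulate

The cohort generator draws depot volumes and BMI as lognormals (right
skew, strict positivity) whose latent normal scores share a common
adiposity factor; means and SDs are matched exactly by moment
inversion.  Defaults are the study conditions: male/female mean VAT
5.0/2.6 L, ASAT 5.9/7.9 L, GFAT 9.3/11.3 L; SDs (2.5/1.5, 2.2/2.8,
2.1/2.6 L) are plausible for an imaged adult cohort.  The
shared-factor loadings are documented tuning constants — variance
fractions 0.99 (VAT), 0.93 (ASAT, GFAT) and 0.97 (BMI) — chosen once
so the pooled depot-BMI Pearson correlations land inside the observed
0.77–0.88 band; VAT needs the higher loading because its large
between-sex mean gap dilutes the pooled correlation.  Genotypes are
independent Binomial(2, MAF) draws and planted effects act on centered
dosage, so there is no LD, no assortment and no population structure;
block-LD panels for clumping are generated separately with
exchangeable within-block r² and zero across blocks.  Passing tests
therefore demonstrate correctness of the statistical machinery under
the stated moments and correlation structure — not robustness to real
LD, relatedness, ancestry stratification or phenotype artefacts.

The cluster generator plants z = A·B + ε with disjoint non-negative
cluster loadings (per-variant loading U(4, 8), per-cluster trait
weights U(0.5, 1.5), noise SD 1), emitting (β, se) with se = 1/√N.
The rare-variant generator splits each gene's mask frequency over six
variants with a mildly concentrated Dirichlet(3) so per-variant
frequencies stay under the rarity cap, and flags genes testable when
they realize ≥ 10 carriers.  All generators draw from a single seeded
NumPy generator per invocation and record spec and seed in their
metadata; regeneration is exact.

## Measurement choices in the acceptance script

Quantities that are single stochastic draws at the stated problem
sizes are reported as replicate averages so they measure the regime
rather than one draw's noise, with the per-run conditions unchanged:
the sex-heterogeneity type-I rate is averaged over ten 20,000-SNP null
panels (r re-estimated per panel); the 24-carrier burden effect
estimate is averaged over 15 replicate cohorts of n = 10,000; the
polygenic-score tail odds ratio pools 2×2 counts over 2,000 replicate
evaluation cohorts of n = 8,000 (the bivariate-normal population value
at r = √0.07 is ≈ 3.07).  The null-inflation check scans 100,000
independent SNPs in 500 individuals — λ_GC's median-based noise scales
with the SNP count, not the sample count.  The burden estimator
averages slightly above the planted 0.98 (≈ 1.0–1.1) because mask
weights are re-estimated from realized cohort frequencies; the
recovery criterion is framed in estimator SEs and is insensitive to
this.

## Known limitations

* No mixed-model engine: results on structured or related samples are
  out of scope by design.
* No real-LD simulation; clumping is validated against a brute-force
  reference on block-exchangeable LD only.
* Allele handling is exact-match; strand-ambiguous resolution is not
  attempted and mismatches raise.
* The ARD hyperprior constant C depends on (a, b) choices the
  underlying model family does not pin down; both are exposed and
  documented, and K selection is robust to them in the tested regimes.
* Burden sample-level QC (relatedness, sex concordance, heterozygosity
  outliers) is consumed as a precomputed inclusion list, not
  recomputed.
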