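# Methods

## The structural model and what it assumes

`ivgrn` treats the transcriptome as a linear simultaneous-equation system
`Y = YΓ + XΨ + ε`. The key assumptions are (i) linearity of regulatory and
cis-genetic effects; (ii) disturbances independent of genotype (the
randomization of alleles at meiosis is what makes cis variants valid
instruments); (iii) `(I − Γ)` invertible, so a unique reduced form exists
even with feedback loops; and (iv) sparsity — each gene has few regulators
and few cis drivers. Nothing requires acyclicity: reciprocal pairs and
longer loops are representable, and identification per gene rests on the
rank condition supplied by that gene's instruments rather than on a
topological ordering.

Estimation is *limited-information*: each gene's equation
`Y_k = Y₋ₖ γ_k + X ψ_k + ε_k` is fit separately, which is what makes the
problem embarrassingly parallel and lets the bootstrap wrap the whole fit.

## Stage 1 — prediction of every gene from the instrument pool

The genome-wide pool contains every selected instrument column of every
gene. For each target of prediction:

- **Screening**: iterative sure independence screening. Columns are ranked
  by absolute correlation with the current residual; a batch (default one
  third of the target size) is admitted, a ridge refit recomputes the
  residual, and the sweep repeats. The iteration matters: a predictor whose
  marginal correlation is masked by another one is invisible to one-pass
  screening but enters once the first predictor is partialled out. The
  retained-set size defaults to `⌊n / log n⌋`, a standard sure-screening
  scale.
- **Ridge + GCV**: the penalty is chosen on a 50-point log grid spanning
  `[1e−4, 1e4] ×` the mean squared singular value of the centered design
  (scale-free coverage), minimizing `GCV(λ) = n·RSS/(n − tr S_λ)²`; the
  smoother trace counts one extra degree of freedom for the intercept,
  which is handled by centering and left unpenalized. Ties resolve to the
  smaller λ, and λ = 0 (pseudo-inverse least squares) is honored when a
  grid contains it.

## Stage 2 — regulator selection on projected data

Gene `k`'s own instrument block `X_Sₖ` is projected out of both sides with
the residual-maker `H_k`. Two implementation details:

- `H_k` is held as an orthonormal basis (pivoted QR, collinear columns
  pruned at 1e−10) and applied as `v − Q(Qᵀv)`; a dense n×n matrix is
  never formed. A gene with no instruments gets the identity.
- The instrument block is **centered before building `H_k`**. Every
  regression in the package carries an unpenalized intercept via
  mean-centering, so the operator must annihilate `span(1, X_Sₖ)` jointly;
  with raw columns the two projections do not commute and the estimator
  would differ from classical two-stage least squares by O(1e−2) even in
  the identified single-regulator limit. With centering the package
  reproduces the textbook 2SLS slope to machine precision (the test suite
  checks 1e−6).

Regulators are selected by adaptive LASSO on `H_k Y_k ~ H_k Ŷ₋ₖ`,
restricted to candidate genes that own at least one instrument (a gene
without instruments has no identifiable predicted component, though it can
still appear as a target). Columns are standardized internally and
coefficients returned on the original scale. Weights are `1/|β̂_init|`
with the initial estimate from ridge-GCV on the same standardized design —
ridge rather than least squares because the candidate count can exceed `n`;
entries below 1e−10 are excluded outright.

**Penalty level.** The λ path is cross-validated (10 folds, fold
assignment fixed by the per-gene seed). The package uses the **1-SE rule**
— the largest λ whose CV error is within one standard error of the
minimum — rather than the plain CV minimum. This is a deliberate choice:
the CV minimum optimizes prediction, and on the package's own benchmark it
admits dozens of near-zero spurious coefficients (edge precision ≈ 0.25
at n = 500); the 1-SE rule restores selection-grade sparsity (precision
≈ 1.0) at a small recall cost. `lasso_rule="min"` and fixed-λ (including
the λ = 0 least-squares limit used by the equivalence tests) remain
available in `FitConfig`.

## Instrument discovery

Cis windows are gene body ± 1000 bp (1-based inclusive coordinates,
clamped at position 1). MAF strata: common ≥ 0.05 > low ≥ 0.01 > rare.
Common variants get a marginal slope t-test; low and rare variants are
pooled (one burden candidate per gene by default) into the adaptive-sum
test: variants with nominally negative marginal effects (p < 0.1) have
their centered coding flipped before summation, and significance is
assessed by phenotype permutation with add-one smoothing
`(r+1)/(n_perm+1)`, ties counted as ≥ observed, because the flip makes the
statistic data-adaptive. Defaults: 1000 permutations, flip threshold 0.1.

Selection keeps candidates with p < 0.05 (no within-gene multiplicity
correction by default — a single prespecified level; a Bonferroni switch
exists), sorts by p with position-then-name tie-breaks for determinism,
and greedily admits candidates whose absolute correlation with everything
already admitted is < 0.3, stopping at three.

The IV scan uses the expression version additionally adjusted for the top
genotype principal components (default 3) to guard against population
stratification; the network stages use the version adjusted for measured
covariates only, since genotype PCs would absorb genuine trans-regulatory
signal.

## Bootstrap confidence and the reported network

Each replicate resamples the `n` samples with replacement (expression and
genotype rows jointly) and re-runs IV discovery plus both stages; freezing
the IV map (`reselect_ivs=False`) is available for speed. The edge score
is the mean adjacency indicator across replicates. Replicate seeds come
from a counter-based scheme on (master seed, replicate id), so results are
independent of execution order and worker count, and completed replicates
cache to disk for resume-safe reruns. Zero-frequency pairs are never
materialized. Default report cutoffs are 1.0 (edges in every replicate)
and 0.95.

Resampling happens on the covariate-adjusted data: adjustment is a
per-gene OLS with a fixed design, so re-estimating it inside the loop
would add cost without changing the residuals' leading behavior.

## Network analysis

Degrees are total (in + out; a reciprocal pair contributes 2). Modularity
is evaluated on symmetrized weights `w_ij = E_ij + E_ji` with the
`1/(2N)` normalization, `N` the number of directed regulations, including
the `i = j` null-model terms (`E_ii = 0` structurally, so self-pairs
contribute only `−d_i²/(2N)²`). This convention makes the statistic
exactly standard Newman modularity on the symmetrized graph: the
all-in-one partition scores identically zero, and the two-triangle fixture
scores 0.5; dropping the self-pair null terms would break both identities.
Community detection is fast-greedy agglomeration (merge the connected pair
with the largest gain, ties to the lowest community-id pair, return the
best partition encountered). "Subnetworks" in reports are weakly-connected
components, sorted largest first.

## Preprocessing

- Expression filter (count+TPM inputs): keep genes with TPM > 0.1 in
  ≥ 20% of samples **and** ≥ 6 reads in ≥ 20% of samples. Count-only
  inputs: drop genes with total < 2.5 × 10⁶ or zero in > 80% of samples
  (zeros are treated as missing for this rule, since count matrices
  back-transformed from log archives encode absence as zero).
- TMM normalization is implemented from its published definition:
  upper-quartile-nearest reference, 30%/5% two-sided trims on M/A values,
  inverse asymptotic-variance weights, factors renormalized to geometric
  mean 1; output is log2 of counts rescaled to the mean effective library
  size with a +0.5 offset. Factors agree with the edgeR reference
  implementation to well under 1% on composition-biased fixtures.
- The variance-stabilizing transform is a deliberately simple substitute:
  median-of-ratios size factors (geometric-mean reference over genes with
  all-positive counts) followed by `log2(x/s + 1)`. The downstream model
  needs variance-stabilized log-scale expression, not DESeq2's exact
  mean-dispersion curve; fitting that curve is out of scope.
- Genotype QC order: samples with > 10% missing calls, then variants with
  > 10% missingness, then Hardy-Weinberg exact test at p < 1e−4, then
  minor-allele count < 5 — the order a PLINK-style workflow applies.
  The HWE test is the exact conditional test (heterozygote counts given
  allele counts), summing probabilities ≤ the observed table's. Remaining
  missing dosages are imputed to the homozygous major genotype; at an
  exact 50/50 allele split the reference homozygote (0) is used.
- Confounder removal is per-gene OLS residualization on an intercept plus
  one-hot covariates (first level dropped; collinear columns pruned by
  pivoted QR with a logged warning). Genotype PCA standardizes columns,
  fixes component signs by the largest-magnitude loading, and refuses
  k > rank.

## The synthetic-data generator

The generator is the package's study-condition definition, not a
convenience. Defaults: 30 genes, 25 directed edges including two
reciprocal pairs, effect magnitudes uniform on [0.4, 0.8] with random
sign; three cis variants per gene with effects on [0.7, 1.2]; MAFs uniform
on [0.1, 0.45]; n = 500; unit Gaussian noise. `Γ` is rescaled (support
preserved) to spectral radius < 0.8 whenever sampling exceeds the bound.
Genes occupy disjoint, well-separated intervals so each variant is cis to
exactly one gene. Options: missing-genotype injection (for QC tests), a
shared-confounder/covariate component folded into the disturbance (so the
structural identity still holds exactly for the stored draw), and a
negative-binomial count rendering (gamma-Poisson with mean proportional to
per-sample abundance share times library size) for normalization tests.

What it does **not** emulate: linkage disequilibrium between variants,
haplotype phase, admixture, batch structure beyond linear covariates, or
nonlinear regulation. Passing tests therefore demonstrate correctness of
the estimator under its own assumptions — independent instruments with
strong planted effects — not performance on real cohorts, where LD-linked
instruments, weak effects and unmodeled confounding will lower both
precision and recall.

## Problem sizes used by the test suite and acceptance script

Benchmark recovery uses 10 simulated networks at the default conditions;
directionality uses 50 two-gene systems at n = 2000; the bootstrap
calibration uses B = 50 on one benchmark dataset; the burden-test
calibration uses 1000 null datasets at 200 permutations; pipeline
determinism runs a 12-gene, B = 6 configuration three times (rerun and
4-worker). These sizes were chosen so each property is measured with
comfortable Monte-Carlo margins while a complete run stays in the
minutes range on a single CPU.

## Known limitations

- Linear effects only; no interaction or saturation terms.
- No analytic standard errors for `γ̂` — confidence is bootstrap edge
  frequency by design.
- Instrument validity is assumed, not tested: a cis variant with a
  pleiotropic path to a target that bypasses its host gene violates the
  exclusion restriction and will bias that edge.
- The bootstrap refits the entire pipeline per replicate; at
  transcriptome scale this is cluster-sized work (the batch planner and
  array-job exporter exist for that reason), and the local executor is
  intended for method-scale problems.
- The 0.3 decorrelation rule uses absolute correlation; with dense local
  LD it can leave a gene fewer than three effective instruments.
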