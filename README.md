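# ivgrn

Transcriptome-wide **causal** gene-regulatory-network inference from paired
expression and genotype data, using each gene's cis genetic variants as
instrumental variables.

Co-expression networks report association; they cannot tell an activator
from a bystander, or distinguish regulation from confounding and reverse
causation. `ivgrn` is aimed at analysts with population-scale RNA-seq plus
genotypes (eQTL-style cohorts) who want directed, possibly cyclic,
regulatory structure with a confidence score on every edge.

## Model

For `n` samples, `p` genes and `q` variants, expression `Y` (n×p) and
dosages `X` (n×q) are modeled by the linear structural system

```
Y = Y Γ + X Ψ + ε
```

where `Γ` (p×p, zero diagonal) holds directed gene→gene effects, `Ψ` (q×p)
holds sparse cis effects, and the disturbance `ε` is independent of `X`.
Cycles and reciprocal regulation are allowed: the system only needs
`(I − Γ)` invertible, so the observed data follow the reduced form
`Y = (XΨ + ε)(I − Γ)⁻¹`.

Estimation is gene-by-gene **two-stage penalized least squares (2SPLS)**:

1. **Instruments.** For each gene, variants in the gene body ±1 kb are
   stratified by MAF (common ≥ 0.05, low ≥ 0.01, rare < 0.01). Common
   variants are tested marginally; low/rare variants are pooled into a
   data-adaptive burden score (aSum, permutation p-value). Up to three
   significant, mutually decorrelated (|r| < 0.3) instruments are kept.
2. **Stage 1.** Each gene's expression is predicted from the genome-wide
   instrument pool — iterative sure independence screening, then ridge
   regression tuned by generalized cross-validation — giving `Ŷⱼ`.
3. **Stage 2.** For each target gene `k`, its own instrument block `X_Sₖ`
   is removed with the residual-maker `H_k = I − X_Sₖ(X_SₖᵀX_Sₖ)⁻¹X_Sₖᵀ`,
   and the regulators are selected by adaptive LASSO in
   `H_k Y_k ~ H_k Ŷ₋ₖ`. Nonzero coefficients are directed edges.
4. **Confidence.** The whole fit is repeated on bootstrap resamples; the
   edge score `Ā_ij` is the fraction of replicates in which the edge
   appears. Thresholding `Ā` gives the reported network, which is broken
   into weakly-connected subnetworks and modularity communities
   (fast-greedy).

A synthetic-data module generates ground-truth systems (genotypes at chosen
MAFs, planted cis effects, sparse cyclic `Γ`, Gaussian noise, optional
negative-binomial counts), so the whole pipeline is testable end to end
without controlled-access data.

## Worked example

```python
from ivgrn import (FitConfig, IvConfig, discover_ivs, fit_network,
                   simulate_dataset)

ds = simulate_dataset(seed=1)          # 30 genes, 25 true edges, n=500
ivmap = discover_ivs(ds.expression, ds.genotypes, ds.gene_annotation,
                     ds.variant_annotation, IvConfig(seed=1))
C = fit_network(ds.expression, ivmap, FitConfig(seed=1))

est, true = C.edge_set(), ds.truth.edge_set()
tp = len(est & true)
print(f"genes with IVs : {len(ivmap.genes_with_ivs())}")
print(f"edges found    : {len(est)} (true: {len(true)})")
print(f"precision      : {tp / len(est):.2f}")
print(f"recall         : {tp / len(true):.2f}")
```

Output:

```
genes with IVs : 30
edges found    : 24 (true: 25)
precision      : 1.00
recall         : 0.96
```

All 30 genes received at least one cis instrument; the fitted coefficient
matrix contains 24 directed edges, all of which are planted regulations
(precision 1.00), recovering 24 of the 25 true edges (recall 0.96) — one
weak effect is missed at this sample size.

The same pipeline is scriptable from the shell:

```bash
ivgrn simulate --out demo --genes 30 --samples 500 --edges 25 --seed 1
ivgrn run-all --input-dir demo --output-dir results --seed 1 --bootstrap-b 25
```

which writes the IV table, bootstrap edge frequencies, thresholded networks
(edge-list TSV / GraphML with community and degree attributes) and a run
manifest with config hashes.

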