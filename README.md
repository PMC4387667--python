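# groupeqtl

Group-wise and individual eQTL mapping with a sparse two-layer
linear-Gaussian model.

## The problem

Expression quantitative trait locus (eQTL) studies regress thousands of
gene-expression traits **z** on thousands of genotyped variants **x**.
Three features of real data defeat plain per-gene regression:

* variants act jointly on *sets* of genes (pathways, regulatory modules),
* some variants also have direct, individual effects on single genes
  (typically *cis*), and
* non-genetic confounders (batch, environment) add correlated variation
  across all genes.

`groupeqtl` models all three at once. Genotypes feed M group latent
variables y = A x + ε₁, and expression is generated as
z = B y + C x + W s + μ_B + ε₂ with s ~ N(0, I_H) confounder latents.
Marginalising the latents gives

    z | x ~ N((B A + C) x + μ_B,  Σ),    Σ = σ₁² B Bᵀ + W Wᵀ + σ₂² I_N.

The product **B A** carries group-wise (SNP-set → gene-set) associations,
**C** carries individual SNP → gene effects, and **W** absorbs confounding.
Laplace priors on A, B, C give the L1-penalized negative log-likelihood

    J + D · (λ‖A‖₁ + γ‖B‖₁ + α‖C‖₁),

minimized by alternating an Orthant-Wise Limited-memory Quasi-Newton
(OWL-QN) pass over [A, B, C, W, log σ₁²] with an exact 1-D update of σ₂².
Because Σ is diagonal-plus-low-rank, its inverse and log-determinant come
from M×M and H×H solves (Woodbury identity + matrix determinant lemma), so
likelihood and gradient evaluations cost O(M³+H³) extra instead of O(N³).

The package also ships the surrounding toolkit: a synthetic-data generator
(block-structured β, low-rank confounders, binomial genotypes), ROC/PR
scoring against a known support, per-SNP regulatory degrees and hotspot
consistency, the two-step cis-enrichment test (per-SNP one-tailed
Mann-Whitney, then a paired two-tailed Wilcoxon across SNPs), a permutation
FDR curve, penalty grid search and (M, H) hold-out selection, TSV I/O and a
thin CLI.

## Worked example

`examples/simulate_and_fit.py` simulates 30 SNPs × 30 genes × 200 samples
with two 5×5 group blocks, ten individual cis links and ten hidden
confounders, then fits the full model:

```
simulated 30 SNPs x 30 genes x 200 samples, realized SNR 1.64
fit converged=True after 3 outer iterations, penalized objective 4046.6
ROC-AUC 1.000, PR-AUC 0.999 against the true support
mean fitted weight on true links 0.967 (simulated strength 1.0)
```

The AUCs say that |B A + C| ranks essentially every true SNP-gene link
above every null pair despite the confounders; the mean fitted weight on
the true support (0.967) recovers the simulated association strength (1.0).
The other example scripts show the shrinkage behaviour of B A versus C on a
seven-predictor toy and the hotspot/enrichment statistics.

The same pipeline is available from the shell:

```bash
groupeqtl simulate --out sim --snps 30 --genes 30 --samples 200 --seed 7
groupeqtl fit --genotype sim/genotype.tsv --expression sim/expression.tsv \
              --out fit --m 2 --h 10 --lam 0.05 --gamma 0.05 --alpha 0.05
groupeqtl evaluate --associations fit/associations.tsv --truth sim/truth.tsv
```

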