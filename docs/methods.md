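# Methods

## Model

`groupeqtl` fits a two-layer linear-Gaussian network to paired genotype
(X, K SNPs × D samples, dosages in {0,1,2}) and expression
(Z, N genes × D samples) matrices. M group latent variables y bridge SNP
sets and gene sets, H latent variables s model non-genetic confounding:

    y | x ~ N(A x, σ₁² I_M),
    z | y, x ~ N(B y + C x + W s + μ_B, σ₂² I_N),   s ~ N(0, I_H).

Marginally z | x ~ N((B A + C) x + μ_B, Σ) with
Σ = σ₁² B Bᵀ + W Wᵀ + σ₂² I_N. Laplace(0, 1/λ), (0, 1/γ), (0, 1/α) priors
on the entries of A, B, C make the MAP objective

    J + D (λ‖A‖₁ + γ‖B‖₁ + α‖C‖₁),

where J is the Gaussian negative log-likelihood summed over samples. The
intercept μ_B has the closed form z̄ − (BA + C) x̄ and is profiled out, so
J is evaluated on column-centered data; μ_B is reported after fitting, not
optimized. The latent intercept μ_A is absorbed into μ_B and fixed at zero.
The "model1" variant fixes C ≡ 0 (group-wise associations only); "model2"
is the full model. W carries no penalty (confounder loadings are not
expected to be sparse), and neither do the variance coordinates.

Key assumptions: additive dosage effects, Gaussian noise, confounding that
is low-rank across genes and independent of genotype, and sparsity of the
association structure. A and B are only identified through their product
B A (a column/row rescaling leaves it unchanged), so all reported
associations are products, never factors.

## Fitting

The penalized objective is minimized by alternating

1. an OWL-QN pass over the stacked vector [A, B, C, W, log σ₁²] with
   per-coordinate L1 weights [D·λ, D·γ, D·α, 0, 0] (model1 omits C), and
2. the exact coordinate update of σ₂²,

until the relative objective change drops below 1e−6 (at most 100 outer
rounds; each OWL-QN pass runs at most 150 iterations with memory 10).
Both stages are individually monotone — OWL-QN by its projected
backtracking line search, the σ₂² step because the current value is kept
when already optimal — so the outer objective trace never increases.

σ₁² is optimized jointly inside the quasi-Newton vector on the log scale
(it enters Σ smoothly and the log-parameterization enforces positivity);
σ₂² gets its own exact step because, after the eigendecomposition of the
low-rank part, the loss is a cheap 1-D function of σ₂² alone. The at most
M + H nonzero eigenvalues of σ₁² B Bᵀ + W Wᵀ come from the Gram matrix of
[σ₁ B, W], never from an N×N decomposition; residual energy in the
zero-eigenvalue complement is handled as a single bulk term. The 1-D
minimization scans a 400-point log grid on [1e−8, 1e6] and polishes the
best bracket with bounded Brent refinement.

### OWL-QN

The optimizer implements the standard orthant-wise recipe: pseudo-gradient
with the right/left-derivative convention at zero (use the right derivative
if negative, the left if positive, else 0), an L-BFGS two-loop direction
built from smooth-gradient differences, projection of the direction onto
strict sign agreement with the steepest-descent direction, orthant-projected
backtracking line search with an Armijo condition on the penalized
objective. Penalized coordinates land exactly at zero; |value| > 1e−8 is
the reported nonzero threshold (guarding round-off only).

### Fast covariance algebra

Σ⁻¹ = T − T W S⁻¹ Wᵀ T with T = σ₂⁻² (I − σ₁² B (σ₂² I_M + σ₁² BᵀB)⁻¹ Bᵀ)
and S = I_H + Wᵀ T W. Only the M×M and H×H matrices are factorized
(Cholesky); Σ⁻¹ is applied to vectors through matrix products, and
log|Σ| = N log σ₂² + log|I_M + (σ₁²/σ₂²) BᵀB| + log|S| by the matrix
determinant lemma applied twice. One likelihood+gradient evaluation
therefore costs O(M³ + H³) plus O(N(M² + H²) + NKD) products instead of
O(N³). A dense reference path (explicit inverse and determinant) exists for
verification and timing only.

### Gradients

The gradients of the centered loss are derived by matrix calculus through
both the mean term (BA + C)(x_d − x̄) and the covariance term. With
P = Σ⁻¹, residual matrix R = Z_c − (BA + C) X_c, and
G_Σ = (D/2) P − ½ (P R)(P R)ᵀ:

    ∂J/∂(BA + C) = −(P R) X_cᵀ,
    ∂J/∂A = Bᵀ ∂J/∂(BA+C),   ∂J/∂B = ∂J/∂(BA+C) Aᵀ + 2 σ₁² G_Σ B,
    ∂J/∂W = 2 G_Σ W,   ∂J/∂σ₁² = tr(G_Σ B Bᵀ),   ∂J/∂σ₂² = tr(G_Σ).

Every block is validated against central finite differences (1e−5
relative) and against the dense-path reference.

## Numerical choices

* **Variance floor.** The likelihood is unbounded below once the
  coefficient degrees of freedom approach D·N: C can interpolate the data,
  σ₂² ratchets toward zero, and the alternation follows that ray while the
  association ranking fills with noise. The noise variance is therefore
  floored at max(1e−6, 1e−3 · pooled Var(Z)) — a minimal measurement-noise
  assumption stated relative to the data scale (an absolute floor would not
  be scale-invariant). σ₁² keeps the absolute 1e−6 floor only, since its
  scale is absorbed by B.
* **Initialization.** The bilinear pathway B A has a stationary point at
  the origin (each factor's gradient is proportional to the other), so a
  tiny random start can stay stuck under an L1 penalty. The default "warm"
  start factorizes a ridge-regression association estimate: its top-M SVD
  seeds (B, A), the top-H principal components of the ridge residual seed
  W, C starts at zero, σ₂² at the residual variance. A "random" start
  (Gaussians, sd 0.01) is kept for experiments where the solution path from
  the origin is itself the object of study (e.g. the shrinkage example),
  and for isolating the capacity difference between the two variants.
* **Stopping.** Outer tolerance 1e−6 relative, inner 1e−7; OWL-QN memory
  10. Degenerate inputs (all-zero residuals) return the variance floor.
* **Ranking ties.** Associations are ranked by |overall weight| with
  (snp_id, gene_id) lexicographic tie-breaks for determinism.

## Model selection

Penalties are tuned by two-fold cross-validated grid search scored by
out-of-sample unpenalized loss; the default grid is
{0.1, 1, 10, 50, 100, 500, 1000, 2000} applied jointly to (λ, γ, α).
Latent counts (M, H) are chosen by a 50/50 hold-out scan with an inner grid
search per combination; the full loss surface is reported. Fold splits are
contiguous blocks of a seeded permutation, recorded for reproducibility.
Out-of-sample loss uses the training-set μ_B and variances; when the
training fit sits at the variance floor the out-of-sample likelihood is
dominated by the misfit variance, which makes this criterion conservative
(it prefers stronger penalties and more confounder factors only when they
genuinely improve held-out fit).

## Synthetic data

The generator emulates a yeast-cross-scale design: K = 100 SNPs
(binomial(2, maf) dosages, maf ~ U(0.05, 0.5)), N = 100 genes, D = 112
samples. The true association matrix β holds four dense group blocks of
sizes 10, 15, 20, 25 along the diagonal plus individual cis links on the
diagonal, all at strength 1. Expression is Z = β X + Ξ + E with noise
E ~ N(0, η), η = 0.1, and confounding Ξ whose rows are N(0, ρ F Fᵀ) with
F (D × U) standard normal, ρ = 0.1, U = 10 hidden factors. The realized
signal-to-noise ratio SNR = sqrt(Var(βX)/Var(Ξ+E)) is reported per draw and
decreases monotonically in η. N and D are package choices (the block
layout needs ~70 genes; D mirrors a 112-segregant panel); the four block
sizes are likewise package defaults.

What the generator does **not** emulate: linkage disequilibrium between
SNPs (dosages are independent across loci), non-Gaussian noise, and
genotype-correlated confounding. Independent loci make per-gene lasso
substantially stronger than on real genotype panels, so benchmark margins
over the lasso baseline here are smaller than one should expect on data
with LD. Passing recovery tests demonstrates correctness of the estimator
under the model's own assumptions, not performance on real yeast data.

The seven-predictor shrinkage toy draws x_i ~ N(0, 0.6 I) (i = 1..7,
100 samples) and z = 5(x₁+x₂) − 3(x₃+x₄) + 2x₅ + ε, ε ~ N(0, I): two
predictor groups, one individual predictor, two nulls.

## Benchmark protocols

The acceptance checks fix these protocols (chosen as package defaults, not
tuned per draw):

* *Shrinkage recovery*: model2, M = 2, H = 0, all penalties at 1e−6 of the
  path maximum (max |Z_c X_cᵀ| / D), 20 seeded replicates; the fitted
  overall coefficients estimate the generating values.
* *Block recovery*: K = N = 30, D = 200, two 5×5 blocks + 10 diagonal
  links, model2 with M = 2, H = 10 at 1e−3 of the path maximum, 10
  replicates.
* *Variant ordering*: on the default simulation, model2 runs at its
  matched group count (M = 4) with penalties at 5% of the path maximum;
  model1, which must route individual signals through its low-rank
  product, runs at M = 60 with 10% penalties (the group-only variant needs
  several-fold more latent capacity and stronger shrinkage — on the real
  yeast panel the analogous choice was M = 150 for the group-only model
  versus 30 for the full one). The lasso baseline is per-gene at 5% of the
  path maximum.
* *Diagonal-rescue*: both variants at M = 20, H = 10, 5% penalties, from
  the **random** start, so the comparison isolates what the C matrix
  contributes rather than what the warm start hands to B A; recall of
  diagonal-only true links is compared at a matched 5% false-positive
  rate.

## Evaluation statistics

ROC-AUC and PR-AUC are computed on |overall weight| with a threshold sweep
over distinct scores (trapezoidal ROC, step-interpolated PR / average
precision). Regulatory degree counts genes with |weight| above threshold
per SNP; hotspot consistency between two analyses is |S₁ᵀ ∩ S₂ᵀ| / T for
the top-T SNPs by degree (lexicographic ties). Cis-enrichment follows the
two-step procedure: per SNP a one-tailed Mann-Whitney test that cis
hypotheses (same chromosome, |SNP pos − gene start| < 500 bp by default)
rank no better than trans, then a paired two-tailed Wilcoxon signed-rank
across SNPs on the p-value pairs; exact small-sample distributions are used
below 25 observations without ties, the normal approximation otherwise,
and all-zero difference vectors report p = 1. SNPs lacking a cis or trans
hypothesis are skipped and recorded. All K×N hypotheses enter the ranking,
not only nonzero ones.

The permutation FDR curve refits the model on expression matrices whose
sample columns are permuted and reports
FDR(t) = mean null count above t / observed count above t, clipped to
[0, 1], 0 where the observed count is zero, and made monotone by a running
minimum. This is generic permutation plumbing, not a calibrated eQTL FDR
procedure.

## Problem sizes

The shipped tests and the acceptance script run desk-scale problems:
N, K ≤ 100, D ≤ 200, with 200 random instances for the covariance-algebra
oracles, 20 for gradient checks, 50 for the σ₂² update, 10–20 seeded
replicates for the recovery experiments, and a single N = 1000 instance for
the timing comparison of the factorized versus dense likelihood path.

## Known limitations

* The MLE is ill-posed without the relative variance floor whenever C is
  flexible enough to interpolate (K + H + 1 ≥ D); conclusions at the floor
  depend on the floor's scale.
* A and B are not separately identified; only B A is meaningful.
* The alternation finds local optima; the warm start makes results
  reproducible but a global optimum is not guaranteed.
* Holdout-loss model selection degrades when every candidate sits at the
  variance floor (the criterion then mostly ranks penalty strength).
* No LD, dominance, epistasis, missing-genotype handling or non-Gaussian
  noise.
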