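# Methods

This note documents the models implemented in `upekit`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not demonstrate.

## Shape model and alignment

A cohort is a set of *registered* triangle meshes: identical vertex count M
and connectivity across subjects, coordinates in millimetres. Generalized
Procrustes alignment removes translation and rotation only — scaling is
deliberately retained because organ size is itself a phenotype (volume GWAS
would be impossible on size-normalized shapes). Rotations are constrained to
det(R) = +1 (no reflections). The iteration aligns every shape to the
running mean and stops when the mean changes by less than 1e-9 in Frobenius
norm (cap: 100 iterations, warning on non-convergence). Alignment is
invariant (to ~1e-8) under rigid pre-transformations of the input and leaves
every centroid at the origin.

Handcrafted indices: enclosed volume by the signed-tetrahedron sum (requires
a closed, consistently wound mesh; winding is auto-repaired by majority when
inconsistent) and the isoperimetric sphericity Ψ = π^(1/3)(6V)^(2/3)/A,
which is 1 for a sphere and scale-invariant. Ψ is a documented stand-in for
clinical sphericity definitions that normalize by a measured long-axis
length; outputs that depend on it are flagged accordingly.

## Shape PCA

SVD of the centred (N, 3M) data matrix; eigenvalues are squared singular
values divided by N−1 (sample covariance convention). Component signs are
fixed by making the largest-|loading| entry positive, so downstream GWAS
effect directions are reproducible across runs and platforms. Default
n_z = 16 components.

## Convolutional mesh autoencoder

Implemented in numpy with explicit forward/backward passes (verified against
finite differences); no GPU framework is used.

* **Filtering.** Chebyshev spectral convolutions of order K = 6 (polynomial
  degrees 0–5) with the standard recursion T_k = 2xT_{k-1} − T_{k-2},
  T_0 = 1, T_1 = x. Some presentations restate this recursion 1-based and
  without the factor 2; we use the standard form, and the filters are
  K−1-hop local by construction. Filtering uses the symmetric-normalized
  Laplacian rescaled to [−1, 1] (L̃ = 2L_sym/λ_max − I; λ_max by Lanczos with
  a deterministic start vector, power-iteration fallback), because Chebyshev
  polynomials are only well behaved on [−1, 1]; the combinatorial Laplacian
  is available behind `ComaConfig.laplacian_mode` for comparison
  experiments. An exact dense spectral-convolution implementation
  (`spectral_convolve_reference`) exists purely as a test oracle.
* **Pooling.** Quadric-error-metric *half-edge* collapses on a single
  template (the cohort mean shape): each collapse moves one endpoint onto
  the other, so surviving vertices keep their template coordinates exactly
  and the down-map is a binary selection matrix. The up-map reprojects each
  removed vertex onto its nearest triangle of the decimated template and
  stores the barycentric weights (exact indicator rows for survivors). Per
  level the target count is ceil(M_prev/factor); decimation below 4 vertices
  is an error.
* **Architecture.** Encoder: per level Chebyshev convolution + bias + ReLU,
  then pooling; channels (16, 16, 32) with ×4 downsampling over three levels
  by default (a 642-vertex mesh yields 642→161→41→11), then dense layers to
  μ and log σ². Decoder mirrors with barycentric unpooling; the final
  convolution outputs 3 channels with no nonlinearity. All of this is
  configurable.
* **Training.** Loss = reconstruction + w_KL · Ω. Reconstruction default L1
  on per-coordinate z-scored inputs (statistics from the train split; the
  inverse transform is applied before any RMSD so "1 mm" is physical).
  Ω is the batch mean of −(1/(2n_z)) Σ_j (log σ_j² − σ_j² − μ_j² + 1), i.e.
  the per-dimension average KL from N(0, I); reparameterized sampling
  z = μ + σε during training, μ(S) at inference. Adam (lr 1e-3 default),
  split 0.8/0.1/0.1 by a seeded permutation. Training is bit-deterministic
  given (seed_weights, seed_split). The w_KL grid {0, 1e-4, 1e-3, 1e-2}
  spans from plain autoencoder to strong posterior regularization; very
  large w_KL collapses the latent variance (tested).
* **Run selection.** A run enters the ensemble iff its mean test-set RMSD is
  strictly below 1 mm — a reconstruction-only criterion, independent of any
  GWAS outcome, which keeps null p-values uniform.

## GWAS

Dosages in [0, 2] (imputed data); missing doses are mean-imputed per variant
so N is constant across variants. QC keeps variants with MAF ≥ 0.01, exact
Hardy–Weinberg p ≥ 1e-5 computed on rounded hard calls (Levene–Haldane
conditional distribution, summing probabilities ≤ the observed
configuration), and imputation info ≥ 0.3. Phenotype adjustment: OLS
residuals on covariates + intercept, then the Blom rank-inverse-normal
transform Φ⁻¹((r − 3/8)/(N + 1/4)) with average ranks for ties. The
association model is simple regression of the INT score on dose; although
the scores are centred, an intercept is included (harmless, robust to
subject subsetting). β̂ is therefore the per-allele effect on the INT scale.
The scan is evaluated with closed-form simple-regression algebra, vectorized
over variants × phenotypes; a perfect fit floors p at the smallest positive
double rather than reporting 0, and a constant phenotype yields β̂ = 0,
p = 1.

## Ensemble aggregation

Pooled latents carry (run, index) provenance. Deduplication scans all column
pairs and drops one member (seeded coin, or deterministically the later
column in "drop-later" mode) whenever |Spearman ρ| > 0.95 — without this the
Bonferroni division would overcorrect. P_SW = P_GW/K uses the
post-deduplication K. Region assignment is a binary search over
non-overlapping half-open [start, end) intervals, applied to the position as
recorded in the GWAS table. Per region and run, p_{ℓ,r} is the minimum p
over the run's phenotypes and the region's variants (all runs share one
variant panel); C_ℓ counts runs with p_{ℓ,r} < P_GW. Classification:
significant iff P_best < P_SW; suggestive iff P_SW ≤ P_best < P_GW and
C_ℓ ≥ 5 (the count rule appears in the literature both as ≥ 5 and as > 5;
the default here is ≥ 5 and it is configurable). Lead-variant ties break by
position, then variant id. Nearest-gene annotation is strand-aware (TSS =
start on +, end on −) with distance 0 inside the gene body.

## Synthetic data generator

The generator defines the study conditions for all experiments.

* **Template.** A prolate spheroid (semi-axes 22/22/40 mm) flattened at
  z = 20 mm, built on a subdivided icosahedron (default M = 642), ~60 mm
  long axis — a closed, consistently wound LV-like surface with an analytic
  clipped-spheroid volume for oracle checks.
* **Deformation fields.** Four analytic fields: isotropic scale, long-axis
  stretch, apex taper and a depth-weighted basal tilt (the basal plane
  reorients while the apex stays put). Every field is projected orthogonal
  to the template's six infinitesimal rigid motions — otherwise Procrustes
  alignment would silently absorb part of the signal, as it must for any
  true rigid component — then Gram-Schmidt orthogonalized in a fixed order
  and normalized to unit per-vertex RMS (1 factor unit = 1 mm RMS
  displacement).
* **Factors and shapes.** factor = genetic part + covariate part +
  Gaussian residual, with the genetic part √h² · sd · standardized-dose per
  causal variant (h² is exact in-sample by construction; default 3% per
  variant, 6 causal variants across distinct regions) and a covariate
  (confounding) share on the size and stretch factors. Shapes = template +
  Σ factor·field + N(0, 0.5 mm) vertex noise. The 0.5 mm noise sets a
  reconstruction floor near 0.87 mm RMSD, which makes the 1 mm selection
  rule a real constraint rather than a formality.
* **Genotypes.** One LD block per ~2 Mb region; within a block, each
  haplotype copies the previous variant's allele with probability 0.8 or
  draws fresh. The allele frequency is drawn once per block (U(0.05, 0.5)),
  which keeps every variant's marginal frequency equal to its recorded p and
  preserves exact HWE under copying. Covariates (sex, age, height, weight,
  BMI) follow simple population-plausible distributions.
* **What it does not emulate.** Population structure and relatedness,
  realistic LD decay (block-copying gives a flat within-block r²),
  imputation uncertainty (info = 1 everywhere by default), non-Gaussian
  factor distributions, and cardiac biomechanics. Passing tests therefore
  demonstrate correctness of the pipeline's statistics under its stated
  model, not robustness to confounding beyond linear covariates.

## Evaluation experiments and problem sizes

`upekit.experiments` drives two standing experiments, used by the test suite
and `scripts/acceptance.py`:

* **Planted-locus recovery** — 20 cohorts of N = 2,000 subjects (162-vertex
  meshes keep the linear algebra light; statistical power depends on N and
  h², not on mesh resolution), 2,000 variants in 40 regions, 6 causal
  variants at h² = 3%. The phenotype ensemble is six shape-PCA runs fitted
  on random 60% subject subsets — genuinely different training samples, the
  cheap analogue of retraining a network with different seeds — encoded on
  the full cohort. Measured: fraction of causal regions classified
  significant/suggestive (expected ≥ 90%) and significant null regions
  (expected ≤ 1 across all 20 cohorts). Because linear runs are nearly
  collinear, deduplication collapses their duplicated components and the
  per-region counts C_ℓ stay small; the C_ℓ ≥ 5 suggestive rule is instead
  exercised on constructed summary statistics in the unit tests.
* **Autoencoder-ensemble smoke** — one cohort of N = 300 with M = 642
  meshes; three runs (seeds × w_KL ∈ {0, 1e-4, 1e-3}, 50 epochs, lr 2e-3)
  trained, selected by the 1 mm rule, encoded, pooled with a PCA baseline
  and pushed through GWAS + aggregation. These sizes keep a full run of the
  suite and the acceptance script within a few CPU-minutes; they are the
  package's default desk-scale conditions, not statements about attainable
  power at biobank scale.

## Known limitations

* The numpy autoencoder is single-threaded and CPU-bound; biobank-scale
  cohorts (meshes with thousands of vertices, tens of thousands of subjects,
  hundreds of epochs) would need a GPU framework, which the layer structure
  mirrors deliberately.
* Mixed-model association (relatedness), X-chromosome handling, conditional
  analysis and LD clumping from genotype data are out of scope; the fixed
  region partition replaces clumping.
* The exact-HWE p-value is discrete; calibration tests treat it as
  super-uniform rather than uniform.
* QEM decimation quality depends on template regularity; the coarsest levels
  of small meshes (≤ ~11 vertices) are connectivity-repaired if a survivor
  loses all faces.
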