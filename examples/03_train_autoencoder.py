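"""Train one variational convolutional mesh autoencoder run.

The encoder stacks Chebyshev spectral graph convolutions with quadric-error
mesh pooling; the bottleneck mean mu(S) is the subject's latent phenotype.
Reconstruction quality is measured as per-subject RMSD in millimetres; runs
with mean test RMSD below 1 mm are eligible for the phenotype ensemble.
"""

import numpy as np

from upekit import (
    SimConfig, simulate_cohort, generalized_procrustes, ComaConfig, train_coma,
)

cfg = SimConfig(n_subjects=200, n_variants=100, n_regions=10, seed=7)
cohort, *_ = simulate_cohort(cfg)
aligned, _ = generalized_procrustes(cohort)

config = ComaConfig(
    n_z=8, epochs=30, channels=(16, 16, 32), downsample_factors=(4, 4, 4),
    w_kl=1e-4, learning_rate=2e-3, seed_weights=1, seed_split=1,
)
model, run = train_coma(aligned, config)

print(f"run {run.run_id}")
print(f"  train loss: {run.history[0]:.3f} -> {run.history[-1]:.3f}")
print(f"  mean test RMSD: {run.test_rmsd_mean:.3f} mm "
      f"({'kept' if run.test_rmsd_mean < 1.0 else 'dropped'} by the 1 mm rule)")
print(f"  latents: {run.latents.shape}, per-dimension sd:",
      np.round(run.latents.std(axis=0), 2))

# With 0.5 mm vertex noise the reconstruction cannot go below ~0.87 mm RMSD;
# a trained run typically lands just under the 1 mm selection threshold.
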