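"""Reproducible evaluation experiments on synthetic cohorts.

These routines run the package's own stages end to end (simulate -> align ->
latents -> QC -> GWAS -> ensemble aggregation) and measure recovery of the
planted causal regions. They are used by the test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .mesh_core import ShapeCohort, generalized_procrustes
from .shape_pca import encode_cohort_pca, fit_shape_pca
from .coma import ComaConfig, train_coma
from .gwas import variant_qc
from .pipeline import ensemble_gwas_and_classify
from .synthetic_data import SimConfig, simulate_cohort
from .upe import EnsembleConfig, select_runs

COVARIATE_COLUMNS = ["sex", "age", "height", "weight", "bmi"]


def subsample_pca_ensemble(
    aligned: ShapeCohort, n_runs: int = 6, frac: float = 0.6,
    n_components: int = 16, seed: int = 0,
) -> dict[str, np.ndarray]:
    """Ensemble of linear runs: shape PCA fitted on random subject subsets.

    Each run sees a different training sample (the ensemble's source of
    diversity here), then encodes the full cohort.
    """
    rng = np.random.default_rng(seed)
    n = aligned.n_subjects
    blocks = {}
    for r in range(n_runs):
        sub = np.sort(rng.choice(n, size=int(frac * n), replace=False))
        subc = ShapeCohort(
            [aligned.subject_ids[i] for i in sub], aligned.shapes[sub],
            aligned.template_faces, aligned=True,
        )
        model = fit_shape_pca(subc, n_components)
        blocks[f"pcarun{r + 1}"] = encode_cohort_pca(model, aligned)
    return blocks


def planted_locus_recovery(
    seed: int,
    n_subjects: int = 2000,
    n_variants: int = 2000,
    n_regions: int = 40,
    subdiv: int = 1,
    n_runs: int = 6,
) -> dict:
    """One recovery experiment: do the GWAS+ensemble stages rediscover the
    planted causal regions, and how many null regions come up significant?
    """
    cfg = SimConfig(
        n_subjects=n_subjects, n_variants=n_variants, n_regions=n_regions,
        subdiv=subdiv, seed=seed,
    )
    cohort, genotypes, covars, truth, partition, genes = simulate_cohort(cfg)
    aligned, _ = generalized_procrustes(cohort)
    keep, _ = variant_qc(genotypes)
    genotypes = genotypes.subset_variants(keep)
    blocks = subsample_pca_ensemble(aligned, n_runs=n_runs, seed=seed + 1)
    cov = covars[COVARIATE_COLUMNS].to_numpy(float)
    loci, info = ensemble_gwas_and_classify(
        blocks, cov, genotypes, partition, genes, EnsembleConfig(dedup_seed=seed)
    )
    causal = set(truth.causal_variants["region_id"])
    res = loci.set_index("region_id")
    recovered = sum(
        res.loc[rid, "classification"] in ("significant", "suggestive") for rid in causal
    )
    false_pos = int(
        ((res["classification"] == "significant") & (~res.index.isin(causal))).sum()
    )
    return {
        "n_causal": len(causal),
        "recovered": int(recovered),
        "false_positives": false_pos,
        "k_pheno": info["k_pheno"],
        "p_sw": info["p_sw"],
        "loci": loci,
    }


def coma_upe_smoke(
    seed: int = 0,
    n_subjects: int = 300,
    n_variants: int = 600,
    n_regions: int = 12,
    epochs: int = 50,
    n_runs: int = 3,
) -> dict:
    """Exercise the full autoencoder path: train several runs with different
    seeds and KL weights, select by the 1 mm test-RMSD rule, encode, and push
    the pooled latents (plus a PCA baseline) through GWAS and aggregation.
    """
    cfg = SimConfig(
        n_subjects=n_subjects, n_variants=n_variants, n_regions=n_regions,
        subdiv=2, seed=seed,
    )
    cohort, genotypes, covars, truth, partition, genes = simulate_cohort(cfg)
    aligned, _ = generalized_procrustes(cohort)

    w_grid = [0.0, 1e-4, 1e-3, 1e-2]
    results = []
    for r in range(n_runs):
        cc = ComaConfig(
            n_z=8, epochs=epochs, channels=(16, 16, 32), downsample_factors=(4, 4, 4),
            w_kl=w_grid[r % len(w_grid)], learning_rate=2e-3, batch_size=32,
            seed_weights=seed * 100 + r, seed_split=seed * 100 + r,
        )
        _, res = train_coma(aligned, cc, run_id=f"coma{r + 1}")
        results.append(res)
    kept = select_runs(results, 1.0)

    blocks = {res.run_id: res.latents for res in kept}
    pca = fit_shape_pca(aligned, 16)
    blocks["pca"] = encode_cohort_pca(pca, aligned)

    keep, _ = variant_qc(genotypes)
    genotypes = genotypes.subset_variants(keep)
    cov = covars[COVARIATE_COLUMNS].to_numpy(float)
    loci, info = ensemble_gwas_and_classify(
        blocks, cov, genotypes, partition, genes, EnsembleConfig(dedup_seed=seed)
    )
    return {
        "test_rmsd": [res.test_rmsd_mean for res in results],
        "n_kept": len(kept),
        "k_pheno": info["k_pheno"],
        "loci": loci,
        "truth": truth,
    }
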