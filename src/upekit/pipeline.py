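"""End-to-end orchestration: align -> latents (PCA / CoMA ensemble) ->
handcrafted indices -> GWAS -> ensemble aggregation -> locus table -> report.

Stages write artifacts under an output directory and record a MANIFEST with
config hashes and seeds; a completed stage whose hash is unchanged is skipped
on re-run.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh_core import (
    ShapeCohort,
    generalized_procrustes,
    handcrafted_phenotypes,
    load_cohort,
    save_cohort,
)
from .shape_pca import encode_cohort_pca, fit_shape_pca, latent_table, save_pca
from .coma import ComaConfig, train_coma
from .gwas import (
    GenotypeMatrix,
    adjust_phenotypes,
    linear_scan,
    read_genotypes_tsv,
    read_genotypes_vcf,
    variant_qc,
    write_sumstats,
)
from .upe import (
    EnsembleConfig,
    RegionPartition,
    annotate_nearest_gene,
    classify_loci,
    count_region_hits,
    pool_and_deduplicate,
    select_runs,
    study_wide_threshold,
)

__version__ = "0.1.0"


def _hash_config(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


class Manifest:
    def __init__(self, outdir: Path):
        self.path = Path(outdir) / "MANIFEST.json"
        self.data = {"tool": "upekit", "version": __version__, "stages": {}}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())

    def stage_done(self, name: str, h: str) -> bool:
        return self.data["stages"].get(name, {}).get("hash") == h

    def record(self, name: str, h: str, artifacts: dict) -> None:
        self.data["stages"][name] = {
            "hash": h,
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "artifacts": artifacts,
        }
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.data, indent=2))


# ---------------------------------------------------------------------------
# Reusable ensemble step (library entry point)
# ---------------------------------------------------------------------------

def ensemble_gwas_and_classify(
    latent_blocks: dict[str, np.ndarray],
    covariates: np.ndarray | None,
    genotypes: GenotypeMatrix,
    partition: RegionPartition,
    genes: pd.DataFrame | None = None,
    config: EnsembleConfig | None = None,
):
    """Pool run latents, dedup, adjust+INT, scan, aggregate and classify.

    Returns (locus table, info dict with k_pheno, p_sw, dedup log and the
    full summary-statistic table).
    """
    cfg = config or EnsembleConfig()
    pooled, prov, dedup_log = pool_and_deduplicate(
        latent_blocks, cfg.spearman_max, cfg.dedup_seed, cfg.dedup_mode
    )
    k_pheno = pooled.shape[1]
    p_sw = study_wide_threshold(cfg.p_gw, k_pheno)
    scores = adjust_phenotypes(pooled, covariates)
    pheno_ids = [f"{rid}:z{j + 1}" for rid, j in prov]
    table = linear_scan(scores, genotypes, phenotype_ids=pheno_ids)
    run_tables = {
        rid: table[table["phenotype_id"].str.startswith(f"{rid}:")]
        for rid in latent_blocks
        if any(p == rid for p, _ in prov)
    }
    region_stats = count_region_hits(run_tables, partition, cfg.p_gw)
    loci = classify_loci(region_stats, p_sw, cfg.p_gw, cfg.suggestive_min_count)
    loci = annotate_nearest_gene(loci, genes)
    info = {
        "k_pheno": k_pheno,
        "p_sw": p_sw,
        "dedup_log": dedup_log,
        "provenance": prov,
        "sumstats": table,
        "scores": scores,
    }
    return loci, info


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict, outdir) -> pd.DataFrame:
    """Execute the full pipeline from a configuration mapping.

    Expected keys (paths): ``cohort`` (cohort archive), ``genotypes_vcf`` or
    (``dosages_tsv``, ``variants_tsv``), ``covariates_tsv``, ``regions_bed``,
    ``genes_tsv`` (optional); ``covariate_columns``; ``ensemble`` — list of
    CoMA config dicts (may be empty); ``n_pca`` (0 disables the PCA run);
    ``ensemble_config`` — EnsembleConfig fields; ``qc`` — thresholds.
    Returns the final locus table.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out)

    cohort = load_cohort(config["cohort"])

    # --- align ---
    h = _hash_config({"stage": "align", "cohort": config["cohort"]})
    aligned_path = out / "aligned.npz"
    if manifest.stage_done("align", h) and aligned_path.exists():
        aligned = load_cohort(aligned_path)
    else:
        aligned, _ = generalized_procrustes(cohort)
        save_cohort(aligned, aligned_path)
        manifest.record("align", h, {"aligned": str(aligned_path)})

    # --- latents ---
    latent_blocks: dict[str, np.ndarray] = {}
    run_results = []
    n_pca = int(config.get("n_pca", 16))
    if n_pca:
        pca = fit_shape_pca(aligned, n_pca)
        z = encode_cohort_pca(pca, aligned)
        latent_blocks["pca"] = z
        save_pca(pca, out / "pca_model.npz")
        latent_table(aligned.subject_ids, z).to_csv(out / "latents_pca.tsv", sep="\t", index=False)
    for i, spec in enumerate(config.get("ensemble", [])):
        cc = ComaConfig(**spec)
        run_id = f"coma_{i + 1}"
        _, res = train_coma(aligned, cc, run_id=run_id)
        run_results.append(res)
        latent_table(aligned.subject_ids, res.latents, prefix="z").to_csv(
            out / f"latents_{run_id}.tsv", sep="\t", index=False
        )

    ens_cfg = EnsembleConfig(**config.get("ensemble_config", {}))
    if run_results:
        kept = select_runs(run_results, ens_cfg.rmsd_keep_mm)
        for res in kept:
            latent_blocks[res.run_id] = res.latents

    # --- handcrafted indices (reported alongside, not pooled) ---
    hc = handcrafted_phenotypes(aligned)
    pd.DataFrame(
        {"subject_id": aligned.subject_ids, "lvedv_mm3": hc[:, 0], "sphericity": hc[:, 1]}
    ).to_csv(out / "handcrafted.tsv", sep="\t", index=False)

    # --- genotypes + QC ---
    if "genotypes_vcf" in config:
        genotypes = read_genotypes_vcf(config["genotypes_vcf"])
    else:
        genotypes = read_genotypes_tsv(config["dosages_tsv"], config["variants_tsv"])
    qc = config.get("qc", {})
    keep, qc_report = variant_qc(
        genotypes,
        maf_min=qc.get("maf_min", 0.01),
        hwe_p_min=qc.get("hwe_p_min", 1e-5),
        info_min=qc.get("info_min", 0.3),
    )
    qc_report.to_csv(out / "variant_qc.tsv", sep="\t", index=False)
    genotypes = genotypes.subset_variants(keep)

    covars_df = pd.read_csv(config["covariates_tsv"], sep="\t")
    cov_cols = config.get("covariate_columns", ["sex", "age", "height", "weight", "bmi"])
    order = {s: i for i, s in enumerate(covars_df["subject_id"])}
    idx = [order[s] for s in aligned.subject_ids]
    cov = covars_df.iloc[idx][cov_cols].to_numpy(float)
    if list(genotypes.subject_ids) != list(aligned.subject_ids):
        gidx = {s: i for i, s in enumerate(genotypes.subject_ids)}
        sel = [gidx[s] for s in aligned.subject_ids]
        genotypes = GenotypeMatrix(
            genotypes.dosages[:, sel], genotypes.variants, list(aligned.subject_ids)
        )

    partition = RegionPartition.from_bed(config["regions_bed"])
    genes = (
        pd.read_csv(config["genes_tsv"], sep="\t") if config.get("genes_tsv") else None
    )

    loci, info = ensemble_gwas_and_classify(
        latent_blocks, cov, genotypes, partition, genes, ens_cfg
    )
    write_sumstats(info["sumstats"], out / "sumstats.tsv.gz")
    loci.to_csv(out / "locus_table.tsv", sep="\t", index=False)
    report = {
        "k_pheno": info["k_pheno"],
        "p_sw": info["p_sw"],
        "p_gw": ens_cfg.p_gw,
        "n_runs": len(latent_blocks),
        "n_variants_tested": int(genotypes.n_variants),
        "dedup_dropped": len(info["dedup_log"]),
        "n_significant": int((loci["classification"] == "significant").sum()),
        "n_suggestive": int((loci["classification"] == "suggestive").sum()),
        "config_hash": _hash_config(config),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    manifest.record("aggregate", _hash_config(config), {"locus_table": str(out / "locus_table.tsv")})
    return loci
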