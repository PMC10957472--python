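"""Synthetic cohorts: LV-like meshes driven by latent factors, HWE genotypes
with block LD and planted causal variants, and confounding covariates.

The generator defines the study conditions for every downstream stage:

* a closed "LV-like" template (prolate spheroid with a flattened basal cap,
  ~60 mm long axis) built from a subdivided icosahedron;
* four analytic deformation fields (isotropic scale, long-axis stretch, apex
  taper, basal-plane tilt) mimicking the dominant modes of ventricular shape
  variation; subject shapes are template + sum_j f_ij D_j + vertex noise;
* per-subject factors f_j with a genetic part (planted causal variants of
  exact in-sample explained variance h2), a covariate (confounding) part and
  a Gaussian residual;
* genotypes in Hardy-Weinberg equilibrium with haplotype-copying LD inside
  blocks (one block per genomic region; block-constant allele frequency so
  the marginal frequency of every variant is its drawn p).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .mesh_core import ShapeCohort, TriangleMesh, build_mesh, save_cohort, write_mesh
from .gwas import GenotypeMatrix
from .upe import RegionPartition

REGION_LENGTH = 2_000_000  # ~2 Mb LD-independent regions


@dataclass
class FactorSpec:
    name: str
    field_id: str       # key into displacement_fields
    sd: float           # factor standard deviation, mm of RMS displacement
    covariate_frac: float = 0.0   # fraction of factor variance from covariates


@dataclass
class CausalSpec:
    factor: str         # factor name
    h2: float = 0.03    # in-sample variance of the factor explained


@dataclass
class SimConfig:
    n_subjects: int = 2000
    subdiv: int = 2                      # M = 10 * 4^(subdiv+1) + 2 -> 642
    factors: list = dc_field(default_factory=lambda: [
        FactorSpec("size", "scale", 2.0, covariate_frac=0.15),
        FactorSpec("stretch", "long_axis", 1.5, covariate_frac=0.05),
        FactorSpec("taper", "apex_taper", 1.2),
        FactorSpec("tilt", "basal_tilt", 1.0),
    ])
    vertex_noise_sd: float = 0.5         # mm
    n_variants: int = 5000
    n_regions: int = 50
    freq_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.8                  # haplotype copy probability in blocks
    causal: list = dc_field(default_factory=lambda: [
        CausalSpec("size"), CausalSpec("size"),
        CausalSpec("stretch"), CausalSpec("taper"),
        CausalSpec("tilt"), CausalSpec("tilt"),
    ])
    seed: int = 0

    def __post_init__(self):
        if self.vertex_noise_sd < 0 or any(f.sd < 0 for f in self.factors):
            raise ValueError("standard deviations must be >= 0")
        names = [f.name for f in self.factors]
        for c in self.causal:
            if c.factor not in names:
                raise ValueError(f"causal variant maps to unknown factor {c.factor!r}")
        for f in self.factors:
            h2_sum = sum(c.h2 for c in self.causal if c.factor == f.name)
            if h2_sum + f.covariate_frac >= 1:
                raise ValueError(
                    f"factor {f.name!r}: h2 + covariate fraction must be < 1"
                )


@dataclass
class TruthTables:
    factor_values: pd.DataFrame          # subject_id + one column per factor
    causal_variants: pd.DataFrame        # variant_id, factor, h2, region_id, beta_std
    variant_regions: pd.DataFrame        # variant_id, region_id
    factor_fields: dict                  # factor name -> displacement field id


# ---------------------------------------------------------------------------
# Template and displacement fields
# ---------------------------------------------------------------------------

TEMPLATE_A = 22.0   # short semi-axes, mm
TEMPLATE_C = 40.0   # long semi-axis, mm
TEMPLATE_BASE = 20.0  # basal clipping plane height, mm


def make_template(subdiv: int = 2) -> TriangleMesh:
    """Closed LV-like surface: prolate spheroid flattened at the base.

    ``subdiv`` counts refinement levels beyond the once-subdivided
    icosahedron, so vertex counts are 162, 642, 2562 for subdiv = 1, 2, 3.
    """
    if subdiv < 1:
        raise ValueError("subdiv must be >= 1")
    ico = trimesh.creation.icosphere(subdivisions=subdiv + 1, radius=1.0)
    v = np.asarray(ico.vertices) * np.array([TEMPLATE_A, TEMPLATE_A, TEMPLATE_C])
    v[:, 2] = np.minimum(v[:, 2], TEMPLATE_BASE)
    return build_mesh(v, np.asarray(ico.faces))


def template_analytic_volume() -> float:
    """Volume of the spheroid clipped at the basal plane (mm^3)."""
    a, c, h = TEMPLATE_A, TEMPLATE_C, TEMPLATE_BASE
    return float(np.pi * a**2 * (h - h**3 / (3 * c**2) + 2 * c / 3))


def _rigid_motion_basis(v: np.ndarray) -> list[np.ndarray]:
    """Orthonormal basis of infinitesimal rigid motions at the template.

    Pose alignment removes translation and rotation, so any displacement
    component in this 6-dimensional subspace cannot survive Procrustes; the
    generator projects it out of every deformation field.
    """
    c = v - v.mean(axis=0)
    m = v.shape[0]
    gens = []
    for axis in range(3):  # translations
        t = np.zeros((m, 3))
        t[:, axis] = 1.0
        gens.append(t.reshape(-1))
    rx = np.column_stack([np.zeros(m), -c[:, 2], c[:, 1]])
    ry = np.column_stack([c[:, 2], np.zeros(m), -c[:, 0]])
    rz = np.column_stack([-c[:, 1], c[:, 0], np.zeros(m)])
    gens += [rx.reshape(-1), ry.reshape(-1), rz.reshape(-1)]
    basis: list[np.ndarray] = []
    for g in gens:
        for b in basis:
            g = g - (g @ b) * b
        basis.append(g / np.linalg.norm(g))
    return basis


def displacement_fields(template: TriangleMesh) -> dict[str, np.ndarray]:
    """Four analytic unit-RMS vertex displacement fields.

    Each raw field is first projected orthogonal to the template's
    infinitesimal rigid motions (so pose alignment cannot absorb it), then
    Gram-Schmidt orthogonalized in a fixed order (scale, long_axis,
    apex_taper, basal_tilt) and normalized to unit per-vertex RMS
    displacement (1 unit of factor value = 1 mm RMS displacement).
    """
    v = template.vertices
    centroid = v.mean(axis=0)
    z = v[:, 2]
    apex_z, base_z = z.min(), z.max()
    raw = {}
    raw["scale"] = v - centroid
    d = np.zeros_like(v)
    d[:, 2] = z - z.mean()
    raw["long_axis"] = d
    w = (base_z - z) / (base_z - apex_z)
    d = np.zeros_like(v)
    d[:, :2] = -w[:, None] * (v[:, :2] - centroid[:2])
    raw["apex_taper"] = d
    # differential tilt: depth-weighted rotation about the x axis, i.e. the
    # basal plane reorients while the apex stays put (non-rigid bending)
    wb = (z - apex_z) / (base_z - apex_z)
    d = np.zeros_like(v)
    d[:, 1] = -wb * (z - centroid[2])
    d[:, 2] = wb * (v[:, 1] - centroid[1])
    raw["basal_tilt"] = d

    m = v.shape[0]
    rigid = _rigid_motion_basis(v)
    out: dict[str, np.ndarray] = {}
    basis: list[np.ndarray] = list(rigid)
    for name, d in raw.items():
        f = d.reshape(-1).astype(float)
        for b in basis:
            f = f - (f @ b) * b
        norm = np.linalg.norm(f)
        if norm < 1e-6 * np.linalg.norm(d):
            raise ValueError(f"degenerate displacement field {name!r}")
        basis.append(f / norm)
        out[name] = (f / norm * np.sqrt(m)).reshape(m, 3)  # unit per-vertex RMS
    return out


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _chrom_of_region(idx: int) -> str:
    return str(idx % 22 + 1)


def make_region_partition(n_regions: int) -> RegionPartition:
    rows = []
    per_chrom: dict[str, int] = {}
    for i in range(n_regions):
        chrom = _chrom_of_region(i)
        k = per_chrom.get(chrom, 0)
        per_chrom[chrom] = k + 1
        rows.append(
            {
                "region_id": f"region_{i + 1}",
                "chrom": chrom,
                "start": k * REGION_LENGTH,
                "end": (k + 1) * REGION_LENGTH,
            }
        )
    return RegionPartition(pd.DataFrame(rows))


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator):
    """HWE genotypes with within-block haplotype-copying LD.

    One LD block per region; the allele frequency is drawn once per block so
    every variant's marginal frequency equals its recorded p under copying.
    Returns (GenotypeMatrix, variant->region table, RegionPartition).
    """
    n, v_total = cfg.n_subjects, cfg.n_variants
    partition = make_region_partition(cfg.n_regions)
    per_region = [v_total // cfg.n_regions] * cfg.n_regions
    for i in range(v_total % cfg.n_regions):
        per_region[i] += 1
    doses = np.empty((v_total, n))
    meta = []
    region_rows = []
    v_idx = 0
    for r in range(cfg.n_regions):
        p = rng.uniform(*cfg.freq_range)
        n_v = per_region[r]
        h = np.empty((n_v, n, 2), dtype=np.int8)
        h[0] = rng.random((n, 2)) < p
        for j in range(1, n_v):
            fresh = rng.random((n, 2)) < p
            copy = rng.random((n, 2)) < cfg.ld_rho
            h[j] = np.where(copy, h[j - 1], fresh)
        reg = partition.regions.iloc[r]
        step = REGION_LENGTH // (n_v + 1)
        for j in range(n_v):
            doses[v_idx] = h[j].sum(axis=1)
            pos = int(reg["start"]) + (j + 1) * step + 1  # 1-based
            meta.append(
                {
                    "variant_id": f"var_{v_idx + 1}",
                    "chrom": reg["chrom"],
                    "pos": pos,
                    "ea": "A",
                    "nea": "G",
                    "info": 1.0,
                    "p_allele": p,
                }
            )
            region_rows.append(
                {"variant_id": f"var_{v_idx + 1}", "region_id": reg["region_id"]}
            )
            v_idx += 1
    subject_ids = [f"subj_{i + 1}" for i in range(n)]
    gm = GenotypeMatrix(doses, pd.DataFrame(meta), subject_ids)
    return gm, pd.DataFrame(region_rows), partition


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    sex = (rng.random(n) < 0.5).astype(int)
    age = rng.normal(55.0, 7.5, n)
    height = rng.normal(163.0, 7.0, n) + sex * 13.0
    bmi = rng.normal(27.0, 4.0, n)
    weight = bmi * (height / 100.0) ** 2
    return pd.DataFrame(
        {
            "subject_id": [f"subj_{i + 1}" for i in range(n)],
            "sex": sex,
            "age": age,
            "height": height,
            "weight": weight,
            "bmi": bmi,
        }
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(cfg: SimConfig):
    """Full synthetic dataset.

    Returns (ShapeCohort, GenotypeMatrix, covariates DataFrame, TruthTables,
    RegionPartition, genes DataFrame).
    """
    rng = np.random.default_rng(cfg.seed)
    genotypes, variant_regions, partition = simulate_genotypes(cfg, rng)
    covars = simulate_covariates(cfg.n_subjects, rng)

    template = make_template(cfg.subdiv)
    fields = displacement_fields(template)

    # choose causal variants: spread across distinct regions, mid-block variant
    region_ids = list(partition.regions["region_id"])
    if len(cfg.causal) > len(region_ids):
        raise ValueError("more causal variants than regions")
    step = max(1, len(region_ids) // max(len(cfg.causal), 1))
    causal_rows = []
    by_region = variant_regions.groupby("region_id")["variant_id"]
    for k, c in enumerate(cfg.causal):
        region = region_ids[(k * step) % len(region_ids)]
        vids = list(by_region.get_group(region))
        causal_rows.append({"variant_id": vids[len(vids) // 2], "factor": c.factor, "h2": c.h2, "region_id": region})

    # standardized doses of causal variants
    vid_index = {vid: i for i, vid in enumerate(genotypes.variants["variant_id"])}
    n = cfg.n_subjects
    cov_std = np.column_stack(
        [
            (covars[c] - covars[c].mean()) / max(covars[c].std(ddof=0), 1e-12)
            for c in ("sex", "age", "height", "weight", "bmi")
        ]
    )
    cov_weights = np.array([0.3, 0.2, 0.6, 0.55, 0.35])
    u = cov_std @ cov_weights
    u = (u - u.mean()) / max(u.std(ddof=0), 1e-12)

    factor_values = {}
    for f in cfg.factors:
        genetic = np.zeros(n)
        for row in causal_rows:
            if row["factor"] != f.name:
                continue
            x = genotypes.dosages[vid_index[row["variant_id"]]]
            sd = x.std(ddof=0)
            if sd < 1e-12:
                raise ValueError("monomorphic causal variant; rerun with another seed")
            x_std = (x - x.mean()) / sd
            genetic = genetic + np.sqrt(row["h2"]) * f.sd * x_std
            row.setdefault("beta_std", {})[f.name] = float(np.sqrt(row["h2"]) * f.sd)
        h2_sum = sum(r["h2"] for r in causal_rows if r["factor"] == f.name)
        resid_var = f.sd**2 * (1.0 - h2_sum - f.covariate_frac)
        eps = rng.standard_normal(n) * np.sqrt(max(resid_var, 0.0))
        factor_values[f.name] = (
            genetic + np.sqrt(f.covariate_frac) * f.sd * u + eps
        )

    # shapes = template + sum_j f_j D_j + vertex noise
    m = template.n_vertices
    shapes = np.broadcast_to(template.vertices, (n, m, 3)).copy()
    for f in cfg.factors:
        shapes += factor_values[f.name][:, None, None] * fields[f.field_id][None]
    if cfg.vertex_noise_sd > 0:
        shapes += rng.standard_normal((n, m, 3)) * cfg.vertex_noise_sd

    cohort = ShapeCohort(
        [f"subj_{i + 1}" for i in range(n)], shapes, template.faces, aligned=False
    )
    truth = TruthTables(
        factor_values=pd.DataFrame({"subject_id": cohort.subject_ids, **factor_values}),
        causal_variants=pd.DataFrame(
            [
                {
                    "variant_id": r["variant_id"],
                    "factor": r["factor"],
                    "h2": r["h2"],
                    "region_id": r["region_id"],
                    "beta_std": r.get("beta_std", {}).get(r["factor"], 0.0),
                }
                for r in causal_rows
            ]
        ),
        variant_regions=variant_regions,
        factor_fields={f.name: f.field_id for f in cfg.factors},
    )
    genes = make_gene_table(partition, rng)
    return cohort, genotypes, covars, truth, partition, genes


def make_gene_table(partition: RegionPartition, rng: np.random.Generator) -> pd.DataFrame:
    """One synthetic gene per region with TSS/TES and strand."""
    rows = []
    for i, reg in partition.regions.iterrows():
        start = int(reg["start"]) + int(rng.integers(1, REGION_LENGTH // 2))
        length = int(rng.integers(10_000, 200_000))
        strand = "+" if rng.random() < 0.5 else "-"
        tss, tes = (start, start + length) if strand == "+" else (start + length, start)
        rows.append(
            {
                "gene": f"GENE{i + 1}",
                "chrom": reg["chrom"],
                "tss": tss,
                "tes": tes,
                "strand": strand,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 with GT (hard calls) and DS (dosage) per sample."""
    var = genotypes.variants
    chroms = list(dict.fromkeys(var["chrom"].astype(str)))
    with open(str(path), "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.subject_ids)
            + "\n"
        )
        order = var.sort_values(["chrom", "pos"]).index
        for i in order:
            row = var.loc[i]
            d = genotypes.dosages[i]
            cells = []
            for x in d:
                if x < 0:
                    cells.append("./.:.")
                else:
                    hard = int(round(x))
                    gt = ["0/0", "0/1", "1/1"][hard]
                    cells.append(f"{gt}:{x:g}")
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t{row['nea']}\t"
                f"{row['ea']}\t.\tPASS\tINFO={row['info']:g}\tGT:DS\t" + "\t".join(cells) + "\n"
            )


def write_fixture(outdir, cohort, genotypes, covars, truth, partition, genes,
                  write_plys: bool = False) -> dict:
    """Write every artifact; returns a manifest of paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    save_cohort(cohort, out / "cohort.npz")
    paths["cohort"] = str(out / "cohort.npz")
    if write_plys:
        mesh_dir = out / "meshes"
        mesh_dir.mkdir(exist_ok=True)
        for i, sid in enumerate(cohort.subject_ids):
            write_mesh(cohort.subject_mesh(i), mesh_dir / f"{sid}.ply")
        paths["meshes"] = str(mesh_dir)
    write_vcf(genotypes, out / "genotypes.vcf")
    paths["vcf"] = str(out / "genotypes.vcf")
    dos = pd.DataFrame(
        genotypes.dosages, index=genotypes.variants["variant_id"], columns=genotypes.subject_ids
    )
    dos.index.name = "variant_id"
    dos.to_csv(out / "dosages.tsv", sep="\t")
    genotypes.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
    covars.to_csv(out / "covariates.tsv", sep="\t", index=False)
    partition.to_bed(out / "regions.bed")
    genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    truth.factor_values.to_csv(out / "truth_factors.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "causal_variants": truth.causal_variants.to_dict(orient="records"),
                "factor_fields": truth.factor_fields,
            },
            fh,
            indent=2,
        )
    paths.update(
        dosages=str(out / "dosages.tsv"),
        variants=str(out / "variants.tsv"),
        covariates=str(out / "covariates.tsv"),
        regions=str(out / "regions.bed"),
        genes=str(out / "genes.tsv"),
        truth=str(out / "truth.json"),
    )
    return paths
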