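"""Genotype QC, covariate adjustment with rank-inverse-normal transform, and
per-variant linear association scans.

The association model for each (phenotype k, variant i) pair is the
univariate additive regression z_k = a + beta_ik X_i + eps, where X_i in
[0, 2] is the effect-allele dose. Phenotypic scores are OLS residuals on the
covariates, rank-inverse normalized (Blom offsets), so beta_hat is the
per-allele effect on the INT scale. P values are two-sided from the t
statistic with n - 2 degrees of freedom.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


MISSING = -1.0  # sentinel for missing dosage


@dataclass
class GenotypeMatrix:
    """Dosage matrix (V, N) in [0, 2] with per-variant metadata."""

    dosages: np.ndarray
    variants: pd.DataFrame  # variant_id, chrom, pos, ea, nea, info
    subject_ids: list[str]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, float)
        req = {"variant_id", "chrom", "pos", "ea", "nea", "info"}
        missing_cols = req - set(self.variants.columns)
        if missing_cols:
            raise ValueError(f"variant table missing columns {sorted(missing_cols)}")
        if self.dosages.shape != (len(self.variants), len(self.subject_ids)):
            raise ValueError("dosages shape does not match variants x subjects")
        valid = (self.dosages == MISSING) | (
            (self.dosages >= 0) & (self.dosages <= 2)
        )
        if not valid.all():
            raise ValueError("dosages must lie in [0, 2] or be missing-marked")
        if self.variants["variant_id"].duplicated().any():
            raise ValueError("variant_ids must be unique")

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[1]

    def subset_variants(self, mask) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[mask],
            self.variants.loc[mask].reset_index(drop=True),
            list(self.subject_ids),
        )


# ---------------------------------------------------------------------------
# Allele frequency and Hardy-Weinberg
# ---------------------------------------------------------------------------

def effect_allele_frequency(doses: np.ndarray) -> float:
    """EAF = mean dose / 2 over non-missing entries."""
    doses = np.asarray(doses, float)
    ok = doses != MISSING
    if not ok.any():
        raise ValueError("all dosages missing for variant")
    return float(doses[ok].mean() / 2.0)


def minor_allele_frequency(doses: np.ndarray) -> float:
    eaf = effect_allele_frequency(doses)
    return min(eaf, 1.0 - eaf)


def hwe_exact_test(n_aa_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    P value is the sum of probabilities of all heterozygote counts (given the
    observed allele counts) that are no more probable than the observed one.
    Symmetric in the two homozygote counts.
    """
    if min(n_aa_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("no genotyped individuals")
    # rare allele count
    n_rare = 2 * min(n_aa_hom1, n_hom2) + n_het
    # heterozygote counts share the parity of n_rare
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    logprob = _hwe_log_prob(hets, n_rare, n)
    logprob -= logprob.max()
    prob = np.exp(logprob)
    prob /= prob.sum()
    observed = prob[hets == n_het][0]
    return float(min(1.0, prob[prob <= observed * (1 + 1e-12)].sum()))


def _hwe_log_prob(n_het: np.ndarray, n_rare: int, n: int) -> np.ndarray:
    """log P(het = n_het | allele counts), Levene-Haldane distribution."""
    from scipy.special import gammaln as lg

    n_hom_rare = (n_rare - n_het) // 2
    n_hom_common = n - n_het - n_hom_rare
    return (
        n_het * math.log(2)
        + lg(n + 1) - lg(n_het + 1) - lg(n_hom_rare + 1) - lg(n_hom_common + 1)
        + lg(n_rare + 1) + lg(2 * n - n_rare + 1) - lg(2 * n + 1)
    )


def hwe_from_dosages(doses: np.ndarray) -> float:
    """HWE exact test on hard calls (rounded dosages)."""
    doses = np.asarray(doses, float)
    ok = doses != MISSING
    hard = np.rint(doses[ok]).astype(int)
    counts = np.bincount(np.clip(hard, 0, 2), minlength=3)
    return hwe_exact_test(int(counts[0]), int(counts[1]), int(counts[2]))


# ---------------------------------------------------------------------------
# Variant QC
# ---------------------------------------------------------------------------

def variant_qc(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-5,
    info_min: float = 0.3,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Keep mask: MAF >= maf_min AND HWE p >= hwe_p_min AND info >= info_min."""
    v = genotypes.n_variants
    maf = np.array([minor_allele_frequency(genotypes.dosages[i]) for i in range(v)])
    hwe_p = np.array([hwe_from_dosages(genotypes.dosages[i]) for i in range(v)])
    info = genotypes.variants["info"].to_numpy(float)
    pass_maf = maf >= maf_min
    pass_hwe = hwe_p >= hwe_p_min
    pass_info = info >= info_min
    keep = pass_maf & pass_hwe & pass_info
    report = pd.DataFrame(
        {
            "variant_id": genotypes.variants["variant_id"],
            "maf": maf,
            "hwe_p": hwe_p,
            "info": info,
            "pass_maf": pass_maf,
            "pass_hwe": pass_hwe,
            "pass_info": pass_info,
            "keep": keep,
        }
    )
    if not keep.any():
        warnings.warn("variant QC removed every variant")
    return keep, report


# ---------------------------------------------------------------------------
# Phenotype adjustment
# ---------------------------------------------------------------------------

def rank_inverse_normal(x: np.ndarray) -> np.ndarray:
    """Blom rank-based INT: Phi^{-1}((r - 3/8) / (n + 1/4)), average ranks."""
    x = np.asarray(x, float)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))


def adjust_phenotype(raw: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """OLS residuals of raw on covariates (+intercept), then rank-INT."""
    raw = np.asarray(raw, float)
    n = raw.size
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        resid = raw - raw.mean()
    else:
        c = np.atleast_2d(np.asarray(covariates, float))
        if c.shape[0] != n:
            c = c.T
        if c.shape[0] != n:
            raise ValueError("covariate matrix does not match phenotype length")
        design = np.column_stack([np.ones(n), c])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            # identify collinear columns by rank increments
            bad = []
            r = 1
            for j in range(1, design.shape[1]):
                rj = np.linalg.matrix_rank(design[:, : j + 1])
                if rj == r:
                    bad.append(j - 1)
                r = rj
            raise ValueError(f"rank-deficient covariates (collinear columns {bad})")
        beta, *_ = np.linalg.lstsq(design, raw, rcond=None)
        resid = raw - design @ beta
    return rank_inverse_normal(resid)


def adjust_phenotypes(
    raw: np.ndarray, covariates: np.ndarray | None
) -> np.ndarray:
    """Column-wise :func:`adjust_phenotype` for an (N, K) phenotype matrix."""
    raw = np.atleast_2d(np.asarray(raw, float))
    if raw.shape[0] == 1:
        raw = raw.T
    return np.column_stack([adjust_phenotype(raw[:, k], covariates) for k in range(raw.shape[1])])


# ---------------------------------------------------------------------------
# Linear scan
# ---------------------------------------------------------------------------

P_FLOOR = 5e-324  # smallest subnormal double; underflowed p-values are flagged


def linear_scan(
    scores: np.ndarray,
    genotypes: GenotypeMatrix,
    phenotype_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Univariate additive GWAS of every phenotype against every variant.

    ``scores`` is (N, K) of INT-adjusted phenotypic scores, subject order
    identical to ``genotypes.subject_ids``. Missing doses are mean-imputed
    per variant. Zero-variance variants are skipped (reported with NaN).

    Returns a long-format table with columns phenotype_id, variant_id, chrom,
    pos, ea, nea, eaf, beta_hat, se, t_stat, p, n.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    if scores.shape[0] == 1:
        scores = scores.T
    n, k = scores.shape
    if n != genotypes.n_subjects:
        raise ValueError("scores and genotypes have different subject counts")
    if phenotype_ids is None:
        phenotype_ids = [f"pheno_{j + 1}" for j in range(k)]

    g = genotypes.dosages.copy()
    miss = g == MISSING
    if miss.any():
        row_mean = np.where(
            miss.all(axis=1), 0.0,
            np.nanmean(np.where(miss, np.nan, g), axis=1),
        )
        g[miss] = np.broadcast_to(row_mean[:, None], g.shape)[miss]
    eaf = g.mean(axis=1) / 2.0

    g_mean = g.mean(axis=1, keepdims=True)
    gc = g - g_mean
    g_ss = (gc**2).sum(axis=1)
    ok = g_ss > 0

    z_mean = scores.mean(axis=0, keepdims=True)
    zc = scores - z_mean
    z_ss = (zc**2).sum(axis=0)

    # simple regression with intercept: beta = Sxy/Sxx; se from residual SS
    sxy = gc @ zc                        # (V, K)
    beta = np.full((g.shape[0], k), np.nan)
    beta[ok] = sxy[ok] / g_ss[ok, None]
    rss = z_ss[None, :] - np.where(ok[:, None], sxy**2 / np.where(ok, g_ss, 1.0)[:, None], 0.0)
    rss = np.maximum(rss, 0.0)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / dof / g_ss[:, None])
        t = beta / se
        # constant phenotype (beta = 0, rss = 0): no association, t = 0
        t = np.where((se == 0) & (beta == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    # t = +/-inf (perfect fit) underflows to the smallest representable p;
    # NaN t (skipped variant) propagates NaN
    p = np.where(~np.isnan(t), np.maximum(p, P_FLOOR), np.nan)

    vmeta = genotypes.variants
    rows = []
    for j, pid in enumerate(phenotype_ids):
        df = pd.DataFrame(
            {
                "phenotype_id": pid,
                "variant_id": vmeta["variant_id"].to_numpy(),
                "chrom": vmeta["chrom"].to_numpy(),
                "pos": vmeta["pos"].to_numpy(),
                "ea": vmeta["ea"].to_numpy(),
                "nea": vmeta["nea"].to_numpy(),
                "eaf": eaf,
                "beta_hat": beta[:, j],
                "se": se[:, j],
                "t_stat": t[:, j],
                "p": p[:, j],
                "n": n,
            }
        )
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    out = out.sort_values(["phenotype_id", "chrom", "pos", "variant_id"]).reset_index(drop=True)
    skipped = ~ok
    if skipped.any():
        warnings.warn(f"{int(skipped.sum())} zero-variance variants skipped")
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_sumstats(table: pd.DataFrame, path) -> None:
    """Gzip TSV, deterministic row order (phenotype, chrom, pos, variant)."""
    with gzip.open(str(path), "wt") as fh:
        table.to_csv(fh, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t", compression="infer")


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read a VCF; DS preferred over GT; INFO field 'INFO' score if present."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = list(vcf.samples)
    doses, meta = [], []
    for var in vcf:
        if "DS" in (var.FORMAT or []):
            ds = np.asarray(var.format("DS"), float).ravel()
            ds = np.where(np.isnan(ds), MISSING, ds)
        else:
            gt = np.asarray(var.genotypes, dtype=object)
            ds = np.array(
                [
                    MISSING
                    if g[0] < 0 or g[1] < 0
                    else float(int(g[0] > 0) + int(g[1] > 0))
                    for g in gt
                ]
            )
        info = var.INFO.get("INFO", 1.0)
        doses.append(ds)
        meta.append(
            {
                "variant_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ea": var.ALT[0] if var.ALT else ".",
                "nea": var.REF,
                "info": float(info),
            }
        )
    return GenotypeMatrix(np.array(doses), pd.DataFrame(meta), subject_ids)


def read_genotypes_tsv(dosage_path, meta_path) -> GenotypeMatrix:
    """TSV dosage matrix (rows=variants, cols=subjects) + variant metadata."""
    d = pd.read_csv(str(dosage_path), sep="\t", index_col=0)
    meta = pd.read_csv(str(meta_path), sep="\t")
    meta["chrom"] = meta["chrom"].astype(str)
    if list(d.index) != list(meta["variant_id"]):
        meta = meta.set_index("variant_id").loc[d.index].reset_index()
    doses = d.to_numpy(float)
    doses = np.where(np.isnan(doses), MISSING, doses)
    return GenotypeMatrix(doses, meta, [str(c) for c in d.columns])
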