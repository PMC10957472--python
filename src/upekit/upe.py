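"""Ensemble aggregation of per-run GWAS into locus calls.

Runs passing the reconstruction criterion contribute their latent phenotypes
to a pooled representation; near-duplicate phenotypes (|Spearman rho| above a
cutoff) are dropped; the genome-wide threshold P_GW is Bonferroni-divided by
the post-deduplication phenotype count K to give the study-wide threshold
P_SW. Hits are counted per LD-independent region: for each run r and region
l, p_{l,r} is the minimum p over that run's phenotypes and the region's
variants, and C_l counts runs with p_{l,r} < P_GW. A region is *significant*
if its overall best p beats P_SW, *suggestive* if it beats P_GW in at least
``suggestive_min_count`` runs, and non-significant otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EnsembleConfig:
    p_gw: float = 5e-8
    rmsd_keep_mm: float = 1.0
    spearman_max: float = 0.95
    suggestive_min_count: int = 5
    dedup_seed: int = 0
    dedup_mode: str = "random"   # or "drop-later"

    def __post_init__(self):
        if not 0 < self.p_gw < 1:
            raise ValueError("p_gw must be in (0, 1)")
        if not 0 < self.spearman_max <= 1:
            raise ValueError("spearman_max must be in (0, 1]")


# ---------------------------------------------------------------------------
# Region partition
# ---------------------------------------------------------------------------

@dataclass
class RegionPartition:
    """Non-overlapping 0-based half-open genomic intervals (BED convention)."""

    regions: pd.DataFrame  # region_id, chrom, start, end

    def __post_init__(self):
        r = self.regions.copy()
        req = {"region_id", "chrom", "start", "end"}
        if req - set(r.columns):
            raise ValueError(f"region table needs columns {sorted(req)}")
        r["chrom"] = r["chrom"].astype(str)
        r = r.sort_values(["chrom", "start"]).reset_index(drop=True)
        if (r["end"] <= r["start"]).any():
            raise ValueError("every region must have end > start")
        for _, grp in r.groupby("chrom"):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError("regions overlap within a chromosome")
        self.regions = r

    @classmethod
    def from_bed(cls, path) -> "RegionPartition":
        df = pd.read_csv(
            str(path), sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "region_id"],
            usecols=[0, 1, 2, 3],
            dtype={0: str},
        )
        if df["region_id"].isna().any():
            df["region_id"] = [f"region_{i + 1}" for i in range(len(df))]
        return cls(df)

    def to_bed(self, path) -> None:
        self.regions[["chrom", "start", "end", "region_id"]].to_csv(
            str(path), sep="\t", header=False, index=False
        )


def assign_regions(table: pd.DataFrame, partition: RegionPartition) -> pd.Series:
    """Region id per row of a GWAS table by (chrom, pos) binary search.

    A row is assigned to the region with start <= pos < end (half-open on the
    position as recorded in the GWAS table, BED start inclusive, BED end
    exclusive). Rows outside all regions get NA with a warning.
    """
    chroms = table["chrom"].astype(str)
    bad = ~chroms.str.match(r"^(chr)?[0-9XYM]+$")
    if bad.any():
        raise ValueError(
            f"malformed chromosome names: {sorted(chroms[bad].unique())[:5]}"
        )
    out = pd.Series(pd.NA, index=table.index, dtype=object)
    for chrom, grp in table.groupby(chroms):
        reg = partition.regions[partition.regions["chrom"] == str(chrom)]
        if reg.empty:
            continue
        starts = reg["start"].to_numpy()
        ends = reg["end"].to_numpy()
        ids = reg["region_id"].to_numpy()
        pos0 = grp["pos"].to_numpy()
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, len(ends) - 1)])
        assigned = np.where(ok, ids[np.clip(idx, 0, len(ids) - 1)], None)
        out.loc[grp.index] = assigned
    n_out = out.isna().sum()
    if n_out:
        warnings.warn(f"{int(n_out)} GWAS rows fall outside every region")
    return out


# ---------------------------------------------------------------------------
# Run selection and phenotype pooling
# ---------------------------------------------------------------------------

def select_runs(runs: list, rmsd_keep_mm: float = 1.0) -> list:
    """Keep runs with mean test RMSD strictly below the threshold (mm)."""
    kept = [r for r in runs if r.test_rmsd_mean < rmsd_keep_mm]
    if not kept:
        raise ValueError(
            f"no run has test RMSD below {rmsd_keep_mm} mm "
            f"(best: {min(r.test_rmsd_mean for r in runs):.3f})"
        )
    return kept


def pool_and_deduplicate(
    latent_blocks: dict[str, np.ndarray],
    spearman_max: float = 0.95,
    dedup_seed: int = 0,
    dedup_mode: str = "random",
) -> tuple[np.ndarray, list[tuple[str, int]], list[dict]]:
    """Concatenate run latents and drop near-duplicate columns.

    ``latent_blocks`` maps run_id -> (N, n_z) latent matrix (identical subject
    order). Whenever a pair of pooled columns has |Spearman rho| >
    ``spearman_max``, one of the two is dropped — chosen by a seeded coin in
    "random" mode or always the later column in "drop-later" mode.

    Returns (pooled (N, K) matrix, provenance [(run_id, latent_index)], log).
    """
    mats, prov = [], []
    n_subjects = None
    for run_id, z in latent_blocks.items():
        z = np.asarray(z, float)
        if n_subjects is None:
            n_subjects = z.shape[0]
        elif z.shape[0] != n_subjects:
            raise ValueError("latent blocks have inconsistent subject counts")
        mats.append(z)
        prov.extend((run_id, j) for j in range(z.shape[1]))
    if n_subjects is None or n_subjects < 10:
        raise ValueError("need at least 10 subjects for rank correlations")
    pooled = np.concatenate(mats, axis=1)
    k_total = pooled.shape[1]

    rho = stats.spearmanr(pooled).statistic
    if np.ndim(rho) == 0:  # spearmanr returns a scalar for exactly 2 columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rng = np.random.default_rng(dedup_seed)
    alive = np.ones(k_total, dtype=bool)
    log = []
    for a in range(k_total):
        if not alive[a]:
            continue
        for b in range(a + 1, k_total):
            if not alive[b]:
                continue
            r = abs(rho[a, b])
            if r > spearman_max:
                if dedup_mode == "drop-later":
                    drop = b
                else:
                    drop = b if rng.random() < 0.5 else a
                alive[drop] = False
                log.append(
                    {"kept": prov[a if drop == b else b], "dropped": prov[drop], "abs_rho": float(r)}
                )
                if drop == a:
                    break
    kept_idx = np.flatnonzero(alive)
    return pooled[:, kept_idx], [prov[i] for i in kept_idx], log


def study_wide_threshold(p_gw: float, k_pheno: int) -> float:
    """P_SW = P_GW / K, the Bonferroni division by the pooled phenotype count."""
    if k_pheno < 1:
        raise ValueError("k_pheno must be >= 1")
    return p_gw / k_pheno


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Generic alpha / n_tests correction (e.g. TWAS tissue-gene pairs)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# Hit counting and classification
# ---------------------------------------------------------------------------

def count_region_hits(
    run_tables: dict[str, pd.DataFrame],
    partition: RegionPartition,
    p_gw: float = 5e-8,
) -> pd.DataFrame:
    """Per-region best p per run, overall P_best, and count C_l.

    ``run_tables`` maps run_id -> GWAS long table covering that run's
    phenotypes. Returns one row per region with columns region_id, p_best,
    count, lead_* fields of the overall best association.
    """
    if partition.regions.empty:
        raise ValueError("empty region partition")
    run_ids = list(run_tables.keys())
    per_region: dict[str, dict] = {
        rid: {"p_best": np.inf, "count": 0, "lead": None}
        for rid in partition.regions["region_id"]
    }
    for run_id, table in run_tables.items():
        t = table.copy()
        t["region_id"] = assign_regions(t, partition)
        t = t.dropna(subset=["region_id", "p"])
        for region_id, grp in t.groupby("region_id"):
            # deterministic lead: min p, ties by position then variant_id
            grp = grp.sort_values(["p", "pos", "variant_id"])
            best = grp.iloc[0]
            entry = per_region[region_id]
            if best["p"] < p_gw:
                entry["count"] += 1
            if best["p"] < entry["p_best"] or (
                best["p"] == entry["p_best"]
                and entry["lead"] is not None
                and (best["pos"], best["variant_id"])
                < (entry["lead"]["pos"], entry["lead"]["variant_id"])
            ):
                entry["p_best"] = float(best["p"])
                entry["lead"] = best
                entry["lead_run"] = run_id
    rows = []
    for region_id, entry in per_region.items():
        lead = entry["lead"]
        rows.append(
            {
                "region_id": region_id,
                "p_best": entry["p_best"] if lead is not None else np.nan,
                "count": entry["count"],
                "lead_variant_id": None if lead is None else lead["variant_id"],
                "lead_phenotype_id": None if lead is None else lead["phenotype_id"],
                "lead_run_id": None if lead is None else entry.get("lead_run"),
                "chrom": None if lead is None else lead["chrom"],
                "pos": None if lead is None else int(lead["pos"]),
                "ea": None if lead is None else lead["ea"],
                "nea": None if lead is None else lead["nea"],
                "eaf": None if lead is None else float(lead["eaf"]),
                "beta_hat": None if lead is None else float(lead["beta_hat"]),
                "se": None if lead is None else float(lead["se"]),
                "n_runs": len(run_ids),
            }
        )
    return pd.DataFrame(rows)


def classify_loci(
    region_stats: pd.DataFrame,
    p_sw: float,
    p_gw: float = 5e-8,
    suggestive_min_count: int = 5,
) -> pd.DataFrame:
    """Attach the significant/suggestive/non-significant classification."""
    out = region_stats.copy()
    p_best = out["p_best"].to_numpy(float)
    count = out["count"].to_numpy(int)
    cls = np.where(
        p_best < p_sw,
        "significant",
        np.where(
            (p_best < p_gw) & (count >= suggestive_min_count),
            "suggestive",
            "non_significant",
        ),
    )
    cls = np.where(np.isnan(p_best), "non_significant", cls)
    out["classification"] = cls
    out["p_sw"] = p_sw
    out["p_gw"] = p_gw
    return out


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def annotate_nearest_gene(loci: pd.DataFrame, genes: pd.DataFrame | None) -> pd.DataFrame:
    """Nearest gene (by TSS distance, strand-aware) for each lead variant.

    Gene table columns: gene, chrom, tss, tes, strand. The distance is signed
    (variant pos minus TSS) and set to 0 when the variant lies inside the
    gene body. Rows without a lead variant are left unannotated.
    """
    out = loci.copy()
    out["nearest_gene"] = None
    out["distance_to_tss"] = np.nan
    out["distance_to_tes"] = np.nan
    if genes is None or len(genes) == 0:
        warnings.warn("empty gene table; nearest-gene annotation skipped")
        return out
    g = genes.copy()
    g["chrom"] = g["chrom"].astype(str)
    for i, row in out.iterrows():
        if row["lead_variant_id"] is None or pd.isna(row["lead_variant_id"]):
            continue
        cand = g[g["chrom"] == str(row["chrom"])]
        if cand.empty:
            continue
        pos = int(row["pos"])
        tss = cand["tss"].to_numpy(int)
        tes = cand["tes"].to_numpy(int)
        lo = np.minimum(tss, tes)
        hi = np.maximum(tss, tes)
        inside = (pos >= lo) & (pos <= hi)
        d_tss = pos - tss
        dist = np.where(inside, 0, np.abs(d_tss))
        j = int(np.argmin(dist))
        out.at[i, "nearest_gene"] = cand.iloc[j]["gene"]
        out.at[i, "distance_to_tss"] = 0 if inside[j] else int(d_tss[j])
        out.at[i, "distance_to_tes"] = 0 if inside[j] else int(pos - tes[j])
    return out
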