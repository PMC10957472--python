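"""Ensemble aggregation: run selection, pooling/dedup, thresholds, region
hit counting, locus classification and gene annotation."""

import numpy as np
import pandas as pd
import pytest

from upekit.coma.train import RunResult
from upekit.upe import (
    EnsembleConfig,
    RegionPartition,
    annotate_nearest_gene,
    assign_regions,
    bonferroni_threshold,
    classify_loci,
    count_region_hits,
    pool_and_deduplicate,
    select_runs,
    study_wide_threshold,
)


def _run(rmsd):
    return RunResult(
        run_id=f"r{rmsd}", config=None, subject_ids=[], latents=np.zeros((1, 1)),
        per_subject_rmsd=np.zeros(1), test_rmsd_mean=rmsd,
    )


def _partition(n=4, length=1000):
    return RegionPartition(
        pd.DataFrame(
            {
                "region_id": [f"R{i+1}" for i in range(n)],
                "chrom": "1",
                "start": np.arange(n) * length,
                "end": (np.arange(n) + 1) * length,
            }
        )
    )


def _sumstats(rows):
    """rows: (phenotype_id, variant_id, pos, p)"""
    return pd.DataFrame(
        [
            {
                "phenotype_id": ph, "variant_id": vid, "chrom": "1", "pos": pos,
                "ea": "A", "nea": "G", "eaf": 0.3, "beta_hat": 0.1, "se": 0.02,
                "t_stat": 5.0, "p": p, "n": 100,
            }
            for ph, vid, pos, p in rows
        ]
    )


class TestSelectRuns:
    def test_strict_one_mm_rule(self):
        runs = [_run(0.8), _run(1.2), _run(0.99)]
        kept = select_runs(runs, 1.0)
        assert [r.test_rmsd_mean for r in kept] == [0.8, 0.99]

    def test_boundary_exactly_one_mm_excluded(self):
        assert select_runs([_run(1.0), _run(0.5)], 1.0)[0].test_rmsd_mean == 0.5

    def test_all_above_threshold_errors(self):
        with pytest.raises(ValueError):
            select_runs([_run(1.5), _run(2.0)], 1.0)


class TestPoolAndDeduplicate:
    def test_duplicated_column_dropped_once(self, rng):
        a = rng.standard_normal((50, 3))
        b = rng.standard_normal((50, 2))
        b[:, 0] = a[:, 1]
        pooled, prov, log = pool_and_deduplicate({"r1": a, "r2": b})
        assert pooled.shape[1] == 4
        assert len(log) == 1
        kept_cols = {p for p in prov}
        assert ("r1", 1) in kept_cols or ("r2", 0) in kept_cols
        assert not (("r1", 1) in kept_cols and ("r2", 0) in kept_cols)

    def test_negated_column_dropped_by_absolute_rule(self, rng):
        a = rng.standard_normal((40, 2))
        b = -a[:, [0]]
        pooled, _, log = pool_and_deduplicate({"r1": a, "r2": b})
        assert pooled.shape[1] == 2
        assert len(log) == 1

    def test_independent_columns_survive(self, rng):
        z = rng.standard_normal((500, 50))
        pooled, prov, log = pool_and_deduplicate({"r1": z})
        assert pooled.shape[1] == 50 and not log

    def test_never_drops_both_members(self, rng):
        a = rng.standard_normal((30, 1))
        blocks = {"r1": a, "r2": a.copy(), "r3": a.copy()}
        pooled, prov, _ = pool_and_deduplicate(blocks)
        assert pooled.shape[1] >= 1

    def test_drop_later_mode_deterministic(self, rng):
        a = rng.standard_normal((30, 2))
        blocks = {"r1": a, "r2": a[:, [0]]}
        _, prov, _ = pool_and_deduplicate(blocks, dedup_mode="drop-later")
        assert ("r1", 0) in prov and ("r2", 0) not in prov

    def test_small_cohort_rejected(self, rng):
        with pytest.raises(ValueError):
            pool_and_deduplicate({"r1": rng.standard_normal((5, 2))})


class TestThresholds:
    def test_study_wide_values(self):
        assert study_wide_threshold(5e-8, 324) == pytest.approx(1.543e-10, rel=1e-3)
        assert study_wide_threshold(5e-8, 16) == pytest.approx(3.125e-9, rel=1e-12)
        assert study_wide_threshold(0.123, 1) == 0.123

    def test_bonferroni_values(self):
        assert bonferroni_threshold(0.05, 324 * 68919) == pytest.approx(2.239e-9, rel=1e-3)
        assert bonferroni_threshold(0.05, 324 * 187535) == pytest.approx(8.229e-10, rel=1e-3)
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            study_wide_threshold(5e-8, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestAssignRegions:
    def test_half_open_boundaries(self):
        part = _partition(2, 1000)
        t = _sumstats(
            [("p1", "v1", 0, 0.5), ("p1", "v2", 999, 0.5), ("p1", "v3", 1000, 0.5),
             ("p1", "v4", 2000, 0.5)]
        )
        got = assign_regions(t, part)
        assert list(got[:3]) == ["R1", "R1", "R2"]
        assert pd.isna(got.iloc[3])  # pos = end of last region: outside

    def test_matches_linear_scan_oracle(self, rng):
        part = _partition(6, 500)
        pos = rng.integers(0, 3500, 200)
        t = _sumstats([("p1", f"v{i}", int(p), 0.5) for i, p in enumerate(pos)])
        got = assign_regions(t, part)
        for i, p in enumerate(pos):
            expected = None
            for _, reg in part.regions.iterrows():
                if reg["start"] <= p < reg["end"]:
                    expected = reg["region_id"]
            if expected is None:
                assert pd.isna(got.iloc[i])
            else:
                assert got.iloc[i] == expected

    def test_malformed_chromosomes_rejected(self):
        t = _sumstats([("p1", "v1", 10, 0.5)])
        t["chrom"] = "weird!!"
        with pytest.raises(ValueError):
            assign_regions(t, _partition())

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError):
            RegionPartition(
                pd.DataFrame(
                    {"region_id": ["a", "b"], "chrom": "1", "start": [0, 500], "end": [1000, 1500]}
                )
            )


class TestCountRegionHits:
    def test_single_run_single_hit(self):
        tables = {"run1": _sumstats([("p1", "v1", 100, 1e-9), ("p1", "v2", 1100, 0.5)])}
        out = count_region_hits(tables, _partition(2), 5e-8).set_index("region_id")
        assert out.loc["R1", "count"] == 1 and out.loc["R2", "count"] == 0
        assert out.loc["R1", "p_best"] == 1e-9
        assert out.loc["R1", "lead_variant_id"] == "v1"

    def test_subthreshold_run_not_counted(self):
        tables = {
            "run1": _sumstats([("p1", "v1", 100, 1e-9)]),
            "run2": _sumstats([("p2", "v1", 100, 1e-7)]),
        }
        out = count_region_hits(tables, _partition(1), 5e-8).set_index("region_id")
        assert out.loc["R1", "count"] == 1
        assert out.loc["R1", "p_best"] == 1e-9

    def test_min_over_phenotypes_within_run(self):
        tables = {
            "run1": _sumstats(
                [("p1", "v1", 100, 1e-6), ("p2", "v2", 200, 1e-10), ("p3", "v3", 300, 1e-9)]
            )
        }
        out = count_region_hits(tables, _partition(1), 5e-8).set_index("region_id")
        assert out.loc["R1", "count"] == 1
        assert out.loc["R1", "lead_variant_id"] == "v2"
        assert out.loc["R1", "lead_phenotype_id"] == "p2"

    def test_matches_triple_loop_oracle(self, rng):
        part = _partition(5, 400)
        run_tables = {}
        for r in range(3):
            rows = []
            for k in range(2):
                for i in range(60):
                    pos = int(rng.integers(0, 2000))
                    rows.append((f"r{r}p{k}", f"v{i}", pos, float(10 ** -rng.uniform(0, 10))))
            run_tables[f"run{r}"] = _sumstats(rows)
        got = count_region_hits(run_tables, part, 5e-8).set_index("region_id")
        # brute force: loop regions x runs x rows
        for _, reg in part.regions.iterrows():
            p_best = np.inf
            count = 0
            for rid, t in run_tables.items():
                in_reg = t[(t["pos"] >= reg["start"]) & (t["pos"] < reg["end"])]
                if len(in_reg) == 0:
                    continue
                p_lr = in_reg["p"].min()
                if p_lr < 5e-8:
                    count += 1
                p_best = min(p_best, p_lr)
            row = got.loc[reg["region_id"]]
            assert row["count"] == count
            if np.isfinite(p_best):
                assert row["p_best"] == pytest.approx(p_best, rel=1e-12)

    def test_count_monotone_in_threshold(self, rng):
        part = _partition(3, 700)
        tables = {
            f"run{r}": _sumstats(
                [(f"p{r}", f"v{i}", int(rng.integers(0, 2100)), float(10 ** -rng.uniform(0, 9)))
                 for i in range(40)]
            )
            for r in range(4)
        }
        loose = count_region_hits(tables, part, 5e-6)["count"]
        tight = count_region_hits(tables, part, 5e-10)["count"]
        assert (tight <= loose).all()
        assert (loose <= 4).all()


class TestClassifyLoci:
    def _stats(self, p_best, count):
        return pd.DataFrame(
            {
                "region_id": [f"R{i}" for i in range(len(p_best))],
                "p_best": p_best,
                "count": count,
            }
        )

    def test_rules(self):
        p_sw = 1.5e-10
        out = classify_loci(
            self._stats([1e-11, 1e-9, 1e-9, 0.5], [1, 6, 2, 0]), p_sw, 5e-8, 5
        )
        assert list(out["classification"]) == [
            "significant", "suggestive", "non_significant", "non_significant",
        ]

    def test_threshold_monotonicity(self, rng):
        p = 10 ** -rng.uniform(0, 12, 30)
        c = rng.integers(0, 10, 30)
        strict = classify_loci(self._stats(p, c), 1e-10, 5e-8, 5)
        weak = classify_loci(self._stats(p, c), 1e-8, 5e-8, 5)
        for s, w in zip(strict["classification"], weak["classification"]):
            if s == "significant":
                assert w == "significant"


class TestAnnotateNearestGene:
    def _loci(self, pos):
        return pd.DataFrame(
            {
                "region_id": ["R1"], "p_best": [1e-9], "count": [1],
                "lead_variant_id": ["v1"], "chrom": ["1"], "pos": [pos],
            }
        )

    def _genes(self):
        return pd.DataFrame(
            {
                "gene": ["G1", "G2"],
                "chrom": ["1", "1"],
                "tss": [1000, 9000],
                "tes": [3000, 7000],
                "strand": ["+", "-"],
            }
        )

    def test_variant_at_tss(self):
        out = annotate_nearest_gene(self._loci(1000), self._genes())
        assert out["nearest_gene"].iloc[0] == "G1"
        assert out["distance_to_tss"].iloc[0] == 0

    def test_variant_inside_gene_body(self):
        out = annotate_nearest_gene(self._loci(2500), self._genes())
        assert out["nearest_gene"].iloc[0] == "G1"
        assert out["distance_to_tss"].iloc[0] == 0

    def test_negative_strand_tss(self):
        out = annotate_nearest_gene(self._loci(8800), self._genes())
        assert out["nearest_gene"].iloc[0] == "G2"
        assert out["distance_to_tss"].iloc[0] == 0  # inside body [7000, 9000]

    def test_matches_exhaustive_oracle(self, rng):
        genes = pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(20)],
                "chrom": "1",
                "tss": rng.integers(0, 100000, 20),
                "tes": rng.integers(0, 100000, 20),
                "strand": "+",
            }
        )
        for pos in rng.integers(0, 100000, 25):
            out = annotate_nearest_gene(self._loci(int(pos)), genes)
            lo = np.minimum(genes["tss"], genes["tes"])
            hi = np.maximum(genes["tss"], genes["tes"])
            inside = (pos >= lo) & (pos <= hi)
            dist = np.where(inside, 0, np.abs(pos - genes["tss"]))
            assert dist[int(np.argmin(dist))] == (
                0 if out["distance_to_tss"].iloc[0] == 0
                else abs(out["distance_to_tss"].iloc[0])
            )

    def test_empty_gene_table_warns(self):
        with pytest.warns(UserWarning):
            out = annotate_nearest_gene(self._loci(100), None)
        assert out["nearest_gene"].iloc[0] is None


def test_ensemble_config_validation():
    with pytest.raises(ValueError):
        EnsembleConfig(p_gw=0.0)
    with pytest.raises(ValueError):
        EnsembleConfig(spearman_max=1.5)
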