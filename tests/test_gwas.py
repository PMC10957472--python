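"""Genotype QC, rank-INT adjustment and the linear association scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from upekit.gwas import (
    MISSING,
    GenotypeMatrix,
    adjust_phenotype,
    effect_allele_frequency,
    hwe_exact_test,
    hwe_from_dosages,
    linear_scan,
    minor_allele_frequency,
    rank_inverse_normal,
    read_genotypes_tsv,
    read_sumstats,
    variant_qc,
    write_sumstats,
)


def _geno(doses, info=None, chrom=None):
    doses = np.atleast_2d(np.asarray(doses, float))
    v, n = doses.shape
    meta = pd.DataFrame(
        {
            "variant_id": [f"v{i+1}" for i in range(v)],
            "chrom": chrom or ["1"] * v,
            "pos": np.arange(1, v + 1) * 100,
            "ea": "A",
            "nea": "G",
            "info": info if info is not None else [1.0] * v,
        }
    )
    return GenotypeMatrix(doses, meta, [f"s{j+1}" for j in range(n)])


class TestAlleleFrequency:
    def test_all_heterozygote(self):
        assert effect_allele_frequency(np.ones(10)) == 0.5

    def test_small_example(self):
        assert effect_allele_frequency(np.array([0.0, 0.0, 1.0, 2.0])) == 0.375

    def test_missing_handled_by_allele_counting_oracle(self, rng):
        doses = rng.integers(0, 3, 50).astype(float)
        doses[rng.choice(50, 10, replace=False)] = MISSING
        ok = doses != MISSING
        oracle = doses[ok].sum() / (2 * ok.sum())
        assert effect_allele_frequency(doses) == pytest.approx(oracle, rel=1e-12)
        assert minor_allele_frequency(doses) == pytest.approx(min(oracle, 1 - oracle))

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            effect_allele_frequency(np.full(5, MISSING))


def _hwe_enumeration_oracle(n_hom1, n_het, n_hom2):
    """Full enumeration over admissible heterozygote counts."""
    from math import comb, factorial

    n = n_hom1 + n_het + n_hom2
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    n_common = 2 * n - n_rare

    def prob(h):
        hr = (n_rare - h) // 2
        hc = n - h - hr
        return (
            2**h * factorial(n) / (factorial(h) * factorial(hr) * factorial(hc))
        ) * factorial(n_rare) * factorial(n_common) / factorial(2 * n)

    hets = range(n_rare % 2, min(n_rare, n_common) + 1, 2)
    probs = {h: prob(h) for h in hets}
    obs = probs[n_het]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-12))


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(5, 0, 0) == 1.0

    @pytest.mark.parametrize(
        "counts", [(1, 2, 1), (5, 10, 5), (20, 5, 3), (0, 4, 0), (7, 1, 7)]
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            _hwe_enumeration_oracle(*counts), rel=1e-10
        )

    @pytest.mark.parametrize("counts", [(1, 2, 1), (8, 4, 2), (3, 9, 14)])
    def test_symmetric_in_homozygotes(self, counts):
        a, h, b = counts
        assert hwe_exact_test(a, h, b) == pytest.approx(hwe_exact_test(b, h, a), rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    def test_null_calibration(self, rng):
        """Under random mating the exact-test p-values are superuniform:
        P(p <= a) <= a approximately, checked at a = 0.05 over 400 variants."""
        n = 300
        hits = 0
        for _ in range(400):
            p = 0.3
            alleles = rng.random((n, 2)) < p
            g = alleles.sum(axis=1)
            counts = np.bincount(g, minlength=3)
            if hwe_exact_test(*counts) < 0.05:
                hits += 1
        assert hits / 400 < 0.08


class TestVariantQc:
    def test_exactly_the_violating_variants_are_dropped(self, rng):
        n = 400
        good = rng.binomial(2, 0.3, (3, n)).astype(float)
        rare = rng.binomial(2, 0.004, n).astype(float)          # MAF < 1%
        lowinfo = rng.binomial(2, 0.3, n).astype(float)          # info 0.29
        hwe_bad = np.ones(n)                                     # all het
        doses = np.vstack([good, rare[None], lowinfo[None], hwe_bad[None]])
        info = [1.0, 1.0, 1.0, 1.0, 0.29, 1.0]
        gm = _geno(doses, info=info)
        keep, report = variant_qc(gm)
        assert list(keep) == [True, True, True, False, False, False]
        # recount oracle
        for i in range(6):
            maf = minor_allele_frequency(doses[i])
            hwe = hwe_from_dosages(doses[i])
            expected = maf >= 0.01 and hwe >= 1e-5 and info[i] >= 0.3
            assert keep[i] == expected
        assert (report["keep"] == keep).all()

    def test_boundary_info_score(self, rng):
        doses = rng.binomial(2, 0.4, (2, 200)).astype(float)
        gm = _geno(doses, info=[0.3, 0.299999])
        keep, _ = variant_qc(gm)
        assert list(keep) == [True, False]


class TestAdjustPhenotype:
    def test_preserves_rank_order_without_covariates(self, rng):
        raw = rng.standard_normal(100)
        out = adjust_phenotype(raw, None)
        assert (np.argsort(out) == np.argsort(raw)).all()

    def test_output_standardized(self, rng):
        raw = rng.exponential(3.0, 500)
        cov = rng.standard_normal((500, 3))
        out = adjust_phenotype(raw + cov @ [1.0, -2.0, 0.5], cov)
        assert abs(out.mean()) < 0.02
        assert abs(out.var() - 1) < 0.05

    def test_invariant_under_monotone_transform(self, rng):
        raw = rng.random(200)
        np.testing.assert_allclose(
            adjust_phenotype(raw, None), adjust_phenotype(np.exp(5 * raw), None), atol=1e-12
        )

    def test_idempotent_up_to_ties(self, rng):
        raw = rng.standard_normal(300)
        cov = rng.standard_normal((300, 2))
        once = adjust_phenotype(raw, cov)
        twice = adjust_phenotype(once, cov)
        assert np.corrcoef(once, twice)[0, 1] > 0.999

    def test_collinear_covariates_named(self, rng):
        cov = rng.standard_normal((50, 2))
        cov = np.column_stack([cov, cov[:, 0] * 2.0])
        with pytest.raises(ValueError, match="collinear"):
            adjust_phenotype(rng.standard_normal(50), cov)

    def test_blom_offsets(self):
        out = rank_inverse_normal(np.array([3.0, 1.0, 2.0]))
        expected = stats.norm.ppf((np.array([3, 1, 2]) - 0.375) / 3.25)
        np.testing.assert_allclose(out, expected)


class TestLinearScan:
    def test_constant_score_gives_null(self, rng):
        gm = _geno(rng.binomial(2, 0.4, (3, 30)).astype(float))
        out = linear_scan(np.ones((30, 1)), gm)
        assert (out["beta_hat"] == 0).all()
        assert (out["p"] == 1.0).all()

    def test_perfect_fit_floors_p(self, rng):
        doses = rng.binomial(2, 0.5, (1, 40)).astype(float)
        gm = _geno(doses)
        score = (doses[0] - doses[0].mean()) / doses[0].std()
        out = linear_scan(score[:, None], gm)
        assert out["p"].iloc[0] > 0
        assert out["p"].iloc[0] <= 1e-300

    def test_closed_form_oracle_n8(self):
        """Hand-computable n = 8 case against normal-equation OLS + t CDF."""
        x = np.array([0, 1, 2, 0, 1, 2, 1, 0], float)
        y = np.array([0.3, 0.5, 1.1, -0.2, 0.4, 0.9, 0.6, 0.1])
        gm = _geno(x[None])
        out = linear_scan(y[:, None], gm)
        design = np.column_stack([np.ones(8), x])
        coef, res_ss, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(np.sum((y - design @ coef) ** 2))
        sxx = np.sum((x - x.mean()) ** 2)
        se = np.sqrt(rss / 6 / sxx)
        t = coef[1] / se
        p = 2 * stats.t.sf(abs(t), 6)
        assert out["beta_hat"].iloc[0] == pytest.approx(coef[1], rel=1e-10)
        assert out["se"].iloc[0] == pytest.approx(se, rel=1e-10)
        assert out["t_stat"].iloc[0] == pytest.approx(t, rel=1e-10)
        assert out["p"].iloc[0] == pytest.approx(p, rel=1e-10)

    def test_internal_consistency_invariants(self, rng):
        gm = _geno(rng.binomial(2, 0.3, (20, 100)).astype(float))
        scores = rng.standard_normal((100, 3))
        out = linear_scan(scores, gm).dropna()
        np.testing.assert_allclose(out["t_stat"], out["beta_hat"] / out["se"], rtol=1e-8)
        np.testing.assert_allclose(
            out["p"], 2 * stats.t.sf(np.abs(out["t_stat"]), 98), rtol=1e-8
        )
        assert (out["p"] > 0).all() and (out["p"] <= 1).all()
        assert (out["se"] > 0).all()

    def test_allele_flip_symmetry(self, rng):
        doses = rng.binomial(2, 0.3, (5, 80)).astype(float)
        scores = rng.standard_normal((80, 2))
        out1 = linear_scan(scores, _geno(doses))
        out2 = linear_scan(scores, _geno(2.0 - doses))
        np.testing.assert_allclose(out1["beta_hat"], -out2["beta_hat"], atol=1e-10)
        np.testing.assert_allclose(out1["eaf"], 1.0 - out2["eaf"], atol=1e-12)
        np.testing.assert_allclose(out1["p"], out2["p"], rtol=1e-10)

    def test_missing_doses_mean_imputed(self, rng):
        doses = rng.binomial(2, 0.4, (1, 60)).astype(float)
        holes = rng.choice(60, 10, replace=False)
        with_missing = doses.copy()
        with_missing[0, holes] = MISSING
        imputed = doses.copy()
        imputed[0, holes] = with_missing[0, with_missing[0] != MISSING].mean()
        scores = rng.standard_normal((60, 1))
        out1 = linear_scan(scores, _geno(with_missing))
        out2 = linear_scan(scores, _geno(imputed))
        assert out1["beta_hat"].iloc[0] == pytest.approx(out2["beta_hat"].iloc[0], rel=1e-10)

    def test_null_fraction_within_binomial_interval(self, rng):
        """Independent genotypes and INT phenotype: fraction of p < 0.05 within
        the exact binomial 99% interval around 0.05 and KS-uniform."""
        n, v = 300, 800
        gm = _geno(rng.binomial(2, 0.3, (v, n)).astype(float))
        score = adjust_phenotype(rng.standard_normal(n), None)
        out = linear_scan(score[:, None], gm)
        frac = (out["p"] < 0.05).mean()
        lo, hi = stats.binom.ppf([0.005, 0.995], v, 0.05) / v
        assert lo <= frac <= hi
        assert stats.kstest(out["p"], "uniform").pvalue > 0.01


def test_sumstats_roundtrip_and_tsv_genotypes(tmp_path, rng):
    gm = _geno(rng.binomial(2, 0.3, (4, 25)).astype(float))
    table = linear_scan(rng.standard_normal((25, 2)), gm)
    write_sumstats(table, tmp_path / "s.tsv.gz")
    back = read_sumstats(tmp_path / "s.tsv.gz")
    np.testing.assert_allclose(back["p"], table["p"], rtol=1e-12)

    dos = pd.DataFrame(gm.dosages, index=gm.variants["variant_id"], columns=gm.subject_ids)
    dos.index.name = "variant_id"
    dos.to_csv(tmp_path / "d.tsv", sep="\t")
    gm.variants.to_csv(tmp_path / "v.tsv", sep="\t", index=False)
    back_gm = read_genotypes_tsv(tmp_path / "d.tsv", tmp_path / "v.tsv")
    np.testing.assert_array_equal(back_gm.dosages, gm.dosages)
    assert back_gm.subject_ids == gm.subject_ids
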