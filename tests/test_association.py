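"""Phenotype preparation, kinship, EMMAX scan, meta-analysis, ACAT."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twaskit.association import (
    EmmaxScan,
    acat_combine,
    compute_kinship,
    lmm_association,
    meta_analyze,
    meta_analyze_table,
    prepare_phenotype,
)
from twaskit.datatypes import GenotypeMatrix, TwasResult


def _raw_pheno(n, seed=0):
    rng = np.random.default_rng(seed)
    d = pd.DataFrame(
        {
            "age": rng.uniform(25, 75, n),
            "sex": rng.integers(0, 2, n).astype(float),
            **{f"PC{i}": rng.standard_normal(n) for i in range(1, 11)},
            "HGB": rng.normal(13.5, 1.4, n),
            "HCT": rng.normal(40, 3.5, n),
            "WBC": np.exp(rng.normal(np.log(6.5), 0.35, n)),
            "PLT": rng.normal(250, 60, n),
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="sample"),
    )
    return d


class TestPreparePhenotype:
    def test_exclusion_bounds_are_strict(self):
        raw = _raw_pheno(200, seed=1)
        raw.loc["s0", "WBC"] = 250.0
        raw.loc["s1", "WBC"] = 200.0  # exactly at the bound -> retained
        raw.loc["s2", "HCT"] = 61.0
        raw.loc["s3", "HCT"] = 60.0
        raw.loc["s4", "HGB"] = 21.0
        with pytest.warns(UserWarning, match="Duffy"):
            wbc = prepare_phenotype(raw, "WBC")
        hct = prepare_phenotype(raw, "HCT")
        hgb = prepare_phenotype(raw, "HGB")
        assert "s0" not in wbc.values.index and "s1" in wbc.values.index
        assert "s2" not in hct.values.index and "s3" in hct.values.index
        assert "s4" not in hgb.values.index
        assert set(wbc.excluded["sample"]) == {"s0"}
        # platelets have no exclusion bound
        raw.loc["s5", "PLT"] = 2000.0
        assert "s5" in prepare_phenotype(raw, "PLT").values.index

    def test_residuals_are_standard_normal(self):
        raw = _raw_pheno(300, seed=2)
        adj = prepare_phenotype(raw, "HGB")
        v = adj.values.to_numpy()
        assert abs(v.mean()) < 1e-8
        assert stats.kstest(v, "norm").pvalue > 0.01

    def test_wbc_log_transform_and_duffy_covariate(self):
        n = 400
        raw = _raw_pheno(n, seed=3)
        rng = np.random.default_rng(4)
        duffy = pd.Series(rng.binomial(2, 0.4, n).astype(float), index=raw.index)
        raw["WBC"] = raw["WBC"] * np.exp(-0.5 * duffy)
        adj = prepare_phenotype(raw, "WBC", duffy_dosage=duffy)
        r_adj = np.corrcoef(adj.values.reindex(raw.index).to_numpy(), duffy)[0, 1]
        assert abs(r_adj) < 0.05
        with pytest.warns(UserWarning):
            un = prepare_phenotype(raw, "WBC")
        r_un = np.corrcoef(un.values.reindex(raw.index).to_numpy(), duffy)[0, 1]
        assert abs(r_un) > abs(r_adj)

    def test_unknown_trait_rejected(self):
        with pytest.raises(ValueError, match="unknown trait"):
            prepare_phenotype(_raw_pheno(50), "RBC")


def _geno(n, m, seed=0):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.5, m)
    variants = pd.DataFrame(
        {"id": [f"v{i}" for i in range(m)], "chrom": "1",
         "pos": 1000 + np.arange(m), "ref": "A", "alt": "G", "imput_rsq": 0.9}
    )
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)], variants=variants,
        dosage=rng.binomial(2, p, size=(n, m)).astype(float),
        population=np.array(["X"] * n),
    )


class TestKinship:
    def test_matches_naive_double_loop(self):
        gm = _geno(5, 120, seed=5)
        K = compute_kinship(gm, maf_min=0.01)
        keep = gm.maf() > 0.01
        X = gm.dosage[:, keep]
        p = X.mean(axis=0) / 2
        Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
        naive = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                naive[i, j] = np.mean(Z[i] * Z[j])
        np.testing.assert_allclose(K, naive, atol=1e-10)

    def test_duplicated_sample_has_offdiagonal_near_diagonal(self):
        gm = _geno(40, 500, seed=6)
        gm2 = GenotypeMatrix(
            samples=gm.samples + ["dup_of_s0"],
            variants=gm.variants,
            dosage=np.vstack([gm.dosage, gm.dosage[[0]]]),
            population=np.append(gm.population, "X"),
        )
        K = compute_kinship(gm2)
        assert K[0, -1] == pytest.approx(K[0, 0], rel=1e-10)

    def test_unrelated_panel_mean_offdiagonal_near_zero(self):
        gm = _geno(100, 1000, seed=7)
        K = compute_kinship(gm)
        off = K[np.triu_indices(100, 1)]
        assert abs(off.mean()) < 0.02
        assert np.linalg.eigvalsh(K).min() > -1e-8

    def test_too_few_variants_rejected(self):
        with pytest.raises(ValueError, match="100 variants"):
            compute_kinship(_geno(10, 50, seed=8))


class TestEmmaxScan:
    def test_identity_kinship_reduces_to_ols(self):
        rng = np.random.default_rng(9)
        n = 200
        y = pd.Series(rng.standard_normal(n), index=[f"s{i}" for i in range(n)])
        g = pd.Series(rng.standard_normal(n), index=y.index)
        res = EmmaxScan(y, np.eye(n)).fit_null().test(g)
        X = np.column_stack([np.ones(n), g])
        coef, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
        r = y.to_numpy() - X @ coef
        s2 = r @ r / (n - 2)
        se = np.sqrt((s2 * np.linalg.inv(X.T @ X))[1, 1])
        z = coef[1] / se
        assert res.beta == pytest.approx(coef[1], abs=1e-6)
        assert res.se == pytest.approx(se, abs=1e-6)
        assert res.p == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-6)

    def test_self_association_is_extreme(self):
        rng = np.random.default_rng(10)
        n = 300
        y = pd.Series(rng.standard_normal(n), index=[f"s{i}" for i in range(n)])
        res = EmmaxScan(y, np.eye(n)).fit_null().test(y)
        assert res.p < 1e-20
        assert res.beta == pytest.approx(1.0, abs=1e-8)

    def test_relatedness_inflates_naive_ols_but_not_lmm(self):
        # phenotype with a strong polygenic component over sib-pair kinship:
        # the mixed model stays calibrated where OLS p-values inflate
        rng = np.random.default_rng(11)
        n, n_sib = 400, 150
        K = np.eye(n)
        for i in range(0, 2 * n_sib, 2):
            K[i, i + 1] = K[i + 1, i] = 0.5
        L = np.linalg.cholesky(K + 1e-9 * np.eye(n))
        idx = [f"s{i}" for i in range(n)]
        n_genes = 150
        count_lmm = count_ols = 0
        for rep in range(8):
            y = pd.Series(2.0 * (L @ rng.standard_normal(n)) + rng.standard_normal(n), index=idx)
            scan = EmmaxScan(y, K).fit_null()
            G = pd.DataFrame(L @ rng.standard_normal((n, n_genes)), index=idx)
            res = scan.test_matrix(G)
            count_lmm += (res["p"] < 0.05).sum()
            ols = EmmaxScan(y, np.eye(n)).fit_null().test_matrix(G)
            count_ols += (ols["p"] < 0.05).sum()
        total = 8 * n_genes
        assert count_lmm / total < 0.08
        assert count_ols > count_lmm

    def test_zero_variance_gene_flagged(self):
        y = pd.Series(np.arange(30.0), index=[f"s{i}" for i in range(30)])
        scan = EmmaxScan(y, np.eye(30)).fit_null()
        with pytest.raises(ValueError, match="zero-variance"):
            scan.test(np.ones(30))
        out = scan.test_matrix(pd.DataFrame({"g": np.ones(30)}, index=y.index))
        assert out["skipped"].iloc[0] == "zero_variance_or_missing"

    def test_non_psd_kinship_rejected(self):
        y = pd.Series(np.arange(10.0), index=[f"s{i}" for i in range(10)])
        K = -np.eye(10)
        with pytest.raises(ValueError, match="positive semi-definite"):
            EmmaxScan(y, K).fit_null()

    def test_lmm_association_aligns_samples(self):
        rng = np.random.default_rng(12)
        n = 60
        idx = [f"s{i}" for i in range(n)]
        y = pd.Series(rng.standard_normal(n), index=idx)
        g = pd.Series(rng.standard_normal(n), index=idx[::-1])  # reversed order
        res = lmm_association(g, y, np.eye(n), gene_id="G")
        res2 = EmmaxScan(y, np.eye(n)).fit_null().test(g.reindex(idx), gene_id="G")
        assert res.beta == pytest.approx(res2.beta)


class TestMeta:
    def test_hand_computed_inverse_variance(self):
        a = TwasResult("g", "HGB", "c1", 0.2, 0.1, 0.05, 100)
        b = TwasResult("g", "HGB", "c2", -0.1, 0.2, 0.5, 100)
        m = meta_analyze([a, b])
        assert m.beta == pytest.approx(0.14, abs=1e-10)
        assert m.se == pytest.approx(np.sqrt(1 / (1 / 0.01 + 1 / 0.04)), abs=1e-10)
        assert m.direction == "(+-)"

    def test_symmetric_cohorts(self):
        a = TwasResult("g", "HGB", "c1", 0.1, 0.1, 0.3, 50)
        b = TwasResult("g", "HGB", "c2", 0.1, 0.1, 0.3, 50)
        m = meta_analyze([a, b])
        assert m.beta == pytest.approx(0.1)
        assert m.se == pytest.approx(0.1 / np.sqrt(2))

    def test_single_cohort_passthrough_and_missing_marker(self):
        a = TwasResult("g", "HGB", "c1", 0.2, 0.1, 0.045, 100)
        m = meta_analyze([a, None])
        assert (m.beta, m.se) == (pytest.approx(0.2), pytest.approx(0.1))
        assert m.direction == "(+?)"
        with pytest.raises(ValueError, match="all cohorts missing"):
            meta_analyze([None, None])

    def test_split_cohort_recovers_pooled_z(self):
        rng = np.random.default_rng(13)
        n = 2000
        idx = [f"s{i}" for i in range(n)]
        g = pd.Series(rng.standard_normal(n), index=idx)
        y = pd.Series(0.1 * g + rng.standard_normal(n), index=idx)
        pooled = EmmaxScan(y, np.eye(n)).fit_null().test(g, gene_id="g")
        halves = []
        for lo, hi in [(0, n // 2), (n // 2, n)]:
            yy, gg = y.iloc[lo:hi], g.iloc[lo:hi]
            halves.append(EmmaxScan(yy, np.eye(hi - lo)).fit_null().test(gg, gene_id="g"))
        m = meta_analyze(halves)
        z_pool, z_meta = pooled.beta / pooled.se, m.beta / m.se
        assert abs(z_meta - z_pool) / abs(z_pool) < 0.02

    def test_table_grouping(self):
        df = pd.DataFrame(
            [
                {"gene_id": "g", "trait": "HGB", "cohort": "c1", "beta": 0.2, "se": 0.1, "p": 0.05, "n": 100},
                {"gene_id": "g", "trait": "HGB", "cohort": "c2", "beta": -0.1, "se": 0.2, "p": 0.5, "n": 80},
            ]
        )
        out = meta_analyze_table(df, cohort_order=["c1", "c2"])
        assert out["meta_beta"].iloc[0] == pytest.approx(0.14, abs=1e-10)
        assert out["n"].iloc[0] == 180


class TestAcat:
    def test_equal_p_identity(self):
        assert acat_combine([0.05, 0.05, 0.05]) == pytest.approx(0.05, abs=1e-12)

    def test_single_p_passthrough(self):
        assert acat_combine([0.01]) == pytest.approx(0.01, abs=1e-12)

    def test_matches_high_precision_formula(self):
        import mpmath

        mpmath.mp.dps = 50
        rng = np.random.default_rng(14)
        for _ in range(30):
            k = rng.integers(2, 6)
            ps = rng.uniform(1e-6, 0.999, size=k)
            T = sum(mpmath.tan((mpmath.mpf("0.5") - mpmath.mpf(float(p))) * mpmath.pi) for p in ps) / k
            expected = float(mpmath.mpf("0.5") - mpmath.atan(T) / mpmath.pi)
            assert acat_combine(ps) == pytest.approx(expected, abs=1e-10)

    def test_monotone_in_each_input(self):
        base = acat_combine([0.01, 0.5, 0.9])
        assert acat_combine([0.001, 0.5, 0.9]) < base
        assert acat_combine([0.01, 0.5, 0.5]) < base

    def test_tiny_p_dominates_without_overflow(self):
        p = acat_combine([1e-300, 0.5, 0.9])
        assert 0 < p < 1e-295

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="empty"):
            acat_combine([])
        with pytest.warns(UserWarning, match="clamped"):
            out = acat_combine([0.0, 0.5])
        assert 0 < out < 1
        # missing entries dropped with weight renormalization
        assert acat_combine([0.02, np.nan]) == pytest.approx(0.02, abs=1e-12)
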