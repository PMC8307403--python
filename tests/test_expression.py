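"""Expression normalization and elastic-net training."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twaskit.datatypes import GenotypeMatrix, WeightModel
from twaskit.expression import (
    adjust_expression,
    filter_models,
    rank_inverse_normal,
    read_weights,
    select_cis_variants,
    train_elastic_net,
    write_weights,
)


def _covariates(n, rng):
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, n).astype(float),
            "age": rng.uniform(30, 70, n),
            "age2": 0.0,  # filled below
            "PC1": rng.standard_normal(n),
            "PC2": rng.standard_normal(n),
        },
        index=[f"s{i}" for i in range(n)],
    ).assign(age2=lambda d: d["age"] ** 2)


class TestAdjustExpression:
    def test_linear_covariate_signal_removed(self):
        rng = np.random.default_rng(0)
        n = 300
        cov = _covariates(n, rng)
        # expression exactly linear in covariates -> residuals ~ 0 pre-transform
        E = pd.DataFrame(
            {"g1": 2.0 * cov["age"] - cov["sex"], "g2": 0.5 * cov["PC1"] + 3},
            index=cov.index,
        )
        X = np.column_stack([np.ones(n), cov.to_numpy()])
        coef, *_ = np.linalg.lstsq(X, E.to_numpy(), rcond=None)
        resid = E.to_numpy() - X @ coef
        assert np.abs(resid).max() < 1e-8

    def test_output_columns_are_standard_normal(self):
        rng = np.random.default_rng(1)
        n = 300
        cov = _covariates(n, rng)
        E = pd.DataFrame(rng.exponential(size=(n, 4)), index=cov.index, columns=list("abcd"))
        adj = adjust_expression(E, cov, n_hidden_factors=0)
        for c in adj.columns:
            stat, p = stats.kstest(adj[c], "norm")
            assert p > 0.01
            assert abs(adj[c].mean()) < 0.05

    def test_injected_batch_factor_removed(self):
        # hidden-factor step should absorb a batch loading on half the genes;
        # oracle = direct residualization on the known batch label
        rng = np.random.default_rng(2)
        n, p = 400, 30
        cov = _covariates(n, rng)
        batch = rng.integers(0, 2, n).astype(float)
        E = rng.standard_normal((n, p))
        E[:, : p // 2] += 3.0 * batch[:, None]
        E = pd.DataFrame(E, index=cov.index, columns=[f"g{i}" for i in range(p)])
        adj = adjust_expression(E, cov, n_hidden_factors=2)
        cors = [abs(np.corrcoef(adj.iloc[:, j], batch)[0, 1]) for j in range(p // 2)]
        assert max(cors) < 0.1
        # oracle check: explicit residualization achieves the same suppression
        X = np.column_stack([np.ones(n), batch])
        coef, *_ = np.linalg.lstsq(X, E.to_numpy(), rcond=None)
        oracle = E.to_numpy() - X @ coef
        oracle_cors = [abs(np.corrcoef(oracle[:, j], batch)[0, 1]) for j in range(p // 2)]
        assert max(oracle_cors) < 0.1

    def test_errors(self):
        rng = np.random.default_rng(3)
        cov = _covariates(50, rng)
        E = pd.DataFrame(rng.standard_normal((50, 2)), index=cov.index, columns=["a", "b"])
        with pytest.raises(ValueError, match="n_hidden_factors"):
            adjust_expression(E, cov, n_hidden_factors=50)
        bad = cov.copy()
        bad["dup"] = bad["age"]
        with pytest.raises(ValueError, match="rank-deficient"):
            adjust_expression(E, bad, n_hidden_factors=0)


class TestSelectCisVariants:
    @pytest.fixture(scope="class")
    def setup(self):
        rng = np.random.default_rng(5)
        n, m = 120, 8
        dosage = rng.integers(0, 3, size=(n, m)).astype(float)
        # v5 duplicates v4 exactly; v6 rare; v7 poorly imputed
        dosage[:, 5] = dosage[:, 4]
        dosage[:, 6] = (rng.random(n) < 0.04).astype(float)
        variants = pd.DataFrame(
            {
                "id": [f"v{i}" for i in range(m)],
                "chrom": "1",
                "pos": [1_200_000, 1_500_000, 2_050_000, 3_050_000, 2_060_000, 2_070_000,
                        2_080_000, 2_090_000],
                "ref": ["A"] * m,
                "alt": ["G"] * m,
                "imput_rsq": [0.9, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9, 0.2],
            }
        )
        gm = GenotypeMatrix(
            samples=[f"s{i}" for i in range(n)], variants=variants, dosage=dosage,
            population=np.array(["A"] * n),
        )
        gene = pd.Series({"gene_id": "G", "chrom": "1", "start": 2_000_000, "end": 2_100_000})
        return gm, gene

    def test_window_is_one_megabase_around_gene_body(self, setup):
        gm, gene = setup
        ids = select_cis_variants(gene, gm, maf_min=0.0, rsq_min=0.0)
        assert "v0" in ids  # 1.2 Mb position, within start - 1 Mb
        assert "v3" not in ids or gene["end"] + 1_000_000 >= 3_050_000
        far = pd.Series({"gene_id": "G2", "chrom": "1", "start": 4_000_000, "end": 4_100_000})
        assert "v0" not in select_cis_variants(far, gm, maf_min=0.0, rsq_min=0.0)

    def test_low_maf_excluded(self, setup):
        gm, gene = setup
        ids = select_cis_variants(gene, gm, maf_min=0.05, rsq_min=0.0)
        assert "v6" not in ids  # MAF 0.04 fails the strict > 0.05 filter

    def test_low_imputation_quality_excluded(self, setup):
        gm, gene = setup
        ids = select_cis_variants(gene, gm, maf_min=0.0, rsq_min=0.3)
        assert "v7" not in ids

    def test_perfectly_correlated_duplicate_dropped(self, setup):
        gm, gene = setup
        ids = select_cis_variants(gene, gm, maf_min=0.0, rsq_min=0.0)
        assert ("v4" in ids) and ("v5" not in ids)  # first by position survives

    def test_empty_result_flags_untrainable(self, setup):
        gm, _ = setup
        gene = pd.Series({"gene_id": "G3", "chrom": "9", "start": 1, "end": 2})
        assert select_cis_variants(gene, gm) == []


def _toy_genotypes(n, m, seed, prefix="v"):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.5, m)
    dosage = rng.binomial(2, p, size=(n, m)).astype(float)
    variants = pd.DataFrame(
        {
            "id": [f"{prefix}{i}" for i in range(m)],
            "chrom": "1", "pos": 1000 + 100 * np.arange(m),
            "ref": "A", "alt": "G", "imput_rsq": 0.99,
        }
    )
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)], variants=variants, dosage=dosage,
        population=np.array(["A"] * n),
    )


class TestTrainElasticNet:
    def test_noiseless_linear_model_recovered(self):
        gm = _toy_genotypes(300, 10, 7)
        y = 0.5 * gm.dosage[:, 0] - 0.3 * gm.dosage[:, 1]
        m = train_elastic_net(y, gm, [f"v{i}" for i in range(10)], "G", seed=0)
        assert m.model_r2 > 0.99
        assert {"v0", "v1"} <= set(m.variant_ids)

    def test_null_calibration_on_pure_noise(self):
        # cv_r2 should not find signal in noise (checked over seeds)
        hits_cv = hits_filter = 0
        n_rep = 25
        for seed in range(n_rep):
            gm = _toy_genotypes(200, 100, 100 + seed)
            rng = np.random.default_rng(seed)
            y = rng.standard_normal(200)
            m = train_elastic_net(y, gm, [f"v{i}" for i in range(100)], "G", seed=seed)
            hits_cv += m.cv_r2 >= 0.05
            hits_filter += m.model_r2 >= 0.05
        assert hits_cv <= max(1, int(0.05 * n_rep) + 1)
        assert hits_filter <= int(0.10 * n_rep) + 1

    def test_weights_beat_zero_model_objective(self):
        gm = _toy_genotypes(250, 40, 9)
        rng = np.random.default_rng(9)
        y = 1.2 * gm.dosage[:, 3] + rng.standard_normal(250)
        y = (y - y.mean()) / y.std()
        m = train_elastic_net(y, gm, [f"v{i}" for i in range(40)], "G", seed=1)
        pred = gm.dosages_for(m.variant_ids) @ m.weights + m.intercept
        # elastic-net objective (any penalty) at the fit <= at the zero vector
        rss_fit = np.mean((y - pred) ** 2) / 2
        rss_zero = np.mean((y - y.mean()) ** 2) / 2
        penalty = np.sum(np.abs(m.weights)) * 0  # penalty at fit >= 0, bounded by rss gap
        assert rss_fit <= rss_zero + 1e-12 or m.n_variants == 0
        assert m.model_r2 > 0.05

    def test_near_unpenalized_fit_approaches_ols(self):
        # with strong signal and n >> p the CV-chosen penalty is small and the
        # sparse fit approaches the normal-equations solution
        gm = _toy_genotypes(2000, 10, 11)
        rng = np.random.default_rng(11)
        beta = rng.standard_normal(10)
        y = gm.dosage @ beta + 0.3 * rng.standard_normal(2000)
        m = train_elastic_net(y, gm, [f"v{i}" for i in range(10)], "G", seed=2)
        X = np.column_stack([np.ones(2000), gm.dosage])
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        w = np.zeros(10)
        for vid, wt in zip(m.variant_ids, m.weights):
            w[int(vid[1:])] = wt
        assert np.abs(w - ols[1:]).max() < 0.05

    def test_deterministic_under_seed(self):
        gm = _toy_genotypes(150, 20, 13)
        rng = np.random.default_rng(13)
        y = 0.5 * gm.dosage[:, 0] + rng.standard_normal(150)
        a = train_elastic_net(y, gm, [f"v{i}" for i in range(20)], "G", seed=5)
        b = train_elastic_net(y, gm, [f"v{i}" for i in range(20)], "G", seed=5)
        assert a.variant_ids == b.variant_ids
        np.testing.assert_array_equal(a.weights, b.weights)
        assert (a.model_r2, a.cv_r2) == (b.model_r2, b.cv_r2)

    def test_error_paths(self):
        gm = _toy_genotypes(50, 5, 15)
        with pytest.raises(ValueError, match="all-constant"):
            train_elastic_net(np.ones(50), gm, ["v0", "v1"], "G")
        with pytest.raises(ValueError, match="2 cis variants"):
            train_elastic_net(np.arange(50.0), gm, ["v0"], "G")
        with pytest.raises(ValueError, match="fewer samples"):
            train_elastic_net(np.arange(8.0), gm.subset_samples(range(8)), ["v0", "v1"], "G", n_folds=10)


class TestFilterAndIO:
    def _model(self, gene, r2):
        return WeightModel(
            gene_id=gene, variant_ids=["v1", "v2"], ref=["A", "C"], alt=["G", "T"],
            weights=[0.123456789012, -0.5], intercept=0.1, model_r2=r2, cv_r2=r2 / 2,
            panel="P", n_train=100, cv_seed=3,
        )

    def test_filter_threshold_is_inclusive(self):
        kept = filter_models([self._model("a", 0.05), self._model("b", 0.049)])
        assert [m.gene_id for m in kept] == ["a"]
        assert filter_models([]) == []

    def test_weights_round_trip(self, tmp_path):
        models = [self._model("a", 0.3), self._model("b", 0.6)]
        path = tmp_path / "w.tsv"
        write_weights(models, path)
        back = read_weights(path)
        assert [m.gene_id for m in back] == ["a", "b"]
        for m0, m1 in zip(models, back):
            np.testing.assert_allclose(m0.weights, m1.weights, atol=1e-10)
            assert m0.variant_ids == m1.variant_ids
            assert m1.panel == "P" and m1.n_train == 100
        summary = pd.read_csv(tmp_path / "w.summary.tsv", sep="\t")
        assert len(summary) == 2

    def test_malformed_table_rejected(self, tmp_path):
        pd.DataFrame({"gene_id": ["a"], "weight": [1.0]}).to_csv(
            tmp_path / "bad.tsv", sep="\t", index=False
        )
        with pytest.raises(ValueError, match="malformed"):
            read_weights(tmp_path / "bad.tsv")


def test_rank_inverse_normal_is_distribution_free():
    rng = np.random.default_rng(17)
    x = rng.lognormal(size=500)
    z = rank_inverse_normal(x)
    assert stats.kstest(z, "norm").pvalue > 0.01
    # strictly monotone in the input ranks
    assert (np.argsort(z) == np.argsort(x)).all()
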