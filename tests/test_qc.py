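"""QC filters, normalization, HVG ranking, PCA and module scores."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from maturatlas.qc import (ConfigurationError, PCASpace, QCThresholds,
                           apply_qc_filters, celltype_correlation_matrix,
                           log_normalize, module_score, pc_count_for_variance,
                           run_pca, select_hvgs, zscore_across_age)

from conftest import make_adata


class TestQCFilters:
    def test_low_gene_cell_removed(self):
        counts = np.zeros((2, 300), dtype=int)
        counts[0, :200] = 3   # 200 detected genes, below the 250 floor
        counts[1, :] = 3
        kept, report = apply_qc_filters(make_adata(counts))
        assert list(kept.obs_names) == ["c1"]
        assert report.loc["c0", "first_failing_rule"] == "min_genes"

    def test_dominant_gene_cell_removed(self):
        counts = np.full((1, 300), 2, dtype=int)
        counts[0, 0] = 200    # top gene holds 200/798 = 25% of counts
        _, report = apply_qc_filters(make_adata(counts))
        assert not report.loc["c0", "passed"]
        assert report.loc["c0", "first_failing_rule"] == "max_top_gene_fraction"

    def test_all_pass_unchanged_and_idempotent(self):
        counts = np.full((4, 300), 3, dtype=int)
        adata = make_adata(counts)
        kept, report = apply_qc_filters(adata)
        assert kept.n_obs == 4 and report["passed"].all()
        again, _ = apply_qc_filters(kept)
        assert (again.X != kept.X).nnz == 0

    def test_category_fraction_rule(self):
        counts = np.full((1, 300), 2, dtype=int)
        adata = make_adata(counts)
        adata.var.loc[adata.var_names[:50], "mito"] = True  # 1/6 of counts
        _, report = apply_qc_filters(adata)
        assert report.loc["c0", "first_failing_rule"] == "max_mito_fraction"

    def test_missing_flags_raise(self):
        adata = make_adata(np.ones((2, 300), dtype=int))
        adata.var = adata.var.drop(columns=["mito", "ieg"])
        with pytest.raises(ConfigurationError, match="mito"):
            apply_qc_filters(adata)

    def test_threshold_validation(self):
        with pytest.raises(ValueError, match="min_umis"):
            QCThresholds(min_umis=1000, max_umis=500)


class TestLogNormalize:
    def test_closed_forms(self):
        counts = np.zeros((1, 4), dtype=int)
        counts[0] = [1, 0, 9999, 0]   # total = 10,000 = scale factor
        norm = log_normalize(make_adata(counts))
        vals = norm.X.toarray()[0]
        assert vals[1] == 0.0 and vals[3] == 0.0
        assert vals[0] == pytest.approx(np.log(2.0))

    def test_depth_invariance(self):
        base = np.array([[3, 5, 0, 2]])
        n1 = log_normalize(make_adata(base)).X.toarray()
        n2 = log_normalize(make_adata(base * 2)).X.toarray()
        np.testing.assert_allclose(n1, n2, atol=1e-12)

    def test_zero_total_cell_named(self):
        counts = np.array([[1, 2], [0, 0]])
        with pytest.raises(ValueError, match="c1"):
            log_normalize(make_adata(counts))


class TestHVGs:
    def test_high_dispersion_gene_first(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, size=(300, 50))
        counts[:, 7] = rng.poisson(5, 300) * rng.integers(0, 2, 300) * 20
        norm = log_normalize(make_adata(counts))
        assert select_hvgs(norm, n=10)[0] == "g7"

    def test_n_larger_than_genes_returns_all(self):
        norm = log_normalize(make_adata(np.ones((20, 5), dtype=int)))
        with pytest.warns(UserWarning, match="expressed genes"):
            got = select_hvgs(norm, n=50)
        assert sorted(got) == [f"g{i}" for i in range(5)]

    def test_deterministic(self, small_norm):
        assert select_hvgs(small_norm, 100) == select_hvgs(small_norm, 100)


class TestPCA:
    def test_variance_fractions_match_dense_eigendecomposition(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(4, size=(150, 80))
        norm = log_normalize(make_adata(counts))
        space = run_pca(norm, n_components=30, seed=0)
        X = norm.X.toarray()
        Z = (X - X.mean(0)) / np.where(X.std(0) == 0, 1, X.std(0))
        evals = np.linalg.eigvalsh(np.cov(Z, rowvar=False))[::-1]
        expected = evals / evals.sum()
        np.testing.assert_allclose(space.variance_fraction, expected[:30],
                                   atol=1e-8)

    def test_reconstruction_error_nonincreasing(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(4, size=(100, 40))
        norm = log_normalize(make_adata(counts))
        space = run_pca(norm, n_components=20, seed=0)
        X = norm.X.toarray()
        Z = (X - space.center) / space.scale
        errs = []
        for k in (2, 5, 10, 20):
            recon = space.scores[:, :k] @ space.loadings[:, :k].T
            errs.append(((Z - recon) ** 2).sum())
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))

    @pytest.mark.parametrize("fractions,expected", [
        ([0.25, 0.10, 0.05], 1),
        ([0.08, 0.07, 0.06, 0.05], 3),
        ([0.001] * 150, 100),
    ])
    def test_pc_count_rule(self, fractions, expected):
        space = PCASpace(genes=[], loadings=np.empty((0, 0)),
                         scores=np.empty((0, 0)),
                         variance_fraction=np.array(fractions),
                         center=np.empty(0), scale=np.empty(0))
        assert pc_count_for_variance(space) == expected

    def test_pc_count_target_validated(self):
        space = PCASpace([], np.empty((0, 0)), np.empty((0, 0)),
                         np.array([0.5]), np.empty(0), np.empty(0))
        with pytest.raises(ValueError, match="target"):
            pc_count_for_variance(space, target=1.5)


class TestModuleScore:
    def test_deterministic_given_seed(self, small_norm):
        genes = list(small_norm.var_names[:15])
        s1 = module_score(small_norm, genes, seed=7)
        s2 = module_score(small_norm, genes, seed=7)
        pd.testing.assert_series_equal(s1, s2)

    def test_null_set_scores_near_zero(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(5, size=(200, 400))
        norm = log_normalize(make_adata(counts))
        means = []
        gene_set = [f"g{i}" for i in rng.choice(400, 20, replace=False)]
        for seed in range(100):
            means.append(module_score(norm, gene_set, seed=seed).mean())
        assert abs(np.mean(means)) < 0.02

    def test_shifted_set_scores_near_delta(self):
        rng = np.random.default_rng(4)
        base = rng.poisson(5, size=(300, 400))
        shifted = base.copy()
        gene_idx = np.arange(20)
        shifted[:, gene_idx] = rng.poisson(5 * np.e, size=(300, 20))
        norm = log_normalize(make_adata(shifted))
        score = module_score(norm, [f"g{i}" for i in gene_idx], seed=0)
        # set genes are ~e-fold above their (count-scale) background
        assert 0.3 < score.mean() < 1.5

    def test_zero_expression_background_invariance(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(5, size=(100, 200))
        gene_set = [f"g{i}" for i in range(10)]
        s1 = module_score(log_normalize(make_adata(counts)), gene_set, seed=1)
        padded = np.hstack([counts, np.zeros((100, 30), dtype=int)])
        s2 = module_score(log_normalize(make_adata(padded)), gene_set, seed=1)
        np.testing.assert_allclose(s1.values, s2.values, atol=1e-12)

    def test_missing_set_raises(self, small_norm):
        with pytest.raises(ValueError, match="missing"):
            module_score(small_norm, ["absent1", "absent2"])


class TestZscoreAcrossAge:
    def test_closed_form(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        ages = pd.Series(["E16", "P10", "P65"], index=scores.index)
        z = zscore_across_age(scores, ages)
        np.testing.assert_allclose(z.values, [-1.224745, 0.0, 1.224745],
                                   atol=1e-6)

    def test_constant_means_zero(self):
        scores = pd.Series([2.0, 2.0], index=["a", "b"])
        ages = pd.Series(["E16", "P65"], index=scores.index)
        assert (zscore_across_age(scores, ages) == 0).all()

    def test_single_age_errors(self):
        scores = pd.Series([1.0, 2.0])
        with pytest.raises(ValueError, match="2 ages"):
            zscore_across_age(scores, pd.Series(["P65", "P65"]))


class TestCelltypeCorrelation:
    def test_identical_and_opposed_profiles(self):
        rng = np.random.default_rng(6)
        a = rng.poisson(6, size=(10, 40))
        counts = np.vstack([a, a])
        adata = make_adata(counts, cell_types=["A"] * 10 + ["B"] * 10)
        corr = celltype_correlation_matrix(log_normalize(adata))
        assert corr.loc["A", "B"] == pytest.approx(1.0, abs=1e-9)

    def test_matches_bruteforce_on_five_types(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(5, size=(50, 30))
        labels = [f"t{i % 5}" for i in range(50)]
        norm = log_normalize(make_adata(counts, cell_types=labels))
        corr = celltype_correlation_matrix(norm)
        X = norm.X.toarray()
        Z = (X - X.mean(0)) / np.where(X.std(0) == 0, 1, X.std(0))
        prof = {t: Z[np.array(labels) == t].mean(0) for t in sorted(set(labels))}
        for a in prof:
            for b in prof:
                expected = np.corrcoef(prof[a], prof[b])[0, 1]
                assert corr.loc[a, b] == pytest.approx(expected, abs=1e-10)

    def test_tiny_type_excluded_with_warning(self):
        counts = np.random.default_rng(8).poisson(5, size=(21, 30))
        labels = ["A"] * 10 + ["B"] * 10 + ["C"]
        norm = log_normalize(make_adata(counts, cell_types=labels))
        with pytest.warns(UserWarning, match="C"):
            corr = celltype_correlation_matrix(norm)
        assert "C" not in corr.index
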