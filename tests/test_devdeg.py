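"""Pseudobulking, age-effect testing, trend fits/clustering, sharing
classes, refinement score and eigentrends."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from maturatlas.devdeg import (classify_sharing, cluster_trends, devdeg_test,
                               eigentrend, filter_gene_sets, fit_trend,
                               pseudobulk_by_sample, refinement_score,
                               two_age_contrast)

from conftest import make_adata


class TestPseudobulk:
    def test_sums_and_conservation(self):
        counts = np.array([[1, 2], [3, 4], [10, 20]])
        adata = make_adata(counts, samples=["s0", "s0", "s1"])
        pb = pseudobulk_by_sample(adata)
        np.testing.assert_array_equal(pb.loc["s0"].values, [4, 6])
        np.testing.assert_array_equal(pb.loc["s1"].values, [10, 20])
        assert pb.values.sum() == counts.sum()

    def test_empty_sample_zero_row_with_warning(self):
        counts = np.array([[1, 2], [3, 4]])
        adata = make_adata(counts, samples=["s0", "s0"])
        adata.obs["sample_id"] = pd.Categorical(
            adata.obs["sample_id"], categories=["s0", "ghost"])
        with pytest.warns(UserWarning, match="ghost"):
            pb = pseudobulk_by_sample(adata)
        np.testing.assert_array_equal(pb.loc["ghost"].values, [0, 0])


def _pb_frame(rng, n_samples_per_age, ages, n_genes=300, trend_idx=(),
              fold=4.0):
    rows, age_of = [], {}
    base = rng.uniform(20, 200, size=n_genes)
    for ai, age in enumerate(ages):
        mult = np.ones(n_genes)
        mult[list(trend_idx)] = fold ** (ai / max(1, len(ages) - 1))
        for r in range(n_samples_per_age):
            s = f"{age}_s{r}"
            rows.append(pd.Series(rng.poisson(base * mult * 50),
                                  name=s))
            age_of[s] = age
    pb = pd.DataFrame(rows)
    pb.columns = [f"g{i}" for i in range(n_genes)]
    return pb, pd.Series(age_of)


class TestDevdegTest:
    def test_null_yields_few_discoveries(self):
        rng = np.random.default_rng(0)
        pb, ages = _pb_frame(rng, 4, ["E16", "P4", "P65"])
        res = devdeg_test(pb, ages)
        assert (res["fdr"] < 0.05).mean() <= 0.01

    def test_planted_trends_recovered(self):
        rng = np.random.default_rng(1)
        pb, ages = _pb_frame(rng, 4, ["E16", "P0", "P10", "P65"],
                             trend_idx=range(30), fold=4.0)
        res = devdeg_test(pb, ages).set_index("gene")
        assert (res.iloc[:30]["fdr"] < 0.05).mean() >= 0.9

    def test_single_sample_age_excluded(self):
        rng = np.random.default_rng(2)
        pb, ages = _pb_frame(rng, 2, ["E16", "P65"])
        lone = pd.Series(rng.poisson(100, pb.shape[1]), index=pb.columns,
                         name="P4_s0")
        pb = pd.concat([pb, lone.to_frame().T])
        ages["P4_s0"] = "P4"
        with pytest.warns(UserWarning, match="P4"):
            res = devdeg_test(pb, ages)
        assert len(res) == pb.shape[1]

    def test_single_age_errors(self):
        rng = np.random.default_rng(3)
        pb, ages = _pb_frame(rng, 4, ["P65"])
        with pytest.raises(ValueError, match="2 ages"):
            devdeg_test(pb, ages)


class TestFitTrend:
    def test_linear_input_reproduced(self):
        y = np.linspace(2.0, 9.0, 8)
        fitted = fit_trend(y)
        assert np.abs(fitted - y).max() < 1e-6 * (y.max() - y.min())

    def test_constant_input(self):
        fitted = fit_trend(np.full(8, 3.5))
        np.testing.assert_allclose(fitted, 3.5, atol=1e-9)

    def test_step_input_bracketed_monotone(self):
        y = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0])
        fitted = fit_trend(y)
        assert fitted.min() > -0.3 and fitted.max() < 1.3
        assert fitted[-1] - fitted[0] > 0.8

    def test_four_ages_cubic(self):
        y = np.array([1.0, 2.0, 2.5, 4.0])
        fitted = fit_trend(y)
        np.testing.assert_allclose(fitted, y, atol=1e-9)  # cubic interpolates 4 pts

    def test_linear_fallback_warns(self):
        with pytest.warns(UserWarning, match="linear"):
            fitted = fit_trend(np.array([1.0, 3.0, 2.0]))
        assert len(fitted) == 3


class TestClusterTrends:
    def test_two_planted_families_separate(self):
        up = np.tile(np.linspace(0, 1, 8), (10, 1))
        down = np.tile(np.linspace(1, 0, 8), (10, 1))
        trends = pd.DataFrame(np.vstack([up, down]))
        res = cluster_trends(trends, 2)
        labels = res.labels.to_numpy()
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_duplicate_lands_with_twin(self):
        rng = np.random.default_rng(4)
        trends = pd.DataFrame(rng.normal(size=(20, 8)))
        trends.loc[20] = trends.loc[7]
        res = cluster_trends(trends, 4)
        assert res.labels.loc[20] == res.labels.loc[7]

    def test_four_noisy_families_ari(self):
        rng = np.random.default_rng(5)
        shapes = [np.linspace(0, 1, 8), np.linspace(1, 0, 8),
                  np.concatenate([np.zeros(4), np.ones(4)]),
                  np.concatenate([np.ones(4), np.zeros(4)])]
        rows, truth = [], []
        for k, s in enumerate(shapes):
            for _ in range(25):
                rows.append(s + rng.normal(0, 0.08, 8))
                truth.append(k)
        res = cluster_trends(pd.DataFrame(rows), 4)
        assert adjusted_rand_score(truth, res.labels) >= 0.8

    def test_validation(self):
        trends = pd.DataFrame(np.ones((3, 8)))
        with pytest.raises(ValueError, match="n_clusters"):
            cluster_trends(trends, 1)
        with pytest.raises(ValueError, match="clusters"):
            cluster_trends(trends, 5)


class TestClassifySharing:
    @pytest.mark.parametrize("frac,expected", [
        (0.75, "shared"),
        (0.10, "cell-type-specific"),
        (0.50, "intermediate"),
        (0.70, "intermediate"),   # boundaries excluded from the extremes
        (0.20, "intermediate"),
    ])
    def test_rule(self, frac, expected):
        det = pd.DataFrame([np.arange(20) < round(frac * 20)], index=["g"])
        assert classify_sharing(det).loc["g"] == expected

    def test_total_partition(self):
        rng = np.random.default_rng(6)
        det = pd.DataFrame(rng.integers(0, 2, size=(50, 10)).astype(bool))
        cats = classify_sharing(det)
        assert set(cats.unique()) <= {"shared", "cell-type-specific",
                                      "intermediate"}
        assert len(cats) == 50


class TestRefinementScore:
    def _contrasts(self, sig, total):
        fdr = np.where(np.arange(total) < sig, 0.001, 0.5)
        return {"ct0": pd.DataFrame({"fdr": fdr, "expressed": True},
                                    index=[f"g{i}" for i in range(total)])}

    def test_worked_example(self):
        genes = [f"g{i}" for i in range(50)]
        assert refinement_score(genes, self._contrasts(5, 50)) == pytest.approx(0.1)

    def test_extremes(self):
        genes = [f"g{i}" for i in range(20)]
        assert refinement_score(genes, self._contrasts(0, 20)) == 0.0
        assert refinement_score(genes, self._contrasts(20, 20)) == 1.0

    def test_zero_denominator_errors(self):
        contrasts = {"ct0": pd.DataFrame({"fdr": [0.5], "expressed": [False]},
                                         index=["g0"])}
        with pytest.raises(ValueError, match="expressed"):
            refinement_score(["g0"], contrasts)

    def test_two_age_contrast_flags_expression(self, small_dataset):
        adata, _ = small_dataset
        sub = adata[adata.obs["cell_type"] == "ct00"].copy()
        res = two_age_contrast(sub, "P10", "P65")
        assert {"fdr", "expressed"} <= set(res.columns)
        assert res["expressed"].any()


class TestEigentrend:
    def test_common_shape_recovered(self):
        shape = np.sin(np.linspace(0, np.pi, 8))
        trends = pd.DataFrame([shape * a + b for a, b in
                               [(1, 0), (2, 5), (0.5, -1), (1.5, 2)]])
        e = eigentrend(trends)
        c = np.corrcoef(e, shape - shape.mean())[0, 1]
        assert c == pytest.approx(1.0, abs=1e-9)

    def test_sign_equivariance(self):
        rng = np.random.default_rng(7)
        trends = pd.DataFrame(rng.normal(size=(6, 8)))
        np.testing.assert_allclose(eigentrend(-trends), -eigentrend(trends),
                                   atol=1e-9)

    def test_majority_phase_wins(self):
        up = np.linspace(0, 1, 8)
        rows = [up] * 6 + [-up] * 4
        e = eigentrend(pd.DataFrame(rows))
        assert np.corrcoef(e, up)[0, 1] > 0.99

    def test_offset_invariance(self):
        rng = np.random.default_rng(8)
        trends = pd.DataFrame(rng.normal(size=(5, 8)))
        shifted = trends + rng.normal(size=(5, 1))
        np.testing.assert_allclose(eigentrend(trends), eigentrend(shifted),
                                   atol=1e-9)

    def test_single_member_warns(self):
        t = pd.DataFrame([np.linspace(0, 1, 8)])
        with pytest.warns(UserWarning, match="fewer than 2"):
            e = eigentrend(t)
        np.testing.assert_allclose(e, np.linspace(0, 1, 8) - 0.5, atol=1e-12)


def test_filter_gene_sets_median_overlap_rule():
    genes = [f"g{i}" for i in range(100)]
    det = pd.DataFrame(True, index=genes, columns=[f"ct{i}" for i in range(5)])
    det.iloc[60:] = False
    sets = {"big": genes[:80], "small": genes[:30]}
    kept = filter_gene_sets(sets, det, min_median_overlap=40)
    assert "big" in kept and "small" not in kept
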