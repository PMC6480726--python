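"""Chemometrics: transforms, multiplicity-controlled testing, PCA/varimax,
OPLS-DA with cross-validation and permutation, MCCV-SVM, random forest."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.cross_decomposition import PLSRegression

from benchnmr import chemometrics as chem
from benchnmr import quantify as quant


def tagged(df, *state):
    df.attrs["state"] = list(state)
    return df


def random_binary_problem(n0=10, n1=14, p=12, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n0 + n1, p))
    X[n0:, 0] += shift
    groups = np.array(["a"] * n0 + ["b"] * n1)
    fm = tagged(pd.DataFrame(X), "tsp")
    return fm, groups


class TestGlog:
    def test_reduces_to_log_at_lambda_zero(self):
        fm = tagged(pd.DataFrame([[1.0, 2.0], [3.0, 4.0]]), "tsp")
        out = chem.glog_transform(fm, lam=0.0)
        np.testing.assert_allclose(out.to_numpy(), np.log(fm.to_numpy()))

    def test_defined_at_zero(self):
        fm = tagged(pd.DataFrame([[0.0], [1.0]]), "tsp")
        out = chem.glog_transform(fm, lam=1.0)
        assert out.iloc[0, 0] == pytest.approx(np.log(0.5))

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(0.01, 100.0))
    def test_strictly_increasing(self, lam):
        x = np.linspace(-5, 5, 201)
        g = np.log((x + np.sqrt(x ** 2 + lam)) / 2)
        assert (np.diff(g) > 0).all()

    def test_requires_normalised_input(self):
        fm = tagged(pd.DataFrame([[1.0], [2.0]]), "raw")
        with pytest.raises(ValueError, match="glog"):
            chem.glog_transform(fm)

    def test_double_apply_rejected(self):
        fm = tagged(pd.DataFrame([[1.0], [2.0]]), "tsp")
        once = chem.glog_transform(fm, lam=1.0)
        with pytest.raises(ValueError):
            chem.glog_transform(once, lam=1.0)


class TestParetoScale:
    def test_hand_computed_two_point_column(self):
        # column {0, 2}: centred ±1, sd √2 → scaled ±1/2^(1/4) = ±0.8409
        fm = tagged(pd.DataFrame({"a": [0.0, 2.0]}), "tsp", "glog")
        out = chem.pareto_scale(fm)
        np.testing.assert_allclose(out["a"], [-0.8409, 0.8409], atol=1e-4)

    def test_mean_zero_and_variance_equals_sd(self):
        rng = np.random.default_rng(0)
        fm = tagged(pd.DataFrame(rng.lognormal(size=(50, 4))), "tsp", "glog")
        out = chem.pareto_scale(fm)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)
        sd_orig = fm.std(axis=0, ddof=1)
        np.testing.assert_allclose(out.var(axis=0, ddof=1), sd_orig,
                                   rtol=1e-10)

    def test_constant_column_named(self):
        fm = tagged(pd.DataFrame({"flat": [1.0, 1.0], "ok": [0.0, 1.0]}),
                    "tsp")
        with pytest.raises(ValueError, match="flat"):
            chem.pareto_scale(fm)


class TestTtestFdr:
    def test_identical_groups_null(self):
        X = np.tile(np.arange(4.0)[:, None], (2, 3))
        fm = pd.DataFrame(X)
        res = chem.ttest_fdr(fm, ["a"] * 4 + ["b"] * 4)
        np.testing.assert_allclose(res["t"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_single_bucket_adjustment_identity(self):
        rng = np.random.default_rng(1)
        fm = pd.DataFrame(rng.normal(size=(10, 1)))
        res = chem.ttest_fdr(fm, ["a"] * 5 + ["b"] * 5)
        assert res["p_adj"].iloc[0] == pytest.approx(res["p"].iloc[0])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(2)
        fm = pd.DataFrame(rng.normal(size=(24, 27)))
        for method in ("BH", "holm"):
            res = chem.ttest_fdr(fm, ["a"] * 10 + ["b"] * 14, method)
            assert (res["p_adj"] >= res["p"] - 1e-15).all()

    def test_power_for_one_large_effect(self):
        # 27 buckets, one 3-sd shift at n = (10, 14): detected after BH in
        # at least 95% of seeded replicates
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(24, 27))
            X[10:, 13] += 3.0
            res = chem.ttest_fdr(pd.DataFrame(X), ["a"] * 10 + ["b"] * 14)
            hits += res["p_adj"].iloc[13] < 0.05
        assert hits >= 38

    def test_degenerate_group_rejected(self):
        fm = pd.DataFrame(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            chem.ttest_fdr(fm, ["a", "a", "b"])


class TestPca:
    def test_collinear_single_component(self):
        x = np.arange(10.0)
        fm = pd.DataFrame({"a": x, "b": 2 * x})
        res = chem.pca(fm, variance_criterion=0.8)
        assert res.scores.shape[1] == 1
        assert res.explained_variance[0] == pytest.approx(1.0)

    def test_varimax_preserves_total_variance(self):
        rng = np.random.default_rng(3)
        fm = pd.DataFrame(rng.normal(size=(30, 6)) @ np.diag([3, 2, 1, 1, 1, 1]))
        plain = chem.pca(fm, 0.9, rotate="none")
        rot = chem.pca(fm, 0.9, rotate="varimax")
        assert rot.explained_variance.sum() == pytest.approx(
            plain.explained_variance.sum(), rel=1e-9)

    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(4)
        row = rng.normal(size=5)
        X = np.vstack([rng.normal(size=(6, 5)), row, row])
        res = chem.pca(pd.DataFrame(X), 0.95)
        np.testing.assert_allclose(res.scores.iloc[-1], res.scores.iloc[-2],
                                   atol=1e-10)

    def test_criterion_validation(self):
        with pytest.raises(ValueError):
            chem.pca(pd.DataFrame(np.eye(3)), variance_criterion=1.5)


class TestOplsda:
    def test_predictive_loading_on_dominant_variable(self):
        fm, groups = random_binary_problem(shift=6.0, seed=5)
        res = chem.oplsda_fit(fm, groups)
        w = np.abs(res.model["w"])
        assert np.argmax(w) == 0
        assert res.vip.idxmax() == 0

    def test_orthogonal_scores_uncorrelated_with_class(self):
        fm, groups = random_binary_problem(shift=3.0, seed=6)
        res = chem.oplsda_fit(fm, groups, n_orthogonal=2)
        y = (groups == "b").astype(float)
        yc = y - y.mean()
        for col in res.scores.columns[1:]:
            assert abs(res.scores[col] @ yc) < 1e-8

    def test_matches_pls_fitted_y(self):
        # predictive + orthogonal components reconstruct the 2-component
        # PLS1 solution exactly on rank-sufficient data
        fm, groups = random_binary_problem(shift=2.0, seed=7)
        y = (groups == "b").astype(float)
        res = chem.oplsda_fit(fm, groups, n_orthogonal=1)
        yhat = res.scores["t_pred"].to_numpy() * res.model["q"] \
            + res.model["y_mean"]
        pls = PLSRegression(n_components=2, scale=False).fit(
            fm.to_numpy(), y)
        np.testing.assert_allclose(yhat, pls.predict(fm.to_numpy()).ravel(),
                                   atol=1e-10)

    def test_permuted_labels_near_chance_r2y(self):
        fm, groups = random_binary_problem(shift=4.0, seed=8)
        obs = chem.oplsda_fit(fm, groups).R2Y
        rng = np.random.default_rng(8)
        null = [chem.oplsda_fit(fm, rng.permutation(groups)).R2Y
                for _ in range(20)]
        assert obs > np.mean(null) + 3 * np.std(null)

    def test_multiclass_rejected(self):
        fm = tagged(pd.DataFrame(np.random.default_rng(0).normal(size=(9, 3))),
                    "tsp")
        with pytest.raises(ValueError):
            chem.oplsda_fit(fm, ["a", "a", "a", "b", "b", "b", "c", "c", "c"])


class TestCrossValidation:
    def test_separable_q2_above_cutoff(self):
        fm, groups = random_binary_problem(shift=6.0, seed=9)
        assert chem.cv_q2(fm, groups) > 0.4

    def test_null_q2_small_on_average(self):
        vals = []
        for seed in range(8):
            fm, groups = random_binary_problem(shift=0.0, seed=seed)
            vals.append(chem.cv_q2(fm, groups, seed=seed))
        assert np.mean(vals) <= 0.1

    def test_q2_not_above_r2y(self):
        for seed in (0, 1, 2):
            fm, groups = random_binary_problem(shift=3.0, seed=seed)
            q2 = chem.cv_q2(fm, groups, seed=seed)
            r2y = chem.oplsda_fit(fm, groups).R2Y
            assert q2 <= r2y + 1e-9

    def test_k_validation(self):
        fm, groups = random_binary_problem()
        with pytest.raises(ValueError):
            chem.cv_q2(fm, groups, k_folds=1)


class TestPermutationTest:
    def test_strong_effect_minimum_p(self):
        fm, groups = random_binary_problem(n0=6, n1=6, p=4, shift=8.0, seed=10)
        res = chem.permutation_test(fm, groups, B=199, k_folds=4, seed=0)
        assert res["p_Q2"] == pytest.approx(1 / 200)
        assert res["p_R2Y"] >= 1 / 200

    def test_minimum_attainable_bound(self):
        fm, groups = random_binary_problem(n0=5, n1=5, p=3, shift=0.0, seed=11)
        res = chem.permutation_test(fm, groups, B=19, k_folds=3, seed=1)
        for key in ("p_Q2", "p_R2Y"):
            assert res[key] >= 1 / 20

    def test_null_p_moderate(self):
        fm, groups = random_binary_problem(n0=8, n1=8, p=4, shift=0.0, seed=12)
        res = chem.permutation_test(fm, groups, B=99, k_folds=4, seed=2)
        assert 0.05 < res["p_R2Y"] < 0.95


class TestMccvSvm:
    def test_perfect_separation(self):
        fm, groups = random_binary_problem(shift=20.0, seed=13)
        res = chem.mccv_svm_roc(fm, groups, (5,), n_splits=30, seed=0)
        assert res.auroc[5][0] == pytest.approx(1.0)

    def test_shuffled_labels_near_half(self):
        fm, groups = random_binary_problem(shift=0.0, seed=14)
        res = chem.mccv_svm_roc(fm, groups, (5,), n_splits=100, seed=0)
        assert res.auroc[5][0] == pytest.approx(0.5, abs=0.12)

    def test_bounded_and_order_insensitive(self):
        fm, groups = random_binary_problem(shift=2.0, seed=15)
        res = chem.mccv_svm_roc(fm, groups, (5,), n_splits=100, seed=0)
        assert 0.0 <= res.auroc[5][0] <= 1.0
        perm = np.random.default_rng(0).permutation(len(fm))
        fm2 = fm.iloc[perm].reset_index(drop=True)
        fm2.attrs = dict(fm.attrs)
        res2 = chem.mccv_svm_roc(fm2, groups[perm], (5,), n_splits=100,
                                 seed=0)
        assert res2.auroc[5][0] == pytest.approx(res.auroc[5][0], abs=0.05)

    def test_tiny_class_rejected(self):
        fm = tagged(pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3))),
                    "tsp")
        with pytest.raises(ValueError):
            chem.mccv_svm_roc(fm, ["a", "a", "a", "a", "b"], (2,),
                              n_splits=10, seed=0)


class TestRandomForest:
    def test_separable_duplicated_feature(self):
        rng = np.random.default_rng(16)
        sep = np.r_[rng.normal(0, 0.2, 12), rng.normal(4, 0.2, 12)]
        fm = pd.DataFrame({"a": sep, "b": sep,
                           "noise": rng.normal(size=24)})
        groups = ["x"] * 12 + ["y"] * 12
        res = chem.random_forest_classify(fm, groups, n_trees=200, m_try=2,
                                          seed=0)
        assert res["oob_accuracy"] >= 0.95
        assert res["confusion"].to_numpy().sum() == 24

    def test_single_tree_flagged_unstable(self):
        fm = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 3)))
        with pytest.warns(UserWarning, match="unstable"):
            chem.random_forest_classify(fm, ["a"] * 10 + ["b"] * 10,
                                        n_trees=1, m_try=2, seed=0)

    def test_mtry_validation(self):
        fm = pd.DataFrame(np.zeros((4, 2)))
        with pytest.raises(ValueError):
            chem.random_forest_classify(fm, ["a", "a", "b", "b"], m_try=7)


class TestExclusionFilter:
    def test_empty_regions_identity(self):
        fm = pd.DataFrame({"x": [1.0]})
        out, dropped = chem.exclusion_filter(fm, [])
        assert dropped == []
        pd.testing.assert_frame_equal(out, fm)

    def test_water_region_bucket_dropped(self):
        table = quant.BucketTable([quant.Bucket(4.5, 4.6, "wet"),
                                   quant.Bucket(2.0, 2.1, "dry")],
                                  exclusions=())
        fm = pd.DataFrame({"wet": [1.0], "dry": [2.0]})
        out, dropped = chem.exclusion_filter(fm, [(4.41, 5.16)], table)
        assert dropped == ["wet"]
        assert list(out.columns) == ["dry"]

    def test_default_table_untouched_by_protocol_exclusions(self,
                                                            bucket_table):
        # the shipped table tiles only unexcluded spectral regions
        fm = pd.DataFrame(np.ones((2, 27)), columns=bucket_table.labels)
        _out, dropped = chem.exclusion_filter(fm, quant.EXCLUSION_REGIONS,
                                              bucket_table)
        assert dropped == []


def test_pipeline_state_contract():
    """Normalise → glog → Pareto runs; skipping normalisation raises."""
    rng = np.random.default_rng(17)
    fm = pd.DataFrame(rng.lognormal(size=(12, 5)))
    fm.attrs["state"] = ["raw"]
    with pytest.raises(ValueError):
        chem.glog_transform(fm)
    norm = quant.constant_sum_normalize(fm)
    out = chem.pareto_scale(chem.glog_transform(norm))
    assert out.attrs["state"][-3:] == ["csn", "glog", "pareto"]
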