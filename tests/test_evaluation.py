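"""LOOCV, metrics arithmetic, permutation machinery, sweeps and the
mass-univariate FDR analysis."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fcmvpa as f
from fcmvpa.evaluation import _FoldCache, _loocv_cached


SMALL = dict(n_features=6, n_neighbors=5, n_components=3)


class TestComputeMetrics:
    def test_perfect_and_inverted(self):
        y = np.r_[np.ones(5), -np.ones(5)]
        m = f.compute_metrics(y, y)
        assert (m.gr, m.ss, m.sc) == (1.0, 1.0, 1.0)
        m = f.compute_metrics(y, -y)
        assert (m.gr, m.ss, m.sc) == (0.0, 0.0, 0.0)

    def test_clinical_confusion_counts(self):
        # 27 of 35 correct in the +1 group, 31 of 32 in the -1 group
        y = np.r_[np.ones(35), -np.ones(32)]
        pred = y.copy()
        pred[:8] = -1
        pred[35] = 1
        m = f.compute_metrics(y, pred)
        assert round(100 * m.gr, 2) == 86.57
        assert round(100 * m.rate_pos, 2) == 77.14
        assert round(100 * m.rate_neg, 2) == 96.88
        # naming conventions map the same two rates differently
        assert m.ss == m.rate_neg and m.sc == m.rate_pos  # patient convention
        printed = f.compute_metrics(y, pred, ss_convention="printed")
        assert printed.ss == printed.rate_pos

    @given(st.integers(min_value=0, max_value=500))
    def test_gr_identity(self, seed):
        rng = np.random.default_rng(seed)
        n_pos, n_neg = int(rng.integers(2, 20)), int(rng.integers(2, 20))
        y = np.r_[np.ones(n_pos), -np.ones(n_neg)]
        pred = np.where(rng.random(n_pos + n_neg) < 0.5, 1, -1)
        m = f.compute_metrics(y, pred)
        assert m.gr * (n_pos + n_neg) == pytest.approx(
            m.rate_pos * n_pos + m.rate_neg * n_neg, abs=1e-10
        )
        assert round(m.gr * (n_pos + n_neg)) == pytest.approx(
            m.gr * (n_pos + n_neg), abs=1e-9
        )


class TestLOOCV:
    def test_separable_cohort_classified_perfectly(self, small_features):
        X, y, _ = small_features
        cv = f.loocv(X, y, **SMALL)
        assert cv.gr == 1.0

    def test_estimator_path_equals_fast_path(self, small_features):
        X, y, _ = small_features
        cv = f.loocv(X, y, **SMALL)
        for i in (0, 7, 19):
            mask = np.arange(len(y)) != i
            est = f.ConnectomeClassifier(**SMALL).fit(X[mask], y[mask])
            assert est.predict(X[i][None, :])[0] == cv.y_pred[i]
            np.testing.assert_allclose(
                np.sort(est.selected_positions_),
                np.sort(cv.folds[i].selected_positions),
            )

    def test_no_information_leak_from_held_out_subject(self, small_features):
        # recomputing a fold's selection from its training rows alone must
        # reproduce the recorded fold state exactly
        X, y, _ = small_features
        cv = f.loocv(X, y, **SMALL)
        i = 3
        mask = np.arange(len(y)) != i
        sel = f.KendallTauSelector(n_features=SMALL["n_features"]).fit(X[mask], y[mask])
        np.testing.assert_array_equal(
            sel.selected_positions_, cv.folds[i].selected_positions
        )
        np.testing.assert_allclose(
            sel.tau_[sel.selected_positions_], cv.folds[i].taus, atol=1e-12
        )
        # and altering the held-out subject's features must not change them
        X2 = X.copy()
        X2[i] += 100.0
        cv2 = f.loocv(X2, y, **SMALL)
        np.testing.assert_array_equal(
            cv2.folds[i].selected_positions, cv.folds[i].selected_positions
        )

    def test_rejects_degenerate_designs(self):
        X = np.random.default_rng(0).normal(size=(3, 5))
        with pytest.raises(ValueError):
            f.loocv(X, np.array([1, 1, -1]), **SMALL)
        X = np.random.default_rng(0).normal(size=(6, 5))
        with pytest.raises(ValueError):
            f.loocv(X, np.array([1, 1, 1, 1, 1, -1]), **SMALL)

    def test_run_record_roundtrip(self, small_features, tmp_path):
        X, y, _ = small_features
        cv = f.loocv(X, y, **SMALL)
        cv.to_json(tmp_path / "run.json")
        import json

        rec = json.loads((tmp_path / "run.json").read_text())
        assert rec["metrics"]["gr"] == cv.gr
        assert len(rec["folds"]) == len(y)

    def test_alternative_backends_run(self, small_features):
        X, y, _ = small_features
        for reducer in ("pca", "none"):
            for clf in ("lda", "cmeans"):
                cv = f.loocv(X, y, reducer=reducer, classifier=clf, **SMALL)
                assert 0.0 <= cv.gr <= 1.0


class TestPermutationTest:
    def test_p_value_consistent_with_null_distribution(self, small_features):
        X, y, _ = small_features
        res = f.permutation_test(X, y, n_permutations=19, seed=0, **SMALL)
        expected = (1 + (res.null_grs >= res.gr0).sum()) / 20
        assert res.p_value == pytest.approx(expected)
        assert 0 < res.p_value <= 1
        assert len(res.null_grs) == 19

    def test_separable_data_beats_every_permutation(self, small_features):
        X, y, _ = small_features
        res = f.permutation_test(X, y, n_permutations=19, seed=1, **SMALL)
        assert res.gr0 == 1.0
        assert res.p_value == pytest.approx(1 / 20)

    def test_gr0_matches_loocv(self, small_features):
        X, y, _ = small_features
        cv = f.loocv(X, y, **SMALL)
        res = f.permutation_test(X, y, n_permutations=1, seed=0, **SMALL)
        assert res.gr0 == cv.gr

    def test_deterministic_under_seed(self, null_cohort_features):
        _, X, y, _ = null_cohort_features
        a = f.permutation_test(X, y, n_permutations=5, seed=3, **SMALL)
        b = f.permutation_test(X, y, n_permutations=5, seed=3, **SMALL)
        np.testing.assert_array_equal(a.null_grs, b.null_grs)
        assert a.p_value == b.p_value


class TestSweep:
    def test_degenerate_grid_equals_direct_loocv(self, small_features):
        X, y, _ = small_features
        table, best = f.sweep(X, y, {"n_features": [6]}, **{k: v for k, v in SMALL.items() if k != "n_features"})
        cv = f.loocv(X, y, **SMALL)
        assert len(table) == 1
        assert table.iloc[0]["gr"] == cv.gr
        assert best["n_features"] == 6

    def test_duplicate_grid_points_identical(self, small_features):
        X, y, _ = small_features
        base = {k: v for k, v in SMALL.items() if k != "n_features"}
        table, _ = f.sweep(X, y, {"n_features": [5, 5]}, **base)
        assert table.iloc[0]["gr"] == table.iloc[1]["gr"]

    def test_bitwise_reproducible(self, small_features):
        X, y, _ = small_features
        base = {k: v for k, v in SMALL.items() if k != "n_features"}
        t1, b1 = f.sweep(X, y, {"n_features": [4, 8]}, **base)
        t2, b2 = f.sweep(X, y, {"n_features": [4, 8]}, **base)
        assert t1.equals(t2) and b1 == b2

    def test_tie_break_prefers_fewer_features(self, small_features):
        X, y, _ = small_features  # separable: every point reaches GR = 1
        base = {k: v for k, v in SMALL.items() if k != "n_features"}
        table, best = f.sweep(X, y, {"n_features": [8, 4]}, **base)
        if table["gr"].nunique() == 1:
            assert best["n_features"] == 4

    def test_empty_grid_rejected(self, small_features):
        X, y, _ = small_features
        with pytest.raises(ValueError):
            f.sweep(X, y, {})


def test_compare_grid_runs_all_nine(small_features):
    X, y, _ = small_features
    table = f.compare_classifiers(X, y, n_features=6, n_neighbors=5, n_components=3)
    assert len(table) == 9
    assert set(table.columns) == {"classifier", "n_features", "SS", "SC", "GR"}
    assert table["GR"].between(0, 100).all()
    assert "lle+svm" in set(table["classifier"])


def test_nested_loocv_runs(small_features):
    X, y, _ = small_features
    cv = f.loocv_nested(
        X, y, {"n_features": [4, 6]}, n_neighbors=5, n_components=3
    )
    assert 0.0 <= cv.gr <= 1.0
    assert len(cv.folds) == len(y)


class TestMassUnivariate:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(15, 40))
        X = np.vstack([base, base])
        y = np.r_[np.ones(15), -np.ones(15)]
        table = f.mass_univariate(X, y)
        assert not table["fdr_significant"].any()

    def test_zero_variance_feature_warns_with_p_one(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 5))
        X[:, 3] = 7.0  # constant in both groups
        y = np.r_[np.ones(10), -np.ones(10)]
        with pytest.warns(UserWarning, match="zero within-class variance"):
            table = f.mass_univariate(X, y)
        assert table.loc[3, "p"] == 1.0
        assert table.loc[3, "t"] == 0.0

    def test_strong_single_effect_detected(self):
        rng = np.random.default_rng(1)
        X = rng.normal(scale=0.5, size=(60, 50))
        y = np.r_[np.ones(30), -np.ones(30)]
        X[y == 1, 7] += 3.0
        table = f.mass_univariate(X, y)
        assert table.loc[7, "fdr_significant"]
        assert table.loc[7, "t"] > 0  # sign convention: control minus patient

    def test_bh_matches_brute_force_step_up(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=100) ** 2
        # run BH through the module by constructing data is indirect; check
        # the correction itself against the definitional step-up scan
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        order = np.argsort(p)
        m = len(p)
        passed = [i for i, idx in enumerate(order) if p[idx] <= 0.05 * (i + 1) / m]
        cutoff = max(passed) if passed else -1
        brute = np.zeros(m, dtype=bool)
        if cutoff >= 0:
            brute[order[: cutoff + 1]] = True
        assert np.array_equal(reject, brute)

    def test_student_vs_welch_flag(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 10))
        y = np.r_[np.ones(15), -np.ones(15)]
        a = f.mass_univariate(X, y, equal_var=True)
        b = f.mass_univariate(X, y, equal_var=False)
        assert not np.allclose(a["p"], b["p"])


def test_fold_cache_matches_fresh_computation(null_cohort_features):
    _, X, y, _ = null_cohort_features
    cache = _FoldCache(X)
    params = f.ConnectomeClassifier(**SMALL).get_params()
    preds, _ = _loocv_cached(cache, y, params)
    cv = f.loocv(X, y, **SMALL)
    np.testing.assert_array_equal(preds, cv.y_pred)
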