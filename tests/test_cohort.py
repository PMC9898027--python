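"""Disease-space PCA, random-forest CV, feature joins and rank statistics."""

import numpy as np
import pandas as pd
import pytest

from reticulin_cif.cohort import (
    CohortMatrix,
    classify,
    combine_features,
    compare_groups,
    fit_disease_space,
    index_sample,
    median_ci,
)
from reticulin_cif.exceptions import DataError, InvalidArgumentError


def make_cohort(X, labels=None, names=None):
    X = np.asarray(X, dtype=float)
    n, f = X.shape
    return CohortMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        labels=labels or [""] * n,
        X=X,
        feature_names=names or [f"f{j}" for j in range(f)],
    )


class TestDiseaseSpace:
    def test_training_mean_projects_to_origin(self):
        rng = np.random.default_rng(0)
        cohort = make_cohort(rng.normal(size=(20, 5)))
        space = fit_disease_space(cohort)
        coords = space.transform(cohort.X.mean(axis=0))
        assert np.allclose(coords, 0.0, atol=1e-9)

    def test_collinear_data_has_rank_one_spectrum(self):
        t = np.linspace(0, 1, 12)
        X = np.stack([t, 3 * t + 1], axis=1)
        space = fit_disease_space(make_cohort(X))
        assert space.explained_variance[1] == pytest.approx(0.0, abs=1e-9)

    def test_loadings_orthonormal_and_variance_sorted(self):
        rng = np.random.default_rng(3)
        space = fit_disease_space(make_cohort(rng.normal(size=(30, 6))))
        gram = space.loadings @ space.loadings.T
        assert np.allclose(gram, np.eye(2), atol=1e-9)
        assert space.explained_variance[0] >= space.explained_variance[1]

    def test_zero_variance_feature_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning):
            space = fit_disease_space(make_cohort(X))
        assert space.feature_names == ["f0", "f2"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(DataError):
            fit_disease_space(make_cohort(np.zeros((2, 3))))

    def test_indexing_matches_fit_time_scores(self):
        rng = np.random.default_rng(5)
        cohort = make_cohort(rng.normal(size=(25, 4)))
        space = fit_disease_space(cohort)
        batch = space.transform(cohort.X)
        single = np.stack([index_sample(space, x) for x in cohort.X])
        assert np.allclose(batch, single)

    def test_duplicate_sample_identical_coordinates(self):
        rng = np.random.default_rng(6)
        cohort = make_cohort(rng.normal(size=(10, 3)))
        space = fit_disease_space(cohort)
        a = index_sample(space, cohort.X[4])
        b = index_sample(space, cohort.X[4].copy())
        assert np.array_equal(a, b)

    def test_missing_feature_named_in_error(self):
        rng = np.random.default_rng(7)
        cohort = make_cohort(rng.normal(size=(10, 3)))
        space = fit_disease_space(cohort)
        with pytest.raises(InvalidArgumentError, match="f2"):
            index_sample(space, {"f0": 1.0, "f1": 2.0})

    def test_json_roundtrip(self, tmp_path):
        from reticulin_cif.cohort import DiseaseSpace

        rng = np.random.default_rng(8)
        cohort = make_cohort(rng.normal(size=(12, 4)))
        space = fit_disease_space(cohort)
        space.to_json(tmp_path / "space.json")
        loaded = DiseaseSpace.from_json(tmp_path / "space.json")
        assert np.allclose(space.transform(cohort.X), loaded.transform(cohort.X))

    def test_severity_trajectory_moves_monotonically(self):
        """Sequential samples of increasing severity drift along one axis."""
        rng = np.random.default_rng(9)
        sev = rng.random(30)
        X = np.stack(
            [sev + rng.normal(0, 0.02, 30), 1 - sev + rng.normal(0, 0.02, 30),
             rng.normal(0, 1, 30)],
            axis=1,
        )
        cohort = make_cohort(X, names=["avg_cif", "p0", "noise"])
        space = fit_disease_space(cohort)
        traj_sev = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        traj = np.stack([
            index_sample(space, {"avg_cif": s, "p0": 1 - s, "noise": 0.0})
            for s in traj_sev
        ])
        axis = int(np.argmax(np.abs(space.loadings[:, 0])))
        coords = traj[:, axis]
        assert np.all(np.diff(coords) > 0) or np.all(np.diff(coords) < 0)


class TestClassify:
    def test_separable_classes_reach_perfect_auc(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (15, 3)), rng.normal(5, 0.1, (15, 3))])
        cohort = make_cohort(X, labels=["a"] * 15 + ["b"] * 15)
        rep = classify(cohort, positive_label="b", seed=1)
        assert rep.auc == pytest.approx(1.0)
        assert len(rep.fold_aucs) == 3
        assert sum(rep.gini_importances.values()) == pytest.approx(1.0)

    def test_permuted_labels_are_uninformative(self):
        """Mean null AUC over several label permutations sits at chance."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 4))
        aucs = []
        for k in range(5):
            labels = ["a"] * 25 + ["b"] * 25
            rng.shuffle(labels)
            rep = classify(make_cohort(X, labels=labels), positive_label="b", seed=k)
            aucs.append(rep.auc)
        assert 0.40 <= np.mean(aucs) <= 0.60

    def test_class_smaller_than_folds_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        cohort = make_cohort(X, labels=["a"] * 8 + ["b"] * 2)
        with pytest.raises(DataError):
            classify(cohort, positive_label="b", folds=3)

    def test_rank_transform_leaves_forest_auc_stable(self):
        """Tree splits depend on order only: rank-transforming features
        barely moves the AUC."""
        rng = np.random.default_rng(11)
        n = 30
        X = rng.normal(size=(2 * n, 3))
        X[n:, 0] += 1.5
        labels = ["a"] * n + ["b"] * n
        rep = classify(make_cohort(X, labels=labels), positive_label="b", seed=3)
        from scipy.stats import rankdata

        Xr = np.apply_along_axis(rankdata, 0, X)
        rep_r = classify(make_cohort(Xr, labels=labels), positive_label="b", seed=3)
        assert abs(rep.auc - rep_r.auc) < 0.05


class TestCombineFeatures:
    def test_identical_table_doubles_columns(self):
        cohort = make_cohort(np.arange(12).reshape(4, 3).astype(float))
        ext = cohort.as_dataframe().drop(columns="class_label")
        combined = combine_features(cohort, ext)
        assert combined.feature_names == [
            "fib.f0", "fib.f1", "fib.f2", "ext.f0", "ext.f1", "ext.f2",
        ]
        assert np.allclose(combined.X[:, :3], combined.X[:, 3:])

    def test_single_overlap_rejected(self):
        cohort = make_cohort(np.zeros((4, 2)))
        ext = pd.DataFrame({"sample_id": ["s0"], "m0": [1.0]})
        with pytest.raises(DataError):
            combine_features(cohort, ext)

    def test_partial_overlap_inner_join(self):
        cohort = make_cohort(np.random.default_rng(0).normal(size=(5, 2)))
        ext = pd.DataFrame(
            {"sample_id": ["s0", "s2", "s4"], "m0": [1.0, 2.0, 3.0]}
        )
        with pytest.warns(UserWarning):
            combined = combine_features(cohort, ext)
        assert combined.sample_ids == ["s0", "s2", "s4"]
        assert combined.X.shape == (3, 3)


class TestCompareGroups:
    def test_fully_separated_small_groups_exact_p(self):
        """{1,2,3} vs {10,11,12}: U = 0, two-sided exact p = 2/C(6,3) * 1 = 0.1."""
        res = compare_groups([1, 2, 3], [10, 11, 12])
        assert res.p_raw == pytest.approx(0.1)
        assert res.statistic == pytest.approx(0.0)

    def test_identical_groups_give_p_one(self):
        res = compare_groups([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_raw == pytest.approx(1.0)
        assert res.p_adjusted == pytest.approx(1.0)

    def test_bonferroni_inflates_and_caps(self):
        res = compare_groups([1, 2, 3], [10, 11, 12], n_comparisons=5)
        assert res.p_adjusted == pytest.approx(0.5)
        res_cap = compare_groups([1, 2, 3], [10, 11, 12], n_comparisons=50)
        assert res_cap.p_adjusted == 1.0
        assert res_cap.p_adjusted >= res_cap.p_raw

    def test_median_ci_covers_sample_median(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        lo, hi = median_ci(x)
        assert lo <= np.median(x) <= hi

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidArgumentError):
            compare_groups([], [1, 2])

    def test_familywise_error_controlled_under_null(self):
        """Bonferroni across 5 features keeps FWER at or below alpha."""
        rng = np.random.default_rng(123)
        n_rep, n_feat, alpha = 400, 5, 0.05
        false_positives = 0
        for _ in range(n_rep):
            any_sig = False
            for _ in range(n_feat):
                a = rng.normal(size=15)
                b = rng.normal(size=15)
                res = compare_groups(a, b, n_comparisons=n_feat)
                if res.p_adjusted < alpha:
                    any_sig = True
            false_positives += any_sig
        rate = false_positives / n_rep
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert rate <= alpha + 2 * se
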