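import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from spectrocycle.discriminate import (
    TwoStageModel,
    anova_f,
    cross_validate,
    fit_canonical_space,
    fit_linear_classifier,
    fit_stage,
    fit_two_stage,
    merge_g2m,
    predict_two_stage,
    project,
    roc_auc,
    select_features,
)


def gaussian_table(n, d, rng, shift=None, labels=None):
    X = rng.standard_normal((n, d))
    if shift is not None and labels is not None:
        X[np.asarray(labels) == 1] += shift
    return pd.DataFrame(X, columns=[f"f{i:02d}" for i in range(d)])


class TestAnova:
    def test_two_group_reference_value(self):
        f, p = anova_f([1, 2, 3, 7, 8, 9], ["a"] * 3 + ["b"] * 3)
        assert f == pytest.approx(54.0)
        assert p == pytest.approx(sps.f.sf(54.0, 1, 4))

    def test_identical_groups(self):
        f, p = anova_f([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert f == 0.0 and p == 1.0

    def test_perfectly_separated_constant_groups(self):
        f, p = anova_f([1, 1, 2, 2], ["a", "a", "b", "b"])
        assert np.isinf(f) and p == 0.0

    def test_null_distribution_matches_f_law(self):
        # permuted labels on Gaussian data: F ~ F(k-1, n-k)
        rng = np.random.default_rng(17)
        fs = []
        for _ in range(1500):
            x = rng.standard_normal(20)
            labels = np.array(["a"] * 10 + ["b"] * 10)
            rng.shuffle(labels)
            fs.append(anova_f(x, labels)[0])
        ks = sps.kstest(fs, sps.f(1, 18).cdf)
        assert ks.pvalue > 0.01


class TestSelection:
    def test_cap_at_thirteen(self):
        rng = np.random.default_rng(2)
        labels = np.array([0] * 30 + [1] * 30)
        table = gaussian_table(60, 20, rng, shift=4.0, labels=labels)
        sel = select_features(table, labels)
        assert len(sel.features) == 13
        assert all(p < 0.005 for p in sel.p_values.values())
        fs = [sel.f_stats[f] for f in sel.features]
        assert fs == sorted(fs, reverse=True)

    def test_pure_noise_raises(self):
        rng = np.random.default_rng(3)
        labels = np.array([0] * 25 + [1] * 25)
        table = gaussian_table(50, 30, rng)
        with pytest.raises(ValueError, match="insufficient discriminative"):
            select_features(table, labels)

    def test_single_informative_feature_ranked_first(self):
        rng = np.random.default_rng(4)
        labels = np.array([0] * 40 + [1] * 40)
        table = gaussian_table(80, 10, rng)
        table["signal"] = labels * 5.0 + rng.standard_normal(80) * 0.5
        sel = select_features(table, labels, alpha=0.05)
        assert sel.features[0] == "signal"


class TestCanonicalSpace:
    def test_axis_aligns_with_separating_direction(self):
        rng = np.random.default_rng(5)
        labels = np.array([0] * 500 + [1] * 500)
        X = rng.standard_normal((1000, 5))
        X[labels == 1, 0] += 6.0
        space = fit_canonical_space(X, labels)
        assert abs(space.weights[0][0]) > 0.99

    def test_fisher_criterion_beats_random_directions(self):
        rng = np.random.default_rng(6)
        labels = np.array([0] * 60 + [1] * 60)
        X = rng.standard_normal((120, 4)) @ np.diag([1, 2, 0.5, 1])
        X[labels == 1] += np.array([1.0, 0.5, -0.8, 0.3])

        def criterion(w):
            z = X @ w
            mu0, mu1 = z[labels == 0].mean(), z[labels == 1].mean()
            v = z[labels == 0].var() + z[labels == 1].var()
            return (mu1 - mu0) ** 2 / v

        space = fit_canonical_space(X, labels)
        best = criterion(space.weights[0])
        dirs = rng.standard_normal((1000, 4))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        assert all(criterion(w) <= best * (1 + 1e-9) for w in dirs)

    def test_class_swap_flips_axis_only_in_sign(self):
        rng = np.random.default_rng(7)
        labels = np.array([0] * 50 + [1] * 50)
        X = rng.standard_normal((100, 3))
        X[labels == 1, 1] += 3.0
        s1 = fit_canonical_space(X, labels)
        s2 = fit_canonical_space(X, 1 - labels)
        assert (np.allclose(s1.weights[0], s2.weights[0])
                or np.allclose(s1.weights[0], -s2.weights[0]))

    def test_axes_orthogonal_in_whitened_metric(self):
        rng = np.random.default_rng(8)
        labels = np.array([0] * 80 + [1] * 80)
        X = rng.standard_normal((160, 6))
        X[labels == 1, 2] += 2.0
        space = fit_canonical_space(X, labels)
        resid = X.copy()
        for c in (0, 1):
            resid[labels == c] -= X[labels == c].mean(axis=0)
        sw = resid.T @ resid / len(X)
        w1, w2 = space.weights
        assert abs(w2 @ sw @ w1) < 1e-6
        np.testing.assert_allclose(np.linalg.norm(space.weights, axis=1), 1.0)

    def test_project_identities(self):
        rng = np.random.default_rng(9)
        labels = np.array([0] * 30 + [1] * 30)
        X = rng.standard_normal((60, 4))
        X[labels == 1, 0] += 2.0
        space = fit_canonical_space(X, labels)
        Z = project(X, space)
        mus = np.stack([X[labels == c].mean(axis=0) for c in (0, 1)])
        np.testing.assert_allclose(project(mus, space), space.class_means)
        np.testing.assert_allclose(project(3 * X, space), 3 * Z)
        with pytest.raises(ValueError):
            project(X[:, :3], space)


class TestLinearClassifier:
    def test_separable_clusters_perfect_training_accuracy(self):
        rng = np.random.default_rng(10)
        labels = np.array([0] * 50 + [1] * 50)
        Z = rng.standard_normal((100, 2)) * 0.3
        Z[labels == 1] += np.array([5.0, 0.0])
        clf = fit_linear_classifier(Z, labels, positive_label=1)
        assert (clf.predict(Z) == labels).all()

    def test_boundary_at_midpoint_for_symmetric_clusters(self):
        rng = np.random.default_rng(11)
        labels = np.array([0] * 2000 + [1] * 2000)
        Z = rng.standard_normal((4000, 2))
        Z[labels == 1] += np.array([2.0, 0.0])
        clf = fit_linear_classifier(Z, labels, positive_label=1)
        # midpoint of projected class means scores ~0
        mid = Z[labels == 0].mean(axis=0) / 2 + Z[labels == 1].mean(axis=0) / 2
        span = abs(clf.scores(Z)).max()
        assert abs(clf.scores(mid[None, :])[0]) / span < 0.01

    def test_scaling_preserves_decisions(self):
        rng = np.random.default_rng(12)
        labels = np.array([0] * 40 + [1] * 40)
        Z = rng.standard_normal((80, 2))
        Z[labels == 1] += 1.0
        c1 = fit_linear_classifier(Z, labels, positive_label=1)
        c10 = fit_linear_classifier(10 * Z, labels, positive_label=1)
        np.testing.assert_array_equal(c1.predict(Z), c10.predict(10 * Z))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.3, 0.2], ["p", "p", "n", "n"], "p")
        assert auc == 1.0

    def test_interleaved_scores(self):
        _, auc = roc_auc([0.9, 0.3, 0.8, 0.2], ["p", "p", "n", "n"], "p")
        assert auc == pytest.approx(0.75)

    def test_ties_get_half_credit(self):
        _, auc = roc_auc([1.0, 1.0, 1.0, 1.0], ["p", "n", "p", "n"], "p")
        assert auc == pytest.approx(0.5)

    def test_matches_rank_formulation(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = rng.integers(10, 60)
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            _, auc = roc_auc(scores, labels, 1)
            assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], ["p", "p"], "p")


class TestCrossValidation:
    def test_partition_contract(self):
        rng = np.random.default_rng(14)
        labels = np.array([0] * 55 + [1] * 45)
        table = gaussian_table(100, 8, rng, shift=3.0, labels=labels)
        rep = cross_validate(table, labels, k=10, seed=3, positive_label=1)
        sizes = np.bincount(rep.fold_assignment)
        assert len(sizes) == 10
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 100

    def test_separable_classes_high_accuracy(self):
        rng = np.random.default_rng(15)
        labels = np.array([0] * 60 + [1] * 60)
        table = gaussian_table(120, 10, rng, shift=4.0, labels=labels)
        rep = cross_validate(table, labels, k=10, seed=0, positive_label=1)
        assert rep.accuracy >= 95.0

    def test_shuffled_labels_give_chance_performance(self):
        rng = np.random.default_rng(16)
        labels = rng.integers(0, 2, size=600)
        table = gaussian_table(600, 15, rng)
        rep = cross_validate(table, labels, k=10, seed=1, positive_label=1,
                             alpha=0.5)  # let noise features through
        assert abs(rep.accuracy - 50.0) <= 5.0
        assert abs(rep.auc - 0.5) <= 0.05

    def test_small_class_falls_back_to_leave_one_out(self):
        rng = np.random.default_rng(17)
        labels = np.array([0] * 30 + [1] * 5)
        table = gaussian_table(35, 5, rng, shift=5.0, labels=labels)
        with pytest.warns(UserWarning, match="leave-one-out"):
            rep = cross_validate(table, labels, k=10, seed=0, positive_label=1)
        assert rep.n == 35

    def test_leakage_canary(self):
        # a feature that is perfectly informative only on one known test fold
        # must not lift accuracy: selection/fitting never see test folds
        from sklearn.model_selection import StratifiedKFold

        rng = np.random.default_rng(18)
        n = 200
        labels = rng.integers(0, 2, size=n)
        table = gaussian_table(n, 10, rng)
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=5)
        fold0_test = next(iter(skf.split(np.zeros(n), labels)))[1]
        canary = rng.standard_normal(n)
        canary[fold0_test] = labels[fold0_test] * 10.0
        table["canary"] = canary
        rep = cross_validate(table, labels, k=10, seed=5, positive_label=1,
                             alpha=0.5)
        assert rep.accuracy < 65.0


@pytest.fixture(scope="module")
def hela(noisy_features):
    return noisy_features[noisy_features.line == "HeLa"]


class TestTwoStage:
    def test_merge_g2m(self):
        out = merge_g2m(np.array(["G1", "S", "G2", "M"]))
        assert list(out) == ["G1", "S", "G2M", "G2M"]

    def test_stage_subsets_may_differ(self, hela):
        model = fit_two_stage(hela, hela["phase"], alpha=0.05)
        assert model.stage1.selection.features  # nonempty
        assert model.stage2.selection.features
        # independence of selection: not forced identical
        assert isinstance(model.stage1.selection.features, tuple)

    def test_single_phase_input_rejected(self, hela):
        g1 = hela[hela.phase == "G1"]
        with pytest.raises(ValueError, match="need G1"):
            fit_two_stage(g1, g1["phase"])

    def test_serialisation_round_trip(self, hela, tmp_path):
        model = fit_two_stage(hela, hela["phase"], alpha=0.05)
        model.save(tmp_path / "model.json")
        loaded = TwoStageModel.load(tmp_path / "model.json")
        np.testing.assert_array_equal(
            predict_two_stage(model, hela), predict_two_stage(loaded, hela))

    def test_predictions_partition_the_classes(self, hela):
        model = fit_two_stage(hela, hela["phase"], alpha=0.05)
        pred = predict_two_stage(model, hela)
        assert set(pred) <= {"G1", "S", "G2M"}
        # stage-1 G1 verdicts are final
        stage1 = model.stage1.predict(hela)
        np.testing.assert_array_equal(pred == "G1", stage1 == "G1")

    def test_missing_feature_column_raises(self, hela):
        model = fit_two_stage(hela, hela["phase"], alpha=0.05)
        broken = hela.drop(columns=[model.stage1.selection.features[0]])
        with pytest.raises(KeyError):
            predict_two_stage(model, broken)
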