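"""Nested cross-validation: chance calibration, leakage, sparsity,
hierarchical feature-group evaluation."""

import numpy as np
import pandas as pd
import pytest

from affectpipe import ml


def _noise(rng, n=120, p=8):
    X = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"f{i}" for i in range(p)])
    y = pd.Series(np.tile([0, 1], n // 2), index=X.index)
    return X, y


class TestNestedCV:
    def test_chance_on_pure_noise(self, rng):
        X, y = _noise(rng, n=200, p=10)
        res = ml.nested_cv_classify(X, y, ml.CVConfig(seed=5))
        acc = res.families["logistic_l1"].test_mean
        half = 2.576 * np.sqrt(0.25 / len(X))  # participant-level 99% CI
        assert 0.5 - half < acc < 0.5 + half

    def test_perfectly_separable_all_families(self, rng):
        X, y = _noise(rng, n=60, p=5)
        X["f0"] = y
        cfg = ml.CVConfig(seed=6, n_repeats=3, model_families=ml.MODEL_FAMILIES,
                          rf_estimators=25)
        res = ml.nested_cv_classify(X, y, cfg)
        for name, fr in res.families.items():
            assert fr.failure is None, name
            assert fr.test_mean == pytest.approx(1.0), name

    def test_fixed_seed_reproducible(self, rng):
        X, y = _noise(rng)
        cfg = ml.CVConfig(seed=7, n_repeats=4)
        a = ml.nested_cv_classify(X, y, cfg)
        b = ml.nested_cv_classify(X, y, cfg)
        np.testing.assert_array_equal(
            a.families["logistic_l1"].test_accuracies,
            b.families["logistic_l1"].test_accuracies,
        )
        assert a.families["logistic_l1"].selected_penalties == b.families[
            "logistic_l1"
        ].selected_penalties

    def test_shuffled_labels_give_chance(self, rng):
        """Training on permuted labels keeps the 20-repeat mean test
        accuracy inside the 99% chance interval (no leakage)."""
        X, y = _noise(rng, n=160, p=6)
        X["f0"] = y  # perfectly informative before the shuffle
        y_shuffled = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        res = ml.nested_cv_classify(X, y_shuffled, ml.CVConfig(seed=8))
        acc = res.families["logistic_l1"].test_mean
        half = 2.576 * np.sqrt(0.25 / len(X))
        assert 0.5 - half < acc < 0.5 + half

    def test_l1_sparsity_monotone_in_penalty(self, rng):
        """The number of near-zero logistic coefficients never decreases as
        the L1 penalty grows."""
        from sklearn.preprocessing import StandardScaler

        X, y = _noise(rng, n=100, p=10)
        X["f0"] = y + 0.5 * rng.standard_normal(len(y))
        Z = StandardScaler().fit_transform(X)
        zero_counts = []
        for lam in (1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0):
            clf = ml._make_classifier("logistic_l1", lam, ml.CVConfig(), 0)
            clf.fit(Z, y)
            zero_counts.append(int((np.abs(clf.coef_) < 1e-8).sum()))
        assert all(a <= b for a, b in zip(zero_counts, zero_counts[1:]))

    def test_uninformative_features_zeroed(self, rng):
        """With a strong penalty and one informative feature, the noise
        features' coefficients collapse to zero."""
        X, y = _noise(rng, n=200, p=6)
        X["f0"] = y * 2.0 + 0.1 * rng.standard_normal(len(y))
        res = ml.nested_cv_classify(
            X, y, ml.CVConfig(seed=9, n_repeats=5, regularization_grid=(1.0,))
        )
        coef = res.families["logistic_l1"].coefficients
        assert abs(coef["f0"]) > 0.5
        assert (coef.drop("f0").abs() < 0.2).all()

    def test_missing_rows_dropped(self, rng):
        X, y = _noise(rng, n=60)
        X.iloc[0, 0] = np.nan
        res = ml.nested_cv_classify(X, y, ml.CVConfig(seed=10, n_repeats=2))
        assert res.families["logistic_l1"].failure is None

    def test_single_class_rejected(self, rng):
        X, _ = _noise(rng, n=20)
        with pytest.raises(ValueError, match="both classes"):
            ml.nested_cv_classify(X, np.zeros(20), ml.CVConfig())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ml.CVConfig(outer_test_fraction=1.5).validate()
        with pytest.raises(ValueError):
            ml.CVConfig(regularization_grid=()).validate()
        with pytest.raises(ValueError):
            ml.CVConfig(model_families=("nope",)).validate()


class TestGroupPCA:
    def test_reduces_wide_blocks_only(self, rng):
        X = rng.standard_normal((40, 12))
        t = ml.GroupwisePCA({"wide": list(range(10)), "narrow": [10, 11]}, k=5)
        out = t.fit(X).transform(X)
        assert out.shape == (40, 7)
        assert t.get_feature_names() == [
            "wide_PC1", "wide_PC2", "wide_PC3", "wide_PC4", "wide_PC5",
            "narrow_0", "narrow_1",
        ]

    def test_shared_reduction_matches_eeg_pca(self, rng):
        table = pd.DataFrame(rng.standard_normal((30, 14)))
        res = ml.reduce_group_pca(table, k=5)
        assert res.scores.shape == (30, 5)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(5), atol=1e-9)


class TestHierarchicalEvaluation:
    def _groups(self, rng, n=160, effect=0.0):
        y = pd.Series(np.tile([0, 1], n // 2))
        base = pd.DataFrame(
            rng.standard_normal((n, 8)) + 0.8 * y.to_numpy()[:, None],
            columns=[f"b{i}" for i in range(8)],
        )
        extra = pd.DataFrame(
            rng.standard_normal((n, 6)) + effect * y.to_numpy()[:, None],
            columns=[f"e{i}" for i in range(6)],
        )
        return {"self_report": base, "extra": extra}, y

    def test_misaligned_groups_rejected(self, rng):
        groups, y = self._groups(rng, n=40)
        groups["extra"] = groups["extra"].iloc[:-2]
        with pytest.raises(ValueError, match="misalignment"):
            ml.hierarchical_evaluation(groups, y, ml.CVConfig(seed=11, n_repeats=2))

    def test_noise_addition_stays_in_no_improvement_band(self, rng):
        groups, y = self._groups(rng, n=160, effect=0.0)
        cfg = ml.CVConfig(seed=12, n_repeats=10)
        table = ml.hierarchical_evaluation(groups, y, cfg).set_index("combination")
        delta = table.loc["self_report+extra", "delta_test_vs_baseline"]
        half = 2.576 * np.sqrt(0.25 / 160)
        assert abs(delta) < half

    def test_injected_shift_detected_alone(self, rng):
        """A group carrying a 1 SD condition shift classifies above chance
        on its own."""
        groups, y = self._groups(rng, n=160, effect=1.0)
        cfg = ml.CVConfig(seed=13, n_repeats=10)
        table = ml.hierarchical_evaluation(groups, y, cfg).set_index("combination")
        half = 2.576 * np.sqrt(0.25 / 160)
        assert table.loc["extra", "test_mean"] > 0.5 + half

    def test_determinism_under_group_order(self, rng):
        """Repeated runs and permuted addition order give identical
        per-combination results at a fixed seed."""
        groups, y = self._groups(rng, n=80)
        extra2 = pd.DataFrame(
            rng.standard_normal((80, 4)), columns=[f"g{i}" for i in range(4)]
        )
        cfg = ml.CVConfig(seed=14, n_repeats=3)
        order_a = {"self_report": groups["self_report"], "extra": groups["extra"],
                   "extra2": extra2}
        order_b = {"self_report": groups["self_report"], "extra2": extra2,
                   "extra": groups["extra"]}
        a = ml.hierarchical_evaluation(order_a, y, cfg).set_index("combination")
        b = ml.hierarchical_evaluation(order_b, y, cfg).set_index("combination")
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())
        c = ml.hierarchical_evaluation(order_a, y, cfg).set_index("combination")
        pd.testing.assert_frame_equal(a, c)

    def test_global_pca_mode(self, rng):
        groups, y = self._groups(rng, n=60)
        cfg = ml.CVConfig(seed=15, n_repeats=2)
        table = ml.hierarchical_evaluation(groups, y, cfg, pca_mode="global")
        assert set(table["combination"]) == {"self_report", "extra", "self_report+extra"}
        assert table["test_mean"].between(0, 1).all()
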