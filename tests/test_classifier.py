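import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone

import flashscreen as fs
from flashscreen.classifier import (
    DEFAULT_FEATURES, SeizureActivityClassifier, assemble_matrix,
    md_to_pvalue, moving_filter, group_proportions,
)
from conftest import two_group_plate


def response_table(n_larvae=10, n_flash=5, seed=0, invalid=()):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_larvae):
        for k in range(1, n_flash + 1):
            feat = rng.lognormal(1.0, 0.5, size=len(DEFAULT_FEATURES))
            row = dict(zip(DEFAULT_FEATURES, feat))
            row.update(subject_id=f"s{i:03d}", flash_index=k,
                       valid=(f"s{i:03d}", k) not in invalid)
            rows.append(row)
    return pd.DataFrame(rows)


class TestAssembleMatrix:
    def test_pooled_shape(self):
        X = assemble_matrix(response_table())
        assert X.shape == (50, 7)
        assert list(X.columns) == DEFAULT_FEATURES

    def test_invalid_rows_excluded_index_preserved(self):
        X = assemble_matrix(response_table(invalid=[("s001", 2), ("s004", 5)]))
        assert X.shape == (48, 7)
        assert ("s001", 2) not in X.index
        assert ("s000", 1) in X.index

    def test_column_order_follows_config(self):
        order = ["n_turns", "max_velocity"]
        X = assemble_matrix(response_table(), feature_set=order)
        assert list(X.columns) == order

    def test_unknown_feature_rejected(self):
        with pytest.raises(fs.ValidationError, match="unknown feature"):
            assemble_matrix(response_table(), feature_set=["max_velocity", "wiggle"])


class TestMovingFilter:
    def test_identity_at_zero_quantile(self):
        X = assemble_matrix(response_table())
        filtered, kept = moving_filter(X, 0.0)
        assert kept.all() and len(filtered) == len(X)

    def test_quantile_arithmetic(self):
        X = pd.DataFrame({"max_velocity": np.arange(1.0, 101.0)})
        filtered, _ = moving_filter(X, 0.1)
        assert len(filtered) == 90
        assert filtered["max_velocity"].min() == 11.0

    def test_zero_movement_rows_always_removed(self):
        v = np.concatenate([np.zeros(5), np.linspace(1, 2, 45)])
        X = pd.DataFrame({"max_velocity": v})
        f0, _ = moving_filter(X, 0.0)
        assert len(f0) == 45
        f1, _ = moving_filter(X, 0.05)
        assert (f1["max_velocity"] > 0).all()

    def test_all_removed_is_error(self):
        X = pd.DataFrame({"max_velocity": np.zeros(10)})
        with pytest.raises(fs.ComputationError):
            moving_filter(X, 0.0)


class TestFit:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        X = pd.DataFrame({"a": x, "b": 2.0 * x + 1.0})
        model = SeizureActivityClassifier(feature_set=["a", "b"],
                                          movement_column="a")
        # column 'a' crosses zero; disable the zero-movement rule by shifting
        X = X + 10.0
        model.fit(X)
        assert model.explained_variance_ratio_[0] == pytest.approx(1.0)
        assert model.cos2_.to_numpy() == pytest.approx([1.0, 1.0])
        assert not model.fallback_

    def test_isotropic_data_triggers_fallback(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(10.0, 1.0, size=(500, 7)),
                         columns=DEFAULT_FEATURES)
        with pytest.warns(UserWarning, match="cos2"):
            model = SeizureActivityClassifier().fit(X)
        assert model.fallback_
        assert list(model.retained_features_) == DEFAULT_FEATURES
        # by symmetry each variable carries ~ 2/7 of two components
        assert model.cos2_.mean() == pytest.approx(2 / 7, abs=0.05)

    def test_loadings_match_eigendecomposition(self):
        """Retained-variable loadings equal the eigenvectors of the
        correlation matrix (independent eigensolver, up to sign)."""
        rng = np.random.default_rng(2)
        base = rng.normal(size=(20, 2))
        X = np.column_stack([base[:, 0], 0.8 * base[:, 0] + 0.6 * base[:, 1],
                             base[:, 1], -base[:, 0] + 0.3 * base[:, 1]]) + 5.0
        Xdf = pd.DataFrame(X, columns=list("abcd"))
        model = SeizureActivityClassifier(
            feature_set=list("abcd"), movement_column="a",
            cos2_threshold=0.0).fit(Xdf)
        corr = np.corrcoef(X, rowvar=False)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        for k in range(2):
            v = evecs[:, order[k]]
            w = model.loadings_[:, k]
            assert min(np.abs(v - w).max(), np.abs(v + w).max()) < 1e-8

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.lognormal(size=(50, 7)), columns=DEFAULT_FEATURES)
        X["dur_highly_mobile"] = 0.7
        with pytest.warns(UserWarning, match="constant"):
            model = SeizureActivityClassifier(cos2_threshold=0.0).fit(X)
        assert "dur_highly_mobile" not in model.retained_features_

    def test_too_few_rows_rejected(self):
        X = pd.DataFrame(np.eye(2) + 1.0, columns=["max_velocity", "n_turns"])
        with pytest.raises(fs.ValidationError):
            SeizureActivityClassifier(feature_set=["max_velocity", "n_turns"]).fit(X)

    def test_sklearn_params_round_trip(self):
        model = SeizureActivityClassifier(md_threshold=2.0, p_threshold=0.15)
        twin = clone(model)
        assert twin.get_params() == model.get_params()
        twin.set_params(md_threshold=2.5)
        assert twin.md_threshold == 2.5


@pytest.fixture()
def fitted():
    rng = np.random.default_rng(4)
    X = pd.DataFrame(rng.lognormal(1.0, 0.6, size=(60, 7)), columns=DEFAULT_FEATURES)
    model = SeizureActivityClassifier(cos2_threshold=0.0).fit(X)
    return model, X


class TestMahalanobis:
    def test_centroid_distance_zero(self, fitted):
        model, X = fitted
        center = pd.DataFrame([X.mean(axis=0)], columns=X.columns)
        assert model.mahalanobis(center)[0] == pytest.approx(0.0, abs=1e-9)

    def test_mean_squared_md_identity(self, fitted):
        """Over the fitting sample, mean MD^2 = d (n-1)/n with ddof=1
        component variances."""
        model, X = fitted
        md = model.mahalanobis(X)
        n = len(X)
        assert np.mean(md ** 2) == pytest.approx(2 * (n - 1) / n)

    def test_matches_full_covariance_oracle(self):
        """PC-subspace MD equals the brute-force inverse-covariance
        Mahalanobis distance computed on the scores."""
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.lognormal(0.5, 0.7, size=(30, 2)),
                         columns=["max_velocity", "n_turns"])
        model = SeizureActivityClassifier(
            feature_set=["max_velocity", "n_turns"], cos2_threshold=0.0).fit(X)
        scores = model.transform(X)
        cov = np.cov(scores, rowvar=False, ddof=1)
        centred = scores - scores.mean(axis=0)
        md_direct = np.sqrt(np.einsum("ij,jk,ik->i", centred,
                                      np.linalg.inv(cov), centred))
        np.testing.assert_allclose(model.mahalanobis(X), md_direct, atol=1e-8)

    def test_row_permutation_invariance(self, fitted):
        model, X = fitted
        perm = X.sample(frac=1.0, random_state=7)
        md_perm = pd.Series(model.mahalanobis(perm), index=perm.index)
        md_orig = pd.Series(model.mahalanobis(X), index=X.index)
        np.testing.assert_allclose(md_perm.sort_index(), md_orig.sort_index())

    def test_affine_invariance(self, fitted):
        """Scaling and offsetting a feature column changes no MD and no
        label (standardization absorbs affine maps)."""
        model, X = fitted
        X2 = X.copy()
        X2["max_velocity"] = X2["max_velocity"] * 3.7 + 11.0
        model2 = clone(model).fit(X2)
        np.testing.assert_allclose(model2.mahalanobis(X2), model.mahalanobis(X),
                                   atol=1e-8)
        assert (model2.predict(X2) == model.predict(X)).all()


class TestPvaluesAndLabels:
    def test_md_zero_gives_one(self):
        assert md_to_pvalue(0.0) == 1.0

    def test_closed_form_df2(self):
        assert md_to_pvalue(2.0, 2) == pytest.approx(np.exp(-2.0), rel=1e-12)
        md = np.linspace(0, 5, 30)
        np.testing.assert_allclose(md_to_pvalue(md, 2), np.exp(-md ** 2 / 2),
                                   rtol=1e-10)

    def test_region_thresholds_consistent(self):
        assert md_to_pvalue(2.5, 2) == pytest.approx(0.0439, abs=5e-4)
        assert md_to_pvalue(2.5, 2) < 0.1

    def test_strictly_decreasing(self):
        md = np.linspace(0, 6, 100)
        p = md_to_pvalue(md, 2)
        assert (np.diff(p) < 0).all()

    def test_negative_md_rejected(self):
        with pytest.raises(fs.ValidationError):
            md_to_pvalue(-0.1)

    def test_label_rule(self, fitted):
        model, X = fitted
        calls = model.activity_calls(X)
        high = (calls["md"] > model.md_threshold) & (calls["p_value"] < model.p_threshold)
        assert (calls["label"] == np.where(high, "high", "low")).all()

    def test_inconsistent_thresholds_warn(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.lognormal(size=(30, 7)), columns=DEFAULT_FEATURES)
        with pytest.warns(UserWarning, match="inconsistent thresholds"):
            SeizureActivityClassifier(md_threshold=2.0, p_threshold=0.05,
                                      cos2_threshold=0.0).fit(X)


class TestGroupProportions:
    def test_hand_built_percentage(self):
        plate = two_group_plate(6, 6)
        subjects = plate.entries["subject_id"]
        calls = pd.DataFrame({
            "subject_id": np.repeat(subjects.to_numpy(), 5),
            "label": "low",
        })
        calls.loc[calls.index[:3], "label"] = "high"  # 3 of the 30 control calls
        out = group_proportions(calls, plate).set_index("group_label")
        assert out.loc["scrambled", "n_responses"] == 30
        assert out.loc["scrambled", "pct_high"] == pytest.approx(10.0)
        assert out.loc["crispant", "pct_high"] == 0.0
        assert (out["n_larvae"] == 6).all()

    def test_unknown_subject_rejected(self):
        plate = two_group_plate(2, 2)
        calls = pd.DataFrame({"subject_id": ["ghost"], "label": ["low"]})
        with pytest.raises(fs.ValidationError, match="absent"):
            group_proportions(calls, plate)

    def test_recovery_on_simulated_screen(self, screen_run):
        """Ground-truth ordering control < crispant is recovered and the
        labels agree with the simulated seizure flags."""
        s = screen_run["summaries"].set_index("group_label")
        assert s.loc["crispant", "pct_high"] > s.loc["scrambled", "pct_high"]
        merged = screen_run["calls"].merge(screen_run["ground_truth"],
                                           on=["subject_id", "flash_index"])
        high = merged["label"] == "high"
        sz = merged["seizure_flag"]
        sens = (high & sz).sum() / sz.sum()
        spec = (~high & ~sz).sum() / (~sz).sum()
        assert sens > 0.8 and spec > 0.8
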