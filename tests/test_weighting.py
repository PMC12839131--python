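"""Control normalisation, conditional inversion, PCA weights and the
composite metric, checked against hand computation and an
eigendecomposition oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from spheromet.plate_io import FeatureTable
from spheromet.weighting import (
    NormalizedFeatureMatrix,
    composite_metric,
    conditional_invert,
    normalize_to_control,
    pca_feature_weights,
    recheck_revert,
)

from _oracles import pca_weights_oracle


def small_table(values: dict[str, list[float]], concs=None) -> FeatureTable:
    n = len(next(iter(values.values())))
    concs = concs if concs is not None else [0.0, 0.0, 100.0, 100.0, 1000.0, 1000.0][:n]
    df = pd.DataFrame(
        {
            "cell_line": "HCT116",
            "compound": "X",
            "concentration_nM": concs,
            "replicate": list(range(1, n + 1)),
            **values,
        }
    )
    return FeatureTable(df)


class TestNormalizeToControl:
    def test_direct_division(self):
        t = small_table({"f": [200.0, 200.0, 100.0, 150.0, 60.0, 40.0]})
        m, ref = normalize_to_control(t)
        assert ref.means["HCT116"]["f"] == 200.0
        np.testing.assert_allclose(m.data["f"], [1.0, 1.0, 0.5, 0.75, 0.3, 0.2])

    def test_control_column_mean_is_one(self):
        t = small_table(
            {"a": [90.0, 110.0, 50.0, 55.0, 20.0, 22.0], "b": [10.0, 30.0, 15.0, 14.0, 5.0, 6.0]}
        )
        m, _ = normalize_to_control(t)
        ctrl = m.data[m.data["concentration_nM"] == 0]
        assert ctrl["a"].mean() == pytest.approx(1.0)
        assert ctrl["b"].mean() == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        rng = np.random.default_rng(4)
        vals = {f"f{j}": rng.uniform(10, 100, 6).tolist() for j in range(2)}
        t = small_table(vals)
        m, _ = normalize_to_control(t)
        for j in range(2):
            col = np.array(vals[f"f{j}"])
            expected = col / col[:2].mean()
            np.testing.assert_allclose(m.data[f"f{j}"], expected, atol=1e-12)

    def test_no_controls_errors(self):
        t = small_table({"f": [1.0, 2.0, 3.0]}, concs=[10.0, 10.0, 100.0])
        with pytest.raises(ValueError, match="control"):
            normalize_to_control(t)

    def test_per_cell_line_independence(self):
        df = pd.concat(
            [
                small_table({"f": [100.0, 100.0, 50.0, 50.0, 10.0, 10.0]}).data,
                small_table({"f": [10.0, 10.0, 5.0, 5.0, 1.0, 1.0]}).data.assign(cell_line="LoVo"),
            ],
            ignore_index=True,
        )
        m, ref = normalize_to_control(FeatureTable(df))
        assert ref.means["HCT116"]["f"] == 100.0
        assert ref.means["LoVo"]["f"] == 10.0
        np.testing.assert_allclose(
            m.data.loc[m.data["cell_line"] == "LoVo", "f"], [1.0, 1.0, 0.5, 0.5, 0.1, 0.1]
        )


def _matrix(values: list[float]) -> NormalizedFeatureMatrix:
    n = len(values)
    df = pd.DataFrame(
        {
            "cell_line": "HCT116",
            "compound": "X",
            "concentration_nM": [100.0 * (i + 1) for i in range(n)],
            "replicate": 1,
            "f": values,
        }
    )
    return NormalizedFeatureMatrix(df, ["f"])


class TestConditionalInvert:
    def test_boundary_all_ones_not_inverted(self):
        m = conditional_invert(_matrix([1.0, 1.0, 1.0]))
        assert not m.inversion_log
        np.testing.assert_allclose(m.data["f"], 1.0)

    def test_rising_column_inverted(self):
        m = conditional_invert(_matrix([1.5, 2.0, 2.5]))
        np.testing.assert_allclose(m.data["f"], [1 / 1.5, 0.5, 0.4])
        entry = m.inversion_log[("HCT116", "f")]
        assert entry["action"] == "inverted"
        assert entry["mean_before"] == pytest.approx(2.0)
        assert entry["mean_after"] == pytest.approx((1 / 1.5 + 0.5 + 0.4) / 3)

    def test_falling_column_untouched(self):
        m = conditional_invert(_matrix([0.2, 0.5, 0.8]))
        assert not m.inversion_log
        np.testing.assert_allclose(m.data["f"], [0.2, 0.5, 0.8])

    def test_means_exclude_control_wells(self):
        df = pd.DataFrame(
            {
                "cell_line": "HCT116", "compound": "X",
                "concentration_nM": [0.0, 100.0, 1000.0],
                "replicate": [1, 1, 1],
                "f": [1.0, 1.5, 2.5],  # treated mean 2.0 > 1 -> invert
            }
        )
        m = conditional_invert(NormalizedFeatureMatrix(df, ["f"]))
        assert ("HCT116", "f") in m.inversion_log
        # control well inverted too (1/1 = 1), keeping the column coherent
        np.testing.assert_allclose(m.data["f"], [1.0, 1 / 1.5, 0.4])


class TestRecheckRevert:
    def test_harmful_inversion_reverted(self):
        # Matrix changed between inversion and re-check (as after a QC
        # replacement): the recorded pre-inversion mean is lower than the
        # current post-inversion mean, so the revert condition holds.
        m = conditional_invert(_matrix([1.5, 2.0, 2.5]))
        m.data.loc[:, "f"] = [2.0, 2.5, 3.0]  # current column now above pre-mean
        out = recheck_revert(m)
        assert out.inversion_log[("HCT116", "f")]["action"] == "reverted"
        np.testing.assert_allclose(out.data["f"], [1.5, 2.0, 2.5])

    def test_clean_inversion_untouched(self):
        m = recheck_revert(conditional_invert(_matrix([1.5, 2.0, 2.5])))
        assert m.inversion_log[("HCT116", "f")]["action"] == "inverted"
        np.testing.assert_allclose(m.data["f"], [1 / 1.5, 0.5, 0.4])

    def test_identity_without_inversions(self):
        m = _matrix([0.9, 0.6, 0.3])
        out = recheck_revert(conditional_invert(m))
        np.testing.assert_allclose(out.data["f"], m.data["f"])


class TestPcaFeatureWeights:
    def test_single_feature_gets_unit_weight(self):
        X = np.random.default_rng(0).normal(size=(10, 1))
        w = pca_feature_weights(X)
        np.testing.assert_allclose(w.weights, [1.0])

    def test_duplicated_features_share_weight_equally(self):
        col = np.random.default_rng(1).normal(size=(25, 1))
        w = pca_feature_weights(np.hstack([col, col]))
        np.testing.assert_allclose(w.weights, [0.5, 0.5], atol=1e-12)
        assert w.k == 1

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("threshold", [0.80, 0.90, 0.95])
    def test_matches_eigendecomposition_oracle(self, seed, threshold):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 5)) @ rng.normal(size=(5, 5)) + rng.uniform(1, 10, 5)
        w = pca_feature_weights(X, cum_var_threshold=threshold)
        ref_w, ref_k, _ = pca_weights_oracle(X, threshold=threshold)
        assert w.k == ref_k
        np.testing.assert_allclose(w.weights, ref_w, atol=1e-10)

    def test_threshold_monotone_in_component_count(self):
        X = np.random.default_rng(3).normal(size=(40, 6))
        assert (
            pca_feature_weights(X, cum_var_threshold=0.95).k
            >= pca_feature_weights(X, cum_var_threshold=0.90).k
        )

    def test_sign_flip_invariance(self):
        X = np.random.default_rng(5).normal(size=(20, 4))
        w = pca_feature_weights(X)
        # recompute from flipped loadings: identical weights by construction
        raw = (
            w.explained_variance_ratios[: w.k, None] * np.abs(-w.loadings[: w.k])
        ).sum(axis=0)
        np.testing.assert_allclose(raw / raw.sum(), w.weights, atol=1e-14)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pca_feature_weights(np.ones((10, 3)))

    def test_bad_threshold_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError):
            pca_feature_weights(X, cum_var_threshold=1.5)

    @given(
        arrays(
            np.float64,
            (12, 4),
            elements=st.floats(0.1, 100.0, allow_nan=False),
        )
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_weights_always_normalised_nonnegative(self, X):
        X = X + np.linspace(0, 1, 4)  # break exact column ties
        if np.allclose(X.std(axis=0), 0):
            return
        w = pca_feature_weights(X)
        assert np.all(w.weights >= 0)
        assert w.weights.sum() == pytest.approx(1.0)


class TestCompositeMetric:
    def test_weighted_sum_example(self):
        df = pd.DataFrame(
            {
                "cell_line": "HCT116", "compound": "X",
                "concentration_nM": [100.0], "replicate": [1],
                "a": [0.4], "b": [0.6],
            }
        )
        m = NormalizedFeatureMatrix(df, ["a", "b"])
        w = pca_feature_weights(np.random.default_rng(0).normal(size=(10, 2)))
        w.weights = np.array([0.5, 0.5])
        w.feature_names = ["a", "b"]
        out = composite_metric(m, w)
        assert out["sigma"].iloc[0] == pytest.approx(0.5)

    def test_clean_controls_score_exactly_one(self, noiseless_tables):
        m, _ = normalize_to_control(noiseless_tables.features)
        m = recheck_revert(conditional_invert(m))
        w = pca_feature_weights(m, cell_line="HCT116")
        out = composite_metric(m, w)
        ctrl = out[out["concentration_nM"] == 0]
        np.testing.assert_allclose(ctrl["sigma"], 1.0, atol=1e-12)

    def test_matches_brute_force_dot_product(self):
        rng = np.random.default_rng(8)
        n = 20
        df = pd.DataFrame(
            {
                "cell_line": "HCT116", "compound": "X",
                "concentration_nM": np.repeat(np.arange(1.0, 11.0), 2) * 10,
                "replicate": np.tile([1, 2], 10),
                **{f"f{j}": rng.uniform(0.1, 2, n) for j in range(4)},
            }
        )
        m = NormalizedFeatureMatrix(df, [f"f{j}" for j in range(4)])
        w = pca_feature_weights(m)
        out = composite_metric(m, w)
        X = df[[f"f{j}" for j in range(4)]].to_numpy()
        np.testing.assert_allclose(out["sigma"], X @ w.weights, atol=1e-12)

    def test_feature_mismatch_rejected(self):
        df = pd.DataFrame(
            {
                "cell_line": "A", "compound": "X", "concentration_nM": [1.0],
                "replicate": [1], "a": [1.0],
            }
        )
        m = NormalizedFeatureMatrix(df, ["a"])
        w = pca_feature_weights(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError, match="feature"):
            composite_metric(m, w)
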