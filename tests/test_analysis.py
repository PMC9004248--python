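import numpy as np
import pandas as pd
import pytest

from hemowave.analysis import (
    sensitivity, normalize_beat, pca, pc_correlations,
    respiratory_stability, screen_correlations,
)
from hemowave.beats import Beat

from conftest import two_gaussian_beat


class TestSensitivity:
    @pytest.mark.parametrize("f0,f1,dpct,expected", [
        (100.0, 110.0, 10.0, 1.0),
        (100.0, 100.0, 10.0, 0.0),
        (100.0, 90.0, 10.0, -1.0),
        (100.0, 90.0, -10.0, 1.0),
        (50.0, 40.0, -20.0, 1.0),
    ])
    def test_percent_over_percent_formula(self, f0, f1, dpct, expected):
        assert sensitivity(f0, f1, dpct) == pytest.approx(expected)

    def test_zero_baseline_is_missing_not_zero(self):
        assert np.isnan(sensitivity(0.0, 5.0, 10.0))

    def test_zero_input_change_rejected(self):
        with pytest.raises(ValueError):
            sensitivity(100.0, 110.0, 0.0)

    def test_sign_preserved_for_negative_baselines(self):
        # a negative-valued feature becoming more negative moves "down"
        assert sensitivity(-100.0, -110.0, 10.0) == pytest.approx(-1.0)


class TestNormalizeBeat:
    def test_unit_square_output(self):
        p, _ = two_gaussian_beat()
        c = normalize_beat(Beat(p=p, fs=400.0), 200)
        assert c.size == 200
        assert c.min() == 0.0 and c.max() == 1.0

    def test_affine_invariance(self):
        p, _ = two_gaussian_beat()
        c1 = normalize_beat(p, 150)
        c2 = normalize_beat(3.2 * p + 17.0, 150)
        assert np.allclose(c1, c2, atol=1e-12)

    def test_linear_ramp_normalizes_to_identity(self):
        ramp = np.linspace(5.0, 25.0, 97)
        c = normalize_beat(ramp, 200)
        assert np.allclose(c, np.linspace(0, 1, 200), atol=1e-9)

    def test_constant_beat_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_beat(np.full(100, 7.0), 200)


class TestPCA:
    def test_explained_variance_sums_to_100_and_reconstructs(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((30, 6)) @ rng.standard_normal((6, 6))
        for std in (False, True):
            res = pca(X, standardize=std)
            assert res.explained_variance.sum() == pytest.approx(100.0, abs=1e-8)
            assert np.all(np.diff(res.explained_variance) <= 1e-9)
            assert np.max(np.abs(res.reconstruct() - X)) <= 1e-8

    def test_rank_one_matrix_is_one_component(self):
        u = np.linspace(-2, 2, 12)[:, None]
        X = u @ np.array([[1.0, 2.0, -1.0]])
        res = pca(X, standardize=False)
        assert res.explained_variance[0] == pytest.approx(100.0, abs=1e-8)

    def test_known_covariance_eigenvalue_split(self):
        # points constructed with sample covariance eigenvalues in ratio
        # 3:1 along (1,1)/sqrt2 and (1,-1)/sqrt2 -> 75% / 25%
        e1 = np.array([1.0, 1.0]) / np.sqrt(2)
        e2 = np.array([1.0, -1.0]) / np.sqrt(2)
        a, b = np.sqrt(3), 1.0
        X = np.vstack([a * e1, -a * e1, b * e2, -b * e2])
        res = pca(X, standardize=False)
        assert res.explained_variance[0] == pytest.approx(75.0, abs=1e-8)
        assert res.explained_variance[1] == pytest.approx(25.0, abs=1e-8)

    def test_constant_column_under_standardization_is_named(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        X[:, 1] = 4.0
        with pytest.raises(ValueError, match="column 1"):
            pca(X, standardize=True)

    def test_sign_convention_makes_top_correlation_positive(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 5))
        res = pca(X, standardize=True)
        for j in range(res.correlations.shape[1]):
            col = res.correlations[:, j]
            assert col[int(np.nanargmax(np.abs(col)))] >= 0

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca(np.ones((2, 4)))


class TestPCCorrelations:
    def test_column_equal_to_score_has_unit_correlation(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((25, 4))
        res = pca(X, standardize=False)
        X2 = np.column_stack([X, res.scores[:, 0]])
        r = pc_correlations(X2, res.scores)
        assert r[-1, 0] == pytest.approx(1.0, abs=1e-10)

    def test_explicitly_orthogonalized_column_is_uncorrelated(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((30, 3))
        res = pca(X, standardize=False)
        v = rng.standard_normal(30)
        v -= v.mean()
        S = res.scores - res.scores.mean(axis=0)
        for j in range(S.shape[1]):
            s = S[:, j]
            v -= (v @ s) / (s @ s) * s
        r = pc_correlations(np.column_stack([X, v]), res.scores)
        assert np.all(np.abs(r[-1, :]) < 1e-8)

    def test_constant_column_reported_missing_and_unscreened(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((20, 3))
        X[:, 2] = 1.0
        res = pca(X[:, :2], standardize=False)
        r = pc_correlations(X, res.scores)
        assert np.all(np.isnan(r[2, :]))
        res2 = pca(X[:, :2], standardize=False)
        res2.correlations = r
        hits = screen_correlations(res2, ["a", "b", "const"])
        assert "const" not in hits["PC1"] + hits["PC2"]


class TestRespiratoryStability:
    def _df(self, values):
        return pd.DataFrame({"beat": range(len(values)), "x": values})

    def test_constant_series_has_zero_rsd(self):
        rsd = respiratory_stability(self._df([42.0] * 12))
        assert rsd["x"] == 0.0

    def test_alternating_series_hand_arithmetic(self):
        rsd = respiratory_stability(self._df([90.0, 110.0] * 6))
        assert rsd["x"] == pytest.approx(10.0)

    def test_sinusoidal_modulation_analytic_sd(self):
        k = np.arange(200)
        series = 100.0 * (1.0 + 0.02 * np.sin(2 * np.pi * k / 20))
        rsd = respiratory_stability(self._df(series))
        assert rsd["x"] == pytest.approx(2.0 / np.sqrt(2.0), rel=1e-6)

    def test_zero_mean_feature_reported_missing(self):
        rsd = respiratory_stability(self._df([1.0, -1.0] * 6))
        assert np.isnan(rsd["x"])

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValueError, match="10"):
            respiratory_stability(self._df([1.0] * 5))
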