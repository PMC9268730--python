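"""Calibration model families: OLS, PCA/PCR, and the Stevens power-law hybrids."""

import numpy as np
import pandas as pd
import pytest

from odorcal.calibration import (
    CalibrationDataset,
    CalibrationResults,
    OdorConcentrationModel,
    fit_mlr,
    fit_pca,
    fit_pcr,
    fit_stevens_geom,
    fit_stevens_pc1,
    fit_stevens_single,
    pca_transform,
)
from odorcal.errors import (
    DegenerateColumnError,
    GeometricMeanDomainError,
    IncompatibleInputError,
    SingularDesignError,
    UnderdeterminedError,
    UnsupportedModeError,
)


def dataset(X, y, mode="SDB", split=None):
    X = pd.DataFrame(np.asarray(X, dtype=float))
    X.columns = [f"CH{j}" for j in range(X.shape[1])]
    split = np.array(["TRAIN"] * len(X) if split is None else split, dtype=object)
    return CalibrationDataset(X=X, y=np.asarray(y, dtype=float), split=split, mode=mode)


class TestMlr:
    def test_exact_recovery_of_noiseless_linear_model(self):
        rng = np.random.default_rng(0)
        X = rng.random((10, 2)) * 5
        y = 2.0 + 3.0 * X[:, 0] - 1.0 * X[:, 1]
        res = fit_mlr(dataset(X, y))
        assert res.intercept == pytest.approx(2.0, abs=1e-8)
        assert res.coefficients == pytest.approx([3.0, -1.0], abs=1e-8)
        assert res.train_r2 == pytest.approx(1.0, abs=1e-10)

    def test_constant_response(self):
        rng = np.random.default_rng(1)
        X = rng.random((8, 3))
        res = fit_mlr(dataset(X, np.full(8, 7.5)))
        assert res.intercept == pytest.approx(7.5, abs=1e-8)
        assert np.allclose(res.coefficients, 0.0, atol=1e-8)

    def test_underdetermined(self):
        with pytest.raises(UnderdeterminedError):
            fit_mlr(dataset(np.random.default_rng(2).random((4, 5)),
                            np.ones(4) * 2))

    def test_rank_deficient_design(self):
        rng = np.random.default_rng(3)
        col = rng.random(10)
        X = np.column_stack([col, col])  # duplicated channel
        with pytest.raises(SingularDesignError):
            fit_mlr(dataset(X, 1 + col))


class TestPca:
    def test_diagonal_line_gives_equal_loadings(self):
        X = np.array([[1, 1], [2, 2], [3, 3.0]])
        state = fit_pca(X, center=True, scale=False)
        assert state.loadings[:, 0] == pytest.approx(
            [1 / np.sqrt(2), 1 / np.sqrt(2)], abs=1e-10
        )
        assert state.explained_variance[1] == pytest.approx(0.0, abs=1e-10)

    def test_isotropic_cloud_variances_equal(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(4000, 2))
        state = fit_pca(X, center=True, scale=False)
        ratio = state.explained_variance[0] / state.explained_variance[1]
        assert ratio == pytest.approx(1.0, rel=0.15)

    def test_constant_column_with_scaling(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(DegenerateColumnError):
            fit_pca(X, center=True, scale=True)

    def test_orthonormal_loadings_and_reconstruction(self):
        rng = np.random.default_rng(5)
        X = rng.random((30, 4)) + rng.random(4)
        state = fit_pca(X)
        gram = state.loadings.T @ state.loadings
        assert np.allclose(gram, np.eye(4), atol=1e-10)
        Z = (X - state.means) / state.scales
        scores = pca_transform(state, X)
        assert np.allclose(scores @ state.loadings.T, Z, atol=1e-8)
        assert np.all(np.diff(state.explained_variance) <= 1e-12)


class TestPcr:
    def test_all_components_equal_mlr(self):
        rng = np.random.default_rng(6)
        X = rng.random((40, 5))
        y = 1 + X @ rng.random(5) + 0.1 * rng.random(40)
        data = dataset(X, y)
        mlr = fit_mlr(data)
        pcr = fit_pcr(data, n_components=5)
        assert pcr.predict(data.X) == pytest.approx(mlr.predict(data.X), abs=1e-8)
        X_new = rng.random((15, 5))
        frame = pd.DataFrame(X_new, columns=data.X.columns)
        assert pcr.predict(frame) == pytest.approx(mlr.predict(frame), abs=1e-8)

    def test_rank_one_matrix_single_component_matches_latent_ols(self):
        rng = np.random.default_rng(7)
        t = rng.random(20) * 4
        direction = np.array([0.5, 1.0, 2.0])
        X = np.outer(t, direction)
        y = 2.0 + 3.0 * t
        pcr = fit_pcr(dataset(X, y), n_components=1)
        # oracle: OLS of y on the latent coordinate predicts y exactly
        assert pcr.predict(pd.DataFrame(X, columns=[f"CH{j}" for j in range(3)])) \
            == pytest.approx(y, abs=1e-8)
        assert pcr.train_r2 == pytest.approx(1.0, abs=1e-10)

    def test_constant_response(self):
        rng = np.random.default_rng(8)
        res = fit_pcr(dataset(rng.random((10, 3)), np.full(10, 4.0)), n_components=2)
        assert res.intercept == pytest.approx(4.0, abs=1e-8)
        assert np.allclose(res.coefficients, 0.0, atol=1e-8)

    def test_auto_selects_true_dimension(self):
        rng = np.random.default_rng(9)
        t = rng.normal(size=40)
        X = np.outer(t, [1.0, 0.8, 1.2]) + 0.01 * rng.normal(size=(40, 3))
        y = 5 + 2 * t
        res = fit_pcr(dataset(X, y), n_components="auto")
        assert res.n_components == 1


class TestStevensSingle:
    def test_noiseless_recovery(self):
        S = np.arange(10.0)
        y = 2.0 * 1.5**S
        res = fit_stevens_single(dataset(S[:, None], y))
        assert res.a == pytest.approx(2.0, abs=1e-8)
        assert res.b == pytest.approx(1.5, abs=1e-8)
        assert res.train_r2 == pytest.approx(1.0, abs=1e-12)

    def test_flat_response(self):
        S = np.arange(6.0)
        res = fit_stevens_single(dataset(S[:, None], np.full(6, 5.0)))
        assert res.a == pytest.approx(5.0, abs=1e-9)
        assert res.b == pytest.approx(1.0, abs=1e-9)

    def test_selects_most_predictive_channel(self):
        rng = np.random.default_rng(10)
        s_good = np.linspace(0, 5, 30)
        s_noise = rng.random(30) * 5
        y = 2.0 * 1.4**s_good
        X = pd.DataFrame({"GOOD": s_good, "NOISE": s_noise})
        data = CalibrationDataset(X=X, y=y, split=np.array(["TRAIN"] * 30, dtype=object),
                                  mode="SDB")
        res = fit_stevens_single(data)
        assert res.selected_channel == "GOOD"


class TestStevensGeom:
    def test_noiseless_recovery_via_row_geometric_mean(self):
        rng = np.random.default_rng(11)
        X = rng.random((20, 2)) * 8 + 1
        g = np.sqrt(X[:, 0] * X[:, 1])
        y = 3.0 * 1.2**g
        res = fit_stevens_geom(dataset(X, y, mode="SDB"))
        assert res.a == pytest.approx(3.0, abs=1e-8)
        assert res.b == pytest.approx(1.2, abs=1e-8)
        # the (4, 9) row exponent is sqrt(36) = 6
        row = pd.DataFrame([[4.0, 9.0]], columns=["CH0", "CH1"])
        assert res.predict(row)[0] == pytest.approx(3.0 * 1.2**6.0, rel=1e-8)

    def test_smax_mode_unsupported(self):
        with pytest.raises(UnsupportedModeError):
            fit_stevens_geom(dataset(np.ones((5, 2)), np.ones(5) * 2, mode="SMAX"))

    def test_nonpositive_rows_dropped_or_strict(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0], [0.5, 2.0], [2.0, 2.0], [-1.0, 5.0]])
        y = np.array([2.0, 3.0, 2.5, 2.8, 9.9])
        with pytest.warns(UserWarning, match="non-positive SdB"):
            res = fit_stevens_geom(dataset(X, y, mode="SDB"))
        assert np.isnan(res.fittedvalues[-1])
        with pytest.raises(GeometricMeanDomainError):
            fit_stevens_geom(dataset(X, y, mode="SDB"), strict=True)


class TestStevensPc1:
    def test_noiseless_recovery_along_one_direction(self):
        t = np.linspace(-2, 2, 25)
        X = np.outer(t, [1.0, 1.0])
        state = fit_pca(X)  # same preprocessing the model applies
        pc1 = pca_transform(state, X)[:, 0]
        y = 2.5 * 1.3**pc1
        res = fit_stevens_pc1(dataset(X, y))
        assert res.a == pytest.approx(2.5, abs=1e-8)
        assert res.b == pytest.approx(1.3, abs=1e-8)

    def test_constant_response_gives_unit_base(self):
        rng = np.random.default_rng(12)
        res = fit_stevens_pc1(dataset(rng.random((10, 3)), np.full(10, 6.0)))
        assert res.b == pytest.approx(1.0, abs=1e-9)

    def test_projection_uses_stored_training_statistics(self):
        rng = np.random.default_rng(13)
        X_train = rng.random((12, 2)) * 3
        y = 2.0 * 1.5 ** (X_train.sum(axis=1))
        res = fit_stevens_pc1(dataset(X_train, y))
        # two test rows whose own mean/scale differ wildly from training's
        X_test = np.array([[10.0, 10.0], [50.0, 55.0]])
        expected_scores = pca_transform(res.pca_state, X_test)[:, 0]
        expected = res.a * res.b**expected_scores
        frame = pd.DataFrame(X_test, columns=["CH0", "CH1"])
        assert res.predict(frame) == pytest.approx(expected, rel=1e-12)
        # the wrong convention (test-set statistics) gives a different answer
        wrong_state = fit_pca(X_test, center=True, scale=True)
        wrong = res.a * res.b ** pca_transform(wrong_state, X_test)[:, 0]
        assert not np.allclose(res.predict(frame), wrong)


class TestPredictDispatch:
    def test_degenerate_power_law_returns_one(self):
        S = np.linspace(1, 5, 6)
        res = fit_stevens_single(dataset(S[:, None], np.ones(6)))
        assert res.a == pytest.approx(1.0) and res.b == pytest.approx(1.0)
        probe = pd.DataFrame({"CH0": [0.0, 17.3, -4.0]})
        assert res.predict(probe) == pytest.approx([1.0, 1.0, 1.0])

    def test_mlr_arithmetic(self):
        rng = np.random.default_rng(14)
        X = rng.random((10, 2))
        y = 2.0 + 3.0 * X[:, 0] - 1.0 * X[:, 1]
        res = fit_mlr(dataset(X, y))
        point = pd.DataFrame({"CH0": [1.0], "CH1": [1.0]})
        assert res.predict(point)[0] == pytest.approx(4.0, abs=1e-8)

    def test_pcr_consistent_with_fitted_values(self):
        rng = np.random.default_rng(15)
        X = rng.random((20, 3))
        y = 1 + X @ [1.0, 2.0, 3.0] + 0.05 * rng.random(20)
        data = dataset(X, y)
        res = fit_pcr(data, n_components=2)
        assert res.predict(data.X) == pytest.approx(res.fittedvalues, abs=1e-10)

    def test_mode_mismatch_rejected(self):
        rng = np.random.default_rng(16)
        X = rng.random((10, 2))
        res = fit_mlr(dataset(X, 1 + X[:, 0], mode="SMAX"))
        with pytest.raises(IncompatibleInputError):
            res.predict(X, mode="SDB")
        with pytest.raises(IncompatibleInputError):
            res.predict(np.ones((2, 5)))  # wrong channel count


@pytest.mark.parametrize("family", ["MLR", "PCR", "STEVENS_SINGLE",
                                    "STEVENS_GEOM", "STEVENS_PC1"])
def test_serialization_round_trip(family):
    rng = np.random.default_rng(17)
    X = rng.random((25, 3)) * 4 + 1
    y = 2 + X @ [1.0, 0.5, 0.2] + 0.1 * rng.random(25)
    data = dataset(X, y, mode="SDB")
    kwargs = {"n_components": 2} if family == "PCR" else {}
    res = OdorConcentrationModel.from_dataset(data, family, **kwargs).fit()
    restored = CalibrationResults.from_json(res.to_json())
    probe = pd.DataFrame(rng.random((6, 3)) * 4 + 1, columns=data.X.columns)
    assert restored.predict(probe) == pytest.approx(res.predict(probe), rel=1e-12)
    assert restored.family == family
    assert "R^2" in res.summary()
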