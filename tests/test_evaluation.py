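"""RMSE, OAQII classification, accordance, selection, psychophysics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odorcal.calibration import CalibrationDataset, fit_mlr
from odorcal.errors import (
    DomainError,
    IncompatibleInputError,
    InvalidInputError,
    InvalidSplitError,
    NonInvertibleError,
)
from odorcal.evaluation import (
    EvaluationReport,
    OaqiiScale,
    PsychophysicalFit,
    accordance,
    classify_oaqii,
    evaluate_model,
    fit_psychophysical,
    rmse,
    scale_from_psychophysics,
    select_best_model,
)


class TestRmse:
    def test_reference_values(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(math.sqrt(12.5), abs=1e-9)
        assert rmse([10.0], [7.0]) == pytest.approx(3.0)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            rmse([1.0], [1.0, 2.0])
        with pytest.raises(InvalidInputError):
            rmse([], [])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 1000))
    def test_triangle_consistency(self, seed):
        rng = np.random.default_rng(seed)
        x, y, z = rng.random((3, 12)) * 50
        assert rmse(x, z) <= rmse(x, y) + rmse(y, z) + 1e-12


class TestClassifyOaqii:
    @pytest.mark.parametrize(
        "cod, expected",
        [(3.0, 0), (3.0001, 1), (10.0, 1), (10.001, 2), (60.0, 2),
         (60.0001, 3), (61.0, 3), (0.5, 0), (1e6, 3)],
    )
    def test_upper_inclusive_boundaries(self, cod, expected):
        assert classify_oaqii(cod) == expected

    def test_nonpositive_concentration(self):
        with pytest.raises(DomainError):
            classify_oaqii(0.0)
        with pytest.raises(DomainError):
            classify_oaqii(-2.0)

    def test_partition_and_monotonicity_over_log_grid(self):
        grid = np.logspace(-3, 4, 10_000)
        labels = classify_oaqii(grid)
        assert set(np.unique(labels)) <= {0, 1, 2, 3}
        assert np.all(np.diff(labels) >= 0)  # monotone non-decreasing
        # every point receives exactly one class (vector output covers all)
        assert labels.shape == grid.shape


class TestAccordance:
    def test_extremes_and_fractions(self):
        assert accordance([0, 1, 2], [0, 1, 2]) == 1.0
        assert accordance([0] * 50, [0] * 49 + [1]) == pytest.approx(0.98)
        assert accordance([0, 1], [1, 0]) == 0.0

    def test_self_accordance_is_one(self):
        labels = np.array([0, 3, 2, 2, 1])
        assert accordance(labels, labels) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            accordance([0, 1], [0])


def linear_dataset(n_train=10, n_test=5, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.random((n_train + n_test, 2)) * 3
    y = 5.0 + 4.0 * X[:, 0] + 2.0 * X[:, 1] + noise * rng.normal(size=len(X))
    split = np.array(["TRAIN"] * n_train + ["TEST"] * n_test, dtype=object)
    return CalibrationDataset(
        X=pd.DataFrame(X, columns=["a", "b"]), y=y, split=split, mode="SDB"
    )


class TestEvaluateModel:
    def test_perfect_model(self):
        data = linear_dataset()
        report = evaluate_model(fit_mlr(data), data)
        assert report.rmse == pytest.approx(0.0, abs=1e-9)
        assert report.accordance == 1.0

    def test_constant_predictor_two_row_fixture(self):
        # model predicting 5 everywhere against truths (1, 50):
        # rmse = sqrt((16 + 2025)/2); labels 1 vs (0, 2) -> no matches
        y_true = np.array([1.0, 50.0])
        y_pred = np.array([5.0, 5.0])
        assert rmse(y_true, y_pred) == pytest.approx(31.945266, abs=1e-5)
        assert accordance(classify_oaqii(y_true), classify_oaqii(y_pred)) == 0.0

    def test_mode_mismatch(self):
        data = linear_dataset()
        model = fit_mlr(data)
        smax_data = CalibrationDataset(
            X=data.X, y=data.y, split=data.split, mode="SMAX"
        )
        with pytest.raises(IncompatibleInputError):
            evaluate_model(model, smax_data)

    def test_empty_test_split(self):
        data = linear_dataset(n_test=0)
        with pytest.raises(InvalidSplitError):
            evaluate_model(fit_mlr(data), data)


def report_stub(rmse_value, accordance_value, name="m"):
    labels = np.zeros(1, dtype=int)
    return EvaluationReport(
        model_family=name, mode="SDB", y_true=np.ones(1), y_pred=np.ones(1),
        rmse=rmse_value, labels_true=labels, labels_pred=labels,
        n_correct=1, accordance=accordance_value, N=1, n_used=1,
    )


class TestSelectBestModel:
    def test_accordance_priority_within_slack(self):
        # the five dB-mode validation results from the study this targets
        reports = [
            report_stub(5.754, 0.75, "Model1"),
            report_stub(5.420, 0.85, "Model2"),
            report_stub(7.120, 0.70, "Model3"),
            report_stub(3.667, 0.90, "Model4"),
            report_stub(4.220, 0.98, "Model5"),
        ]
        best = select_best_model(reports, rmse_slack=0.25)
        assert best.model_family == "Model5"
        assert best.rmse == pytest.approx(4.220)
        assert best.accordance == pytest.approx(0.98)

    def test_single_report(self):
        only = report_stub(2.0, 0.5)
        assert select_best_model([only]) is only

    def test_stable_tie_break(self):
        first = report_stub(2.0, 0.9, "first")
        second = report_stub(2.0, 0.9, "second")
        assert select_best_model([first, second]) is first

    def test_zero_slack_equal_accordance_is_argmin_rmse(self):
        reports = [report_stub(4.0, 0.8), report_stub(2.5, 0.8), report_stub(3.0, 0.8)]
        assert select_best_model(reports, rmse_slack=0.0).rmse == 2.5

    def test_empty_list(self):
        with pytest.raises(InvalidInputError):
            select_best_model([])


class Session:
    def __init__(self, cod, intensity=None, hedonic=None):
        self.cod = cod
        self.intensity = intensity
        self.hedonic = hedonic


class TestPsychophysics:
    def test_exact_linear_recovery(self):
        cods = [1.0, 3.0, 10.0, 30.0, 100.0]
        sessions = [Session(c, intensity=1 + 2 * math.log10(c)) for c in cods]
        fit = fit_psychophysical(sessions, "INTENSITY")
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_annotation(self):
        sessions = [Session(c, hedonic=-2.0) for c in (1.0, 5.0, 25.0)]
        assert fit_psychophysical(sessions, "HEDONIC").slope == pytest.approx(0.0, abs=1e-9)

    def test_insufficient_sessions(self):
        with pytest.raises(InvalidInputError):
            fit_psychophysical([Session(1, intensity=0), Session(2, intensity=1)],
                               "INTENSITY")

    def test_identity_fits_reproduce_canonical_bounds(self):
        identity = PsychophysicalFit("INTENSITY", slope=1.0, intercept=0.0, r2=1.0)
        identity_h = PsychophysicalFit("HEDONIC", slope=1.0, intercept=0.0, r2=1.0)
        cuts = (math.log10(3.0), 1.0, math.log10(60.0))
        scale = scale_from_psychophysics(identity, identity_h, cuts, cuts)
        assert scale.bounds == pytest.approx([3.0, 10.0, 60.0])
        assert classify_oaqii(3.0, scale) == 0 and classify_oaqii(61.0, scale) == 3

    def test_zero_slope_not_invertible(self):
        flat = PsychophysicalFit("HEDONIC", slope=0.0, intercept=-1.0, r2=0.0)
        good = PsychophysicalFit("INTENSITY", slope=1.0, intercept=0.0, r2=1.0)
        with pytest.raises(NonInvertibleError):
            scale_from_psychophysics(good, flat, (0.5, 1.0, 1.8), (-1.5, -2.5, -3.5))

    def test_default_scale_is_canonical(self):
        assert OaqiiScale().bounds == [3.0, 10.0, 60.0]


def test_validation_plot_returns_axes():
    import matplotlib

    matplotlib.use("Agg")
    data = linear_dataset()
    report = evaluate_model(fit_mlr(data), data)
    ax = __import__("odorcal.evaluation", fromlist=["validation_plot"]).validation_plot(report)
    assert ax.get_xlabel()
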