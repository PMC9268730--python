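"""Calibration of a gas-sensor array against olfactometric odor concentrations.

Five model families link the per-channel features S_i (either raw signal
maxima or decibel peak-to-baseline ratios) to the odor concentration C_od
measured by a field-olfactometry panel:

=================  ==========================================================
family             calibration form
=================  ==========================================================
``MLR``            C_od = a0 + sum_i a_i * S_i           (ordinary least squares)
``PCR``            C_od = a0 + sum_i a_i * PC_i          (principal component
                   regression: OLS on the leading PCA scores)
``STEVENS_SINGLE`` C_od = a * b**S_j  for the single best channel j
``STEVENS_GEOM``   C_od = a * b**g,   g = geometric mean of the SdB channels
``STEVENS_PC1``    C_od = a * b**PC1, PC1 = first principal component score
=================  ==========================================================

The Stevens families invert Stevens' psychophysical power law: the sensor
feature plays the role of perceived magnitude and the concentration is
recovered as an exponential in the feature.  They are fitted by ordinary
least squares in log10-concentration space (``log10 C = log10 a + S log10 b``),
which linearizes the power-law form; MLR and PCR are fitted on raw
concentrations, exactly as their linear equations are written.

Usage follows the statsmodels convention: build an
:class:`OdorConcentrationModel` from data, call :meth:`~OdorConcentrationModel.fit`,
and work with the returned :class:`CalibrationResults` (coefficients,
``train_r2``, ``predict``, ``summary``, JSON round-trip).  The
``fit_mlr`` / ``fit_pcr`` / ``fit_stevens_*`` helpers are one-line wrappers
over that pair.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    DegenerateColumnError,
    GeometricMeanDomainError,
    IncompatibleInputError,
    InvalidInputError,
    LogDomainError,
    SingularDesignError,
    UnderdeterminedError,
    UnsupportedModeError,
)

__all__ = [
    "CalibrationDataset",
    "PcaState",
    "OdorConcentrationModel",
    "CalibrationResults",
    "fit_pca",
    "pca_transform",
    "fit_mlr",
    "fit_pcr",
    "fit_stevens_single",
    "fit_stevens_geom",
    "fit_stevens_pc1",
    "predict",
    "FAMILIES",
]

Family = Literal["MLR", "PCR", "STEVENS_SINGLE", "STEVENS_GEOM", "STEVENS_PC1"]
FAMILIES: tuple[str, ...] = (
    "MLR",
    "PCR",
    "STEVENS_SINGLE",
    "STEVENS_GEOM",
    "STEVENS_PC1",
)


@dataclass
class CalibrationDataset:
    """Aligned features and olfactometric concentrations with a split.

    Attributes
    ----------
    X
        m windows x k channels feature matrix (columns = channel ids),
        extracted under a single declared mode.
    y
        Odor concentrations in ou/m^3, strictly positive, aligned to X rows.
    split
        Per-row ``"TRAIN"`` / ``"TEST"`` labels.
    mode
        ``"SMAX"`` or ``"SDB"`` — which feature representation X holds.
    """

    X: pd.DataFrame
    y: np.ndarray
    split: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.split = np.asarray(self.split, dtype=object)
        if len(self.X) != self.y.size or self.y.size != self.split.size:
            raise InvalidInputError(
                f"misaligned dataset: X has {len(self.X)} rows, "
                f"y {self.y.size}, split {self.split.size}"
            )
        if np.any(self.y <= 0) or not np.all(np.isfinite(self.y)):
            raise InvalidInputError("odor concentrations must be finite and > 0")
        if self.mode not in ("SMAX", "SDB"):
            raise InvalidInputError(f"mode must be SMAX or SDB, got {self.mode!r}")

    @property
    def channel_ids(self) -> list[str]:
        return list(self.X.columns)

    def rows(self, label: str) -> tuple[pd.DataFrame, np.ndarray]:
        mask = self.split == label
        return self.X.loc[mask], self.y[mask]

    @property
    def n_train(self) -> int:
        return int(np.sum(self.split == "TRAIN"))

    @property
    def n_test(self) -> int:
        return int(np.sum(self.split == "TEST"))


# ---------------------------------------------------------------------------
# PCA with a deterministic sign convention
# ---------------------------------------------------------------------------


@dataclass
class PcaState:
    """Frozen PCA preprocessing state for test-time projection.

    ``loadings`` has one column per component (orthonormal directions in
    channel space, ordered by decreasing explained variance).  The sign of
    each component is fixed so its largest-magnitude element is positive —
    required because ``b**PC1`` is not sign-invariant.
    """

    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PcaState":
        return cls(
            means=np.asarray(d["means"], dtype=float),
            scales=np.asarray(d["scales"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            explained_variance=np.asarray(d["explained_variance"], dtype=float),
        )


def fit_pca(X, center: bool = True, scale: bool = True) -> PcaState:
    """Principal component analysis with mean centering and unit-variance scaling.

    Components are eigenvectors of the covariance of the (centered, scaled)
    data, ordered by decreasing variance, sign-fixed so each component's
    largest-magnitude element is positive.  Sample standard deviations
    (ddof=1) are used for scaling, matching the chemometric autoscaling
    convention.

    Raises
    ------
    DegenerateColumnError
        If scaling is requested and a column has zero variance.
    InvalidInputError
        With fewer than 2 rows.
    """
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise InvalidInputError("PCA requires a 2-D matrix with at least 2 rows")
    n, k = arr.shape
    means = arr.mean(axis=0) if center else np.zeros(k)
    if scale:
        scales = arr.std(axis=0, ddof=1)
        if np.any(scales == 0):
            bad = np.flatnonzero(scales == 0).tolist()
            raise DegenerateColumnError(
                f"zero-variance column(s) {bad} cannot be scaled to unit variance"
            )
    else:
        scales = np.ones(k)
    Z = (arr - means) / scales
    # SVD of the centered/scaled matrix == eigendecomposition of its covariance
    _, svals, vt = np.linalg.svd(Z, full_matrices=False)
    explained = svals**2 / max(n - 1, 1)
    loadings = vt.T  # columns = components
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    return PcaState(means, scales, loadings, explained)


def pca_transform(state: PcaState, X) -> np.ndarray:
    """Project new rows onto the stored components using the *stored*
    training means and scales (never test-set statistics)."""
    arr = np.atleast_2d(np.asarray(X, dtype=float))
    return (arr - state.means) / state.scales @ state.loadings


# ---------------------------------------------------------------------------
# Internal fitting helpers
# ---------------------------------------------------------------------------


def _r2(y: np.ndarray, fitted: np.ndarray) -> float:
    """Coefficient of determination; a perfectly fitted constant response
    counts as R^2 = 1 (the 0/0 case)."""
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if np.isclose(ss_res, 0.0) else 0.0
    return 1.0 - ss_res / ss_tot


def _ols(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS with an explicit rank check; ``design`` already includes the
    intercept column."""
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise SingularDesignError(
            f"design matrix rank {rank} < {design.shape[1]} columns"
        )
    return sm.OLS(y, design).fit().params


def _loglinear(exponent: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Fit ``log10 y = log10 a + s * log10 b`` by OLS.

    Returns ``(a, b, r2)`` with R^2 computed in log10 space.
    """
    if np.any(y <= 0):
        raise LogDomainError("Stevens fits require strictly positive concentrations")
    logy = np.log10(y)
    design = np.column_stack([np.ones_like(exponent), exponent])
    if np.ptp(exponent) == 0:
        # flat exponent: the best power law is the constant a = gmean(y), b = 1
        params = np.array([float(np.mean(logy)), 0.0])
    else:
        params = _ols(design, logy)
    fitted = design @ params
    return 10.0 ** params[0], 10.0 ** params[1], _r2(logy, fitted)


def _row_geometric_mean(X: np.ndarray, strict: bool) -> np.ndarray:
    """Per-row geometric mean; rows with any non-positive entry become NaN
    (warn) or raise in strict mode."""
    bad = np.any(X <= 0, axis=1)
    if bad.any():
        if strict:
            raise GeometricMeanDomainError(
                f"{int(bad.sum())} row(s) contain non-positive SdB values; "
                "geometric mean undefined"
            )
        warnings.warn(
            f"{int(bad.sum())} row(s) with non-positive SdB dropped from the "
            "geometric-mean exponent (set strict=True to raise)",
            stacklevel=3,
        )
    out = np.full(X.shape[0], np.nan)
    ok = ~bad
    if ok.any():
        out[ok] = np.exp(np.mean(np.log(X[ok]), axis=1))
    return out


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class OdorConcentrationModel:
    """A calibration model family bound to training data.

    Parameters
    ----------
    endog
        Training odor concentrations (ou/m^3, > 0).
    exog
        Training feature matrix (DataFrame or array), one column per channel.
    family
        One of :data:`FAMILIES`.
    mode
        Feature mode of ``exog`` (``"SMAX"`` or ``"SDB"``).  ``STEVENS_GEOM``
        is only defined for SDB features.
    n_components
        For PCR: an integer, or ``"auto"`` to pick the count minimizing
        leave-one-out cross-validated RMSE on the training rows.
    pca_center, pca_scale
        PCA preprocessing toggles (apply to PCR and STEVENS_PC1).
    strict
        If True, non-positive SdB rows in STEVENS_GEOM raise instead of
        being dropped with a warning.

    Examples
    --------
    >>> model = OdorConcentrationModel(y_train, X_train, family="STEVENS_PC1",
    ...                                mode="SDB")
    >>> res = model.fit()
    >>> res.predict(X_test)  # doctest: +SKIP
    """

    def __init__(
        self,
        endog,
        exog,
        family: Family,
        mode: str = "SDB",
        channel_ids: Optional[Sequence[str]] = None,
        n_components: Union[int, str] = "auto",
        pca_center: bool = True,
        pca_scale: bool = True,
        strict: bool = False,
    ) -> None:
        if family not in FAMILIES:
            raise InvalidInputError(f"unknown family {family!r}; choose from {FAMILIES}")
        if mode not in ("SMAX", "SDB"):
            raise InvalidInputError(f"mode must be SMAX or SDB, got {mode!r}")
        if family == "STEVENS_GEOM" and mode != "SDB":
            raise UnsupportedModeError(
                "STEVENS_GEOM uses the geometric mean of SdB signals and is "
                "only defined for mode='SDB'"
            )
        if isinstance(exog, pd.DataFrame):
            if channel_ids is None:
                channel_ids = list(exog.columns)
            exog = exog.to_numpy(dtype=float)
        else:
            exog = np.atleast_2d(np.asarray(exog, dtype=float))
        self.endog = np.asarray(endog, dtype=float)
        self.exog = exog
        if self.endog.size != self.exog.shape[0]:
            raise InvalidInputError(
                f"endog length {self.endog.size} != exog rows {self.exog.shape[0]}"
            )
        self.family = family
        self.mode = mode
        self.channel_ids = (
            list(channel_ids)
            if channel_ids is not None
            else [f"S{i+1}" for i in range(self.exog.shape[1])]
        )
        self.n_components = n_components
        self.pca_center = pca_center
        self.pca_scale = pca_scale
        self.strict = strict

    @classmethod
    def from_dataset(
        cls, data: CalibrationDataset, family: Family, **kwargs
    ) -> "OdorConcentrationModel":
        """Bind a family to the TRAIN rows of a :class:`CalibrationDataset`."""
        X_train, y_train = data.rows("TRAIN")
        return cls(y_train, X_train, family=family, mode=data.mode, **kwargs)

    # -- family fitters -----------------------------------------------------

    def fit(self) -> "CalibrationResults":
        y, X = self.endog, self.exog
        n, k = X.shape
        fitter = getattr(self, f"_fit_{self.family.lower()}")
        return fitter(y, X, n, k)

    def _fit_mlr(self, y, X, n, k) -> "CalibrationResults":
        if n <= k:
            raise UnderdeterminedError(
                f"MLR needs more training rows ({n}) than channels ({k})"
            )
        params = _ols(np.column_stack([np.ones(n), X]), y)
        fitted = params[0] + X @ params[1:]
        return CalibrationResults(
            model=self,
            intercept=float(params[0]),
            coefficients=np.asarray(params[1:], dtype=float),
            train_r2=_r2(y, fitted),
            fittedvalues=fitted,
        )

    def _fit_pcr(self, y, X, n, k) -> "CalibrationResults":
        if n <= 2:
            raise UnderdeterminedError("PCR needs at least 3 training rows")
        if self.n_components == "auto":
            m = self._select_pcr_components(y, X, k)
        else:
            m = int(self.n_components)
            if not 1 <= m <= k:
                raise InvalidInputError(
                    f"n_components must be in [1, {k}], got {m}"
                )
        state = fit_pca(X, center=self.pca_center, scale=self.pca_scale)
        scores = pca_transform(state, X)[:, :m]
        params = _ols(np.column_stack([np.ones(n), scores]), y)
        fitted = params[0] + scores @ params[1:]
        return CalibrationResults(
            model=self,
            intercept=float(params[0]),
            coefficients=np.asarray(params[1:], dtype=float),
            pca_state=state,
            n_components=m,
            train_r2=_r2(y, fitted),
            fittedvalues=fitted,
        )

    def _select_pcr_components(self, y, X, k) -> int:
        """Leave-one-out CV over candidate component counts; PCA is refit
        inside every fold so no test-row statistics leak into the projection.
        Ties go to the smaller count."""
        n = len(y)
        press = np.zeros(k)
        for m in range(1, k + 1):
            errors = np.empty(n)
            for i in range(n):
                keep = np.arange(n) != i
                try:
                    state = fit_pca(X[keep], self.pca_center, self.pca_scale)
                except DegenerateColumnError:
                    errors[:] = np.inf
                    break
                scores = pca_transform(state, X[keep])[:, :m]
                params = _ols(
                    np.column_stack([np.ones(n - 1), scores]), y[keep]
                )
                held = pca_transform(state, X[i : i + 1])[:, :m]
                errors[i] = y[i] - (params[0] + held @ params[1:])[0]
            press[m - 1] = np.sqrt(np.mean(errors**2))
        return int(np.argmin(press)) + 1

    def _fit_stevens_single(self, y, X, n, k) -> "CalibrationResults":
        if n < 3:
            raise UnderdeterminedError(
                "STEVENS_SINGLE needs at least 3 training rows"
            )
        best = None
        for j in range(k):
            a, b, r2 = _loglinear(X[:, j], y)
            if best is None or r2 > best[3]:
                best = (j, a, b, r2)
        j, a, b, r2 = best
        return CalibrationResults(
            model=self,
            a=a,
            b=b,
            selected_channel=self.channel_ids[j],
            train_r2=r2,
            fittedvalues=a * b ** X[:, j],
        )

    def _fit_stevens_geom(self, y, X, n, k) -> "CalibrationResults":
        g = _row_geometric_mean(X, self.strict)
        ok = np.isfinite(g)
        if ok.sum() < 3:
            raise UnderdeterminedError(
                "STEVENS_GEOM needs at least 3 usable training rows"
            )
        a, b, r2 = _loglinear(g[ok], y[ok])
        fitted = np.full(n, np.nan)
        fitted[ok] = a * b ** g[ok]
        return CalibrationResults(
            model=self, a=a, b=b, train_r2=r2, fittedvalues=fitted
        )

    def _fit_stevens_pc1(self, y, X, n, k) -> "CalibrationResults":
        state = fit_pca(X, center=self.pca_center, scale=self.pca_scale)
        pc1 = pca_transform(state, X)[:, 0]
        a, b, r2 = _loglinear(pc1, y)
        return CalibrationResults(
            model=self,
            a=a,
            b=b,
            pca_state=state,
            train_r2=r2,
            fittedvalues=a * b**pc1,
        )


@dataclass
class CalibrationResults:
    """Fitted calibration model: coefficients, diagnostics, prediction.

    Which fields are populated depends on the family: MLR/PCR carry
    ``intercept`` and ``coefficients`` (on the channel or PC basis), the
    Stevens families carry the power-law pair ``(a, b)``; PCR and
    STEVENS_PC1 additionally carry the frozen :class:`PcaState`, and
    STEVENS_SINGLE records its ``selected_channel``.
    """

    model: OdorConcentrationModel
    intercept: Optional[float] = None
    coefficients: Optional[np.ndarray] = None
    a: Optional[float] = None
    b: Optional[float] = None
    pca_state: Optional[PcaState] = None
    n_components: Optional[int] = None
    selected_channel: Optional[str] = None
    train_r2: float = float("nan")
    fittedvalues: np.ndarray = field(default_factory=lambda: np.array([]))

    # -- convenience --------------------------------------------------------

    @property
    def family(self) -> str:
        return self.model.family

    @property
    def mode(self) -> str:
        return self.model.mode

    @property
    def channel_ids(self) -> list[str]:
        return self.model.channel_ids

    def _coerce(self, X_new, mode: Optional[str]) -> np.ndarray:
        if mode is not None and mode != self.mode:
            raise IncompatibleInputError(
                f"model was fitted on {self.mode} features, got {mode}"
            )
        if isinstance(X_new, pd.DataFrame):
            missing = [c for c in self.channel_ids if c not in X_new.columns]
            if missing:
                raise IncompatibleInputError(f"missing channel column(s) {missing}")
            X_new = X_new[self.channel_ids].to_numpy(dtype=float)
        else:
            X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != len(self.channel_ids):
            raise IncompatibleInputError(
                f"expected {len(self.channel_ids)} channels, got {X_new.shape[1]}"
            )
        return X_new

    def predict(self, X_new, mode: Optional[str] = None) -> np.ndarray:
        """Predicted odor concentrations (ou/m^3) for new feature rows.

        ``mode``, when given, is checked against the fitted mode.  Stevens
        families return strictly positive values for finite inputs.
        """
        X = self._coerce(X_new, mode)
        fam = self.family
        if fam == "MLR":
            return self.intercept + X @ self.coefficients
        if fam == "PCR":
            scores = pca_transform(self.pca_state, X)[:, : self.n_components]
            return self.intercept + scores @ self.coefficients
        if fam == "STEVENS_SINGLE":
            j = self.channel_ids.index(self.selected_channel)
            return self.a * self.b ** X[:, j]
        if fam == "STEVENS_GEOM":
            g = _row_geometric_mean(X, self.model.strict)
            return self.a * self.b**g
        if fam == "STEVENS_PC1":
            pc1 = pca_transform(self.pca_state, X)[:, 0]
            return self.a * self.b**pc1
        raise InvalidInputError(f"unknown family {fam!r}")  # pragma: no cover

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            "Odor concentration calibration",
            "=" * 46,
            f"family:        {self.family}",
            f"feature mode:  {self.mode}",
            f"channels:      {', '.join(self.channel_ids)}",
            f"n (train):     {len(self.model.endog)}",
            f"train R^2:     {self.train_r2:.4f}"
            + ("  (log10 space)" if self.family.startswith("STEVENS") else ""),
        ]
        if self.family in ("MLR", "PCR"):
            basis = (
                [f"PC{i+1}" for i in range(self.n_components)]
                if self.family == "PCR"
                else self.channel_ids
            )
            lines.append(f"intercept a0:  {self.intercept:.6g}")
            for name, c in zip(basis, self.coefficients):
                lines.append(f"  a[{name}]: {c:.6g}")
        else:
            lines.append(f"a: {self.a:.6g}    b: {self.b:.6g}")
            if self.selected_channel:
                lines.append(f"selected channel: {self.selected_channel}")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "mode": self.mode,
            "channel_ids": self.channel_ids,
            "intercept": self.intercept,
            "coefficients": (
                None if self.coefficients is None else self.coefficients.tolist()
            ),
            "a": self.a,
            "b": self.b,
            "pca_state": None if self.pca_state is None else self.pca_state.to_dict(),
            "n_components": self.n_components,
            "selected_channel": self.selected_channel,
            "train_r2": self.train_r2,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResults":
        shell = OdorConcentrationModel(
            endog=np.array([1.0]),
            exog=np.zeros((1, len(d["channel_ids"]))),
            family=d["family"],
            mode=d["mode"],
            channel_ids=d["channel_ids"],
        )
        return cls(
            model=shell,
            intercept=d["intercept"],
            coefficients=(
                None
                if d["coefficients"] is None
                else np.asarray(d["coefficients"], dtype=float)
            ),
            a=d["a"],
            b=d["b"],
            pca_state=(
                None if d["pca_state"] is None else PcaState.from_dict(d["pca_state"])
            ),
            n_components=d["n_components"],
            selected_channel=d["selected_channel"],
            train_r2=d["train_r2"],
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationResults":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Functional wrappers over the Model/Results pair
# ---------------------------------------------------------------------------


def fit_mlr(data: CalibrationDataset, **kwargs) -> CalibrationResults:
    """Multiple linear regression of C_od on the channel features."""
    return OdorConcentrationModel.from_dataset(data, "MLR", **kwargs).fit()


def fit_pcr(
    data: CalibrationDataset, n_components: Union[int, str] = "auto", **kwargs
) -> CalibrationResults:
    """Principal component regression; ``n_components="auto"`` uses
    leave-one-out CV on the training rows."""
    return OdorConcentrationModel.from_dataset(
        data, "PCR", n_components=n_components, **kwargs
    ).fit()


def fit_stevens_single(data: CalibrationDataset, **kwargs) -> CalibrationResults:
    """Stevens power law with the single best channel as exponent; the
    channel with the highest training R^2 (log space) is selected."""
    return OdorConcentrationModel.from_dataset(data, "STEVENS_SINGLE", **kwargs).fit()


def fit_stevens_geom(data: CalibrationDataset, **kwargs) -> CalibrationResults:
    """Stevens power law with the geometric mean of the SdB channels as
    exponent; SDB mode only."""
    return OdorConcentrationModel.from_dataset(data, "STEVENS_GEOM", **kwargs).fit()


def fit_stevens_pc1(data: CalibrationDataset, **kwargs) -> CalibrationResults:
    """Stevens power law with the first principal component score as
    exponent (PCA: centered, unit-variance scaled, fit on training rows)."""
    return OdorConcentrationModel.from_dataset(data, "STEVENS_PC1", **kwargs).fit()


def predict(model: CalibrationResults, X_new, mode: Optional[str] = None) -> np.ndarray:
    """Functional alias for :meth:`CalibrationResults.predict`."""
    return model.predict(X_new, mode=mode)
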