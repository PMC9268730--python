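"""Model validation, the OAQII scale, accordance, and model selection.

The Odor Air Quality Index (OAQII) is a four-class scale over odor
concentration, each class carrying verbal intensity and hedonic descriptors:

====== =========== ========================== ======================== ==============
index  label       intensity descriptor       hedonic descriptor       C_od (ou/m^3)
====== =========== ========================== ======================== ==============
0      very good   non-perceptible, very weak neutral, slightly unpl.  0 < C <= 3
1      moderate    weak                       moderately unpleasant    3 < C <= 10
2      bad         distinct and strong        very unpleasant          10 < C <= 60
3      very bad    very and extremely strong  extremely unpleasant     C > 60
====== =========== ========================== ======================== ==============

Boundaries are lower-exclusive / upper-inclusive, so C = 3 is class 0 and
C = 60 is class 2.  Model quality on a test split is measured two ways:
RMSE in concentration units, and *accordance* — the fraction of test
measurements the model and the olfactometric reference assign to the same
OAQII class.  Selection prefers high accordance among models whose RMSE is
within a configurable relative slack of the best, reflecting that a small
concentration error matters less than landing in the wrong index class.

The scale itself can be rebuilt from psychophysical data: intensity and
hedonic annotations regressed on log10 concentration (Weber–Fechner), then
inverted at annotation cut-points to concentration bounds.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .calibration import CalibrationDataset, CalibrationResults, _ols, _r2
from .errors import (
    DomainError,
    IncompatibleInputError,
    InvalidInputError,
    InvalidSplitError,
    NonInvertibleError,
)

__all__ = [
    "OaqiiClass",
    "OaqiiScale",
    "EvaluationReport",
    "PsychophysicalFit",
    "rmse",
    "classify_oaqii",
    "accordance",
    "evaluate_model",
    "select_best_model",
    "fit_psychophysical",
    "scale_from_psychophysics",
    "validation_plot",
]


@dataclass(frozen=True)
class OaqiiClass:
    """One OAQII class: index, label, descriptors, and its lower-exclusive /
    upper-inclusive concentration interval in ou/m^3."""

    index: int
    label: str
    descriptor_intensity: str
    descriptor_hedonic: str
    lower: float  # exclusive
    upper: float  # inclusive; inf for the top class


_DEFAULT_CLASSES = (
    OaqiiClass(0, "very good", "non-perceptible and very weak",
               "neutral and slightly unpleasant", 0.0, 3.0),
    OaqiiClass(1, "moderate", "weak", "moderately unpleasant", 3.0, 10.0),
    OaqiiClass(2, "bad", "distinct and strong", "very unpleasant", 10.0, 60.0),
    OaqiiClass(3, "very bad", "very and extremely strong",
               "extremely unpleasant", 60.0, math.inf),
)


@dataclass(frozen=True)
class OaqiiScale:
    """Ordered, contiguous OAQII classes covering (0, inf).

    The default is the canonical four-class scale with bounds 3, 10 and
    60 ou/m^3.  Use :meth:`from_bounds` to build a scale with the same
    labels but different interior bounds (e.g. psychophysically derived).
    """

    classes: tuple[OaqiiClass, ...] = _DEFAULT_CLASSES

    def __post_init__(self) -> None:
        cls = self.classes
        if not cls:
            raise InvalidInputError("scale needs at least one class")
        if cls[0].lower != 0.0 or not math.isinf(cls[-1].upper):
            raise InvalidInputError("scale must cover (0, inf)")
        for lo, hi in zip(cls, cls[1:]):
            if lo.upper != hi.lower:
                raise InvalidInputError(
                    f"classes {lo.index} and {hi.index} are not contiguous"
                )
            if lo.upper <= lo.lower:
                raise InvalidInputError(f"class {lo.index} interval is empty")

    @property
    def bounds(self) -> list[float]:
        """Interior class boundaries (finite upper bounds)."""
        return [c.upper for c in self.classes[:-1]]

    @classmethod
    def from_bounds(cls, bounds: Sequence[float]) -> "OaqiiScale":
        bounds = [float(b) for b in bounds]
        if len(bounds) != len(_DEFAULT_CLASSES) - 1 or sorted(bounds) != bounds:
            raise InvalidInputError(
                f"need {len(_DEFAULT_CLASSES) - 1} increasing bounds, got {bounds}"
            )
        edges = [0.0, *bounds, math.inf]
        classes = tuple(
            OaqiiClass(c.index, c.label, c.descriptor_intensity,
                       c.descriptor_hedonic, edges[i], edges[i + 1])
            for i, c in enumerate(_DEFAULT_CLASSES)
        )
        return cls(classes)


def rmse(y_true, y_pred) -> float:
    """Root mean square error between observed and predicted concentrations:
    the Euclidean distance between the two vectors scaled by 1/sqrt(n)."""
    a = np.asarray(y_true, dtype=float)
    b = np.asarray(y_pred, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise InvalidInputError(
            f"rmse needs equal-length non-empty vectors, got {a.shape} vs {b.shape}"
        )
    return float(np.sqrt(np.mean((a - b) ** 2)))


def classify_oaqii(cod, scale: Optional[OaqiiScale] = None):
    """OAQII class index (0-3) for one or many concentrations.

    Boundaries are upper-inclusive: a concentration exactly at a class's
    upper bound belongs to that class.

    Raises
    ------
    DomainError
        For any non-positive concentration.
    """
    scale = scale or OaqiiScale()
    arr = np.asarray(cod, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise DomainError("odor concentration must be finite and > 0")
    edges = np.array(scale.bounds)
    # index = number of interior bounds strictly below cod
    idx = np.searchsorted(edges, arr, side="left")
    # searchsorted(side='left') puts cod == bound at that bound's class
    indices = np.array([scale.classes[i].index for i in np.atleast_1d(idx)])
    if arr.ndim == 0:
        return int(indices[0])
    return indices


def accordance(labels_true, labels_pred) -> float:
    """Fraction of measurements assigned to the same OAQII class by the
    model and by the olfactometric reference."""
    a = np.asarray(labels_true)
    b = np.asarray(labels_pred)
    if a.shape != b.shape or a.size == 0:
        raise InvalidInputError(
            f"accordance needs equal-length non-empty label vectors, "
            f"got {a.shape} vs {b.shape}"
        )
    return float(np.mean(a == b))


@dataclass
class EvaluationReport:
    """Test-split validation of one fitted model.

    ``n_used`` may be smaller than ``N`` when a Stevens-geometric-mean model
    could not predict some rows (non-positive SdB); metrics cover the
    ``n_used`` valid pairs.
    """

    model_family: str
    mode: str
    y_true: np.ndarray
    y_pred: np.ndarray
    rmse: float
    labels_true: np.ndarray
    labels_pred: np.ndarray
    n_correct: int
    accordance: float
    N: int
    n_used: int = 0
    descriptor: str = ""

    def to_dict(self) -> dict:
        return {
            "model_family": self.model_family,
            "mode": self.mode,
            "descriptor": self.descriptor,
            "rmse": self.rmse,
            "accordance": self.accordance,
            "n_correct": self.n_correct,
            "N": self.N,
            "n_used": self.n_used,
            "y_true": self.y_true.tolist(),
            "y_pred": self.y_pred.tolist(),
            "labels_true": self.labels_true.tolist(),
            "labels_pred": self.labels_pred.tolist(),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def evaluate_model(
    model: CalibrationResults,
    data: CalibrationDataset,
    scale: Optional[OaqiiScale] = None,
) -> EvaluationReport:
    """Predict on the TEST rows and score RMSE, OAQII labels and accordance.

    Predicted concentrations are floored at a small positive value before
    classification so a linear model's occasional negative output still
    receives the lowest class rather than crashing the index.
    """
    scale = scale or OaqiiScale()
    if data.mode != model.mode:
        raise IncompatibleInputError(
            f"model mode {model.mode} vs dataset mode {data.mode}"
        )
    X_test, y_test = data.rows("TEST")
    if len(X_test) == 0:
        raise InvalidSplitError("dataset has no TEST rows")
    y_pred = model.predict(X_test)
    ok = np.isfinite(y_pred)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} test prediction(s) undefined for "
            f"{model.family}; excluded from metrics",
            stacklevel=2,
        )
    y_used, p_used = y_test[ok], y_pred[ok]
    if y_used.size == 0:
        raise InvalidInputError("no valid test predictions to evaluate")
    labels_true = classify_oaqii(y_used, scale)
    labels_pred = classify_oaqii(np.maximum(p_used, 1e-9), scale)
    n_correct = int(np.sum(labels_true == labels_pred))
    return EvaluationReport(
        model_family=model.family,
        mode=model.mode,
        y_true=y_used,
        y_pred=p_used,
        rmse=rmse(y_used, p_used),
        labels_true=labels_true,
        labels_pred=labels_pred,
        n_correct=n_correct,
        accordance=n_correct / y_used.size,
        N=int(len(X_test)),
        n_used=int(y_used.size),
        descriptor=f"{model.family} ({model.mode})",
    )


def select_best_model(
    reports: Sequence[EvaluationReport], rmse_slack: float = 0.25
) -> EvaluationReport:
    """Pick the preferred model: among those whose RMSE is within
    ``(1 + rmse_slack)`` of the minimum, maximize accordance; break ties by
    lower RMSE, then by input order.

    With ``rmse_slack=0`` and equal accordances this reduces to plain
    argmin-RMSE.  The default slack of 0.25 encodes the judgement that an
    RMSE difference of this size is outweighed by better class accordance.
    """
    reports = list(reports)
    if not reports:
        raise InvalidInputError("no reports to select from")
    best_rmse = min(r.rmse for r in reports)
    cutoff = (1.0 + rmse_slack) * best_rmse
    candidates = [r for r in reports if r.rmse <= cutoff]
    return min(candidates, key=lambda r: (-r.accordance, r.rmse))


@dataclass(frozen=True)
class PsychophysicalFit:
    """Linear Weber–Fechner fit: annotation = intercept + slope*log10(C_od)."""

    variable: Literal["INTENSITY", "HEDONIC"]
    slope: float
    intercept: float
    r2: float

    def invert(self, value: float) -> float:
        """Concentration (ou/m^3) at which the fitted line reaches ``value``."""
        if self.slope == 0:
            raise NonInvertibleError(
                f"{self.variable} fit has zero slope and cannot be inverted"
            )
        return float(10.0 ** ((value - self.intercept) / self.slope))


def fit_psychophysical(sessions, variable: str) -> PsychophysicalFit:
    """OLS of an ordinal annotation on log10 odor concentration.

    ``sessions`` is an iterable of objects with ``cod`` and
    ``intensity``/``hedonic`` attributes (e.g. :class:`~odorcal.olfactometry.
    OlfactometrySession`); sessions missing the annotation are skipped.
    At least 3 annotated sessions with positive cod are required.
    """
    variable = variable.upper()
    if variable not in ("INTENSITY", "HEDONIC"):
        raise InvalidInputError(f"variable must be INTENSITY or HEDONIC, got {variable!r}")
    attr = variable.lower()
    pairs = [
        (s.cod, getattr(s, attr))
        for s in sessions
        if getattr(s, attr) is not None and s.cod is not None and s.cod > 0
    ]
    if len(pairs) < 3:
        raise InvalidInputError(
            f"need >= 3 sessions with {attr} annotations and cod > 0, got {len(pairs)}"
        )
    cod = np.array([p[0] for p in pairs])
    ann = np.array([p[1] for p in pairs], dtype=float)
    x = np.log10(cod)
    design = np.column_stack([np.ones_like(x), x])
    if np.ptp(x) == 0:
        raise InvalidInputError("all sessions share one concentration; fit undefined")
    params = _ols(design, ann)
    fitted = design @ params
    return PsychophysicalFit(
        variable=variable,
        slope=float(params[1]),
        intercept=float(params[0]),
        r2=_r2(ann, fitted),
    )


def scale_from_psychophysics(
    fit_intensity: PsychophysicalFit,
    fit_hedonic: PsychophysicalFit,
    intensity_cutpoints: Sequence[float],
    hedonic_cutpoints: Sequence[float],
) -> OaqiiScale:
    """Derive the OAQII concentration bounds from the two psychophysical fits.

    Each fit is inverted at its three annotation-scale cut-points, giving two
    candidate concentrations per class boundary; the candidates are combined
    by geometric mean (concentrations combine multiplicatively).  The result
    is validated as a contiguous increasing scale.
    """
    if len(intensity_cutpoints) != 3 or len(hedonic_cutpoints) != 3:
        raise InvalidInputError("exactly 3 cut-points per annotation scale required")
    bounds = []
    for ci, ch in zip(intensity_cutpoints, hedonic_cutpoints):
        bi = fit_intensity.invert(ci)
        bh = fit_hedonic.invert(ch)
        bounds.append(math.sqrt(bi * bh))
    if sorted(bounds) != bounds:
        raise InvalidInputError(
            f"derived bounds {bounds} are not increasing; check cut-points"
        )
    return OaqiiScale.from_bounds(bounds)


def validation_plot(report: EvaluationReport, scale: Optional[OaqiiScale] = None,
                    ax=None):
    """Observed-vs-predicted scatter with OAQII class rectangles.

    Points whose predicted class matches the observed class are drawn in
    black, mismatches in red; shaded squares mark the class-concordant
    regions.  Cosmetic output; returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    scale = scale or OaqiiScale()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    top = max(report.y_true.max(), report.y_pred.max()) * 1.3
    for c in scale.classes:
        hi = min(c.upper, top)
        ax.add_patch(
            plt.Rectangle((c.lower, c.lower), hi - c.lower, hi - c.lower,
                          alpha=0.15, color="tab:blue", linewidth=0)
        )
    match = report.labels_true == report.labels_pred
    ax.scatter(report.y_true[match], report.y_pred[match], c="k", s=18,
               label="within class")
    ax.scatter(report.y_true[~match], report.y_pred[~match], c="r", s=18,
               label="outside class")
    ax.set_xlabel("olfactometric $C_{od}$ [ou/m$^3$]")
    ax.set_ylabel("predicted $C_{od}$ [ou/m$^3$]")
    ax.set_title(
        f"{report.descriptor}: RMSE={report.rmse:.3f}, "
        f"accordance={report.accordance:.2f}"
    )
    ax.set_xlim(0, top)
    ax.set_ylim(0, top)
    ax.legend(loc="upper left", fontsize=8)
    return ax
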