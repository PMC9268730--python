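"""End-to-end calibration workflow: features -> models -> validation -> OAQII.

:func:`run_pipeline` executes the full study protocol on a bundle of
sessions and exposure windows: per requested feature mode it extracts
features, applies the interferent rejection filter, fits every compatible
model family on the TRAIN split (four families for SMAX — the geometric-mean
Stevens family needs dB features — five for SDB), validates each on the TEST
split, and selects the preferred model per mode and overall.  It finally
emits a per-window OAQII classification stream from the overall best model,
the continuous-monitoring view of the calibrated array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    FAMILIES,
    CalibrationDataset,
    CalibrationResults,
    OdorConcentrationModel,
)
from .errors import AlignmentError, ConfigError
from .evaluation import (
    EvaluationReport,
    OaqiiScale,
    classify_oaqii,
    evaluate_model,
    fit_psychophysical,
    scale_from_psychophysics,
    select_best_model,
)
from .features import (
    ExposureWindow,
    FeatureVector,
    estimate_baseline,
    extract_features,
    reject_interferent_records,
)
from .olfactometry import OlfactometrySession
from .synthetic import StudyBundle

__all__ = ["PipelineConfig", "PipelineResult", "build_dataset", "run_pipeline",
           "classify_stream"]

#: Annotation-scale cut-points at the three OAQII class boundaries, on the
#: default intensity (0..6) and hedonic (0..-4) ordinal scales: midpoints
#: between the descriptor bands of adjacent classes.
DEFAULT_INTENSITY_CUTPOINTS = (1.5, 2.5, 4.5)
DEFAULT_HEDONIC_CUTPOINTS = (-1.5, -2.5, -3.5)


@dataclass(frozen=True)
class PipelineConfig:
    """What to run and how.

    ``scale_source`` is ``"canonical"`` for the canonical OAQII bounds
    (3, 10, 60 ou/m^3) or ``"derived"`` to rebuild the scale from the
    training sessions' intensity/hedonic annotations.
    """

    modes: tuple[str, ...] = ("SMAX", "SDB")
    families: tuple[str, ...] = FAMILIES
    scale_source: str = "canonical"
    cod_low: float = 3.0
    z_high: float = 3.0
    reject_interferents: bool = True
    rmse_slack: float = 0.25
    baseline_method: str = "flagged"
    mos_channels: Optional[tuple[str, ...]] = None  # inferred from bundle if None
    intensity_cutpoints: tuple[float, float, float] = DEFAULT_INTENSITY_CUTPOINTS
    hedonic_cutpoints: tuple[float, float, float] = DEFAULT_HEDONIC_CUTPOINTS
    strict: bool = False

    def __post_init__(self) -> None:
        if not self.modes:
            raise ConfigError("at least one feature mode is required")
        if not self.families:
            raise ConfigError("at least one model family is required")
        bad_modes = [m for m in self.modes if m not in ("SMAX", "SDB")]
        if bad_modes:
            raise ConfigError(f"unknown mode(s) {bad_modes}")
        bad = [f for f in self.families if f not in FAMILIES]
        if bad:
            raise ConfigError(f"unknown model famil(ies) {bad}")
        if "STEVENS_GEOM" in self.families and "SDB" not in self.modes:
            raise ConfigError(
                "STEVENS_GEOM requires SDB features; add 'SDB' to modes or "
                "drop the family"
            )
        if self.scale_source not in ("canonical", "derived"):
            raise ConfigError("scale_source must be 'canonical' or 'derived'")

    def families_for_mode(self, mode: str) -> tuple[str, ...]:
        if mode == "SMAX":
            return tuple(f for f in self.families if f != "STEVENS_GEOM")
        return self.families


@dataclass
class PipelineResult:
    """Everything the workflow produced, keyed by feature mode."""

    datasets: dict
    models: dict  # (mode, family) -> CalibrationResults
    reports: dict  # mode -> list[EvaluationReport]
    best_by_mode: dict  # mode -> EvaluationReport
    best_overall: EvaluationReport
    scale: OaqiiScale
    rejection_logs: dict = field(default_factory=dict)
    stream: Optional[pd.DataFrame] = None

    def summary(self) -> str:
        lines = ["Pipeline summary", "=" * 52]
        for mode, reports in self.reports.items():
            lines.append(f"[{mode}] {len(reports)} models fitted")
            for r in reports:
                marker = " *" if r is self.best_by_mode[mode] else "  "
                lines.append(
                    f"{marker} {r.model_family:<15} RMSE={r.rmse:8.3f}  "
                    f"accordance={r.accordance:.2f}  (N={r.n_used})"
                )
        best = self.best_overall
        lines.append(
            f"selected overall: {best.model_family} ({best.mode}) — "
            f"RMSE={best.rmse:.3f}, accordance={best.accordance:.2f}"
        )
        return "\n".join(lines)


def build_dataset(
    sessions: Sequence[OlfactometrySession],
    windows: Sequence[ExposureWindow],
    split: Sequence[str],
    mode: str,
    config: Optional[PipelineConfig] = None,
    mos_channels: Optional[Sequence[str]] = None,
) -> tuple[CalibrationDataset, list[dict]]:
    """Aligned feature matrix and concentrations for one mode.

    Sessions and windows are matched positionally and must agree in count;
    window ids are carried as the row index.  The interferent rejection
    filter runs before assembly (unless disabled) and its log is returned.
    """
    config = config or PipelineConfig()
    if len(sessions) != len(windows) or len(sessions) != len(split):
        raise AlignmentError(
            f"{len(sessions)} sessions vs {len(windows)} windows vs "
            f"{len(split)} split labels"
        )
    feats: list[FeatureVector] = []
    for w in windows:
        s0 = estimate_baseline(w, method=config.baseline_method)
        feats.append(extract_features(w, mode, s0=s0))
    cod = np.array([s.cod for s in sessions], dtype=float)
    log: list[dict] = []
    if config.reject_interferents:
        mos = tuple(mos_channels or config.mos_channels or ())
        retained, log = reject_interferent_records(
            feats, cod, mos, cod_low=config.cod_low, z_high=config.z_high
        )
        kept_ids = {f.window_id for f in retained}
        mask = np.array([f.window_id in kept_ids for f in feats])
        feats = retained
        cod = cod[mask]
        split = np.asarray(split, dtype=object)[mask]
    X = pd.DataFrame({f.window_id: f.values for f in feats}).T
    dataset = CalibrationDataset(X=X, y=cod, split=np.asarray(split, dtype=object),
                                 mode=mode)
    return dataset, log


def _resolve_scale(
    config: PipelineConfig, sessions: Sequence[OlfactometrySession], split
) -> OaqiiScale:
    if config.scale_source == "canonical":
        return OaqiiScale()
    train_sessions = [s for s, lab in zip(sessions, split) if lab == "TRAIN"]
    fit_i = fit_psychophysical(train_sessions, "INTENSITY")
    fit_h = fit_psychophysical(train_sessions, "HEDONIC")
    return scale_from_psychophysics(
        fit_i, fit_h, config.intensity_cutpoints, config.hedonic_cutpoints
    )


def classify_stream(
    model: CalibrationResults,
    windows: Sequence[ExposureWindow],
    scale: Optional[OaqiiScale] = None,
    baseline_method: str = "flagged",
) -> pd.DataFrame:
    """Per-window monitoring stream: predicted C_od and OAQII class."""
    scale = scale or OaqiiScale()
    rows = []
    for w in windows:
        s0 = estimate_baseline(w, method=baseline_method)
        fv = extract_features(w, model.mode, s0=s0)
        pred = float(model.predict(fv.values.to_frame().T)[0])
        rows.append(
            {
                "window_id": w.window_id,
                "cod_pred": pred,
                "oaqii": int(classify_oaqii(max(pred, 1e-9), scale)),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    bundle_or_parts,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run the full workflow on a :class:`~odorcal.synthetic.StudyBundle`
    or a ``(sessions, windows, split)`` triple.

    Returns a :class:`PipelineResult` with fitted models, per-mode
    evaluation reports, per-mode and overall selections, and the
    classification stream of the overall best model over all windows.
    """
    config = config or PipelineConfig()
    if isinstance(bundle_or_parts, StudyBundle):
        sessions = bundle_or_parts.sessions
        windows = bundle_or_parts.windows
        split = bundle_or_parts.split
        mos = tuple(
            c.channel_id for c in bundle_or_parts.config.channels if c.kind == "MOS"
        )
    else:
        sessions, windows, split = bundle_or_parts
        mos = tuple(config.mos_channels or ())
    scale = _resolve_scale(config, sessions, split)

    datasets, models, reports, best_by_mode, logs = {}, {}, {}, {}, {}
    for mode in config.modes:
        dataset, log = build_dataset(
            sessions, windows, split, mode, config, mos_channels=mos
        )
        datasets[mode] = dataset
        logs[mode] = log
        mode_reports = []
        for family in config.families_for_mode(mode):
            results = OdorConcentrationModel.from_dataset(
                dataset, family, strict=config.strict
            ).fit()
            models[(mode, family)] = results
            mode_reports.append(evaluate_model(results, dataset, scale))
        reports[mode] = mode_reports
        best_by_mode[mode] = select_best_model(mode_reports, config.rmse_slack)

    all_reports = [r for rs in reports.values() for r in rs]
    best_overall = select_best_model(all_reports, config.rmse_slack)
    best_model = models[(best_overall.mode, best_overall.model_family)]
    stream = classify_stream(best_model, windows, scale, config.baseline_method)
    return PipelineResult(
        datasets=datasets,
        models=models,
        reports=reports,
        best_by_mode=best_by_mode,
        best_overall=best_overall,
        scale=scale,
        rejection_logs=logs,
        stream=stream,
    )
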