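"""Signal-feature extraction from gas-sensor-array time series.

Two per-channel representations of a recorded exposure window are supported:

``SMAX``
    The raw maximum signal over the window, in signal units.
``SDB``
    The peak-to-baseline ratio on a decibel scale,
    ``S_dB = 10 * log10(Smax / S0)``, where ``S0`` is the channel baseline
    measured in clean (synthetic) air.  The logarithmic form mirrors the
    Weber–Fechner picture of odor perception and, usefully, is invariant to
    a channel's electrical gain: rescaling both ``Smax`` and ``S0`` by the
    same factor leaves ``S_dB`` unchanged, whereas ``SMAX`` features shift.

The module also implements the interferent-record rejection rule: metal-oxide
(MOS) channels respond to odorless gases such as methane, so records that
combine a low olfactometric odor concentration with an extreme MOS response
are treated as interferent artefacts and dropped before calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    BaselineError,
    DomainError,
    EmptyWindowError,
)

__all__ = [
    "SensorChannel",
    "ExposureWindow",
    "FeatureVector",
    "estimate_baseline",
    "extract_smax",
    "to_decibels",
    "extract_features",
    "reject_interferent_records",
]

Mode = Literal["SMAX", "SDB"]

#: MAD-to-sigma consistency factor for a normal distribution.
_MAD_SCALE = 1.4826


@dataclass(frozen=True)
class SensorChannel:
    """Metadata for one array channel.

    ``kind`` is ``"MOS"`` for metal-oxide-semiconductor chemiresistors
    (broad-spectrum, methane-sensitive) or ``"EC"`` for electrochemical
    cells (target-gas selective, near-linear response).
    """

    channel_id: str
    kind: Literal["MOS", "EC"]
    baseline_s0: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("MOS", "EC"):
            raise DomainError(f"channel kind must be MOS or EC, got {self.kind!r}")
        if not np.isfinite(self.baseline_s0) or self.baseline_s0 <= 0:
            raise BaselineError(
                f"channel {self.channel_id!r}: baseline_s0 must be positive"
            )


@dataclass
class ExposureWindow:
    """One recorded exposure: per-channel signal series on a common clock.

    Attributes
    ----------
    window_id
        Label linking the window to an olfactometric session.
    timestamps
        Strictly increasing sample times (seconds or ISO-convertible).
    signals
        DataFrame with one column per channel_id, same length as timestamps.
    baseline_segment
        Optional ``(start, stop)`` index range (stop exclusive) flagged as a
        clean-air reference for baseline estimation.
    """

    window_id: str
    timestamps: np.ndarray
    signals: pd.DataFrame
    baseline_segment: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.signals) != len(self.timestamps):
            raise DomainError(
                f"window {self.window_id!r}: signals length {len(self.signals)} "
                f"!= timestamps length {len(self.timestamps)}"
            )
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise DomainError(
                f"window {self.window_id!r}: timestamps must be strictly increasing"
            )

    @property
    def channel_ids(self) -> list[str]:
        return list(self.signals.columns)


@dataclass
class FeatureVector:
    """Per-channel features for one window under a declared extraction mode.

    ``values`` holds the mode-dependent feature (signal units for SMAX, dB
    for SDB); ``smax_raw`` retains the raw per-channel maxima regardless of
    mode so the rejection filter and diagnostics can always see them.
    """

    window_id: str
    mode: Mode
    values: pd.Series
    smax_raw: pd.Series


def estimate_baseline(
    window: ExposureWindow,
    method: str = "flagged",
    *,
    quantile: float = 0.05,
    roll_window: int = 25,
) -> pd.Series:
    """Per-channel baseline S0 from clean air.

    ``method="flagged"`` (default) averages the window's flagged clean-air
    segment — the offline synthetic-air procedure.  ``method="rolling-quantile"``
    is a field fallback: the minimum of a rolling ``quantile`` over windows of
    ``roll_window`` samples, for logs with no flagged reference.

    Raises
    ------
    BaselineError
        If no flagged segment exists in flagged mode, or any estimated
        baseline is non-positive.
    """
    if method == "flagged":
        if window.baseline_segment is None:
            raise BaselineError(
                f"window {window.window_id!r}: no flagged clean-air segment; "
                "use method='rolling-quantile'"
            )
        start, stop = window.baseline_segment
        segment = window.signals.iloc[start:stop]
        if segment.empty:
            raise BaselineError(
                f"window {window.window_id!r}: empty clean-air segment"
            )
        s0 = segment.mean()
    elif method == "rolling-quantile":
        n = min(roll_window, len(window.signals))
        if n == 0:
            raise EmptyWindowError(f"window {window.window_id!r} is empty")
        s0 = window.signals.rolling(n, min_periods=1).quantile(quantile).min()
    else:
        raise DomainError(f"unknown baseline method {method!r}")
    if not np.all(np.isfinite(s0)) or (s0 <= 0).any():
        bad = s0.index[~(s0 > 0)].tolist()
        raise BaselineError(
            f"window {window.window_id!r}: non-positive baseline for {bad}"
        )
    return s0.astype(float)


def extract_smax(window: ExposureWindow) -> pd.Series:
    """Per-channel maximum signal over the window."""
    if len(window.signals) == 0:
        raise EmptyWindowError(f"window {window.window_id!r} is empty")
    return window.signals.max().astype(float)


def to_decibels(smax, s0):
    """Peak-to-baseline ratio in decibels: ``10 * log10(smax / s0)``.

    Accepts scalars or aligned array-likes.  Strictly increasing in ``smax``;
    exactly 0 when ``smax == s0``.
    """
    smax_arr = np.asarray(smax, dtype=float)
    s0_arr = np.asarray(s0, dtype=float)
    if np.any(smax_arr <= 0) or np.any(s0_arr <= 0):
        raise DomainError("to_decibels requires strictly positive smax and s0")
    result = 10.0 * np.log10(smax_arr / s0_arr)
    if np.isscalar(smax) and np.isscalar(s0):
        return float(result)
    return result


def extract_features(
    window: ExposureWindow,
    mode: Mode,
    s0: Optional[pd.Series] = None,
    baseline_method: str = "flagged",
) -> FeatureVector:
    """Extract a :class:`FeatureVector` from one window.

    In SDB mode the baseline ``s0`` may be supplied explicitly (e.g. from a
    bench synthetic-air run); otherwise it is estimated from the window via
    :func:`estimate_baseline`.
    """
    smax = extract_smax(window)
    if mode == "SMAX":
        values = smax.copy()
    elif mode == "SDB":
        if s0 is None:
            s0 = estimate_baseline(window, method=baseline_method)
        s0 = s0.reindex(smax.index)
        if s0.isna().any():
            raise DomainError(
                f"window {window.window_id!r}: baseline missing for channels "
                f"{s0.index[s0.isna()].tolist()}"
            )
        values = pd.Series(to_decibels(smax.values, s0.values), index=smax.index)
    else:
        raise DomainError(f"unknown feature mode {mode!r}")
    return FeatureVector(window.window_id, mode, values.astype(float), smax)


def _robust_z(values: np.ndarray) -> np.ndarray:
    """Robust z-scores via median/MAD.  A zero MAD makes any deviation
    from the median infinitely extreme (and the median itself score 0)."""
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    scale = _MAD_SCALE * mad
    if scale == 0:
        z = np.where(values == med, 0.0, np.inf)
    else:
        z = np.abs(values - med) / scale
    return z


def reject_interferent_records(
    features: Sequence[FeatureVector],
    cod: Sequence[float],
    mos_channels: Sequence[str],
    cod_low: float = 3.0,
    z_high: float = 3.0,
) -> tuple[list[FeatureVector], list[dict]]:
    """Drop records where an odorless interferent inflated the MOS channels.

    A record is rejected iff its odor concentration is at or below ``cod_low``
    (ou/m^3) *and* at least one MOS-channel feature exceeds ``z_high`` robust
    z-scores (median/MAD computed over the full input set, single pass).
    Order of retained records is preserved.

    Returns
    -------
    (retained, rejection_log)
        ``rejection_log`` has one dict per rejected record with the window_id,
        its cod, and the offending channels with their z-scores.

    Raises
    ------
    AlignmentError
        If ``features`` and ``cod`` differ in length.
    """
    features = list(features)
    cod_arr = np.asarray(list(cod), dtype=float)
    if len(features) != cod_arr.size:
        raise AlignmentError(
            f"{len(features)} feature records vs {cod_arr.size} concentrations"
        )
    if not features:
        return [], []

    table = pd.DataFrame(
        {f.window_id: f.values for f in features}
    ).T  # rows = records
    mos_present = [c for c in mos_channels if c in table.columns]
    z = pd.DataFrame(
        {c: _robust_z(table[c].to_numpy()) for c in mos_present},
        index=table.index,
    )

    retained: list[FeatureVector] = []
    log: list[dict] = []
    for i, fv in enumerate(features):
        extreme = z.iloc[i][z.iloc[i] > z_high] if mos_present else pd.Series(dtype=float)
        if cod_arr[i] <= cod_low and len(extreme) > 0:
            log.append(
                {
                    "window_id": fv.window_id,
                    "cod": float(cod_arr[i]),
                    "channels": {k: float(v) for k, v in extreme.items()},
                    "reason": (
                        f"cod {cod_arr[i]:g} <= {cod_low:g} ou/m3 with MOS "
                        f"robust z > {z_high:g}"
                    ),
                }
            )
        else:
            retained.append(fv)
    if log:
        warnings.warn(
            f"rejected {len(log)} interferent-suspect record(s): "
            + ", ".join(entry["window_id"] for entry in log),
            stacklevel=2,
        )
    return retained, log
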