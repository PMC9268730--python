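"""Field-olfactometry panel readings and session odor concentrations.

A field olfactometer (e.g. the Nasal Ranger) dilutes ambient air with
carbon-filtered air at fixed dilution-to-threshold (D/T) ratios.  Each
assessor steps the dial until the odor disappears, yielding two readings:
``dt_yes`` — the last dilution at which the odor was still detectable —
and ``dt_no`` — the first dilution at which it was not.  The individual
threshold estimate (ZITE, EN 13725 convention) is the geometric mean of
the bracketing Z values, Z = D/T + 1::

    ZITE = sqrt((dt_yes + 1) * (dt_no + 1))

and the session odor concentration C_od (in ou/m^3) is the geometric mean
of the panel's individual estimates.  One odor unit per cubic metre is,
by construction, odor exactly at the panel detection threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (
    EmptyPanelError,
    InsufficientPanelError,
    InvalidEstimateError,
    InvalidReadingError,
)

__all__ = [
    "AssessorReading",
    "OlfactometrySession",
    "compute_zite",
    "session_concentration",
    "build_session",
]

#: Minimum panel size for a valid session ("at least two people").
MIN_PANEL_SIZE = 2


@dataclass(frozen=True)
class AssessorReading:
    """One assessor's pair of dilution-to-threshold dial readings.

    Parameters
    ----------
    assessor_id
        Opaque label for the panel member.
    dt_yes
        D/T ratio at which the odor was detectable (dimensionless, >= 0).
    dt_no
        D/T ratio at which the odor was not detectable (dimensionless, >= 0).

    Notes
    -----
    Any non-negative pair is accepted.  Typical instrument practice steps
    from high dilution down, so ``dt_no >= dt_yes`` is expected but not
    required; a reversed pair triggers a warning, not an error.
    """

    assessor_id: str
    dt_yes: float
    dt_no: float

    def __post_init__(self) -> None:
        for name, value in (("dt_yes", self.dt_yes), ("dt_no", self.dt_no)):
            if not math.isfinite(value) or value < 0:
                raise InvalidReadingError(
                    f"{name}={value!r} for assessor {self.assessor_id!r}: "
                    "dial readings must be finite and non-negative"
                )
        if self.dt_no < self.dt_yes:
            warnings.warn(
                f"assessor {self.assessor_id!r}: dt_no ({self.dt_no}) < dt_yes "
                f"({self.dt_yes}); dials usually step from high dilution down",
                stacklevel=3,
            )


@dataclass
class OlfactometrySession:
    """A completed olfactometric measurement session.

    Attributes
    ----------
    session_id, timestamp
        Identification of the session.
    readings
        The panel's :class:`AssessorReading` list (length >= 2).
    zite_values
        Individual threshold estimates, one per reading (each >= 1).
    cod
        Session odor concentration in ou/m^3 — the geometric mean of
        ``zite_values``.
    intensity, hedonic
        Optional ordinal annotations collected alongside the panel readings.
    """

    session_id: str
    timestamp: str
    readings: list[AssessorReading]
    zite_values: list[float] = field(default_factory=list)
    cod: float = float("nan")
    intensity: Optional[float] = None
    hedonic: Optional[float] = None


def compute_zite(reading: AssessorReading) -> float:
    """Individual threshold estimate for one assessor.

    Returns ``sqrt((dt_yes + 1) * (dt_no + 1))``; always >= 1 because both
    Z factors are >= 1.
    """
    return math.sqrt((reading.dt_yes + 1.0) * (reading.dt_no + 1.0))


def session_concentration(zite_values: Sequence[float]) -> float:
    """Session odor concentration: geometric mean of the panel's estimates.

    Computed as ``exp(mean(log(zite)))`` for numerical stability; invariant
    to the ordering of the inputs.

    Raises
    ------
    EmptyPanelError
        If the list is empty.
    InvalidEstimateError
        If any estimate is below 1 or non-finite.
    """
    values = np.asarray(list(zite_values), dtype=float)
    if values.size == 0:
        raise EmptyPanelError("cannot aggregate an empty panel")
    if not np.all(np.isfinite(values)) or np.any(values < 1.0):
        raise InvalidEstimateError(
            "individual threshold estimates must be finite and >= 1; "
            f"got {values.tolist()}"
        )
    return float(np.exp(np.mean(np.log(values))))


def build_session(
    readings: Iterable[AssessorReading],
    session_id: str = "",
    timestamp: str = "",
    intensity: Optional[float] = None,
    hedonic: Optional[float] = None,
    *,
    min_panel: int = MIN_PANEL_SIZE,
    on_small_panel: str = "raise",
) -> OlfactometrySession:
    """Assemble a session: compute all ZITE values and the session C_od.

    Parameters
    ----------
    readings
        At least ``min_panel`` assessor readings.
    on_small_panel
        ``"raise"`` (default) raises :class:`InsufficientPanelError` when the
        panel is too small; ``"warn"`` downgrades to a warning so single-reader
        field notes can still be processed.
    """
    readings = list(readings)
    if len(readings) < min_panel:
        message = (
            f"session {session_id!r}: {len(readings)} reading(s), "
            f"panel minimum is {min_panel}"
        )
        if on_small_panel == "warn":
            warnings.warn(message, stacklevel=2)
        else:
            raise InsufficientPanelError(message)
    if not readings:
        raise EmptyPanelError(f"session {session_id!r} has no readings")
    zite_values = [compute_zite(r) for r in readings]
    return OlfactometrySession(
        session_id=session_id,
        timestamp=timestamp,
        readings=readings,
        zite_values=zite_values,
        cod=session_concentration(zite_values),
        intensity=intensity,
        hedonic=hedonic,
    )
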