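"""Classical odor-nuisance indices from the environmental-odour literature.

Seven widely used indices for characterizing odor emissions from industrial
and municipal facilities:

* ``SOER`` — specific odor emission rate, Q_air * C_od / A_base [ou/(m^2 s)]
* ``OER``  — odor emission rate, SOER * A_emit [ou/s]
* ``OEF``  — odor emission factor, OER / activity-index [ou per activity unit]
* ``AOI``  (a.k.a. OAV) — analytical odor index, sum of concentration-to-
  threshold ratios over the odorants detected analytically [dimensionless]
* ``SOI``  — sensorial odor index, U_i / U_s [dimensionless]
* ``OI``   — odor index, 10 * log10(C_od) [dimensionless]
* ``OAI``  — odor annoyance index, weighted mean of resident odor ratings

A packaged fixture of literature olfactory-threshold ranges for common
odorants supports AOI/OAV demonstrations; because published thresholds are
ranges, :func:`threshold_point` reduces a (low, high) pair to a point
estimate under a declared policy (default: geometric mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import pandas as pd

from .errors import DomainError

__all__ = [
    "EmissionScenario",
    "OdorantPanel",
    "soer",
    "oer",
    "oef",
    "aoi",
    "soi",
    "oi",
    "oai",
    "load_odor_thresholds",
    "threshold_point",
]


@dataclass(frozen=True)
class EmissionScenario:
    """Source-level emission parameters for the rate indices.

    Units: ``q_air`` m^3/s, ``a_base`` and ``a_emit`` m^2, ``cod`` ou/m^3;
    ``activity_index`` is any positive scalar with a caller-declared unit
    (plant capacity, processed mass, ...).
    """

    q_air: float
    cod: float
    a_base: float
    a_emit: Optional[float] = None
    activity_index: Optional[float] = None


@dataclass(frozen=True)
class OdorantPanel:
    """Analytically detected odorants: (name, concentration, threshold)
    triples sharing one concentration unit (threshold > 0)."""

    entries: tuple[tuple[str, float, float], ...]


def _require_positive(**values: float) -> None:
    for name, v in values.items():
        if v is None or not math.isfinite(v) or v <= 0:
            raise DomainError(f"{name} must be finite and positive, got {v!r}")


def soer(scenario: EmissionScenario) -> float:
    """Specific odor emission rate, ou/(m^2 s)."""
    _require_positive(q_air=scenario.q_air, cod=scenario.cod, a_base=scenario.a_base)
    return scenario.q_air * scenario.cod / scenario.a_base


def oer(scenario: EmissionScenario) -> float:
    """Odor emission rate, ou/s: SOER scaled by the emitting surface."""
    _require_positive(a_emit=scenario.a_emit)
    return soer(scenario) * scenario.a_emit


def oef(scenario: EmissionScenario) -> float:
    """Odor emission factor: OER per unit of plant activity."""
    _require_positive(activity_index=scenario.activity_index)
    return oer(scenario) / scenario.activity_index


def aoi(panel: OdorantPanel) -> float:
    """Analytical odor index / odor activity value: sum of C_y / OT_y."""
    total = 0.0
    for name, conc, threshold in panel.entries:
        if not math.isfinite(threshold) or threshold <= 0:
            raise DomainError(f"odorant {name!r}: threshold must be positive")
        if not math.isfinite(conc) or conc < 0:
            raise DomainError(f"odorant {name!r}: concentration must be >= 0")
        total += conc / threshold
    return total


def soi(u_i: float, u_s: float) -> float:
    """Sensorial odor index: sampling-point concentration over the standard
    sensorially detectable concentration."""
    _require_positive(u_i=u_i, u_s=u_s)
    return u_i / u_s


def oi(cod: float) -> float:
    """Odor index: ``10 * log10(C_od)`` — the dB-style transform also used
    for the sensor features."""
    _require_positive(cod=cod)
    return 10.0 * math.log10(cod)


def oai(counts: Sequence[float], weights: Sequence[float]) -> float:
    """Odor annoyance index: weighted mean rating over resident observations.

    ``counts[i]`` observations received rating ``i`` with weight
    ``weights[i]``; OAI = sum(w_i * N_i) / N_t.  The rating weights are not
    standardized in the literature and must be supplied by the caller.
    """
    if len(counts) != len(weights):
        raise DomainError(
            f"counts ({len(counts)}) and weights ({len(weights)}) differ in length"
        )
    n_t = float(sum(counts))
    if n_t <= 0:
        raise DomainError("total number of observations must be positive")
    if any(c < 0 for c in counts):
        raise DomainError("observation counts must be non-negative")
    return sum(w * n for w, n in zip(weights, counts)) / n_t


def threshold_point(low: float, high: float, policy: str = "geometric-mean") -> float:
    """Point estimate from a published (low, high) threshold range."""
    _require_positive(low=low, high=high)
    if policy == "low":
        return low
    if policy == "high":
        return high
    if policy == "geometric-mean":
        return math.sqrt(low * high)
    raise DomainError(f"unknown threshold policy {policy!r}")


def load_odor_thresholds(policy: str = "geometric-mean") -> pd.DataFrame:
    """Literature olfactory-threshold ranges for common odorants.

    Returns a DataFrame with columns ``compound``, ``threshold_low``,
    ``threshold_high``, ``unit``, ``odor_character`` and a derived
    ``threshold`` column reduced per ``policy``
    (``low`` | ``high`` | ``geometric-mean``).
    """
    with resources.files("odorcal.data").joinpath("odor_thresholds.csv").open() as fh:
        table = pd.read_csv(fh)
    table["threshold"] = [
        threshold_point(lo, hi, policy)
        for lo, hi in zip(table["threshold_low"], table["threshold_high"])
    ]
    return table
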