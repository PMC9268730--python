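"""Synthetic measurement campaigns for offline testing of the pipeline.

The generator emulates a field campaign at an episodic odor source (a
compost screening yard): a five-channel gas-sensor array (three broad-band
MOS chemiresistors, two electrochemical cells) records exposure windows
while a small human panel performs field-olfactometry sessions alongside.

Emulated structure:

* a 60-session campaign split chronologically 40 train / 20 test;
* background odor with episodic high-concentration events (lognormal
  amplitudes on a Bernoulli schedule);
* per-channel sensor responses — MOS channels follow a saturable power-law
  in concentration and also couple to an *odorless interferent* (methane-like
  landfill gas), electrochemical channels are linear and interferent-blind;
* additive Gaussian noise, slow multiplicative baseline drift, and a flagged
  clean-air segment at the start of every window;
* panel readings quantized to the discrete dilution dial positions of a
  field olfactometer, with lognormal perception noise per assessor;
* intensity and hedonic annotations linear in log10 concentration
  (Weber–Fechner) with rounding to an ordinal scale.

All randomness flows from one integer seed through named substreams, so
e.g. changing the panel noise never perturbs the emission draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .features import ExposureWindow, SensorChannel
from .olfactometry import AssessorReading, OlfactometrySession, build_session

__all__ = [
    "ChannelSpec",
    "GeneratorConfig",
    "StudyBundle",
    "generate_emission_profile",
    "simulate_sensor_array",
    "simulate_panel",
    "simulate_annotations",
    "make_study",
]

# named substreams off the master seed
_STREAM_EMISSION = 0
_STREAM_INTERFERENT = 1
_STREAM_SENSOR = 2
_STREAM_PANEL = 3
_STREAM_ANNOTATION = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, stream)))


@dataclass(frozen=True)
class ChannelSpec:
    """Simulation parameters for one array channel.

    The peak (noise-free) signal of an exposure at true concentration C with
    interferent level I is

    * ``affine`` response:   ``S0 * (1 + gain * C**exponent + h * I)``
    * ``powerlaw`` response: ``S0 * (gain * C)**exponent`` (requires C > 0;
      makes the dB feature exactly linear in log10 C, the configuration the
      single-channel Stevens family assumes)

    with ``h = interferent_gain`` forced to 0 for EC channels.  An optional
    ``saturation`` caps the peak at ``S0 * saturation`` to emulate MOS
    saturation by high gas loads (off by default).
    """

    channel_id: str
    kind: str  # "MOS" | "EC"
    s0: float
    gain: float
    exponent: float = 1.0
    interferent_gain: float = 0.0
    response: str = "affine"
    saturation: Optional[float] = None

    def peak(self, cod: float, interferent: float, jitter: float = 1.0) -> float:
        h = self.interferent_gain if self.kind == "MOS" else 0.0
        if self.response == "affine":
            value = self.s0 * (
                1.0 + jitter * self.gain * cod**self.exponent + h * interferent
            )
        elif self.response == "powerlaw":
            value = self.s0 * (
                jitter * (self.gain * cod) ** self.exponent + h * interferent
            )
        else:
            raise ConfigError(f"unknown response form {self.response!r}")
        if self.saturation is not None:
            value = min(value, self.s0 * self.saturation)
        return value

    def as_channel(self) -> SensorChannel:
        return SensorChannel(self.channel_id, self.kind, self.s0)


def _default_channels() -> tuple[ChannelSpec, ...]:
    """Five-channel roster: three Figaro-style MOS sensors and two
    electrochemical cells.  The methane-class MOS channel (TGS2612) carries
    the strongest interferent coupling."""
    return (
        ChannelSpec("TGS2602", "MOS", s0=0.45, gain=0.30, exponent=0.55,
                    interferent_gain=0.06),
        ChannelSpec("TGS2603", "MOS", s0=0.40, gain=0.22, exponent=0.60,
                    interferent_gain=0.04),
        ChannelSpec("TGS2612", "MOS", s0=0.55, gain=0.10, exponent=0.50,
                    interferent_gain=0.10),
        ChannelSpec("H2S", "EC", s0=0.06, gain=0.035),
        ChannelSpec("NH3", "EC", s0=0.08, gain=0.020),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of a synthetic campaign.

    Defaults describe the campaign the pipeline targets: 60 sessions split
    40/20 chronologically, episodic events with a median amplitude of
    20 ou/m^3 over a 1.5 ou/m^3 background, moderate sensor noise and
    panel perception noise, and a methane-like interferent on one fifth of
    the sessions.  See ``docs/methods.md`` for the reasoning behind each
    default.
    """

    seed: int = 0
    n_sessions: int = 60
    train_fraction: float = 40.0 / 60.0
    channels: tuple[ChannelSpec, ...] = field(default_factory=_default_channels)
    # emission model
    baseline_cod: float = 1.5
    event_prob: float = 0.5
    event_mu_log: float = math.log(20.0)
    event_sigma_log: float = 1.0
    # interferent model (odorless, MOS-only)
    interferent_prob: float = 0.2
    interferent_mu_log: float = math.log(5.0)
    interferent_sigma_log: float = 0.8
    # sensor noise / drift / window geometry
    noise_sigma: float = 0.003
    drift_amplitude: float = 0.01
    #: per-session lognormal scatter of each channel's odor response,
    #: emulating session-to-session selectivity variation of real sensors
    #: (without it the channels are functionally collinear and raw-space
    #: calibrations acquire physically implausible sign-flipped weights)
    response_scatter_sigma: float = 0.2
    samples_per_window: int = 60
    baseline_samples: int = 20
    sample_interval_s: float = 1.0
    # panel
    n_assessors: int = 2
    dials: Optional[tuple[float, ...]] = (2.0, 4.0, 7.0, 15.0, 30.0, 60.0)
    panel_sigma_log: float = 0.2
    # psychophysics (intensity 0..6, hedonic -4..0 ordinal scales)
    intensity_slope: float = 2.3
    intensity_intercept: float = 0.4
    hedonic_slope: float = -1.5
    hedonic_intercept: float = -0.8
    annotation_sigma: float = 0.25
    annotation_resolution: float = 0.5
    intensity_range: tuple[float, float] = (0.0, 6.0)
    hedonic_range: tuple[float, float] = (-4.0, 0.0)
    split: str = "ordered"  # or "random"
    start_date: str = "2021-09-01"

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ConfigError("n_sessions must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("train_fraction must lie in (0, 1)")
        if self.n_assessors < 2:
            raise ConfigError("panel needs at least two assessors")
        if self.dials is not None:
            if len(self.dials) == 0:
                raise ConfigError("dial set must be non-empty (or None for continuous)")
            d = list(self.dials)
            if sorted(d) != d or any(x < 0 for x in d):
                raise ConfigError("dial set must be non-negative and increasing")
        for name in ("event_sigma_log", "interferent_sigma_log", "noise_sigma",
                     "panel_sigma_log", "annotation_sigma", "drift_amplitude",
                     "response_scatter_sigma"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.event_prob <= 1 or not 0 <= self.interferent_prob <= 1:
            raise ConfigError("event probabilities must lie in [0, 1]")
        if self.baseline_cod <= 0:
            raise ConfigError("baseline_cod must be > 0")
        if self.baseline_samples >= self.samples_per_window:
            raise ConfigError("baseline segment must leave room for the response")
        if self.split not in ("ordered", "random"):
            raise ConfigError("split must be 'ordered' or 'random'")

    @property
    def n_train(self) -> int:
        return round(self.train_fraction * self.n_sessions)

    @classmethod
    def low_noise(cls, seed: int = 0, **overrides) -> "GeneratorConfig":
        """A low-noise variant of the default campaign: sensor noise and
        drift nearly off, tight panel perception noise, no interferent."""
        params = dict(
            seed=seed,
            noise_sigma=0.0005,
            drift_amplitude=0.0,
            response_scatter_sigma=0.02,
            panel_sigma_log=0.05,
            interferent_prob=0.0,
            annotation_sigma=0.1,
        )
        params.update(overrides)
        return cls(**params)

    def replace(self, **overrides) -> "GeneratorConfig":
        return replace(self, **overrides)


@dataclass
class StudyBundle:
    """A complete synthetic campaign, aligned stage by stage.

    One exposure window per olfactometric session; ``truth`` holds the
    latent concentrations and interferent levels the generator used, and
    ``split`` the per-session TRAIN/TEST labels.
    """

    sessions: list[OlfactometrySession]
    windows: list[ExposureWindow]
    truth: pd.DataFrame
    split: np.ndarray
    config: GeneratorConfig

    def __post_init__(self) -> None:
        if len(self.sessions) != len(self.windows):
            raise ConfigError("bundle requires one window per session")


def generate_emission_profile(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-session true odor concentrations and interferent levels.

    Concentration = background level plus, on event sessions, a lognormal
    event amplitude.  The interferent is drawn independently of the odor
    (odorless landfill gas does not register on the panel).
    """
    rng_e = _rng(config.seed, _STREAM_EMISSION)
    rng_i = _rng(config.seed, _STREAM_INTERFERENT)
    n = config.n_sessions
    events = rng_e.random(n) < config.event_prob
    amplitudes = rng_e.lognormal(config.event_mu_log, config.event_sigma_log, n)
    cod = np.full(n, config.baseline_cod) + np.where(events, amplitudes, 0.0)
    hits = rng_i.random(n) < config.interferent_prob
    levels = rng_i.lognormal(config.interferent_mu_log, config.interferent_sigma_log, n)
    interferent = np.where(hits, levels, 0.0)
    return cod, interferent


def _response_profile(m: int) -> np.ndarray:
    """Triangular rise-and-fall reaching exactly 1 at its apex, so the
    window maximum equals the configured peak in the noise-free case."""
    apex = (m - 1) // 2
    up = np.linspace(0.0, 1.0, apex + 1)
    down = np.linspace(1.0, 0.2, m - apex)[1:] if m - apex > 1 else np.array([])
    return np.concatenate([up, down])


def simulate_sensor_array(
    cod: Sequence[float],
    interferent: Sequence[float],
    config: GeneratorConfig,
) -> list[ExposureWindow]:
    """Sensor-array exposure windows for each session.

    Each window starts with ``baseline_samples`` of flagged clean air at the
    channel baselines, then a triangular exposure transient peaking at the
    channel's response to (C, I).  Slow sinusoidal drift (random phase per
    window) multiplies the whole trace; white Gaussian noise is added on top.
    """
    rng = _rng(config.seed, _STREAM_SENSOR)
    cod = np.asarray(cod, dtype=float)
    interferent = np.asarray(interferent, dtype=float)
    n_total = config.samples_per_window
    n_base = config.baseline_samples
    t = np.arange(n_total) * config.sample_interval_s
    profile = _response_profile(n_total - n_base)
    windows: list[ExposureWindow] = []
    for i in range(cod.size):
        data = {}
        phase = rng.uniform(0, 2 * np.pi, len(config.channels))
        if config.response_scatter_sigma > 0:
            jitters = rng.lognormal(0.0, config.response_scatter_sigma,
                                    len(config.channels))
        else:
            jitters = np.ones(len(config.channels))
        for j, ch in enumerate(config.channels):
            peak = ch.peak(cod[i], interferent[i], jitter=jitters[j])
            series = np.full(n_total, ch.s0)
            series[n_base:] = ch.s0 + (peak - ch.s0) * profile
            if config.drift_amplitude > 0:
                period = 4.0 * t[-1] if t[-1] > 0 else 1.0
                series = series * (
                    1.0 + config.drift_amplitude * np.sin(2 * np.pi * t / period + phase[j])
                )
            if config.noise_sigma > 0:
                series = series + rng.normal(0.0, config.noise_sigma, n_total)
            data[ch.channel_id] = np.clip(series, 1e-9, None)
        windows.append(
            ExposureWindow(
                window_id=f"S{i:03d}",
                timestamps=t,
                signals=pd.DataFrame(data),
                baseline_segment=(0, n_base),
            )
        )
    return windows


def _bracket(perceived: float, dials: Optional[tuple[float, ...]]) -> tuple[float, float]:
    """Quantize a perceived threshold to a (dt_yes, dt_no) dial pair.

    The perceived Z value (= dilution + 1) is bracketed by adjacent dial
    positions: dt_yes is the largest dial with ``dial + 1 <= perceived``,
    dt_no the next dial up.  Below the lowest dial the pair degenerates to
    ``(0, lowest)``; above the highest it saturates at
    ``(highest, highest)``.  ``dials=None`` means a continuous dial:
    dt_yes = dt_no = perceived - 1 (floored at 0).
    """
    if dials is None:
        dt = max(perceived - 1.0, 0.0)
        return dt, dt
    lowest, highest = dials[0], dials[-1]
    if perceived < lowest + 1.0:
        return 0.0, lowest
    if perceived >= highest + 1.0:
        return highest, highest
    below = [d for d in dials if d + 1.0 <= perceived]
    dt_yes = below[-1]
    dt_no = next(d for d in dials if d > dt_yes)
    return dt_yes, dt_no


def simulate_panel(
    cod: Sequence[float], config: GeneratorConfig
) -> list[list[AssessorReading]]:
    """Per-session panel readings.

    Each assessor's perceived detection threshold is ``C * exp(eps)`` with
    ``eps ~ Normal(0, panel_sigma_log)``, then quantized to the olfactometer
    dial set (see :func:`_bracket`).
    """
    rng = _rng(config.seed, _STREAM_PANEL)
    panels: list[list[AssessorReading]] = []
    for i, c in enumerate(np.asarray(cod, dtype=float)):
        readings = []
        for a in range(config.n_assessors):
            eps = rng.normal(0.0, config.panel_sigma_log) if config.panel_sigma_log else 0.0
            perceived = c * math.exp(eps)
            dt_yes, dt_no = _bracket(perceived, config.dials)
            readings.append(AssessorReading(f"A{a+1}", dt_yes, dt_no))
        panels.append(readings)
    return panels


def simulate_annotations(
    cod: Sequence[float], config: GeneratorConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Intensity and hedonic annotations per session.

    Annotation = intercept + slope * log10(C) + noise, rounded to the
    ordinal resolution and clipped to the configured scale range.
    """
    rng = _rng(config.seed, _STREAM_ANNOTATION)
    logc = np.log10(np.asarray(cod, dtype=float))
    n = logc.size
    out = []
    for slope, intercept, (lo, hi) in (
        (config.intensity_slope, config.intensity_intercept, config.intensity_range),
        (config.hedonic_slope, config.hedonic_intercept, config.hedonic_range),
    ):
        values = intercept + slope * logc
        if config.annotation_sigma > 0:
            values = values + rng.normal(0.0, config.annotation_sigma, n)
        if config.annotation_resolution > 0:
            values = np.round(values / config.annotation_resolution) * config.annotation_resolution
        out.append(np.clip(values, lo, hi))
    return out[0], out[1]


def make_study(config: Optional[GeneratorConfig] = None) -> StudyBundle:
    """Generate a full campaign: emissions, sensor windows, panel sessions,
    annotations, and the train/test split.

    The default split is chronological (first ``train_fraction`` of the
    campaign is TRAIN), mirroring a calibrate-then-validate field protocol;
    ``split="random"`` shuffles instead.  Fully reproducible from the seed.
    """
    config = config or GeneratorConfig()
    cod_true, interferent = generate_emission_profile(config)
    windows = simulate_sensor_array(cod_true, interferent, config)
    panels = simulate_panel(cod_true, config)
    intensity, hedonic = simulate_annotations(cod_true, config)

    dates = pd.date_range(config.start_date, periods=config.n_sessions, freq="D")
    sessions = [
        build_session(
            panels[i],
            session_id=f"S{i:03d}",
            timestamp=dates[i].isoformat(),
            intensity=float(intensity[i]),
            hedonic=float(hedonic[i]),
        )
        for i in range(config.n_sessions)
    ]
    truth = pd.DataFrame(
        {
            "session_id": [s.session_id for s in sessions],
            "cod_true": cod_true,
            "interferent": interferent,
        }
    )
    split = np.array(["TEST"] * config.n_sessions, dtype=object)
    if config.split == "ordered":
        split[: config.n_train] = "TRAIN"
    else:
        rng = _rng(config.seed, 5)
        split[rng.choice(config.n_sessions, config.n_train, replace=False)] = "TRAIN"
    return StudyBundle(sessions, windows, truth, split, config)
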