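"""Forward simulation of the multiplexed detector signals.

Each LED is driven with sinusoidally modulated intensity; every fluorescent
species responds instantaneously and linearly, so the photocurrent on
detector *k* is

    y_k(t) = sum_j I_j(t) * sum_s S[k,j,s] * c_s(t) + background_k + noise

with the coupling tensor S from :mod:`fluomux.optics` and the species traces
c_s from :mod:`fluomux.kinetics`.  Shot noise is modelled as Gaussian with
variance proportional to the instantaneous signal (high-flux PMT regime)
plus a signal-independent dark term; all randomness comes from a single
seeded generator, so identical (config, seed) gives bit-identical traces.

Artifact injectors add an unmodulated flash transient (which phase-sensitive
demodulation rejects) and a multiplicative mixing disturbance at the stop of
the flow (which the analysis layer crops using the recorded window).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ParameterError
from .kinetics import ConcentrationTraces
from .optics import CouplingTensor, ExcitationChannel

logger = logging.getLogger("fluomux")


@dataclass(frozen=True)
class NoiseSpec:
    """Detector noise model: var = dark_sd² + shot_scale·max(signal, 0)."""

    shot_scale: float = 0.0
    dark_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.shot_scale < 0 or self.dark_sd < 0:
            raise ParameterError("noise scales must be >= 0")

    @property
    def enabled(self) -> bool:
        return self.shot_scale > 0 or self.dark_sd > 0


@dataclass(frozen=True)
class AcquisitionConfig:
    """Sampling geometry of one simulated recording."""

    duration_s: float
    excitation_channels: tuple
    detection_channels: tuple
    sim_rate_hz: float = 1.0e6
    fastm_enabled: bool = True
    common_mod_freq_hz: float | None = None  # used when fastm_enabled is False
    background: dict = field(default_factory=dict)  # detector name -> DC level

    def __post_init__(self):
        object.__setattr__(self, "excitation_channels", tuple(self.excitation_channels))
        object.__setattr__(self, "detection_channels", tuple(self.detection_channels))
        if self.duration_s <= 0 or self.sim_rate_hz <= 0:
            raise ParameterError("duration_s and sim_rate_hz must be > 0")
        if not self.excitation_channels or not self.detection_channels:
            raise ConfigurationError("need >= 1 excitation and detection channel")
        fmax = max(c.mod_freq_hz for c in self.excitation_channels)
        if self.common_mod_freq_hz is not None:
            fmax = max(fmax, self.common_mod_freq_hz)
        if self.sim_rate_hz < 2.5 * fmax:
            raise ConfigurationError(
                f"sim_rate_hz = {self.sim_rate_hz:g} must be >= 2.5x the highest "
                f"modulation frequency ({fmax:g} Hz)")
        if self.fastm_enabled:
            freqs = [c.mod_freq_hz for c in self.excitation_channels]
            if len(set(freqs)) != len(freqs):
                raise ConfigurationError(
                    "multiplexed excitation channels must have distinct "
                    f"modulation frequencies, got {freqs}")
        for name in self.background:
            if name not in {d.name for d in self.detection_channels}:
                raise ConfigurationError(f"background names unknown detector {name!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sim_rate_hz))

    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sim_rate_hz


@dataclass(frozen=True)
class RawTraceSet:
    """High-rate multiplexed detector time series plus provenance metadata."""

    time_s: np.ndarray
    signals: dict  # detector name -> np.ndarray
    sim_rate_hz: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.time_s, float)
        for name, y in self.signals.items():
            y = np.asarray(y, float)
            if y.shape != t.shape:
                raise ParameterError(f"detector {name!r}: trace length mismatch")
            if not np.all(np.isfinite(y)):
                raise ParameterError(f"detector {name!r}: non-finite samples")
        object.__setattr__(self, "time_s", t)

    @property
    def detectors(self) -> tuple:
        return tuple(self.signals)

    def checksum(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.signals):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.signals[name]).tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# Excitation
# ---------------------------------------------------------------------------

def led_intensity(exch: ExcitationChannel, time_s, fastm_enabled: bool = True,
                  common_freq_hz: float | None = None,
                  sim_rate_hz: float | None = None) -> np.ndarray:
    """Instantaneous LED intensity I(t) = intensity·(1 + m·cos(2πft + φ))/2.

    With multiplexing disabled every channel is forced onto one common
    frequency (the optical-filtering-only control condition); the waveform is
    otherwise identical.  The time average over whole periods is intensity/2.
    """
    f = exch.mod_freq_hz
    if not fastm_enabled:
        if common_freq_hz is None:
            raise ParameterError("common_freq_hz is required when multiplexing is off")
        f = common_freq_hz
    if sim_rate_hz is not None and f >= sim_rate_hz / 2.0:
        raise ConfigurationError(
            f"modulation frequency {f:g} Hz at or above Nyquist ({sim_rate_hz / 2:g} Hz)")
    t = np.asarray(time_s, float)
    return exch.intensity * 0.5 * (1.0 + exch.mod_depth
                                   * np.cos(2.0 * np.pi * f * t + exch.phase_rad))


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

def simulate_acquisition(cfg: AcquisitionConfig, S: CouplingTensor,
                         kin: ConcentrationTraces,
                         noise: NoiseSpec | None = None) -> RawTraceSet:
    """Simulate the PMT outputs for one recording.

    Kinetic traces are resampled to the simulation grid by linear
    interpolation; the species axis of the coupling tensor must match the
    kinetic species by name (order-insensitive).  Species present in the
    tensor but absent from the kinetics are held at constant concentration 1
    (e.g. the ambient stray-light term).
    """
    noise = noise or NoiseSpec()
    det_names = tuple(d.name for d in cfg.detection_channels)
    exc_names = tuple(c.name for c in cfg.excitation_channels)
    if det_names != S.detector_names or exc_names != S.excitation_names:
        raise ConfigurationError(
            "coupling tensor channel names do not match the acquisition config: "
            f"{S.detector_names}/{S.excitation_names} vs {det_names}/{exc_names}")
    unknown = set(kin.species) - set(S.species_names)
    if unknown:
        raise ConfigurationError(
            f"kinetic species {sorted(unknown)} not present in the coupling tensor "
            f"(tensor species: {list(S.species_names)})")

    t = cfg.time()
    ones = None
    c = []
    kin_rs = kin.resample(t)
    for name in S.species_names:
        if name in kin_rs.traces:
            c.append(kin_rs[name])
        else:
            if ones is None:
                ones = np.ones_like(t)
            c.append(ones)

    common = cfg.common_mod_freq_hz
    if not cfg.fastm_enabled and common is None:
        common = cfg.excitation_channels[0].mod_freq_hz
    intensities = [led_intensity(ch, t, cfg.fastm_enabled, common, cfg.sim_rate_hz)
                   for ch in cfg.excitation_channels]

    rng = np.random.default_rng(noise.seed)
    signals = {}
    for k, det in enumerate(cfg.detection_channels):
        y = np.full_like(t, float(cfg.background.get(det.name, 0.0)))
        for j in range(len(cfg.excitation_channels)):
            mix = np.zeros_like(t)
            for s in range(len(S.species_names)):
                coef = S.values[k, j, s]
                if coef != 0.0:
                    mix += coef * c[s]
            y += intensities[j] * mix
        if noise.enabled:
            sd = np.sqrt(noise.dark_sd ** 2 + noise.shot_scale * np.clip(y, 0.0, None))
            y = y + rng.standard_normal(t.size) * sd
        signals[det.name] = y

    meta = {
        "sim_rate_hz": cfg.sim_rate_hz,
        "fastm_enabled": cfg.fastm_enabled,
        "seed": noise.seed,
        "mod_freqs_hz": {ch.name: (ch.mod_freq_hz if cfg.fastm_enabled else common)
                         for ch in cfg.excitation_channels},
        "flash_windows": [],
        "mixing_artifacts": [],
    }
    return RawTraceSet(time_s=t, signals=signals, sim_rate_hz=cfg.sim_rate_hz,
                       metadata=meta)


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------

def _smooth_gate(t: np.ndarray, start: float, stop: float, edge_s: float) -> np.ndarray:
    """Rectangular window with raised-cosine edges of width ``edge_s``."""
    if edge_s <= 0:
        return ((t >= start) & (t < stop)).astype(float)
    up = np.clip((t - start) / edge_s, 0.0, 1.0)
    down = np.clip((stop - t) / edge_s, 0.0, 1.0)
    return (0.5 - 0.5 * np.cos(np.pi * up)) * (0.5 - 0.5 * np.cos(np.pi * down))


def inject_flash_artifact(raw: RawTraceSet, window, amplitude: float,
                          detectors=None, edge_s: float = 1.0e-3) -> RawTraceSet:
    """Add an unmodulated additive transient (e.g. an uncaging flash).

    The transient is a rectangular pulse with raised-cosine edge smoothing,
    added to the selected detectors over ``window = (start_s, stop_s)``.
    Being unmodulated, it is strongly rejected by the demodulator; the window
    is recorded in the metadata.
    """
    start, stop = window
    t = raw.time_s
    if not (t[0] <= start < stop <= t[-1] + 1.0 / raw.sim_rate_hz):
        raise ParameterError(f"flash window {window} outside the trace")
    detectors = list(raw.signals) if detectors is None else list(detectors)
    gate = amplitude * _smooth_gate(t, start, stop, edge_s)
    signals = {name: (y + gate if name in detectors else y.copy())
               for name, y in raw.signals.items()}
    meta = dict(raw.metadata)
    meta["flash_windows"] = list(meta.get("flash_windows", [])) + [
        {"start_s": float(start), "stop_s": float(stop),
         "amplitude": float(amplitude), "detectors": detectors}]
    return RawTraceSet(t, signals, raw.sim_rate_hz, meta)


def inject_mixing_artifact(raw: RawTraceSet, stop_time_s: float,
                           amplitude: float, decay_s: float) -> RawTraceSet:
    """Multiplicative disturbance decaying from the stop of the flow.

    All detectors are scaled by 1 + amplitude·e^{−(t−stop)/decay} for
    t >= stop.  The metadata records a crop window of 5 decay constants,
    which removes > 99.99% of the disturbance energy.
    """
    if decay_s <= 0:
        raise ParameterError("decay_s must be > 0")
    t = raw.time_s
    factor = np.ones_like(t)
    m = t >= stop_time_s
    factor[m] += amplitude * np.exp(-(t[m] - stop_time_s) / decay_s)
    signals = {name: y * factor for name, y in raw.signals.items()}
    meta = dict(raw.metadata)
    meta["mixing_artifacts"] = list(meta.get("mixing_artifacts", [])) + [
        {"stop_time_s": float(stop_time_s), "amplitude": float(amplitude),
         "decay_s": float(decay_s),
         "crop_until_s": float(stop_time_s + 5.0 * decay_s)}]
    return RawTraceSet(t, signals, raw.sim_rate_hz, meta)


# ---------------------------------------------------------------------------
# Stopped-flow arithmetic
# ---------------------------------------------------------------------------

def dead_time(dead_volume_ul: float, flow_rate_ml_per_s: float) -> float:
    """Stopped-flow dead time in seconds: dead volume / flow rate.

    E.g. a 36.6 µl dead volume at 1 ml/s gives 36.6 ms; at 2 ml/s, 18.3 ms.
    """
    if dead_volume_ul <= 0 or flow_rate_ml_per_s <= 0:
        raise ParameterError("dead volume and flow rate must be > 0")
    return (dead_volume_ul / 1000.0) / flow_rate_ml_per_s
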