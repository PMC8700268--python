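"""Ground-truth kinetic scenarios for the simulator.

Each generator returns a :class:`ConcentrationTraces` object: a uniform time
grid plus one nonnegative, baseline-normalized relative-concentration (or
relative-fluorescence) trace per species.  The scenarios emulate the kinds of
experiments the instrument model is aimed at:

* a chemoattractant-triggered signalling cascade in sperm — a pulse-like
  membrane-voltage hyperpolarization followed by sustained pH/Na rises and a
  delayed Ca rise;
* first-order Ca unbinding from an indicator quenched by excess chelator
  (stopped-flow k_off measurement);
* the same cascade triggered by a UV uncaging flash, with the flash window
  reported for artifact injection;
* a toy second-messenger system in which a high-affinity FRET sensor buffers
  cAMP and delays activation of a low-affinity effector channel.

Waveform time constants and latencies are fixture choices with realistic
orders of magnitude; the acceptance of the signal chain rests on processing
fidelity, not on these biological parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, ParameterError


# ---------------------------------------------------------------------------
# Container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcentrationTraces:
    """Per-species relative concentration on a uniform time grid."""

    time_s: np.ndarray
    traces: dict  # name -> np.ndarray, >= 0

    def __post_init__(self):
        t = np.asarray(self.time_s, float)
        if t.ndim != 1 or t.size < 2:
            raise ParameterError("time grid must be 1-D with >= 2 samples")
        dt = np.diff(t)
        if not np.all(dt > 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=0):
            raise ParameterError("time grid must be strictly increasing and uniform")
        clean = {}
        for name, c in self.traces.items():
            c = np.asarray(c, float)
            if c.shape != t.shape:
                raise ParameterError(f"trace {name!r} length mismatch")
            if not np.all(np.isfinite(c)) or np.any(c < 0):
                raise ParameterError(f"trace {name!r} must be finite and >= 0")
            clean[name] = c
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "traces", clean)

    @property
    def species(self) -> tuple:
        return tuple(self.traces)

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    def __getitem__(self, name: str) -> np.ndarray:
        return self.traces[name]

    def resample(self, time_s: np.ndarray) -> "ConcentrationTraces":
        """Linear interpolation onto a new grid; constant extrapolation."""
        t = np.asarray(time_s, float)
        out = {name: np.interp(t, self.time_s, c) for name, c in self.traces.items()}
        return ConcentrationTraces(t, out)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"time_s": self.time_s, **self.traces})


def time_grid(duration_s: float, dt_s: float, start_s: float = 0.0) -> np.ndarray:
    n = int(round(duration_s / dt_s))
    return start_s + np.arange(n) * dt_s


# ---------------------------------------------------------------------------
# Waveform primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseWaveform:
    """Transient pulse: A·(1−e^{−(t−t0)/τ_r})·e^{−(t−t0)/τ_d}, zero before t0.

    Peaks at t−t0 = τ_r·ln(1 + τ_d/τ_r) and fully recovers to 0.
    """

    latency_s: float
    rise_tau_s: float
    decay_tau_s: float
    amplitude: float

    def __post_init__(self):
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise ParameterError("pulse time constants must be > 0")

    @property
    def peak_time_s(self) -> float:
        return self.latency_s + self.rise_tau_s * math.log1p(
            self.decay_tau_s / self.rise_tau_s)


@dataclass(frozen=True)
class RiseWaveform:
    """Saturating rise: A·(1−e^{−(t−t0)/τ}), zero before t0, → A."""

    latency_s: float
    tau_s: float
    amplitude: float

    def __post_init__(self):
        if self.tau_s <= 0:
            raise ParameterError("rise time constant must be > 0")


def pulse_waveform(p: PulseWaveform, time_s) -> np.ndarray:
    t = np.asarray(time_s, float) - p.latency_s
    w = np.zeros_like(t)
    m = t >= 0
    w[m] = p.amplitude * (1.0 - np.exp(-t[m] / p.rise_tau_s)) * np.exp(-t[m] / p.decay_tau_s)
    return w


def saturating_rise(p: RiseWaveform, time_s) -> np.ndarray:
    t = np.asarray(time_s, float) - p.latency_s
    w = np.zeros_like(t)
    m = t >= 0
    w[m] = p.amplitude * (1.0 - np.exp(-t[m] / p.tau_s))
    return w


# ---------------------------------------------------------------------------
# Chemoattractant cascade
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CascadeParams:
    """Default waveforms for the signalling cascade fixture.

    The event order (voltage pulse first, then pH/Na, then Ca) is part of the
    modelled biology and validated; amplitudes are relative fluorescence
    changes around a baseline of 1.
    """

    vm: PulseWaveform = field(default_factory=lambda: PulseWaveform(
        latency_s=0.050, rise_tau_s=0.020, decay_tau_s=0.200, amplitude=-0.30))
    ph: RiseWaveform = field(default_factory=lambda: RiseWaveform(
        latency_s=0.150, tau_s=0.300, amplitude=0.20))
    na: RiseWaveform = field(default_factory=lambda: RiseWaveform(
        latency_s=0.150, tau_s=0.300, amplitude=0.15))
    ca: RiseWaveform = field(default_factory=lambda: RiseWaveform(
        latency_s=0.400, tau_s=0.500, amplitude=0.50))


def _dose_latency(base_latency_s: float, dose_scale: float) -> float:
    # Monotone stand-in for the dose dependence of response latencies:
    # higher dose -> shorter latency; denominator clipped to stay positive.
    return base_latency_s / max(1.0 + math.log10(dose_scale), 0.1)


def resact_cascade_fixture(time_s, dose_scale: float = 1.0,
                           params: CascadeParams | None = None) -> ConcentrationTraces:
    """Cascade of a voltage pulse, pH and Na rises, and a delayed Ca rise.

    Species emitted: ``vm``, ``ph``, ``na``, ``ca``, each a relative
    fluorescence-equivalent trace with baseline 1.  ``dose_scale`` scales the
    stimulus: latencies shorten and the voltage pulse deepens monotonically
    with dose; ``dose_scale = 0`` leaves every trace flat at baseline.
    """
    p = params or CascadeParams()
    if not (p.vm.latency_s < p.ph.latency_s <= p.na.latency_s < p.ca.latency_s):
        raise ConfigurationError(
            "cascade latencies must be ordered vm < ph <= na < ca, got "
            f"{p.vm.latency_s}/{p.ph.latency_s}/{p.na.latency_s}/{p.ca.latency_s}")
    t = np.asarray(time_s, float)
    if dose_scale < 0:
        raise ParameterError("dose_scale must be >= 0")
    if dose_scale == 0:
        flat = np.ones_like(t)
        return ConcentrationTraces(t, {k: flat.copy() for k in ("vm", "ph", "na", "ca")})

    depth = 2.0 * dose_scale / (1.0 + dose_scale)  # 1 at dose 1, monotone in dose
    vm = replace(p.vm, latency_s=_dose_latency(p.vm.latency_s, dose_scale),
                 amplitude=max(p.vm.amplitude * depth, -0.95))
    ph = replace(p.ph, latency_s=_dose_latency(p.ph.latency_s, dose_scale))
    na = replace(p.na, latency_s=_dose_latency(p.na.latency_s, dose_scale))
    ca = replace(p.ca, latency_s=_dose_latency(p.ca.latency_s, dose_scale))
    return ConcentrationTraces(t, {
        "vm": 1.0 + pulse_waveform(vm, t),
        "ph": 1.0 + saturating_rise(ph, t),
        "na": 1.0 + saturating_rise(na, t),
        "ca": 1.0 + saturating_rise(ca, t),
    })


# ---------------------------------------------------------------------------
# Chelator-quench dissociation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DissociationModel:
    """First-order unbinding in the excess-chelator regime (no rebinding)."""

    k_off_per_s: float
    bound_fraction_initial: float = 1.0

    def __post_init__(self):
        if self.k_off_per_s <= 0:
            raise ParameterError("k_off_per_s must be > 0")
        if not (0.0 < self.bound_fraction_initial <= 1.0):
            raise ParameterError("bound_fraction_initial must be in (0, 1]")


def dissociation_traces(m: DissociationModel, time_s,
                        start_s: float = 0.0) -> ConcentrationTraces:
    """Bound fraction b0·e^{−k_off·(t−start)} and its complement.

    Species: ``bound`` and ``free``; they sum to 1 at every sample.  Before
    ``start_s`` (mixing) the bound fraction holds at its initial value.
    """
    t = np.asarray(time_s, float)
    age = np.clip(t - start_s, 0.0, None)
    bound = m.bound_fraction_initial * np.exp(-m.k_off_per_s * age)
    return ConcentrationTraces(t, {"bound": bound, "free": 1.0 - bound})


# ---------------------------------------------------------------------------
# Flash uncaging
# ---------------------------------------------------------------------------

def uncaging_step_fixture(flash_start_s: float, flash_dur_s: float, time_s,
                          params: CascadeParams | None = None,
                          dose_scale: float = 1.0):
    """Cascade triggered by an intracellular uncaging flash.

    All latencies are referenced to ``flash_start_s``; responses are exactly
    baseline before the flash.  Returns ``(traces, (flash_start, flash_end))``
    so the acquisition layer can inject the corresponding detector artifact.
    """
    t = np.asarray(time_s, float)
    if not (t[0] <= flash_start_s and flash_start_s + flash_dur_s <= t[-1]):
        raise ParameterError("flash window must lie within the time grid")
    p = params or CascadeParams()
    # Latencies are defined relative to the flash: evaluate the cascade on a
    # flash-referenced clock, then restate the result on the absolute grid.
    shifted = resact_cascade_fixture(t - flash_start_s, dose_scale=dose_scale,
                                     params=p)
    traces = ConcentrationTraces(t, dict(shifted.traces))
    return traces, (flash_start_s, flash_start_s + flash_dur_s)


# ---------------------------------------------------------------------------
# Messenger buffering toy
# ---------------------------------------------------------------------------

def _free_messenger(total, kd, sensor_total):
    """Rapid-equilibrium free concentration: positive root of
    free² + (Kd + B − total)·free − Kd·total = 0."""
    b = kd + sensor_total - total
    free = 0.5 * (-b + np.sqrt(b * b + 4.0 * kd * total))
    if np.any(free < -1e-12):
        raise AssertionError("negative free messenger concentration (internal error)")
    return np.clip(free, 0.0, None)


def buffered_messenger_fixture(sensor_kd_um: float, sensor_total_um: float,
                               channel_k12_um: float,
                               production_rate_um_per_s: float,
                               time_s, hill_coefficient: float = 2.0,
                               ) -> ConcentrationTraces:
    """Constant-rate messenger production buffered by a binding sensor.

    Total messenger obeys d[total]/dt = production rate, integrated with a
    fixed-step 4th-order Runge–Kutta scheme on the trace grid; the sensor is
    in rapid binding equilibrium (quadratic solution for the free
    concentration), and a downstream effector channel opens as a Hill
    function of free messenger.  Species (all µM except the dimensionless
    last two): ``total``, ``free``, ``sensor_bound``, ``sensor_occupancy``,
    ``channel_open``.  Total = free + sensor_bound exactly at every step.
    """
    for name, v in (("sensor_kd_um", sensor_kd_um),
                    ("channel_k12_um", channel_k12_um),
                    ("production_rate_um_per_s", production_rate_um_per_s)):
        if v <= 0:
            raise ParameterError(f"{name} must be > 0")
    if sensor_total_um < 0:
        raise ParameterError("sensor_total_um must be >= 0")
    t = np.asarray(time_s, float)
    dt = t[1] - t[0]

    # RK4 on d(total)/dt = r (constant source; exact here, but the integrator
    # is kept general for time-varying production rates).
    rate = float(production_rate_um_per_s)
    total = np.empty_like(t)
    total[0] = 0.0
    for i in range(1, t.size):
        k1 = k2 = k3 = k4 = rate
        total[i] = total[i - 1] + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    free = _free_messenger(total, sensor_kd_um, sensor_total_um)
    bound = np.maximum(total - free, 0.0)  # guard round-off at sensor_total = 0
    occupancy = bound / sensor_total_um if sensor_total_um > 0 else np.zeros_like(t)
    h = hill_coefficient
    channel = free ** h / (free ** h + channel_k12_um ** h)
    return ConcentrationTraces(t, {
        "total": total, "free": free, "sensor_bound": bound,
        "sensor_occupancy": occupancy, "channel_open": channel,
    })
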