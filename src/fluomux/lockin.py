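"""Software lock-in amplifier (phase-sensitive demodulation).

Each logical channel is a (detector, reference frequency) pair.  The raw
detector trace is multiplied by quadrature references, lowpass-filtered by a
cascade of identical single-pole RC stages — ``order`` stages of per-stage
time constant τ give the commercial "n-th order, 6n dB/octave" response, 18
dB/octave at order 3 — and decimated to the experiment's output interval by
subsampling the filtered stream (the cascade itself is the anti-alias
filter).

Amplitude convention: an input A·cos(2πft + φ) demodulated at f with matched
phase settles to an in-phase output X = A.  Auto-phasing picks φ to zero the
quadrature over a calibration window, so X carries the full signed signal;
magnitude output R = sqrt(X² + Y²) is available but rectifies noise near
zero signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .acquisition import RawTraceSet
from .errors import ParameterError

logger = logging.getLogger("fluomux")


@dataclass(frozen=True)
class LockInConfig:
    """Demodulator settings.

    ``time_constant_s`` is the per-stage time constant of each of the
    ``order`` identical lowpass stages.  ``settle_factor``·order·τ of output
    at the start of every trace is flagged as settling and excluded from
    analysis by default.
    """

    time_constant_s: float
    output_interval_s: float
    order: int = 3
    phase_mode: str = "auto"      # "auto" | "fixed"
    phase_rad: float = 0.0        # used when phase_mode == "fixed"
    output_mode: str = "in_phase"  # "in_phase" | "magnitude"
    settle_factor: float = 10.0
    calibration_window_s: tuple | None = None  # default: chosen per trace

    def __post_init__(self):
        if self.time_constant_s <= 0:
            raise ParameterError("time_constant_s must be > 0")
        if self.output_interval_s <= 0:
            raise ParameterError("output_interval_s must be > 0")
        if self.order < 1:
            raise ParameterError("order must be >= 1")
        if self.phase_mode not in ("auto", "fixed"):
            raise ParameterError("phase_mode must be 'auto' or 'fixed'")
        if self.output_mode not in ("in_phase", "magnitude"):
            raise ParameterError("output_mode must be 'in_phase' or 'magnitude'")

    @property
    def settle_time_s(self) -> float:
        return self.settle_factor * self.order * self.time_constant_s


@dataclass(frozen=True)
class DemodulatedTraceSet:
    """Low-rate per-channel outputs of the demodulator."""

    time_s: np.ndarray
    traces: dict        # label -> np.ndarray
    channel_info: dict  # label -> {"detector", "frequency_hz", "phase_rad"}
    settling_mask: np.ndarray  # True where the filter is still settling
    config: LockInConfig
    metadata: dict = field(default_factory=dict)

    @property
    def labels(self) -> tuple:
        return tuple(self.traces)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.traces[label]

    def valid(self, label: str):
        """(time, values) with the settling span removed."""
        m = ~self.settling_mask
        return self.time_s[m], self.traces[label][m]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"time_s": self.time_s, **self.traces})


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def cascaded_lowpass(signal, tau_s: float, order: int, dt_s: float) -> np.ndarray:
    """Cascade of ``order`` identical single-pole recursive lowpass stages.

    Each stage computes y[n] = y[n−1] + (dt/(τ+dt))·(u[n] − y[n−1]) from rest
    (y[−1] = 0).  DC gain is exactly 1; the asymptotic rolloff is 6·order
    dB/octave and |H(f)| = (1 + (2πfτ)²)^(−order/2).
    """
    if tau_s <= 0:
        raise ParameterError("time constant must be > 0")
    if order < 1:
        raise ParameterError("order must be >= 1")
    if tau_s <= dt_s / 10.0:
        logger.warning("lock-in time constant %.3g s is below dt/10 = %.3g s; "
                       "the discrete filter is a poor approximation", tau_s, dt_s / 10.0)
    alpha = dt_s / (tau_s + dt_s)
    b, a = [alpha], [1.0, alpha - 1.0]
    y = np.asarray(signal, float)
    for _ in range(order):
        y = lfilter(b, a, y)
    return y


def settle_mask(cfg: LockInConfig, time_s) -> np.ndarray:
    """True where the filter cascade has not yet settled (t < factor·order·τ)."""
    t = np.asarray(time_s, float)
    return (t - t[0]) < cfg.settle_time_s


# ---------------------------------------------------------------------------
# Phase
# ---------------------------------------------------------------------------

def auto_phase(raw: RawTraceSet, detector: str, freq_hz: float,
               window_s: tuple) -> float:
    """Reference phase that maximizes the in-phase output of one channel.

    Projects the raw signal onto quadrature references over ``window_s`` and
    returns φ = atan2(⟨Y⟩, ⟨X⟩); demodulating with this φ drives the mean
    quadrature to ~0.  The window must span at least 20 modulation periods.
    """
    t0, t1 = window_s
    if (t1 - t0) * freq_hz < 20.0:
        raise ParameterError(
            f"auto-phase window of {t1 - t0:g} s spans fewer than 20 periods at "
            f"{freq_hz:g} Hz")
    t = raw.time_s
    sel = (t >= t0) & (t < t1)
    if not np.any(sel):
        raise ParameterError("auto-phase window outside the trace")
    y = raw.signals[detector][sel]
    wt = 2.0 * np.pi * freq_hz * t[sel]
    x_mean = 2.0 * np.mean(y * np.cos(wt))
    y_mean = -2.0 * np.mean(y * np.sin(wt))
    return math.atan2(y_mean, x_mean)


# ---------------------------------------------------------------------------
# Demodulation
# ---------------------------------------------------------------------------

def _decimation_step(cfg: LockInConfig, dt: float) -> int:
    ratio = cfg.output_interval_s / dt
    m = max(int(round(ratio)), 1)
    if abs(ratio - m) > 1e-6 * max(ratio, 1.0):
        logger.warning("output interval %.3g s is not an integer multiple of the "
                       "simulation step %.3g s; snapping to %d samples (%.3g s)",
                       cfg.output_interval_s, dt, m, m * dt)
    return m


def demodulate(raw: RawTraceSet, freqs, cfg: LockInConfig,
               channel_map=None) -> DemodulatedTraceSet:
    """Phase-sensitively demodulate a raw trace set.

    ``freqs`` is a list of reference frequencies applied to every detector,
    unless ``channel_map`` restricts the logical channels: a list of
    ``(detector, frequency_hz, label)`` tuples.  Per channel the demodulator
    forms X = 2·LPF[y·cos(2πft+φ)] and Y = −2·LPF[y·sin(2πft+φ)], applies the
    auto or fixed reference phase, and subsamples the filtered stream at the
    output interval.  Output is the in-phase X (default) or the magnitude R.
    """
    dt = 1.0 / raw.sim_rate_hz
    if channel_map is None:
        channel_map = [(det, float(f), f"{det}@{f / 1000.0:g}kHz")
                       for det in raw.signals for f in freqs]
    labels = [lab for _, _, lab in channel_map]
    if len(set(labels)) != len(labels):
        raise ParameterError(f"duplicate channel labels in {labels}")

    t = raw.time_s
    m = _decimation_step(cfg, dt)
    t_out = t[::m]
    mask_out = settle_mask(cfg, t_out)

    traces, info = {}, {}
    for det, f, label in channel_map:
        if f >= raw.sim_rate_hz / 2.0:
            raise ParameterError(
                f"reference frequency {f:g} Hz at or above Nyquist "
                f"({raw.sim_rate_hz / 2:g} Hz)")
        y = raw.signals[det]
        if cfg.phase_mode == "fixed":
            phi = cfg.phase_rad
        else:
            win = cfg.calibration_window_s
            if win is None:
                start = min(cfg.settle_time_s, 0.5 * (t[-1] - t[0]))
                length = max(30.0 / f, 20.0 * dt)
                win = (t[0] + start, min(t[0] + start + max(length, 0.05), t[-1]))
            phi = auto_phase(raw, det, f, win)
        wt = 2.0 * np.pi * f * t + phi
        x = 2.0 * cascaded_lowpass(y * np.cos(wt), cfg.time_constant_s, cfg.order, dt)
        if cfg.output_mode == "magnitude":
            q = -2.0 * cascaded_lowpass(y * np.sin(wt), cfg.time_constant_s,
                                        cfg.order, dt)
            out = np.hypot(x, q)
        else:
            out = x
        traces[label] = out[::m]
        info[label] = {"detector": det, "frequency_hz": f, "phase_rad": phi}

    meta = dict(raw.metadata)
    meta["lockin"] = {"time_constant_s": cfg.time_constant_s, "order": cfg.order,
                      "output_interval_s": m * dt, "output_mode": cfg.output_mode}
    return DemodulatedTraceSet(time_s=t_out, traces=traces, channel_info=info,
                               settling_mask=mask_out, config=cfg, metadata=meta)
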