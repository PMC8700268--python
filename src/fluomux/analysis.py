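"""Quantitative analysis of demodulated fluorescence traces.

Implements the standard photometry statistics: percent change relative to a
baseline window (ΔF/F₀, and ΔR/R₀ for dual-excitation ratiometric probes),
control-trace subtraction, sliding-average smoothing, the slope-based
crosstalk percentage, signal-to-noise ratio, onset/latency detection,
unconstrained monoexponential rate fitting for dissociation kinetics, and
membrane-voltage calibration of a voltage-dye signal against K⁺ Nernst
potentials.

Crosstalk convention: the fluorescence of the loaded probe's channel is the
regressor (abscissa) and the orthogonal channel the response; 100× the OLS
slope is reported as percent crosstalk, so a channel regressed on itself
gives exactly 100%.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import FitError, ParameterError

logger = logging.getLogger("fluomux")

GAS_CONSTANT = 8.31446261815324       # J/(mol K)
FARADAY_CONSTANT = 96485.33212331001  # C/mol


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProcessedTrace:
    """A baseline-referenced trace: percent change or calibrated millivolts."""

    time_s: np.ndarray
    values: np.ndarray
    kind: str  # "dff_pct" | "drr_pct" | "mV" | "raw"
    baseline_window_s: tuple | None = None
    provenance: tuple = ()

    def __post_init__(self):
        t = np.asarray(self.time_s, float)
        v = np.asarray(self.values, float)
        if t.shape != v.shape or t.ndim != 1:
            raise ParameterError("time and values must be matching 1-D arrays")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "provenance", tuple(self.provenance))

    def derive(self, values, kind=None, note=None) -> "ProcessedTrace":
        return ProcessedTrace(self.time_s, values, kind or self.kind,
                              self.baseline_window_s,
                              self.provenance + ((note,) if note else ()))


@dataclass(frozen=True)
class CrosstalkResult:
    """OLS regression of target channel on source channel."""

    slope: float
    intercept: float
    window_s: tuple
    n_points: int
    slope_se: float = math.nan

    @property
    def percent(self) -> float:
        return 100.0 * self.slope


@dataclass(frozen=True)
class ExpFitResult:
    """Monoexponential fit y(t) = offset + amplitude·e^{−k·(t−t₀)}."""

    k_per_s: float
    amplitude: float
    offset: float
    k_se: float
    amplitude_se: float
    offset_se: float
    residual_rms: float
    t0_s: float
    n_points: int


@dataclass(frozen=True)
class CalibrationResult:
    """Voltage-dye calibration: peak ΔF/F₀ vs K⁺ Nernst potential line."""

    sensitivity_pct_per_mv: float
    v_rest_mv: float
    sensitivity_se: float
    v_rest_se: float
    e_k_mv: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "e_k_mv", tuple(self.e_k_mv))


@dataclass(frozen=True)
class OnsetResult:
    """Detected response onset; ``latency_s`` is None when no onset exists."""

    latency_s: float | None
    direction: int = 0         # +1 rising, -1 falling, 0 none
    threshold: float = math.nan
    baseline_mean: float = math.nan
    baseline_sd: float = math.nan

    @property
    def detected(self) -> bool:
        return self.latency_s is not None


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _window_indices(time_s, window_s, min_points=1, what="window"):
    t0, t1 = window_s
    idx = np.nonzero((time_s >= t0) & (time_s <= t1))[0]
    if idx.size < min_points:
        raise ParameterError(
            f"{what} [{t0:g}, {t1:g}] s holds {idx.size} samples, needs >= {min_points}")
    return idx


def default_baseline_window(time_s, settling_mask=None, n_points: int = 10):
    """Baseline = the first ``n_points`` valid samples of the trace.

    "Valid" excludes the demodulator's settling span when a mask is given.
    The published convention uses the mean of the first 5-10 points before
    signal onset; ``n_points`` is configurable in 3-10.
    """
    if not (3 <= n_points <= 10):
        raise ParameterError("baseline n_points must be in 3..10")
    t = np.asarray(time_s, float)
    valid = np.ones(t.shape, bool) if settling_mask is None else ~np.asarray(settling_mask)
    idx = np.nonzero(valid)[0]
    if idx.size < n_points:
        raise ParameterError("not enough valid samples for a baseline window")
    sel = idx[:n_points]
    return float(t[sel[0]]), float(t[sel[-1]])


# ---------------------------------------------------------------------------
# Baseline-referenced measures
# ---------------------------------------------------------------------------

def dff0(time_s, values, baseline_window_s, settling_mask=None,
         provenance=()) -> ProcessedTrace:
    """Percent fluorescence change, 100·(F − F̄₀)/F̄₀.

    F̄₀ is the mean over the baseline window (>= 3 samples, outside the
    settling span).  Invariant under any positive gain on the raw trace; a
    nonpositive F̄₀ signals mis-set background subtraction and raises.
    """
    t = np.asarray(time_s, float)
    v = np.asarray(values, float)
    idx = _window_indices(t, baseline_window_s, min_points=3, what="baseline window")
    if settling_mask is not None and np.any(np.asarray(settling_mask)[idx]):
        raise ParameterError("baseline window overlaps the demodulator settling span")
    f0 = float(np.mean(v[idx]))
    if f0 <= 0:
        raise ParameterError(f"baseline mean F0 = {f0:g} <= 0; check background "
                             "subtraction and channel assignment")
    return ProcessedTrace(t, 100.0 * (v - f0) / f0, "dff_pct",
                          tuple(baseline_window_s), tuple(provenance) + ("dff0",))


def ratio_trace(time_s, numerator, denominator, baseline_window_s,
                provenance=()) -> ProcessedTrace:
    """Dual-excitation ratio R = num/den as percent change ΔR/R₀.

    Invariant under independent positive gains on the two input channels.
    Raises (with the sample index) if the denominator is not positive
    throughout.
    """
    t = np.asarray(time_s, float)
    num = np.asarray(numerator, float)
    den = np.asarray(denominator, float)
    bad = np.nonzero(den <= 0)[0]
    if bad.size:
        raise ParameterError(f"denominator channel is <= 0 at sample {bad[0]} "
                             f"(t = {t[bad[0]]:g} s)")
    r = num / den
    idx = _window_indices(t, baseline_window_s, min_points=3, what="baseline window")
    r0 = float(np.mean(r[idx]))
    if r0 <= 0:
        raise ParameterError("baseline ratio must be > 0")
    return ProcessedTrace(t, 100.0 * (r - r0) / r0, "drr_pct",
                          tuple(baseline_window_s), tuple(provenance) + ("ratio",))


def subtract_control(stim: ProcessedTrace, control: ProcessedTrace) -> ProcessedTrace:
    """Subtract the vehicle-control response, pinning its level to 0.

    The control is linearly resampled onto the stimulus grid; disjoint time
    ranges are an error.  Drift shared by both traces cancels exactly.
    """
    if control.time_s[-1] < stim.time_s[0] or control.time_s[0] > stim.time_s[-1]:
        raise ParameterError("stimulus and control traces cover disjoint time ranges")
    ctrl = np.interp(stim.time_s, control.time_s, control.values)
    return stim.derive(stim.values - ctrl, note="control_subtracted")


def sliding_average(values, window_points: int | None = None,
                    window_s: float | None = None, dt_s: float | None = None):
    """Centered moving mean with symmetrically shrinking edge windows.

    Pass either ``window_points`` or ``window_s`` together with the sample
    interval.  The published smoothing uses an 80 ms window.
    """
    v = np.asarray(values, float)
    if window_points is None:
        if window_s is None or dt_s is None:
            raise ParameterError("need window_points, or window_s with dt_s")
        window_points = int(round(window_s / dt_s))
    m = int(window_points)
    if m < 3:
        raise ParameterError("sliding-average window must span >= 3 samples")
    if m > v.size:
        raise ParameterError("sliding-average window longer than the trace")
    half = (m - 1) // 2
    csum = np.concatenate(([0.0], np.cumsum(v)))
    out = np.empty_like(v)
    n = v.size
    for i in range(n):
        r = min(half, i, n - 1 - i)
        out[i] = (csum[i + r + 1] - csum[i - r]) / (2 * r + 1)
    return out


# ---------------------------------------------------------------------------
# Crosstalk and S/N
# ---------------------------------------------------------------------------

def crosstalk(source, target, time_s=None, window_s=None) -> CrosstalkResult:
    """Percent crosstalk: 100× the OLS slope of target vs source.

    ``source`` and ``target`` are baseline-normalized traces on a common
    grid (ProcessedTrace or arrays with ``time_s``).  Not symmetric: the
    loaded probe's channel goes on the abscissa.  A source with zero
    variance in the window is degenerate and raises.
    """
    if isinstance(source, ProcessedTrace):
        time_s = source.time_s
        src = source.values
    else:
        src = np.asarray(source, float)
    tgt = target.values if isinstance(target, ProcessedTrace) else np.asarray(target, float)
    if time_s is None:
        raise ParameterError("time_s is required with bare-array inputs")
    t = np.asarray(time_s, float)
    if src.shape != tgt.shape or src.shape != t.shape:
        raise ParameterError("source and target must share one time grid")
    if window_s is None:
        window_s = (float(t[0]), float(t[-1]))
    idx = _window_indices(t, window_s, min_points=10, what="crosstalk window")
    x, y = src[idx], tgt[idx]
    if np.ptp(x) == 0.0:
        raise ParameterError("source channel has zero variance in the window; "
                             "crosstalk slope is undefined")
    res = stats.linregress(x, y)
    return CrosstalkResult(slope=float(res.slope), intercept=float(res.intercept),
                           window_s=(float(window_s[0]), float(window_s[1])),
                           n_points=int(idx.size), slope_se=float(res.stderr))


def snr(values, window_points: int = 200, start: int = 0) -> float:
    """Signal-to-noise ratio: mean / SD over ``window_points`` samples.

    The trace must be stationary over the window.  Zero SD is reported as
    +inf with a warning rather than an error.
    """
    v = np.asarray(values, float)[start:start + window_points]
    if v.size != window_points:
        raise ParameterError(
            f"need exactly {window_points} samples, got {v.size}")
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        warnings.warn("zero standard deviation in S/N window; reporting inf")
        return math.inf
    return float(np.mean(v)) / sd


# ---------------------------------------------------------------------------
# Exponential kinetics
# ---------------------------------------------------------------------------

def fit_monoexponential(time_s, values, t_range_s=None,
                        settling_mask=None) -> ExpFitResult:
    """Unconstrained least-squares fit of y = offset + amplitude·e^{−k(t−t₀)}.

    t₀ is the first sample inside ``t_range_s`` (amplitude is quoted there).
    Initial values come from a log-linear regression of |y − tail mean|;
    the refined fit is plain (homoscedastic, unweighted) least squares.
    Raises :class:`FitError` — carrying the initializer's rate — on
    degenerate input or non-convergence.
    """
    t = np.asarray(time_s, float)
    v = np.asarray(values, float)
    sel = np.ones(t.shape, bool)
    if settling_mask is not None:
        sel &= ~np.asarray(settling_mask, bool)
    if t_range_s is not None:
        sel &= (t >= t_range_s[0]) & (t <= t_range_s[1])
    t_fit, y = t[sel], v[sel]
    if t_fit.size < 20:
        raise ParameterError(f"monoexponential fit needs >= 20 points, got {t_fit.size}")
    t0 = float(t_fit[0])
    x = t_fit - t0

    tail = float(np.mean(y[-max(t_fit.size // 10, 3):]))
    dev = y - tail
    amp0 = float(dev[0])
    if abs(amp0) < 1e-12 * max(abs(tail), 1.0) or np.ptp(y) == 0.0:
        raise FitError("degenerate amplitude: trace is flat over the fit range")
    # log-linear initializer on the early, clearly-decaying part
    good = np.abs(dev) > 0.05 * abs(amp0)
    if np.count_nonzero(good) >= 5:
        lr = stats.linregress(x[good], np.log(np.abs(dev[good])))
        k0 = max(-float(lr.slope), 1e-9)
    else:
        k0 = 1.0 / max(x[-1], 1e-9)

    def model(xx, off, amp, k):
        return off + amp * np.exp(-k * xx)

    try:
        popt, pcov = optimize.curve_fit(model, x, y, p0=(tail, amp0, k0), maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"monoexponential fit failed: {exc}", k_init=k0) from exc
    if not np.all(np.isfinite(popt)):
        raise FitError("monoexponential fit diverged", k_init=k0)
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None)) if np.all(np.isfinite(pcov)) \
        else np.full(3, math.nan)
    resid = y - model(x, *popt)
    return ExpFitResult(k_per_s=float(popt[2]), amplitude=float(popt[1]),
                        offset=float(popt[0]), k_se=float(perr[2]),
                        amplitude_se=float(perr[1]), offset_se=float(perr[0]),
                        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
                        t0_s=t0, n_points=int(t_fit.size))


# ---------------------------------------------------------------------------
# Membrane-voltage calibration
# ---------------------------------------------------------------------------

def nernst_potential(k_out_mm: float, k_in_mm: float = 423.0,
                     temp_k: float = 291.15) -> float:
    """K⁺ Nernst potential (RT/F)·ln([K⁺]ₒ/[K⁺]ᵢ) in millivolts.

    The default intracellular concentration of 423 mM and 18 °C reflect the
    marine-invertebrate calibration conditions.
    """
    if k_out_mm <= 0 or k_in_mm <= 0 or temp_k <= 0:
        raise ParameterError("concentrations and temperature must be > 0")
    return (GAS_CONSTANT * temp_k / FARADAY_CONSTANT) * math.log(k_out_mm / k_in_mm) * 1000.0


def calibrate_vm(peak_dff_pct, e_k_mv) -> CalibrationResult:
    """Fit peak ΔF/F₀ against the K⁺ Nernst potential.

    The OLS slope is the dye's voltage sensitivity (%ΔF/F₀ per mV) and the
    x-intercept the resting potential (the Nernst potential at which the
    stimulus no longer changes V_m).  Needs >= 3 distinct potentials; a
    near-zero slope leaves V_rest undefined and raises.
    """
    peaks = np.asarray(peak_dff_pct, float)
    ek = np.asarray(e_k_mv, float)
    if peaks.shape != ek.shape or peaks.ndim != 1 or peaks.size < 3:
        raise ParameterError("need >= 3 (E_K, peak) pairs")
    if np.unique(ek).size < 3:
        raise ParameterError("E_K values must be distinct")
    res = stats.linregress(ek, peaks)
    s, b = float(res.slope), float(res.intercept)
    scale = float(np.max(np.abs(peaks))) if np.any(peaks) else 1.0
    if abs(s) < 1e-12 * max(scale, 1.0) / max(np.ptp(ek), 1.0) or s == 0.0:
        raise ParameterError("calibration slope is ~0; V_rest is undefined")
    v_rest = -b / s
    # first-order error propagation for the intercept/slope ratio
    se_b = float(res.intercept_stderr)
    se_s = float(res.stderr)
    v_rest_se = abs(v_rest) * math.sqrt(
        (se_b / b) ** 2 + (se_s / s) ** 2) if b != 0 else se_b / abs(s)
    return CalibrationResult(sensitivity_pct_per_mv=s, v_rest_mv=v_rest,
                             sensitivity_se=se_s, v_rest_se=v_rest_se,
                             e_k_mv=tuple(ek))


def vm_from_dff(trace: ProcessedTrace, cal: CalibrationResult) -> ProcessedTrace:
    """Convert a ΔF/F₀ trace to membrane voltage: V = V_rest + ΔF/F₀ / s.

    With positive sensitivity a negative-going fluorescence change maps below
    V_rest (hyperpolarization).
    """
    if cal.sensitivity_pct_per_mv == 0:
        raise ParameterError("calibration sensitivity must be nonzero")
    v = cal.v_rest_mv + trace.values / cal.sensitivity_pct_per_mv
    return trace.derive(v, kind="mV", note="vm_calibrated")


# ---------------------------------------------------------------------------
# Onset / latency
# ---------------------------------------------------------------------------

def detect_onset(time_s, values, baseline_window_s, k_sd: float = 3.0,
                 min_consecutive: int = 5, stimulus_time_s: float = 0.0,
                 direction: int | None = None) -> OnsetResult:
    """First time the trace leaves its baseline band for good.

    Onset = the first of >= ``min_consecutive`` successive samples beyond
    baseline mean ± ``k_sd``·SD, in the response direction (auto-detected
    from the sign of the post-baseline extremum unless given).  The latency
    is reported relative to ``stimulus_time_s``; a trace that never crosses
    returns a no-onset sentinel.
    """
    t = np.asarray(time_s, float)
    v = np.asarray(values, float)
    idx = _window_indices(t, baseline_window_s, min_points=3, what="baseline window")
    mu = float(np.mean(v[idx]))
    sd = float(np.std(v[idx], ddof=1))
    after = idx[-1] + 1
    if after >= v.size:
        raise ParameterError("baseline window leaves no samples to search")
    post = v[after:]
    if direction is None:
        ext = post[int(np.argmax(np.abs(post - mu)))]
        direction = 1 if ext >= mu else -1
    thr = mu + direction * k_sd * sd
    beyond = (post - thr) * direction >= 0 if sd > 0 else (post - mu) * direction > 0
    run = 0
    for i, flag in enumerate(beyond):
        run = run + 1 if flag else 0
        if run >= min_consecutive:
            onset_idx = after + i - min_consecutive + 1
            return OnsetResult(latency_s=float(t[onset_idx] - stimulus_time_s),
                               direction=direction, threshold=float(thr),
                               baseline_mean=mu, baseline_sd=sd)
    return OnsetResult(latency_s=None, direction=0, threshold=float(thr),
                       baseline_mean=mu, baseline_sd=sd)


def vm_at_onset(vm_trace: ProcessedTrace, latency_s: float,
                stimulus_time_s: float = 0.0) -> float:
    """Calibrated membrane voltage at a detected onset time.

    Linear interpolation between output samples; a latency outside the trace
    is an error.
    """
    t_onset = stimulus_time_s + latency_s
    t = vm_trace.time_s
    if not (t[0] <= t_onset <= t[-1]):
        raise ParameterError(f"onset time {t_onset:g} s outside the trace "
                             f"[{t[0]:g}, {t[-1]:g}] s")
    return float(np.interp(t_onset, t, vm_trace.values))
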