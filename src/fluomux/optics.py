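"""Spectral model of the photometer: probes, LEDs, filters, detectors.

Everything optical is reduced to a linear *coupling tensor*
``S[detector, excitation channel, species]`` — the effective brightness with
which each fluorescent species appears on each logical channel.  The tensor
entries are overlap integrals of excitation-side spectra (LED × excitation
filter × species excitation) and emission-side spectra (species emission ×
emission filters × detector sensitivity), so spectral crosstalk between
overlapping probes falls out of the same arithmetic as the intended signal.

Spectra are wavelength-indexed curves on a common nanometre grid; probe
spectra shipped in :data:`PROBE_LIBRARY` are parametric sum-of-Gaussian
approximations to the published shapes of the common indicators, adequate for
studying multiplexing and crosstalk but not calibrated photometry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, ParameterError

logger = logging.getLogger("fluomux")

#: Default wavelength grid: 300-750 nm at 1 nm, which resolves the narrowest
#: bandpass in use (370/10) with >= 10 samples across its passband.
DEFAULT_GRID = np.arange(300.0, 751.0, 1.0)


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Spectrum:
    """A nonnegative intensity or transmission curve on a wavelength grid.

    Evaluation outside the grid returns 0 (spectra have compact support).
    Transmission curves must additionally stay <= 1; pass
    ``is_transmission=True`` to enforce that.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    is_transmission: bool = False

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or wl.shape != v.shape:
            raise ParameterError("wavelengths and values must be 1-D arrays of equal length")
        if wl.size < 2:
            raise ParameterError("a spectrum needs at least two grid points")
        if not np.all(np.diff(wl) > 0):
            raise ParameterError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ParameterError("spectrum values must be finite and >= 0")
        if self.is_transmission and np.any(v > 1.0 + 1e-12):
            raise ParameterError("transmission values must be <= 1")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", v)

    def __call__(self, wavelengths_nm) -> np.ndarray:
        """Linear interpolation; zero outside the stored grid."""
        return np.interp(wavelengths_nm, self.wavelengths_nm, self.values,
                         left=0.0, right=0.0)

    def resample(self, grid: np.ndarray) -> "Spectrum":
        return Spectrum(np.asarray(grid, float), self(grid),
                        is_transmission=self.is_transmission)

    @property
    def peak_nm(self) -> float:
        return float(self.wavelengths_nm[int(np.argmax(self.values))])

    @staticmethod
    def flat(value: float, grid: np.ndarray | None = None,
             is_transmission: bool = False) -> "Spectrum":
        grid = DEFAULT_GRID if grid is None else np.asarray(grid, float)
        return Spectrum(grid, np.full(grid.shape, float(value)),
                        is_transmission=is_transmission)

    @staticmethod
    def gaussian(peaks, grid: np.ndarray | None = None) -> "Spectrum":
        """Sum of (possibly two-sided) Gaussians.

        ``peaks``: iterable of ``(center_nm, fwhm_nm, amplitude)`` for
        symmetric peaks or ``(center_nm, fwhm_blue_nm, fwhm_red_nm,
        amplitude)`` for peaks with different widths on the short- and
        long-wavelength sides.  Real absorption bands cut off steeply on the
        red side while emission bands carry a red tail; the asymmetric form
        captures both.
        """
        grid = DEFAULT_GRID if grid is None else np.asarray(grid, float)
        v = np.zeros_like(grid)
        to_sigma = 2.0 * math.sqrt(2.0 * math.log(2.0))
        for peak in peaks:
            if len(peak) == 3:
                center, fwhm_lo, amp = peak
                fwhm_hi = fwhm_lo
            else:
                center, fwhm_lo, fwhm_hi, amp = peak
            if fwhm_lo <= 0 or fwhm_hi <= 0 or amp < 0:
                raise ParameterError("gaussian peaks need fwhm > 0 and amplitude >= 0")
            sigma = np.where(grid < center, fwhm_lo / to_sigma, fwhm_hi / to_sigma)
            v += amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
        # truncate the far tails to give spectra genuinely compact support
        v[v < 1e-10 * v.max()] = 0.0
        return Spectrum(grid, v)

    @staticmethod
    def boxcar(lo_nm: float, hi_nm: float, amplitude: float = 1.0,
               grid: np.ndarray | None = None) -> "Spectrum":
        """Rectangular spectrum, handy for analytically checkable overlaps."""
        grid = DEFAULT_GRID if grid is None else np.asarray(grid, float)
        v = np.where((grid >= lo_nm) & (grid <= hi_nm), float(amplitude), 0.0)
        return Spectrum(grid, v)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterSpec:
    """Interference filter: ``bandpass`` (center/fwhm) or ``longpass`` (cutoff).

    Edges are raised-cosine ramps of half-width ``edge_softness_nm`` with
    transmission 0.5 exactly at the nominal half-power wavelength; softness 0
    gives an ideal hard edge.  The field notation "X/Y" (e.g. "485/20") maps
    to a bandpass with center X and FWHM Y; "593LP" to a longpass at 593 nm.
    """

    kind: str
    center_nm: float | None = None
    fwhm_nm: float | None = None
    cutoff_nm: float | None = None
    edge_softness_nm: float = 2.0

    def __post_init__(self):
        if self.kind not in ("bandpass", "longpass"):
            raise ParameterError(f"unknown filter kind {self.kind!r}")
        if self.edge_softness_nm < 0:
            raise ParameterError("edge_softness_nm must be >= 0")
        if self.kind == "bandpass":
            if self.center_nm is None or self.fwhm_nm is None:
                raise ParameterError("bandpass filter needs center_nm and fwhm_nm")
            if self.fwhm_nm <= 0:
                raise ParameterError("fwhm_nm must be > 0")
        else:
            if self.cutoff_nm is None:
                raise ParameterError("longpass filter needs cutoff_nm")

    @staticmethod
    def parse(text: str, edge_softness_nm: float = 2.0) -> "FilterSpec":
        """Parse "485/20" (bandpass) or "593LP" (longpass)."""
        t = text.strip()
        if t.upper().endswith("LP"):
            return FilterSpec("longpass", cutoff_nm=float(t[:-2]),
                              edge_softness_nm=edge_softness_nm)
        if "/" in t:
            c, w = t.split("/")
            return FilterSpec("bandpass", center_nm=float(c), fwhm_nm=float(w),
                              edge_softness_nm=edge_softness_nm)
        raise ParameterError(f"cannot parse filter notation {text!r}")

    def transmission(self, wavelengths_nm) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, dtype=float)
        w = self.edge_softness_nm
        if self.kind == "bandpass":
            d = np.abs(wl - self.center_nm)
            h = self.fwhm_nm / 2.0
            if w == 0.0:
                return np.where(d < h, 1.0, np.where(d > h, 0.0, 0.5))
            t = np.clip((d - (h - w)) / (2.0 * w), 0.0, 1.0)
            return 0.5 * (1.0 + np.cos(math.pi * t))
        # longpass: ramp up through the cutoff
        if w == 0.0:
            return np.where(wl > self.cutoff_nm, 1.0,
                            np.where(wl < self.cutoff_nm, 0.0, 0.5))
        t = np.clip((wl - (self.cutoff_nm - w)) / (2.0 * w), 0.0, 1.0)
        return 0.5 * (1.0 - np.cos(math.pi * t))


def filter_transmission(flt: FilterSpec, wavelengths_nm=None) -> Spectrum:
    """Evaluate a filter onto a wavelength grid as a transmission Spectrum."""
    grid = DEFAULT_GRID if wavelengths_nm is None else np.asarray(wavelengths_nm, float)
    return Spectrum(grid, flt.transmission(grid), is_transmission=True)


# ---------------------------------------------------------------------------
# Species and channels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Species:
    """One fluorescent species: a probe, one binding state of a probe, or a
    broadband ambient term (flat spectra, used to model stray light).

    ``brightness`` is a relative quantum-yield × extinction factor; coupling
    coefficients scale linearly with it.  A Stokes shift (emission peak at or
    above the excitation peak) is enforced unless ``allow_anti_stokes``.
    """

    name: str
    excitation: Spectrum
    emission: Spectrum
    brightness: float = 1.0
    allow_anti_stokes: bool = False

    def __post_init__(self):
        if self.brightness <= 0:
            raise ParameterError(f"species {self.name!r}: brightness must be > 0")
        if (not self.allow_anti_stokes
                and self.emission.peak_nm < self.excitation.peak_nm):
            raise ParameterError(
                f"species {self.name!r}: emission peak {self.emission.peak_nm} nm "
                f"below excitation peak {self.excitation.peak_nm} nm (no Stokes shift)")


@dataclass(frozen=True)
class ExcitationChannel:
    """One modulated LED behind an excitation filter."""

    name: str
    led_spectrum: Spectrum
    ex_filter: FilterSpec
    mod_freq_hz: float
    mod_depth: float = 1.0
    intensity: float = 1.0
    phase_rad: float = 0.0

    def __post_init__(self):
        if self.mod_freq_hz <= 0:
            raise ParameterError(f"channel {self.name!r}: mod_freq_hz must be > 0")
        if not (0.0 < self.mod_depth <= 1.0):
            raise ParameterError(f"channel {self.name!r}: mod_depth must be in (0, 1]")
        if self.intensity <= 0:
            raise ParameterError(f"channel {self.name!r}: intensity must be > 0")


@dataclass(frozen=True)
class DetectionChannel:
    """One detector (PMT) behind a stack of emission filters.

    ``sensitivity`` defaults to a flat unit spectrum (no published QE curve
    is assumed); ``gain`` is a linear electronic gain.
    """

    name: str
    em_filters: tuple = ()
    sensitivity: Spectrum | None = None
    gain: float = 1.0

    def __post_init__(self):
        if self.gain <= 0:
            raise ParameterError(f"detector {self.name!r}: gain must be > 0")
        object.__setattr__(self, "em_filters", tuple(self.em_filters))

    def transmission(self, wavelengths_nm) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, float)
        t = np.ones_like(wl)
        for f in self.em_filters:
            t = t * f.transmission(wl)
        if self.sensitivity is not None:
            t = t * self.sensitivity(wl)
        return t


# ---------------------------------------------------------------------------
# Coupling tensor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CouplingTensor:
    """Effective brightness S[detector, excitation channel, species] >= 0."""

    values: np.ndarray  # shape (n_detectors, n_excitation, n_species)
    detector_names: tuple
    excitation_names: tuple
    species_names: tuple

    def __post_init__(self):
        v = np.asarray(self.values, float)
        expected = (len(self.detector_names), len(self.excitation_names),
                    len(self.species_names))
        if v.shape != expected:
            raise ParameterError(f"coupling tensor shape {v.shape} != {expected}")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ParameterError("coupling tensor must be finite and >= 0")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "detector_names", tuple(self.detector_names))
        object.__setattr__(self, "excitation_names", tuple(self.excitation_names))
        object.__setattr__(self, "species_names", tuple(self.species_names))

    def coefficient(self, detector: str, excitation: str, species: str) -> float:
        return float(self.values[self.detector_names.index(detector),
                                 self.excitation_names.index(excitation),
                                 self.species_names.index(species)])


def coupling_coefficient(species: Species, exch: ExcitationChannel,
                         det: DetectionChannel,
                         grid: np.ndarray | None = None) -> float:
    """Overlap-integral brightness of one (species, LED, detector) triple.

    Returns ``brightness * intensity * gain *
    ∫ led·ex_filter·excitation dλ * ∫ emission·em_filters·sensitivity dλ``
    (trapezoid rule on the common grid).  Disjoint spectral supports give 0.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, float)
    ex_weight = (exch.led_spectrum(grid)
                 * exch.ex_filter.transmission(grid)
                 * species.excitation(grid))
    em_weight = species.emission(grid) * det.transmission(grid)
    ex_int = float(np.trapezoid(ex_weight, grid))
    em_int = float(np.trapezoid(em_weight, grid))
    return species.brightness * exch.intensity * det.gain * ex_int * em_int


def build_coupling_tensor(species, excitation_channels, detection_channels,
                          grid: np.ndarray | None = None) -> CouplingTensor:
    """Evaluate coupling_coefficient for every (detector, LED, species) triple."""
    species = list(species)
    excitation_channels = list(excitation_channels)
    detection_channels = list(detection_channels)
    if not species or not excitation_channels or not detection_channels:
        raise ConfigurationError("need at least one species, excitation channel "
                                 "and detection channel")
    problems = []
    for label, items in (("species", [s.name for s in species]),
                         ("excitation channel", [c.name for c in excitation_channels]),
                         ("detection channel", [d.name for d in detection_channels])):
        dupes = {n for n in items if items.count(n) > 1}
        if dupes:
            problems.append(f"duplicate {label} name(s): {sorted(dupes)}")
    if problems:
        raise ConfigurationError(problems)

    S = np.empty((len(detection_channels), len(excitation_channels), len(species)))
    for k, det in enumerate(detection_channels):
        for j, exch in enumerate(excitation_channels):
            for s, sp in enumerate(species):
                S[k, j, s] = coupling_coefficient(sp, exch, det, grid=grid)
    return CouplingTensor(S,
                          tuple(d.name for d in detection_channels),
                          tuple(c.name for c in excitation_channels),
                          tuple(s.name for s in species))


# ---------------------------------------------------------------------------
# Frequency planning
# ---------------------------------------------------------------------------

def cascade_amplitude_response(delta_f_hz, tau_s: float, order: int):
    """|H| of `order` identical single-pole stages at offset ``delta_f_hz``:
    (1 + (2π f τ)²)^(−order/2)."""
    x = 2.0 * math.pi * np.asarray(delta_f_hz, float) * tau_s
    return (1.0 + x * x) ** (-order / 2.0)


def cascade_noise_bandwidth(tau_s: float, order: int) -> float:
    """Equivalent noise bandwidth ∫|H|² df of the RC cascade in Hz.

    Closed form: (1/2πτ)·(π/2)·(2n−3)!!/(2n−2)!!; 93.75 Hz for τ = 1 ms,
    order 3.
    """
    if order < 1:
        raise ParameterError("order must be >= 1")
    num, den = 1.0, 1.0
    for i in range(3, 2 * order - 2, 2):
        num *= i
    for i in range(2, 2 * order - 1, 2):
        den *= i
    integral = (math.pi / 2.0) * num / den
    return integral / (2.0 * math.pi * tau_s)


@dataclass(frozen=True)
class FrequencyPlan:
    """Report of :func:`plan_frequencies`; informational, never raises."""

    ok: bool
    issues: tuple
    freqs_hz: tuple
    noise_bandwidth_hz: float
    worst_leakage: float  # worst-case |H(Δf)| between any channel pair
    pair_leakage: dict = field(default_factory=dict)


def _alias(f: float, rate: float) -> float:
    r = f % rate
    return min(r, rate - r)


def plan_frequencies(freqs_hz, tau_s: float, order: int, sim_rate_hz: float,
                     min_separation_factor: float = 5.0,
                     harmonics: int = 3) -> FrequencyPlan:
    """Sanity-check a set of modulation frequencies against the lock-in filter.

    Flags (i) pairs closer than ``min_separation_factor`` times the filter
    cascade's noise bandwidth, (ii) a frequency or its harmonics (2nd, 3rd by
    default — relevant for square-wave modulation) aliasing onto another
    channel under ``sim_rate_hz``, and (iii) frequencies at or above Nyquist.
    Report-only: nothing here raises.
    """
    freqs = [float(f) for f in freqs_hz]
    issues = []
    if any(f <= 0 for f in freqs):
        issues.append("non-positive frequency in plan")
    nbw = cascade_noise_bandwidth(tau_s, order)
    min_sep = min_separation_factor * nbw
    pair_leakage = {}
    worst = 0.0
    for i, fi in enumerate(freqs):
        if fi >= sim_rate_hz / 2.0:
            issues.append(f"{fi:g} Hz is at or above Nyquist ({sim_rate_hz / 2:g}/2 Hz rate)")
        for j, fj in enumerate(freqs):
            if j <= i:
                continue
            df = abs(fi - fj)
            leak = float(cascade_amplitude_response(df, tau_s, order))
            pair_leakage[(fi, fj)] = leak
            worst = max(worst, leak)
            if df < min_sep:
                issues.append(
                    f"{fi:g} Hz and {fj:g} Hz are {df:g} Hz apart, closer than "
                    f"{min_separation_factor:g}x the filter noise bandwidth ({nbw:.1f} Hz)")
            for m in range(2, harmonics + 1):
                for a, b, fa in ((fi, fj, _alias(m * fi, sim_rate_hz)),
                                 (fj, fi, _alias(m * fj, sim_rate_hz))):
                    if abs(fa - b) < min_sep and _alias(a, sim_rate_hz) != fa:
                        issues.append(
                            f"harmonic {m}x of {a:g} Hz aliases to {fa:g} Hz, "
                            f"near channel at {b:g} Hz")
    return FrequencyPlan(ok=not issues, issues=tuple(issues), freqs_hz=tuple(freqs),
                         noise_bandwidth_hz=nbw, worst_leakage=worst,
                         pair_leakage=pair_leakage)


# ---------------------------------------------------------------------------
# Probe spectral library
# ---------------------------------------------------------------------------

def _probe(name, ex_peaks, em_peaks, brightness=1.0, anti_stokes=False):
    return Species(name,
                   excitation=Spectrum.gaussian(ex_peaks),
                   emission=Spectrum.gaussian(em_peaks),
                   brightness=brightness,
                   allow_anti_stokes=anti_stokes)


#: Parametric (sum-of-Gaussian) approximations of common indicator spectra.
#: These are plausible shapes with roughly correct peak positions and widths,
#: *not* measured data; crosstalk magnitudes computed from them are therefore
#: qualitative.  Excitation bands are two-sided Gaussians with a broad blue
#: wing and a steep red edge (absorption onset); emission bands mirror that
#: with a steep blue edge and a red tail.  Ratiometric probes appear as two
#: species (ion-bound / free, protonated / deprotonated); voltage dyes carry
#: a secondary ~400 nm excitation band as described for the
#: photoinduced-electron-transfer dyes.
PROBE_LIBRARY = {
    "fura2_free": _probe("fura2_free", [(370, 60, 28, 1.0)], [(510, 35, 75, 1.0)]),
    "fura2_bound": _probe("fura2_bound", [(340, 55, 26, 1.0)], [(505, 35, 70, 1.0)]),
    "furaff_free": _probe("furaff_free", [(370, 60, 28, 1.0)], [(510, 35, 75, 1.0)]),
    "furaff_bound": _probe("furaff_bound", [(340, 55, 26, 1.0)], [(505, 35, 70, 1.0)]),
    "bcecf_base": _probe("bcecf_base", [(503, 55, 20, 1.0)], [(528, 28, 80, 1.0)]),
    "bcecf_acid": _probe("bcecf_acid", [(470, 60, 30, 1.0)], [(528, 28, 80, 0.7)]),
    "fluo4": _probe("fluo4", [(494, 40, 18, 1.0)], [(516, 25, 70, 1.0)]),
    "phrodo": _probe("phrodo", [(560, 50, 22, 1.0)], [(585, 28, 75, 1.0)]),
    "ang2": _probe("ang2", [(517, 42, 20, 1.0)], [(540, 26, 75, 1.0)]),
    "calbryte630": _probe("calbryte630", [(607, 45, 20, 1.0)], [(626, 28, 75, 1.0)]),
    "vf21cl": _probe("vf21cl", [(522, 42, 20, 1.0), (400, 45, 45, 0.3)],
                     [(535, 26, 70, 1.0)]),
    "rhovr": _probe("rhovr", [(565, 45, 20, 1.0), (400, 45, 45, 0.25)],
                    [(590, 28, 75, 1.0)]),
    "berst": _probe("berst", [(658, 50, 24, 1.0), (400, 50, 50, 0.2)],
                    [(683, 30, 80, 1.0)]),
    "cerulean": _probe("cerulean", [(433, 45, 22, 1.0)], [(475, 28, 70, 1.0)]),
    "citrine": _probe("citrine", [(516, 40, 18, 1.0)], [(529, 25, 70, 1.0)]),
}

#: Flat-spectrum pseudo-species standing in for broadband stray/scattered
#: light and autofluorescence; gives off-target channels a realistic nonzero
#: modulated baseline.  Scale via brightness in the experiment config.
AMBIENT = Species("ambient",
                  excitation=Spectrum.flat(1.0),
                  emission=Spectrum.flat(1.0),
                  brightness=1.0,
                  allow_anti_stokes=True)


def get_probe(name: str, brightness: float | None = None) -> Species:
    """Look up a library probe, optionally rescaling its brightness."""
    if name == "ambient":
        sp = AMBIENT
    else:
        try:
            sp = PROBE_LIBRARY[name]
        except KeyError:
            raise ConfigurationError(
                f"unknown probe {name!r}; known: {sorted(PROBE_LIBRARY)} + ['ambient']")
    if brightness is not None:
        sp = replace(sp, brightness=brightness)
    return sp


def led_channel(name: str, center_nm: float, mod_freq_hz: float,
                ex_filter: str | FilterSpec, fwhm_nm: float = 25.0,
                mod_depth: float = 1.0, intensity: float = 1.0,
                phase_rad: float = 0.0) -> ExcitationChannel:
    """Convenience builder: Gaussian LED spectrum + parsed excitation filter."""
    if isinstance(ex_filter, str):
        ex_filter = FilterSpec.parse(ex_filter)
    return ExcitationChannel(name=name,
                             led_spectrum=Spectrum.gaussian([(center_nm, fwhm_nm, 1.0)]),
                             ex_filter=ex_filter,
                             mod_freq_hz=mod_freq_hz, mod_depth=mod_depth,
                             intensity=intensity, phase_rad=phase_rad)


def detector(name: str, em_filters, gain: float = 1.0) -> DetectionChannel:
    """Convenience builder: detector behind parsed emission filter(s)."""
    parsed = tuple(FilterSpec.parse(f) if isinstance(f, str) else f
                   for f in ([em_filters] if isinstance(em_filters, (str, FilterSpec))
                             else em_filters))
    return DetectionChannel(name=name, em_filters=parsed, gain=gain)
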