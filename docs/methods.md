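# Methods

## Scope and model

`fluomux` models a frequency-multiplexed fluorescence photometer as three
linear stages followed by an analysis layer.

**Optical coupling.** Every light-emitting or light-filtering element is a
wavelength-indexed curve on a 300–750 nm grid at 1 nm (fine enough to put
≥ 10 samples across the narrowest bandpass in use, 370/10). A probe
species couples to a (detector k, excitation channel j) pair through

    S[k, j, s] = brightness · intensity · gain
                 · ∫ LED_j(λ) · T_ex,j(λ) · ex_s(λ) dλ
                 · ∫ em_s(λ) · T_em,k(λ) · QE_k(λ) dλ

with trapezoid integration. This factorized overlap integral assumes the
emission spectrum does not depend on which band excites the probe (valid
for the single-emitter dyes modelled here) and ignores inner-filter
effects, photobleaching and absolute radiometry, which are out of scope.
Detector quantum efficiency defaults to flat.

Interference filters are raised-cosine-edged ideal filters
(transmission 0.5 at the nominal half-power wavelength, edge half-width
2 nm by default); the field notation "485/20" (center/FWHM) and "593LP"
parses directly. Soft edges avoid the integration artifacts of hard
boxcars while staying near-ideal.

**Probe spectra are approximations.** No tabulated spectra ship with the
package. Each library probe is a sum of one or two two-sided Gaussians
with plausible peak positions and widths: excitation bands have a broad
blue wing and a steep red edge (absorption onset), emission bands a steep
blue edge and a red tail, and the far tails are truncated to give genuine
compact support. Voltage dyes of the photoinduced-electron-transfer family
carry a secondary ~400 nm excitation band. Consequences: self-channel
signals and the *structure* of crosstalk are realistic, but crosstalk
percentages for specific real dye pairs are qualitative, not predictions.

**Stray light.** Real off-target channels show a lowered but nonzero
baseline from scattered broadband light and autofluorescence. The fixtures
model this with a flat-spectrum `ambient` species at constant
concentration (brightness 0.03, putting a few percent of a probe's
own-channel signal on every detector/LED pair). Without it, baseline
normalization of an empty channel would divide by ~0 and inflate crosstalk
estimates — the same pathology that affects slope-based crosstalk
estimates on near-empty channels in real recordings.

**Excitation and acquisition.** LED intensity is
`I_j(t) = intensity · (1 + m·cos(2πf_j t + φ_j))/2` — sinusoidal
modulation, depth m = 1 by default. Sinusoids put no energy at harmonics,
so channel separation is set by the lock-in filter alone; square-wave
modulation is deliberately not the default. With multiplexing disabled,
all channels share one common frequency (the optical-filtering-only
control). The detector signal is the coupling-weighted sum over species
and LEDs plus a DC background; noise is Gaussian with variance
`dark_sd² + shot_scale · signal(t)` — the high-flux PMT limit of shot
noise, chosen over Poisson counting for speed and exact seedability. The
default internal rate is 1 MHz (≥ 2.5× the highest modulation frequency
used anywhere in the fixtures, 103.7 kHz). All noise flows from one seeded
generator; identical (config, seed) reproduces traces bit-exactly.
Artifacts: an *unmodulated* additive flash pulse with raised-cosine edges
(uncaging), and a multiplicative exponential mixing transient whose
metadata records a 5-decay-constant crop window (> 99.99% of the
disturbance energy).

**Lock-in demodulation.** Each logical channel (detector, reference
frequency) is mixed with quadrature references, lowpass-filtered and
decimated. The filter is a cascade of `order` identical single-pole stages
`y[n] = y[n−1] + dt/(τ+dt)·(u[n]−y[n−1])`; τ is the *per-stage* time
constant, matching the commercial "n-th order, 6n dB/octave" convention,
so order 3 with τ = 1 ms gives the classic 18 dB/octave response with
`|H(f)| = (1+(2πfτ)²)^(−3/2)` and an equivalent noise bandwidth of
3/(32τ) = 93.75 Hz. Amplitude convention: an input `A·cos(2πft+φ)`
demodulated at f with matched phase settles to in-phase output X = A.
Auto-phasing estimates φ = atan2(⟨Y⟩, ⟨X⟩) over a ≥ 20-period calibration
window and rotates all signal into X; the signed in-phase output is the
default (magnitude R rectifies noise near zero and hides signal polarity).
Decimation subsamples the filtered stream — the cascade itself is the
anti-alias filter — snapping non-integer ratios with a logged warning.
The first `10·order·τ` of every output trace is flagged by a settling
mask and excluded from analysis; an order-3 step response exceeds 99% of
its final value well inside that span. The frequency planner flags channel
pairs closer than 5× the cascade noise bandwidth, harmonic aliases under
the simulation rate, and Nyquist violations, and reports the worst-case
closed-form leakage `|H(Δf)|`.

**Analysis.** ΔF/F₀ (%) is referenced to the mean of a baseline window —
by default the first 10 valid samples after the settling mask (the field
convention is 5–10 points before onset; 10 minimizes baseline variance,
and 3–10 is accepted). Ratiometric ΔR/R₀ uses the per-sample ratio of two
channels and is invariant under independent channel gains. Crosstalk is
100 × the OLS slope of the target channel regressed on the loaded probe's
channel over a 2 s window, with intercept (the intercept absorbs static
offsets); the regression direction is fixed — loaded channel on the
abscissa — and the self-case is exactly 100%. Baseline-normalized traces
are used so the identity holds exactly. S/N is mean/SD over 200 samples.
k_off fitting is plain unconstrained least squares of
`offset + amplitude·e^(−k(t−t₀))` initialized by log-linear regression;
errors come from the covariance of the fit. Voltage calibration fits peak
ΔF/F₀ against K⁺ Nernst potentials (intracellular K⁺ 423 mM, 18 °C by
default): the slope is the dye sensitivity (%/mV) and the x-intercept the
resting potential; traces convert via `V = V_rest + ΔF/F₀ / sensitivity`.
Onset latency uses a debounced threshold rule — the first ≥ 5 consecutive
samples beyond baseline ± 3 SD in the auto-detected response direction —
because no standard closed-form latency criterion exists for these data;
the parameters are exposed.

## Synthetic scenarios

The kinetic generators produce relative (baseline-1) concentration
traces; species in an experiment config map a scenario trace through
`c = max(1 + scale·(trace − trace₀), 0)`, so inverted-response probes
(e.g. a Ca probe excited on the wavelength that *dims* with Ca binding)
use a negative scale.

* **Cascade** — voltage pulse `A(1−e^{−t/τ_r})e^{−t/τ_d}` (onset 50 ms,
  τ_r 20 ms, τ_d 200 ms, amplitude −0.30) followed by saturating pH and
  Na rises (onset 150 ms, τ 300 ms) and a delayed Ca rise (onset 400 ms,
  τ 500 ms). The *ordering* is the modelled biology; the time constants
  are fixture choices with realistic magnitudes, since the package's
  claims rest on signal-processing fidelity, not on these parameters.
  Dose scaling divides latencies by `max(1 + log₁₀ dose, 0.1)` and scales
  the pulse depth by `2·dose/(1+dose)` — simple monotone stand-ins for a
  dose-response.
* **Dissociation** — excess-chelator quench: bound fraction `b₀e^{−k_off t}`,
  free = 1 − bound; rebinding neglected.
* **Uncaging** — the cascade with all latencies referenced to a flash
  window (default 50 ms), returned for artifact injection; responses are
  exactly baseline before the flash.
* **Messenger buffering** — constant-rate second-messenger production
  (fixed-step RK4 on the trace grid; exact for a constant source, kept
  general), a rapid-equilibrium binding sensor (quadratic solution for
  free messenger; total = free + bound conserved to < 1e−9), and a
  downstream channel opening as a Hill function (coefficient 2 by
  default). Defaults — sensor K_d 70 nM vs channel K_1/2 10 µM, sensor
  10 µM, production 1 µM/s — reproduce the qualitative effect that a
  high-affinity sensor delays effector activation more than a low-affinity
  one. FRET is not modelled; in the single-cell fixture the donor and
  acceptor species simply follow sensor occupancy with opposite signs.

Fixture noise (`shot_scale` 0.02, `dark_sd` 0.05 at unit LED intensity)
gives raw per-sample S/N near 100 at 1 MHz — a bright population
measurement — and demodulated baseline S/N of a few hundred to a few
thousand at τ = 1 ms.

**What passing tests do and do not show.** The simulator exercises the
full causal chain the instrument relies on (spectral mixing, frequency
tagging, phase-sensitive separation, filter leakage, shot noise,
artifacts), so recovery of rates, latencies and crosstalk bounds is a
genuine end-to-end result. It does not model real probe spectra in cells,
PMT gain drift, LED thermal transients, probe photobleaching or detector
saturation (a soft-saturation option is out of scope), so absolute
crosstalk percentages for named dye pairs and absolute S/N values are
indicative only.

## Numerical choices

* Trapezoid integration on the 1 nm grid; spectra evaluate to 0 outside
  their support; Gaussian tails below 1e−10 of peak truncated to 0.
* Reference phases accumulate as `2πft` in double precision — over the
  longest fixture (60 s × 103.7 kHz) the phase error stays below 1e−8 rad.
* The discrete single-pole stage deviates from the analog `|H(f)|` by
  < 0.2% up to 20 kHz at 1 MHz sampling; the closed-form equivalence test
  budget is 2%.
* Monoexponential fits reject flat traces (degenerate amplitude) and
  carry the log-linear initializer's rate when the refinement fails.
* Per-stage RNG streams are derived from the root seed by hashing
  `(seed, stage name)`, so a stage re-run in isolation sees the same
  stream; all derived seeds stay below 2³¹.
* Problem sizes: the crosstalk studies simulate 2.3–2.6 s at 1 MHz (the
  analysis window is the standard first 2 s of valid output); quench
  kinetics simulate 120 ms at 1 MHz with τ = 100 µs and fit from 4 ms
  (past the 3 ms settling span); the single-cell fixture runs 20 s at
  250 kHz. These sizes reproduce the published operating conditions while
  keeping every fixture comfortably inside a desktop-scale run.

## Design decisions that were genuinely open

* **X vs R output**: which quadrature convention the hardware reported is
  not documented; both are implemented, signed X is the default (see
  above).
* **Crosstalk on normalized vs raw traces**: normalized-to-baseline chosen
  because it makes the 100% self-case exact and matches how the plots that
  define the statistic are constructed.
* **Baseline length**: "first 5–10 points" is a range; 10 chosen,
  configurable 3–10.
* **Modulation waveform**: unstated in the source instrument; sinusoidal
  chosen (no harmonic collisions), see above.
* **Latency rule**: unspecified; debounced threshold crossing, parameters
  exposed.

## Known limitations

Linear detectors only; no Poisson statistics at low flux; no spatial
dimension (single-cell mode is a photometry average); ratiometric
calibration to absolute ion concentrations (requires in-situ K_d
calibrations) is not implemented; crosstalk magnitudes for real dye pairs
are qualitative because the shipped spectra are parametric approximations.
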