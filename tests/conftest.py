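import numpy as np
import pytest

from fluomux import (AcquisitionConfig, DetectionChannel, ExcitationChannel,
                     FilterSpec, NoiseSpec, Species, Spectrum,
                     build_coupling_tensor, simulate_acquisition)
from fluomux.kinetics import ConcentrationTraces


@pytest.fixture
def boxcar_setup():
    """Hand-integrable optics: rectangular spectra with hard-edged filters.

    Excitation overlap covers 400-405 nm (trapezoid area 5 on the 1 nm
    grid); emission overlap covers 500-520 nm (area 20); expected coupling
    coefficient = brightness * intensity * gain * 5 * 20.
    """
    species = Species("box",
                      excitation=Spectrum.boxcar(400, 410),
                      emission=Spectrum.boxcar(500, 520),
                      brightness=2.0)
    exch = ExcitationChannel("led", led_spectrum=Spectrum.boxcar(395, 405),
                             ex_filter=FilterSpec("bandpass", center_nm=400,
                                                  fwhm_nm=300, edge_softness_nm=0.0),
                             mod_freq_hz=1000.0, intensity=3.0)
    det = DetectionChannel("pmt", em_filters=(), gain=1.5)
    return species, exch, det


@pytest.fixture
def tone_raw():
    """Noiseless single-tone acquisition for demodulator tests."""
    def make(freq_hz=30400.0, amplitude=5.0, phase=0.0, dc=2.0,
             duration_s=0.2, rate_hz=1.0e6):
        from fluomux.acquisition import RawTraceSet
        t = np.arange(int(duration_s * rate_hz)) / rate_hz
        y = dc + amplitude * np.cos(2 * np.pi * freq_hz * t + phase)
        return RawTraceSet(t, {"pmt": y}, rate_hz, {})
    return make


@pytest.fixture
def mono_acquisition():
    """One species / one LED / one detector forward model with unit coupling."""
    def make(duration_s=0.1, rate_hz=2.5e5, freq_hz=30400.0, conc=None,
             noise=None, background=0.0):
        species = Species("dye", excitation=Spectrum.boxcar(380, 420),
                          emission=Spectrum.boxcar(480, 540))
        exch = ExcitationChannel("led", led_spectrum=Spectrum.boxcar(380, 420),
                                 ex_filter=FilterSpec("bandpass", center_nm=400,
                                                      fwhm_nm=300,
                                                      edge_softness_nm=0.0),
                                 mod_freq_hz=freq_hz)
        det = DetectionChannel("pmt")
        S = build_coupling_tensor([species], [exch], [det])
        cfg = AcquisitionConfig(duration_s=duration_s,
                                excitation_channels=[exch],
                                detection_channels=[det],
                                sim_rate_hz=rate_hz,
                                background={"pmt": background})
        t = cfg.time()
        if conc is None:
            conc = np.ones_like(t)
        kin = ConcentrationTraces(t, {"dye": conc})
        raw = simulate_acquisition(cfg, S, kin, noise or NoiseSpec())
        return raw, S, cfg
    return make
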