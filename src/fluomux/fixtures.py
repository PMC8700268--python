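"""Ready-made experiment configurations.

Each builder returns an :class:`~fluomux.io.ExperimentConfig` describing one
of the acquisition geometries the package models:

``cascade_triple``
    Three-probe recording of a chemoattractant-triggered cascade in sperm
    (Ca via Fura-2 at 380-nm-side excitation, pH via BCECF, voltage via
    RhoVR) on two detectors, LEDs modulated at 30.4/37.3/50 kHz.
``ratiometric_dual_ex``
    Dual-excitation ratiometric Fura-FF + BCECF recording on one detector,
    four frequencies (87.3/73.51/61.7/103.7 kHz).
``uncaging_flash``
    Fluo-4 + pHrodo + BeRST cascade triggered by a 50 ms UV uncaging flash,
    with the flash artifact injected into both detectors.
``bapta_quench``
    Stopped-flow Ca-dissociation kinetics: Ca-loaded indicators mixed with
    excess chelator; fast lock-in (τ = 100 µs) and monoexponential k_off
    fits.  Single-probe variants serve the rate-recovery studies.
``single_cell_fret``
    Single-cell microscopy toy: a cAMP FRET sensor (cerulean/citrine) and
    Calbryte 630 under two modulation frequencies, with the messenger-
    buffering kinetics.

Every builder accepts ``loaded`` to restrict which probes are present (the
excitation and detection geometry never changes), mirroring single- vs
triple-loaded samples.  A flat-spectrum ``ambient`` species provides the
stray-light baseline every real channel shows; its brightness and the shot
noise scale are fixture constants chosen to give realistic baseline
signal-to-noise at τ = 1 ms.
"""

from __future__ import annotations

from .io import ExperimentConfig

#: Relative brightness of the flat-spectrum stray-light term.  Chosen so the
#: stray baseline on a (detector, LED) pair is a few percent of a loaded
#: probe's own-channel signal — the lowered-but-visible baseline off-target
#: channels show on a real instrument.
AMBIENT_BRIGHTNESS = 0.03

#: Default detector noise: shot variance per unit signal and dark SD.
DEFAULT_NOISE = {"shot_scale": 0.02, "dark_sd": 0.05}


def _species(entries, loaded):
    out = [dict(e) for e in entries if loaded is None or e["name"] in loaded]
    out.append({"name": "ambient", "probe": "ambient",
                "brightness": AMBIENT_BRIGHTNESS, "trace": "constant"})
    return out


def cascade_triple(loaded=None, fastm_enabled=True, dose_scale=1.0,
                   duration_s=2.6, sim_rate_hz=1.0e6, seed=0) -> ExperimentConfig:
    """Two-detector, three-frequency cascade recording.

    ``loaded`` restricts the probe set, e.g. ``("bcecf",)`` for the
    single-loaded crosstalk experiments; ``fastm_enabled=False`` drives all
    LEDs at one common frequency (optical filtering alone).
    """
    species = _species([
        {"name": "fura2", "probe": "fura2_free", "brightness": 1.0,
         "trace": "ca", "response_scale": -0.6},
        {"name": "bcecf", "probe": "bcecf_base", "brightness": 1.0,
         "trace": "ph", "response_scale": 1.0},
        {"name": "rhovr", "probe": "rhovr", "brightness": 1.0,
         "trace": "vm", "response_scale": 1.0},
    ], loaded)
    data = {
        "name": "cascade_triple",
        "seed": seed,
        "species": species,
        "excitation": [
            {"name": "led375", "center_nm": 375, "ex_filter": "379/34",
             "mod_freq_hz": 30400.0},
            {"name": "led455", "center_nm": 455, "ex_filter": "438/24",
             "mod_freq_hz": 37300.0},
            {"name": "led490", "center_nm": 490, "ex_filter": "485/20",
             "mod_freq_hz": 50000.0},
        ],
        "detection": [
            {"name": "short", "em_filters": ["524/24"]},
            {"name": "long", "em_filters": ["607/36"]},
        ],
        "channels": [
            {"label": "fura2", "detector": "short", "excitation": "led375"},
            {"label": "bcecf", "detector": "short", "excitation": "led490"},
            {"label": "rhovr", "detector": "long", "excitation": "led455"},
        ],
        "kinetics": {"scenario": "cascade", "params": {"dose_scale": dose_scale}},
        "acquisition": {
            "sim_rate_hz": sim_rate_hz,
            "duration_s": duration_s,
            "fastm_enabled": fastm_enabled,
            "common_mod_freq_hz": None if fastm_enabled else 30400.0,
            "noise": dict(DEFAULT_NOISE),
            "background": {"short": 0.05, "long": 0.05},
        },
        "lockin": {"time_constant_s": 1.0e-3, "order": 3,
                   "output_interval_s": 1.0e-3},
        "analysis": {
            "baseline_points": 10,
            "onsets": ["fura2", "bcecf", "rhovr"],
        },
    }
    # crosstalk is only meaningful for single-loaded samples: with several
    # probes loaded, the channels carry correlated *genuine* responses
    if loaded is not None and len(loaded) == 1:
        source = loaded[0]
        data["analysis"]["crosstalk"] = [
            {"source": source, "target": t, "window_s": 2.0}
            for t in ("fura2", "bcecf", "rhovr") if t != source]
    return ExperimentConfig(data)


def ratiometric_dual_ex(loaded=None, duration_s=2.2, sim_rate_hz=1.0e6,
                        seed=0) -> ExperimentConfig:
    """Dual-excitation Fura-FF + BCECF on one detector, four frequencies."""
    species = _species([
        {"name": "furaff_bound", "probe": "furaff_bound", "brightness": 1.0,
         "trace": "ca", "response_scale": 0.6},
        {"name": "furaff_free", "probe": "furaff_free", "brightness": 0.8,
         "trace": "ca", "response_scale": -0.4},
        {"name": "bcecf_base", "probe": "bcecf_base", "brightness": 1.0,
         "trace": "ph", "response_scale": 0.8},
        {"name": "bcecf_acid", "probe": "bcecf_acid", "brightness": 0.6,
         "trace": "ph", "response_scale": -0.5},
    ], loaded)
    data = {
        "name": "ratiometric_dual_ex",
        "seed": seed,
        "species": species,
        "excitation": [
            {"name": "led340", "center_nm": 340, "ex_filter": "340/22",
             "mod_freq_hz": 87300.0},
            {"name": "led375", "center_nm": 375, "ex_filter": "370/10",
             "mod_freq_hz": 73510.0},
            {"name": "led445", "center_nm": 445, "ex_filter": "445/20",
             "mod_freq_hz": 61700.0},
            {"name": "led490", "center_nm": 490, "ex_filter": "485/20",
             "mod_freq_hz": 103700.0},
        ],
        "detection": [{"name": "green", "em_filters": ["524/24"]}],
        "channels": [
            {"label": "fura_340", "detector": "green", "excitation": "led340"},
            {"label": "fura_370", "detector": "green", "excitation": "led375"},
            {"label": "bcecf_445", "detector": "green", "excitation": "led445"},
            {"label": "bcecf_485", "detector": "green", "excitation": "led490"},
        ],
        "kinetics": {"scenario": "cascade", "params": {"dose_scale": 1.0}},
        "acquisition": {
            "sim_rate_hz": sim_rate_hz,
            "duration_s": duration_s,
            "fastm_enabled": True,
            "noise": dict(DEFAULT_NOISE),
            "background": {"green": 0.05},
        },
        "lockin": {"time_constant_s": 1.0e-3, "order": 3,
                   "output_interval_s": 5.0e-3},
        "analysis": {
            "baseline_points": 10,
            "ratios": [
                {"numerator": "fura_340", "denominator": "fura_370",
                 "label": "fura_ratio"},
                {"numerator": "bcecf_485", "denominator": "bcecf_445",
                 "label": "bcecf_ratio"},
            ],
        },
    }
    return ExperimentConfig(data)


def uncaging_flash(loaded=None, flash_amplitude=30.0, duration_s=1.8,
                   sim_rate_hz=1.0e6, seed=0) -> ExperimentConfig:
    """Flash-uncaging cascade with an unmodulated flash artifact."""
    species = _species([
        {"name": "fluo4", "probe": "fluo4", "brightness": 1.0,
         "trace": "ca", "response_scale": 1.5},
        {"name": "phrodo", "probe": "phrodo", "brightness": 1.0,
         "trace": "ph", "response_scale": -0.8},
        {"name": "berst", "probe": "berst", "brightness": 1.0,
         "trace": "vm", "response_scale": 1.0},
    ], loaded)
    data = {
        "name": "uncaging_flash",
        "seed": seed,
        "species": species,
        "excitation": [
            {"name": "led490", "center_nm": 490, "ex_filter": "494/20",
             "mod_freq_hz": 37300.0},
            {"name": "led565", "center_nm": 565, "ex_filter": "575/19",
             "mod_freq_hz": 30100.0},
            {"name": "led455", "center_nm": 455, "ex_filter": "438/24",
             "mod_freq_hz": 50300.0},
        ],
        "detection": [
            {"name": "short", "em_filters": ["542/20"]},
            {"name": "long", "em_filters": ["593LP"]},
        ],
        "channels": [
            {"label": "fluo4", "detector": "short", "excitation": "led490"},
            {"label": "phrodo", "detector": "long", "excitation": "led565"},
            {"label": "berst", "detector": "long", "excitation": "led455"},
        ],
        "kinetics": {"scenario": "uncaging",
                     "params": {"flash_start_s": 0.3, "flash_dur_s": 0.05}},
        "acquisition": {
            "sim_rate_hz": sim_rate_hz,
            "duration_s": duration_s,
            "fastm_enabled": True,
            "noise": dict(DEFAULT_NOISE),
            "background": {"short": 0.05, "long": 0.05},
        },
        "artifacts": {"flash": {"window": None, "amplitude": flash_amplitude,
                                "detectors": ["short", "long"]}},
        "lockin": {"time_constant_s": 1.0e-3, "order": 3,
                   "output_interval_s": 1.0e-3},
        "analysis": {"baseline_points": 10,
                     "onsets": ["fluo4", "phrodo", "berst"]},
    }
    return ExperimentConfig(data)


def bapta_quench(loaded=None, k_off_per_s=None, duration_s=0.12,
                 sim_rate_hz=1.0e6, seed=0) -> ExperimentConfig:
    """Stopped-flow chelator-quench kinetics with a fast lock-in.

    ``k_off_per_s`` overrides the dissociation rate (default 354 s⁻¹, the
    Fluo-4 class of rates).  Restrict ``loaded`` to one probe for the
    single-rate recovery experiments; each probe keeps its own modulation
    frequency and detector.
    """
    k = 354.0 if k_off_per_s is None else float(k_off_per_s)
    species = _species([
        {"name": "fura2_bound", "probe": "fura2_bound", "brightness": 1.0,
         "trace": "bound", "response_scale": 0.95},
        {"name": "fura2_free", "probe": "fura2_free", "brightness": 0.8,
         "trace": "free", "response_scale": 0.9},
        {"name": "fluo4", "probe": "fluo4", "brightness": 1.0,
         "trace": "bound", "response_scale": 0.95},
        {"name": "calbryte", "probe": "calbryte630", "brightness": 1.0,
         "trace": "bound", "response_scale": 0.95},
    ], loaded)
    data = {
        "name": "bapta_quench",
        "seed": seed,
        "species": species,
        "excitation": [
            {"name": "led340", "center_nm": 340, "ex_filter": "340/22",
             "mod_freq_hz": 87310.0},
            {"name": "led375", "center_nm": 375, "ex_filter": "370/10",
             "mod_freq_hz": 103700.0},
            {"name": "led490", "center_nm": 490, "ex_filter": "485/20",
             "mod_freq_hz": 59510.0},
            {"name": "led565", "center_nm": 565, "ex_filter": "586/20",
             "mod_freq_hz": 47100.0},
        ],
        "detection": [
            {"name": "short", "em_filters": ["524/24"]},
            {"name": "long", "em_filters": ["647/57"]},
        ],
        "channels": [
            {"label": "fura_340", "detector": "short", "excitation": "led340"},
            {"label": "fura_370", "detector": "short", "excitation": "led375"},
            {"label": "fluo4", "detector": "short", "excitation": "led490"},
            {"label": "calbryte", "detector": "long", "excitation": "led565"},
        ],
        "kinetics": {"scenario": "dissociation",
                     "params": {"k_off_per_s": k, "start_s": 0.0}},
        "acquisition": {
            "sim_rate_hz": sim_rate_hz,
            "duration_s": duration_s,
            "fastm_enabled": True,
            "noise": dict(DEFAULT_NOISE),
            "background": {"short": 0.05, "long": 0.05},
        },
        "lockin": {"time_constant_s": 1.0e-4, "order": 3,
                   "output_interval_s": 1.0e-4},
        "analysis": {
            "baseline_points": 10,
            "fits": [{"channel": label, "t_range": [0.004, duration_s]}
                     for label, needs in (("fura_340", "fura2_bound"),
                                          ("fura_370", "fura2_free"),
                                          ("fluo4", "fluo4"),
                                          ("calbryte", "calbryte"))
                     if loaded is None or needs in loaded],
        },
    }
    return ExperimentConfig(data)


def single_cell_fret(sensor_kd_um=0.07, sensor_total_um=10.0, duration_s=20.0,
                     sim_rate_hz=2.5e5, seed=0) -> ExperimentConfig:
    """Single-cell FRET cAMP sensor + Ca probe under two frequencies.

    FRET itself is not modelled; the donor dims and the acceptor brightens
    with sensor occupancy, and the Ca probe follows the downstream channel
    opening of the messenger-buffering toy model.
    """
    species = _species([
        {"name": "cerulean", "probe": "cerulean", "brightness": 1.0,
         "trace": "sensor_occupancy", "response_scale": 0.4},
        {"name": "citrine", "probe": "citrine", "brightness": 0.8,
         "trace": "sensor_occupancy", "response_scale": -0.4},
        {"name": "calbryte", "probe": "calbryte630", "brightness": 1.0,
         "trace": "channel_open", "response_scale": 1.5},
    ], None)
    data = {
        "name": "single_cell_fret",
        "seed": seed,
        "species": species,
        "excitation": [
            {"name": "led455", "center_nm": 455, "ex_filter": "438/24",
             "mod_freq_hz": 36100.0},
            {"name": "led565", "center_nm": 565, "ex_filter": "565/24",
             "mod_freq_hz": 49500.0},
        ],
        "detection": [
            {"name": "donor", "em_filters": ["475/28"]},
            {"name": "acceptor", "em_filters": ["578/105"]},
        ],
        "channels": [
            {"label": "cerulean", "detector": "donor", "excitation": "led455"},
            {"label": "citrine", "detector": "acceptor", "excitation": "led455"},
            {"label": "calbryte", "detector": "acceptor", "excitation": "led565"},
        ],
        "kinetics": {"scenario": "buffered",
                     "params": {"sensor_kd_um": sensor_kd_um,
                                "sensor_total_um": sensor_total_um,
                                "channel_k12_um": 10.0,
                                "production_rate_um_per_s": 1.0,
                                "hill_coefficient": 2.0}},
        "acquisition": {
            "sim_rate_hz": sim_rate_hz,
            "duration_s": duration_s,
            "fastm_enabled": True,
            "noise": dict(DEFAULT_NOISE),
            "background": {"donor": 0.05, "acceptor": 0.05},
        },
        "lockin": {"time_constant_s": 1.0e-2, "order": 3,
                   "output_interval_s": 5.0e-3},
        "analysis": {"baseline_points": 10,
                     "onsets": ["cerulean", "citrine", "calbryte"]},
    }
    return ExperimentConfig(data)


FIXTURES = {
    "cascade_triple": cascade_triple,
    "ratiometric_dual_ex": ratiometric_dual_ex,
    "uncaging_flash": uncaging_flash,
    "bapta_quench": bapta_quench,
    "single_cell_fret": single_cell_fret,
}


def get_fixture(name: str, **kwargs) -> ExperimentConfig:
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    return builder(**kwargs)


def list_fixtures() -> list:
    return sorted(FIXTURES)
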