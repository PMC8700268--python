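"""Experiment configuration, trace serialization, and the pipeline driver.

An experiment is described by a structured YAML document (species, modulated
excitation channels, detectors, logical channel map, kinetic scenario,
acquisition/noise settings, lock-in settings, analysis recipe, seed).
:func:`load_config` validates the whole document and reports *all* problems,
not just the first; unknown keys are rejected for typo safety.

:func:`run_pipeline` executes simulate → inject artifacts → demodulate →
analyze and returns a :class:`ResultBundle` whose content is bit-reproducible
for a fixed (config, seed) pair.  Traces round-trip through TSV files with a
JSON metadata sidecar.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acquisition as acq
from . import analysis as ana
from . import kinetics as kin
from . import lockin as li
from . import optics as opt
from .errors import ConfigurationError, ParameterError

logger = logging.getLogger("fluomux")

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# Trace file round trip
# ---------------------------------------------------------------------------

def write_traces(path, time_s, traces: dict, metadata: dict | None = None) -> Path:
    """Write a trace set as TSV (time_s + one labeled column per channel)
    with a JSON metadata sidecar next to it."""
    path = Path(path)
    labels = list(traces)
    if len(set(labels)) != len(labels):
        raise ParameterError(f"duplicate channel labels: {labels}")
    df = pd.DataFrame({"time_s": np.asarray(time_s, float),
                       **{k: np.asarray(v, float) for k, v in traces.items()}})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(metadata or {}, fh, indent=1, default=_jsonable)
    return path


def read_traces(path):
    """Read a TSV trace file; returns ``(time_s, traces, metadata)``.

    A missing sidecar is a warning (metadata comes back empty); a malformed
    table is a parse error carrying the offending line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise ParameterError(f"malformed trace file {path}: {exc}") from exc
    if "time_s" not in df.columns:
        raise ParameterError(f"{path}: first column must be 'time_s'")
    if any(c.startswith("time_s.") or c.endswith(".1") for c in df.columns):
        raise ParameterError(f"{path}: duplicate channel labels in header")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 2  # header + 1-based
        raise ParameterError(f"{path}: ragged or non-numeric row near line {row}")
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            metadata = json.load(fh)
    else:
        warnings.warn(f"no metadata sidecar next to {path}; metadata is empty")
        metadata = {}
    time_s = df.pop("time_s").to_numpy()
    return time_s, {c: df[c].to_numpy() for c in df.columns}, metadata


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Configuration schema
# ---------------------------------------------------------------------------

_TOP_KEYS = {"name", "seed", "species", "excitation", "detection", "channels",
             "kinetics", "acquisition", "artifacts", "lockin", "analysis"}
_SPECIES_KEYS = {"name", "probe", "brightness", "trace", "response_scale"}
_EXC_KEYS = {"name", "center_nm", "fwhm_nm", "ex_filter", "mod_freq_hz",
             "mod_depth", "intensity", "phase_rad"}
_DET_KEYS = {"name", "em_filters", "gain"}
_CHAN_KEYS = {"label", "detector", "excitation"}
_KIN_KEYS = {"scenario", "params"}
_ACQ_KEYS = {"sim_rate_hz", "duration_s", "fastm_enabled", "common_mod_freq_hz",
             "noise", "background"}
_NOISE_KEYS = {"shot_scale", "dark_sd"}
_ART_KEYS = {"flash", "mixing"}
_FLASH_KEYS = {"window", "amplitude", "detectors", "edge_s"}
_MIX_KEYS = {"stop_time_s", "amplitude", "decay_s"}
_LOCKIN_KEYS = {"time_constant_s", "order", "output_interval_s", "phase_mode",
                "phase_rad", "output_mode", "settle_factor"}
_ANA_KEYS = {"baseline_points", "smoothing_window_s", "crosstalk", "fits",
             "snr_channels", "onsets", "ratios"}
_SCENARIOS = {"cascade", "dissociation", "uncaging", "buffered", "constant"}


def _check_keys(entry, allowed, where, errors):
    if not isinstance(entry, dict):
        errors.append(f"{where}: expected a mapping, got {type(entry).__name__}")
        return
    unknown = set(entry) - allowed
    if unknown:
        errors.append(f"{where}: unknown key(s) {sorted(unknown)}")


def validate_config(data: dict) -> list:
    """Return a list of all validation problems (empty when valid)."""
    errors = []
    _check_keys(data, _TOP_KEYS, "top level", errors)
    if not isinstance(data, dict):
        return errors
    for section in ("species", "excitation", "detection", "channels",
                    "kinetics", "acquisition", "lockin"):
        if section not in data:
            errors.append(f"missing required section {section!r}")
    if errors:
        return errors

    known_probes = set(opt.PROBE_LIBRARY) | {"ambient"}
    sp_names, exc_names, det_names, ch_labels = [], [], [], []
    for i, sp in enumerate(data["species"]):
        _check_keys(sp, _SPECIES_KEYS, f"species[{i}]", errors)
        if isinstance(sp, dict):
            sp_names.append(sp.get("name", sp.get("probe", f"species[{i}]")))
            if sp.get("probe") not in known_probes:
                errors.append(f"species[{i}]: unknown probe {sp.get('probe')!r}")
    for i, ch in enumerate(data["excitation"]):
        _check_keys(ch, _EXC_KEYS, f"excitation[{i}]", errors)
        if isinstance(ch, dict):
            exc_names.append(ch.get("name", f"excitation[{i}]"))
    for i, d in enumerate(data["detection"]):
        _check_keys(d, _DET_KEYS, f"detection[{i}]", errors)
        if isinstance(d, dict):
            det_names.append(d.get("name", f"detection[{i}]"))
    for i, c in enumerate(data["channels"]):
        _check_keys(c, _CHAN_KEYS, f"channels[{i}]", errors)
        if not isinstance(c, dict):
            continue
        ch_labels.append(c.get("label", f"channels[{i}]"))
        if c.get("detector") not in det_names:
            errors.append(f"channels[{i}]: unknown detector {c.get('detector')!r}")
        if c.get("excitation") not in exc_names:
            errors.append(f"channels[{i}]: unknown excitation {c.get('excitation')!r}")
    for label, names in (("species", sp_names), ("excitation", exc_names),
                         ("detection", det_names), ("channel label", ch_labels)):
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            errors.append(f"duplicate {label} name(s): {sorted(dup)}")

    kin_sec = data["kinetics"]
    _check_keys(kin_sec, _KIN_KEYS, "kinetics", errors)
    if isinstance(kin_sec, dict) and kin_sec.get("scenario") not in _SCENARIOS:
        errors.append(f"kinetics.scenario must be one of {sorted(_SCENARIOS)}")

    acq_sec = data["acquisition"]
    _check_keys(acq_sec, _ACQ_KEYS, "acquisition", errors)
    if isinstance(acq_sec, dict):
        if isinstance(acq_sec.get("noise"), dict):
            _check_keys(acq_sec["noise"], _NOISE_KEYS, "acquisition.noise", errors)
        bg = acq_sec.get("background", {})
        if isinstance(bg, dict):
            for name in bg:
                if name not in det_names:
                    errors.append(f"acquisition.background: unknown detector {name!r}")
    _check_keys(data["lockin"], _LOCKIN_KEYS, "lockin", errors)
    if "artifacts" in data:
        _check_keys(data["artifacts"], _ART_KEYS, "artifacts", errors)
        art = data["artifacts"]
        if isinstance(art, dict):
            if "flash" in art:
                _check_keys(art["flash"], _FLASH_KEYS, "artifacts.flash", errors)
            if "mixing" in art:
                _check_keys(art["mixing"], _MIX_KEYS, "artifacts.mixing", errors)
    if "analysis" in data:
        _check_keys(data["analysis"], _ANA_KEYS, "analysis", errors)
        ana_sec = data["analysis"]
        if isinstance(ana_sec, dict):
            for i, pair in enumerate(ana_sec.get("crosstalk") or []):
                for side in ("source", "target"):
                    if pair.get(side) not in ch_labels:
                        errors.append(
                            f"analysis.crosstalk[{i}]: unknown channel {pair.get(side)!r}")
            for i, fit in enumerate(ana_sec.get("fits") or []):
                if fit.get("channel") not in ch_labels:
                    errors.append(f"analysis.fits[{i}]: unknown channel "
                                  f"{fit.get('channel')!r}")
            for i, rat in enumerate(ana_sec.get("ratios") or []):
                for side in ("numerator", "denominator"):
                    if rat.get(side) not in ch_labels:
                        errors.append(
                            f"analysis.ratios[{i}]: unknown channel {rat.get(side)!r}")
    return errors


@dataclass(frozen=True)
class ExperimentConfig:
    """A fully validated experiment description.

    Thin immutable wrapper over the canonical configuration mapping; builder
    methods produce the concrete optics/kinetics/acquisition objects.
    """

    data: dict

    def __post_init__(self):
        errors = validate_config(self.data)
        if errors:
            raise ConfigurationError(errors)

    # -- identity ----------------------------------------------------------
    @property
    def name(self) -> str:
        return self.data.get("name", "unnamed")

    @property
    def seed(self) -> int:
        return int(self.data.get("seed", 0))

    def canonical(self) -> dict:
        return json.loads(json.dumps(self.data, sort_keys=True, default=_jsonable))

    def hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    # -- builders ----------------------------------------------------------
    def species(self) -> list:
        out = []
        for sp in self.data["species"]:
            out.append(opt.get_probe(sp["probe"], brightness=sp.get("brightness")))
        # species carry their config name, which may differ from the library key
        return [opt.Species(cfg["name"], s.excitation, s.emission, s.brightness,
                            s.allow_anti_stokes)
                for cfg, s in zip(self.data["species"], out)]

    def excitation_channels(self) -> list:
        return [opt.led_channel(ch["name"], ch["center_nm"], ch["mod_freq_hz"],
                                ch["ex_filter"], fwhm_nm=ch.get("fwhm_nm", 25.0),
                                mod_depth=ch.get("mod_depth", 1.0),
                                intensity=ch.get("intensity", 1.0),
                                phase_rad=ch.get("phase_rad", 0.0))
                for ch in self.data["excitation"]]

    def detection_channels(self) -> list:
        return [opt.detector(d["name"], d["em_filters"], gain=d.get("gain", 1.0))
                for d in self.data["detection"]]

    def coupling_tensor(self) -> opt.CouplingTensor:
        return opt.build_coupling_tensor(self.species(), self.excitation_channels(),
                                         self.detection_channels())

    def channel_map(self) -> list:
        freq = {ch["name"]: ch["mod_freq_hz"] for ch in self.data["excitation"]}
        acq_sec = self.data["acquisition"]
        if not acq_sec.get("fastm_enabled", True):
            common = acq_sec.get("common_mod_freq_hz",
                                 self.data["excitation"][0]["mod_freq_hz"])
            freq = {name: common for name in freq}
        return [(c["detector"], float(freq[c["excitation"]]), c["label"])
                for c in self.data["channels"]]

    def acquisition_config(self) -> acq.AcquisitionConfig:
        a = self.data["acquisition"]
        return acq.AcquisitionConfig(
            duration_s=a["duration_s"],
            excitation_channels=self.excitation_channels(),
            detection_channels=self.detection_channels(),
            sim_rate_hz=a.get("sim_rate_hz", 1.0e6),
            fastm_enabled=a.get("fastm_enabled", True),
            common_mod_freq_hz=a.get("common_mod_freq_hz"),
            background=dict(a.get("background", {})))

    def noise_spec(self, seed: int) -> acq.NoiseSpec:
        n = self.data["acquisition"].get("noise", {}) or {}
        return acq.NoiseSpec(shot_scale=n.get("shot_scale", 0.0),
                             dark_sd=n.get("dark_sd", 0.0), seed=seed)

    def lockin_config(self) -> li.LockInConfig:
        l = self.data["lockin"]
        return li.LockInConfig(time_constant_s=l["time_constant_s"],
                               output_interval_s=l["output_interval_s"],
                               order=l.get("order", 3),
                               phase_mode=l.get("phase_mode", "auto"),
                               phase_rad=l.get("phase_rad", 0.0),
                               output_mode=l.get("output_mode", "in_phase"),
                               settle_factor=l.get("settle_factor", 10.0))

    def kinetic_traces(self, time_s) -> tuple:
        """Scenario traces and the flash window (None unless uncaging)."""
        sec = self.data["kinetics"]
        params = dict(sec.get("params") or {})
        scenario = sec["scenario"]
        flash_window = None
        if scenario == "cascade":
            traces = kin.resact_cascade_fixture(
                time_s, dose_scale=params.get("dose_scale", 1.0))
        elif scenario == "dissociation":
            model = kin.DissociationModel(
                k_off_per_s=params["k_off_per_s"],
                bound_fraction_initial=params.get("bound_fraction_initial", 1.0))
            traces = kin.dissociation_traces(model, time_s,
                                             start_s=params.get("start_s", 0.0))
        elif scenario == "uncaging":
            traces, flash_window = kin.uncaging_step_fixture(
                params.get("flash_start_s", 0.1), params.get("flash_dur_s", 0.05),
                time_s, dose_scale=params.get("dose_scale", 1.0))
        elif scenario == "buffered":
            traces = kin.buffered_messenger_fixture(
                sensor_kd_um=params.get("sensor_kd_um", 0.07),
                sensor_total_um=params.get("sensor_total_um", 10.0),
                channel_k12_um=params.get("channel_k12_um", 10.0),
                production_rate_um_per_s=params.get("production_rate_um_per_s", 1.0),
                time_s=time_s,
                hill_coefficient=params.get("hill_coefficient", 2.0))
        else:  # constant
            t = np.asarray(time_s, float)
            traces = kin.ConcentrationTraces(t, {"constant": np.ones_like(t)})
        return traces, flash_window

    def species_concentrations(self, time_s) -> tuple:
        """Map scenario traces onto species: c = max(1 + scale·Δtrace, 0).

        Δtrace is the trace's departure from its initial value, so every
        species starts at relative concentration 1 regardless of scenario.
        Species bound to the ``constant`` trace (e.g. ambient light) stay
        flat.  Returns (ConcentrationTraces keyed by species, flash window).
        """
        traces, flash_window = self.kinetic_traces(time_s)
        t = np.asarray(time_s, float)
        out = {}
        for sp in self.data["species"]:
            ref = sp.get("trace", "constant")
            scale = sp.get("response_scale", 1.0)
            if ref == "constant":
                out[sp["name"]] = np.ones_like(t)
                continue
            if ref not in traces.traces:
                raise ConfigurationError(
                    f"species {sp['name']!r} references kinetic trace {ref!r}; "
                    f"scenario provides {list(traces.traces)}")
            tr = traces[ref]
            out[sp["name"]] = np.clip(1.0 + scale * (tr - tr[0]), 0.0, None)
        return kin.ConcentrationTraces(t, out), flash_window

    def frequency_plan(self) -> opt.FrequencyPlan:
        lc = self.lockin_config()
        a = self.data["acquisition"]
        freqs = {f for _, f, _ in self.channel_map()}
        return opt.plan_frequencies(sorted(freqs), lc.time_constant_s, lc.order,
                                    a.get("sim_rate_hz", 1.0e6))


def loads_config(data: dict) -> ExperimentConfig:
    return ExperimentConfig(data)


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ExperimentConfig(data)


def dump_config(config: ExperimentConfig, path=None) -> str:
    text = yaml.safe_dump(config.canonical(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResultBundle:
    """All outputs of one pipeline run, reproducible from (config, seed)."""

    config_hash: str
    seed: int
    version: str
    results: dict
    demodulated: li.DemodulatedTraceSet | None = None
    raw: acq.RawTraceSet | None = None
    processed: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"config_hash": self.config_hash, "seed": self.seed,
                           "version": self.version, "results": self.results},
                          indent=1, sort_keys=True, default=_jsonable)


def _stage_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage substream below 2**31."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_pipeline(config: ExperimentConfig, seed: int | None = None,
                 keep_raw: bool = False) -> ResultBundle:
    """Execute simulate → artifacts → demodulate → analyze for one config."""
    t_start = _time.perf_counter()
    root_seed = config.seed if seed is None else int(seed)
    plan = config.frequency_plan()
    logger.info("pipeline %s: seed=%d hash=%s", config.name, root_seed,
                config.hash()[:12])
    logger.info("frequency plan: %s (noise bandwidth %.1f Hz, worst leakage %.2e)",
                "ok" if plan.ok else f"issues: {plan.issues}",
                plan.noise_bandwidth_hz, plan.worst_leakage)
    lc = config.lockin_config()
    logger.info("lock-in: tau=%g s, order=%d, output interval %g s",
                lc.time_constant_s, lc.order, lc.output_interval_s)

    # --- simulate ---------------------------------------------------------
    acq_cfg = config.acquisition_config()
    tensor = config.coupling_tensor()
    sim_time = acq_cfg.time()
    conc, flash_window = config.species_concentrations(sim_time)
    noise = config.noise_spec(_stage_seed(root_seed, "acquisition"))
    raw = acq.simulate_acquisition(acq_cfg, tensor, conc, noise)

    # --- artifacts --------------------------------------------------------
    artifacts = config.data.get("artifacts", {}) or {}
    if "flash" in artifacts:
        spec = dict(artifacts["flash"])
        window = tuple(spec.get("window") or flash_window)
        raw = acq.inject_flash_artifact(raw, window, spec["amplitude"],
                                       detectors=spec.get("detectors"),
                                       edge_s=spec.get("edge_s", 1.0e-3))
    if "mixing" in artifacts:
        spec = artifacts["mixing"]
        raw = acq.inject_mixing_artifact(raw, spec["stop_time_s"], spec["amplitude"],
                                        spec["decay_s"])

    # --- demodulate -------------------------------------------------------
    demod = li.demodulate(raw, [], lc, channel_map=config.channel_map())

    # --- analyze ----------------------------------------------------------
    ana_sec = config.data.get("analysis", {}) or {}
    crop_until = max((a["crop_until_s"] for a in raw.metadata.get("mixing_artifacts", [])),
                     default=-np.inf)
    valid_mask = demod.settling_mask | (demod.time_s < crop_until)
    results = {"frequency_plan": {"ok": plan.ok, "issues": list(plan.issues),
                                  "noise_bandwidth_hz": plan.noise_bandwidth_hz,
                                  "worst_leakage": plan.worst_leakage}}
    processed = {}
    n_base = ana_sec.get("baseline_points", 10)
    baselines = {}
    for label in demod.labels:
        try:
            bw = ana.default_baseline_window(demod.time_s, valid_mask, n_points=n_base)
            processed[label] = ana.dff0(demod.time_s, demod[label], bw,
                                        settling_mask=valid_mask,
                                        provenance=(label,))
            baselines[label] = bw
        except ParameterError as exc:
            raise ConfigurationError([f"analysis stage, channel {label!r}: {exc}"])

    smooth = ana_sec.get("smoothing_window_s")
    if smooth:
        dt_out = float(demod.time_s[1] - demod.time_s[0])
        for label, tr in processed.items():
            processed[label] = tr.derive(
                ana.sliding_average(tr.values, window_s=smooth, dt_s=dt_out),
                note=f"smoothed_{smooth}s")

    xt_out = []
    for pair in ana_sec.get("crosstalk") or []:
        window = pair.get("window_s", 2.0)
        src = processed[pair["source"]]
        t_ok = src.time_s[~valid_mask]
        w0 = float(t_ok[0])
        res = ana.crosstalk(src.values[~valid_mask],
                            processed[pair["target"]].values[~valid_mask],
                            time_s=t_ok, window_s=(w0, w0 + float(window)))
        xt_out.append({"source": pair["source"], "target": pair["target"],
                       "percent": res.percent, "slope_se": res.slope_se,
                       "n_points": res.n_points})
    if xt_out:
        results["crosstalk"] = xt_out

    fits_out = []
    for fit in ana_sec.get("fits") or []:
        label = fit["channel"]
        t_range = fit.get("t_range")
        res = ana.fit_monoexponential(demod.time_s, demod[label],
                                      t_range_s=t_range, settling_mask=valid_mask)
        fits_out.append({"channel": label, "k_per_s": res.k_per_s, "k_se": res.k_se,
                         "amplitude": res.amplitude, "offset": res.offset,
                         "residual_rms": res.residual_rms, "n_points": res.n_points})
    if fits_out:
        results["fits"] = fits_out

    snr_out = {}
    for label in ana_sec.get("snr_channels") or []:
        start = int(np.nonzero(~valid_mask)[0][0])
        snr_out[label] = ana.snr(demod[label], window_points=min(
            200, int(np.count_nonzero(~valid_mask))), start=start)
    if snr_out:
        results["snr"] = snr_out

    onsets_out = {}
    for label in ana_sec.get("onsets") or []:
        res = ana.detect_onset(processed[label].time_s, processed[label].values,
                               baselines[label])
        onsets_out[label] = res.latency_s
    if onsets_out:
        results["onset_latency_s"] = onsets_out

    ratios_out = []
    for rat in ana_sec.get("ratios") or []:
        num, den = rat["numerator"], rat["denominator"]
        bw = baselines[num]
        tr = ana.ratio_trace(demod.time_s, demod[num], demod[den], bw,
                             provenance=(num, den))
        label = rat.get("label", f"{num}/{den}")
        processed[label] = tr
        ratios_out.append(label)
    if ratios_out:
        results["ratio_channels"] = ratios_out

    logger.info("pipeline %s finished in %.2f s", config.name,
                _time.perf_counter() - t_start)
    return ResultBundle(config_hash=config.hash(), seed=root_seed,
                        version=__version__, results=results,
                        demodulated=demod, raw=raw if keep_raw else None,
                        processed=processed)
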