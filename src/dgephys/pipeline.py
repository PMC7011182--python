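"""Config-driven orchestration: simulate -> detect -> classify -> metrics.

A run is described by one mapping (typically a YAML file) with a global seed,
a stage list, and one parameter block per stage whose defaults mirror the
analysis constants used throughout the package (250 Hz detection band, 500 Hz
noise band, 4 SD threshold, 12 ms response window, 2000 shuffles, alpha 0.05).
Given the same config the pipeline writes byte-identical outputs.
"""

from __future__ import annotations

import json
from copy import deepcopy
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dgephys.core import StimulusProtocol, SweepSet, read_sweepset, write_sweepset
from dgephys.events import EventTable, detect_events
from dgephys.psc import normalize_train, psc_kinetics, pulse_charges
from dgephys.responsive import classify_responsive, split_evoked, success_record
from dgephys.simulate import PSCShape, SynapseModel, simulate_sweepset

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline", "load_config"]

KNOWN_STAGES = ("simulate", "detect", "classify", "metrics")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(KNOWN_STAGES),
    "simulate": {
        "n_sweeps": 20,
        "rate_hz": 20000.0,
        "duration_ms": None,
        "protocol": {
            "onsets_ms": [100.0],
            "width_ms": 0.2,
            "modality": "laser",
            "train_rate_hz": None,
        },
        "synapse": {
            "amplitude_pa": 50.0,
            "tau_rise_ms": 1.0,
            "tau_decay_ms": 10.0,
            "polarity": -1,
            "failure_prob": 0.2,
            "latency_mean_ms": 2.0,
            "latency_jitter_sd_ms": 0.3,
            "train_scale": [1.0],
            "spont_rate_hz": 0.5,
            "noise_sd_pa": 2.0,
        },
    },
    "detect": {
        "polarity": -1,
        "k_sd": 4.0,
        "low_cutoff_hz": 250.0,
        "noise_cutoff_hz": 500.0,
        "refractory_ms": 2.0,
    },
    "classify": {"window_ms": 12.0, "n_shuffles": 2000, "alpha": 0.05},
    "metrics": {"psc_class": "IPSC", "direction": "IN_to_GC"},
}


def load_config(path: str | Path) -> dict:
    """Load a YAML config, filling unspecified fields from the defaults."""
    with open(path) as f:
        user = yaml.safe_load(f) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    cfg = deepcopy(DEFAULT_CONFIG)

    def _merge(dst: dict, src: dict) -> None:
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                _merge(dst[k], v)
            else:
                dst[k] = v

    _merge(cfg, user)
    return cfg


def validate_config(config: dict) -> list[str]:
    """Return a list of violations (empty iff the config is valid)."""
    errors: list[str] = []
    stages = config.get("stages", [])
    for s in stages:
        if s not in KNOWN_STAGES:
            errors.append(f"stages: unknown stage {s!r}")
    seed = config.get("seed")
    if not isinstance(seed, (int, np.integer)) or isinstance(seed, bool):
        errors.append("seed: must be an integer")
    sim = config.get("simulate", {})
    syn = sim.get("synapse", {})
    if not 0.0 <= syn.get("failure_prob", 0.0) <= 1.0:
        errors.append("simulate.synapse.failure_prob: must lie in [0, 1]")
    if syn.get("amplitude_pa", 1.0) <= 0:
        errors.append("simulate.synapse.amplitude_pa: must be positive")
    if not 0 < syn.get("tau_rise_ms", 1.0) < syn.get("tau_decay_ms", 10.0):
        errors.append("simulate.synapse: need 0 < tau_rise_ms < tau_decay_ms")
    if sim.get("n_sweeps", 1) < 1:
        errors.append("simulate.n_sweeps: must be >= 1")
    det = config.get("detect", {})
    if det.get("k_sd", 4.0) <= 0:
        errors.append("detect.k_sd: must be positive")
    if det.get("low_cutoff_hz", 250.0) <= 0:
        errors.append("detect.low_cutoff_hz: must be positive")
    cls = config.get("classify", {})
    if cls.get("window_ms", 12.0) <= 0:
        errors.append("classify.window_ms: must be positive")
    if cls.get("n_shuffles", 2000) < 1:
        errors.append("classify.n_shuffles: must be >= 1")
    if not 0.0 < cls.get("alpha", 0.05) < 1.0:
        errors.append("classify.alpha: must lie in (0, 1)")
    met = config.get("metrics", {})
    if met.get("psc_class", "IPSC") not in ("IPSC", "EPSC"):
        errors.append("metrics.psc_class: must be IPSC or EPSC")
    if met.get("direction", "IN_to_GC") not in ("IN_to_GC", "GC_to_IN"):
        errors.append("metrics.direction: must be IN_to_GC or GC_to_IN")
    return errors


_FLOAT_FMT = "%.6f"


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the configured stages, writing one artifact per stage.

    Artifacts (all plain text except the HDF5 sweep container):
    ``sweeps.h5`` + ``ground_truth.csv`` (simulate), ``events.csv``
    (detect), ``responsiveness.csv`` (classify), ``kinetics.csv`` and, for
    train protocols, ``train_charges.csv`` (metrics), plus ``manifest.json``
    echoing every parameter and the seed.  Returns the in-memory results.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config["stages"]
    seed = int(config["seed"])
    results: dict = {"config": deepcopy(config)}

    sweepset: SweepSet | None = None
    truth = None
    if "simulate" in stages:
        sweepset, truth = _stage_simulate(config, seed, out)
        results["ground_truth"] = truth
    elif any(s in stages for s in ("detect", "classify", "metrics")):
        sweepset = read_sweepset(out / "sweeps.h5")
    results["sweepset"] = sweepset

    table: EventTable | None = None
    if "detect" in stages:
        table = _stage_detect(config, sweepset, out)
        results["events"] = table

    if "classify" in stages:
        cls_cfg = config["classify"]
        res = classify_responsive(
            table,
            sweepset.protocol,
            sweep_duration_ms=sweepset.duration_ms,
            n_sweeps=sweepset.n_sweeps,
            window_ms=cls_cfg["window_ms"],
            n_shuffles=cls_cfg["n_shuffles"],
            alpha=cls_cfg["alpha"],
            seed=seed,
        )
        table = split_evoked(
            table, sweepset.protocol, cls_cfg["window_ms"], responsive=res.responsive
        )
        results["responsiveness"] = res
        results["events"] = table
        pd.DataFrame(
            [
                {
                    "observed": res.observed_in_window,
                    "p_value": res.p_value,
                    "responsive": res.responsive,
                    "n_shuffles": res.n_shuffles,
                    "window_ms": res.window_ms,
                    "seed": seed,
                }
            ]
        ).to_csv(out / "responsiveness.csv", index=False, float_format=_FLOAT_FMT)
        table.to_frame().to_csv(out / "events.csv", index=False, float_format=_FLOAT_FMT)

    if "metrics" in stages:
        results["metrics"] = _stage_metrics(config, sweepset, table, out)

    manifest = {"seed": seed, "stages": list(stages), "parameters": deepcopy(config)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return results


def _stage_simulate(config: dict, seed: int, out: Path):
    sim = config["simulate"]
    proto_cfg = sim["protocol"]
    protocol = StimulusProtocol(
        onsets_ms=np.asarray(proto_cfg["onsets_ms"], dtype=float),
        width_ms=proto_cfg["width_ms"],
        modality=proto_cfg["modality"],
        train_rate_hz=proto_cfg.get("train_rate_hz"),
    )
    syn = sim["synapse"]
    shape = PSCShape(
        amplitude_pa=syn["amplitude_pa"],
        tau_rise_ms=syn["tau_rise_ms"],
        tau_decay_ms=syn["tau_decay_ms"],
        polarity=syn["polarity"],
    )
    model = SynapseModel(
        shape=shape,
        failure_prob=syn["failure_prob"],
        latency_mean_ms=syn["latency_mean_ms"],
        latency_jitter_sd_ms=syn["latency_jitter_sd_ms"],
        train_scale=tuple(syn["train_scale"]),
        spont_rate_hz=syn["spont_rate_hz"],
        noise_sd_pa=syn["noise_sd_pa"],
    )
    sweepset, truth = simulate_sweepset(
        model,
        protocol,
        n_sweeps=sim["n_sweeps"],
        seed=seed,
        duration_ms=sim.get("duration_ms"),
        rate_hz=sim["rate_hz"],
    )
    write_sweepset(sweepset, out / "sweeps.h5", format="hdf5")
    pd.DataFrame(
        {
            "sweep": [e.sweep_index for e in truth.events],
            "onset_ms": [e.onset_ms for e in truth.events],
            "amplitude_pa": [e.amplitude_pa for e in truth.events],
            "label": [e.label for e in truth.events],
        }
    ).to_csv(out / "ground_truth.csv", index=False, float_format=_FLOAT_FMT)
    return sweepset, truth


def _stage_detect(config: dict, sweepset: SweepSet, out: Path) -> EventTable:
    det = config["detect"]
    table = EventTable(params={})
    for i, tr in enumerate(sweepset.sweeps):
        t = detect_events(
            tr,
            polarity=det["polarity"],
            k_sd=det["k_sd"],
            low_cutoff_hz=det["low_cutoff_hz"],
            noise_cutoff_hz=det["noise_cutoff_hz"],
            refractory_ms=det["refractory_ms"],
            sweep_index=i,
        )
        table.extend(t.events)
        table.params = t.params
    table.to_frame().to_csv(out / "events.csv", index=False, float_format=_FLOAT_FMT)
    return table


def _stage_metrics(config: dict, sweepset: SweepSet, table: EventTable, out: Path) -> dict:
    met = config["metrics"]
    protocol = sweepset.protocol
    rec = success_record(table, protocol, sweepset.n_sweeps)
    # mean trace over success sweeps (sweeps with >= 1 evoked event)
    success_sweeps = sorted(
        {e.sweep_index for e in table.events if e.label == "evoked"}
    )
    metrics: dict = {"success_probability": rec.success_probability}
    if success_sweeps:
        mean = sweepset.mean_trace(success_sweeps)
        stim = float(protocol.onsets_ms[0])
        pre = mean.samples[mean.times_ms < stim]
        baseline = float(np.median(pre)) if pre.size else 0.0
        sel = mean.times_ms >= stim
        from dgephys.core import Trace

        seg = Trace(
            samples=mean.samples[sel] - baseline,
            sampling_rate=mean.sampling_rate,
            kind="voltage_clamped_current",
            t0=0.0,
        )
        kin = psc_kinetics(seg, met["psc_class"], rec)
        metrics["kinetics"] = kin
        pd.DataFrame(
            [
                {
                    "amplitude_pa": kin.amplitude_pa,
                    "mean_success_amplitude_pa": kin.mean_success_amplitude_pa,
                    "success_probability": kin.success_probability,
                    "rise_ms": kin.rise_ms,
                    "decay_ms": kin.decay_ms,
                    "half_width_ms": kin.half_width_ms,
                    "onset_latency_ms": kin.onset_latency_ms,
                }
            ]
        ).to_csv(out / "kinetics.csv", index=False, float_format=_FLOAT_FMT)
    if protocol.n_pulses >= 2:
        mean = sweepset.mean_trace(success_sweeps or None)
        tr_resp = normalize_train(pulse_charges(mean, protocol), met["direction"])
        metrics["train"] = tr_resp
        pd.DataFrame(
            {
                "pulse": np.arange(1, tr_resp.n_pulses + 1),
                "charge_pa_ms": tr_resp.charges_pa_ms,
                "ratio": tr_resp.ratios,
            }
        ).to_csv(out / "train_charges.csv", index=False, float_format=_FLOAT_FMT)
    return metrics
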