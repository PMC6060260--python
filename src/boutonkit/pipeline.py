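"""End-to-end pipeline: stack -> bleach-corrected F/F0 -> ROIs ->
responder labels -> kinetics, with a reproducibility manifest.

A run is fully described by one structured config (YAML) plus a seed:
identical config + seed produce byte-identical outputs, recorded as
SHA-256 checksums in ``manifest.json``. Inputs are either a TIFF +
metadata sidecar or a synthetic acquisition generated on the fly.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import io as bio
from .classify import build_raster, classify_responders
from .core import BoutonkitError, ParameterError, StimulusProtocol, Trace
from .kinetics import summarize_kinetics
from .preprocess import (
    BleachModel,
    compute_f_over_f0,
    correct_bleach,
    fit_bleach_model,
    subtract_background,
)
from .segmentation import (
    SegmentationParams,
    detect_puncta,
    extract_traces,
    pick_background_rois,
    temporal_average,
)
from .simulate import (
    DEFAULT_FRAME_INTERVAL_S,
    NoiseModel,
    random_bouton_field,
    simulate_bleach_control,
    simulate_movie,
)

__all__ = ["default_config", "load_config", "save_config", "run_pipeline"]


# double-exponential bleach of the no-stimulus controls
DEFAULT_BLEACH = {"a1": 0.6, "tau1_s": 5.0, "a2": 0.4, "tau2_s": 50.0,
                  "c": 0.0}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "input": {"tiff": None, "meta": None},   # None -> synthetic run
    "synthetic": {
        "n_boutons": 40,
        "responder_fraction": 0.3,
        "frame_shape": [64, 256],
        "n_frames": 120,
        "frame_interval_s": DEFAULT_FRAME_INTERVAL_S,
        "onset_time_s": 2.0,
        "n_stimuli": 10,
        "frequency_hz": 20.0,
        "intensity_v": 20.0,
        "amp_per_stim": 0.1,
        "tau_decay_s": 0.5,
        "saturation_cap": 2.0,
        "green_rest": 100.0,
        "red_level": 100.0,
        "psf_sigma_px": 1.5,
        "min_spacing_px": 8.0,
        "noise": {"photon_gain": 1.0, "read_sigma": 2.0,
                  "background_level": 20.0, "background_smoothness_px": 8.0},
        "bleach": dict(DEFAULT_BLEACH),
        # bleach controls span ~50 s so the slow time constant is
        # identifiable from the record
        "control_frames": 200,
        "control_frame_interval_s": 0.25,
    },
    "segmentation": {"k_sd": 3.0, "min_area_px": 2, "max_area_px": 100,
                     "connectivity": 8, "background_offset_px": 5},
    "classification": {"stim_window_s": 2.0, "min_response": None},
    "kinetics": {"auc_duration_s": 2.0, "slope_points": 3},
    "output": {"dir": "boutonkit_out", "raster_sort": "peak"},
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path) -> dict:
    """Read a YAML config, filling unset parameters with defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def save_config(config: dict, path) -> None:
    """Canonical YAML serialization (sorted keys; byte-stable round trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _acquire(config: dict, seed: int):
    """Return (stack, control_stack, truth-or-None) per the config."""
    inp = config["input"]
    if inp.get("tiff"):
        stack = bio.read_stack(inp["tiff"], inp["meta"])
        control = None
        if inp.get("control_tiff"):
            control = bio.read_stack(inp["control_tiff"],
                                     inp.get("control_meta", inp["meta"]))
        return stack, control, None
    syn = config["synthetic"]
    stim = StimulusProtocol(onset_time_s=syn["onset_time_s"],
                            n_stimuli=syn["n_stimuli"],
                            frequency_hz=syn["frequency_hz"],
                            intensity_v=syn["intensity_v"])
    noise = NoiseModel(**syn["noise"])
    bleach = BleachModel(**syn["bleach"])
    boutons = random_bouton_field(
        syn["n_boutons"], tuple(syn["frame_shape"]),
        responder_fraction=syn["responder_fraction"],
        min_spacing_px=syn["min_spacing_px"], seed=seed,
        psf_sigma_px=syn["psf_sigma_px"], green_rest=syn["green_rest"],
        red_level=syn["red_level"], amp_per_stim=syn["amp_per_stim"],
        tau_decay_s=syn["tau_decay_s"], saturation_cap=syn["saturation_cap"])
    shape = (syn["n_frames"],) + tuple(syn["frame_shape"])
    stack, truth = simulate_movie(boutons, stim, noise, bleach, shape,
                                  syn["frame_interval_s"], seed=seed)
    control = simulate_bleach_control(
        noise, bleach, (syn["control_frames"],) + tuple(syn["frame_shape"]),
        syn["control_frame_interval_s"], seed=seed + 1)
    return stack, control, truth


def run_pipeline(config: dict, seed: Optional[int] = None) -> dict:
    """Execute the full analysis and write all artifacts.

    Returns a summary dict (counts, responder proportion, manifest
    path). Stage errors propagate as :class:`BoutonkitError` subclasses
    annotated with the failing stage.
    """
    config = _merge(DEFAULT_CONFIG, config)
    if seed is not None:
        config["seed"] = int(seed)
    seed = int(config["seed"])
    out_dir = Path(config["output"]["dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "acquire"
    try:
        stack, control, truth = _acquire(config, seed)

        stage = "bleach"
        if control is not None:
            ctrl_trace = Trace(times_s=control.times_s(),
                               values=control.green.mean(axis=(1, 2)),
                               stage="raw")
            bleach_model = fit_bleach_model(ctrl_trace)
        else:
            bleach_model = BleachModel.identity()

        stage = "segmentation"
        seg_cfg = config["segmentation"]
        params = SegmentationParams(
            k_sd=seg_cfg["k_sd"], min_area_px=seg_cfg["min_area_px"],
            max_area_px=seg_cfg["max_area_px"],
            connectivity=seg_cfg["connectivity"])
        avg = temporal_average(stack.green)
        puncta = detect_puncta(avg, params)
        bg_rois, skipped = pick_background_rois(
            puncta, stack.frame_shape,
            offset_px=seg_cfg["background_offset_px"], seed=seed)

        stage = "traces"
        raw_traces = extract_traces(stack.green, puncta,
                                    stack.frame_interval_s)
        bg_traces = extract_traces(stack.green, bg_rois,
                                   stack.frame_interval_s)
        bg_by_id = {tr.roi_id: tr for tr in bg_traces}

        stage = "normalize"
        onset = (stack.stim.onset_time_s if stack.stim is not None
                 else config["synthetic"]["onset_time_s"])
        norm_traces: List[Trace] = []
        for tr in raw_traces:
            corrected = correct_bleach(tr, bleach_model)
            bg = bg_by_id.get(f"bg_{tr.roi_id}")
            if bg is not None:
                bg_corr = correct_bleach(bg, bleach_model)
                corrected = subtract_background(corrected,
                                                float(bg_corr.values.mean()))
            norm_traces.append(compute_f_over_f0(corrected, onset))

        stage = "classification"
        cls_cfg = config["classification"]
        if norm_traces:
            result = classify_responders(norm_traces, stim_onset_s=0.0,
                                         stim_window_s=cls_cfg["stim_window_s"],
                                         min_response=cls_cfg["min_response"])
            labels = result.labels
            proportion = result.proportion
        else:
            labels = np.zeros(0, dtype=bool)
            proportion = 0.0
            result = None

        stage = "kinetics"
        kin_cfg = config["kinetics"]
        kin_rows = []
        for tr, is_resp in zip(norm_traces, labels):
            if not is_resp:
                continue
            summ = summarize_kinetics(tr, stim_onset_s=0.0,
                                      auc_duration_s=kin_cfg["auc_duration_s"],
                                      slope_points=kin_cfg["slope_points"])
            kin_rows.append({"roi_id": tr.roi_id, "peak": summ.peak,
                             "time_to_peak_s": summ.time_to_peak_s,
                             "initial_slope_per_s": summ.initial_slope_per_s,
                             "fast_tau_s": summ.fast_tau_s,
                             "auc": summ.auc})

        stage = "outputs"
        bio.write_rois(list(puncta) + list(bg_rois),
                       out_dir / "rois.csv", out_dir / "rois.json")
        bio.write_traces(raw_traces, out_dir / "traces_raw.csv")
        bio.write_traces(norm_traces, out_dir / "traces_ff0.csv")
        with open(out_dir / "bleach_model.json", "w") as fh:
            json.dump(bleach_model.to_dict(), fh, sort_keys=True)
        with open(out_dir / "labels.csv", "w") as fh:
            fh.write("roi_id,responder\n")
            for tr, lab in zip(norm_traces, labels):
                fh.write(f"{tr.roi_id},{int(lab)}\n")
        with open(out_dir / "kinetics.csv", "w") as fh:
            cols = ["roi_id", "peak", "time_to_peak_s",
                    "initial_slope_per_s", "fast_tau_s", "auc"]
            fh.write(",".join(cols) + "\n")
            for row in kin_rows:
                fh.write(",".join("" if row[c] is None else
                                  (row[c] if isinstance(row[c], str)
                                   else repr(float(row[c])))
                                  for c in cols) + "\n")
        if norm_traces:
            raster = build_raster(norm_traces,
                                  sort_by=config["output"]["raster_sort"])
            np.savetxt(out_dir / "raster.csv", raster, delimiter=",")

        save_config(config, out_dir / "config.yaml")
        artifact_names = sorted(p.name for p in out_dir.iterdir()
                                if p.name != "manifest.json")
        manifest = {
            "seed": seed,
            "config": config,
            "skipped_background_rois": skipped,
            "checksums": {name: _sha256(out_dir / name)
                          for name in artifact_names},
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, sort_keys=True, indent=1)
    except BoutonkitError as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    summary: Dict = {
        "n_rois": len(puncta),
        "n_background_rois": len(bg_rois),
        "n_responders": int(labels.sum()),
        "proportion": float(proportion),
        "manifest": str(out_dir / "manifest.json"),
    }
    if truth is not None:
        summary["true_proportion"] = (float(truth.responder_labels.mean())
                                      if truth.boutons else 0.0)
    return summary
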