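"""Readers and writers for stacks, traces, ROIs and acquisition metadata.

Stacks travel as multi-page 16-bit grayscale TIFF with frames alternating
between the two excitation channels, accompanied by a YAML sidecar that
declares the frame interval, the interleave order and the stimulus
protocol. Traces and ROI summaries are plain long-format CSV; ROI pixel
sets and simulation ground truth are JSON.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import tifffile
import yaml

from .core import (
    MalformedInputError,
    MetadataError,
    ParameterError,
    Roi,
    ShapeError,
    StimulusProtocol,
    Trace,
    TwoChannelStack,
)

__all__ = [
    "deinterleave",
    "interleave",
    "read_stack",
    "write_stack",
    "write_traces",
    "read_traces",
    "write_rois",
    "read_rois",
]

CHANNEL_ORDERS = ("GR", "RG")


# ---------------------------------------------------------------------------
# Deinterleaving
# ---------------------------------------------------------------------------

def deinterleave(frames: np.ndarray, order: str = "GR"
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Split an alternating-excitation frame sequence into (green, red).

    ``order`` names which channel the first frame belongs to: ``"GR"``
    (green leads) or ``"RG"``. Re-interleaving the outputs in the same
    order reproduces the input exactly.
    """
    if order not in CHANNEL_ORDERS:
        raise ParameterError(f"order must be one of {CHANNEL_ORDERS}, got {order!r}")
    frames = np.asarray(frames)
    if len(frames) % 2 != 0:
        raise MalformedInputError(
            f"interleaved sequence must have even length, got {len(frames)}"
        )
    first, second = frames[0::2], frames[1::2]
    return (first, second) if order == "GR" else (second, first)


def interleave(green: np.ndarray, red: np.ndarray, order: str = "GR"
               ) -> np.ndarray:
    """Inverse of :func:`deinterleave`."""
    if order not in CHANNEL_ORDERS:
        raise ParameterError(f"order must be one of {CHANNEL_ORDERS}, got {order!r}")
    green, red = np.asarray(green), np.asarray(red)
    if green.shape != red.shape:
        raise ShapeError("green and red must have identical shape")
    first, second = (green, red) if order == "GR" else (red, green)
    out = np.empty((2 * len(first),) + first.shape[1:], dtype=first.dtype)
    out[0::2], out[1::2] = first, second
    return out


# ---------------------------------------------------------------------------
# Stack + metadata sidecar
# ---------------------------------------------------------------------------

_REQUIRED_META = ("frame_interval_s", "channel_order")


def _stim_from_meta(meta: dict) -> Optional[StimulusProtocol]:
    stim = meta.get("stimulus")
    if stim is None:
        return None
    try:
        return StimulusProtocol(
            onset_time_s=float(stim["onset_time_s"]),
            n_stimuli=int(stim["n_stimuli"]),
            frequency_hz=float(stim.get("frequency_hz", 20.0)),
            intensity_v=float(stim.get("intensity_v", 20.0)),
        )
    except KeyError as exc:
        raise MetadataError(f"stimulus metadata missing key {exc}") from exc


def read_stack(path, meta_path) -> TwoChannelStack:
    """Read an interleaved TIFF + YAML sidecar into a deinterleaved stack."""
    meta_path = Path(meta_path)
    if not meta_path.exists():
        raise MetadataError(f"metadata sidecar not found: {meta_path}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh) or {}
    for key in _REQUIRED_META:
        if key not in meta:
            raise MetadataError(f"metadata missing required key {key!r}")
    order = str(meta["channel_order"]).upper()
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    green, red = deinterleave(frames, order)
    if np.any(frames.astype(np.int64, copy=False) < 0):
        raise MalformedInputError("negative intensities in stack")
    return TwoChannelStack(
        green=green,
        red=red,
        frame_interval_s=float(meta["frame_interval_s"]),
        stim=_stim_from_meta(meta),
    )


def write_stack(stack: TwoChannelStack, path, meta_path,
                order: str = "GR") -> None:
    """Write a stack as interleaved 16-bit TIFF + YAML sidecar.

    Integer-valued data round-trips bit-exactly through
    :func:`read_stack`; floating data is rounded to uint16.
    """
    frames = interleave(stack.green, stack.red, order)
    if not np.issubdtype(frames.dtype, np.integer):
        frames = np.clip(np.rint(frames), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, frames.astype(np.uint16))
    meta: dict = {
        "frame_interval_s": float(stack.frame_interval_s),
        "channel_order": order,
    }
    if stack.stim is not None:
        meta["stimulus"] = {
            "onset_time_s": float(stack.stim.onset_time_s),
            "n_stimuli": int(stack.stim.n_stimuli),
            "frequency_hz": float(stack.stim.frequency_hz),
            "intensity_v": float(stack.stim.intensity_v),
        }
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Traces (long-format CSV)
# ---------------------------------------------------------------------------

def write_traces(traces: Sequence[Trace], path) -> None:
    """Write traces as long-format CSV: roi_id, time_s, value, stage.

    Masked (invalid) samples are written with an empty value cell.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["roi_id", "time_s", "value", "stage"])
        for i, tr in enumerate(traces):
            rid = tr.roi_id if tr.roi_id is not None else str(i)
            mask = tr.mask if tr.mask is not None else np.zeros(len(tr), bool)
            for t, v, bad in zip(tr.times_s, tr.values, mask):
                writer.writerow([rid, repr(float(t)),
                                 "" if bad else repr(float(v)), tr.stage])


def read_traces(path) -> List[Trace]:
    """Read a trace CSV written by :func:`write_traces` (order-preserving)."""
    by_id: Dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) < {
                "roi_id", "time_s", "value", "stage"}:
            raise MalformedInputError("trace CSV missing required header")
        for row in reader:
            rec = by_id.setdefault(row["roi_id"],
                                   {"t": [], "v": [], "m": [],
                                    "stage": row["stage"]})
            rec["t"].append(float(row["time_s"]))
            bad = row["value"] == ""
            rec["m"].append(bad)
            rec["v"].append(np.nan if bad else float(row["value"]))
    traces = []
    for rid, rec in by_id.items():
        mask = np.array(rec["m"], bool)
        stage = rec["stage"]
        # f0 is not serialized; a normalized trace read back keeps stage
        # but carries f0=1.0 as a placeholder scale.
        f0 = 1.0 if stage == "normalized" else None
        traces.append(Trace(np.array(rec["t"]), np.array(rec["v"]),
                            stage=stage, f0=f0, roi_id=rid,
                            mask=mask if mask.any() else None))
    return traces


# ---------------------------------------------------------------------------
# ROIs (summary CSV + pixel-list JSON)
# ---------------------------------------------------------------------------

def write_rois(rois: Sequence[Roi], csv_path, json_path=None) -> None:
    """ROI summary CSV (id, kind, center, size) plus optional pixel JSON."""
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "kind", "center_row", "center_col", "n_pixels"])
        for roi in rois:
            writer.writerow([roi.id, roi.kind, roi.center[0], roi.center[1],
                             len(roi)])
    if json_path is not None:
        payload = {roi.id: {"kind": roi.kind,
                            "center": list(roi.center),
                            "pixels": sorted(map(list, roi.pixels))}
                   for roi in rois}
        with open(json_path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)


def read_rois(json_path) -> List[Roi]:
    with open(json_path) as fh:
        payload = json.load(fh)
    return [Roi(id=rid, pixels=frozenset(map(tuple, rec["pixels"])),
                center=tuple(rec["center"]), kind=rec["kind"])
            for rid, rec in sorted(payload.items())]
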