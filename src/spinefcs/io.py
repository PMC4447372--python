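"""Plain-text serialization of traces, correlation curves, FRAP data and fits.

All formats are columnar text with '#'-prefixed ``key: value`` header
lines, so files remain inspectable and diff-able.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .correlator import CorrelationCurve
from .frap import FrapCurve
from .synthetic_data import PhotonTrace


def _header(meta: dict) -> str:
    return "\n".join(f"{k}: {v}" for k, v in meta.items())


def _read_header(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
    return meta


def write_trace(path, trace: PhotonTrace) -> None:
    """Two-column text (time_s, counts)."""
    meta = {"bin_width": trace.bin_width}
    for key in ("seed", "duration", "config_hash"):
        if key in trace.metadata:
            meta[key] = trace.metadata[key]
    data = np.column_stack([trace.time, trace.counts])
    np.savetxt(
        path, data, fmt=["%.9g", "%d"], header=_header(meta), comments="# "
    )


def read_trace(path) -> PhotonTrace:
    meta = _read_header(path)
    data = np.loadtxt(path)
    bin_width = float(meta.get("bin_width", data[1, 0] - data[0, 0]))
    return PhotonTrace(
        bin_width=bin_width,
        counts=data[:, 1].astype(np.int64),
        metadata={"source": str(path), **meta},
    )


def write_curve(path, curve: CorrelationCurve) -> None:
    """Three-column text (lag_s, g, g_sd)."""
    meta = {"total_intensity": curve.total_intensity}
    for key in ("g_zero", "n_segments", "scheme", "bin_width"):
        if key in curve.metadata:
            meta[key] = curve.metadata[key]
    data = np.column_stack([curve.lags, curve.g, curve.g_sd])
    np.savetxt(path, data, fmt="%.10g", header=_header(meta), comments="# ")


def read_curve(path) -> CorrelationCurve:
    meta = _read_header(path)
    data = np.loadtxt(path)
    return CorrelationCurve(
        lags=data[:, 0],
        g=data[:, 1],
        g_sd=data[:, 2],
        total_intensity=float(meta.get("total_intensity", np.nan)),
        metadata={"source": str(path), **meta},
    )


def write_frap_curve(path, curve: FrapCurve) -> None:
    """Two-column text (time_s, normalized_intensity); bleach at t = 0."""
    meta = {"n_prebleach": curve.n_prebleach, "bleach_time": 0.0}
    data = np.column_stack([curve.time, curve.intensity])
    np.savetxt(path, data, fmt="%.9g", header=_header(meta), comments="# ")


def read_frap_curve(path) -> FrapCurve:
    meta = _read_header(path)
    data = np.loadtxt(path)
    return FrapCurve(
        time=data[:, 0],
        intensity=data[:, 1],
        n_prebleach=int(meta.get("n_prebleach", np.sum(data[:, 0] < 0))),
        metadata={"source": str(path), **meta},
    )


def read_frap_rois(path):
    """Four-column ROI table (time_s, spine, background, reference)."""
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 4:
        raise ValueError("ROI table must have columns time, spine, "
                         "background, reference")
    return data[:, 0], data[:, 1], data[:, 2], data[:, 3]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float):
        return obj if np.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_fit_json(path, fit, extra: dict | None = None) -> None:
    """Flat JSON record of any fit/report dataclass."""
    record = _jsonable(fit)
    if extra:
        record.update(_jsonable(extra))
    Path(path).write_text(json.dumps(record, indent=2, allow_nan=False))
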