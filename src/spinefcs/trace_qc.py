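"""Trace quality control and display normalization.

Recordings contaminated by movement of the entire spine head show
correlation amplitude at lags well beyond ~1 s, where intra-spine filament
diffusion has fully decorrelated.  The selection rule compares the mean
correlation over a long-lag motion window against the curve's own noise
floor and rejects the trace when the plateau is significantly above it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .correlator import CorrelationCurve

__all__ = ["QcReport", "detect_spine_motion", "normalize_curve"]

DEFAULT_MOTION_WINDOW = (1.0, None)
DEFAULT_THRESHOLD_RATIO = 3.0


@dataclass(frozen=True)
class QcReport:
    passed: Optional[bool]  # None when the curve cannot be assessed
    status: str  # "passed" | "failed" | "not_assessable"
    long_lag_amplitude: float
    noise_floor: float
    threshold_ratio: float


def detect_spine_motion(
    curve: CorrelationCurve,
    motion_window: Tuple[float, Optional[float]] = DEFAULT_MOTION_WINDOW,
    threshold_ratio: float = DEFAULT_THRESHOLD_RATIO,
) -> QcReport:
    """Flag whole-spine motion from the long-lag correlation plateau.

    long_lag_amplitude is the mean g over ``motion_window`` (default 1 s to
    the last lag); noise_floor is the median per-lag error estimate there.
    The trace fails when the plateau exceeds ``threshold_ratio`` times the
    noise floor.  A curve that does not reach past the window start is
    explicitly not assessable, never silently passed.
    """
    lo, hi = motion_window
    if hi is None:
        hi = float(curve.lags[-1])
    mask = curve.window(lo, hi)
    if curve.lags[-1] <= lo or not np.any(mask):
        return QcReport(
            passed=None,
            status="not_assessable",
            long_lag_amplitude=np.nan,
            noise_floor=np.nan,
            threshold_ratio=threshold_ratio,
        )
    amp = float(np.mean(curve.g[mask]))
    # use only genuinely segment-estimated error bars: beyond
    # g_sd_valid_max_lag the values are carried forward and, on a
    # motion-contaminated trace, already inflated by the motion itself
    valid_max = curve.metadata.get("g_sd_valid_max_lag", np.inf)
    sd_mask = mask & (curve.lags <= valid_max)
    if not np.any(sd_mask):
        sd_mask = curve.window(lo / 3.0, min(hi, valid_max))
    sd = curve.g_sd[sd_mask]
    sd = sd[np.isfinite(sd)]
    if len(sd) == 0:
        return QcReport(
            passed=None,
            status="not_assessable",
            long_lag_amplitude=amp,
            noise_floor=np.nan,
            threshold_ratio=threshold_ratio,
        )
    floor = float(np.median(sd))
    ok = amp <= threshold_ratio * floor
    return QcReport(
        passed=bool(ok),
        status="passed" if ok else "failed",
        long_lag_amplitude=amp,
        noise_floor=floor,
        threshold_ratio=threshold_ratio,
    )


def normalize_curve(curve: CorrelationCurve, mode: str = "first") -> CorrelationCurve:
    """Divide a curve by its amplitude so it starts at 1 (display only).

    mode "first" uses the first finite-lag amplitude; mode "fit" uses the
    zero-lag amplitude of a two-component fit.  The divisor is recorded in
    the metadata; fitting always consumes unnormalized curves.
    """
    if mode == "first":
        finite = np.isfinite(curve.g)
        if not np.any(finite):
            raise ValueError("no finite correlation amplitudes")
        divisor = float(curve.g[finite][0])
    elif mode == "fit":
        from .fcs_models import fit_two_component

        fit = fit_two_component(curve)
        divisor = float(sum(fit.amplitudes))
    else:
        raise ValueError("mode must be 'first' or 'fit'")
    if not np.isfinite(divisor) or divisor <= 0:
        raise ValueError("non-positive reference amplitude")
    meta = dict(curve.metadata)
    meta["normalization_divisor"] = divisor * meta.get(
        "normalization_divisor", 1.0
    )
    return CorrelationCurve(
        lags=curve.lags.copy(),
        g=curve.g / divisor,
        g_sd=curve.g_sd / divisor,
        total_intensity=curve.total_intensity,
        metadata=meta,
    )
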