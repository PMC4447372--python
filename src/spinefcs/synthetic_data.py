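"""Synthetic fluorescence-fluctuation and FRAP data generator.

Stands in for live-cell recordings: point particles (actin filament
fragments of an effective size) diffuse through a periodic box containing a
three-dimensional Gaussian two-photon detection profile

    W(x, y, z) = exp(-4 (x^2 + y^2) / w_xy^2 - 4 z^2 / w_z^2),

where the quoted focal extents (~200 nm diameter, ~500 nm height) are read
as 1/e^2 full widths.  The per-bin expected photon count is the
brightness-weighted sum of W over all particles plus a background rate, and
emitted counts are Poisson.  The diffusion-time convention is the two-photon
one, tau_D = w_xy^2 / (8 D).

A species with mean_number N is dosed so that the small-lag correlation
amplitude of an otherwise clean trace is 1/N: the box density is
N / V_eff with V_eff = (pi/2)^(3/2) w_xy^2 w_z the effective Gaussian
volume.  The mean count rate contributed by the species is then
N * brightness * GAMMA_3DG with GAMMA_3DG = 2^(-3/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import lfilter

from . import _kernels

__all__ = [
    "SpeciesSpec",
    "FocalVolumeSpec",
    "DriftSpec",
    "SimulationConfig",
    "PhotonTrace",
    "GAMMA_3DG",
    "effective_volume",
    "simulate_trace",
    "add_drift",
    "simulate_frap_curve",
]

#: Mean detection-profile value per particle in effective-volume units,
#: <W> = integral(W^2) / integral(W) for the 3D Gaussian profile.
GAMMA_3DG = 2.0 ** -1.5

_CHUNK = 8192  # time bins per kernel call; fixed so traces are seed-stable


@dataclass(frozen=True)
class SpeciesSpec:
    """One diffusing species: transit time, mean occupancy, peak brightness.

    diffusion_time : seconds, focal-volume transit time tau_D (> 0)
    mean_number    : average particles in the effective volume, N (>= 0)
    brightness     : counts/s per particle at the focus center (>= 0)
    """

    diffusion_time: float
    mean_number: float
    brightness: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.diffusion_time) or self.diffusion_time <= 0:
            raise ValueError("diffusion_time must be finite and > 0")
        if not np.isfinite(self.mean_number) or self.mean_number < 0:
            raise ValueError("mean_number must be finite and >= 0")
        if not np.isfinite(self.brightness) or self.brightness < 0:
            raise ValueError("brightness must be finite and >= 0")


@dataclass(frozen=True)
class FocalVolumeSpec:
    """Two-photon focal volume: 1/e^2 full widths (nm) and shape parameter.

    shape_parameter is the instrumental f of the diffusion model; for the
    Gaussian volume it equals (lateral_extent / axial_extent)^2.
    """

    lateral_extent: float = 200.0
    axial_extent: float = 500.0
    shape_parameter: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.lateral_extent <= 0:
            raise ValueError("lateral_extent must be > 0")
        if self.axial_extent < self.lateral_extent:
            raise ValueError("axial_extent must be >= lateral_extent")
        if self.shape_parameter is None:
            object.__setattr__(
                self,
                "shape_parameter",
                (self.lateral_extent / self.axial_extent) ** 2,
            )
        if self.shape_parameter < 0:
            raise ValueError("shape_parameter must be >= 0")


@dataclass(frozen=True)
class DriftSpec:
    """Slow whole-spine intensity modulation (amplitude, timescale > 1 s)."""

    amplitude: float
    timescale: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.timescale <= 1.0:
            raise ValueError(
                "drift timescale must exceed 1 s (whole-spine motion regime)"
            )


@dataclass(frozen=True)
class SimulationConfig:
    species: Sequence[SpeciesSpec]
    volume: FocalVolumeSpec = FocalVolumeSpec()
    duration: float = 120.0
    bin_width: float = 1e-4
    box_scale: float = 5.0
    background_rate: float = 0.0
    drift: Optional[DriftSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.bin_width <= 0 or self.bin_width >= self.duration:
            raise ValueError("need 0 < bin_width < duration")
        if self.box_scale < 5:
            raise ValueError("box_scale must be >= 5")
        if not np.isfinite(self.background_rate) or self.background_rate < 0:
            raise ValueError("background_rate must be finite and >= 0")


@dataclass
class PhotonTrace:
    """Binned photon counts from one observation volume."""

    bin_width: float
    counts: np.ndarray
    metadata: dict = field(default_factory=dict)
    #: per-bin expected counts (simulation truth); kept in memory only
    expected_rate: Optional[np.ndarray] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or len(self.counts) == 0:
            raise ValueError("counts must be a non-empty 1-d sequence")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def duration(self) -> float:
        return len(self.counts) * self.bin_width

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.counts)) * self.bin_width

    @property
    def mean_rate(self) -> float:
        """Mean count rate in counts/s."""
        return float(np.mean(self.counts)) / self.bin_width


def effective_volume(volume: FocalVolumeSpec) -> float:
    """Effective Gaussian volume (pi/2)^(3/2) w_xy^2 w_z, in nm^3."""
    return (np.pi / 2.0) ** 1.5 * volume.lateral_extent**2 * volume.axial_extent


def diffusion_coefficient(diffusion_time: float, volume: FocalVolumeSpec) -> float:
    """D in nm^2/s from the two-photon convention tau_D = w_xy^2 / (8 D)."""
    return volume.lateral_extent**2 / (8.0 * diffusion_time)


def _species_rate(rng, spec, cfg, n_bins):
    """Summed detection-profile weight per bin for one species (counts/s
    when multiplied by brightness)."""
    vol = cfg.volume
    box = np.array(
        [
            cfg.box_scale * vol.lateral_extent,
            cfg.box_scale * vol.lateral_extent,
            cfg.box_scale * vol.axial_extent,
        ]
    )
    v_box = float(np.prod(box))
    # canonical (fixed-count) box: the per-trace species concentration is
    # exact rather than carrying a Poisson draw.  A closed box of n
    # particles has slightly sub-Poisson focal-volume occupancy,
    # G(0) = (V_box/V_eff - 1)/n, so the dose uses (V_box/V_eff - 1) to
    # make the correlation amplitude match the open-volume model's 1/N
    # (the mean count rate then sits V_eff/V_box ~ 1.6% below the ideal
    # gamma calibration).
    mean_in_box = spec.mean_number * (v_box / effective_volume(vol) - 1.0)
    n_part = int(round(mean_in_box))
    out = np.zeros(n_bins, dtype=np.float64)
    if n_part == 0:
        return out
    d_coef = diffusion_coefficient(spec.diffusion_time, vol)
    step_sd = np.sqrt(2.0 * d_coef * cfg.bin_width)
    width = np.full(3, _kernels.UNIFORM_SCALE * step_sd)
    pos = (rng.random((n_part, 3)).astype(np.float32) - 0.5) * box.astype(
        np.float32
    )
    inv4w2 = 4.0 / vol.lateral_extent**2
    inv4wz2 = 4.0 / vol.axial_extent**2
    buf = np.empty((min(_CHUNK, n_bins), n_part, 3), dtype=np.float32)
    for start in range(0, n_bins, _CHUNK):
        m = min(_CHUNK, n_bins - start)
        u = buf[:m]
        rng.random(out=u, dtype=np.float32)
        _kernels.accumulate(
            u, pos, width, box, inv4w2, inv4wz2, out[start : start + m]
        )
    return out


def simulate_trace(config: SimulationConfig) -> PhotonTrace:
    """Brownian-dynamics photon trace for a mixture of diffusing species.

    Particle positions advance once per time bin with per-axis step variance
    2 D bin_width in a periodic box of side box_scale times the focal
    extents; the per-bin expected count is the brightness-weighted sum of
    the detection profile over particles plus the background, and counts
    are Poisson around it.  Identical configs (including seed) give
    bit-identical traces.
    """
    import hashlib

    rng = np.random.default_rng(config.seed)
    n_bins = int(round(config.duration / config.bin_width))
    meta: dict = {
        "seed": config.seed,
        "bin_width": config.bin_width,
        "duration": n_bins * config.bin_width,
        "config_hash": hashlib.md5(repr(config).encode()).hexdigest()[:12],
        "warnings": [],
    }
    if config.species:
        slowest = max(s.diffusion_time for s in config.species)
        if config.duration < 10.0 * slowest:
            meta["warnings"].append(
                "duration shorter than 10x the slowest diffusion time; "
                "curve statistics will be poor"
            )
    rate = np.full(n_bins, config.background_rate, dtype=np.float64)
    for spec in config.species:
        rate += spec.brightness * _species_rate(rng, spec, config, n_bins)
    expected = rate * config.bin_width
    counts = rng.poisson(expected)
    trace = PhotonTrace(
        bin_width=config.bin_width,
        counts=counts,
        metadata=meta,
        expected_rate=expected,
    )
    if config.drift is not None:
        trace = add_drift(trace, config.drift, seed=rng.integers(2**31))
    return trace


def add_drift(trace: PhotonTrace, drift: DriftSpec, seed: int) -> PhotonTrace:
    """Contaminate a trace with a slow whole-spine intensity modulation.

    The per-bin expectation is multiplied by a smooth lognormal envelope
    exp(a u(t) - a^2 / 2) with u an Ornstein-Uhlenbeck process of unit
    stationary variance and the given correlation timescale; the envelope
    has unit mean, so the count rate is preserved within sampling error.
    Counts are re-drawn as Poisson around the modulated expectation.
    """
    if drift.amplitude == 0:
        return trace
    if trace.expected_rate is not None:
        expected = trace.expected_rate
    else:
        # observed counts as a (shot-noisy) stand-in for the expectation
        expected = trace.counts.astype(np.float64)
    rng = np.random.default_rng(seed)
    n = len(expected)
    alpha = np.exp(-trace.bin_width / drift.timescale)
    xi = rng.standard_normal(n)
    u0 = rng.standard_normal()
    u, _ = lfilter(
        [np.sqrt(1.0 - alpha**2)], [1.0, -alpha], xi, zi=np.array([alpha * u0])
    )
    env = np.exp(drift.amplitude * u - drift.amplitude**2 / 2.0)
    modulated = expected * env
    counts = rng.poisson(modulated)
    meta = dict(trace.metadata)
    meta["drift"] = {
        "amplitude": drift.amplitude,
        "timescale": drift.timescale,
        "seed": int(seed),
    }
    return PhotonTrace(
        bin_width=trace.bin_width,
        counts=counts,
        metadata=meta,
        expected_rate=modulated,
    )


def simulate_frap_curve(
    f_s: float,
    f_f: float,
    lam: float,
    noise_sd: float = 0.05,
    n_pre: int = 5,
    n_post: int = 55,
    dt: float = 2.0,
    seed: int = 0,
):
    """Synthetic normalized FRAP recovery curve.

    Pre-bleach samples sit at 1 plus noise; post-bleach samples follow the
    single-exponential turnover model F(t) = 1 - f_s - f_f exp(-t/lam)
    (stable fraction f_s, dynamic fraction f_f, monomeric remainder) plus
    independent Gaussian noise.  Sampling defaults mirror confocal FRAP at
    2-s frame intervals.
    """
    from .frap import FrapCurve  # local import to avoid a cycle

    if f_s < 0 or f_f < 0:
        raise ValueError("fractions must be non-negative")
    if f_s + f_f > 1:
        raise ValueError("f_s + f_f must not exceed 1 (monomeric fraction < 0)")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if n_pre < 1 or n_post < 1:
        raise ValueError("need at least one sample on each side of the bleach")
    rng = np.random.default_rng(seed)
    t_pre = -dt * np.arange(n_pre, 0, -1)
    t_post = dt * np.arange(n_post)
    f_pre = 1.0 + noise_sd * rng.standard_normal(n_pre)
    f_post = (
        1.0
        - f_s
        - f_f * np.exp(-t_post / lam)
        + noise_sd * rng.standard_normal(n_post)
    )
    return FrapCurve(
        time=np.concatenate([t_pre, t_post]),
        intensity=np.concatenate([f_pre, f_post]),
        n_prebleach=n_pre,
        metadata={
            "truth": {"f_s": f_s, "f_f": f_f, "lam": lam},
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )
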