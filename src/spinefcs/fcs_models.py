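"""One- and two-component brightness-weighted diffusion models and fits.

The two-component model for the correlation of a mixture of a dim "short"
species (per-particle brightness I, number N1, transit time tau1) and a
bright "long" species (brightness A*I, number N2, transit time tau2) is

    G(tau) = [I^2 N1 M1(tau) + (A I)^2 N2 M2(tau)] / (I N1 + A I N2)^2

with the single-species decay

    M(tau) = 1 / (1 + tau/tau_d) * 1 / sqrt(1 + f * tau/tau_d)

for a three-dimensional Gaussian focal volume of shape parameter
f = (w_xy / w_z)^2 (a purely multiplicative axial variant is available
behind ``axial="linear"``).

Identifiability.  G is homogeneous of degree 0 in I, so the curve alone
determines only the component amplitudes

    a1 = N1 / (N1 + A N2)^2,    a2 = A^2 N2 / (N1 + A N2)^2

together with tau1 and tau2; the brightness ratio A is *not* identifiable
from the correlation curve.  The fit therefore runs in (a1, a2, tau1,
tau2) space and decomposes into particle numbers using an assumed A
(default 100, the Rouse-model scale of the two populations' ~100-fold
diffusion-time ratio, inside the physically motivated 0-150 range; pass
``brightness_factor="rouse"`` to close instead with the per-fit ratio
tau2_hat/tau1_hat, which is unbiased on average but inherits the full
noise of both diffusion-time estimates).  The absolute brightness I is
anchored to the measured count rate afterwards
(:func:`derived_quantities`).

Estimation.  Because the bright slow species dominates the curve, its
finite-sampling realization error is strongly correlated across lags and
easily an order of magnitude larger than the lag-local noise that limits
how well the small fast component can be read off.  A single joint
weighted least squares is unstable in that situation, so the fit is
scale-separated and iterative: the slow component is fitted on long lags
(beyond ``split_lag``) with the current fast estimate subtracted, then the
fast component is fitted on short lags with the slow model subtracted and
a low-order polynomial nuisance background absorbing the smooth remnant of
the slow realization error; a few rounds converge.  On noiseless model
curves the nuisance terms vanish and the recovery is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np
from scipy import stats as sps
from scipy.optimize import least_squares

from .correlator import CorrelationCurve
from .synthetic_data import GAMMA_3DG

__all__ = [
    "ModelParams",
    "TwoComponentFit",
    "ModelSelection",
    "DerivedQuantities",
    "model_component",
    "model_curve",
    "fit_two_component",
    "fit_one_component",
    "select_model",
    "rouse_size_ratio",
    "derived_quantities",
]

A_MAX = 150.0  # physically motivated bound on the brightness ratio
A_DEFAULT = 100.0  # Rouse-scale default: ~100-fold size/diffusion-time ratio
DEFAULT_SHAPE = 0.16  # (200 nm / 500 nm)^2 from the quoted focal extents
DEFAULT_FIT_WINDOW = (1e-4, 1.0)
DEFAULT_SPLIT_LAG = 0.05  # boundary between the fast and slow fitting stages


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the diffusion model (two components when tau2 is set)."""

    tau1: float
    n1: float
    tau2: Optional[float] = None
    n2: Optional[float] = None
    brightness: Optional[float] = None  # I of the short form, counts/s
    brightness_factor: Optional[float] = None  # A = I_long / I_short
    shape: float = DEFAULT_SHAPE

    def __post_init__(self) -> None:
        if self.tau1 <= 0:
            raise ValueError("tau1 must be > 0")
        if self.tau2 is not None and self.tau2 <= self.tau1:
            raise ValueError("tau2 must exceed tau1")
        if self.n1 < 0 or (self.n2 is not None and self.n2 < 0):
            raise ValueError("particle numbers must be >= 0")
        if self.brightness_factor is not None and not (
            0 <= self.brightness_factor <= A_MAX
        ):
            raise ValueError(f"brightness_factor must lie in [0, {A_MAX}]")
        if self.shape < 0:
            raise ValueError("shape must be >= 0")


@dataclass
class TwoComponentFit:
    """Result of a weighted least-squares fit of the diffusion model."""

    params: ModelParams
    uncertainties: dict
    residuals: np.ndarray  # weighted residuals over the fitted lags
    goodness: float  # reduced chi-square
    converged: bool
    n_components: int
    amplitudes: Tuple[float, ...] = ()  # fitted (a1[, a2])
    fit_window: Tuple[float, float] = DEFAULT_FIT_WINDOW
    lags: np.ndarray = field(default_factory=lambda: np.empty(0))
    ssr: float = np.nan  # weighted residual sum of squares


@dataclass(frozen=True)
class ModelSelection:
    n_components: int
    f_statistic: float
    f_pvalue: float
    runs_statistic: float
    runs_pvalue: float
    alpha: float


def model_component(tau, tau_d: float, shape: float, axial: str = "sqrt"):
    """Single-species decay M(tau); M(0) = 1, strictly decreasing."""
    if tau_d <= 0:
        raise ValueError("tau_d must be > 0")
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    x = tau / tau_d
    lateral = 1.0 / (1.0 + x)
    if axial == "sqrt":
        ax = 1.0 / np.sqrt(1.0 + shape * x)
    elif axial == "linear":
        ax = 1.0 / (1.0 + shape * x)
    else:
        raise ValueError("axial must be 'sqrt' or 'linear'")
    out = lateral * ax
    return float(out) if out.ndim == 0 else out


def model_curve(lags, params: ModelParams, axial: str = "sqrt"):
    """Model G(tau); reduces exactly to M1(tau)/N1 when n2 is absent or 0."""
    lags = np.asarray(lags, dtype=float)
    m1 = model_component(lags, params.tau1, params.shape, axial)
    two = params.n2 is not None and params.n2 > 0
    if not two:
        if params.n1 == 0:
            raise ValueError("N1 = N2 = 0: amplitude undefined")
        return m1 / params.n1
    if params.tau2 is None:
        raise ValueError("two-component params require tau2")
    a_fac = params.brightness_factor
    if a_fac is None:
        raise ValueError("two-component params require brightness_factor")
    m2 = model_component(lags, params.tau2, params.shape, axial)
    denom = (params.n1 + a_fac * params.n2) ** 2
    return (params.n1 * m1 + a_fac**2 * params.n2 * m2) / denom


def amplitudes_to_numbers(
    a1: float, a2: float, a_fac: float
) -> Tuple[float, float]:
    """Invert a1 = N1/s^2, a2 = A^2 N2/s^2 with s = N1 + A N2 at given A."""
    if a1 <= 0 and a2 <= 0:
        raise ValueError("at least one amplitude must be positive")
    s = 1.0 / (a1 + a2 / a_fac) if a_fac > 0 else 1.0 / a1
    n1 = a1 * s**2
    n2 = a2 * s**2 / a_fac**2 if a_fac > 0 else 0.0
    return n1, n2


def local_noise(lags: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Lag-local scatter of a correlation curve, per multi-tau block.

    The slow component's realization noise is almost perfectly correlated
    across neighboring lags, so segment-to-segment error bars vastly
    overstate the *local* uncertainty that limits how well the curve's
    shape is known.  Within each multi-tau block the lag spacing is
    uniform, so the curve is detrended with a quadratic per block and the
    residual standard deviation used as that block's per-lag noise.
    """
    sd = np.empty(len(lags))
    spacing = np.round(np.diff(np.concatenate([[0.0], lags])), 12)
    _, block_ids = np.unique(spacing, return_inverse=True)
    for b in np.unique(block_ids):
        idx = np.nonzero(block_ids == b)[0]
        if len(idx) >= 5:
            x = np.arange(len(idx), dtype=float)
            coef = np.polyfit(x, g[idx], 2)
            resid = g[idx] - np.polyval(coef, x)
            sd[idx] = np.std(resid) * np.sqrt(len(idx) / (len(idx) - 3))
        else:
            sd[idx] = np.nan
    finite = np.isfinite(sd)
    if not np.any(finite):
        return np.full(len(lags), max(np.max(np.abs(g)) * 1e-2, 1e-12))
    sd[~finite] = np.interp(
        np.nonzero(~finite)[0], np.nonzero(finite)[0], sd[finite]
    )
    return sd


def _prepare(curve: CorrelationCurve, fit_lag_window, min_points: int):
    lo, hi = fit_lag_window
    mask = curve.window(lo, hi) & (curve.lags > 0)
    lags = curve.lags[mask]
    g = curve.g[mask]
    if len(lags) < min_points:
        raise ValueError(
            f"only {len(lags)} lags in the fit window; need >= {min_points}"
        )
    if np.all(g == 0):
        raise ValueError("all-zero correlation curve: nothing to fit")
    sd = local_noise(lags, g)
    floor = max(1e-6 * np.nanmax(np.abs(g)), 1e-12)
    sd[~np.isfinite(sd) | (sd < floor)] = floor
    return lags, g, sd


def _fit_slow_stage(lags, target, sd, mask, shape, axial, t2_init, a2_init, hi):
    """Slow component on the long-lag side; returns the fit of (a2, tau2).

    """
    ll, tt, ss = lags[mask], target[mask], sd[mask]

    def resid(p):
        return (p[0] * model_component(ll, p[1], shape, axial) - tt) / ss

    best = None
    for t2_start in {t2_init, 0.1, 0.4, hi}:
        try:
            r = least_squares(
                resid,
                [max(a2_init, 1e-9), float(np.clip(t2_start, 2e-3, 3 * hi))],
                bounds=([0.0, 1e-3], [np.inf, 3.0 * hi]),
            )
        except Exception:
            continue
        if best is None or r.cost < best.cost:
            best = r
    if best is None:
        raise RuntimeError("slow-stage fit failed")
    return best


def _fit_fast_stage(lags, target, sd, mask, shape, axial, lo, split):
    """Fast component + polynomial nuisance background on short lags.

    Grid search over tau1 with a linear solve of (a1, c0, c1, c2), then a
    bounded polish.  Returns the least_squares result and (tau1, a1).
    """
    ll, tt, ss = lags[mask], target[mask], sd[mask]
    x = ll / split
    w = 1.0 / ss
    ones = np.ones(len(ll))
    best = None
    for t1g in np.exp(np.linspace(np.log(lo / 3.0), np.log(split / 2.0), 25)):
        m1 = model_component(ll, t1g, shape, axial)
        design = np.column_stack([m1, ones, x, x * x])
        sol, *_ = np.linalg.lstsq(design * w[:, None], tt * w, rcond=None)
        if sol[0] < 0:
            sub = np.linalg.lstsq(
                design[:, 1:] * w[:, None], tt * w, rcond=None
            )[0]
            sol = np.array([0.0, *sub])
        rr = float(np.sum(((design @ sol - tt) * w) ** 2))
        if best is None or rr < best[0]:
            best = (rr, t1g, sol)
    _, t1, sol = best

    def resid(p):
        return (
            p[1] * model_component(ll, p[0], shape, axial)
            + p[2]
            + p[3] * x
            + p[4] * x * x
            - tt
        ) * w

    x0 = [
        float(np.clip(t1, lo / 3.0, split / 2.0)),
        max(sol[0], 0.0),
        sol[1],
        sol[2],
        sol[3],
    ]
    r = least_squares(
        resid,
        x0,
        bounds=(
            [lo / 3.0, 0.0, -np.inf, -np.inf, -np.inf],
            [split / 2.0, np.inf, np.inf, np.inf, np.inf],
        ),
    )
    return r


def _stderr_from_lsq(result, index):
    """Approximate parameter standard error from a least_squares result."""
    try:
        jac = result.jac
        dof = max(jac.shape[0] - jac.shape[1], 1)
        cov = np.linalg.pinv(jac.T @ jac) * 2.0 * result.cost / dof
        return float(np.sqrt(cov[index, index]))
    except Exception:
        return np.nan


def fit_two_component(
    curve: CorrelationCurve,
    init: Optional[ModelParams] = None,
    fit_lag_window: Tuple[float, float] = DEFAULT_FIT_WINDOW,
    shape: float = DEFAULT_SHAPE,
    axial: str = "sqrt",
    brightness_factor: Union[float, str] = A_DEFAULT,
    split_lag: float = DEFAULT_SPLIT_LAG,
    n_iter: int = 4,
) -> TwoComponentFit:
    """Scale-separated iterative fit of the two-component model.

    ``brightness_factor`` is the assumed long/short brightness ratio used
    to decompose the fitted amplitudes into particle numbers (see the
    module docstring); pass the string ``"rouse"`` to use the per-fit
    ratio tau2_hat/tau1_hat clipped to [0, 150] instead of a fixed value.
    """
    lags, g, sd = _prepare(curve, fit_lag_window, min_points=6)
    lo, hi = max(fit_lag_window[0], float(lags[0])), float(lags[-1])
    split = min(split_lag, hi / 4.0)
    short = lags <= split
    if short.sum() < 8 or (~short).sum() < 4:
        raise ValueError(
            "fit window does not span both timescales around the split lag"
        )

    t2_init = init.tau2 if init is not None and init.tau2 else 0.3
    a2_init = max(float(g[~short][0]), 1e-6)
    fast_model = np.zeros_like(g)
    t1 = lo
    a1 = 0.0
    slow_fit = fast_fit = None
    for _ in range(n_iter):
        long_mask = lags >= max(5.0 * t1, split / 2.5)
        slow_fit = _fit_slow_stage(
            lags, g - fast_model, sd, long_mask, shape, axial,
            t2_init, a2_init, hi,
        )
        a2, t2 = slow_fit.x
        a2_init, t2_init = a2, t2
        slow_part = a2 * model_component(lags, t2, shape, axial)
        fast_fit = _fit_fast_stage(
            lags, g - slow_part, sd, short, shape, axial, lo, split
        )
        t1, a1 = fast_fit.x[0], fast_fit.x[1]
        fast_model = a1 * model_component(lags, t1, shape, axial)

    a2, t2 = slow_fit.x
    # relabel so tau1 < tau2
    if t2 < t1:
        t1, t2, a1, a2 = t2, t1, a2, a1
    if t2 <= t1:
        t2 = t1 * (1.0 + 1e-9)

    if brightness_factor == "rouse":
        a_fac = float(np.clip(t2 / t1, 0.0, A_MAX))
    else:
        a_fac = float(brightness_factor)
        if not 0 < a_fac <= A_MAX:
            raise ValueError(f"brightness_factor must lie in (0, {A_MAX}]")
    n1, n2 = amplitudes_to_numbers(max(a1, 0.0), max(a2, 0.0), a_fac)

    model = a1 * model_component(lags, t1, shape, axial) + a2 * model_component(
        lags, t2, shape, axial
    )
    weighted_resid = (model - g) / sd
    ssr = float(np.sum(weighted_resid**2))
    n_free = 4
    unc = {
        "tau1": _stderr_from_lsq(fast_fit, 0),
        "a1": _stderr_from_lsq(fast_fit, 1),
        "a2": _stderr_from_lsq(slow_fit, 0),
        "tau2": _stderr_from_lsq(slow_fit, 1),
    }
    # propagate amplitude errors through the decomposition at fixed A
    base = np.array([max(a1, 1e-15), max(a2, 1e-15)])
    errs = np.array([unc["a1"], unc["a2"]])
    for name, idx in (("n1", 0), ("n2", 1)):
        grads = []
        for i in range(2):
            h = base[i] * 1e-6
            up, dn = base.copy(), base.copy()
            up[i] += h
            dn[i] -= h
            vu = amplitudes_to_numbers(up[0], up[1], a_fac)[idx]
            vd = amplitudes_to_numbers(dn[0], dn[1], a_fac)[idx]
            grads.append((vu - vd) / (2 * h))
        unc[name] = float(np.sqrt(np.nansum((np.array(grads) * errs) ** 2)))

    params = ModelParams(
        tau1=t1, tau2=t2, n1=n1, n2=n2, brightness_factor=a_fac, shape=shape
    )
    converged = bool(slow_fit.success and fast_fit.success)
    return TwoComponentFit(
        params=params,
        uncertainties=unc,
        residuals=weighted_resid,
        goodness=ssr / max(len(lags) - n_free, 1),
        converged=converged,
        n_components=2,
        amplitudes=(float(a1), float(a2)),
        fit_window=tuple(fit_lag_window),
        lags=lags,
        ssr=ssr,
    )


def fit_one_component(
    curve: CorrelationCurve,
    init: Optional[ModelParams] = None,
    fit_lag_window: Tuple[float, float] = DEFAULT_FIT_WINDOW,
    shape: float = DEFAULT_SHAPE,
    axial: str = "sqrt",
) -> TwoComponentFit:
    """Single-species weighted fit G(tau) = a1 M(tau); N1 = 1/a1."""
    lags, g, sd = _prepare(curve, fit_lag_window, min_points=3)
    lo, hi = max(float(lags[0]), 1e-6), float(lags[-1])

    def resid(p):
        return (p[0] * model_component(lags, p[1], shape, axial) - g) / sd

    g0 = max(float(np.max(g)), 1e-6)
    starts = list(np.exp(np.linspace(np.log(lo * 2), np.log(hi), 6)))
    if init is not None:
        starts.append(init.tau1)
    best = None
    for t_start in starts:
        try:
            r = least_squares(
                resid,
                [g0, float(np.clip(t_start, lo / 30, hi * 3))],
                bounds=([0.0, lo / 30.0], [np.inf, hi * 3.0]),
            )
        except Exception:
            continue
        if best is None or r.cost < best.cost:
            best = r
    if best is None:
        raise RuntimeError("one-component fit failed")
    a1, t1 = best.x
    n1 = 1.0 / a1 if a1 > 0 else np.inf
    e_a1 = _stderr_from_lsq(best, 0)
    unc = {
        "a1": e_a1,
        "tau1": _stderr_from_lsq(best, 1),
        "n1": e_a1 / a1**2 if a1 > 0 and np.isfinite(e_a1) else np.nan,
    }
    weighted_resid = best.fun
    ssr = float(2.0 * best.cost)
    return TwoComponentFit(
        params=ModelParams(tau1=t1, n1=n1, shape=shape),
        uncertainties=unc,
        residuals=weighted_resid,
        goodness=ssr / max(len(lags) - 2, 1),
        converged=bool(best.success),
        n_components=1,
        amplitudes=(float(a1),),
        fit_window=tuple(fit_lag_window),
        lags=lags,
        ssr=ssr,
    )


def _runs_test(residuals: np.ndarray) -> Tuple[float, float]:
    """Wald-Wolfowitz runs test on residual signs (normal approximation)."""
    signs = np.sign(residuals[residuals != 0])
    n_pos = int(np.sum(signs > 0))
    n_neg = int(np.sum(signs < 0))
    n = n_pos + n_neg
    if n_pos == 0 or n_neg == 0 or n < 3:
        return 0.0, 1.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 0.0, 1.0
    z = (runs - mu) / np.sqrt(var)
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


def select_model(
    fit1: TwoComponentFit, fit2: TwoComponentFit, alpha: float = 0.05
) -> ModelSelection:
    """Choose between the one- and two-component fits of the same curve.

    Two components are selected only when (a) an F-test on the weighted
    residual sums of squares rejects the one-component model at ``alpha``
    (accounting for the extra parameters) and (b) a Wald-Wolfowitz runs
    test rejects randomness of the one-component residual signs at
    ``alpha``; parsimony wins otherwise.
    """
    if fit1.fit_window != fit2.fit_window or len(fit1.lags) != len(fit2.lags):
        raise ValueError("fits must share the same curve and lag window")
    n = len(fit1.residuals)
    k1, k2 = 2, 4
    if n <= k2:
        raise ValueError("not enough lags for the F-test")
    num = (fit1.ssr - fit2.ssr) / (k2 - k1)
    den = fit2.ssr / (n - k2)
    f_stat = num / den if den > 0 else np.inf
    f_p = float(sps.f.sf(f_stat, k2 - k1, n - k2)) if f_stat > 0 else 1.0
    runs_z, runs_p = _runs_test(fit1.residuals)
    choice = 2 if (f_p < alpha and runs_p < alpha) else 1
    return ModelSelection(
        n_components=choice,
        f_statistic=float(f_stat),
        f_pvalue=f_p,
        runs_statistic=runs_z,
        runs_pvalue=runs_p,
        alpha=alpha,
    )


def rouse_size_ratio(tau_ref: float, tau_new: float) -> float:
    """Fold-change in monomer number inferred from two diffusion times.

    Under the Rouse model the diffusion time of a polymer is roughly
    proportional to its monomer number, so tau_ref/tau_new is the inferred
    size reduction factor.
    """
    if tau_ref <= 0 or tau_new <= 0:
        raise ValueError("diffusion times must be > 0")
    return tau_ref / tau_new


@dataclass(frozen=True)
class DerivedQuantities:
    n1: float
    n2: Optional[float]
    brightness_short: float  # I, counts/s per particle at focus center
    brightness_long: Optional[float]  # A*I; None when N2 = 0
    model_total_intensity: float  # counts/s predicted by the decomposition
    intensity_ratio: float  # model total / measured total
    gamma: float = GAMMA_3DG


def derived_quantities(
    fit: TwoComponentFit,
    curve: CorrelationCurve,
    background_rate: float = 0.0,
) -> DerivedQuantities:
    """Anchor per-particle brightnesses to the measured count rate.

    The mean detected rate of the model is gamma * (I N1 + A I N2) +
    background with gamma = 2^(-3/2), the mean detection-profile value of
    the 3D Gaussian volume, so I follows from the measured
    ``curve.total_intensity``.  The recombined model total is checked
    against the measurement and the ratio reported.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; derived quantities undefined")
    p = fit.params
    signal = curve.total_intensity - background_rate
    if signal <= 0:
        raise ValueError("no signal above background")
    two = p.n2 is not None and p.n2 > 0
    weight = p.n1 + (p.brightness_factor * p.n2 if two else 0.0)
    if weight <= 0:
        raise ValueError("zero total particle weight")
    bright = signal / (GAMMA_3DG * weight)
    model_total = GAMMA_3DG * bright * weight + background_rate
    return DerivedQuantities(
        n1=p.n1,
        n2=p.n2 if p.n2 is not None else None,
        brightness_short=bright,
        brightness_long=p.brightness_factor * bright if two else None,
        model_total_intensity=model_total,
        intensity_ratio=model_total / curve.total_intensity,
    )
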