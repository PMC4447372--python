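"""Shared benchmark routines for the validation suite and the acceptance
script.

Each function generates its own inputs from an explicit seed, runs the
package end to end, and returns plain dictionaries of measured
quantities.  Problem sizes default to the scales used in the validation
suite; the docstrings state them so reported numbers are reproducible.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
from scipy import stats as sps

from .correlator import CorrelationCurve, autocorrelate, autocorrelate_bruteforce
from .fcs_models import (
    ModelParams,
    fit_one_component,
    fit_two_component,
    model_curve,
    select_model,
)
from .frap import fit_frap
from .pipeline import default_study_config, run_study
from .stats import paired_ttest, unpaired_ttest
from .synthetic_data import (
    DriftSpec,
    PhotonTrace,
    SimulationConfig,
    SpeciesSpec,
    add_drift,
    simulate_frap_curve,
    simulate_trace,
)
from .trace_qc import detect_spine_motion

#: two-species study regime: published diffusion times, equal-mass number
#: split, Rouse-scale brightness ratio (see docs/methods.md)
STUDY_TRUTH = ModelParams(
    tau1=4.1e-3,
    tau2=0.467,
    n1=40.0,
    n2=0.2,
    brightness=10000.0,
    brightness_factor=100.0,
)

HEAVY_BIN_WIDTH = 2e-4  # benchmark runs use a 200-us bin (methods note)

#: FRAP ground truths: stable/dynamic fractions before and after
#: potentiation; turnover time 20 s (not printed in the source text)
FRAP_BEFORE = (0.219, 0.642, 20.0)
FRAP_AFTER = (0.102, 0.786, 20.0)


def _truth_species(truth: ModelParams = STUDY_TRUTH):
    return [
        SpeciesSpec(truth.tau1, truth.n1, truth.brightness),
        SpeciesSpec(
            truth.tau2, truth.n2, truth.brightness * truth.brightness_factor
        ),
    ]


def correlator_oracle_check(seed: int) -> Dict[str, float]:
    """Multi-tau vs brute-force agreement on a 4096-bin Poisson trace, and
    the hand-computable alternating-trace values."""
    rng = np.random.default_rng(seed)
    trace = PhotonTrace(bin_width=1.0, counts=rng.poisson(3.0, size=4096))
    mt = autocorrelate(trace, max_lag=1024.0)
    lag_bins = np.round(mt.lags).astype(int)
    bf = autocorrelate_bruteforce(trace, list(lag_bins[:16]))
    max_diff = float(np.max(np.abs(mt.g[:16] - bf.g)))
    alt = PhotonTrace(bin_width=1.0, counts=np.array([2, 0] * 4))
    hand = autocorrelate_bruteforce(alt, [0, 1, 2])
    return {
        "max_abs_diff": max_diff,
        "hand_g0": float(hand.g[0]),
        "hand_g_lag1": float(hand.g[1]),
        "hand_g_lag2": float(hand.g[2]),
        "n_bins": 4096,
    }


def amplitude_check(
    seed: int, n_rep_single: int = 8, n_rep_two: int = 3,
    duration_single: float = 40.0, duration_two: float = 60.0,
) -> Dict[str, float]:
    """Small-lag amplitude identities over replicate traces.

    Single species (N = 5): mean over the first three lags of each of
    `n_rep_single` traces versus the model value (~1/5).  Two species
    (study regime, `n_rep_two` traces): first-lag g versus
    (N1 + A^2 N2)/(N1 + A N2)^2 decayed to that lag.  The standard error
    is taken across the independent replicate traces (floored by the
    per-trace segment estimate), which captures the slow-passage
    realization noise that per-trace segment errors underestimate.
    """
    k = 3
    singles, twos = [], []
    single_seg_se, two_seg_se = [], []
    model_single = model_two = None
    for r in range(n_rep_single):
        cfg1 = SimulationConfig(
            species=[SpeciesSpec(4.1e-3, 5.0, 10000.0)],
            duration=duration_single,
            bin_width=HEAVY_BIN_WIDTH,
            seed=seed + 2 * r,
        )
        c1 = autocorrelate(simulate_trace(cfg1), max_lag=2.0)
        model_single = float(
            np.mean(model_curve(c1.lags[:k], ModelParams(tau1=4.1e-3, n1=5.0)))
        )
        singles.append(float(np.mean(c1.g[:k])))
        single_seg_se.append(float(np.mean(c1.g_sd[:k])))
    for r in range(n_rep_two):
        cfg2 = SimulationConfig(
            species=_truth_species(),
            duration=duration_two,
            bin_width=HEAVY_BIN_WIDTH,
            seed=seed + 2 * r + 1,
        )
        c2 = autocorrelate(simulate_trace(cfg2), max_lag=10.0)
        model_two = float(np.mean(model_curve(c2.lags[:k], STUDY_TRUTH)))
        twos.append(float(np.mean(c2.g[:k])))
        two_seg_se.append(float(np.mean(c2.g_sd[:k])))

    def z(vals, expected, seg_se):
        # the spread over few replicates can fluctuate to near zero, so
        # floor the standard error with the per-trace segment estimate
        n = len(vals)
        se = max(
            np.std(vals, ddof=1) / np.sqrt(n), np.mean(seg_se) / np.sqrt(n)
        )
        return (np.mean(vals) - expected) / se, se

    single_z, single_se = z(singles, model_single, single_seg_se)
    two_z, two_se = z(twos, model_two, two_seg_se)
    return {
        "single_measured": float(np.mean(singles)),
        "single_expected": model_single,
        "single_se": float(single_se),
        "single_z": float(single_z),
        "two_measured": float(np.mean(twos)),
        "two_expected": model_two,
        "two_se": float(two_se),
        "two_z": float(two_z),
        "n_rep": n_rep_single,
    }


def recovery_benchmark(
    seed: int, n_traces: int = 20, duration: float = 120.0
) -> Dict[str, object]:
    """Seeded parameter-recovery study at the published before-treatment
    regime: `n_traces` independent traces of `duration` seconds, each
    correlated and fitted; success = diffusion times within +/-25% and
    particle numbers within +/-30% of the generating truth."""
    truth = {
        "tau1": STUDY_TRUTH.tau1,
        "tau2": STUDY_TRUTH.tau2,
        "n1": STUDY_TRUTH.n1,
        "n2": STUDY_TRUTH.n2,
    }
    tol = {"tau1": 0.25, "tau2": 0.25, "n1": 0.30, "n2": 0.30}
    errors = {k: [] for k in truth}
    rng = np.random.default_rng(seed)
    for _ in range(n_traces):
        cfg = SimulationConfig(
            species=_truth_species(),
            duration=duration,
            bin_width=HEAVY_BIN_WIDTH,
            seed=int(rng.integers(2**31)),
        )
        curve = autocorrelate(simulate_trace(cfg), max_lag=10.0)
        fit = fit_two_component(curve, fit_lag_window=(HEAVY_BIN_WIDTH, 1.0))
        for k, tv in truth.items():
            errors[k].append((getattr(fit.params, k) - tv) / tv)
    out: Dict[str, object] = {"n_traces": n_traces, "duration": duration}
    for k in truth:
        err = np.asarray(errors[k])
        out[f"{k}_rate"] = float(np.mean(np.abs(err) <= tol[k]))
        out[f"{k}_bias"] = float(np.mean(err))
        out[f"{k}_sd"] = float(np.std(err))
    return out


def _noisy_model_curve(params: ModelParams, rng) -> CorrelationCurve:
    """Model curve plus independent noise with the absolute profile
    measured on simulated traces (small at short lags, larger long)."""
    lags = []
    scale = 1
    base = 1e-4
    block = np.arange(1, 17)
    while True:
        cand = (block if scale == 1 else np.arange(9, 17)) * scale * base
        cand = cand[cand <= 10.0]
        if len(cand) == 0:
            break
        lags.append(cand)
        scale *= 2
    lags = np.concatenate(lags)
    g = model_curve(lags, params)
    # calibrated to the lag-local noise measured on simulated 120-s traces
    # at the study regime (short-lag floor ~2e-4, rising toward long lags)
    sd = 2e-4 + 5e-3 * (lags / lags[-1]) ** 0.5
    noisy = g + rng.normal(0.0, sd)
    return CorrelationCurve(
        lags=lags, g=noisy, g_sd=sd, total_intensity=1e5
    )


def selection_benchmark(seed: int, n_each: int = 20) -> Dict[str, float]:
    """Model-selection operating characteristics on noisy synthetic curves:
    fraction of two-component-truth curves where the one-component fit is
    rejected, and fraction of one-component-truth curves where it is
    accepted (F-test + runs test, alpha = 0.05)."""
    rng = np.random.default_rng(seed)
    one_truth = ModelParams(tau1=4.1e-3, n1=5.0)
    reject_two = accept_one = 0
    for _ in range(n_each):
        c2 = _noisy_model_curve(STUDY_TRUTH, rng)
        sel = select_model(fit_one_component(c2), fit_two_component(c2))
        reject_two += sel.n_components == 2
        c1 = _noisy_model_curve(one_truth, rng)
        sel = select_model(fit_one_component(c1), fit_two_component(c1))
        accept_one += sel.n_components == 1
    return {
        "two_component_detection_rate": reject_two / n_each,
        "one_component_acceptance_rate": accept_one / n_each,
        "n_each": n_each,
    }


def qc_benchmark(
    seed: int,
    n_each: int = 50,
    duration: float = 60.0,
    amplitude: float = 0.3,
    timescale: float = 5.0,
) -> Dict[str, float]:
    """Motion-QC operating characteristics on drifted/clean twin traces.

    `n_each` clean single-species traces (N = 5, 60 s, 0.5-ms bins) and
    their drift-contaminated twins (same underlying expectation, lognormal
    envelope of the given amplitude and timescale).  Curves use 20
    segments and a 6-s maximum lag: fine segmentation against a 5-s
    motion timescale keeps the between-segment floor honest, and the
    motion window then concentrates where the drift correlation is
    strong.
    """
    rng = np.random.default_rng(seed)
    flagged = passed = 0
    for _ in range(n_each):
        cfg = SimulationConfig(
            species=[SpeciesSpec(4.1e-3, 5.0, 10000.0)],
            duration=duration,
            bin_width=5e-4,
            seed=int(rng.integers(2**31)),
        )
        clean = simulate_trace(cfg)
        drifted = add_drift(
            clean,
            DriftSpec(amplitude=amplitude, timescale=timescale),
            seed=int(rng.integers(2**31)),
        )
        qc_clean = detect_spine_motion(
            autocorrelate(clean, max_lag=6.0, n_segments=20)
        )
        qc_drift = detect_spine_motion(
            autocorrelate(drifted, max_lag=6.0, n_segments=20)
        )
        passed += qc_clean.passed is True
        flagged += qc_drift.passed is False
    return {
        "sensitivity": flagged / n_each,
        "specificity": passed / n_each,
        "n_each": n_each,
    }


def frap_benchmark(
    seed: int,
    n_curves: int = 200,
    n_meta: int = 20,
    noise_sd: float = 0.05,
) -> Dict[str, float]:
    """FRAP estimator calibration and cohort separation.

    Bias of the stable-fraction estimate over `n_curves` noisy curves at
    each published truth (2-s sampling, 110-s post-bleach window), and the
    fraction of `n_meta` simulated cohort pairs (n = 16 before vs n = 19
    after) separated at p < 0.05 by the unpaired two-tailed t-test."""
    rng = np.random.default_rng(seed)
    biases = {}
    for label, (fs, ff, lam) in (("before", FRAP_BEFORE), ("after", FRAP_AFTER)):
        est = [
            fit_frap(
                simulate_frap_curve(
                    fs, ff, lam, noise_sd=noise_sd,
                    seed=int(rng.integers(2**31)),
                )
            ).stable_fraction
            for _ in range(n_curves)
        ]
        biases[label] = float(np.mean(est) - fs)
    separated = 0
    for _ in range(n_meta):
        fs_b = [
            fit_frap(
                simulate_frap_curve(
                    *FRAP_BEFORE, noise_sd=noise_sd,
                    seed=int(rng.integers(2**31)),
                )
            ).stable_fraction
            for _ in range(16)
        ]
        fs_a = [
            fit_frap(
                simulate_frap_curve(
                    *FRAP_AFTER, noise_sd=noise_sd,
                    seed=int(rng.integers(2**31)),
                )
            ).stable_fraction
            for _ in range(19)
        ]
        separated += unpaired_ttest(fs_b, fs_a).p < 0.05
    return {
        "fs_bias_before": biases["before"],
        "fs_bias_after": biases["after"],
        "cohort_separation_rate": separated / n_meta,
        "n_curves": n_curves,
        "n_meta": n_meta,
    }


def type1_benchmark(seed: int, n_rep: int = 2000, n_pairs: int = 8) -> Dict[str, float]:
    """Empirical type-I error of the paired test at alpha = 0.05 under the
    null, plus the maximum deviation from scipy on random inputs."""
    rng = np.random.default_rng(seed)
    d = rng.normal(size=(n_rep, n_pairs))
    t = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(n_pairs))
    p = 2 * sps.t.sf(np.abs(t), n_pairs - 1)
    spot = paired_ttest(np.zeros(n_pairs), d[0])
    assert abs(spot.p - p[0]) < 1e-12
    rate = float(np.mean(p < 0.05))

    max_diff = 0.0
    for _ in range(50):
        a = rng.normal(size=int(rng.integers(3, 25)))
        b = a + rng.normal(size=a.size)
        ours = paired_ttest(a, b)
        ref = sps.ttest_rel(b, a)
        max_diff = max(
            max_diff,
            abs(ours.statistic - ref.statistic),
            abs(ours.p - ref.pvalue),
        )
    return {"type1_rate": rate, "scipy_max_abs_diff": float(max_diff), "n_rep": n_rep}


STUDY_EFFECT_PARAMS = ("tau1", "tau2", "n2")
CONTROL_CONDITIONS = ("tea_no_growth", "untreated", "tea_ap5_verapamil")


def study_benchmark(
    seed: int, n_reps: int = 2, duration: float = 30.0
) -> Dict[str, object]:
    """End-to-end cohort study at published condition means.

    Runs `n_reps` full four-condition studies with `duration`-second
    traces and majority-votes each condition x parameter significance
    across replicates.  Reports the growing-spine p-values of the last
    replicate, the majority-vote detection flags, and the fraction of
    control-condition tests on tau1/tau2/N2 that reached significance.
    """
    votes: Dict[str, Dict[str, int]] = {}
    last = None
    control_sig = control_total = 0
    for rep in range(n_reps):
        report = run_study(
            default_study_config(seed=seed + rep, trace_duration=duration)
        )
        last = report
        for cond, sig in report.significant.items():
            for param in STUDY_EFFECT_PARAMS:
                votes.setdefault(cond, {}).setdefault(param, 0)
                votes[cond][param] += bool(sig[param])
                if cond in CONTROL_CONDITIONS:
                    control_total += 1
                    control_sig += bool(sig[param])
    majority = {
        cond: {p: (v > n_reps / 2.0) for p, v in d.items()}
        for cond, d in votes.items()
    }
    growth_tests = last.per_condition["tea_growth"]["tests"]
    out: Dict[str, object] = {
        "majority": majority,
        "control_significant_fraction": control_sig / max(control_total, 1),
        "n_reps": n_reps,
        "duration": duration,
    }
    for param in STUDY_EFFECT_PARAMS:
        t = growth_tests[param]
        out[f"tea_growth_p_{param}"] = float(t.p) if t is not None else np.nan
    return out
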