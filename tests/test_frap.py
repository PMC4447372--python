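"""FRAP: ROI processing corrections, turnover-model fitting identities,
and the empirical half-time definition."""

import numpy as np
import pytest

from spinefcs import (
    fit_frap,
    process_frap_rois,
    recovery_halftime_empirical,
    simulate_frap_curve,
)
from spinefcs.frap import FrapCurve, frap_model


class TestSimulateFrap:
    def test_plateau_and_monomer_fraction_before_tea_values(self):
        c = simulate_frap_curve(0.219, 0.642, 20.0, noise_sd=0.0, n_post=200)
        assert c.intensity[-1] == pytest.approx(1 - 0.219, abs=1e-3)
        assert c.intensity[c.n_prebleach] == pytest.approx(0.139, abs=1e-9)

    def test_full_recovery_limits(self):
        c = simulate_frap_curve(0.0, 1.0, 5.0, noise_sd=0.0, n_post=100)
        assert c.intensity[c.n_prebleach] == pytest.approx(0.0, abs=1e-12)
        assert c.intensity[-1] == pytest.approx(1.0, abs=1e-9)

    def test_overfull_fractions_rejected(self):
        with pytest.raises(ValueError):
            simulate_frap_curve(0.6, 0.5, 10.0)

    def test_determinism(self):
        a = simulate_frap_curve(0.2, 0.6, 20.0, seed=3)
        b = simulate_frap_curve(0.2, 0.6, 20.0, seed=3)
        np.testing.assert_array_equal(a.intensity, b.intensity)


class TestProcessRois:
    def test_inert_corrections(self):
        spine = np.array([10.0, 10, 10, 2, 4, 6, 8])
        out = process_frap_rois(spine, np.zeros(7), np.full(7, 50.0), 3)
        np.testing.assert_allclose(out.intensity, spine / 10.0)
        assert out.n_prebleach == 3
        assert out.time[3] == 0.0

    def test_reference_decay_corrected(self):
        # spine and reference decay identically -> corrected curve flat
        decay = np.linspace(1.0, 0.9, 10)
        out = process_frap_rois(100 * decay, np.zeros(10), 200 * decay, 4)
        np.testing.assert_allclose(out.intensity, 1.0, rtol=1e-12)

    def test_background_subtraction_roundtrip(self):
        truth = simulate_frap_curve(0.2, 0.6, 15.0, noise_sd=0.0, n_pre=4, n_post=40)
        bg = 7.0
        ref_decay = np.linspace(1.0, 0.85, len(truth.time))
        spine = 120.0 * truth.intensity * ref_decay + bg
        reference = 80.0 * ref_decay + bg
        out = process_frap_rois(spine, np.full_like(spine, bg), reference, 4)
        np.testing.assert_allclose(out.intensity, truth.intensity, rtol=1e-9)

    def test_reference_below_background_rejected(self):
        with pytest.raises(ValueError):
            process_frap_rois(np.ones(5), np.full(5, 2.0), np.full(5, 1.5), 2)


class TestFitFrap:
    @pytest.mark.parametrize(
        "fs,ff,mono",
        [(0.219, 0.642, 0.139), (0.102, 0.786, 0.112)],
        ids=["before-tea", "after-tea"],
    )
    def test_noiseless_exact_recovery(self, fs, ff, mono):
        c = simulate_frap_curve(fs, ff, 20.0, noise_sd=0.0, n_post=60)
        fit = fit_frap(c)
        assert fit.stable_fraction == pytest.approx(fs, abs=1e-6)
        assert fit.dynamic_fraction == pytest.approx(ff, abs=1e-6)
        assert fit.turnover_time == pytest.approx(20.0, rel=1e-5)
        assert fit.monomer_fraction == pytest.approx(mono, abs=1e-6)

    def test_model_identities_hold_exactly(self):
        c = simulate_frap_curve(0.3, 0.5, 12.0, noise_sd=0.03, seed=5)
        fit = fit_frap(c)
        assert fit.plateau == 1.0 - fit.stable_fraction
        assert fit.half_time == fit.turnover_time * np.log(2.0)
        total = fit.stable_fraction + fit.dynamic_fraction + fit.monomer_fraction
        assert total == pytest.approx(1.0, abs=1e-12)
        assert 0 <= fit.stable_fraction <= 1 and 0 <= fit.dynamic_fraction <= 1

    def test_no_dynamic_fraction_flags_lambda(self):
        c = simulate_frap_curve(0.4, 0.0, 20.0, noise_sd=0.0, n_post=30)
        fit = fit_frap(c)
        assert not fit.lambda_identifiable
        assert fit.stable_fraction == pytest.approx(0.4, abs=1e-4)


class TestHalftime:
    def test_noiseless_equals_lambda_ln2(self):
        c = simulate_frap_curve(0.2, 0.6, 20.0, noise_sd=0.0, n_post=200, dt=0.25)
        fit = fit_frap(c)
        half = recovery_halftime_empirical(c, plateau=fit.plateau)
        assert half.status == "ok"
        assert half.seconds == pytest.approx(20.0 * np.log(2), abs=0.3)

    def test_coarse_sampling_within_one_step(self):
        c = simulate_frap_curve(0.0, 1.0, 1.0, noise_sd=0.0, n_post=30, dt=2.0)
        half = recovery_halftime_empirical(c, plateau=1.0)
        assert half.status in ("ok", "immediate")
        assert abs(half.seconds - np.log(2)) <= 2.0

    def test_never_crossing_flagged(self):
        curve = FrapCurve(
            time=np.array([-2.0, 0.0, 2.0, 4.0]),
            intensity=np.array([1.0, 0.2, 0.25, 0.3]),
            n_prebleach=1,
        )
        half = recovery_halftime_empirical(curve, plateau=0.9)
        assert half.status == "not_reached" and np.isnan(half.seconds)

    def test_already_recovered_is_immediate(self):
        curve = FrapCurve(
            time=np.array([-2.0, 0.0, 2.0]),
            intensity=np.array([1.0, 0.95, 0.96]),
            n_prebleach=1,
        )
        half = recovery_halftime_empirical(curve, plateau=0.9)
        assert half.status == "immediate" and half.seconds == 0.0


def test_frap_model_closed_form():
    t = np.array([0.0, 10.0, np.log(2) * 20.0])
    f = frap_model(t, 0.2, 0.6, 20.0)
    np.testing.assert_allclose(f[0], 0.2)
    np.testing.assert_allclose(f[2], 0.8 - 0.3)
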