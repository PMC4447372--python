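"""Diffusion-model math, fitting on noiseless and noisy curves, model
selection and the derived brightness/number decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinefcs import (
    CorrelationCurve,
    ModelParams,
    derived_quantities,
    fit_one_component,
    fit_two_component,
    model_component,
    model_curve,
    rouse_size_ratio,
    select_model,
)
from spinefcs.synthetic_data import GAMMA_3DG

TWO_COMP_TRUTH = ModelParams(
    tau1=4.1e-3, tau2=0.467, n1=40.0, n2=0.2, brightness_factor=100.0
)


def multitau_lags(base=1e-4, max_lag=10.0):
    lags = [np.arange(1, 17) * base]
    scale = 2
    while True:
        block = np.arange(9, 17) * scale * base
        if block[0] > max_lag:
            break
        lags.append(block[block <= max_lag])
        scale *= 2
    return np.concatenate(lags)


def make_curve(params, noise_profile=None, seed=0, intensity=6e4):
    lags = multitau_lags()
    g = model_curve(lags, params)
    if noise_profile is None:
        sd = np.full(len(lags), 1e-6)
        noisy = g
    else:
        # absolute noise rising toward long lags, mimicking measured curves
        sd = noise_profile[0] + noise_profile[1] * (lags / lags[-1]) ** 0.5
        noisy = g + np.random.default_rng(seed).normal(0.0, sd)
    return CorrelationCurve(
        lags=lags, g=noisy, g_sd=sd, total_intensity=intensity
    )


class TestModelComponent:
    def test_normalized_at_zero_lag(self):
        assert model_component(0.0, 1e-3, 0.16) == 1.0

    def test_half_at_tau_d_without_axial_term(self):
        assert model_component(2e-3, 2e-3, 0.0) == pytest.approx(0.5)

    def test_closed_form_with_unit_shape(self):
        assert model_component(1.0, 1.0, 1.0) == pytest.approx(1 / (2 * np.sqrt(2)))

    def test_linear_axial_variant(self):
        assert model_component(1.0, 1.0, 1.0, axial="linear") == pytest.approx(0.25)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            model_component(1.0, -1.0, 0.16)
        with pytest.raises(ValueError):
            model_component(-1.0, 1.0, 0.16)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        tau_d=st.floats(min_value=1e-4, max_value=1.0),
        shape=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_strictly_decreasing(self, tau_d, shape):
        taus = np.logspace(-5, 1, 50)
        m = model_component(taus, tau_d, shape)
        assert np.all(np.diff(m) < 0)


class TestModelCurve:
    def test_single_species_amplitude(self):
        p = ModelParams(tau1=4.1e-3, n1=5.0)
        assert model_curve([0.0], p)[0] == pytest.approx(0.2)

    def test_two_component_reduces_to_one_when_n2_zero(self):
        lags = np.logspace(-4, 0, 50)
        one = ModelParams(tau1=3e-3, n1=4.0)
        two = ModelParams(tau1=3e-3, tau2=0.4, n1=4.0, n2=0.0, brightness_factor=50.0)
        np.testing.assert_array_equal(model_curve(lags, one), model_curve(lags, two))

    def test_equal_species_merge(self):
        lags = np.logspace(-4, 0, 30)
        merged = ModelParams(
            tau1=5e-3, tau2=5.000001e-3, n1=3.0, n2=3.0, brightness_factor=1.0
        )
        expected = model_component(lags, 5e-3, 0.16) / 6.0
        np.testing.assert_allclose(model_curve(lags, merged), expected, rtol=1e-5)

    def test_brightness_weighted_amplitude_hand_value(self):
        p = ModelParams(tau1=1e-3, tau2=1.0, n1=4.0, n2=1.0, brightness_factor=10.0)
        assert model_curve([0.0], p)[0] == pytest.approx(104 / 196)

    def test_independent_of_absolute_brightness(self):
        lags = np.logspace(-4, 0, 20)
        dim = ModelParams(
            tau1=1e-3, tau2=0.2, n1=2.0, n2=0.5, brightness=100.0,
            brightness_factor=20.0,
        )
        bright = ModelParams(
            tau1=1e-3, tau2=0.2, n1=2.0, n2=0.5, brightness=1e6,
            brightness_factor=20.0,
        )
        np.testing.assert_array_equal(model_curve(lags, dim), model_curve(lags, bright))

    def test_empty_mixture_rejected(self):
        with pytest.raises(ValueError):
            model_curve([0.0], ModelParams(tau1=1e-3, n1=0.0))


class TestFitNoiseless:
    def test_two_component_recovery_at_published_values(self):
        fit = fit_two_component(make_curve(TWO_COMP_TRUTH))
        p = fit.params
        assert p.tau1 == pytest.approx(4.1e-3, rel=1e-3)
        assert p.tau2 == pytest.approx(0.467, rel=1e-3)
        assert p.n1 == pytest.approx(40.0, rel=1e-3)
        assert p.n2 == pytest.approx(0.2, rel=1e-3)
        assert fit.converged

    def test_one_component_exact(self):
        truth = ModelParams(tau1=4.1e-3, n1=5.0)
        fit = fit_one_component(make_curve(truth))
        assert fit.params.tau1 == pytest.approx(4.1e-3, rel=1e-6)
        assert fit.params.n1 == pytest.approx(5.0, rel=1e-6)

    def test_one_component_amplitude_matches_small_lag_plateau(self):
        truth = ModelParams(tau1=5e-3, n1=8.0)
        curve = make_curve(truth)
        fit = fit_one_component(curve)
        # the first lag sits at tau/tau_d = 0.02, so the plateau is ~2% decayed
        assert 1.0 / fit.params.n1 == pytest.approx(curve.g[0], rel=0.03)

    def test_two_component_fit_collapses_on_single_species(self):
        fit = fit_two_component(make_curve(ModelParams(tau1=4.1e-3, n1=5.0)))
        a1, a2 = fit.amplitudes
        collapsed = min(a1, a2) < 1e-3 * max(a1, a2)
        close_taus = fit.params.tau2 / fit.params.tau1 < 3.0
        assert collapsed or close_taus

    def test_rouse_closure_option(self):
        fit = fit_two_component(
            make_curve(TWO_COMP_TRUTH), brightness_factor="rouse"
        )
        assert fit.params.brightness_factor == pytest.approx(
            0.467 / 4.1e-3, rel=1e-2
        )

    def test_brightness_factor_bound_respected(self):
        truth = ModelParams(
            tau1=1e-3, tau2=0.9, n1=10.0, n2=0.1, brightness_factor=150.0
        )
        fit = fit_two_component(make_curve(truth), brightness_factor="rouse")
        assert 0 <= fit.params.brightness_factor <= 150.0


NOISE = (5e-4, 5e-3)  # short-lag floor and long-lag rise, absolute in g


class TestSelectModel:
    def test_two_component_truth_selected(self):
        curve = make_curve(TWO_COMP_TRUTH, noise_profile=NOISE, seed=1)
        sel = select_model(fit_one_component(curve), fit_two_component(curve))
        assert sel.n_components == 2
        assert sel.f_pvalue < 0.05 and sel.runs_pvalue < 0.05

    def test_one_component_truth_selected(self):
        curve = make_curve(
            ModelParams(tau1=4.1e-3, n1=5.0), noise_profile=NOISE, seed=2
        )
        sel = select_model(fit_one_component(curve), fit_two_component(curve))
        assert sel.n_components == 1

    def test_equal_fits_prefer_parsimony(self):
        curve = make_curve(ModelParams(tau1=4.1e-3, n1=5.0))
        fit1 = fit_one_component(curve)
        fit2 = fit_one_component(curve)
        fit2.n_components = 2
        sel = select_model(fit1, fit2)
        assert sel.n_components == 1

    def test_mismatched_windows_rejected(self):
        curve = make_curve(TWO_COMP_TRUTH)
        f1 = fit_one_component(curve, fit_lag_window=(1e-4, 0.5))
        f2 = fit_two_component(curve, fit_lag_window=(1e-4, 1.0))
        with pytest.raises(ValueError):
            select_model(f1, f2)


class TestRouse:
    @pytest.mark.parametrize(
        "ref,new,expected",
        [(0.467, 0.176, 2.6534), (4.1e-3, 1.7e-3, 2.4118), (0.3, 0.3, 1.0)],
    )
    def test_size_ratios(self, ref, new, expected):
        assert rouse_size_ratio(ref, new) == pytest.approx(expected, rel=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rouse_size_ratio(-1.0, 2.0)


class TestDerivedQuantities:
    def test_one_component_brightness_from_intensity(self):
        curve = make_curve(ModelParams(tau1=4.1e-3, n1=5.0), intensity=5e4)
        fit = fit_one_component(curve)
        d = derived_quantities(fit, curve)
        # observed counts per molecule: gamma * peak brightness = rate / N
        assert d.brightness_short * GAMMA_3DG == pytest.approx(1e4, rel=1e-3)
        assert d.brightness_long is None
        assert d.intensity_ratio == pytest.approx(1.0)

    def test_two_component_brightness_ratio(self):
        curve = make_curve(TWO_COMP_TRUTH, intensity=6e4)
        fit = fit_two_component(curve)
        d = derived_quantities(fit, curve)
        assert d.brightness_long / d.brightness_short == pytest.approx(100.0)

    def test_background_subtracted(self):
        curve = make_curve(ModelParams(tau1=4.1e-3, n1=5.0), intensity=5e4)
        fit = fit_one_component(curve)
        d = derived_quantities(fit, curve, background_rate=1e4)
        assert d.brightness_short * GAMMA_3DG == pytest.approx(8e3, rel=1e-3)

    def test_unconverged_fit_rejected(self):
        curve = make_curve(ModelParams(tau1=4.1e-3, n1=5.0))
        fit = fit_one_component(curve)
        fit.converged = False
        with pytest.raises(ValueError):
            derived_quantities(fit, curve)
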