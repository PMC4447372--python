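"""Trace generator: count-rate calibration, amplitude 1/N, determinism,
drift behavior and input validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinefcs import (
    DriftSpec,
    FocalVolumeSpec,
    SimulationConfig,
    SpeciesSpec,
    add_drift,
    autocorrelate,
    simulate_trace,
)
from spinefcs.synthetic_data import GAMMA_3DG, effective_volume


class TestSpecs:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"diffusion_time": -1.0, "mean_number": 1, "brightness": 1},
            {"diffusion_time": 1.0, "mean_number": -2, "brightness": 1},
            {"diffusion_time": 1.0, "mean_number": 1, "brightness": -5},
            {"diffusion_time": np.inf, "mean_number": 1, "brightness": 1},
        ],
    )
    def test_invalid_species_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SpeciesSpec(**kwargs)

    def test_volume_shape_parameter_defaults_to_aspect_squared(self):
        vol = FocalVolumeSpec(lateral_extent=200.0, axial_extent=500.0)
        assert vol.shape_parameter == pytest.approx(0.16)

    def test_axial_must_exceed_lateral(self):
        with pytest.raises(ValueError):
            FocalVolumeSpec(lateral_extent=500.0, axial_extent=200.0)

    def test_box_scale_floor(self):
        with pytest.raises(ValueError):
            SimulationConfig(species=[], box_scale=4.0)

    def test_drift_timescale_must_exceed_one_second(self):
        with pytest.raises(ValueError):
            DriftSpec(amplitude=0.2, timescale=0.5)

    def test_effective_volume_closed_form(self):
        vol = FocalVolumeSpec(200.0, 500.0)
        expected = (np.pi / 2) ** 1.5 * 200.0**2 * 500.0
        assert effective_volume(vol) == pytest.approx(expected)


class TestSimulateTrace:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(
            species=[SpeciesSpec(2e-3, 3.0, 2000.0)], duration=5.0, seed=11
        )
        a = simulate_trace(cfg)
        b = simulate_trace(cfg)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_different_seed_differs(self):
        base = dict(species=[SpeciesSpec(2e-3, 3.0, 2000.0)], duration=5.0)
        a = simulate_trace(SimulationConfig(seed=1, **base))
        b = simulate_trace(SimulationConfig(seed=2, **base))
        assert not np.array_equal(a.counts, b.counts)

    def test_mean_rate_matches_gamma_calibration(self):
        """Mean rate = background + sum N * brightness * 2^(-3/2)."""
        cfg = SimulationConfig(
            species=[SpeciesSpec(4.1e-3, 5.0, 3000.0)],
            duration=30.0,
            bin_width=5e-4,
            background_rate=500.0,
            seed=8,
        )
        tr = simulate_trace(cfg)
        expected = 500.0 + 5.0 * 3000.0 * GAMMA_3DG
        n = len(tr.counts)
        # allow 3 standard errors plus the finite-box concentration rounding
        sem = np.std(tr.counts) / np.sqrt(n) / tr.bin_width
        assert abs(tr.mean_rate - expected) < 3 * sem + 0.02 * expected

    @pytest.mark.parametrize("n_particles", [1.0, 5.0, 20.0])
    def test_small_lag_amplitude_near_one_over_n(self, n_particles):
        cfg = SimulationConfig(
            species=[SpeciesSpec(2e-3, n_particles, 8000.0)],
            duration=40.0,
            bin_width=2e-4,
            seed=int(n_particles),
        )
        curve = autocorrelate(simulate_trace(cfg), max_lag=2.0)
        short = curve.lags <= 4e-4
        measured = float(np.mean(curve.g[short]))
        assert measured == pytest.approx(1.0 / n_particles, rel=0.25)

    def test_background_only_trace_is_flat(self):
        cfg = SimulationConfig(
            species=[], duration=20.0, bin_width=1e-3,
            background_rate=5000.0, seed=3,
        )
        curve = autocorrelate(simulate_trace(cfg), max_lag=5.0)
        z = np.abs(curve.g) / np.where(curve.g_sd > 0, curve.g_sd, np.inf)
        assert np.mean(z <= 3.0) >= 0.9

    def test_short_duration_warning_recorded(self):
        cfg = SimulationConfig(
            species=[SpeciesSpec(1.0, 1.0, 100.0)], duration=5.0,
            bin_width=1e-2, seed=0,
        )
        tr = simulate_trace(cfg)
        assert any("slowest diffusion" in w for w in tr.metadata["warnings"])


class TestAddDrift:
    def test_zero_amplitude_is_identity(self, single_species_trace):
        out = add_drift(single_species_trace, DriftSpec(0.0, 5.0), seed=1)
        assert out is single_species_trace

    def test_mean_rate_preserved(self, single_species_trace):
        out = add_drift(single_species_trace, DriftSpec(0.3, 5.0), seed=2)
        assert out.mean_rate == pytest.approx(single_species_trace.mean_rate, rel=0.25)

    def test_long_lag_plateau_appears(self, single_species_trace):
        out = add_drift(single_species_trace, DriftSpec(0.3, 5.0), seed=3)
        c = autocorrelate(out, max_lag=7.0)
        win = c.window(1.0, 7.0)
        assert np.mean(c.g[win]) > 0.01

    def test_metadata_records_drift(self, single_species_trace):
        out = add_drift(single_species_trace, DriftSpec(0.2, 3.0), seed=4)
        assert out.metadata["drift"]["amplitude"] == 0.2


@settings(deadline=None, max_examples=10, derandomize=True)
@given(
    fs=st.floats(min_value=0.0, max_value=0.5),
    ff=st.floats(min_value=0.0, max_value=0.5),
    lam=st.floats(min_value=1.0, max_value=100.0),
)
def test_frap_simulation_respects_model_bounds(fs, ff, lam):
    from spinefcs import simulate_frap_curve

    c = simulate_frap_curve(fs, ff, lam, noise_sd=0.0, n_pre=3, n_post=50)
    post = c.intensity[c.n_prebleach :]
    assert post[0] == pytest.approx(1 - fs - ff, abs=1e-9)
    assert np.all(np.diff(post) >= -1e-12)  # noiseless recovery is monotone
    assert post[-1] <= 1 - fs + 1e-9
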