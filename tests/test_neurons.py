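"""LIF rate curve, gain/bias inversion, spiking dynamics, encoders."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nefsim.neurons import (
    LIFParams,
    LIFState,
    gain_bias,
    lif_rate,
    lif_step,
    sample_encoders,
    tuning_curves,
)


class TestLIFRate:
    def test_subthreshold_is_silent(self, lif):
        assert lif_rate(0.5, lif) == 0.0
        assert lif_rate(1.0, lif) == 0.0

    def test_closed_form_at_twice_threshold(self, lif):
        # 1 / (tau_ref + tau_rc * ln 2) with the default constants
        expected = 1.0 / (0.002 + 0.02 * np.log(2.0))
        assert lif_rate(2.0, lif) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(63.04000219, rel=1e-8)

    def test_refractory_ceiling(self, lif):
        assert lif_rate(1e12, lif) == pytest.approx(1.0 / lif.tau_ref, rel=1e-3)
        assert lif_rate(1e12, lif) < 1.0 / lif.tau_ref

    def test_strictly_increasing_above_threshold(self, lif):
        J = np.linspace(1.001, 10, 500)
        rates = lif_rate(J, lif)
        assert np.all(np.diff(rates) > 0)


class TestGainBias:
    def test_constraints_hold_at_both_ends(self, lif):
        gain, bias = gain_bias(400.0, 0.0, lif)
        assert lif_rate(gain * 1.0 + bias, lif) == pytest.approx(400.0, abs=1e-6)
        # current at the intercept sits exactly at the threshold
        assert gain * 0.0 + bias == pytest.approx(1.0, abs=1e-12)

    def test_larger_intercept_gives_steeper_gain(self, lif):
        g_low, _ = gain_bias(300.0, 0.0, lif)
        g_high, _ = gain_bias(300.0, 0.9, lif)
        assert g_high > g_low

    def test_unreachable_rate_rejected(self, lif):
        with pytest.raises(ValueError, match="ceiling"):
            gain_bias(600.0, 0.0, lif)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        max_rate=st.floats(min_value=5.0, max_value=499.0),
        intercept=st.floats(min_value=-0.999, max_value=0.999),
    )
    def test_round_trip_over_parameter_space(self, max_rate, intercept):
        params = LIFParams(1)
        gain, bias = gain_bias(max_rate, intercept, params)
        assert gain > 0
        assert lif_rate(gain + bias, params) == pytest.approx(max_rate, abs=1e-6)
        assert gain * intercept + bias == pytest.approx(1.0, abs=1e-9)


class TestLIFStep:
    def test_no_drive_no_spikes(self, lif):
        state = LIFState.zeros(lif.n_neurons)
        total = 0.0
        for _ in range(100):
            _, spikes = lif_step(state, np.zeros(lif.n_neurons), 0.001, lif)
            total += spikes.sum()
        assert total == 0.0

    def test_constant_drive_matches_analytic_rate(self, lif):
        params = LIFParams(1)
        state = LIFState.zeros(1)
        J = np.array([1.5])
        dt, T = 0.001, 10.0
        count = 0.0
        for _ in range(int(T / dt)):
            _, spikes = lif_step(state, J, dt, params)
            count += spikes[0] * dt
        measured = count / T
        assert measured == pytest.approx(lif_rate(1.5, params), rel=0.02)

    def test_refractory_clamps_voltage(self):
        params = LIFParams(1, tau_ref=0.005)
        state = LIFState(np.array([0.0]), np.array([0.004]))
        lif_step(state, np.array([100.0]), 0.001, params)
        # most of the step is refractory: voltage barely integrates
        assert state.voltage[0] < 5.0
        state2 = LIFState(np.array([0.0]), np.array([0.0]))
        lif_step(state2, np.array([100.0]), 0.001, params)
        assert state2.refractory_time[0] > 0  # it spiked and entered refractory

    def test_spike_impulse_has_area_one(self, lif):
        params = LIFParams(1)
        state = LIFState(np.array([0.999]), np.array([0.0]))
        _, spikes = lif_step(state, np.array([5.0]), 0.001, params)
        assert spikes[0] == pytest.approx(1.0 / 0.001)
        assert state.voltage[0] == 0.0


class TestEncoders:
    def test_one_dimensional_encoders_are_signs(self):
        enc = sample_encoders(100, 1, 0)
        assert set(np.unique(enc)) <= {-1.0, 1.0}

    def test_rows_have_unit_norm(self):
        enc = sample_encoders(500, 7, 42)
        assert np.allclose(np.linalg.norm(enc, axis=1), 1.0, atol=1e-12)

    def test_mean_direction_vanishes_on_sphere(self):
        enc = sample_encoders(10000, 3, 7)
        assert np.all(np.abs(enc.mean(axis=0)) < 0.03)

    def test_same_seed_bit_identical(self):
        assert np.array_equal(sample_encoders(50, 4, 9), sample_encoders(50, 4, 9))


class TestTuningCurves:
    @pytest.fixture
    def resolved(self):
        from nefsim.builder import resolve_ensemble
        from nefsim.model import EnsembleSpec

        ens = EnsembleSpec("e", LIFParams(30), 2, radius=1.5)
        return resolve_ensemble(ens, np.random.default_rng(0))

    def test_nonnegative_everywhere(self, resolved, rng):
        x = rng.uniform(-1.5, 1.5, size=(200, 2))
        assert np.all(tuning_curves(resolved, x) >= 0)

    def test_max_rate_attained_along_encoder_at_radius(self, resolved):
        for j in range(5):
            x = resolved.encoders[j] * resolved.radius
            rate = tuning_curves(resolved, x[None, :])[0, j]
            assert rate == pytest.approx(resolved.max_rates[j], abs=1e-6)

    def test_silent_at_and_below_intercept(self, resolved):
        j = int(np.argmax(resolved.intercepts))
        x = resolved.encoders[j] * resolved.radius * (resolved.intercepts[j] - 0.01)
        assert tuning_curves(resolved, x[None, :])[0, j] == 0.0
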