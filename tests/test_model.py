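"""Oscillator drift, Euler-Maruyama integration, and convergence."""

import numpy as np
import pytest

from eegosc.model import (
    OscillatorParams,
    OscillatorState,
    SimulationConfig,
    SimulationBlowUp,
    convergence_check,
    drift,
    simulate_em,
)


class TestDrift:
    def test_origin_is_equilibrium(self, feasible_params):
        d = drift(OscillatorState(), feasible_params)
        assert d == (0.0, 0.0, 0.0, 0.0)

    def test_relative_displacement_terms_vanish_when_positions_equal(self):
        """With x1 == x2 the cubic coupling does not depend on b2."""
        state = OscillatorState(1.0, 0.0, 1.0, 0.0)
        base = dict(k1=2.0, k2=1.0, b1=1.0, eps1=1.0, eps2=1.0, mu=0.0)
        d_small = drift(state, OscillatorParams(b2=1e-3, **base))
        d_large = drift(state, OscillatorParams(b2=1e3, **base))
        assert d_small == d_large

    def test_hand_evaluated_accelerations(self):
        state = OscillatorState(1.0, 0.0, 0.0, 0.0)
        params = OscillatorParams(k1=2, k2=1, b1=1, b2=1, eps1=1, eps2=1, mu=0)
        dx1, dv1, dx2, dv2 = drift(state, params)
        assert (dx1, dx2) == (0.0, 0.0)
        assert dv1 == -5.0  # -(k1+k2)*1 - b1 - b2
        assert dv2 == 2.0   # k2*1 + b2

    def test_nonfinite_state_rejected(self):
        with pytest.raises(ValueError):
            OscillatorState(np.nan, 0.0, 0.0, 0.0)


class TestSimulate:
    def test_zero_noise_zero_state_gives_zero_output(self, feasible_params):
        params = OscillatorParams(**{**feasible_params.as_dict(), "mu": 0.0})
        block = simulate_em(params, SimulationConfig(duration=2.0, burn_in=0.0))
        assert np.all(block.data == 0.0)

    def test_seed_determinism(self, feasible_params, short_cfg):
        a = simulate_em(feasible_params, short_cfg)
        b = simulate_em(feasible_params, short_cfg)
        assert np.array_equal(a.data, b.data)

    def test_different_seeds_differ(self, feasible_params, short_cfg):
        from dataclasses import replace
        a = simulate_em(feasible_params, short_cfg)
        b = simulate_em(feasible_params, replace(short_cfg, seed=1))
        assert not np.array_equal(a.data, b.data)

    def test_output_length_and_rate(self, feasible_params):
        cfg = SimulationConfig(duration=8.0, fs=125.0)
        block = simulate_em(feasible_params, cfg)
        assert block.n_samples == 1000
        assert block.fs == 125.0

    def test_linear_limit_matches_analytic_eigenfrequencies(self):
        """With negligible nonlinearity the spectrum peaks at the
        eigenfrequencies of the linear stiffness matrix, within 1 bin."""
        k1, k2 = 7286.5, 4523.5
        params = OscillatorParams(k1, k2, 1e-8, 1e-8, 1e-8, 1e-8, 0.0)
        cfg = SimulationConfig(
            duration=8.0, burn_in=0.0, substeps=100,
            initial_state=OscillatorState(1.0, 0.0, 0.0, 0.0),
        )
        block = simulate_em(params, cfg)
        stiffness = np.array([[k1 + k2, -k2], [-k2, k2]])
        eig = np.sort(np.linalg.eigvalsh(stiffness))
        expected = np.sqrt(eig) / (2 * np.pi)

        from scipy.signal import find_peaks

        # Hann window against leakage; fine substeps keep the explicit
        # scheme's spurious high-mode amplification (growth ~ (w*h)^2/2
        # per step for an undamped mode) from burying the low mode
        spec = np.abs(np.fft.rfft(block.data * np.hanning(block.n_samples)))
        freqs = np.fft.rfftfreq(block.n_samples, d=1 / cfg.fs)
        df = freqs[1] - freqs[0]
        peaks, _ = find_peaks(spec, distance=int(2.0 / df),
                              height=spec.max() * 1e-4)
        top2 = sorted(sorted(peaks, key=lambda i: -spec[i])[:2])
        measured = freqs[top2]
        assert np.all(np.abs(measured - expected) <= df + 1e-9)

    def test_van_der_pol_limit_cycle_is_bounded_and_stable(self):
        """A single nearly-uncoupled van der Pol oscillator settles to a
        bounded periodic orbit from a small start (no blow-up over ~100
        periods, stable amplitude)."""
        params = OscillatorParams(100.0, 1e-6, 1e-10, 1e-10, 5.0, 1e-10, 0.0)
        period = 2 * np.pi / np.sqrt(100.0)
        cfg = SimulationConfig(
            duration=100 * period, burn_in=0.0, output_channel="x1",
            initial_state=OscillatorState(0.1, 0.0, 0.0, 0.0),
        )
        x = simulate_em(params, cfg).data
        n = x.size
        # amplitude of the last two quarters agree and are O(2)
        a1 = np.max(np.abs(x[n // 2: 3 * n // 4]))
        a2 = np.max(np.abs(x[3 * n // 4:]))
        assert 1.0 < a1 < 3.0
        assert abs(a1 - a2) / a1 < 0.05

    def test_output_variance_nondecreasing_in_noise(self, feasible_params):
        mus = [0.2, 1.0, 2.0]
        means = []
        for mu in mus:
            params = OscillatorParams(**{**feasible_params.as_dict(), "mu": mu})
            vs = [np.var(simulate_em(
                params, SimulationConfig(duration=4.0, burn_in=1.0, seed=s)).data)
                for s in range(20)]
            means.append(np.mean(vs))
        assert means[0] <= means[1] <= means[2]

    def test_blowup_raises_with_step_index(self):
        params = OscillatorParams(1e4, 1e4, 5e3, 5e3, 3333.0, 3333.0, 2.0)
        cfg = SimulationConfig(duration=4.0, seed=0,
                               initial_state=OscillatorState(1.0, 0, 0, 0))
        with pytest.raises(SimulationBlowUp) as err:
            simulate_em(params, cfg)
        assert err.value.step >= 0
        assert err.value.params is params


class TestConvergence:
    def test_deterministic_euler_is_first_order(self):
        """Order-1 signature against the 8x-refined self reference: a
        global error C*h gives endpoint errors proportional to
        (h - h/8) : (h/2 - h/8) : (h/4 - h/8) = 7 : 3 : 1, i.e. ratios
        7/3 and 3 between successive refinements."""
        params = OscillatorParams(100.0, 30.0, 5.0, 2.0, 2.0, 1.0, 0.0)
        cfg = SimulationConfig(
            duration=1.0, seed=3,
            initial_state=OscillatorState(0.5, 0.0, 0.2, 0.0))
        table = convergence_check(params, cfg, horizon=1.0)
        err = table["endpoint_error"].to_numpy()
        assert err[0] / err[1] == pytest.approx(7 / 3, rel=0.15)
        assert err[1] / err[2] == pytest.approx(3.0, rel=0.15)

    def test_stochastic_strong_error_shrinks_with_step(self, feasible_params):
        cfg = SimulationConfig(duration=1.0, seed=5)
        table = convergence_check(feasible_params, cfg, horizon=1.0)
        err = table["endpoint_error"].to_numpy()
        assert err[0] > err[1] > err[2] > 0

    def test_zero_dynamics_zero_error(self):
        params = OscillatorParams(1e-8, 1e-8, 1e-8, 1e-8, 1e-8, 1e-8, 0.0)
        table = convergence_check(params, SimulationConfig(seed=1), horizon=0.5)
        assert np.all(table["endpoint_error"].to_numpy() == 0.0)


class TestParams:
    def test_nonpositive_stiffness_rejected(self):
        with pytest.raises(ValueError):
            OscillatorParams(0.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.5)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            OscillatorParams(1.0, 1.0, 1.0, 1.0, 1.0, 1.0, -0.1)

    def test_array_round_trip(self, feasible_params):
        arr = feasible_params.as_array()
        assert OscillatorParams.from_array(arr) == feasible_params
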