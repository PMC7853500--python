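"""Conductance-model core: kinetics, gating, delays, fixed points, integration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thalcort.model import (
    CHANNELS,
    FREE_CONNECTIONS,
    POPULATIONS,
    StateVector,
    build_default_model,
    find_steady_state,
    firing_rate,
    integrate,
    mg_block,
    state_derivative,
)

# standard normal CDF at 1, frozen from an independent erf series evaluation
_PHI_1 = 0.8413447460685429
# 1/(1 + 0.2 e^{3.6}), hand evaluation of the magnesium gate at -60 mV, alpha 0.06
_MG_M60 = 0.12019740902152373


class TestBuildDefaultModel:
    def test_printed_delays(self, default_spec):
        assert default_spec.delay_tc == 3.0
        assert default_spec.delay_ct == 8.0

    def test_free_mask_has_twelve_connections(self, default_spec):
        assert len(default_spec.free_mask) == 12
        assert set(default_spec.free_mask) == set(FREE_CONNECTIONS)

    def test_free_decays_are_glutamatergic(self, default_spec):
        assert default_spec.free_decay == ("AMPA", "NMDA")

    def test_override_passthrough(self):
        spec = build_default_model({"V_R": -45.0})
        assert spec.V_R == -45.0
        assert spec.delay_tc == 3.0

    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError, match="no_such_field"):
            build_default_model({"no_such_field": 1.0})

    def test_mh_channels_only_on_projection_and_relay(self, default_spec):
        for pop in POPULATIONS:
            has_mh = np.any(default_spec.mh_target[:, default_spec.index(pop)] > 0)
            assert has_mh == (pop in ("tp", "rl"))

    def test_invalid_channel_placement_rejected(self, default_spec):
        rng = np.random.default_rng(0)
        for _ in range(10):
            spec = build_default_model()
            pop = rng.choice([p for p in POPULATIONS if p not in ("tp", "rl")])
            spec.mh_target[rng.integers(2), spec.index(pop)] = 0.3
            with pytest.raises(ValueError, match="tp and rl"):
                spec.validate()

    def test_inhibitory_source_cannot_use_glutamate(self, default_spec):
        rng = np.random.default_rng(1)
        for _ in range(10):
            spec = build_default_model()
            src = rng.choice(["si", "di", "rt"])
            kind = rng.choice([CHANNELS.index("AMPA"), CHANNELS.index("NMDA")])
            spec.gains[kind, rng.integers(spec.n_pop), spec.index(src)] = 0.5
            with pytest.raises(ValueError, match="inhibitory"):
                spec.validate()

    def test_serialisation_round_trip(self, default_spec, tmp_path):
        import json

        from thalcort.model import ModelSpec

        d = default_spec.to_dict()
        path = tmp_path / "spec.json"
        path.write_text(json.dumps(d))
        back = ModelSpec.from_dict(json.loads(path.read_text()))
        assert back.populations == default_spec.populations
        np.testing.assert_array_equal(back.gains, default_spec.gains)
        np.testing.assert_array_equal(back.kappa, default_spec.kappa)
        assert back.free_mask == default_spec.free_mask


class TestFiringRate:
    def test_half_activation_at_threshold(self):
        for sigma in (1.0, 4.0, 10.0):
            assert firing_rate(-40.0, -40.0, sigma) == pytest.approx(0.5)

    def test_one_sigma_above_threshold(self):
        assert firing_rate(-36.0, -40.0, 4.0) == pytest.approx(_PHI_1, abs=1e-12)

    def test_lower_limit(self):
        assert firing_rate(-1e4, -40.0, 4.0) == 0.0

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ValueError):
            firing_rate(-40.0, -40.0, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-68, -26), st.floats(2, 20))
    def test_strictly_increasing(self, v, sigma):
        assert firing_rate(v + 0.5, -40.0, sigma) > firing_rate(v, -40.0, sigma)


class TestMgBlock:
    def test_value_at_zero(self):
        assert mg_block(0.0) == pytest.approx(1.0 / 1.2, abs=1e-15)

    def test_hand_evaluated_point(self):
        assert mg_block(-60.0, 0.06) == pytest.approx(_MG_M60, abs=1e-12)

    def test_saturates_at_depolarisation(self):
        assert mg_block(1e4) == pytest.approx(1.0)

    def test_monotone_on_grid(self):
        v = np.linspace(-100, 60, 1000)
        f = mg_block(v)
        assert np.all(np.diff(f) > 0)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            mg_block(0.0, alpha_nmda=-0.01)


def _decoupled_spec():
    spec = build_default_model()
    spec.gains[:] = 0.0
    spec.mh_target[:] = 0.0
    return spec


class TestStateDerivative:
    def test_leak_equilibrium(self):
        spec = _decoupled_spec()
        state = StateVector(V=np.full(8, spec.V_L), g=np.zeros((6, 8)))
        d = state_derivative(spec, state, lambda t: state, np.zeros(8))
        assert np.abs(d.V).max() == 0.0
        assert np.abs(d.g).max() == 0.0

    def test_ampa_driving_force_sign(self):
        spec = _decoupled_spec()
        g = np.zeros((6, 8))
        g[CHANNELS.index("AMPA"), 0] = 0.5
        state = StateVector(V=np.full(8, -70.0), g=g)
        d = state_derivative(spec, state, lambda t: state, np.zeros(8))
        assert d.V[0] > 0  # below the AMPA reversal, the current depolarises

    def test_nmda_gating_grows_with_depolarisation(self):
        spec = _decoupled_spec()
        g = np.zeros((6, 8))
        g[CHANNELS.index("NMDA"), 0] = 0.5
        i_n = CHANNELS.index("NMDA")
        vrev = spec.v_rev[i_n]

        def nmda_current(v):
            state = StateVector(V=np.full(8, v), g=g)
            d = state_derivative(spec, state, lambda t: state, np.zeros(8))
            # subtract the leak contribution to isolate the NMDA term
            leak = spec.g_L * (spec.V_L - v) / spec.C[0]
            return d.V[0] - leak

        assert abs(nmda_current(-30.0)) > abs(nmda_current(-80.0))
        assert nmda_current(-30.0) / (vrev - (-30.0)) > 0

    def test_missing_history_rejected(self, default_spec, default_rest):
        def bad_history(t):
            raise KeyError(t)

        with pytest.raises(ValueError, match="history must cover"):
            state_derivative(default_spec, default_rest, bad_history, np.zeros(8))


class TestSteadyState:
    def test_decoupled_rest_is_leak_reversal(self):
        spec = _decoupled_spec()
        ss = find_steady_state(spec, 0.0)
        np.testing.assert_allclose(ss.V, spec.V_L, atol=1e-12)
        np.testing.assert_allclose(ss.g, 0.0, atol=1e-15)

    def test_default_residual_below_tolerance(self, default_spec, default_rest):
        d = state_derivative(default_spec, default_rest,
                             lambda t: default_rest, default_spec.u_baseline)
        assert max(np.abs(d.V).max(), np.abs(d.g).max()) < 1e-9

    def test_fixed_point_is_stationary_under_integration(self, default_spec, default_rest):
        u = np.tile(default_spec.u_baseline, (2 * 600 + 1, 1))
        traj = integrate(default_spec, u, 300.0, 0.5, init=default_rest)
        assert np.abs(traj.V - default_rest.V).max() < 1e-6

    def test_root_and_relaxation_agree(self):
        # root-found fixed points match long relaxation for perturbed gains
        rng = np.random.default_rng(42)
        for _ in range(20):
            spec = build_default_model()
            spec.gains *= rng.uniform(0.8, 1.2, (8, 8))[None]
            ss = find_steady_state(spec, spec.u_baseline)
            start = StateVector(V=ss.V + 0.5, g=ss.g.copy())
            n_steps = int(4000 / 0.5)
            u = np.tile(spec.u_baseline, (2 * n_steps + 1, 1))
            traj = integrate(spec, u, 4000.0, 0.5, init=start)
            assert np.abs(traj.V[-1] - ss.V).max() < 1e-6


class TestIntegrate:
    def test_thalamocortical_delay_law(self, default_spec, default_rest):
        # an impulse into the relay reaches spiny stellates delay_tc later
        dt = 0.25
        t0 = 20.0
        n_steps = int(60 / dt)
        u = np.tile(default_spec.u_baseline, (2 * n_steps + 1, 1))
        th = np.arange(2 * n_steps + 1) * dt / 2
        pulse = (th >= t0) & (th < t0 + 1.0)
        u[pulse, default_spec.index("rl")] += 10.0
        traj = integrate(default_spec, u, 60.0, dt, init=default_rest)
        dev = np.abs(traj.V - default_rest.V)
        thresh = 1e-9
        i_ss = default_spec.index("ss")
        onset_ss = traj.t[np.argmax(dev[:, i_ss] > thresh)]
        assert onset_ss == pytest.approx(t0 + default_spec.delay_tc, abs=2 * dt)

    def test_corticothalamic_delay_law(self, default_spec, default_rest):
        dt = 0.25
        t0 = 20.0
        n_steps = int(60 / dt)
        u = np.tile(default_spec.u_baseline, (2 * n_steps + 1, 1))
        th = np.arange(2 * n_steps + 1) * dt / 2
        u[(th >= t0) & (th < t0 + 1.0), default_spec.index("tp")] += 10.0
        traj = integrate(default_spec, u, 60.0, dt, init=default_rest)
        dev = np.abs(traj.V - default_rest.V)
        i_rl, i_rt = default_spec.index("rl"), default_spec.index("rt")
        onset = traj.t[np.argmax((dev[:, i_rl] > 1e-9) | (dev[:, i_rt] > 1e-9))]
        assert onset == pytest.approx(t0 + default_spec.delay_ct, abs=2 * dt)

    def test_delay_law_random_settings(self):
        rng = np.random.default_rng(3)
        dt = 0.25
        for _ in range(5):
            d_tc = float(rng.uniform(2.0, 6.0))
            d_ct = float(rng.uniform(6.0, 12.0))
            spec = build_default_model({"delay_tc": d_tc, "delay_ct": d_ct})
            rest = find_steady_state(spec, spec.u_baseline)
            n_steps = int(60 / dt)
            u = np.tile(spec.u_baseline, (2 * n_steps + 1, 1))
            th = np.arange(2 * n_steps + 1) * dt / 2
            u[(th >= 20.0) & (th < 21.0), spec.index("rl")] += 10.0
            traj = integrate(spec, u, 60.0, dt, init=rest)
            dev = np.abs(traj.V - rest.V)
            onset = traj.t[np.argmax(dev[:, spec.index("ss")] > 1e-9)]
            assert onset == pytest.approx(20.0 + d_tc, abs=2 * dt)

    def test_step_halving_convergence(self, default_spec, default_rest):
        def run(dt):
            n_steps = int(200 / dt)
            u = np.tile(default_spec.u_baseline, (2 * n_steps + 1, 1))
            th = np.arange(2 * n_steps + 1) * dt / 2
            u[:, default_spec.index("rl")] += 6.0 * np.exp(-0.5 * ((th - 64) / 16) ** 2)
            return integrate(default_spec, u, 200.0, dt, init=default_rest)

        v4 = run(0.4).V[-1]
        v2 = run(0.2).V[-1]
        v1 = run(0.1).V[-1]
        err4 = np.abs(v4 - v1).max()
        err2 = np.abs(v2 - v1).max()
        assert err2 < err4            # error decreases with the step
        assert err2 < 1e-3            # terminal voltages converged

    def test_degenerate_inputs_rejected(self, default_spec, default_rest):
        with pytest.raises(ValueError):
            integrate(default_spec, None, 0.0, 0.25, init=default_rest)
        with pytest.raises(ValueError):
            integrate(default_spec, None, 100.0, -0.1, init=default_rest)
        with pytest.raises(ValueError):
            integrate(default_spec, None, 100.0, 0.75, init=default_rest)
        with pytest.raises(ValueError):
            integrate(default_spec, None, 2.0, 0.25, init=default_rest)

    def test_kernel_matches_reference_derivative(self, default_spec, default_rest):
        """One RK4 step of the JIT kernel equals the numpy reference step."""
        dt = 0.25
        spec = default_spec
        n_steps = int(8.0 / dt)
        u = np.tile(spec.u_baseline, (2 * n_steps + 1, 1))
        traj = integrate(spec, u, 8.0, dt, init=default_rest)

        hist = lambda t: default_rest
        ub = spec.u_baseline

        def f(state):
            d = state_derivative(spec, state, hist, ub)
            return d

        y0 = default_rest
        k1 = f(y0)
        mid1 = StateVector(V=y0.V + dt / 2 * k1.V, g=y0.g + dt / 2 * k1.g)
        k2 = f(mid1)
        mid2 = StateVector(V=y0.V + dt / 2 * k2.V, g=y0.g + dt / 2 * k2.g)
        k3 = f(mid2)
        end = StateVector(V=y0.V + dt * k3.V, g=y0.g + dt * k3.g)
        k4 = f(end)
        v_next = y0.V + dt / 6 * (k1.V + 2 * k2.V + 2 * k3.V + k4.V)
        g_next = y0.g + dt / 6 * (k1.g + 2 * k2.g + 2 * k3.g + k4.g)
        np.testing.assert_allclose(traj.V[1], v_next, atol=1e-12)
        np.testing.assert_allclose(traj.g[1], g_next, atol=1e-12)
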