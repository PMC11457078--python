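"""Unit and property tests of the signaling ODE system and integrators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imdsim import (
    COMPONENTS,
    ConstitutiveParameters,
    ImdParameters,
    ImdState,
    IntegrationError,
    IntegratorConfig,
    SinusoidalInput,
    Trajectory,
    constitutive_derivative,
    induced_derivatives,
    integrate,
)

IDX = {name: i for i, name in enumerate(COMPONENTS)}


class TestInducedDerivatives:
    def test_zero_state_only_basal_receptor_production(self, default_params):
        dy = induced_derivatives(np.zeros(9), default_params, 0.0)
        expected = np.zeros(9)
        expected[IDX["R"]] = default_params.R0
        np.testing.assert_allclose(dy, expected)

    def test_single_bacterium_drives_proliferation_and_pg_release(self):
        params = ImdParameters(k0=0.1, alpha=2.0, lambda1=0.01)
        state = ImdState(B=1.0)
        dy = induced_derivatives(state.as_array(), params, 0.0)
        assert dy[IDX["B"]] == pytest.approx(0.1)  # k0 * B
        assert dy[IDX["G"]] == pytest.approx(0.2)  # alpha * k0 * B, G=0
        assert dy[IDX["R"]] == pytest.approx(params.R0)

    def test_amp_production_saturates_at_beta6_when_relish_is_abundant(self, default_params):
        state = np.zeros(9)
        state[IDX["N"]] = 1e12
        state[IDX["A"]] = 0.3
        dy = induced_derivatives(state, default_params, 0.0)
        expected = default_params.beta6 - default_params.lambda2 * 0.3
        assert dy[IDX["A"]] == pytest.approx(expected, rel=1e-9)

    def test_negative_inputs_are_rejected(self, default_params):
        bad = np.zeros(9)
        bad[0] = -0.1
        with pytest.raises(ValueError):
            induced_derivatives(bad, default_params, 0.0)
        with pytest.raises(ValueError):
            induced_derivatives(np.zeros(9), default_params, -1.0)

    def test_repression_decreases_amp_production(self, default_params):
        """dA/dt falls as repressosome rises; weaker binding (larger Zs) lifts it."""
        state = np.zeros(9)
        state[IDX["N"]] = 2.0
        rates = []
        for s in (0.0, 1.0, 5.0):
            state[IDX["S"]] = s
            rates.append(induced_derivatives(state, default_params, 0.0)[IDX["A"]])
        assert rates[0] > rates[1] > rates[2]
        state[IDX["S"]] = 1.0
        weak = induced_derivatives(state, default_params.replace(Zs=50.0), 0.0)[IDX["A"]]
        assert weak > rates[1]

    def test_pirk_and_scavenger_feedbacks_pull_down_signaling(self, default_params):
        state = np.zeros(9)
        state[IDX["R"]], state[IDX["G"]], state[IDX["C"]] = 1.0, 1.0, 1.0
        low = induced_derivatives(state.copy(), default_params, 0.0)
        state[IDX["P"]] = 2.0
        high_p = induced_derivatives(state.copy(), default_params, 0.0)
        assert high_p[IDX["C"]] < low[IDX["C"]]
        assert high_p[IDX["R"]] < low[IDX["R"]]
        state[IDX["P"]] = 0.0
        state[IDX["L"]] = 2.0
        high_l = induced_derivatives(state, default_params, 0.0)
        assert high_l[IDX["G"]] < low[IDX["G"]]


class TestConstitutiveDerivative:
    @pytest.mark.parametrize(
        "B,A,k0,f,expected",
        [
            (1.0, 0.5, 0.1, 0.0, -0.4),
            (0.0, 0.7, 0.2, 0.0, 0.0),  # extinction is absorbing without influx
            (2.0, 0.1, 0.1, 0.3, 0.3),  # proliferation and killing cancel
        ],
    )
    def test_examples(self, B, A, k0, f, expected):
        assert constitutive_derivative(B, A, k0, f) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            constitutive_derivative(-1.0, 0.5, 0.1, 0.0)
        with pytest.raises(ValueError):
            constitutive_derivative(1.0, 0.5, 0.1, -0.2)


class TestIntegrate:
    def test_constitutive_decay_matches_exponential(self):
        params = ConstitutiveParameters(A=0.5, k0=0.1)
        traj = integrate("constitutive", params, 0.0, 1.0, IntegratorConfig(t_end=10.0))
        exact = math.exp((0.1 - 0.5) * 10.0)
        assert traj.component("B")[-1] == pytest.approx(exact, rel=0.01)
        # RK4 nails it to much higher order
        traj4 = integrate(
            "constitutive", params, 0.0, 1.0, IntegratorConfig(t_end=10.0, method="rk4")
        )
        assert traj4.component("B")[-1] == pytest.approx(exact, rel=1e-8)

    def test_receptors_relax_to_basal_level_without_input(self, default_params):
        cfg = IntegratorConfig(t_end=100.0)
        traj = integrate("induced", default_params, 0.0, None, cfg)
        r0, lam2 = default_params.R0, default_params.lambda2
        expected = r0 * (1 - np.exp(-lam2 * traj.times)) / lam2
        np.testing.assert_allclose(traj.component("R"), expected, rtol=1e-2, atol=1e-4)
        for name in COMPONENTS:
            if name != "R":
                assert np.all(traj.component(name) == 0)

    def test_zero_input_fixed_point_is_stationary(self, default_params):
        r_star = default_params.R0 / default_params.lambda2
        init = ImdState(R=r_star).as_array()
        traj = integrate("induced", default_params, 0.0, init, IntegratorConfig(t_end=20.0))
        np.testing.assert_allclose(traj.component("R"), r_star, rtol=1e-9)

    def test_zero_horizon_returns_initial_state_only(self, default_params):
        traj = integrate("induced", default_params, 0.0, None, IntegratorConfig(t_end=0.0))
        assert traj.times.shape == (1,)
        np.testing.assert_array_equal(traj.states, np.zeros((1, 9)))

    def test_recording_stride_keeps_both_endpoints(self, default_params):
        cfg = IntegratorConfig(t_end=1.0, record_stride=7)
        traj = integrate("induced", default_params, 0.0, None, cfg)
        assert traj.times[0] == 0.0
        assert traj.times[-1] == pytest.approx(1.0)
        assert np.all(np.diff(traj.times) > 0)

    def test_blowup_raises_with_location(self):
        params = ConstitutiveParameters(A=0.01, k0=0.5)
        with pytest.raises(IntegrationError, match="step"):
            integrate("constitutive", params, 0.0, 1e308, IntegratorConfig(t_end=5.0))

    def test_no_defense_means_unbounded_growth(self):
        """Without AMP production the average bacterial load keeps climbing."""
        params = ImdParameters(beta6=0.0)
        averages = []
        for t_end in (20.0, 40.0, 60.0):
            traj = integrate("induced", params, 0.5, None, IntegratorConfig(t_end=t_end))
            averages.append(traj.component("B").mean())
        assert averages[0] < averages[1] < averages[2]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        omega=st.floats(0.0, 5.0),
        phi=st.floats(1e-3, 1.0),
    )
    def test_clipping_keeps_all_components_non_negative(self, seed, omega, phi):
        rng = np.random.default_rng(seed)
        params = ImdParameters(
            alpha=rng.uniform(0.2, 4),
            k0=rng.uniform(0.05, 0.5),
            lambda1=rng.uniform(0.005, 0.1),
            lambda2=rng.uniform(0.01, 2),
            lambda3=rng.uniform(0.01, 2),
            R0=rng.uniform(0.01, 2),
            **{f"beta{i}": rng.uniform(0.01, 5) for i in range(1, 7)},
            Zn=rng.uniform(0.1, 10),
            Zs=rng.uniform(0.1, 10),
        )
        init = rng.uniform(0, 5, size=9)
        traj = integrate(
            "induced", params, SinusoidalInput(omega=omega, phi=phi), init,
            IntegratorConfig(t_end=5.0),
        )
        assert traj.states.min() >= 0.0

    def test_euler_agrees_with_scipy_oracle(self, default_params):
        """Independent LSODA integration reproduces the fixed-step solution."""
        scipy_integrate = pytest.importorskip("scipy.integrate")
        from imdsim import induced_derivatives as rhs

        sin = SinusoidalInput(omega=1.0, phi=0.05)
        cfg = IntegratorConfig(t_end=50.0, record_stride=50, method="rk4")
        traj = integrate("induced", default_params, sin, None, cfg)

        sol = scipy_integrate.solve_ivp(
            lambda t, y: rhs(np.maximum(y, 0.0), default_params, sin(t)),
            (0.0, 50.0),
            np.zeros(9),
            t_eval=traj.times,
            method="LSODA",
            rtol=1e-8,
            atol=1e-10,
        )
        scale = np.abs(sol.y.T).max(axis=0) + 1e-12
        err = np.abs(traj.states - sol.y.T).max(axis=0) / scale
        assert err.max() < 1e-4


class TestTrajectory:
    def test_row_count_must_match_times(self):
        with pytest.raises(ValueError):
            Trajectory(times=np.arange(3.0), states=np.zeros((2, 9)), input_values=np.zeros(3))

    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            Trajectory(
                times=np.array([0.0, 1.0, 1.0]),
                states=np.zeros((3, 9)),
                input_values=np.zeros(3),
            )

    def test_means_and_component_access(self, default_params):
        traj = integrate(
            "induced", default_params, 0.3, None, IntegratorConfig(t_end=5.0)
        )
        assert traj.means()["B"] == pytest.approx(traj.component("B").mean())
        with pytest.raises(KeyError):
            traj.component("X")


class TestParameterValidation:
    @pytest.mark.parametrize("field,value", [("lambda2", -1.0), ("Zn", 0.0), ("k0", -0.1)])
    def test_nonpositive_rates_rejected(self, field, value):
        with pytest.raises(ValueError, match=field):
            ImdParameters(**{field: value})

    def test_production_rates_may_be_knocked_out(self):
        params = ImdParameters(beta5=0.0, beta6=0.0)
        assert params.beta5 == 0.0

    def test_degradation_override_validated(self):
        with pytest.raises(ValueError):
            ImdParameters(degradation_rates={"X": 0.5})
        params = ImdParameters(degradation_rates={"A": 0.5})
        packed = params.packed()
        assert packed[-1] == 0.5  # A-specific rate
        assert packed[-2] == params.lambda2  # others keep the shared rate
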