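"""Mass-balance structure: saturable fluxes, conservation, numerical guards."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ergopk
from ergopk.model import (
    N_STATE,
    NumericalStateError,
    SystemState,
    michaelis_menten_flux,
    rhs,
)


class TestMichaelisMenten:
    def test_zero_substrate_gives_zero_flux(self):
        assert michaelis_menten_flux(11.1, 21.0, 0.0) == 0.0

    def test_half_saturation_identity(self):
        assert michaelis_menten_flux(10227.0, 21.0, 21.0) == pytest.approx(10227.0 / 2)

    def test_baseline_precursor_uptake(self):
        # V_max 11.1, K_m 21.0 at the 3.16 μM plasma baseline
        assert michaelis_menten_flux(11.1, 21.0, 3.16) == pytest.approx(1.4518, abs=1e-4)

    def test_negative_substrate_rejected(self):
        with pytest.raises(ValueError):
            michaelis_menten_flux(11.1, 21.0, -0.5)

    @given(
        vmax=st.floats(0.1, 1e6),
        km=st.floats(0.1, 1e3),
        c1=st.floats(0.0, 1e4),
        c2=st.floats(0.0, 1e4),
    )
    def test_monotone_and_bounded(self, vmax, km, c1, c2):
        lo, hi = sorted((c1, c2))
        f_lo = michaelis_menten_flux(vmax, km, lo)
        f_hi = michaelis_menten_flux(vmax, km, hi)
        assert 0.0 <= f_lo <= f_hi < vmax + 1e-9


class TestRHS:
    def test_empty_system_is_inert(self, params):
        quiet = params.replace(R=0.0)
        dy = rhs(0.0, np.zeros(N_STATE), quiet)
        assert np.all(dy == 0.0)

    @given(seed=st.integers(0, 500))
    def test_conservation_identity(self, params, derived, seed):
        """Summed amount derivatives equal dietary input minus urine outflow
        for any non-negative state: nothing else crosses the body boundary."""
        rng = np.random.default_rng(seed)
        y = rng.uniform(0.0, 50.0, N_STATE)
        y[19] *= 10  # precursor amount runs larger
        y[20] *= 20  # RBC concentration runs larger
        dy = rhs(0.0, y, params, derived)
        net = ergopk.total_amount(dy, params)
        expected = params.R - params.Q_u * y[18]
        assert net == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_conservation_with_systemic_absorption_route(self, params):
        systemic = params.replace(absorption_route="systemic")
        y = np.linspace(0.5, 10.0, N_STATE)
        dy = rhs(0.0, y, systemic)
        assert ergopk.total_amount(dy, systemic) == pytest.approx(
            systemic.R - systemic.Q_u * y[18], rel=1e-9
        )

    def test_local_steady_state_zeroes_non_pinned_derivatives(self, params, init_316):
        dy = rhs(0.0, init_316.y, params)
        scale = np.maximum(np.abs(init_316.y), 1.0)
        free = np.delete(np.arange(N_STATE), [1, 20])  # plasma/RBC are pinned data
        assert np.max(np.abs(dy[free]) / scale[free]) < 1e-9

    def test_nonfinite_state_names_compartment(self, params):
        y = np.ones(N_STATE)
        y[18] = np.nan
        with pytest.raises(NumericalStateError, match="C_d"):
            rhs(0.0, y, params)


class TestSystemState:
    def test_vector_round_trip(self):
        y = np.arange(N_STATE, dtype=float)
        state = SystemState.from_vector(y)
        assert np.array_equal(state.to_vector(), y)
        assert state.C_p == 1.0 and state.C_RBC == 20.0
        assert list(state.C_he) == [2.0, 3.0, 4.0, 5.0, 6.0]

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            SystemState.from_vector(np.zeros(7))


class TestTrajectoryProperties:
    """Flux saturation, positivity, and conservation along an actual solution."""

    @pytest.fixture(scope="class")
    def trajectory(self, params, derived, init_316):
        from scipy.integrate import odeint

        from ergopk.model import pack_parameters, rhs_packed

        p = pack_parameters(params, derived)
        f = lambda t, y: rhs_packed(t, y, p)
        dose = ergopk.dose_mg_to_umol(8.0)
        states, times = [], []
        y = init_316.y.copy()
        t_grid = np.linspace(0.0, 24.0, 241)
        for day in range(3):
            y = y.copy()
            y[0] += dose
            out = odeint(f, y, t_grid, rtol=1e-8, atol=1e-10, tfirst=True, mxstep=100000)
            states.append(out)
            times.append(day * 24.0 + t_grid)
            y = out[-1]
        return np.vstack(states), np.concatenate(times)

    def test_states_stay_non_negative(self, trajectory):
        states, _ = trajectory
        assert states.min() > -1e-9

    def test_transporter_fluxes_bounded_by_vmax(self, params, derived, trajectory):
        states, _ = trajectory
        km = params.K_m
        for cols, vmax in [
            (slice(2, 7), derived.V_max["liver"] / 5.0),
            ((12,), derived.V_max["adipose"]),
            ((14,), derived.V_max["skin"]),
            ((16,), derived.V_max["muscle"]),
            ((18,), params.V_maxD),
            ((1,), params.V_maxP),
        ]:
            c = states[:, cols]
            flux = vmax * c / (km + c)
            assert np.all(flux <= vmax)

    def test_cumulative_mass_balance(self, params, trajectory):
        """Body amount change equals dietary + bolus input minus the urine
        integral, to integrator tolerance."""
        states, times = trajectory
        amounts = np.array([ergopk.total_amount(y, params) for y in states])
        urine = params.Q_u * states[:, 18]
        # per-day segments each start with a bolus; integrate urine within days
        n = 241
        total_in = 3 * ergopk.dose_mg_to_umol(8.0) + params.R * 72.0
        total_out = 0.0
        for day in range(3):
            seg = slice(day * n, (day + 1) * n)
            total_out += np.trapezoid(urine[seg], times[seg])
        gained = amounts[-1] - (amounts[0] - ergopk.dose_mg_to_umol(8.0))
        assert gained == pytest.approx(total_in - total_out, rel=1e-6)


class TestStiffVsFixedStepOracle:
    def test_adaptive_solution_matches_rk4(self, params, derived, init_316):
        """LSODA and a brute-force fixed-step RK4 agree on every compartment
        over a 72-h three-dose horizon."""
        from scipy.integrate import odeint

        from ergopk.model import pack_parameters, rhs_packed

        p = pack_parameters(params, derived)
        f = lambda t, y: rhs_packed(t, y, p)
        dose = ergopk.dose_mg_to_umol(8.0)
        y_a = init_316.y.copy()
        y_rk = init_316.y.copy()
        for _ in range(3):
            y_a = y_a.copy()
            y_a[0] += dose
            y_a = odeint(f, y_a, [0.0, 24.0], rtol=1e-10, atol=1e-12,
                         tfirst=True, mxstep=1000000)[-1]
            y_rk = y_rk.copy()
            y_rk[0] += dose
            y_rk = ergopk.rk4_integrate(y_rk, params, (0.0, 24.0), dt=2e-4)
        rel = np.abs(y_a - y_rk) / np.maximum(np.abs(y_rk), 1e-12)
        assert rel.max() < 1e-4
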