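"""Plasma and brain model machinery: analytic solutions vs ODE oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from piperbrain.core_model import (
    BrainModelParams,
    DosingRegimen,
    PlasmaModelParams,
    brain_profile,
    plasma_concentration,
    simulate_brain_course,
    steady_state_ratio,
    unbound_concentration,
)


def _plasma_ode(params, regimen, t_eval, extra_states=False):
    """Independent numerical oracle: stiff-free ODE integration in amounts."""
    k10 = params.CL / params.Vc
    k12 = params.Q / params.Vc
    k21 = params.Q / params.Vp

    def infusion_rate(t):
        return sum(
            regimen.rate
            for td in regimen.dose_times
            if td <= t < td + regimen.t_inf
        )

    def rhs(t, y):
        ac, ap = y[0], y[1]
        dac = infusion_rate(t) - (k10 + k12) * ac + k21 * ap
        dap = k12 * ac - k21 * ap
        if extra_states:
            return [dac, dap, k10 * ac, infusion_rate(t)]
        return [dac, dap]

    y0 = [0.0, 0.0, 0.0, 0.0] if extra_states else [0.0, 0.0]
    sol = solve_ivp(rhs, (0.0, t_eval[-1]), y0, t_eval=t_eval,
                    rtol=1e-10, atol=1e-12, max_step=regimen.t_inf / 4)
    return sol


class TestPlasmaModel:
    def test_zero_before_any_dose(self, plasma_simple):
        reg = DosingRegimen(dose=4000.0, tau=8.0, t_inf=0.5)
        assert plasma_concentration(plasma_simple, reg, 0.0) == 0.0

    def test_continuous_infusion_steady_state_equals_rate_over_cl(self, plasma_simple):
        # 500 mg/h against CL 10 L/h -> 50 mg/L at steady state
        reg = DosingRegimen(dose=12000.0, tau=24.0, t_inf=24.0, mode="continuous", n_doses=40)
        css = plasma_concentration(plasma_simple, reg, 800.0)
        assert css == pytest.approx(500.0 / 10.0, rel=1e-9)

    def test_multidose_matches_ode_oracle(self, plasma):
        reg = DosingRegimen(dose=4000.0, tau=8.0, t_inf=0.5, n_doses=6)
        t = np.linspace(0.0, 48.0, 481)
        ana = plasma_concentration(plasma, reg, t)
        ode = _plasma_ode(plasma, reg, t).y[0] / plasma.Vc
        mask = ode > 1e-3 * ode.max()
        assert np.max(np.abs(ana[mask] - ode[mask]) / ode[mask]) < 1e-6

    def test_superposition_of_shifted_single_doses(self, plasma_simple):
        reg = DosingRegimen(dose=3000.0, tau=6.0, t_inf=1.0, n_doses=4)
        single = DosingRegimen(dose=3000.0, tau=6.0, t_inf=1.0, n_doses=1)
        t = np.linspace(0.0, 36.0, 181)
        total = plasma_concentration(plasma_simple, reg, t)
        manual = np.zeros_like(t)
        for k in range(4):
            shifted = np.clip(t - 6.0 * k, 0.0, None)
            manual += plasma_concentration(plasma_simple, single, shifted)
        nz = total > 0
        assert np.max(np.abs(total[nz] - manual[nz]) / total[nz]) < 1e-8

    def test_linearity_doubling_dose_doubles_concentration(self, plasma_simple):
        t = np.linspace(0.0, 24.0, 97)
        c1 = plasma_concentration(plasma_simple, DosingRegimen(dose=2000.0, tau=8.0, t_inf=0.5, n_doses=3), t)
        c2 = plasma_concentration(plasma_simple, DosingRegimen(dose=4000.0, tau=8.0, t_inf=0.5, n_doses=3), t)
        assert np.allclose(c2, 2.0 * c1, rtol=1e-10, atol=1e-12)

    def test_mass_balance(self, plasma):
        # compartment amounts plus cumulative elimination equal infused drug
        reg = DosingRegimen(dose=4000.0, tau=8.0, t_inf=0.5, n_doses=3)
        t = np.linspace(0.0, 24.0, 49)
        sol = _plasma_ode(plasma, reg, t, extra_states=True)
        ac, ap, eliminated, infused = sol.y
        assert np.all(infused[-1] == pytest.approx(3 * 4000.0, rel=1e-6))
        balance = ac + ap + eliminated
        assert np.allclose(balance[1:], infused[1:], rtol=1e-6)
        # and the analytic concentration matches this same integration
        ana = plasma_concentration(plasma, reg, t)
        assert np.allclose(ana, ac / plasma.Vc, rtol=1e-6, atol=1e-9)

    def test_invalid_regimen_rejected(self):
        with pytest.raises(ValueError, match="infusion duration"):
            DosingRegimen(dose=4000.0, tau=8.0, t_inf=9.0)
        with pytest.raises(ValueError, match="dose"):
            DosingRegimen(dose=-1.0, tau=8.0, t_inf=0.5)
        with pytest.raises(ValueError, match="continuous"):
            DosingRegimen(dose=1000.0, tau=12.0, t_inf=12.0, mode="continuous")

    def test_invalid_plasma_params_rejected(self):
        with pytest.raises(ValueError, match="FU"):
            PlasmaModelParams(CL=10, Q=10, Vc=10, Vp=10, FU=1.5)
        with pytest.raises(ValueError, match="CL"):
            PlasmaModelParams(CL=0, Q=10, Vc=10, Vp=10)


class TestUnboundFraction:
    def test_seventy_percent_binding(self):
        assert unbound_concentration(10.0, 0.70) == pytest.approx(7.0)

    def test_identity_and_zero(self):
        assert unbound_concentration(3.3, 1.0) == pytest.approx(3.3)
        assert unbound_concentration(0.0, 0.7) == 0.0

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            unbound_concentration(1.0, 0.0)
        with pytest.raises(ValueError):
            unbound_concentration(1.0, 1.2)


class TestBrainModel:
    def test_zero_before_first_dose_lag(self, truth):
        cu = lambda t: np.full_like(np.asarray(t, float), 7.0)
        t = np.array([0.0, 1.0, 2.0, 2.69])
        conc = brain_profile(truth, cu, "first_dose", t)
        assert np.all(conc == 0.0)

    def test_constant_input_steady_state_ratio(self, truth):
        # closed form: brain/unbound-plasma ratio K_pb / K_bp at steady state
        cu = lambda t: np.full_like(np.asarray(t, float), 7.0)
        conc = brain_profile(truth, cu, "multiple_dose", np.array([0.0, 80.0]))
        expected = 7.0 * steady_state_ratio(truth.K_pb, truth.K_bp_md)
        assert conc[-1] == pytest.approx(expected, rel=1e-6)

    def test_zero_input_zero_everywhere(self, truth):
        cu = lambda t: np.zeros_like(np.asarray(t, float))
        conc = brain_profile(truth, cu, "first_dose", np.linspace(0, 10, 11))
        assert np.all(conc == 0.0)

    def test_cascade_matches_ode_oracle(self, truth):
        # same structure integrated independently with solve_ivp
        a, b = truth.K_pb, truth.K_bp_md
        cu = lambda t: 5.0 * np.exp(-0.4 * np.asarray(t, float)) * np.asarray(t, float)

        def rhs(t, y):
            tr, br = y
            return [a * cu(t) - a * tr, a * tr - b * br]

        t = np.linspace(0.0, 20.0, 81)
        sol = solve_ivp(rhs, (0, 20), [0, 0], t_eval=t, rtol=1e-11, atol=1e-13)
        conc = brain_profile(truth, cu, "multiple_dose", t, step=0.005)
        assert np.max(np.abs(conc - sol.y[1])) < 1e-6

    def test_course_linearity_in_dose(self, truth, plasma):
        t = np.linspace(0.0, 24.0, 97)
        r1 = DosingRegimen(dose=2000.0, tau=8.0, t_inf=0.5, n_doses=3)
        r2 = DosingRegimen(dose=4000.0, tau=8.0, t_inf=0.5, n_doses=3)
        c1 = simulate_brain_course(truth, plasma, r1, t)
        c2 = simulate_brain_course(truth, plasma, r2, t)
        assert np.allclose(c2, 2.0 * c1, rtol=1e-9, atol=1e-12)

    def test_unsorted_grid_rejected(self, truth):
        cu = lambda t: np.zeros_like(np.asarray(t, float))
        with pytest.raises(ValueError, match="sorted"):
            brain_profile(truth, cu, "first_dose", np.array([1.0, 0.5]))

    def test_invalid_brain_params_rejected(self):
        with pytest.raises(ValueError, match="rate constant"):
            BrainModelParams(K_pb=0.0, K_bp_fd=1.0, K_bp_md=1.0, T_lag_fd=1.0)
        with pytest.raises(ValueError, match="lag"):
            BrainModelParams(K_pb=0.3, K_bp_fd=1.0, K_bp_md=1.0, T_lag_fd=-0.1)


class TestSteadyStateRatio:
    def test_reference_rates(self):
        assert steady_state_ratio(0.32, 4.39) == pytest.approx(0.0729, abs=5e-5)

    def test_symmetry(self):
        assert steady_state_ratio(1.7, 1.7) == 1.0

    def test_degenerate_zero_uptake_warns(self):
        with pytest.warns(UserWarning, match="no brain uptake"):
            assert steady_state_ratio(0.0, 2.0) == 0.0

    def test_nonpositive_elimination_rejected(self):
        with pytest.raises(ValueError):
            steady_state_ratio(0.3, 0.0)
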