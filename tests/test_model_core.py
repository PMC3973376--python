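"""Core model: parameterization, closed forms, solver, regime checks."""

import numpy as np
import pytest
from hypothesis import given, settings

from neurogen import (CellState, ParameterError, asymptotic_ratio,
                      check_assumption_3_2, check_stem_decline, closed_form_c1,
                      closed_form_c2, derived_rates, rhs, solve_system)
from conftest import params_strategy


class TestParameters:
    @pytest.mark.parametrize("field,value", [
        ("a1", 0.3), ("a1", 1.2), ("a2", 0.49), ("theta1", -0.1),
        ("theta2", 1.5), ("kappa", 2.0), ("p1", 0.0), ("p2", -1.0),
        ("p3", 0.0), ("d2", -0.2), ("d5", float("nan")),
    ])
    def test_out_of_range_rejected_with_named_error(self, s52_params, field, value):
        with pytest.raises(ParameterError, match=field):
            s52_params.replace(**{field: value})

    def test_negative_cell_counts_rejected(self):
        with pytest.raises(ParameterError, match="c3"):
            CellState(1.0, 1.0, -1.0, 0.0, 0.0)

    @given(params_strategy())
    @settings(max_examples=50, deadline=None)
    def test_derived_rate_identities(self, p):
        r = derived_rates(p)
        assert r.k12 >= 0 and r.k23 >= 0 and r.k15 >= 0
        assert np.isclose(r.net_event_change, r.lambda1 / p.p1)
        if p.a1 < 1 - 1e-9 and p.theta1 > 1e-9:
            # kappa-branching of the asymmetric division is a partition
            asym = 2 * (1 - p.a1) * p.theta1 * p.p1
            share = r.k12 / asym + (r.k15 - (1 - p.theta1) * p.p1) / asym
            assert np.isclose(share, 1.0)


class TestDerivedRates:
    def test_canonical_set(self, s52_params):
        r = derived_rates(s52_params)
        assert r.lambda1 == pytest.approx(-0.23)
        assert r.lambda2 == pytest.approx(-1.2)
        assert r.k12 == pytest.approx(0.378)

    def test_balanced_divisions_give_zero_net_rate(self, s52_params):
        p = s52_params.replace(a1=0.5, theta1=1.0)
        r = derived_rates(p)
        assert r.lambda1 == 0.0
        assert r.net_event_change == 0.0


class TestRhs:
    def test_zero_state_maps_to_zero(self, s52_params):
        assert np.all(rhs(s52_params, CellState(0, 0, 0, 0, 0)) == 0.0)

    def test_stem_derivative_is_lambda1_c1(self, s52_params, s52_init):
        dc = rhs(s52_params, s52_init)
        assert dc[0] == pytest.approx(-0.23 * 10000)

    def test_no_stem_influx_to_progenitors_without_asymmetric_divisions(self, s52_params):
        p = s52_params.replace(a1=1.0, theta1=1.0)
        dc = rhs(p, CellState(1000, 0, 0, 0, 0))
        assert dc[1] == 0.0


class TestClosedForms:
    def test_c1_initial_condition_and_value(self, s52_params):
        assert closed_form_c1(s52_params, 10000, 0.0) == pytest.approx(10000)
        assert closed_form_c1(s52_params, 10000, 1.0) == pytest.approx(7945.336, rel=1e-6)

    def test_c1_constant_at_balance(self, s52_params):
        p = s52_params.replace(a1=0.5, theta1=1.0)
        t = np.linspace(0, 20, 7)
        assert np.allclose(closed_form_c1(p, 10000, t), 10000)

    def test_negative_time_rejected(self, s52_params):
        with pytest.raises(ValueError):
            closed_form_c1(s52_params, 10000, -1.0)

    def test_c2_initial_and_decoupled(self, s52_params):
        assert closed_form_c2(s52_params, 10000, 5000, 0.0) == pytest.approx(5000)
        p = s52_params.replace(kappa=0.0)
        lam2 = derived_rates(p).lambda2
        assert closed_form_c2(p, 10000, 5000, 2.0) == pytest.approx(5000 * np.exp(2 * lam2))

    def test_c2_canonical_value(self, s52_params):
        assert closed_form_c2(s52_params, 10000, 5000, 1.0) == pytest.approx(3428.47, rel=1e-5)

    def test_c2_equal_rates_limit_matches_solver(self, s52_params):
        # tune progenitor kinetics so lambda2 == lambda1: confluent t*exp branch
        p = s52_params.replace(a2=0.5, theta2=0.908, d2=0.0)
        r = derived_rates(p)
        assert abs(r.lambda1 - r.lambda2) < 1e-14
        grid = np.linspace(0, 5, 21)
        traj = solve_system(p, CellState(10000, 5000, 0, 0, 0), grid)
        assert np.allclose(closed_form_c2(p, 10000, 5000, grid), traj.states[:, 1], rtol=1e-7)


class TestSolver:
    def test_zero_initial_state_stays_zero(self, s52_params):
        traj = solve_system(s52_params, CellState(0, 0, 0, 0, 0), np.linspace(0, 10, 11))
        assert np.all(traj.states == 0.0)

    def test_first_row_is_initial_state(self, s52_params, s52_init):
        traj = solve_system(s52_params, s52_init, np.linspace(0, 1, 5))
        assert np.array_equal(traj.states[0], s52_init.to_array())

    def test_matches_closed_forms(self, s52_params, s52_init):
        grid = np.linspace(0, 30, 301)
        traj = solve_system(s52_params, s52_init, grid)
        np.testing.assert_allclose(traj.states[:, 0],
                                   closed_form_c1(s52_params, 10000, grid),
                                   rtol=1e-8, atol=1e-8)
        np.testing.assert_allclose(traj.states[:, 1],
                                   closed_form_c2(s52_params, 10000, 5000, grid),
                                   rtol=1e-8, atol=1e-8)

    def test_superposition(self, s52_params):
        grid = np.linspace(0, 10, 21)
        a = solve_system(s52_params, CellState(7000, 0, 100, 0, 50), grid)
        b = solve_system(s52_params, CellState(3000, 5000, 0, 200, 0), grid)
        c = solve_system(s52_params, CellState(10000, 5000, 100, 200, 50), grid)
        np.testing.assert_allclose(a.states + b.states, c.states, rtol=1e-8, atol=1e-6)

    @given(params_strategy())
    @settings(max_examples=25, deadline=None)
    def test_nonnegativity(self, p):
        grid = np.linspace(0, 20, 41)
        traj = solve_system(p, CellState(1000, 500, 200, 100, 50), grid)
        assert np.all(traj.states >= 0.0)


class TestRegimeChecks:
    def test_decline_condition(self, s52_params):
        declining, margin = check_stem_decline(s52_params)
        assert declining and margin == pytest.approx(0.115)
        assert check_stem_decline(s52_params.replace(a1=1.0, theta1=1.0)) == (False, -0.5)
        boundary = s52_params.replace(a1=0.5, theta1=1.0)
        assert check_stem_decline(boundary) == (True, 0.0)

    @pytest.mark.parametrize("a1,theta1", [(0.55, 0.7), (0.6, 0.9), (0.8, 0.7)])
    def test_decline_flag_matches_numeric_monotonicity(self, s52_params, a1, theta1):
        p = s52_params.replace(a1=a1, theta1=theta1)
        traj = solve_system(p, CellState(10000, 0, 0, 0, 0), np.linspace(0, 10, 101))
        diffs = np.diff(traj.states[:, 0])
        declining, _ = check_stem_decline(p)
        assert (np.all(diffs <= 1e-9 * 10000)) == declining

    def test_asymptotic_ratio_zero_when_stem_depletes_faster(self, s52_params):
        p = s52_params.replace(a1=0.5, theta1=0.2, d2=0.0, a2=0.7, theta2=0.9)
        r = derived_rates(p)
        assert r.lambda1 < r.lambda2
        assert asymptotic_ratio(p) == 0.0

    def test_asymptotic_ratio_canonical_and_numeric(self, s52_params, s52_init):
        ratio = asymptotic_ratio(s52_params)
        assert ratio == pytest.approx(0.97 / 0.378, rel=1e-12)
        traj = solve_system(s52_params, s52_init, np.linspace(0, 50, 501))
        tail = traj.states[-1, 0] / traj.states[-1, 1]
        assert abs(tail - ratio) < 1e-3

    def test_asymptotic_ratio_diverges_without_flux(self, s52_params):
        assert asymptotic_ratio(s52_params.replace(kappa=0.0)) == np.inf

    def test_assumption_flags(self, s52_params):
        assert check_assumption_3_2(s52_params) == (True, True)
        assert check_assumption_3_2(s52_params.replace(a1=1.0, theta1=1.0))[0] is False
        p_eq = s52_params.replace(a2=0.5, theta2=0.908, d2=0.0)  # lambda2 ~= lambda1
        assert check_assumption_3_2(p_eq)[1] is False
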