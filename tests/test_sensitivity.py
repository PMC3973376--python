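"""Forward sensitivities, sign sequences, knockout difference curves."""

import numpy as np
import pytest

from neurogen import (CellState, LabelingProtocol, ParameterError, SignSequence,
                      brdu_incorporating_sensitivities, closed_form_c1,
                      finite_difference_sensitivity, forward_sensitivities,
                      ko_response, label_sensitivities, phase_count,
                      sign_sequence, table1_report)


class TestForwardSensitivities:
    def test_count_derivatives_start_at_zero(self, s52_params, s52_init, grid30):
        for par in ("a1", "p1", "theta1"):
            curves = forward_sensitivities(s52_params, s52_init, par, grid30)
            for q in ("c1", "c2", "c3", "c4", "c5"):
                assert curves[q].values[0] == 0.0

    def test_stem_self_renewal_derivative_matches_hand_formula(self, s52_params, s52_init):
        # d c1/d a1 = 2 theta1 p1 t c1(t), from differentiating n1 e^{(2 a1 th1 - 1) p1 t}
        grid = np.linspace(0, 2, 21)
        curve = forward_sensitivities(s52_params, s52_init, "a1", grid)["c1"]
        expected = 2 * 0.7 * 1.0 * grid * closed_form_c1(s52_params, 10000, grid)
        np.testing.assert_allclose(curve.values, expected, rtol=1e-8, atol=1e-6)
        assert np.interp(1.0, grid, curve.values) == pytest.approx(11123.47, rel=1e-5)

    @pytest.mark.parametrize("par", ["kappa", "d5", "d2"])
    def test_stem_count_independent_of_downstream_parameters(self, s52_params, s52_init, par):
        grid = np.linspace(0, 10, 21)
        curve = forward_sensitivities(s52_params, s52_init, par, grid)["c1"]
        assert curve.max_abs() == 0.0

    def test_agreement_with_central_differences(self, s52_params, s52_init):
        grid = np.linspace(0, 30, 61)
        for par in ("a1", "p1", "theta1", "a2", "d4"):
            fw = forward_sensitivities(s52_params, s52_init, par, grid)
            fd = finite_difference_sensitivity(s52_params, s52_init, par, grid)
            for q in ("c1", "c2", "c3", "c4", "c5"):
                if fw[q].max_abs() == 0.0:
                    # structurally zero derivative: central difference sees
                    # only solver noise (absolute, relative to ~1e5 counts)
                    assert np.max(np.abs(fd[q].values)) < 1e-2
                else:
                    err = np.max(np.abs(fw[q].values - fd[q].values))
                    assert err / fw[q].max_abs() < 1e-4

    def test_finite_difference_error_scales_quadratically(self, s52_params, s52_init):
        grid = np.linspace(0, 10, 11)
        fw = forward_sensitivities(s52_params, s52_init, "p1", grid)["c2"]
        errs = []
        for h in (1e-2, 5e-3):
            fd = finite_difference_sensitivity(s52_params, s52_init, "p1", grid, h=h)["c2"]
            errs.append(np.max(np.abs(fd.values - fw.values)))
        assert errs[1] < 0.35 * errs[0]  # ~h^2: factor 4 expected

    def test_domain_violation_at_step_rejected(self, s52_init):
        from neurogen import S52_PARAMS

        p = S52_PARAMS.replace(theta1=1.0)
        with pytest.raises(ParameterError):
            finite_difference_sensitivity(p, s52_init, "theta1", np.linspace(0, 1, 3))


class TestLabelSensitivities:
    def test_incorporating_stem_derivative_at_zero(self, s52_params, s52_init):
        # l1+ = F1 theta1 2 a1 c1; at t = 0, c1 = n1 is a1-independent
        grid = np.linspace(0, 5, 11)
        curve = brdu_incorporating_sensitivities(s52_params, s52_init, "a1", grid, 0.1)["l1+"]
        assert curve.values[0] == pytest.approx(1332.276, rel=1e-5)

    @pytest.mark.parametrize("par", ["a1", "p1", "theta1"])
    def test_label_response_is_instantaneous(self, s52_params, s52_init, par):
        grid = np.linspace(0, 5, 11)
        curve = brdu_incorporating_sensitivities(s52_params, s52_init, par, grid, 0.1)["l1+"]
        assert curve.values[0] != 0.0

    def test_labelled_neuron_derivative_zero_at_window_end(self, s52_params, s52_init, grid30):
        for par in ("a1", "p1", "theta1"):
            curve = brdu_incorporating_sensitivities(s52_params, s52_init, par, grid30, 0.1)["l4+"]
            assert curve.max_abs() == 0.0

    def test_chase_curves_match_finite_differences(self, s52_params, s52_init):
        tau = np.linspace(0, 10, 21)
        proto = LabelingProtocol(t_hat=2.0, delta=0.1)
        fw = label_sensitivities(s52_params, s52_init, "a1", proto, tau)
        fd = finite_difference_sensitivity(s52_params, s52_init, "a1", tau,
                                           kind="label", protocol=proto)
        for q in ("l1", "l2", "l4"):
            scale = max(fw[q].max_abs(), 1e-9)
            assert np.max(np.abs(fw[q].values - fd[q].values)) / scale < 1e-4


class TestSignSequence:
    def test_constant_positive(self):
        seq = sign_sequence(np.ones(50), np.linspace(0, 1, 50))
        assert seq.symbols == ("+",)

    def test_single_crossing_with_refined_time(self):
        t = np.linspace(0, 2, 201)
        seq = sign_sequence(t - 1.0, t)
        assert seq.symbols == ("-", "0", "+")
        assert seq.crossing_times[0] == pytest.approx(1.0, abs=1e-8)

    def test_all_zero_curve(self):
        assert sign_sequence(np.zeros(10), np.linspace(0, 1, 10)).symbols == ("0",)

    def test_analytic_crossing_of_astrocyte_label_response(self, s52_params, s52_init, grid30):
        # d l5+/d a1 crosses zero at exactly 1/(2 theta1 p1 (1 - a1))
        curve = brdu_incorporating_sensitivities(s52_params, s52_init, "a1", grid30, 0.1)["l5+"]
        seq = sign_sequence(curve)
        assert seq.symbols == ("-", "0", "+")
        t0 = 1.0 / (2 * 0.7 * 1.0 * 0.45)
        assert seq.crossing_times[0] == pytest.approx(t0, rel=1e-6)

    @pytest.mark.parametrize("symbols,expected", [
        (("0", "-", "0", "+"), 2), (("+",), 1), (("-", "0", "+", "0", "-"), 3),
        (("0",), 0),
    ])
    def test_phase_count(self, symbols, expected):
        assert phase_count(SignSequence(symbols)) == expected


class TestTable1:
    def test_self_renewal_row(self, s52_params, s52_init):
        rep = table1_report(s52_params, s52_init)
        row = {q: str(rep.sequences[("a1", q)]) for q in ("c1", "l1+", "c2", "l2+", "l5+")}
        assert row == {"c1": "(0, +)", "l1+": "(+)", "c2": "(0, -, 0, +)",
                       "l2+": "(-, 0, +)", "l5+": "(-, 0, +)"}
        assert rep.assumption_ok == (True, True)

    def test_report_flags_assumption_violation(self, s52_params, s52_init):
        p = s52_params.replace(a1=0.9, theta1=0.9)
        rep = table1_report(p, s52_init, grid=np.linspace(0, 10, 501))
        assert rep.assumption_ok[0] is False
        assert len(rep.sequences) == 15  # still produced


class TestKOResponse:
    def test_zero_perturbation_gives_zero_differences(self, s52_params, s52_init):
        diffs = ko_response(s52_params, s52_init, "a1", 0.0, np.linspace(0, 5, 11))
        assert all(np.all(v == 0.0) for v in diffs.values())

    def test_first_order_taylor_agreement(self, s52_params, s52_init):
        grid = np.linspace(0, 10, 21)
        dp = 1e-4
        diffs = ko_response(s52_params, s52_init, "a1", dp, grid)
        fw = forward_sensitivities(s52_params, s52_init, "a1", grid)
        for q in ("c1", "c2", "c4"):
            scale = max(fw[q].max_abs(), 1e-9)
            assert np.max(np.abs(diffs[q] / dp - fw[q].values)) / scale < 0.01

    def test_faster_proliferation_depletes_stem_pool(self, s52_params, s52_init):
        grid = np.linspace(0, 10, 21)
        diffs = ko_response(s52_params, s52_init, "p1", 0.05, grid)
        assert np.all(diffs["c1"][1:] < 0.0)

    def test_perturbation_leaving_domain_rejected(self, s52_params, s52_init):
        with pytest.raises(ParameterError):
            ko_response(s52_params, s52_init, "a1", 0.7, np.linspace(0, 1, 3))


class TestLongTimeBehaviour:
    """Effects of stem-parameter changes fade as the stem pool empties.

    Every analysed derivative is a product of the declining stem pool
    and an at-most-affine factor, so it tends to zero; the neuron count
    is the exception whose fate depends on the neuron death rate.  The
    slowest system timescale here is 1/d4 = 20 time units, so the
    horizons below are several multiples of it.
    """

    def test_progenitor_effect_decays_to_zero(self, s52_params, s52_init):
        grid = np.linspace(0, 60, 1201)
        curve = forward_sensitivities(s52_params, s52_init, "a1", grid)["c2"]
        assert abs(curve.values[-1]) < 1e-3 * curve.max_abs()

    def test_neuron_response_plateaus_without_neuron_death(self, s52_params, s52_init):
        grid = np.linspace(0, 100, 2001)
        p0 = s52_params.replace(d4=0.0)
        curve = forward_sensitivities(p0, s52_init, "a1", grid)["c4"]
        window = curve.values[grid >= 80]
        assert window[-1] > 0.0
        assert np.max(np.abs(window - window[-1])) / window[-1] < 1e-4

    def test_neuron_response_decays_with_neuron_death(self, s52_params, s52_init):
        grid = np.linspace(0, 100, 2001)
        curve = forward_sensitivities(s52_params, s52_init, "a1", grid)["c4"]
        assert abs(curve.values[-1]) < 0.05 * curve.max_abs()
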