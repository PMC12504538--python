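"""Grünwald–Letnikov stepper, breath references and closed-loop runs."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.special import erfcx

import fracvent as fv
from fracvent.mittag_leffler import mittag_leffler


def scalar_relaxation(alpha):
    """D^alpha x = -x + u as a 1x1 model."""
    return fv.FractionalStateModel(
        a=[[-1.0]], b=[[1.0]], c=[[1.0]], d=[[0.0]], alpha=alpha
    )


class TestGlCoefficients:
    def test_integer_orders_reduce_to_finite_differences(self):
        np.testing.assert_allclose(
            fv.gl_coefficients(1.0, 4), [1, -1, 0, 0, 0], atol=1e-15
        )
        # alpha -> 2 is an open endpoint; the limit weights are (1, -2, 1, 0, ...)
        w = fv.gl_coefficients(2.0 - 1e-12, 4)
        np.testing.assert_allclose(w, [1, -2, 1, 0, 0], atol=1e-10)

    def test_half_order_recurrence_by_hand(self):
        w = fv.gl_coefficients(0.5, 3)
        assert w[1] == pytest.approx(-0.5)
        assert w[2] == pytest.approx(-0.125)  # w1 * (1 - 1.5/2)
        assert w[3] == pytest.approx(-0.0625)

    def test_weights_sum_toward_zero(self):
        # sum_j w_j = (1-1)^alpha = 0 in the limit of infinitely many terms
        w = fv.gl_coefficients(0.7, 4000)
        assert abs(w.sum()) < 1e-2
        assert abs(w.sum()) < abs(w[:100].sum())


class TestMittagLeffler:
    def test_half_order_closed_form(self):
        x = np.array([0.2, 1.0, 2.0, 3.5])
        np.testing.assert_allclose(
            mittag_leffler(0.5, -x), erfcx(x), rtol=1e-8
        )

    def test_exponential_special_case(self):
        x = np.linspace(0, 5, 11)
        # cancellation in the alternating series limits accuracy near x = 5
        np.testing.assert_allclose(
            mittag_leffler(1.0, -x), np.exp(-x), rtol=1e-9
        )

    def test_argument_range_guard(self):
        with pytest.raises(ValueError, match="unreliable"):
            mittag_leffler(0.5, -100.0)


class TestLtiSimulation:
    @pytest.mark.parametrize("alpha", [0.5, 1.55])
    def test_step_response_matches_mittag_leffler(self, alpha):
        """x(t) = 1 - E_alpha(-t^alpha) for D^alpha x = -x + 1 from rest."""
        glcfg = fv.GlConfig(dt=1e-3, t_end=1.0)
        t, x, _ = fv.simulate_lti_fractional(
            scalar_relaxation(alpha), lambda _: 1.0, glcfg
        )
        exact = 1.0 - mittag_leffler(alpha, -(1.0**alpha))
        assert x[-1, 0] == pytest.approx(exact, rel=1e-3)

    def test_integer_order_matches_matrix_exponential(self):
        a = np.array([[-1.0, 2.0], [0.0, -3.0]])
        b = np.array([[0.0], [1.0]])
        model = fv.FractionalStateModel(a=a, b=b, c=[[1.0, 0.0]], d=[[0.0]], alpha=1.0)
        exact = np.linalg.solve(a, (expm(a * 1.0) - np.eye(2)) @ b).ravel()
        errs = []
        for dt in (2e-3, 1e-3):
            _, x, _ = fv.simulate_lti_fractional(
                model, lambda _: 1.0, fv.GlConfig(dt=dt, t_end=1.0)
            )
            errs.append(np.abs(x[-1] - exact).max())
        assert errs[1] < 1e-3 * np.abs(exact).max()
        assert 1.5 < errs[0] / errs[1] < 3.0  # first-order convergence in dt

    def test_zero_input_stays_at_rest(self, nominal):
        model, _ = nominal
        _, x, y = fv.simulate_lti_fractional(
            model, lambda _: 0.0, fv.GlConfig(dt=1e-2, t_end=0.5)
        )
        assert np.all(x == 0) and np.all(y == 0)

    def test_superposition(self):
        model = scalar_relaxation(1.3)
        glcfg = fv.GlConfig(dt=1e-2, t_end=2.0)
        u1 = lambda t: np.sin(3 * t)
        u2 = lambda t: 0.5 * (t < 1.0)
        _, x1, _ = fv.simulate_lti_fractional(model, u1, glcfg)
        _, x2, _ = fv.simulate_lti_fractional(model, u2, glcfg)
        _, x12, _ = fv.simulate_lti_fractional(
            model, lambda t: u1(t) + u2(t), glcfg
        )
        np.testing.assert_allclose(x12, x1 + x2, atol=1e-12)

    def test_sinusoid_amplitude_matches_transfer_evaluation(self, nominal):
        """Steady 1 Hz response amplitude agrees with |Y(j*2*pi)| to 0.5%."""
        model, _ = nominal
        omega = 2 * np.pi
        t, _, y = fv.simulate_lti_fractional(
            model, lambda s: np.sin(omega * s), fv.GlConfig(dt=1e-3, t_end=12.0)
        )
        sel = t >= 7.0
        basis = np.column_stack([np.sin(omega * t[sel]), np.cos(omega * t[sel])])
        coef, *_ = np.linalg.lstsq(basis, y[sel, 0], rcond=None)
        amplitude = float(np.hypot(*coef))
        expected = abs(fv.ladder_admittance(model, omega))
        assert amplitude == pytest.approx(expected, rel=5e-3)

    def test_explicit_scheme_agrees_with_implicit(self):
        model = scalar_relaxation(0.8)
        _, xi, _ = fv.simulate_lti_fractional(
            model, lambda _: 1.0, fv.GlConfig(dt=1e-3, t_end=1.0)
        )
        _, xe, _ = fv.simulate_lti_fractional(
            model, lambda _: 1.0, fv.GlConfig(dt=1e-3, t_end=1.0, scheme="explicit")
        )
        assert xi[-1, 0] == pytest.approx(xe[-1, 0], rel=5e-3)

    def test_divergence_detection_names_the_step(self):
        unstable = fv.FractionalStateModel(
            a=[[5.0]], b=[[1.0]], c=[[1.0]], d=[[0.0]], alpha=1.0
        )
        with pytest.raises(fv.SimulationDivergedError, match="step"):
            fv.simulate_lti_fractional(
                unstable, lambda _: 1.0, fv.GlConfig(dt=1e-2, t_end=8.0)
            )


class TestReferenceSignal:
    def test_breath_cycle_values(self):
        profile = fv.VentilationProfile()
        assert profile.period == pytest.approx(3.75)
        assert profile.t_inspiration == pytest.approx(1.25)
        assert fv.reference_signal(profile, 0.5) == 0.48
        assert fv.reference_signal(profile, 2.0) == 0.0
        assert fv.reference_signal(profile, 3.75) == 0.48  # next cycle start

    def test_vectorized_evaluation(self):
        profile = fv.VentilationProfile()
        t = np.array([0.0, 1.24, 1.25, 3.74, 3.75])
        np.testing.assert_array_equal(
            fv.reference_signal(profile, t), [0.48, 0.48, 0.0, 0.0, 0.48]
        )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="t"):
            fv.reference_signal(fv.VentilationProfile(), -0.1)


class TestClosedLoopSimulation:
    def test_tracking_of_the_published_design(self, tracking_trace):
        """Mean flow error stays below 5% of the setpoint during the second
        inspiration, past the initial transient."""
        trace, profile = tracking_trace
        t = trace.time
        t0 = profile.period + 0.3 * profile.t_inspiration
        t1 = profile.period + profile.t_inspiration
        sel = (t >= t0) & (t < t1)
        mean_rel_err = np.mean(
            np.abs(trace.flow[sel] - 0.48)
        ) / 0.48
        assert mean_rel_err < 0.05

    def test_pressure_zero_during_expiration(self, tracking_trace):
        trace, _ = tracking_trace
        assert np.all(trace.pressure[~trace.phase] == 0.0)
        assert np.abs(trace.pressure[trace.phase]).max() > 0

    def test_zero_setpoint_keeps_everything_at_rest(self, nominal, printed_gains):
        model, _ = nominal
        profile = fv.VentilationProfile(flow_setpoint=0.0, n_cycles=1)
        trace = fv.simulate_closed_loop(
            model, printed_gains, profile, fv.GlConfig(dt=5e-3, t_end=3.75)
        )
        assert np.all(trace.flow == 0) and np.all(trace.pressure == 0)

    def test_step_refinement_converges(self, nominal, printed_gains):
        """Tidal volume from the measured flow changes < 1% when dt halves."""
        model, _ = nominal
        profile = fv.VentilationProfile(n_cycles=1)
        volumes = []
        for dt in (4e-3, 2e-3):
            trace = fv.simulate_closed_loop(
                model, printed_gains, profile, fv.GlConfig(dt=dt, t_end=3.75)
            )
            sel = trace.phase
            volumes.append(np.trapezoid(trace.flow[sel], trace.time[sel]))
        assert abs(volumes[1] - volumes[0]) / abs(volumes[1]) < 0.01

    def test_windup_variant_differs_from_default(self, nominal, printed_gains):
        # letting the integrators track the passive outflow changes the
        # second breath drastically (the documented windup failure mode)
        model, _ = nominal
        profile = fv.VentilationProfile(n_cycles=2)
        glcfg = fv.GlConfig(dt=5e-3, t_end=7.5)
        frozen = fv.simulate_closed_loop(
            model, printed_gains, profile, glcfg, expiration="freeze"
        )
        tracking = fv.simulate_closed_loop(
            model, printed_gains, profile, glcfg, expiration="track"
        )
        second = frozen.time >= profile.period
        assert (
            np.abs(tracking.flow[second] - frozen.flow[second]).max() > 0.1
        )

    def test_memory_truncation_close_to_full_history(self, nominal, printed_gains):
        model, _ = nominal
        profile = fv.VentilationProfile(n_cycles=1)
        full = fv.simulate_closed_loop(
            model, printed_gains, profile, fv.GlConfig(dt=5e-3, t_end=3.75)
        )
        short = fv.simulate_closed_loop(
            model, printed_gains, profile,
            fv.GlConfig(dt=5e-3, t_end=3.75, memory=400),
        )
        # the truncated tail mostly affects the slow passive-expiration decay;
        # the actively controlled inspiration phase is barely touched
        insp = full.phase
        assert np.abs(short.flow[insp] - full.flow[insp]).max() < 1e-3
        assert np.abs(short.flow - full.flow).max() < 0.05

    def test_trace_csv_round_trip(self, tmp_path, nominal, printed_gains):
        import pandas as pd

        model, _ = nominal
        profile = fv.VentilationProfile(n_cycles=1)
        trace = fv.simulate_closed_loop(
            model, printed_gains, profile, fv.GlConfig(dt=1e-2, t_end=1.0)
        )
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["t", "v", "y", "u", "phase"]
        np.testing.assert_allclose(frame["y"], trace.flow)
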