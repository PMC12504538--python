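"""Frequency response, ITAE ranking, volume metrics and robustness study."""

import numpy as np
import pandas as pd
import pytest

import fracvent as fv
from fracvent.analysis import CLASSIFY_TOL, default_frequency_grid


def first_order_lowpass(f_c):
    """Integer-order pole at -2*pi*f_c with unit DC gain."""
    w_c = 2 * np.pi * f_c
    return fv.FractionalStateModel(
        a=[[-w_c]], b=[[w_c]], c=[[1.0]], d=[[0.0]], alpha=1.0
    )


class TestFrequencyResponse:
    def test_near_unity_tracking_in_band(self, nominal_closed_loop):
        h = fv.frequency_response(nominal_closed_loop, [0.01])
        assert abs(h[0]) == pytest.approx(1.0, rel=0.1)

    def test_rolloff_at_high_frequency(self, nominal_closed_loop):
        h = fv.frequency_response(nominal_closed_loop, [0.01, 50.0, 500.0])
        assert abs(h[1]) < 0.5 * abs(h[0])
        assert abs(h[2]) < abs(h[1])

    def test_nonpositive_frequency_rejected(self, nominal_closed_loop):
        with pytest.raises(ValueError, match="frequencies"):
            fv.frequency_response(nominal_closed_loop, [0.0])


class TestPassband:
    def test_published_design_passband_near_6_hz(self, nominal_closed_loop):
        assert fv.passband(nominal_closed_loop) == pytest.approx(6.0, abs=1.5)

    def test_first_order_closed_form(self):
        f_c = 2.0
        measured = fv.passband(first_order_lowpass(f_c))
        assert measured == pytest.approx(f_c, rel=0.01)

    def test_peak_reference_convention_is_lower(self, nominal_closed_loop):
        # the response peaks above the plateau, so the peak-referenced
        # passband is the more conservative number
        low = fv.passband(nominal_closed_loop, reference="low_freq")
        peak = fv.passband(nominal_closed_loop, reference="peak")
        assert peak < low

    def test_flat_response_raises(self):
        allpass = fv.FractionalStateModel(
            a=[[-1.0]], b=[[1.0]], c=[[0.0]], d=[[1.0]], alpha=1.0
        )
        with pytest.raises(ValueError, match="grid"):
            fv.passband(allpass)

    def test_bisection_refinement_agrees(self, nominal_closed_loop):
        """Grid passband is stable to < 0.5% under local grid refinement."""
        coarse = fv.passband(nominal_closed_loop)
        fine_grid = np.logspace(
            np.log10(coarse / 1.5), np.log10(coarse * 1.5), 2000
        )
        mag0 = abs(fv.frequency_response(nominal_closed_loop, [0.01])[0])
        mags = np.abs(fv.frequency_response(nominal_closed_loop, fine_grid))
        threshold = mag0 * 10 ** (-3 / 20)
        crossing = fine_grid[np.max(np.nonzero(mags >= threshold))]
        assert coarse == pytest.approx(crossing, rel=5e-3)


class TestItae:
    def test_zero_error_gives_zero(self):
        t = np.linspace(0, 2, 101)
        trace = fv.SimulationTrace(
            time=t, flow=np.full_like(t, 0.3), pressure=np.zeros_like(t),
            reference=np.full_like(t, 0.3), phase=np.ones_like(t, dtype=bool),
        )
        assert fv.itae(trace) == 0.0

    def test_constant_error_closed_form(self):
        # integral of t*e over [0, T] = e*T^2/2
        t = np.linspace(0, 2, 2001)
        e = 0.25
        trace = fv.SimulationTrace(
            time=t, flow=np.zeros_like(t), pressure=np.zeros_like(t),
            reference=np.full_like(t, e), phase=np.ones_like(t, dtype=bool),
        )
        assert fv.itae(trace) == pytest.approx(e * 2.0**2 / 2, rel=1e-6)

    def test_horizon_outside_trace_rejected(self):
        t = np.linspace(0, 1, 11)
        trace = fv.SimulationTrace(
            time=t, flow=np.zeros_like(t), pressure=np.zeros_like(t),
            reference=np.zeros_like(t), phase=np.ones_like(t, dtype=bool),
        )
        with pytest.raises(ValueError, match="horizon"):
            fv.itae(trace, horizon=(0.0, 2.0))


class TestVolumeMetrics:
    def test_reference_profile_delivers_published_volumes(self):
        tidal, minute = fv.volume_metrics(fv.VentilationProfile())
        assert tidal == pytest.approx(600.0)
        assert minute == pytest.approx(9.6)

    def test_linearity_in_setpoint(self):
        tidal, minute = fv.volume_metrics(
            fv.VentilationProfile(flow_setpoint=0.24)
        )
        assert tidal == pytest.approx(300.0)
        assert minute == pytest.approx(4.8)

    def test_measured_flow_delivers_near_nominal_volume(self, tracking_trace):
        trace, profile = tracking_trace
        tidal, minute = fv.volume_metrics(trace, profile, cycle=-1)
        assert tidal == pytest.approx(600.0, rel=0.05)
        assert minute == pytest.approx(9.6, rel=0.05)

    def test_incomplete_cycle_rejected(self, nominal, printed_gains):
        model, _ = nominal
        trace = fv.simulate_closed_loop(
            model, printed_gains, fv.VentilationProfile(n_cycles=1),
            fv.GlConfig(dt=1e-2, t_end=1.0),
        )
        with pytest.raises(ValueError, match="cycle"):
            fv.volume_metrics(trace, fv.VentilationProfile())


class TestGridSearch:
    def test_default_design_grid_has_27_combinations(self):
        grid = fv.design_grid()
        assert len(grid) == 27
        assert len(set(grid)) == 27
        assert (200.0, 5.0, 500.0) in grid

    def test_single_point_grid(self, nominal):
        model, _ = nominal
        # single-combination sweep on a reduced simulation horizon
        table = fv.grid_search(
            model,
            r_list=(200.0,), theta_deg_list=(5.0,), kr_list=(500.0,),
            profile=fv.VentilationProfile(n_cycles=1),
            glcfg=fv.GlConfig(dt=5e-3, t_end=3.75),
        )
        assert len(table) == 1
        assert table.loc[0, "status"] == "ok"
        assert np.isfinite(table.loc[0, "itae"]) and table.loc[0, "itae"] > 0

    def test_table_sorted_by_itae(self, nominal):
        model, _ = nominal
        table = fv.grid_search(
            model,
            r_list=(150.0, 200.0), theta_deg_list=(5.0,), kr_list=(500.0,),
            profile=fv.VentilationProfile(n_cycles=1),
            glcfg=fv.GlConfig(dt=5e-3, t_end=3.75),
        )
        assert len(table) == 2
        itaes = table["itae"].to_numpy()
        assert np.all(np.diff(itaes[np.isfinite(itaes)]) >= 0)


class TestRobustness:
    def test_zero_perturbation_reproduces_nominal(self, nominal, printed_gains,
                                                  design_region):
        model, net = nominal
        cfg = fv.RobustnessConfig(perturbation_pct=0.0, n_draws=5, seed=1)
        report = fv.robustness_study(model, net, printed_gains, cfg, design_region)
        assert report.draws["stable"].all()
        assert report.draws["all_in_region"].all()
        np.testing.assert_array_equal(report.draws["rho_r"], 1.0)
        for ev in report.eigenvalues[1:]:
            np.testing.assert_allclose(
                np.sort_complex(ev), np.sort_complex(report.eigenvalues[0])
            )

    def test_identical_seed_reproducible(self, nominal, printed_gains,
                                         design_region):
        model, net = nominal
        cfg = fv.RobustnessConfig(perturbation_pct=10.0, n_draws=10, seed=42)
        r1 = fv.robustness_study(model, net, printed_gains, cfg, design_region)
        r2 = fv.robustness_study(model, net, printed_gains, cfg, design_region)
        pd.testing.assert_frame_equal(r1.draws, r2.draws)

    def test_region_excursions_monotone_in_perturbation(
        self, nominal, printed_gains, design_region
    ):
        """Nested draws: larger bands can only push more draws out of S."""
        model, net = nominal
        counts = []
        for pct in (2.0, 5.0, 15.0):
            cfg = fv.RobustnessConfig(perturbation_pct=pct, n_draws=30, seed=7)
            report = fv.robustness_study(
                model, net, printed_gains, cfg, design_region
            )
            counts.append(report.n_left_region)
        assert counts == sorted(counts)

    def test_classification_consistency(self, nominal, printed_gains,
                                        design_region):
        # inside-S implies stable whenever theta respects the sector bound
        model, net = nominal
        assert design_region.theta <= fv.max_sector_angle(model.alpha)
        cfg = fv.RobustnessConfig(perturbation_pct=15.0, n_draws=20, seed=3)
        report = fv.robustness_study(model, net, printed_gains, cfg, design_region)
        flags = report.draws
        assert (flags["stable"] | ~flags["all_in_region"]).all()
        for ev, stable in zip(report.eigenvalues, flags["stable"]):
            assert stable == fv.is_in_stability_region(
                ev, model.alpha, tol=CLASSIFY_TOL
            )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="perturbation_pct"):
            fv.RobustnessConfig(perturbation_pct=100.0)
        with pytest.raises(ValueError, match="n_draws"):
            fv.RobustnessConfig(n_draws=0)


def test_default_grid_covers_identified_band():
    grid = default_frequency_grid()
    assert grid[0] == pytest.approx(0.01)
    assert grid[-1] == pytest.approx(50.0)
    assert len(grid) >= 400
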