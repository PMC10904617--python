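import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pcabsim as ps
from pcabsim.nca import (
    MetricsError,
    ObservedSeries,
    fold_change_flag,
    geometric_mean_ci,
    pearson_r,
    terminal_slope,
)
from pcabsim.pbpk import PKProfile


def _synthetic_profile(times, conc, calibrated_pk):
    """Wrap an arbitrary concentration series in a PKProfile shell."""
    return PKProfile(
        time_h=np.asarray(times, dtype=float),
        plasma_ng_mL=np.asarray(conc, dtype=float),
        stomach_free_ng_mL=np.zeros(len(times)),
        amounts_ug=np.zeros((len(times), calibrated_pk.amounts_ug.shape[1])),
        compound=calibrated_pk.compound,
        regimen=calibrated_pk.regimen,
        physiology=calibrated_pk.physiology,
    )


class TestComputeMetrics:
    def test_monoexponential_closed_form(self, calibrated_pk):
        t = np.arange(0, 120.0, 0.01)
        prof = _synthetic_profile(t, 100 * np.exp(-0.1 * t), calibrated_pk)
        m = ps.compute_pk_metrics(prof)
        assert m.auc_0_inf == pytest.approx(1000.0, rel=1e-4)
        assert m.terminal_half_life == pytest.approx(6.931, abs=1e-3)
        assert m.cmax == pytest.approx(100.0, rel=1e-6)
        assert m.tmax == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_profile_flagged_undefined(self, calibrated_pk):
        t = np.arange(0, 48.0, 0.01)
        m = ps.compute_pk_metrics(_synthetic_profile(t, np.zeros_like(t), calibrated_pk))
        assert m.auc_0_t == 0.0
        assert m.cmax == 0.0
        assert math.isnan(m.auc_0_inf)
        assert math.isnan(m.terminal_half_life)

    def test_quadratic_peak_refinement_beats_grid(self, calibrated_pk):
        # peak of 10*exp(-(t-3)^2) lies between grid points
        t = np.arange(0, 10.0, 0.13)
        prof = _synthetic_profile(t, 10 * np.exp(-((t - 3.0) ** 2)), calibrated_pk)
        m = ps.compute_pk_metrics(prof)
        assert m.tmax == pytest.approx(3.0, abs=0.01)
        assert m.cmax == pytest.approx(10.0, abs=0.01)

    def test_trapezoid_converges_on_halved_grid(self, vonoprazan_calibrated, phys):
        from pcabsim.pbpk import SolverOptions

        coarse = ps.simulate_pk(
            vonoprazan_calibrated,
            ps.DoseRegimen(dose_mg=20, duration_h=48),
            phys,
            SolverOptions(output_step_h=0.02),
        )
        fine = ps.simulate_pk(
            vonoprazan_calibrated,
            ps.DoseRegimen(dose_mg=20, duration_h=48),
            phys,
            SolverOptions(output_step_h=0.01),
        )
        a1 = ps.compute_pk_metrics(coarse).auc_0_t
        a2 = ps.compute_pk_metrics(fine).auc_0_t
        assert abs(a1 - a2) / a2 < 1e-4


class TestTerminalSlope:
    def test_exact_exponential(self):
        t = np.linspace(0, 40, 200)
        lam, r2 = terminal_slope(t, 50 * np.exp(-0.2 * t))
        assert lam == pytest.approx(0.2, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_biexponential_window_in_terminal_phase(self):
        t = np.linspace(0, 60, 600)
        c = 80 * np.exp(-1.0 * t) + 20 * np.exp(-0.05 * t)
        lam, _ = terminal_slope(t, c, window=(30, 60))
        assert lam == pytest.approx(0.05, rel=0.01)

    def test_constant_series_has_zero_slope(self):
        t = np.linspace(0, 10, 50)
        lam, _ = terminal_slope(t, np.full_like(t, 5.0))
        assert lam == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(MetricsError, match=">=3"):
            terminal_slope([0, 1], [1.0, 0.5])


class TestStatistics:
    def test_geometric_mean_trivial_cases(self):
        gm, lo, hi = geometric_mean_ci([4.0, 4.0, 4.0])
        assert gm == pytest.approx(4.0)
        assert lo == pytest.approx(4.0)
        gm, _, _ = geometric_mean_ci([1.0, 100.0])
        assert gm == pytest.approx(10.0)

    def test_geometric_mean_monte_carlo_lognormal(self):
        rng = np.random.default_rng(42)
        v = np.exp(rng.normal(0, 1, size=10_000))
        gm, lo, hi = geometric_mean_ci(v)
        assert gm == pytest.approx(1.0, rel=0.03)
        assert lo < gm < hi

    def test_single_value_degenerates(self):
        gm, lo, hi = geometric_mean_ci([7.0])
        assert gm == pytest.approx(7.0)
        assert lo == gm and hi == gm

    def test_geometric_mean_rejects_nonpositive(self):
        with pytest.raises(MetricsError):
            geometric_mean_ci([1.0, 0.0])

    @given(st.floats(0.1, 100), st.floats(0.1, 100))
    @settings(max_examples=50, deadline=None)
    def test_fold_change_symmetric_and_bounded(self, a, b):
        fc = fold_change_flag(a, b)
        assert fc.ratio >= 1.0
        assert fc.ratio == pytest.approx(fold_change_flag(b, a).ratio)

    def test_two_fold_rule_boundary_inclusive(self):
        assert fold_change_flag(10, 5).significant
        assert not fold_change_flag(10, 6).significant
        assert fold_change_flag(3, 3).ratio == 1.0
        assert not fold_change_flag(3, 3).significant

    def test_geometric_mean_scale_equivariance(self):
        v = [1.3, 2.9, 8.1, 0.4]
        gm, _, _ = geometric_mean_ci(v)
        gm_scaled, _, _ = geometric_mean_ci([10 * x for x in v])
        assert gm_scaled == pytest.approx(10 * gm, rel=1e-12)

    def test_pearson_exact_lines(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_pearson_hand_computed_table(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        # hand computation: cov = 2.5, sx^2 = 2.5, sy^2 = 2.5 -> r = 0.8
        assert pearson_r(x, y) == pytest.approx(0.8, abs=1e-12)

    def test_pearson_zero_variance_rejected(self):
        with pytest.raises(MetricsError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_observed_series_validation(self):
        with pytest.raises(MetricsError):
            ObservedSeries(time_h=np.array([2.0, 1.0]), concentration_ng_mL=np.array([1.0, 2.0]))
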