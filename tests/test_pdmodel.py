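import math

import numpy as np
import pytest

import pcabsim as ps
from pcabsim.pdmodel import (
    PDConfig,
    PDError,
    PDProfile,
    PotencyParameters,
    _integrate_inhibition,
    binding_rate_constant,
    holding_time_percentage,
    kd_from_half_life,
    ki_from_ic50,
    onset_time,
    ph_mapping,
)

LN2 = math.log(2)


class TestPotencyDerivations:
    @pytest.mark.parametrize(
        "t_half, expected, digits",
        [(4.7, 0.147, 3), (LN2, 1.0, 9), (LN2 / 2, 2.0, 9)],
    )
    def test_kd_from_half_life(self, t_half, expected, digits):
        assert kd_from_half_life(t_half) == pytest.approx(expected, abs=0.5 * 10**-digits)

    @pytest.mark.parametrize("ic50, ki", [(0.019, 0.0095), (1.0, 0.5), (0.31, 0.155)])
    def test_ki_is_half_ic50(self, ic50, ki):
        assert ki_from_ic50(ic50) == pytest.approx(ki, rel=1e-12)

    @pytest.mark.parametrize(
        "ki, expected",
        [(0.0095, 15.524), (0.0145, 10.171), (0.155, 0.951), (0.5, 0.294)],
    )
    def test_binding_rate_constant_matches_published_table(self, ki, expected):
        k = binding_rate_constant(LN2 / 4.7, ki)
        assert k == pytest.approx(expected, rel=5e-3)

    def test_identity_case(self):
        assert binding_rate_constant(1.0, 1.0) == 1.0

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_domain_errors(self, bad):
        with pytest.raises(PDError):
            kd_from_half_life(bad)
        with pytest.raises(PDError):
            ki_from_ic50(bad)
        with pytest.raises(PDError):
            binding_rate_constant(1.0, bad)

    def test_potency_dataclass_fills_derived_fields(self):
        p = PotencyParameters(ic50_uM=0.019, dissociation_half_life_h=4.7)
        assert p.ki_uM == pytest.approx(0.0095)
        assert p.kd_1_h == pytest.approx(LN2 / 4.7, rel=1e-12)
        assert p.k_per_uM_h == pytest.approx(15.524, rel=5e-4)


class TestInhibitionODE:
    def test_zero_drive_stays_at_zero(self):
        t = np.linspace(0, 24, 100)
        p = PotencyParameters(ic50_uM=0.019, dissociation_half_life_h=4.7)
        out = _integrate_inhibition(t, np.zeros_like(t), p)
        assert np.all(out == 0)

    def test_constant_drive_reaches_closed_form_steady_state(self):
        p = PotencyParameters(ic50_uM=1.0, dissociation_half_life_h=4.7)
        ce = 0.05  # uM; modest drive so the steady state is interior
        k, kd = p.k_per_uM_h, p.kd_1_h
        t_end = 10.0 / (k * ce + kd)
        t = np.linspace(0, t_end, 2000)
        out = _integrate_inhibition(t, np.full_like(t, ce), p)
        i_ss = k * ce * p.imax / (k * ce + kd)
        assert out[-1] == pytest.approx(i_ss, rel=1e-3)

    def test_irreversible_limit_is_non_decreasing(self):
        p = PotencyParameters(
            ic50_uM=1.0, dissociation_half_life_h=4.7, kd_1_h=0.0, k_per_uM_h=0.5
        )
        rng = np.random.default_rng(5)
        t = np.linspace(0, 24, 500)
        ce = np.abs(rng.normal(0.1, 0.1, size=t.size))
        out = _integrate_inhibition(t, ce, p)
        assert np.all(np.diff(out) >= -1e-15)

    def test_inhibition_bounded_by_imax(self, calibrated_pk, potency, calibrated_pd_config):
        prof = ps.simulate_pd(calibrated_pk, potency, calibrated_pd_config)
        assert np.all(prof.inhibition >= 0)
        assert np.all(prof.inhibition <= potency.imax)
        assert np.allclose(prof.residual_secretion, 1 - prof.inhibition)

    def test_higher_binding_rate_never_lowers_holding_time(
        self, calibrated_pk, calibrated_pd_config
    ):
        # published K values span 0.294 ... 15.524 at fixed kd
        ks = [0.294, 0.546, 0.951, 1.735, 2.269, 10.171, 15.524]
        kd = LN2 / 4.7
        holdings = []
        for k in ks:
            # fixed kd, target k reached through ki = kd/k (ic50 = 2 ki)
            p = PotencyParameters(ic50_uM=2 * kd / k, dissociation_half_life_h=4.7)
            prof = ps.simulate_pd(calibrated_pk, p, calibrated_pd_config)
            holdings.append(holding_time_percentage(prof))
        assert np.all(np.diff(holdings) >= -1e-9)


class TestMappingAndEndpoints:
    def test_mapping_endpoints(self):
        cfg = PDConfig(ph_baseline=1.2, ph_max=7.0)
        assert ph_mapping(np.array([0.0]), cfg)[0] == pytest.approx(1.2)
        assert ph_mapping(np.array([1.0]), cfg)[0] == pytest.approx(7.0)
        assert ph_mapping(np.array([0.5]), cfg)[0] == pytest.approx(4.1)

    def _profile(self, ph):
        t = np.linspace(0, 30, len(ph))
        p = PotencyParameters(ic50_uM=0.019, dissociation_half_life_h=4.7)
        return PDProfile(
            time_h=t,
            ce_uM=np.zeros_like(t),
            inhibition=np.zeros_like(t),
            ph=np.asarray(ph, dtype=float),
            potency=p,
            config=PDConfig(),
        )

    def test_constant_high_ph_holds_100_percent(self):
        prof = self._profile(np.full(400, 7.0))
        assert holding_time_percentage(prof) == pytest.approx(100.0)
        assert onset_time(prof) == 0.0

    def test_constant_low_ph_holds_0_percent(self):
        prof = self._profile(np.full(400, 1.2))
        assert holding_time_percentage(prof) == pytest.approx(0.0)
        assert math.isnan(onset_time(prof))

    def test_square_pulse_interpolated_crossings(self):
        # pH 7 between t=6 and t=18 on a coarse grid: holding 50% of 24 h
        t = np.linspace(0, 30, 3001)
        ph = np.where((t >= 6) & (t <= 18), 7.0, 1.2)
        prof = self._profile(ph)
        assert holding_time_percentage(prof) == pytest.approx(50.0, abs=0.1)
        assert onset_time(prof) == pytest.approx(6.0, abs=0.02)

    def test_window_longer_than_profile_rejected(self):
        prof = self._profile(np.full(100, 7.0))
        with pytest.raises(PDError, match="window"):
            holding_time_percentage(prof, window_h=100.0)


class TestPhCeilingCalibration:
    def test_bisection_hits_target_holding(self, calibrated_pk, potency):
        cfg = ps.calibrate_ph_max(calibrated_pk, potency, 88.88)
        prof = ps.simulate_pd(calibrated_pk, potency, cfg)
        assert holding_time_percentage(prof) == pytest.approx(88.88, abs=0.01)
        assert 4.0 < cfg.ph_max < 14.0

    def test_unreachable_target_raises(self, vonoprazan_calibrated, potency, phys):
        tiny = ps.simulate_pk(
            vonoprazan_calibrated, ps.DoseRegimen(dose_mg=1e-7, duration_h=30), phys
        )
        with pytest.raises(PDError, match="unreachable"):
            ps.calibrate_ph_max(tiny, potency, 99.9)
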