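"""Runner physiology: aerobic curve, dynamics, bend force constraint."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trackpace import (
    RunnerParams,
    SigmaProfile,
    bend_force_cap,
    default_winner,
    dynamics_rhs,
    max_speed,
    sigma_of_e,
    vo2_to_power,
)


@pytest.fixture()
def profile():
    return SigmaProfile(
        sigma_max=8.54, sigma_rest=2.562, sigma_final=6.832,
        phi_ramp=0.9, phi_final=0.2,
    )


class TestSigmaCurve:
    def test_boundary_values(self, profile):
        e0 = 600.0
        assert sigma_of_e(e0, e0, profile) == pytest.approx(profile.sigma_rest)
        assert sigma_of_e(0.0, e0, profile) == pytest.approx(profile.sigma_final)
        assert sigma_of_e(0.9 * e0, e0, profile) == pytest.approx(profile.sigma_max)
        assert sigma_of_e(0.2 * e0, e0, profile) == pytest.approx(profile.sigma_max)

    def test_drop_midpoint_interpolates(self, profile):
        e0 = 600.0
        mid = sigma_of_e(0.5 * profile.phi_final * e0, e0, profile)
        assert mid == pytest.approx((profile.sigma_final + profile.sigma_max) / 2)

    @given(st.floats(0.05, 0.95))
    @settings(max_examples=100, deadline=None)
    def test_continuity_at_breakpoints(self, frac):
        e0 = 500.0
        prof = SigmaProfile(10.0, 3.0, 8.0, phi_ramp=max(min(frac, 0.95), 0.51),
                            phi_final=0.5 * min(frac, 0.5) + 1e-3)
        for brk in (prof.phi_final * e0, prof.phi_ramp * e0):
            left = sigma_of_e(brk - 1e-9 * e0, e0, prof)
            right = sigma_of_e(brk + 1e-9 * e0, e0, prof)
            assert abs(left - right) < 1e-6

    def test_domain_error(self, profile):
        with pytest.raises(ValueError):
            sigma_of_e(-1.0, 600.0, profile)
        with pytest.raises(ValueError):
            sigma_of_e(601.0, 600.0, profile)

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            SigmaProfile(10.0, 3.0, 8.0, phi_ramp=0.2, phi_final=0.9)
        with pytest.raises(ValueError):
            SigmaProfile(10.0, 12.0, 8.0)


class TestAerobicConversion:
    def test_zero(self):
        assert vo2_to_power(0.0) == 0.0

    def test_vo2max_85(self):
        # 85 mL/kg/min * 20.9 J/mL / 60 s
        assert vo2_to_power(85.0) == pytest.approx(29.6083, abs=1e-4)

    def test_85_percent_of_vo2max(self):
        assert 0.85 * vo2_to_power(85.0) == pytest.approx(25.167, abs=1e-3)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            vo2_to_power(-1.0)


class TestDynamics:
    def test_steady_state_speed(self, profile):
        p = default_winner()
        # f = v/tau and sigma balanced: both derivatives vanish
        v = np.sqrt(p.sigma.sigma_max * p.tau)
        f = v / p.tau
        e_mid = 0.5 * p.e0  # plateau
        dv, df, de = dynamics_rhs(v, f, e_mid, 0.0, p)
        assert dv == pytest.approx(0.0, abs=1e-12)
        assert de == pytest.approx(0.0, abs=1e-9)

    def test_direct_substitution(self):
        p = default_winner().with_field("tau", 1.5)
        dv, df, de = dynamics_rhs(6.0, 4.0, 0.5 * p.e0, 0.1, p)
        assert dv == pytest.approx(4.0 - 6.0 / 1.5)
        assert df == pytest.approx(0.1)
        assert de == pytest.approx(p.sigma.sigma_max - 24.0)

    def test_energy_balance_sign(self):
        p = default_winner()
        e_mid = 0.5 * p.e0
        sigma = p.sigma_at(e_mid)
        _, _, de_slow = dynamics_rhs(1.0, 0.5, e_mid, 0.0, p)   # f*v << sigma
        _, _, de_fast = dynamics_rhs(7.0, 1.7, e_mid, 0.0, p)   # f*v >> sigma
        assert de_slow > 0 and sigma > 0.5 * 1.0
        assert de_fast < 0 and sigma < 1.7 * 7.0


class TestBendForceCap:
    def test_straight_returns_full_budget(self):
        assert bend_force_cap(7.0, np.inf, 8.0) == pytest.approx(8.0)
        assert bend_force_cap(0.0, 36.5, 8.0) == pytest.approx(8.0)

    def test_worked_example(self):
        # sqrt(64 - 7^4 / 36.5^2)
        assert bend_force_cap(7.0, 36.5, 8.0) == pytest.approx(7.8866, abs=1e-4)

    def test_saturation(self):
        v = np.sqrt(8.0 * 36.5)
        assert bend_force_cap(v, 36.5, 8.0) == pytest.approx(0.0, abs=1e-6)
        assert bend_force_cap(v + 1.0, 36.5, 8.0) == 0.0

    @given(
        st.floats(0.1, 10.0), st.floats(0.1, 10.0),
        st.floats(10.0, 100.0), st.floats(1.0, 10.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotonicity(self, v, dv, R, f_M):
        # non-increasing in v, non-decreasing in R and f_M
        assert bend_force_cap(v + dv, R, f_M) <= bend_force_cap(v, R, f_M) + 1e-12
        assert bend_force_cap(v, R + 1.0, f_M) >= bend_force_cap(v, R, f_M) - 1e-12
        assert bend_force_cap(v, R, f_M + 1.0) >= bend_force_cap(v, R, f_M)


class TestRunnerParams:
    def test_max_speed_product(self):
        p = default_winner().with_field("f_M", 1.6).with_field("tau", 4.0)
        assert max_speed(p) == pytest.approx(6.4)
        assert p.max_speed == pytest.approx(6.4)

    def test_max_speed_exceeds_cruise_speed(self):
        p = default_winner()
        assert p.max_speed > np.sqrt(p.sigma.sigma_max * p.tau)

    def test_positive_fields_enforced(self):
        with pytest.raises(ValueError):
            default_winner().with_field("tau", -1.0)

    def test_implausible_max_speed_rejected(self):
        with pytest.raises(ValueError, match="maximal-speed"):
            default_winner().with_field("tau", 20.0)

    def test_json_roundtrip(self, tmp_path):
        p = default_winner()
        path = tmp_path / "runner.json"
        p.to_json(path)
        assert RunnerParams.from_json(path) == p

    def test_invalid_key_reported(self):
        with pytest.raises(ValueError, match="invalid runner parameters"):
            RunnerParams.from_dict({"e0": 600.0, "bogus": 1.0})
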