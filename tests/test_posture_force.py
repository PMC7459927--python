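"""Trunk geometry and the erector spinae torque balance."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from waistload import (DomainError, HeightRangeError, custom_profile,
                       erector_force, force_coefficients,
                       torque_balance_oracle, trunk_cosine,
                       valid_height_range)

G_PER_KG = 9.8


class TestTrunkCosine:
    def test_lower_bound_is_fully_flexed(self, std):
        p = trunk_cosine(28.6, std)
        assert p.in_range
        assert p.cos_alpha == pytest.approx(0.0, abs=1e-3)
        assert p.alpha_deg == pytest.approx(90.0, abs=0.1)

    def test_above_upper_bound_is_out_of_range(self, std):
        assert not trunk_cosine(74.1, std).in_range

    def test_cosine_at_70cm_matches_published_rounding(self, std):
        # 3.70 * 70/168 - 0.63
        assert trunk_cosine(70, std).cos_alpha == pytest.approx(0.9117, abs=5e-4)

    def test_derived_mode_uses_exact_fraction(self, std):
        p = trunk_cosine(70, std, mode="derived")
        assert p.cos_alpha == pytest.approx((70 / 168 + 0.37 - 0.54) / 0.27)

    def test_negative_height_is_hard_error(self, std):
        with pytest.raises(DomainError):
            trunk_cosine(-1, std)

    @given(h=st.floats(min_value=29, max_value=73.9))
    @settings(derandomize=True, max_examples=60)
    def test_pythagorean_identity(self, h):
        p = trunk_cosine(h)
        assert p.cos_alpha ** 2 + p.sin_alpha ** 2 == pytest.approx(1.0)
        if p.in_range:
            assert 0 <= p.cos_alpha < 1 and 0 < p.sin_alpha <= 1


class TestValidHeightRange:
    def test_standard_bounds_to_one_decimal(self, std):
        lo, hi = valid_height_range(std)
        assert round(lo, 1) == 28.6
        assert round(hi, 1) == 74.0

    def test_bounds_scale_linearly_with_stature(self, std):
        lo, hi = valid_height_range(std)
        tall = custom_profile(168 * 1.25, 59)
        lo2, hi2 = valid_height_range(tall)
        assert (lo2, hi2) == pytest.approx((lo * 1.25, hi * 1.25))

    def test_lower_bound_posture_is_fully_flexed(self, std):
        lo, _ = valid_height_range(std)
        assert trunk_cosine(lo, std).sin_alpha == pytest.approx(1.0, abs=1e-6)

    def test_upper_bound_excluded(self, std):
        _, hi = valid_height_range(std)
        assert not trunk_cosine(hi, std).in_range
        with pytest.raises(HeightRangeError):
            erector_force(0.0, hi, std)


class TestForceCoefficients:
    def test_published_rounded_pair(self, std):
        assert force_coefficients(std) == (3.42, 9.06)

    def test_derived_pair_from_lever_fractions(self, std):
        c1, c2 = force_coefficients(std, mode="derived")
        assert c1 == pytest.approx(3.421, abs=5e-4)
        assert c2 == pytest.approx(9.060, abs=5e-4)

    def test_derived_coefficients_linear_in_k2(self, std):
        from dataclasses import replace
        doubled = replace(std, k2=2 * std.k2)
        c1, c2 = force_coefficients(std, mode="derived")
        d1, d2 = force_coefficients(doubled, mode="derived")
        assert d2 == pytest.approx(2 * c2)
        assert d1 == pytest.approx(c1 + std.j2 * std.k2 / std.erector_arm_frac)


class TestErectorForce:
    def test_reproduces_peak_force_at_limit_load(self, std):
        # G = weight of the 34-cm recommended limit (14.871 kg)
        res = erector_force(145.74, 34, std)
        assert res.erector_force_F == pytest.approx(3273.8, abs=0.5)

    def test_zero_load_at_lower_bound_gives_trunk_constant(self, std):
        lo, _ = valid_height_range(std)
        res = erector_force(0.0, lo, std)
        assert res.erector_force_F == pytest.approx(3.42 * 578, abs=1e-9)
        assert res.posture.sin_alpha == 1.0

    def test_abdominal_relief_magnitude(self, std):
        on = erector_force(200, 50, std, mode="derived", include_abdominal=True)
        off = erector_force(200, 50, std, mode="derived", include_abdominal=False)
        assert off.erector_force_F - on.erector_force_F == pytest.approx(
            0.0228 * 578, abs=0.1)

    def test_out_of_range_height_names_interval(self, std):
        with pytest.raises(HeightRangeError) as exc:
            erector_force(10.0, 20.0, std)
        assert "28.6" in str(exc.value) and "74.0" in str(exc.value)

    def test_negative_load_rejected(self, std):
        with pytest.raises(DomainError):
            erector_force(-5.0, 50, std)

    @given(g=st.floats(min_value=0, max_value=588), h=st.floats(30, 73))
    @settings(derandomize=True, max_examples=60)
    def test_force_increases_with_load(self, g, h):
        base = erector_force(g, h).erector_force_F
        more = erector_force(g + 10, h).erector_force_F
        assert more > base

    @given(h=st.floats(min_value=30, max_value=72.5))
    @settings(derandomize=True, max_examples=60)
    def test_force_decreases_with_height_at_fixed_load(self, h):
        f1 = erector_force(100.0, h).erector_force_F
        f2 = erector_force(100.0, h + 0.5).erector_force_F
        assert f2 < f1

    @given(h=st.floats(min_value=30, max_value=73),
           scale=st.floats(min_value=0.8, max_value=1.35))
    @settings(derandomize=True, max_examples=40)
    def test_posture_depends_only_on_h_over_H(self, std, h, scale):
        scaled = custom_profile(168 * scale, 59)
        a = erector_force(100.0, h, std).posture
        b = erector_force(100.0, h * scale, scaled).posture
        assert b.sin_alpha == pytest.approx(a.sin_alpha, rel=1e-9)

    def test_rounded_and_derived_modes_agree_within_half_percent(self, std):
        for h in range(30, 73):
            for g_kg in (0, 20, 40, 60):
                fr = erector_force(g_kg * G_PER_KG, h, std).erector_force_F
                fd = erector_force(g_kg * G_PER_KG, h, std,
                                   mode="derived").erector_force_F
                # largest relative spread sits near the upright end where
                # sin(alpha) is smallest
                assert fd == pytest.approx(fr, rel=0.025)


class TestTorqueBalanceOracle:
    """Lever-by-lever moment sum as an independent check of the closed form."""

    def test_matches_closed_form_on_grid(self, std):
        for h in [30 + 4.3 * i for i in range(10)]:
            for g in [0, 50, 150, 350, 600]:
                for abdominal in (False, True):
                    oracle = torque_balance_oracle(g, h, std, abdominal)
                    closed = erector_force(g, h, std, mode="derived",
                                           include_abdominal=abdominal)
                    assert oracle == pytest.approx(
                        closed.erector_force_F, rel=1e-12)

    def test_zero_load_constant_unrounded(self, std):
        lo, _ = valid_height_range(std, mode="derived")
        assert torque_balance_oracle(0.0, lo, std) == pytest.approx(1977.3, abs=0.5)

    @given(g=st.floats(min_value=1, max_value=600),
           h=st.floats(min_value=30, max_value=73))
    @settings(derandomize=True, max_examples=40)
    def test_load_contribution_is_linear(self, std, g, h):
        c2 = force_coefficients(std, mode="derived")[1]
        sin_a = trunk_cosine(h, std, mode="derived").sin_alpha
        diff = torque_balance_oracle(g, h, std) - torque_balance_oracle(0.0, h, std)
        assert diff == pytest.approx(c2 * g * sin_a, abs=1e-9 * max(1.0, diff))
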