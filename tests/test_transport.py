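"""Unit and property tests for the pointwise physics layer."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bioprotonic import (
    DEFAULT_CONSTANTS,
    PHOSPHATE_5MM,
    BufferSpec,
    ChannelGating,
    ElectrodeSpec,
    MembraneSpec,
    PhysicalConstants,
    buffer_capacity,
    bulk_concentration_from_pH,
    effective_permeability,
    electrode_current_density,
    ghk_current_density,
    nernst_potential,
    proton_content,
    thermal_voltage_factor,
)

F = DEFAULT_CONSTANTS.faraday
f = DEFAULT_CONSTANTS.f_thermal

concentrations = st.floats(min_value=1e-8, max_value=1e3)
voltages = st.floats(min_value=-0.5, max_value=0.5)


class TestConstants:
    def test_defaults_are_the_conventional_values(self):
        c = PhysicalConstants()
        assert c.faraday == 96485.0
        assert round(c.f_thermal, 2) == 38.66
        assert c.elementary_charge == pytest.approx(1.602176634e-19)

    def test_f_thermal_matches_room_temperature(self):
        # F/RT at 300.15 K reproduces the conventional 38.66 V^-1 to 2 dp
        assert round(thermal_voltage_factor(300.15), 2) == 38.66

    def test_ph7_bulk_concentration(self):
        assert bulk_concentration_from_pH(7.0) == pytest.approx(1e-4, rel=1e-12)

    @pytest.mark.parametrize("bad", [{"faraday": -1.0}, {"f_thermal": 0.0}])
    def test_nonpositive_constants_rejected(self, bad):
        with pytest.raises(ValueError):
            PhysicalConstants(**bad)


class TestGHK:
    @pytest.mark.parametrize(
        "P, V, c_B, c_IL, expected, rel",
        [
            # no gradient, no field
            (0.58, 0.0, 1e-4, 1e-4, 0.0, None),
            # closed-form evaluation at the gA permeability; the measured
            # device maximum is -45 A/m2 (checked separately below)
            (0.58, -0.2, 1e-4, 1e-4, -43.26927716, 1e-8),
            # ALM permeability at -200 mV: -5.52 mA/cm2
            (0.74, -0.2, 1e-4, 1e-4, -55.20562948, 1e-8),
            # V -> 0+ with a pure concentration gradient: P*F*(c_IL - c_B)
            (1.0, 1e-12, 1e-4, 2e-4, 9.6485, 1e-6),
        ],
    )
    def test_closed_form_values(self, P, V, c_B, c_IL, expected, rel):
        j = ghk_current_density(P, V, c_B, c_IL)
        if expected == 0.0:
            assert j == 0.0
        else:
            assert j == pytest.approx(expected, rel=rel)

    def test_ga_value_consistent_with_measured_maximum(self):
        # model steady current vs the measured -4.5 mA/cm2 gA maximum
        j = ghk_current_density(0.58, -0.2, 1e-4, 1e-4) / 10.0
        assert abs(j - (-4.5)) / 4.5 < 0.04

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(P_eff=0.5, V_m=0.1, c_B=0.0, c_IL=1e-4),
            dict(P_eff=0.5, V_m=0.1, c_B=1e-4, c_IL=-1e-5),
            dict(P_eff=0.5, V_m=float("nan"), c_B=1e-4, c_IL=1e-4),
            dict(P_eff=0.5, V_m=float("inf"), c_B=1e-4, c_IL=1e-4),
            dict(P_eff=-0.1, V_m=0.1, c_B=1e-4, c_IL=1e-4),
        ],
    )
    def test_domain_errors(self, kwargs):
        with pytest.raises(ValueError):
            ghk_current_density(**kwargs)

    def test_finite_at_extreme_fields(self):
        for V in (-5.0, 5.0):
            assert math.isfinite(ghk_current_density(1.0, V, 1e-4, 1e-4))

    @given(c_B=concentrations, c_IL=concentrations, sign=st.sampled_from([-1.0, 1.0]))
    def test_continuity_across_series_switch(self, c_B, c_IL, sign):
        # the closed form and its small-field series must agree at the
        # |f*V| = 1e-6 branch boundary to well under 1e-9 relative
        u0 = sign * 1e-6
        lo = ghk_current_density(1.0, u0 * (1 - 1e-10) / f, c_B, c_IL)
        hi = ghk_current_density(1.0, u0 * (1 + 1e-10) / f, c_B, c_IL)
        scale = max(abs(lo), abs(hi), F * max(c_B, c_IL) * 1e-6)
        assert abs(hi - lo) / scale < 1e-9

    @given(
        c_B=st.floats(min_value=1e-5, max_value=10.0),
        c_IL=st.floats(min_value=1e-5, max_value=10.0),
        V=st.floats(min_value=-0.2, max_value=0.2),
    )
    def test_monotone_in_concentrations(self, c_B, c_IL, V):
        j = ghk_current_density(0.58, V, c_B, c_IL)
        assert ghk_current_density(0.58, V, c_B, c_IL * 1.01) > j
        assert ghk_current_density(0.58, V, c_B * 1.01, c_IL) < j


class TestNernst:
    def test_equal_concentrations_give_zero(self):
        assert nernst_potential(5e-4, 5e-4) == 0.0

    def test_decade_ratio(self):
        assert nernst_potential(1e-3, 1e-4) == pytest.approx(math.log(10) / 38.66, rel=1e-12)
        assert nernst_potential(1e-3, 1e-4) == pytest.approx(0.05956, abs=5e-6)

    @given(a=concentrations, b=concentrations)
    def test_exact_antisymmetry(self, a, b):
        assert nernst_potential(a, b) == -nernst_potential(b, a)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nernst_potential(0.0, 1e-4)
        with pytest.raises(ValueError):
            nernst_potential(1e-4, -1.0)


class TestElectrode:
    def test_zero_overpotential_is_exchange_equilibrium(self):
        e = ElectrodeSpec(i0=10.0, alpha=0.5, V0=-0.25)
        assert electrode_current_density(e, e.V0, 0.0, True) == 0.0
        e2 = ElectrodeSpec(i0=10.0, alpha=0.5, V0=-0.22233)
        V_N = 0.01
        assert electrode_current_density(e2, e2.V0 + V_N, V_N, True) == pytest.approx(0.0, abs=1e-10)

    def test_linear_regime(self):
        e = ElectrodeSpec(i0=10.0, alpha=0.5, V0=0.0)
        eta = 1e-5
        i = electrode_current_density(e, eta, 0.0, True)
        assert i == pytest.approx(e.i0 * f * eta, rel=1e-3)

    def test_oxidation_branch_suppressed_without_hydride(self):
        # hand evaluation: i = -i0 * exp((1-alpha)*f*0.1) = -69.1 A/m2
        e = ElectrodeSpec(i0=10.0, alpha=0.5, V0=0.0)
        i = electrode_current_density(e, -0.1, 0.0, hydride_available=False)
        assert i == pytest.approx(-10.0 * math.exp(0.5 * 38.66 * 0.1), rel=1e-12)
        assert i == pytest.approx(-69.1, abs=0.05)

    def test_fractional_availability_scales_anodic_branch(self):
        e = ElectrodeSpec(i0=5.0, alpha=0.4, V0=0.0)
        full = electrode_current_density(e, 0.05, 0.0, True)
        none = electrode_current_density(e, 0.05, 0.0, False)
        half = electrode_current_density(e, 0.05, 0.0, 0.5)
        assert half == pytest.approx((full + none) / 2, rel=1e-12)

    def test_overflow_guarded(self):
        e = ElectrodeSpec(i0=10.0, alpha=0.5, V0=0.0)
        assert math.isfinite(electrode_current_density(e, 50.0, 0.0, True))
        assert math.isfinite(electrode_current_density(e, -50.0, 0.0, True))

    @given(
        eta=st.floats(min_value=-0.3, max_value=0.3),
        alpha=st.floats(min_value=0.05, max_value=0.95),
    )
    def test_sign_and_monotonicity_in_overpotential(self, eta, alpha):
        e = ElectrodeSpec(i0=3.0, alpha=alpha, V0=0.0)
        i = electrode_current_density(e, eta, 0.0, True)
        assert math.copysign(1.0, i) == math.copysign(1.0, eta) or i == 0.0
        assert electrode_current_density(e, eta + 1e-4, 0.0, True) > i

    @pytest.mark.parametrize("bad", [{"i0": 0.0}, {"alpha": 1.0}, {"alpha": 0.0}, {"x_max": 1.5}])
    def test_spec_validation(self, bad):
        with pytest.raises(ValueError):
            ElectrodeSpec(**bad)


class TestBufferCapacity:
    def test_pure_water_at_neutral_pH(self):
        # both water terms equal 1e-4 mol/m3 at pH 7
        beta = buffer_capacity(BufferSpec(), 7.0)
        assert beta == pytest.approx(math.log(10) * 2e-4, rel=1e-12)

    def test_phosphate_van_slyke_value(self):
        # 5 mol/m3 phosphate (pKa 7.21) at pH 7 with water
        beta = buffer_capacity(PHOSPHATE_5MM, 7.0)
        assert beta == pytest.approx(2.7168, rel=1e-4)

    def test_override_short_circuits(self):
        spec = BufferSpec(species=((5.0, 7.21),), beta_override=10.0)
        assert buffer_capacity(spec, 3.0) == 10.0
        assert buffer_capacity(spec, 11.0) == 10.0

    def test_zero_capacity_configuration_rejected(self):
        with pytest.raises(ValueError):
            buffer_capacity(BufferSpec(include_water=False), 7.0)

    @given(pH=st.floats(min_value=2.0, max_value=12.0))
    def test_buffered_solution_exceeds_water_only(self, pH):
        water = buffer_capacity(BufferSpec(), pH)
        assert buffer_capacity(PHOSPHATE_5MM, pH) >= water

    @given(pH=st.floats(min_value=3.0, max_value=11.0))
    def test_content_is_antiderivative_of_capacity(self, pH):
        # dT/dpH = -beta, checked by central difference
        h = 1e-5
        dT = (proton_content(PHOSPHATE_5MM, pH + h) - proton_content(PHOSPHATE_5MM, pH - h)) / (2 * h)
        assert dT == pytest.approx(-buffer_capacity(PHOSPHATE_5MM, pH), rel=1e-6)


class TestEffectivePermeability:
    def test_alm_gating_closed_at_rest_open_at_minus_200(self):
        gating = ChannelGating(mode="voltage_threshold")
        m = MembraneSpec(P_base=0.006, P_channel=0.74, gating=gating)
        assert effective_permeability(m, 0.0) == 0.006
        assert effective_permeability(m, -0.2) == 0.74
        assert effective_permeability(m, 0.1) == 0.74
        assert effective_permeability(m, 0.059) == 0.006
        assert effective_permeability(m, 0.06) == 0.74

    def test_calcium_block_reduces_ga_to_bare_bilayer(self):
        m = MembraneSpec(P_base=0.006, P_channel=0.58, block_factor=0.0)
        for V in (-0.2, 0.0, 0.1):
            assert effective_permeability(m, V) == 0.006

    def test_always_open_channel(self):
        m = MembraneSpec(P_base=0.006, P_channel=0.58)
        assert effective_permeability(m, 0.0) == 0.58

    @given(
        V=voltages,
        block=st.floats(min_value=0.0, max_value=1.0),
        width=st.floats(min_value=0.0, max_value=0.05),
    )
    def test_bounded_between_base_and_channel(self, V, block, width):
        gating = ChannelGating(mode="voltage_threshold", smoothing_width=width)
        m = MembraneSpec(P_base=0.006, P_channel=0.74, gating=gating, block_factor=block)
        p = effective_permeability(m, V)
        assert 0.006 <= p <= 0.74

    def test_sigmoid_smoothing_is_gradual(self):
        gating = ChannelGating(mode="voltage_threshold", smoothing_width=0.01)
        m = MembraneSpec(P_base=0.006, P_channel=0.74, gating=gating)
        at_threshold = effective_permeability(m, 0.06)
        assert 0.006 < at_threshold < 0.74

    @pytest.mark.parametrize(
        "bad",
        [
            dict(P_base=0.5, P_channel=0.1),
            dict(P_base=-0.1, P_channel=0.1),
            dict(P_base=0.1, P_channel=0.5, block_factor=1.5),
        ],
    )
    def test_spec_validation(self, bad):
        with pytest.raises(ValueError):
            MembraneSpec(**bad)

    def test_unknown_gating_mode_rejected(self):
        with pytest.raises(ValueError):
            ChannelGating(mode="sometimes_open")
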