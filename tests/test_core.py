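import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import tplquad

from canopyflow import (
    AirProperties,
    CanopyLayer,
    FlowCondition,
    InfeasibleMeasurementError,
    JetGeometry,
    VelocityProfile,
    drag_force,
    dynamic_pressure,
    resistance_from_T,
    resistance_from_k,
    resistance_limit_k0,
    solve_k,
    velocity_at,
    velocity_profile,
    windward_area_per_volume,
)

from conftest import LAB_CAMPAIGN, REFERENCE_K, REFERENCE_T, make_layer


class TestVelocityAt:
    def test_surface_identity(self):
        assert velocity_at(FlowCondition(4), 0.746, 0.0) == 4.0

    def test_zero_attenuation(self):
        assert velocity_at(FlowCondition(7), 0.0, 0.5) == 7.0

    def test_direct_evaluation(self):
        # 4 * exp(-0.746 * 0.3) = 4 * exp(-0.2238)
        assert velocity_at(FlowCondition(4), 0.746, 0.3) == pytest.approx(
            4 * math.exp(-0.2238), rel=1e-12
        )
        assert velocity_at(FlowCondition(4), 0.746, 0.3) == pytest.approx(3.198, abs=1e-3)

    @pytest.mark.parametrize("y,k", [(-0.1, 1.0), (0.1, -1.0)])
    def test_negative_inputs_rejected(self, y, k):
        with pytest.raises(ValueError):
            velocity_at(FlowCondition(4), k, y)

    @given(
        v=st.floats(0.1, 20),
        k=st.floats(0.01, 5),
        y=st.floats(0.001, 2),
    )
    def test_strictly_below_surface_velocity(self, v, k, y):
        assert 0 < velocity_at(FlowCondition(v), k, y) < v


class TestVelocityProfile:
    def test_elementwise_and_monotone(self, depth_grid):
        prof = velocity_profile(FlowCondition(4), 0.746, depth_grid)
        expected = [velocity_at(FlowCondition(4), 0.746, y) for y in depth_grid]
        np.testing.assert_allclose(prof.velocities, expected, rtol=1e-14)
        assert np.all(np.diff(prof.velocities) < 0)
        assert prof.velocities[0] < 4.0

    def test_zero_incoming_velocity(self, depth_grid):
        prof = velocity_profile(FlowCondition(0), 1.2, depth_grid)
        assert np.all(prof.velocities == 0.0)

    def test_monotone_in_k(self, depth_grid):
        lo = velocity_profile(FlowCondition(8), 1.159, depth_grid)
        hi = velocity_profile(FlowCondition(8), 1.682, depth_grid)
        assert np.all(lo.velocities > hi.velocities)

    def test_unsorted_depths_rejected(self):
        with pytest.raises(ValueError):
            velocity_profile(FlowCondition(4), 1.0, [0.3, 0.15])

    def test_negative_depths_rejected(self):
        with pytest.raises(ValueError):
            velocity_profile(FlowCondition(4), 1.0, [-0.1, 0.15])

    def test_profile_type_validates_lengths(self):
        with pytest.raises(ValueError):
            VelocityProfile([0.1, 0.2], [1.0])


class TestDynamicPressure:
    def test_closed_form(self):
        assert dynamic_pressure(AirProperties(rho=1.29), 4.0).dp == pytest.approx(10.32)

    def test_zero_velocity(self):
        assert dynamic_pressure(AirProperties(rho=1.29), 0.0).dp == 0.0

    @given(v=st.floats(0.1, 30), rho=st.floats(0.5, 2.0))
    def test_quadratic_scaling(self, v, rho):
        air = AirProperties(rho=rho)
        assert dynamic_pressure(air, 2 * v).dp == pytest.approx(
            4 * dynamic_pressure(air, v).dp, rel=1e-12
        )

    def test_negative_velocity_rejected(self):
        with pytest.raises(ValueError):
            dynamic_pressure(AirProperties(), -1.0)


class TestDragForce:
    def test_unit_area(self):
        assert drag_force(AirProperties(1.29, 1.0), 4.0, 1.0) == pytest.approx(10.32)

    def test_campaign_scale_area(self):
        assert drag_force(AirProperties(1.29, 1.0), 4.0, 0.057) == pytest.approx(
            0.588, abs=5e-4
        )

    def test_zero_area(self):
        assert drag_force(AirProperties(), 10.0, 0.0) == 0.0

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            drag_force(AirProperties(), 1.0, -0.1)


class TestWindwardAreaPerVolume:
    @pytest.mark.parametrize("s,expected", [(0.057, 2.353), (0.065, 2.673)])
    def test_reference_values(self, s, expected, jet):
        assert windward_area_per_volume(s, jet, 0.3) == pytest.approx(
            expected, rel=0.015
        )

    def test_normalisation(self, jet):
        s = math.pi * jet.R**2 * 0.3
        assert windward_area_per_volume(s, jet, 0.3) == pytest.approx(1.0, rel=1e-14)

    def test_nonpositive_rejected(self, jet):
        with pytest.raises(ValueError):
            windward_area_per_volume(0.0, jet, 0.3)
        with pytest.raises(ValueError):
            windward_area_per_volume(0.05, jet, 0.0)


class TestResistanceFromK:
    def test_reference_forward_evaluation(self, air, sparse_layer):
        f = resistance_from_k(0.746, sparse_layer, FlowCondition(4), air)
        assert f == pytest.approx(0.97, rel=0.005)

    def test_small_k_approaches_limit(self, air, sparse_layer, cond4):
        limit = resistance_limit_k0(sparse_layer, cond4, air)
        assert limit == pytest.approx(0.057 * 1.29 * 16 * 0.9 / 0.6, rel=1e-12)
        f = resistance_from_k(1e-9, sparse_layer, cond4, air)
        assert f == pytest.approx(limit, rel=1e-6)

    def test_nonpositive_k_rejected(self, air, sparse_layer, cond4):
        with pytest.raises(ValueError):
            resistance_from_k(0.0, sparse_layer, cond4, air)

    @given(
        k1=st.floats(0.01, 5),
        k2=st.floats(0.01, 5),
    )
    def test_strictly_decreasing_in_k(self, k1, k2):
        air = AirProperties()
        layer = CanopyLayer(4.15, 0.057, 0.9, 0.3)
        cond = FlowCondition(8)
        f1 = resistance_from_k(k1, layer, cond, air)
        f2 = resistance_from_k(k2, layer, cond, air)
        if k1 < k2:
            assert f1 > f2
        elif k1 > k2:
            assert f1 < f2

    def test_quadrature_oracle(self, air, jet):
        # Independent check: triple-integrate the volumetric drag density
        # 0.5*rho*(v* e^{-ky})^2 * T over the cylinder of radius R, depth D.
        rho, R, D, Dp = air.rho, jet.R, 0.9, 0.3
        for k, s, v in [(0.746, 0.057, 4.0), (2.401, 0.065, 12.0)]:
            T = s / (math.pi * R**2 * Dp)

            def integrand(z, y, x, k=k, v=v, T=T):
                return 0.5 * rho * (v * math.exp(-k * y)) ** 2 * T

            val, err = tplquad(
                integrand,
                -R, R,
                lambda x: 0.0, lambda x: D,
                lambda x, y: -math.sqrt(max(R**2 - x**2, 0.0)),
                lambda x, y: math.sqrt(max(R**2 - x**2, 0.0)),
                epsabs=1e-10, epsrel=1e-10,
            )
            layer = CanopyLayer(4.15, s, D, Dp)
            closed = resistance_from_k(k, layer, FlowCondition(v), air)
            assert closed == pytest.approx(val, rel=1e-8)


class TestResistanceFromT:
    @given(
        k=st.floats(0.05, 5),
        s=st.floats(0.01, 0.2),
        v=st.floats(0.5, 15),
        d=st.floats(0.3, 1.5),
        dp=st.floats(0.1, 0.6),
    )
    @settings(max_examples=200)
    def test_identity_with_resistance_from_k(self, k, s, v, d, dp):
        air = AirProperties()
        jet = JetGeometry(0.16)
        layer = CanopyLayer(4.15, s, d, dp)
        cond = FlowCondition(v)
        T = windward_area_per_volume(s, jet, dp)
        f_T = resistance_from_T(k, T, jet, d, cond, air)
        f_k = resistance_from_k(k, layer, cond, air)
        assert f_T == pytest.approx(f_k, rel=1e-12)

    def test_rounded_T_forward_evaluation(self, air, jet):
        # with the published (rounded) T the force lands near 2.96
        f = resistance_from_T(1.159, 2.353, jet, 0.9, FlowCondition(8), air)
        assert f == pytest.approx(2.95, abs=0.02)

    def test_quadratic_in_v_star(self, air, jet):
        f1 = resistance_from_T(1.0, 2.4, jet, 0.9, FlowCondition(5), air)
        f2 = resistance_from_T(1.0, 2.4, jet, 0.9, FlowCondition(10), air)
        assert f2 == pytest.approx(4 * f1, rel=1e-12)


class TestSolveK:
    def test_reference_cell(self, air, sparse_layer, cond4):
        fit = solve_k(0.97, sparse_layer, cond4, air)
        assert fit.k == pytest.approx(0.746, rel=0.02)
        assert fit.residual < 1e-8

    def test_dense_high_velocity_cell(self, air):
        layer = make_layer(5.65)
        fit = solve_k(4.11, layer, FlowCondition(12), air)
        # independent bisection oracle gives 2.4166
        assert fit.k == pytest.approx(2.4166, rel=0.01)
        assert fit.k == pytest.approx(2.401, rel=0.01)

    @given(k_true=st.floats(0.05, 10))
    @settings(max_examples=100)
    def test_roundtrip_identity(self, k_true):
        air = AirProperties()
        layer = CanopyLayer(4.15, 0.057, 0.9, 0.3)
        cond = FlowCondition(8)
        f = resistance_from_k(k_true, layer, cond, air)
        fit = solve_k(f, layer, cond, air)
        assert fit.k == pytest.approx(k_true, rel=1e-8)

    def test_infeasible_above_supremum(self, air, sparse_layer, cond4):
        sup = resistance_limit_k0(sparse_layer, cond4, air)
        with pytest.raises(InfeasibleMeasurementError) as exc:
            solve_k(sup * 1.01, sparse_layer, cond4, air)
        assert exc.value.supremum == pytest.approx(sup)

    def test_infeasible_nonpositive_force(self, air, sparse_layer, cond4):
        with pytest.raises(InfeasibleMeasurementError):
            solve_k(0.0, sparse_layer, cond4, air)

    @pytest.mark.parametrize("lr,v", sorted(REFERENCE_K))
    def test_full_reference_grid(self, lr, v, air):
        s, f = LAB_CAMPAIGN[(lr, v)]
        layer = CanopyLayer(lr, s, 0.9, 0.3)
        fit = solve_k(f, layer, FlowCondition(v), air)
        assert fit.k == pytest.approx(REFERENCE_K[(lr, v)], rel=0.02)


class TestTypes:
    def test_air_invariants(self):
        with pytest.raises(ValueError):
            AirProperties(rho=-1.0)
        with pytest.raises(ValueError):
            AirProperties(c_d=0.0)

    def test_layer_invariants(self):
        with pytest.raises(ValueError):
            CanopyLayer(4.15, 0.057, 0.0, 0.3)

    def test_flow_condition(self):
        with pytest.raises(ValueError):
            FlowCondition(-1.0)

    def test_jet_geometry(self):
        with pytest.raises(ValueError):
            JetGeometry(0.0)
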