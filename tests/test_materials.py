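"""Flesh and foam constitutive laws, compression cycle, HU/SHAPE recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sitpress.materials import (
    FoamParams,
    OgdenParams,
    StressStrainCurve,
    cycle_dissipation,
    default_foam_loading_curve,
    equilibrium_strain,
    foam_loading_stress,
    foam_unloading_stress,
    identify_unloading_params,
    ogden_compressive_stretch,
    ogden_energy,
    ogden_uniaxial_stress,
    simulate_compression_test,
)


@pytest.fixture(scope="module")
def curve():
    return default_foam_loading_curve()


@pytest.fixture(scope="module")
def foam(curve):
    return FoamParams(loading_curve=curve, hu=0.65, shape=8.0, scale=1.15)


class TestOgden:
    def test_reference_state_is_stress_free(self):
        p = OgdenParams.neo_hookean(3.0)
        assert ogden_uniaxial_stress(p, 1.0) == 0.0

    def test_neo_hookean_closed_form(self):
        p = OgdenParams.neo_hookean(3.0)
        assert ogden_uniaxial_stress(p, 0.5) == pytest.approx(3.0 * (0.5 - 4.0))

    def test_small_strain_modulus(self):
        # incompressible: dsigma/dlambda at 1 equals 3*mu for alpha=2
        p = OgdenParams.neo_hookean(3.0)
        h = 1e-7
        slope = (ogden_uniaxial_stress(p, 1 + h) - ogden_uniaxial_stress(p, 1 - h)) / (2 * h)
        assert slope == pytest.approx(9.0, rel=1e-6)

    @pytest.mark.parametrize(
        "terms", [((3.0, 2.0),), ((2.0, 1.5), (1.0, 4.0)), ((5.0, -2.0), (4.0, 3.0))]
    )
    def test_stress_is_energy_derivative(self, terms):
        p = OgdenParams(terms=terms)
        h = 1e-6
        for lam in (0.4, 0.7, 1.0, 1.3, 2.0):
            num = (ogden_energy(p, lam + h) - ogden_energy(p, lam - h)) / (2 * h)
            assert ogden_uniaxial_stress(p, lam) == pytest.approx(num, rel=1e-7, abs=1e-8)

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(ValueError):
            ogden_uniaxial_stress(OgdenParams.neo_hookean(3.0), 0.0)

    def test_compressive_stretch_inverts_the_law(self):
        p = OgdenParams.neo_hookean(3.0)
        lam = ogden_compressive_stretch(p, 8.0)
        assert ogden_uniaxial_stress(p, lam) == pytest.approx(-8.0, abs=1e-9)
        assert ogden_compressive_stretch(p, 0.0) == 1.0


class TestFoamLoading:
    def test_origin(self, foam):
        assert foam_loading_stress(foam, 0.0) == 0.0

    def test_knots_exact(self, foam, curve):
        for e, s in curve[1:]:
            assert foam_loading_stress(foam, e) == pytest.approx(1.15 * s, rel=1e-12)

    def test_scale_linearity(self, curve):
        p1 = FoamParams(loading_curve=curve, scale=1.0)
        p115 = FoamParams(loading_curve=curve, scale=1.15)
        e = np.linspace(0.01, 0.8, 40)
        ratio = np.asarray(foam_loading_stress(p115, e)) / np.asarray(foam_loading_stress(p1, e))
        assert ratio == pytest.approx(np.full_like(e, 1.15))

    def test_no_extrapolation(self, foam):
        with pytest.raises(ValueError, match="range"):
            foam_loading_stress(foam, 0.9)


class TestFoamUnloading:
    def test_branch_continuity_at_max_strain(self, foam):
        assert foam_unloading_stress(foam, 0.8, 0.8) == pytest.approx(
            foam_loading_stress(foam, 0.8), rel=1e-12
        )

    def test_hu_one_is_elastic(self, curve):
        p = FoamParams(loading_curve=curve, hu=1.0, shape=8.0)
        e = np.linspace(0, 0.8, 30)
        np.testing.assert_allclose(
            foam_unloading_stress(p, e, 0.8), foam_loading_stress(p, e), rtol=1e-12
        )

    def test_unloading_below_loading(self, foam):
        e = np.linspace(0, 0.8, 50)
        su = foam_unloading_stress(foam, e, 0.8)
        sl = np.asarray(foam_loading_stress(foam, e))
        assert (su <= sl + 1e-12).all()
        assert (su >= foam.hu * sl - 1e-12).all()

    def test_cycle_dissipation_positive(self, foam, curve):
        load, unload = simulate_compression_test(foam, strain_step=0.005)
        diss = cycle_dissipation(load, unload)
        assert diss > 0
        # independent trapezoid oracle on the loop
        e = load.strain
        loop = np.trapezoid(load.stress, e) - np.trapezoid(unload.stress[::-1], e)
        assert diss == pytest.approx(loop, rel=1e-9)
        elastic = FoamParams(loading_curve=curve, hu=1.0, shape=8.0)
        l2, u2 = simulate_compression_test(elastic, strain_step=0.005)
        assert cycle_dissipation(l2, u2) == pytest.approx(0.0, abs=1e-12)

    def test_strain_beyond_history_rejected(self, foam):
        with pytest.raises(ValueError):
            foam_unloading_stress(foam, 0.5, 0.4)


class TestCompressionTest:
    def test_branches_match_pointwise(self, foam):
        load, unload = simulate_compression_test(foam, max_strain=0.8, strain_step=0.02)
        np.testing.assert_allclose(
            load.stress, np.asarray(foam_loading_stress(foam, load.strain)), rtol=1e-12
        )
        np.testing.assert_allclose(
            unload.stress, foam_unloading_stress(foam, unload.strain, 0.8), rtol=1e-12
        )
        assert load.mode == "loading" and unload.mode == "unloading"

    @pytest.mark.parametrize("mass_kg", [1.0, 2.0, 3.0])
    def test_mass_on_foam_equilibrium(self, foam, mass_kg):
        """Static mass over a 50x50 mm face: equilibrium strain solves
        sigma_L(e) = m g / A; cross-checked with a manual bisection oracle."""
        area_mm2 = 50.0 * 50.0
        stress_kpa = mass_kg * 9.81 / area_mm2 * 1e3
        e_star = equilibrium_strain(foam, stress_kpa)
        assert foam_loading_stress(foam, e_star) == pytest.approx(stress_kpa, abs=1e-9)
        lo, hi = 0.0, 0.8
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if foam_loading_stress(foam, mid) < stress_kpa:
                lo = mid
            else:
                hi = mid
        assert e_star == pytest.approx(0.5 * (lo + hi), abs=1e-6)

    def test_curve_scaling_shifts_equilibrium(self, curve):
        p1 = FoamParams(loading_curve=curve, scale=1.0)
        p115 = FoamParams(loading_curve=curve, scale=1.15)
        e = 0.45
        # same strain carries 1.15x the stress ...
        assert foam_loading_stress(p115, e) == pytest.approx(1.15 * foam_loading_stress(p1, e))
        # ... so a fixed load settles at the scaled curve's inverse
        stress = foam_loading_stress(p1, e)
        assert equilibrium_strain(p115, stress) == pytest.approx(
            equilibrium_strain(p115, foam_loading_stress(p115, equilibrium_strain(p115, stress)))
        )
        assert equilibrium_strain(p115, stress) < e


class TestIdentification:
    @pytest.mark.parametrize("hu,shape", [(0.65, 8.0), (0.65, 5.0)])
    def test_noise_free_recovery(self, curve, hu, shape):
        truth = FoamParams(loading_curve=curve, hu=hu, shape=shape, scale=1.15)
        _, unload = simulate_compression_test(truth, strain_step=0.02)
        hu_f, shape_f, rmse = identify_unloading_params(curve, unload, scale=1.15)
        assert hu_f == pytest.approx(hu, rel=0.01)
        assert shape_f == pytest.approx(shape, rel=0.01)
        assert rmse < 1e-6

    @pytest.mark.parametrize("hu,shape", [(0.65, 8.0), (0.65, 5.0)])
    def test_recovery_under_multiplicative_noise(self, curve, hu, shape):
        truth = FoamParams(loading_curve=curve, hu=hu, shape=shape, scale=1.15)
        _, unload = simulate_compression_test(truth, strain_step=0.02)
        rng = np.random.default_rng(2024)
        noisy = StressStrainCurve(
            points=np.column_stack(
                [unload.strain, unload.stress * rng.normal(1.0, 0.02, unload.stress.size)]
            ),
            mode="unloading",
        )
        hu_f, shape_f, _ = identify_unloading_params(curve, noisy, scale=1.15)
        assert hu_f == pytest.approx(hu, rel=0.10)
        assert shape_f == pytest.approx(shape, rel=0.10)

    def test_elastic_data_flag_shape_unidentifiable(self, curve):
        truth = FoamParams(loading_curve=curve, hu=1.0, shape=8.0)
        _, unload = simulate_compression_test(truth, strain_step=0.02)
        hu_f, shape_f, _ = identify_unloading_params(curve, unload)
        assert hu_f == 1.0
        assert np.isnan(shape_f)

    def test_degenerate_curve_rejected(self, curve):
        flat = StressStrainCurve(points=np.column_stack([np.linspace(0, 0.5, 5), np.zeros(5)]),
                                 mode="unloading")
        with pytest.raises(ValueError, match="degenerate"):
            identify_unloading_params(curve, flat)


@given(st.floats(0.2, 1.0), st.floats(0.5, 15.0), st.floats(0.05, 0.8))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_unloading_bounded_by_loading_everywhere(hu, shape, e_max):
    p = FoamParams(loading_curve=default_foam_loading_curve(), hu=hu, shape=shape)
    e = np.linspace(0, e_max, 25)
    su = foam_unloading_stress(p, e, e_max)
    sl = np.asarray(foam_loading_stress(p, e))
    assert (su <= sl + 1e-9).all()
    assert su[-1] == pytest.approx(sl[-1], rel=1e-9, abs=1e-12)
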