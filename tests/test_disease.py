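"""Ferritin turnover model: conversion rate, steady state, trajectories."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ferrodyn.disease import (DiseaseParameters, DrugEffectParameters,
                              ExposureTimeline, FerritinState,
                              conversion_rate, disease_status_scaling,
                              drug_effect, ferritin_rhs, simulate_ferritin,
                              steady_state)
from ferrodyn.exceptions import ComputationalError, DomainError


class TestStatusScaling:
    def test_median_ferritin_returns_reference(self, disease):
        scl_i, shp_i = disease_status_scaling(disease.ferritin_med, disease)
        assert scl_i == pytest.approx(disease.scl_ref, rel=1e-14)
        assert shp_i == pytest.approx(disease.shp_ref, rel=1e-14)

    @given(ferritin=st.floats(min_value=10.0, max_value=2e4))
    def test_zero_exponents_are_identity(self, disease, ferritin):
        flat = disease.without_status_scaling()
        scl_i, shp_i = disease_status_scaling(ferritin, flat)
        assert scl_i == flat.scl_ref
        assert shp_i == flat.shp_ref

    def test_doubled_ferritin_scale_factor(self, disease):
        # 2**0.845, evaluated independently
        scl_i, _ = disease_status_scaling(2.0 * disease.ferritin_med, disease)
        assert scl_i == pytest.approx(0.383 * 1.7962647457678684, rel=1e-12)


class TestConversionRate:
    def test_flat_when_shape_zero(self):
        params = DiseaseParameters(shp_ref=0.0, theta_scl=0.0, theta_shp=0.0)
        for f in (100.0, 2000.0, 9000.0):
            assert conversion_rate(f, params) == pytest.approx(params.scl_ref)

    def test_reference_value_at_median(self, disease):
        # 0.383 * exp(-0.00026 * 2260), independent spreadsheet arithmetic
        assert conversion_rate(disease.ferritin_med, disease) == pytest.approx(
            0.21281749962806212, rel=1e-12)

    def test_vanishes_at_extreme_overload(self, disease):
        assert conversion_rate(5e5, disease) < 1e-10


class TestDrugEffect:
    def test_zero_exposure(self, drug):
        assert drug_effect(0.0, drug) == 0.0

    def test_unit_exposure_equals_slope(self, drug):
        assert drug_effect(1.0, drug) == pytest.approx(4.81)

    @given(c=st.floats(min_value=0.0, max_value=50.0))
    def test_linearity(self, drug, c):
        assert drug_effect(2.0 * c, drug) == pytest.approx(
            2.0 * drug_effect(c, drug), rel=1e-12)


class TestFerritinRhs:
    def test_trivial_steady_state(self, drug):
        params = DiseaseParameters(scl_ref=0.0)
        f_star = params.kin / params.kout
        assert ferritin_rhs(FerritinState(f_star), 0.0, params, drug) == \
            pytest.approx(0.0, abs=1e-18)

    def test_net_accumulation_below_untreated_equilibrium(self, disease, drug):
        assert ferritin_rhs(FerritinState(2500.0), 0.0, disease, drug) > 0


class TestSteadyState:
    def test_linear_limit(self, drug):
        params = DiseaseParameters(scl_ref=0.0)
        assert steady_state(params, drug, 0.0) == pytest.approx(
            params.kin / params.kout, rel=1e-9)
        # kin/kout = 0.0002 / 0.0000045
        assert params.kin / params.kout == pytest.approx(44.4444444, rel=1e-6)

    def test_untreated_equilibrium_without_status_scaling(self, disease, drug):
        """Without the disease-status power laws the untreated equilibrium
        solves 0.0002 + 0.383 exp(-0.00026 F) = 4.5e-6 F, near 8.8e3 ug/L
        (value frozen from an independent bisection oracle)."""
        flat = disease.without_status_scaling()
        assert steady_state(flat, drug, 0.0) == pytest.approx(
            8763.33097656603, rel=1e-9)

    def test_matches_long_run_trajectory(self, disease, drug):
        for exposure in (0.0, 2.0, 4.35):
            target = steady_state(disease, drug, exposure)
            _, f = simulate_ferritin(3000.0, exposure, disease, drug,
                                     horizon=60 * 8766.0, method="rk4")
            assert f[-1] == pytest.approx(target, rel=1e-3)

    def test_strictly_decreasing_in_exposure(self, disease, drug):
        grid = [steady_state(disease, drug, e)
                for e in np.linspace(0.0, 8.0, 9)]
        assert np.all(np.diff(grid) < 0)

    def test_no_bracket_raises(self, drug):
        params = DiseaseParameters(scl_ref=0.0)
        with pytest.raises(ComputationalError):
            steady_state(params, drug, 0.0, bracket=(1e3, 1e6))


class TestSimulateFerritin:
    def test_linear_limit_matches_closed_form(self, drug):
        """With the transfusion term off the model is a linear first-order
        ODE with the analytic solution F* + (f0 - F*) exp(-k t)."""
        params = DiseaseParameters(scl_ref=0.0)
        f0, exposure = 1000.0, 0.0
        grid = np.linspace(0.0, 2e6, 200)
        f_star = params.kin / params.kout
        for method in ("rk4", "bdf"):
            t, f = simulate_ferritin(f0, exposure, params, drug, grid[-1],
                                     output_grid=grid, method=method)
            exact = f_star + (f0 - f_star) * np.exp(-params.kout * t)
            assert np.max(np.abs(f - exact) / exact) < 1e-6

    def test_engines_agree(self, disease, drug):
        timeline = ExposureTimeline([0.0, 2000.0, 5000.0], [4.0, 0.0, 2.0])
        grid = np.linspace(0.0, 20000.0, 101)
        _, fast = simulate_ferritin(3000.0, timeline, disease, drug,
                                    grid[-1], output_grid=grid, method="rk4")
        _, stiff = simulate_ferritin(3000.0, timeline, disease, drug,
                                     grid[-1], output_grid=grid, method="bdf")
        assert np.max(np.abs(fast - stiff) / stiff) < 1e-6

    def test_grid_refinement_consistency(self, disease, drug):
        coarse = np.linspace(0.0, 50000.0, 51)
        fine = np.linspace(0.0, 50000.0, 101)
        _, fc = simulate_ferritin(4000.0, 3.0, disease, drug, 50000.0,
                                  output_grid=coarse, method="bdf")
        _, ff = simulate_ferritin(4000.0, 3.0, disease, drug, 50000.0,
                                  output_grid=fine, method="bdf")
        assert np.allclose(fc, ff[::2], rtol=1e-6)

    @given(f0=st.floats(min_value=50.0, max_value=12000.0),
           exposure=st.floats(min_value=0.0, max_value=10.0))
    def test_positivity(self, disease, drug, f0, exposure):
        _, f = simulate_ferritin(f0, exposure, disease, drug,
                                 horizon=5 * 8766.0, method="rk4")
        assert np.all(f > 0.0)

    @given(seed=st.integers(min_value=0, max_value=10 ** 6))
    def test_monotone_response_to_exposure(self, disease, drug, seed):
        """A pointwise-larger exposure timeline never yields a larger
        ferritin trajectory from the same start."""
        rng = np.random.default_rng(seed)
        bounds = np.sort(rng.uniform(0.0, 40000.0, size=3))
        times = np.concatenate([[0.0], bounds])
        lo = rng.uniform(0.0, 4.0, size=4)
        hi = lo + rng.uniform(0.0, 4.0, size=4)
        grid = np.linspace(0.0, 50000.0, 60)
        f0 = rng.uniform(500.0, 9000.0)
        _, f_lo = simulate_ferritin(f0, ExposureTimeline(times, lo), disease,
                                    drug, 50000.0, output_grid=grid,
                                    method="rk4")
        _, f_hi = simulate_ferritin(f0, ExposureTimeline(times, hi), disease,
                                    drug, 50000.0, output_grid=grid,
                                    method="rk4")
        assert np.all(f_hi <= f_lo + 1e-9)

    def test_baseline_fixed_scaling_variant(self, disease, drug):
        """Freezing the status power laws at f0 equals running the dynamic
        engine with pre-scaled reference parameters and zero exponents."""
        f0 = 4000.0
        scl_i, shp_i = disease_status_scaling(f0, disease)
        frozen = DiseaseParameters(
            kin=disease.kin, kout=disease.kout, scl_ref=scl_i,
            shp_ref=shp_i, theta_scl=0.0, theta_shp=0.0,
            ferritin_med=disease.ferritin_med)
        grid = np.linspace(0.0, 30000.0, 40)
        _, a = simulate_ferritin(f0, 2.0, disease, drug, 30000.0,
                                 output_grid=grid, scaling="baseline",
                                 method="rk4")
        _, b = simulate_ferritin(f0, 2.0, frozen, drug, 30000.0,
                                 output_grid=grid, scaling="dynamic",
                                 method="rk4")
        assert np.allclose(a, b, rtol=1e-12)

    def test_input_validation(self, disease, drug):
        with pytest.raises(DomainError):
            simulate_ferritin(0.0, 1.0, disease, drug, 100.0)
        with pytest.raises(DomainError):
            simulate_ferritin(1000.0, 1.0, disease, drug, -5.0)
        with pytest.raises(DomainError):
            simulate_ferritin(1000.0, 1.0, disease, drug, 100.0,
                              method="euler")
        with pytest.raises(DomainError):
            ExposureTimeline([0.0, 10.0], [1.0, -0.5])


def test_parameter_invariants():
    with pytest.raises(DomainError):
        DiseaseParameters(kout=0.0)
    with pytest.raises(DomainError):
        DiseaseParameters(kin=-1e-4)
    with pytest.raises(DomainError):
        DrugEffectParameters(slope=-1.0)
    with pytest.raises(DomainError):
        FerritinState(-1.0)
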