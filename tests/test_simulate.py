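import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import deglypk as d
from deglypk.exceptions import ConfigurationError
from deglypk.model import slot_names
from deglypk.simulate import simulate_amounts

from test_model import rate_maps


def test_zero_dose_gives_zero_profiles(ref_params, study_grid):
    rh2, ppd = d.simulate_profile(ref_params, d.DoseEvent(d.Route.IV_RH2, 0.0), study_grid)
    assert np.all(rh2.concentrations == 0) and np.all(ppd.concentrations == 0)


def test_one_compartment_closed_form(ref_params):
    """With peripheral exchange, biliary excretion and transformation shut
    off, I.V. Rh2 follows the mono-exponential bolus solution."""
    p = ref_params.replace(k_47=0.0, k_74=0.0, k_43=0.0, k_45=0.0)
    dose = d.DoseEvent(d.Route.IV_RH2, 10.0)
    times = np.linspace(0.0, 12.0, 25)
    rh2, _ = d.simulate_profile(p, dose, times)
    expected = dose.amount_nmol_per_kg / p.V_rh2_plasma * np.exp(-p.k_40 * times)
    assert rh2.concentrations == pytest.approx(expected, rel=1e-6)


def test_ppd_double_peak_after_iv_rh2(ref_params):
    """The formation of PPD through the fast plasma route and the delayed
    biliary/colonic route produces the characteristic double peak."""
    times = np.linspace(0.0, 24.0, 2401)
    _, ppd = d.simulate_profile(ref_params, d.DoseEvent(d.Route.IV_RH2, 10.0), times)
    c = ppd.concentrations
    n_maxima = int(np.sum((c[1:-1] > c[:-2]) & (c[1:-1] > c[2:])))
    assert n_maxima >= 2


@given(rate_maps(max_value=20.0), st.sampled_from([d.Route.IV_RH2, d.Route.PO_RH2, d.Route.IV_PPD]))
@settings(max_examples=25, deadline=None)
def test_mass_balance_and_dose_linearity(values, route):
    """Any simulation conserves the dose; doubling the dose doubles every
    concentration (the system is linear)."""
    params = d.build_parameter_set(values)
    times = np.array([0.5, 1.0, 4.0, 12.0, 24.0])
    dose1 = d.DoseEvent(route, 5.0)
    states = simulate_amounts(params, dose1, times)
    total = states.sum(axis=1)
    assert total == pytest.approx(np.full_like(total, dose1.amount_nmol_per_kg), rel=1e-6)

    rh2_1, ppd_1 = d.simulate_profile(params, dose1, times)
    rh2_2, ppd_2 = d.simulate_profile(params, d.DoseEvent(route, 10.0), times)
    assert rh2_2.concentrations == pytest.approx(2.0 * rh2_1.concentrations, rel=1e-9, abs=1e-12)
    assert ppd_2.concentrations == pytest.approx(2.0 * ppd_1.concentrations, rel=1e-9, abs=1e-12)


def test_grid_refinement_leaves_shared_times_unchanged(ref_params):
    dose = d.DoseEvent(d.Route.IV_RH2, 10.0)
    coarse = np.array([1.0, 4.0, 12.0])
    fine = np.linspace(0.0, 12.0, 49)  # includes the coarse times
    _, ppd_c = d.simulate_profile(ref_params, dose, coarse)
    _, ppd_f = d.simulate_profile(ref_params, dose, fine)
    shared = np.isin(fine, coarse)
    assert ppd_f.concentrations[shared] == pytest.approx(ppd_c.concentrations, rel=1e-8)


def test_expm_and_lsoda_agree(ref_params, study_grid):
    dose = d.DoseEvent(d.Route.PO_RH2, 10.0)
    a = simulate_amounts(ref_params, dose, study_grid, method="expm")
    b = simulate_amounts(ref_params, dose, study_grid, method="lsoda")
    assert b == pytest.approx(a, rel=1e-6, abs=1e-8 * dose.amount_nmol_per_kg)


def test_po_rh2_plasma_structurally_zero(ref_params, study_grid):
    """The model has no intact-Rh2 absorption path, so plasma Rh2 after an
    oral dose is identically zero (below any positive LLOQ)."""
    rh2, _ = d.simulate_profile(ref_params, d.DoseEvent(d.Route.PO_RH2, 20.0), study_grid)
    assert np.all(rh2.concentrations == 0.0)


def test_route_submodel_mismatch_rejected(ref_params, study_grid):
    with pytest.raises(ConfigurationError):
        d.simulate_profile(
            ref_params, d.DoseEvent(d.Route.PO_RH2, 10.0), study_grid,
            submodel=d.build_submodel("A"),
        )


def test_individual_degenerate_variability_equals_typical(ref_params, study_grid):
    dose = d.DoseEvent(d.Route.IV_RH2, 10.0)
    rh2_t, ppd_t = d.simulate_profile(ref_params, dose, study_grid)
    rh2_i, ppd_i = d.simulate_individual(ref_params, dose, study_grid, residual_seed=5)
    assert np.array_equal(rh2_i.concentrations, rh2_t.concentrations)
    assert np.array_equal(ppd_i.concentrations, ppd_t.concentrations)


def test_individual_same_seed_bitwise_identical(ref_params_var, study_grid):
    dose = d.DoseEvent(d.Route.IV_RH2, 10.0)
    eta = {"k_e": 0.1, "V_rh2_plasma": -0.2}
    a = d.simulate_individual(ref_params_var, dose, study_grid, iiv_draw=eta, residual_seed=11)
    b = d.simulate_individual(ref_params_var, dose, study_grid, iiv_draw=eta, residual_seed=11)
    assert np.array_equal(a[0].concentrations, b[0].concentrations)
    assert np.array_equal(a[1].concentrations, b[1].concentrations)


def test_residual_error_monte_carlo_cv(ref_params):
    """sigma=0.2 multiplicative noise gives an empirical CV near 20% at a
    single time point (2000 replicates)."""
    p = ref_params.replace(sigma=0.2)
    dose = d.DoseEvent(d.Route.IV_RH2, 10.0)
    rng = np.random.default_rng(2024)
    draws = [
        d.simulate_individual(p, dose, [1.0], residual_seed=rng)[0].concentrations[0]
        for _ in range(2000)
    ]
    cv = np.std(draws) / np.mean(draws)
    assert 0.18 <= cv <= 0.22
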