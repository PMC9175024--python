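import numpy as np
import pytest

import deglypk as d
from deglypk.exceptions import InfeasibleFreezeError, StagedCalibrationError
from deglypk.fitting import (
    derive_frozen_biliary,
    objective_multiplicative,
    proportional_residuals,
)
from deglypk.synth import staged_datasets


def test_frozen_biliary_reproduces_reference_pair():
    k_43, k_40 = derive_frozen_biliary(4.67, 0.276, 0.09)
    assert round(k_43, 2) == 1.29
    assert round(k_40, 2) == 3.29


def test_frozen_biliary_zero_fraction():
    k_43, k_40 = derive_frozen_biliary(4.67, 0.0, 0.09)
    assert k_43 == 0.0
    assert k_40 == pytest.approx(4.58)


def test_frozen_biliary_infeasible():
    with pytest.raises(InfeasibleFreezeError):
        derive_frozen_biliary(1.0, 0.5, 0.6)


def test_objective_zero_residuals_at_generating_params(ref_params, noise_free_study):
    spec = d.build_submodel("A")
    r = proportional_residuals(ref_params, staged_datasets(noise_free_study)["A"], spec)
    assert float(np.abs(r).max()) < 1e-9


def test_objective_scale_invariance_of_residual_term(ref_params, noise_free_study):
    """Proportional error: scaling observations and predictions by 10
    leaves the residual term unchanged (only the log f Jacobian shifts by
    n*log 10)."""
    spec = d.build_submodel("A")
    ds = staged_datasets(noise_free_study)["A"].copy()
    obj1 = objective_multiplicative(ref_params, ds, spec, sigma=0.2)
    ds10 = ds.copy()
    ds10["conc_nmol_per_L"] *= 10.0
    p10 = ref_params.replace(V_rh2_plasma=ref_params.V_rh2_plasma / 10.0)
    obj2 = objective_multiplicative(p10, ds10, spec, sigma=0.2)
    n = len(ds[(~ds["blq"])])
    assert obj2 - obj1 == pytest.approx(n * np.log(10.0), rel=1e-9)


def test_removing_record_never_increases_residual_sum(ref_params_var):
    study = d.generate_study(d.default_design(), ref_params_var, seed=9)
    spec = d.build_submodel("A")
    ds = staged_datasets(study)["A"]
    r_full = proportional_residuals(ref_params_var, ds, spec)
    r_less = proportional_residuals(ref_params_var, ds.iloc[:-1], spec)
    assert (r_less**2).sum() <= (r_full**2).sum() + 1e-12


def test_submodel_a_noise_free_recovery(ref_params, noise_free_study, perturbed_init):
    """Noise-free recovery oracle: starting from perturbed values, the
    stage-A fit recovers the generating disposition parameters to 0.1%."""
    spec = d.build_submodel("A")
    fit = d.fit_submodel(spec, staged_datasets(noise_free_study)["A"], perturbed_init["A"])
    truth = {"V_rh2_plasma": 2.39, "k_e": 4.67, "k_47": 2.08, "k_74": 0.48}
    for name, value in truth.items():
        assert fit.estimates[name] == pytest.approx(value, rel=1e-3)
    assert fit.converged


def test_objective_not_worse_than_init(ref_params_var, perturbed_init):
    study = d.generate_study(d.default_design(), ref_params_var, seed=77)
    spec = d.build_submodel("A")
    ds = staged_datasets(study)["A"]
    obj_init = objective_multiplicative(
        d.build_parameter_set(perturbed_init["A"], submodel="A"), ds, spec
    )
    fit = d.fit_submodel(spec, ds, perturbed_init["A"], n_starts=2)
    assert fit.objective_value <= obj_init + 1e-9


def test_staged_noise_free_recovery_within_one_percent(
    ref_params, noise_free_study, perturbed_init
):
    """End-to-end staged calibration on noise-free data reassembles the
    full generating parameter set to within 1% per parameter."""
    result = d.staged_calibration(staged_datasets(noise_free_study), init=perturbed_init)
    est = result.parameters.as_dict()
    for name, truth in ref_params.as_dict().items():
        if truth > 0:
            assert est[name] == pytest.approx(truth, rel=0.01), name


def test_staged_frozen_pair_and_staging_contract(
    ref_params, noise_free_study, perturbed_init
):
    result = d.staged_calibration(staged_datasets(noise_free_study), init=perturbed_init)
    # frozen pair satisfies the freezing arithmetic exactly
    k_e = result.fits["A"].estimates["k_e"]
    assert result.parameters.k_43 == pytest.approx(0.276 * k_e, rel=1e-12)
    # stage 3 carries stage-1 estimates through bit-identically
    assert result.fits["C"].fixed["V_rh2_plasma"] == result.fits["A"].estimates["V_rh2_plasma"]
    assert result.fits["C"].fixed["k_e"] == k_e
    # CV% is reported only for estimated parameters; frozen ones have none
    assert set(result.fits["C"].cv_percent) == {"k_45", "k_t", "k_60"}


def test_staged_missing_step_aborts_with_step_identity(noise_free_study, perturbed_init):
    datasets = staged_datasets(noise_free_study)
    del datasets["B"]
    with pytest.raises(StagedCalibrationError, match="step 2"):
        d.staged_calibration(datasets, init=perturbed_init)
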