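"""Parameter estimation via the four-stage model-reduction strategy.

Estimation is naive-pooled maximum likelihood under the proportional
(multiplicative) residual-error model y = f*(1+eps), eps ~ N(0, sigma^2),
with sigma profiled out.  Parameters are optimised on the log scale with a
bounded multi-start least-squares pass on the relative residuals followed by
a Nelder-Mead polish of the full profiled likelihood; CV% comes from the
Gauss-Newton inverse-Hessian approximation at the optimum.  A full
nonlinear mixed-effects engine is deliberately out of scope: with three
animals per group the data cannot support stable random-effects estimation,
and between-subject spread is absorbed into the proportional error.

The four stages mirror how the model was identified:

1. sub-model A — Rh2 two-compartment disposition from I.V. Rh2 data;
2. sub-model B — PPD two-compartment disposition from I.V. PPD data;
3. freeze k_43/k_40 from the reported biliary-excretion fraction, then
   sub-model C — metabolite formation/transit from PPD after I.V. Rh2;
4. sub-model D — stomach handling from PPD after P.O. Rh2 with k_t and
   k_60 carried over from stage 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .exceptions import (
    DataError,
    InfeasibleFreezeError,
    ObjectiveError,
    ParameterConsistencyError as ParameterConsistencyError_,
    StagedCalibrationError,
)
from .model import Analyte, DoseEvent, Route, SubModelSpec, build_submodel
from .parameters import ParameterSet, build_parameter_set
from .simulate import simulate_profile

__all__ = [
    "FitResult",
    "StagedResult",
    "objective_multiplicative",
    "proportional_residuals",
    "derive_frozen_biliary",
    "fit_submodel",
    "staged_calibration",
]

#: Default biliary-excretion fraction of Rh2 used for freezing; reproduces
#: the frozen reference pair k_43=1.29, k_40=3.29 at two decimals.
DEFAULT_BILIARY_FRACTION = 0.276

_LOG_BOUNDS = (math.log(1e-5), math.log(1e4))


@dataclass(frozen=True)
class FitResult:
    """Estimates with relative standard errors and optimiser diagnostics.

    ``cov_log`` is the covariance of the log-scale estimates (order of
    ``estimates``); in a staged fit it includes the propagated uncertainty
    of parameters carried over from earlier stages.
    """

    estimates: Mapping[str, float]
    cv_percent: Mapping[str, float]
    ci95: Mapping[str, tuple[float, float]]
    objective_value: float
    converged: bool
    fixed: Mapping[str, float] = field(default_factory=dict)
    sigma_hat: float = float("nan")
    n_obs: int = 0
    cov_log: np.ndarray | None = None


@dataclass(frozen=True)
class StagedResult:
    parameters: ParameterSet
    fits: Mapping[str, FitResult]
    biliary_fraction: float


def derive_frozen_biliary(
    k_e: float, biliary_fraction: float, k_45: float
) -> tuple[float, float]:
    """Split k_e into the frozen pair (k_43, k_40) given the reported
    biliary-excretion fraction: k_43 = fraction*k_e, k_40 = k_e-k_43-k_45."""
    if not 0.0 <= biliary_fraction <= 1.0:
        raise InfeasibleFreezeError("biliary fraction must lie in [0, 1]")
    if k_45 > k_e:
        raise InfeasibleFreezeError("k_45 exceeds k_e")
    k_43 = biliary_fraction * k_e
    k_40 = k_e - k_43 - k_45
    if k_40 < 0:
        raise InfeasibleFreezeError(
            f"k_43 + k_45 = {k_43 + k_45:.4g} exceeds k_e = {k_e:.4g}"
        )
    return k_43, k_40


def _fit_records(dataset: pd.DataFrame, spec: SubModelSpec) -> pd.DataFrame:
    """Non-BLQ records of the analyte/route combination this stage fits."""
    if spec.fit_analyte is None:
        raise DataError("FULL model has no single-stage fit analyte")
    routes = {r.value for r in spec.compatible_routes}
    sel = dataset[
        (dataset["analyte"] == spec.fit_analyte.value)
        & (dataset["route"].isin(routes))
        & (~dataset["blq"].astype(bool))
    ]
    if sel.empty:
        raise DataError(
            f"no quantifiable {spec.fit_analyte.value} records for sub-model {spec.tag}"
        )
    return sel


class _PredictionPlan:
    """Precomputed grouping of fit records so repeated objective
    evaluations skip the pandas machinery: one simulated typical profile
    per (route, dose) serves all subjects (naive pooling)."""

    def __init__(self, records: pd.DataFrame, spec: SubModelSpec) -> None:
        self.spec = spec
        self.analyte = Analyte(spec.fit_analyte)
        self.y = records["conc_nmol_per_L"].to_numpy(dtype=float)
        self.n = len(records)
        self.groups: list[tuple[DoseEvent, np.ndarray, np.ndarray, np.ndarray]] = []
        times_all = records["time_h"].to_numpy(dtype=float)
        for (route, dose_mg), idx in records.groupby(["route", "dose_mg_per_kg"]).groups.items():
            pos = records.index.get_indexer(idx)
            t = times_all[pos]
            times, inverse = np.unique(t, return_inverse=True)
            self.groups.append(
                (DoseEvent(Route(route), float(dose_mg)), times, pos, inverse)
            )

    def predict(self, params: ParameterSet) -> np.ndarray:
        preds = np.empty(self.n)
        for dose, times, pos, inverse in self.groups:
            rh2, ppd = simulate_profile(params, dose, times, submodel=self.spec)
            curve = rh2 if self.analyte == Analyte.RH2 else ppd
            preds[pos] = curve.concentrations[inverse]
        return preds


def _predictions(params: ParameterSet, records: pd.DataFrame, spec: SubModelSpec) -> np.ndarray:
    """Model predictions aligned with the record rows (naive pooled: one
    typical-profile prediction per route/dose)."""
    return _PredictionPlan(records, spec).predict(params)


def _build_params(values: Mapping[str, float], spec: SubModelSpec) -> ParameterSet:
    return build_parameter_set(dict(values), submodel=spec.tag)


def proportional_residuals(
    params: ParameterSet, dataset: pd.DataFrame, submodel: SubModelSpec
) -> np.ndarray:
    """Relative residuals (y - f)/f of the non-BLQ fit records."""
    records = _fit_records(dataset, submodel)
    f = _predictions(params, records, submodel)
    if np.any(f <= 0):
        raise ObjectiveError("model predicts non-positive concentration at an observation time")
    y = records["conc_nmol_per_L"].to_numpy(dtype=float)
    return (y - f) / f


def objective_multiplicative(
    params: ParameterSet,
    dataset: pd.DataFrame,
    submodel: SubModelSpec,
    sigma: float | None = None,
) -> float:
    """Negative log-likelihood under the proportional error model.

    With ``sigma=None`` the residual SD is profiled out analytically.
    """
    records = _fit_records(dataset, submodel)
    f = _predictions(params, records, submodel)
    if np.any(f <= 0):
        raise ObjectiveError("model predicts non-positive concentration at an observation time")
    y = records["conc_nmol_per_L"].to_numpy(dtype=float)
    r = (y - f) / f
    n = r.size
    log_f = float(np.log(f).sum())
    if sigma is not None:
        if sigma <= 0:
            raise ObjectiveError("sigma must be positive")
        return (
            log_f
            + n * math.log(sigma)
            + float((r**2).sum()) / (2.0 * sigma**2)
            + 0.5 * n * math.log(2.0 * math.pi)
        )
    s2 = max(float((r**2).mean()), 1e-300)
    return log_f + 0.5 * n * (math.log(s2) + 1.0 + math.log(2.0 * math.pi))


def fit_submodel(
    spec: SubModelSpec,
    dataset: pd.DataFrame,
    init: Mapping[str, float],
    fixed: Mapping[str, float] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_starts: int = 4,
    seed: int = 0,
    fixed_uncertainty: tuple[list[str], np.ndarray] | None = None,
) -> FitResult:
    """Fit one sub-model stage by profiled proportional-error ML.

    ``init`` supplies starting values for ``spec.estimated_parameters``;
    ``fixed`` supplies values for ``spec.fixed_parameters`` (held exactly).
    ``fixed_uncertainty`` is an optional ``(names, cov_log)`` pair giving
    the log-scale covariance of a subset of the fixed parameters (earlier
    stage estimates); its uncertainty is propagated into the reported
    covariance by the delta method, so staged CIs do not pretend the
    carried-over values are known exactly.  Non-convergence is flagged on
    the result, not raised.
    """
    fixed = dict(fixed or {})
    names = list(spec.estimated_parameters)
    missing = [n for n in names if n not in init]
    if missing:
        raise DataError(f"init missing starting values for {missing}")
    records = _fit_records(dataset, spec)  # validates data up front
    plan = _PredictionPlan(records, spec)
    y = plan.y

    def assemble(x_log: np.ndarray) -> ParameterSet:
        values = dict(fixed)
        values.update({n: math.exp(v) for n, v in zip(names, x_log)})
        return _build_params(values, spec)

    def residuals(x_log: np.ndarray) -> np.ndarray:
        f = plan.predict(assemble(x_log))
        if np.any(f <= 0):
            raise ObjectiveError("non-positive prediction at an observation time")
        return (y - f) / f

    lo = np.full(len(names), _LOG_BOUNDS[0])
    hi = np.full(len(names), _LOG_BOUNDS[1])
    for i, n in enumerate(names):
        if bounds and n in bounds:
            lo[i], hi[i] = math.log(bounds[n][0]), math.log(bounds[n][1])

    x_init = np.array([math.log(init[n]) for n in names])
    x_init = np.clip(x_init, lo, hi)
    rng = np.random.default_rng(seed)
    starts = [x_init] + [
        np.clip(x_init + rng.uniform(-math.log(2.0), math.log(2.0), len(names)), lo, hi)
        for _ in range(max(n_starts - 1, 0))
    ]

    best = None
    for x0 in starts:
        try:
            res = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-12
            )
        except ObjectiveError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise ObjectiveError("all optimisation starts produced invalid predictions")

    # polish the full profiled likelihood (differs from least squares by the
    # Jacobian term sum(log f)); never accept a point worse than the start
    def nll(x_log: np.ndarray) -> float:
        try:
            f = plan.predict(assemble(x_log))
        except (ObjectiveError, ParameterConsistencyError_):
            return float("inf")
        if np.any(f <= 0):
            return float("inf")
        r = (y - f) / f
        s2 = max(float((r**2).mean()), 1e-300)
        return float(np.log(f).sum()) + 0.5 * r.size * (
            math.log(s2) + 1.0 + math.log(2.0 * math.pi)
        )

    candidates = [(nll(x_init), x_init, True), (nll(best.x), best.x, best.status > 0)]
    x_start = min(candidates, key=lambda c: c[0])[1]
    polish = minimize(
        nll, x_start, method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 1200},
    )
    candidates.append((polish.fun, np.clip(polish.x, lo, hi), bool(polish.success)))
    obj, x_best, converged = min(candidates, key=lambda c: c[0])

    # Gauss-Newton covariance on the log scale -> CV% is the relative SE
    res_final = least_squares(
        residuals, x_best, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14, max_nfev=10
    )
    r = res_final.fun
    J = res_final.jac
    n_obs, p = r.size, len(names)
    s2 = float((r**2).sum()) / max(n_obs - p, 1)
    cov = None
    try:
        jtj_inv = np.linalg.inv(J.T @ J)
        cov = s2 * jtj_inv
        if fixed_uncertainty is not None:
            # delta method: theta_hat(phi) solves J' r = 0, so
            # d theta / d phi = -(J'J)^{-1} J' J_phi, and the carried
            # uncertainty Sigma_phi adds G Sigma_phi G' to the covariance
            phi_names, sigma_phi = fixed_uncertainty
            h = 1e-5
            J_phi = np.empty((n_obs, len(phi_names)))
            for k, pname in enumerate(phi_names):
                saved = fixed[pname]
                fixed[pname] = saved * math.exp(h)
                J_phi[:, k] = (residuals(x_best) - r) / h
                fixed[pname] = saved
            G = -jtj_inv @ J.T @ J_phi
            cov = cov + G @ np.asarray(sigma_phi) @ G.T
        se_log = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se_log = np.full(p, float("nan"))

    estimates = {n: math.exp(v) for n, v in zip(names, x_best)}
    cv = {n: 100.0 * se for n, se in zip(names, se_log)}
    # clamp the exponent so an ill-conditioned Hessian yields a huge (not
    # overflowing) interval
    ci = {
        n: (
            est * math.exp(-min(1.96 * se, 700.0)) if math.isfinite(se) else float("nan"),
            est * math.exp(min(1.96 * se, 700.0)) if math.isfinite(se) else float("nan"),
        )
        for (n, est), se in zip(estimates.items(), se_log)
    }
    return FitResult(
        estimates=estimates,
        cv_percent=cv,
        ci95=ci,
        objective_value=float(obj),
        converged=converged,
        fixed=fixed,
        sigma_hat=math.sqrt(s2),
        n_obs=int(n_obs),
        cov_log=cov,
    )


def _block_diag_uncertainty(
    *blocks: tuple[list[str], np.ndarray | None]
) -> tuple[list[str], np.ndarray] | None:
    """Assemble a block-diagonal log-scale covariance for carried-over
    parameters (cross-stage correlations neglected); None if any block's
    covariance is unavailable."""
    names: list[str] = []
    mats: list[np.ndarray] = []
    for block_names, cov in blocks:
        if cov is None or not np.all(np.isfinite(cov)):
            return None
        names.extend(block_names)
        mats.append(np.asarray(cov))
    total = sum(m.shape[0] for m in mats)
    out = np.zeros((total, total))
    offset = 0
    for m in mats:
        k = m.shape[0]
        out[offset : offset + k, offset : offset + k] = m
        offset += k
    return names, out


def _carried_uncertainty_c(fit_a: FitResult, fit_b: FitResult):
    """Stage-C carried covariance: stage A's estimates plus the frozen
    k_43, whose log-variance equals k_e's (k_43 = fraction * k_e), plus
    stage B's estimates."""
    if fit_a.cov_log is None:
        return None
    a_names = list(fit_a.estimates)  # V_rh2_plasma, k_e, k_47, k_74
    cov_a = np.asarray(fit_a.cov_log)
    i_ke = a_names.index("k_e")
    # append k_43 as a copy of the k_e row/column (perfectly correlated)
    cov_a_ext = np.zeros((len(a_names) + 1, len(a_names) + 1))
    cov_a_ext[: len(a_names), : len(a_names)] = cov_a
    cov_a_ext[-1, : len(a_names)] = cov_a[i_ke, :]
    cov_a_ext[: len(a_names), -1] = cov_a[:, i_ke]
    cov_a_ext[-1, -1] = cov_a[i_ke, i_ke]
    return _block_diag_uncertainty(
        (a_names + ["k_43"], cov_a_ext), (list(fit_b.estimates), fit_b.cov_log)
    )


def _carried_uncertainty_d(fit_b: FitResult, fit_c: FitResult):
    """Stage-D carried covariance: k_t/k_60 from stage C plus stage B's
    estimates."""
    if fit_c.cov_log is None:
        return None
    c_names = list(fit_c.estimates)
    idx = [c_names.index(n) for n in ("k_t", "k_60")]
    cov_tc = np.asarray(fit_c.cov_log)[np.ix_(idx, idx)]
    return _block_diag_uncertainty(
        (["k_t", "k_60"], cov_tc), (list(fit_b.estimates), fit_b.cov_log)
    )


_STEP_OF = {"A": 1, "B": 2, "C": 3, "D": 4}

DEFAULT_STAGE_INIT: Mapping[str, Mapping[str, float]] = {
    "A": {"V_rh2_plasma": 1.0, "k_e": 2.0, "k_47": 1.0, "k_74": 0.5},
    "B": {"V_ppd_plasma": 0.5, "k_50": 2.0, "k_58": 5.0, "k_85": 2.0},
    "C": {"k_45": 0.2, "k_t": 1.0, "k_60": 1.0},
    "D": {"k_13": 0.5, "k_12": 0.5, "k_20": 5.0},
}


def staged_calibration(
    datasets: Mapping[str, pd.DataFrame],
    biliary_fraction: float = DEFAULT_BILIARY_FRACTION,
    init: Mapping[str, Mapping[str, float]] | None = None,
    n_starts: int = 4,
    seed: int = 0,
) -> StagedResult:
    """Run the full four-stage calibration and assemble the parameter set.

    ``datasets`` maps sub-model tags A-D to long-format datasets (stage 1:
    Rh2 after I.V. Rh2; stage 2: PPD after I.V. PPD; stage 3: PPD after
    I.V. Rh2; stage 4: PPD after P.O. Rh2).  A missing or failing stage
    aborts with the step named.
    """
    init = {**{k: dict(v) for k, v in DEFAULT_STAGE_INIT.items()}, **{
        k: dict(v) for k, v in (init or {}).items()
    }}
    for tag in ("A", "B", "C", "D"):
        if tag not in datasets:
            raise StagedCalibrationError(
                f"step {_STEP_OF[tag]} (sub-model {tag}): dataset missing"
            )

    fits: dict[str, FitResult] = {}

    def run(tag: str, fixed: Mapping[str, float], bounds=None, fixed_unc=None) -> FitResult:
        spec = build_submodel(tag)
        try:
            fit = fit_submodel(
                spec, datasets[tag], init[tag], fixed=fixed,
                bounds=bounds, n_starts=n_starts, seed=seed + _STEP_OF[tag],
                fixed_uncertainty=fixed_unc,
            )
        except Exception as exc:  # noqa: BLE001 - re-raise with step identity
            raise StagedCalibrationError(
                f"step {_STEP_OF[tag]} (sub-model {tag}) failed: {exc}"
            ) from exc
        fits[tag] = fit
        return fit

    fit_a = run("A", {})
    fit_b = run("B", {})

    k_e = fit_a.estimates["k_e"]
    k_43_frozen = biliary_fraction * k_e
    fixed_c = {
        "k_e": k_e,
        "k_43": k_43_frozen,
        "V_rh2_plasma": fit_a.estimates["V_rh2_plasma"],
        "k_47": fit_a.estimates["k_47"],
        "k_74": fit_a.estimates["k_74"],
        **{n: fit_b.estimates[n] for n in ("V_ppd_plasma", "k_50", "k_58", "k_85")},
    }
    # keep k_40 = k_e - k_43 - k_45 non-negative during the search
    bounds_c = {"k_45": (1e-5, max((k_e - k_43_frozen) * 0.999, 2e-5))}
    fit_c = run("C", fixed_c, bounds=bounds_c, fixed_unc=_carried_uncertainty_c(fit_a, fit_b))

    fixed_d = {
        "k_t": fit_c.estimates["k_t"],
        "k_60": fit_c.estimates["k_60"],
        **{n: fit_b.estimates[n] for n in ("V_ppd_plasma", "k_50", "k_58", "k_85")},
    }
    fit_d = run("D", fixed_d, fixed_unc=_carried_uncertainty_d(fit_b, fit_c))

    k_43, k_40 = derive_frozen_biliary(k_e, biliary_fraction, fit_c.estimates["k_45"])
    full = build_parameter_set(
        {
            "V_rh2_plasma": fit_a.estimates["V_rh2_plasma"],
            "k_47": fit_a.estimates["k_47"],
            "k_74": fit_a.estimates["k_74"],
            "V_ppd_plasma": fit_b.estimates["V_ppd_plasma"],
            "k_50": fit_b.estimates["k_50"],
            "k_58": fit_b.estimates["k_58"],
            "k_85": fit_b.estimates["k_85"],
            "k_45": fit_c.estimates["k_45"],
            "k_43": k_43,
            "k_40": k_40,
            "k_t": fit_c.estimates["k_t"],
            "k_60": fit_c.estimates["k_60"],
            "k_13": fit_d.estimates["k_13"],
            "k_12": fit_d.estimates["k_12"],
            "k_20": fit_d.estimates["k_20"],
        },
        submodel="FULL",
    )
    return StagedResult(parameters=full, fits=fits, biliary_fraction=biliary_fraction)
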