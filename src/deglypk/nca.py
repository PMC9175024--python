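"""Non-compartmental analysis of concentration-time profiles.

Metrics follow the conventional definitions: C_max/T_max from the observed
maximum, AUC by the linear trapezoidal rule, the terminal slope lambda_z by
log-linear regression over the best terminal window (maximum adjusted R^2,
at least three points, excluding T_max), t_1/2 = ln2/lambda_z, and — for
intravenous profiles — V_ss = Dose * AUMC_inf / AUC_inf^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterValidationError, UndefinedHalfLifeError
from .model import DOSED_ANALYTE, Analyte, DoseEvent, Route
from .simulate import ConcentrationProfile

__all__ = ["NcaResult", "auc_linear_trapezoid", "terminal_slope", "nca_summary"]


@dataclass(frozen=True)
class NcaResult:
    c_max: float
    t_max: float
    auc_0_t: float
    lambda_z: float | None
    t_half: float | None
    v_ss: float | None
    auc_extrapolated_fraction: float | None


def auc_linear_trapezoid(profile: ConcentrationProfile) -> float:
    """Area under the curve by the linear trapezoidal rule (h*nmol/L).

    Zero for a single point.
    """
    if len(profile) == 0:
        raise ParameterValidationError("profile has no points")
    t, c = profile.times, profile.concentrations
    if t.size < 2:
        return 0.0
    return float(np.trapezoid(c, t))


def _aumc_linear_trapezoid(profile: ConcentrationProfile) -> float:
    t, c = profile.times, profile.concentrations
    if t.size < 2:
        return 0.0
    return float(np.trapezoid(c * t, t))


def terminal_slope(
    profile: ConcentrationProfile, min_points: int = 3
) -> tuple[float, float]:
    """Terminal elimination rate constant and half-life.

    Candidate windows are the tails of the profile starting strictly after
    T_max with at least ``min_points`` positive concentrations; the window
    with the highest adjusted R^2 of the log-linear regression wins.
    lambda_z is the negated slope; a non-decaying tail raises
    :class:`UndefinedHalfLifeError`.
    """
    if min_points < 3:
        raise ParameterValidationError("min_points must be >= 3")
    t, c = profile.times, profile.concentrations
    pos = c > 0
    t, c = t[pos], c[pos]
    if t.size < min_points + 1:
        raise UndefinedHalfLifeError("too few positive concentrations for a terminal window")
    i_max = int(np.argmax(c))
    logc = np.log(c)

    best: tuple[float, float] | None = None  # (adj_r2, lambda_z)
    for start in range(i_max + 1, t.size - min_points + 1):
        tw, yw = t[start:], logc[start:]
        n = tw.size
        slope, intercept = np.polyfit(tw, yw, 1)
        resid = yw - (slope * tw + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((yw - yw.mean()) ** 2).sum())
        r2 = 1.0 if ss_tot == 0 and ss_res == 0 else 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if best is None or adj_r2 > best[0] + 1e-12:
            best = (adj_r2, -slope)
    if best is None:
        raise UndefinedHalfLifeError("no admissible terminal window after T_max")
    lambda_z = best[1]
    if lambda_z <= 0:
        raise UndefinedHalfLifeError("terminal phase does not decay (slope >= 0)")
    return float(lambda_z), float(math.log(2.0) / lambda_z)


def nca_summary(profile: ConcentrationProfile, dose: DoseEvent) -> NcaResult:
    """Full NCA metric set for one profile.

    V_ss is reported only when the profile's analyte was itself dosed
    intravenously (for orally dosed or formed analytes the true amount
    reaching the circulation is unknown, so a volume is not identifiable).
    """
    if len(profile) == 0:
        raise ParameterValidationError("profile has no points")
    t, c = profile.times, profile.concentrations
    i_max = int(np.argmax(c))
    c_max, t_max = float(c[i_max]), float(t[i_max])
    auc_t = auc_linear_trapezoid(profile)

    lambda_z = t_half = v_ss = auc_extra = None
    try:
        lambda_z, t_half = terminal_slope(profile)
    except UndefinedHalfLifeError:
        pass
    route = Route(dose.route)
    intravenous = route in (Route.IV_RH2, Route.IV_PPD)
    if lambda_z is not None and auc_t > 0:
        c_last, t_last = float(c[c > 0][-1]), float(t[c > 0][-1])
        auc_inf = auc_t + c_last / lambda_z
        aumc_inf = (
            _aumc_linear_trapezoid(profile)
            + c_last * t_last / lambda_z
            + c_last / lambda_z**2
        )
        auc_extra = (auc_inf - auc_t) / auc_inf
        if intravenous and DOSED_ANALYTE[route] == Analyte(profile.analyte):
            v_ss = dose.amount_nmol_per_kg * aumc_inf / auc_inf**2
    return NcaResult(
        c_max=c_max,
        t_max=t_max,
        auc_0_t=auc_t,
        lambda_z=lambda_z,
        t_half=t_half,
        v_ss=v_ss,
        auc_extrapolated_fraction=auc_extra,
    )
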