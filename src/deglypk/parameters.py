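"""Parameter container for the Rh2/PPD deglycosylation model.

All rate constants are first-order (1/h); volumes are apparent distribution
volumes per kg body weight (L/kg).  The total elimination rate constant of
Rh2 from the central compartment, ``k_e``, is by construction the sum of its
three components: transformation to PPD in the systemic circulation
(``k_45``), biliary excretion (``k_43``) and unknown-route loss (``k_40``).
The container stores the three components and exposes ``k_e`` as their sum;
:func:`build_parameter_set` accepts a ``k_e`` key and either checks it
against supplied components or back-fills ``k_40 = k_e - k_43 - k_45``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

from .exceptions import (
    ConfigurationError,
    ParameterConsistencyError,
    ParameterValidationError,
)

__all__ = [
    "ParameterSet",
    "build_parameter_set",
    "rat_reference_parameters",
    "RATE_NAMES",
    "VOLUME_NAMES",
    "PARAMETER_NAMES",
    "DEFAULT_OMEGA",
    "DEFAULT_SIGMA",
]

VOLUME_NAMES = ("V_rh2_plasma", "V_ppd_plasma")
RATE_NAMES = (
    "k_40",
    "k_43",
    "k_45",
    "k_47",
    "k_74",
    "k_50",
    "k_58",
    "k_85",
    "k_t",
    "k_60",
    "k_12",
    "k_13",
    "k_20",
)
PARAMETER_NAMES = VOLUME_NAMES + RATE_NAMES

#: Default inter-individual variability (log-scale SD) applied to the
#: clearance/volume-like parameters, and default proportional residual SD.
#: The source study does not report these magnitudes; the values are stated
#: assumptions (see docs/methods.md).
DEFAULT_OMEGA: Mapping[str, float] = {
    "V_rh2_plasma": 0.3,
    "k_e": 0.3,
    "V_ppd_plasma": 0.3,
    "k_50": 0.3,
}
DEFAULT_SIGMA = 0.2

_KE_REL_TOL = 1e-9


@dataclass(frozen=True)
class ParameterSet:
    """Validated set of rate constants, volumes and variability terms.

    ``omega`` maps parameter names (``k_e`` allowed as a joint entry for its
    three components) to log-scale inter-individual SDs; ``sigma`` is the
    proportional residual-error SD.
    """

    V_rh2_plasma: float = 1.0
    V_ppd_plasma: float = 1.0
    k_40: float = 0.0
    k_43: float = 0.0
    k_45: float = 0.0
    k_47: float = 0.0
    k_74: float = 0.0
    k_50: float = 0.0
    k_58: float = 0.0
    k_85: float = 0.0
    k_t: float = 0.0
    k_60: float = 0.0
    k_12: float = 0.0
    k_13: float = 0.0
    k_20: float = 0.0
    omega: Mapping[str, float] = field(default_factory=dict)
    sigma: float = 0.0

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ParameterValidationError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise ParameterValidationError(f"{name} must be non-negative, got {value!r}")
        for name in VOLUME_NAMES:
            if getattr(self, name) <= 0:
                raise ParameterValidationError(f"{name} must be strictly positive")
        for name, sd in self.omega.items():
            if sd < 0:
                raise ParameterValidationError(f"omega[{name!r}] must be non-negative")
        if self.sigma < 0:
            raise ParameterValidationError("sigma must be non-negative")

    @property
    def k_e(self) -> float:
        """Total Rh2 elimination rate constant, k_40 + k_43 + k_45 (1/h)."""
        return self.k_40 + self.k_43 + self.k_45

    def replace(self, **changes: object) -> "ParameterSet":
        return replace(self, **changes)

    def individualized(self, eta: Mapping[str, float]) -> "ParameterSet":
        """Apply log-normal multipliers theta_i = theta * exp(eta).

        An ``"k_e"`` entry scales ``k_40``, ``k_43`` and ``k_45`` jointly so
        the route split (and the k_e identity) is preserved within a subject.
        """
        changes: dict[str, float] = {}
        for name, value in eta.items():
            factor = math.exp(value)
            if name == "k_e":
                for comp in ("k_40", "k_43", "k_45"):
                    changes[comp] = getattr(self, comp) * factor
            elif name in PARAMETER_NAMES:
                changes[name] = getattr(self, name) * factor
            else:
                raise ParameterValidationError(f"unknown parameter in eta: {name!r}")
        return self.replace(**changes) if changes else self

    def as_dict(self, include_k_e: bool = True) -> dict[str, float]:
        out = {name: getattr(self, name) for name in PARAMETER_NAMES}
        if include_k_e:
            out["k_e"] = self.k_e
        return out


#: Parameter names each sub-model's dynamics depend on (k_e counts as the
#: elimination triple).
_REQUIRED_BY_SUBMODEL = {
    "A": {"V_rh2_plasma", "k_e", "k_47", "k_74"},
    "B": {"V_ppd_plasma", "k_50", "k_58", "k_85"},
    "C": {
        "V_rh2_plasma", "k_e", "k_47", "k_74",
        "V_ppd_plasma", "k_50", "k_58", "k_85",
        "k_43", "k_45", "k_t", "k_60",
    },
    "D": {"V_ppd_plasma", "k_50", "k_58", "k_85", "k_t", "k_60", "k_12", "k_13", "k_20"},
    "FULL": set(PARAMETER_NAMES) | {"k_e"},
}

_ACCEPTED_KEYS = set(PARAMETER_NAMES) | {"k_e", "omega", "sigma"}


def build_parameter_set(
    values: Mapping[str, object], submodel: str | None = None
) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a flat name->value map.

    ``k_e`` may be supplied instead of (or in addition to) ``k_40``: when
    ``k_40`` is absent it is back-filled as ``k_e - k_43 - k_45``; when both
    are present the identity is enforced to 1e-9 relative.  Unknown keys are
    rejected.  ``submodel`` (one of A/B/C/D/FULL) additionally requires the
    parameters that sub-model's dynamics use.
    """
    unknown = set(values) - _ACCEPTED_KEYS
    if unknown:
        raise ParameterValidationError(f"unknown parameter name(s): {sorted(unknown)}")
    numeric = {
        k: v for k, v in values.items() if k not in ("omega", "sigma")
    }
    for name, value in numeric.items():
        if not isinstance(value, (int, float)) or not math.isfinite(float(value)):
            raise ParameterValidationError(f"{name} must be a finite number, got {value!r}")

    if submodel is not None:
        required = _REQUIRED_BY_SUBMODEL.get(submodel.upper())
        if required is None:
            raise ConfigurationError(f"unknown sub-model tag: {submodel!r}")
        supplied = set(numeric)
        if "k_e" in supplied or "k_40" in supplied:
            supplied |= {"k_e", "k_40"}
        missing = {r for r in required if r not in supplied}
        if missing:
            raise ParameterValidationError(
                f"sub-model {submodel}: missing required parameter(s) {sorted(missing)}"
            )

    kwargs: dict[str, object] = {
        k: float(v) for k, v in numeric.items() if k != "k_e"
    }
    if "k_e" in numeric:
        k_e = float(numeric["k_e"])
        k_43 = float(numeric.get("k_43", 0.0))
        k_45 = float(numeric.get("k_45", 0.0))
        if "k_40" in numeric:
            total = float(numeric["k_40"]) + k_43 + k_45
            if abs(total - k_e) > _KE_REL_TOL * max(abs(k_e), 1.0):
                raise ParameterConsistencyError(
                    f"k_e={k_e} inconsistent with k_40+k_43+k_45={total}"
                )
        else:
            k_40 = k_e - k_43 - k_45
            if k_40 < -_KE_REL_TOL * max(abs(k_e), 1.0):
                raise ParameterConsistencyError(
                    f"k_e={k_e} smaller than k_43+k_45={k_43 + k_45}"
                )
            kwargs["k_40"] = max(k_40, 0.0)
    if "omega" in values:
        kwargs["omega"] = dict(values["omega"])  # type: ignore[arg-type]
    if "sigma" in values:
        kwargs["sigma"] = float(values["sigma"])  # type: ignore[arg-type]
    return ParameterSet(**kwargs)  # type: ignore[arg-type]


#: Published parameter estimates from the rat study of Rh2 deglycosylation
#: (I.V./P.O. Rh2 at 10 mg/kg; I.V. PPD at 0.2 mg/kg).
REFERENCE_ESTIMATES: Mapping[str, float] = {
    "V_rh2_plasma": 2.39,
    "k_e": 4.67,
    "k_47": 2.08,
    "k_74": 0.48,
    "V_ppd_plasma": 0.29,
    "k_50": 4.88,
    "k_58": 27.3,
    "k_85": 3.38,
    "k_45": 0.09,
    "k_43": 1.29,
    "k_40": 3.29,
    "k_60": 1.38,
    "k_t": 0.63,
    "k_13": 0.22,
    "k_12": 0.14,
    "k_20": 22.2,
}


def rat_reference_parameters(variability: bool = False) -> ParameterSet:
    """The reference rat parameter estimates as a validated ParameterSet.

    With ``variability=True`` the assumed default omega/sigma terms are
    attached (the study itself does not publish them).
    """
    values: dict[str, object] = dict(REFERENCE_ESTIMATES)
    if variability:
        values["omega"] = dict(DEFAULT_OMEGA)
        values["sigma"] = DEFAULT_SIGMA
    return build_parameter_set(values, submodel="FULL")
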