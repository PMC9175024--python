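"""Compartmental structure of the Rh2 -> PPD deglycosylation model.

The model tracks the parent glycoside (ginsenoside Rh2) and its aglycone
metabolite (protopanaxadiol, PPD) simultaneously.  Rh2 in the central
(plasma) compartment distributes to a peripheral compartment and is lost by
three first-order routes: direct transformation to PPD in the systemic
circulation (k_45), biliary excretion into the gut lumen (k_43) and an
unknown route (k_40).  Biliary Rh2 moves down a chain of identical transit
compartments (rate k_t) and is deglycosylated to PPD on entering the colon,
where PPD is either absorbed (k_t) or lost (k_60).  After an oral dose,
stomach Rh2 is partly transformed to PPD by gastric acid (k_12) — that PPD
is absorbed (k_t) or lost (k_20) — and partly transits to the intestine
(k_13), joining the same chain.  PPD in plasma follows its own
two-compartment disposition (k_50, k_58, k_85).  Hepatic transformation is
merged into the plasma compartment (no separate liver compartment).

Amounts are in nmol per kg body weight throughout; the system is linear and
mass-closed once four cumulative-elimination bookkeeping slots are included.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields
from typing import Mapping

import numpy as np

from .exceptions import ConfigurationError, ParameterValidationError
from .parameters import ParameterSet

__all__ = [
    "Route",
    "Analyte",
    "DoseEvent",
    "ModelState",
    "SubModelSpec",
    "build_submodel",
    "model_rhs",
    "system_matrix",
    "slot_names",
    "MOLAR_MASS",
    "DEFAULT_N_TRANSIT",
]

DEFAULT_N_TRANSIT = 3

#: Default molar masses (g/mol); standard literature values, overridable per
#: DoseEvent.
MOLAR_MASS = {"RH2": 622.87, "PPD": 460.73}


class Route(str, enum.Enum):
    IV_RH2 = "IV_RH2"
    PO_RH2 = "PO_RH2"
    IV_PPD = "IV_PPD"


class Analyte(str, enum.Enum):
    RH2 = "RH2"
    PPD = "PPD"


#: Analyte dosed on each route.
DOSED_ANALYTE = {Route.IV_RH2: Analyte.RH2, Route.PO_RH2: Analyte.RH2, Route.IV_PPD: Analyte.PPD}


@dataclass(frozen=True)
class DoseEvent:
    """A single bolus dose.

    I.V. Rh2 enters the Rh2 central compartment, oral Rh2 the stomach, and
    I.V. PPD the PPD central compartment.
    """

    route: Route
    dose_mg_per_kg: float
    time_h: float = 0.0
    molar_mass: float | None = None

    def __post_init__(self) -> None:
        if self.dose_mg_per_kg < 0:
            raise ParameterValidationError("dose must be non-negative")
        if self.time_h < 0:
            raise ParameterValidationError("dose time must be non-negative")
        if isinstance(self.route, str) and not isinstance(self.route, Route):
            object.__setattr__(self, "route", Route(self.route))
        if self.molar_mass is None:
            object.__setattr__(
                self, "molar_mass", MOLAR_MASS[DOSED_ANALYTE[self.route].value]
            )

    @property
    def amount_nmol_per_kg(self) -> float:
        """Dose converted to nmol/kg: mg/kg * 1e6 / (g/mol)."""
        return self.dose_mg_per_kg * 1e6 / self.molar_mass


def slot_names(n_transit: int = DEFAULT_N_TRANSIT) -> list[str]:
    """Ordered state-vector slot names for a chain of ``n_transit`` transit
    compartments (amounts first, cumulative-elimination bookkeeping last)."""
    return (
        ["a_sto_rh2", "a_sto_ppd"]
        + [f"a_T{i}" for i in range(1, n_transit + 1)]
        + ["a_col_ppd", "a_pl_rh2", "a_pc_rh2", "a_pl_ppd", "a_pc_ppd"]
        + [
            "cum_elim_rh2_unknown",
            "cum_elim_ppd_central",
            "cum_elim_ppd_stomach",
            "cum_elim_ppd_colon",
        ]
    )


N_CUMULATIVE = 4


@dataclass(frozen=True)
class ModelState:
    """Amounts (nmol/kg) in the eleven compartments of the default
    three-transit model plus cumulative-elimination bookkeeping."""

    a_sto_rh2: float = 0.0
    a_sto_ppd: float = 0.0
    a_T1: float = 0.0
    a_T2: float = 0.0
    a_T3: float = 0.0
    a_col_ppd: float = 0.0
    a_pl_rh2: float = 0.0
    a_pc_rh2: float = 0.0
    a_pl_ppd: float = 0.0
    a_pc_ppd: float = 0.0
    cum_elim_rh2_unknown: float = 0.0
    cum_elim_ppd_central: float = 0.0
    cum_elim_ppd_stomach: float = 0.0
    cum_elim_ppd_colon: float = 0.0

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in slot_names(3)], dtype=float)

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "ModelState":
        return cls(**dict(zip(slot_names(3), map(float, vec))))

    @property
    def total(self) -> float:
        return float(sum(getattr(self, f.name) for f in fields(self)))


def system_matrix(params: ParameterSet, n_transit: int = DEFAULT_N_TRANSIT) -> np.ndarray:
    """Rate matrix A of the linear system dx/dt = A x.

    Ordering follows :func:`slot_names`.  The matrix is mass-closed: every
    column sums to zero because each first-order loss appears either as a
    transfer into another compartment or as an accrual into a cumulative
    elimination slot.
    """
    if n_transit < 1:
        raise ConfigurationError("n_transit must be >= 1")
    names = slot_names(n_transit)
    ix = {name: i for i, name in enumerate(names)}
    n = len(names)
    A = np.zeros((n, n))
    p = params

    sto_rh2, sto_ppd = ix["a_sto_rh2"], ix["a_sto_ppd"]
    col, pl_rh2, pc_rh2 = ix["a_col_ppd"], ix["a_pl_rh2"], ix["a_pc_rh2"]
    pl_ppd, pc_ppd = ix["a_pl_ppd"], ix["a_pc_ppd"]
    t_first, t_last = ix["a_T1"], ix[f"a_T{n_transit}"]

    # stomach Rh2: acid transformation to PPD vs transit to the intestine
    A[sto_rh2, sto_rh2] = -(p.k_12 + p.k_13)
    A[sto_ppd, sto_rh2] = p.k_12
    A[t_first, sto_rh2] = p.k_13
    # stomach PPD: absorption (k_t) vs unknown loss (k_20)
    A[sto_ppd, sto_ppd] = -(p.k_t + p.k_20)
    A[pl_ppd, sto_ppd] = p.k_t
    A[ix["cum_elim_ppd_stomach"], sto_ppd] = p.k_20
    # transit chain; biliary Rh2 joins at the head
    A[t_first, pl_rh2] += p.k_43
    for i in range(t_first, t_last + 1):
        A[i, i] -= p.k_t
        A[i + 1, i] += p.k_t  # T_last feeds the colon slot, which follows it
    # colon PPD: absorption vs colonic loss
    A[col, col] = -(p.k_t + p.k_60)
    A[pl_ppd, col] += p.k_t
    A[ix["cum_elim_ppd_colon"], col] = p.k_60
    # Rh2 disposition: three elimination routes plus peripheral exchange
    A[pl_rh2, pl_rh2] = -(p.k_40 + p.k_43 + p.k_45 + p.k_47)
    A[pl_rh2, pc_rh2] = p.k_74
    A[pc_rh2, pl_rh2] = p.k_47
    A[pc_rh2, pc_rh2] = -p.k_74
    A[pl_ppd, pl_rh2] += p.k_45
    A[ix["cum_elim_rh2_unknown"], pl_rh2] = p.k_40
    # PPD disposition
    A[pl_ppd, pl_ppd] = -(p.k_50 + p.k_58)
    A[pl_ppd, pc_ppd] = p.k_85
    A[pc_ppd, pl_ppd] = p.k_58
    A[pc_ppd, pc_ppd] = -p.k_85
    A[ix["cum_elim_ppd_central"], pl_ppd] = p.k_50
    return A


def model_rhs(state: ModelState, params: ParameterSet) -> ModelState:
    """Time-derivative of every state slot (pure function, default chain)."""
    A = system_matrix(params, 3)
    return ModelState.from_vector(A @ state.to_vector())


_AMOUNT_SLOTS_3 = tuple(slot_names(3)[:-N_CUMULATIVE])

_A_SET = frozenset({"a_pl_rh2", "a_pc_rh2"})
_B_SET = frozenset({"a_pl_ppd", "a_pc_ppd"})
_C_SET = _A_SET | _B_SET | frozenset({"a_T1", "a_T2", "a_T3", "a_col_ppd"})
_D_SET = _B_SET | frozenset({"a_sto_rh2", "a_sto_ppd", "a_T1", "a_T2", "a_T3", "a_col_ppd"})


@dataclass(frozen=True)
class SubModelSpec:
    """One stage of the model-reduction strategy.

    ``estimated_parameters`` are fitted at that stage; ``fixed_parameters``
    are carried through from earlier stages or frozen from external data.
    """

    tag: str
    active_compartments: frozenset[str]
    estimated_parameters: tuple[str, ...]
    fixed_parameters: tuple[str, ...]
    compatible_routes: frozenset[Route]
    fit_analyte: Analyte | None

    def __post_init__(self) -> None:
        overlap = set(self.estimated_parameters) & set(self.fixed_parameters)
        if overlap:
            raise ConfigurationError(f"parameters both estimated and fixed: {sorted(overlap)}")


_SUBMODELS: Mapping[str, SubModelSpec] = {
    # Stage 1: Rh2 two-compartment disposition from I.V. Rh2 data.  The
    # route split of k_e is unidentifiable from Rh2 concentrations alone, so
    # only the total is estimated here.
    "A": SubModelSpec(
        "A", _A_SET, ("V_rh2_plasma", "k_e", "k_47", "k_74"), (),
        frozenset({Route.IV_RH2}), Analyte.RH2,
    ),
    # Stage 2: PPD two-compartment disposition from I.V. PPD data.
    "B": SubModelSpec(
        "B", _B_SET, ("V_ppd_plasma", "k_50", "k_58", "k_85"), (),
        frozenset({Route.IV_PPD}), Analyte.PPD,
    ),
    # Stage 3: metabolite formation after I.V. Rh2.  k_43 and k_40 are
    # frozen from the reported biliary-excretion fraction; A/B carried over.
    "C": SubModelSpec(
        "C", _C_SET, ("k_45", "k_t", "k_60"),
        ("k_43", "k_40", "V_rh2_plasma", "k_e", "k_47", "k_74",
         "V_ppd_plasma", "k_50", "k_58", "k_85"),
        frozenset({Route.IV_RH2}), Analyte.PPD,
    ),
    # Stage 4: stomach handling after P.O. Rh2, with k_t/k_60 from stage 3.
    "D": SubModelSpec(
        "D", _D_SET, ("k_13", "k_12", "k_20"),
        ("k_t", "k_60", "V_ppd_plasma", "k_50", "k_58", "k_85"),
        frozenset({Route.PO_RH2}), Analyte.PPD,
    ),
    "FULL": SubModelSpec(
        "FULL", frozenset(_AMOUNT_SLOTS_3),
        ("V_rh2_plasma", "k_e", "k_47", "k_74",
         "V_ppd_plasma", "k_50", "k_58", "k_85",
         "k_45", "k_t", "k_60", "k_13", "k_12", "k_20"),
        ("k_43", "k_40"),
        frozenset({Route.IV_RH2, Route.PO_RH2, Route.IV_PPD}), None,
    ),
}


def build_submodel(tag: str) -> SubModelSpec:
    """Return the sub-model specification for tag A, B, C, D or FULL."""
    try:
        return _SUBMODELS[str(tag).upper()]
    except KeyError:
        raise ConfigurationError(f"unknown sub-model tag: {tag!r}") from None


def dose_slot(route: Route, n_transit: int = DEFAULT_N_TRANSIT) -> int:
    """State-vector index that receives the bolus for the given route."""
    names = slot_names(n_transit)
    target = {Route.IV_RH2: "a_pl_rh2", Route.PO_RH2: "a_sto_rh2", Route.IV_PPD: "a_pl_ppd"}
    return names.index(target[Route(route)])
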