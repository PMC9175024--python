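"""Synthetic rat-study generator.

Emulates the design of the source study: four Rh2 groups of three rats
(I.V. and P.O. at 10 and 20 mg/kg), an auxiliary I.V. PPD group (0.2 mg/kg,
used to calibrate PPD disposition), and the fixed sampling schedule
0.25, 0.5, 1, 2, 4, 8, 12, 16 and 20-or-24 h after dosing.  Each subject
gets log-normal inter-individual parameter multipliers and multiplicative
residual noise; values below the assay LLOQ are flagged BLQ with the raw
value kept in a shadow column.  Body-weight variation is ignored because
all rates and volumes are per-kg, so weight cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datasets import SHADOW_COLUMN, validate_dataset
from .exceptions import ParameterValidationError
from .model import Analyte, DoseEvent, Route
from .parameters import ParameterSet
from .simulate import simulate_individual

__all__ = ["Group", "StudyDesign", "default_design", "generate_study", "DEFAULT_LLOQ"]

#: Assumed assay lower limits of quantitation (nmol/L); the study's own
#: LLOQs are not published.
DEFAULT_LLOQ: Mapping[str, float] = {"RH2": 1.0, "PPD": 1.0}

_STUDY_TIMES = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 16.0)

#: Sampling schedule of the auxiliary I.V. PPD study (a prior experiment
#: whose exact schedule is not described with the Rh2 study design).  PPD
#: distributes with a half-life of roughly a minute, so a realistic rat
#: I.V. design samples the distribution phase: 2, 5, 15 and 30 min, then
#: 1, 2, 4, 8, 12 and 24 h.
_PPD_IV_TIMES = (1 / 30, 1 / 12, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)


@dataclass(frozen=True)
class Group:
    name: str
    route: Route
    dose_mg_per_kg: float
    n_subjects: int
    #: per-group override of the design-level sampling schedule
    sampling_times: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterValidationError("n_subjects must be >= 1")
        if self.dose_mg_per_kg < 0:
            raise ParameterValidationError("dose must be non-negative")
        if self.sampling_times is not None:
            times = tuple(float(t) for t in self.sampling_times)
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ParameterValidationError("sampling times must be strictly increasing")
            object.__setattr__(self, "sampling_times", times)


@dataclass(frozen=True)
class StudyDesign:
    groups: tuple[Group, ...]
    sampling_times: tuple[float, ...]
    lloq: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_LLOQ))
    horizon_h: float = 24.0

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.sampling_times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ParameterValidationError("sampling times must be strictly increasing")
        if any(v < 0 for v in self.lloq.values()):
            raise ParameterValidationError("lloq must be non-negative")
        object.__setattr__(self, "sampling_times", times)


def default_design(final_sample_h: float = 24.0, n_subjects: int = 3) -> StudyDesign:
    """The emulated study design: 4 Rh2 groups (I.V./P.O. x 10/20 mg/kg,
    n=3) plus an auxiliary I.V. PPD 0.2 mg/kg group; final sample at 20 or
    24 h (24 by default)."""
    if final_sample_h not in (20.0, 24.0):
        raise ParameterValidationError("final sample is drawn at 20 or 24 h")
    groups = (
        Group("IV_RH2_10", Route.IV_RH2, 10.0, n_subjects),
        Group("IV_RH2_20", Route.IV_RH2, 20.0, n_subjects),
        Group("PO_RH2_10", Route.PO_RH2, 10.0, n_subjects),
        Group("PO_RH2_20", Route.PO_RH2, 20.0, n_subjects),
        Group("IV_PPD_0.2", Route.IV_PPD, 0.2, n_subjects, sampling_times=_PPD_IV_TIMES),
    )
    return StudyDesign(
        groups=groups,
        sampling_times=_STUDY_TIMES + (final_sample_h,),
        horizon_h=final_sample_h,
    )


def generate_study(
    design: StudyDesign, params: ParameterSet, seed: int
) -> pd.DataFrame:
    """Simulate one complete study as a validated long-format dataset.

    Deterministic per seed.  Inter-individual variability uses
    ``params.omega`` (log-scale SDs) and residual noise ``params.sigma``;
    with both zero every subject reproduces the noise-free profile exactly.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict[str, object]] = []
    for group in design.groups:
        times = np.asarray(group.sampling_times or design.sampling_times, dtype=float)
        analytes = (
            (Analyte.PPD,) if group.route == Route.IV_PPD else (Analyte.RH2, Analyte.PPD)
        )
        dose = DoseEvent(group.route, group.dose_mg_per_kg)
        for i in range(1, group.n_subjects + 1):
            subject = f"{group.name}_R{i}"
            eta = {
                name: rng.normal(0.0, sd) if sd > 0 else 0.0
                for name, sd in params.omega.items()
            }
            rh2, ppd = simulate_individual(
                params, dose, times, iiv_draw=eta, residual_seed=rng, subject=subject
            )
            profile = {Analyte.RH2: rh2, Analyte.PPD: ppd}
            for analyte in analytes:
                lloq = float(design.lloq.get(analyte.value, 0.0))
                for t, y in zip(times, profile[analyte].concentrations):
                    blq = y < lloq
                    rows.append(
                        {
                            "subject_id": subject,
                            "group": group.name,
                            "route": group.route.value,
                            "analyte": analyte.value,
                            "dose_mg_per_kg": group.dose_mg_per_kg,
                            "time_h": float(t),
                            "conc_nmol_per_L": float("nan") if blq else float(y),
                            "blq": bool(blq),
                            SHADOW_COLUMN: float(y),
                        }
                    )
    return validate_dataset(pd.DataFrame(rows))


def staged_datasets(study: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Slice one generated study into the four calibration datasets
    (10 mg/kg groups plus the I.V. PPD group, as in the original staged
    fit; the 20 mg/kg groups are reserved for external validation)."""
    iv10 = study[(study["route"] == "IV_RH2") & (study["dose_mg_per_kg"] == 10.0)]
    po10 = study[(study["route"] == "PO_RH2") & (study["dose_mg_per_kg"] == 10.0)]
    ivppd = study[study["route"] == "IV_PPD"]
    return {
        "A": iv10[iv10["analyte"] == "RH2"],
        "B": ivppd[ivppd["analyte"] == "PPD"],
        "C": iv10[iv10["analyte"] == "PPD"],
        "D": po10[po10["analyte"] == "PPD"],
    }
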