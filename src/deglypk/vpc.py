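"""Visual predictive check.

Simulates many replicate studies under the fitted model with
inter-individual and residual variability, pools the simulated observations
per nominal sampling time, and reports the empirical 5th/50th/95th
percentiles.  Observed data falling mostly inside the 90% band validates
the model; the conventional stricter 90%-coverage reference is reported
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, ParameterValidationError
from .model import Analyte, DoseEvent
from .parameters import ParameterSet
from .simulate import simulate_individual

__all__ = ["PercentileBands", "CoverageResult", "run_vpc", "coverage_fraction", "plot_vpc"]


@dataclass(frozen=True)
class PercentileBands:
    analyte: Analyte
    dose: DoseEvent
    times: np.ndarray
    p05: np.ndarray
    p50: np.ndarray
    p95: np.ndarray
    n_replicates: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ParameterValidationError("n_replicates must be >= 1")
        if np.any(self.p05 > self.p50) or np.any(self.p50 > self.p95):
            raise ParameterValidationError("percentiles must be ordered p05 <= p50 <= p95")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "p05": self.p05,
                "p50": self.p50,
                "p95": self.p95,
                "analyte": self.analyte.value,
            }
        )


@dataclass(frozen=True)
class CoverageResult:
    fraction: float
    n_observations: int
    #: the validation verdict used here: a majority of observations inside
    #: the 90% prediction interval
    majority_within: bool
    #: stricter conventional reference: at least 90% of observations inside
    meets_090: bool


def run_vpc(
    params: ParameterSet,
    dose: DoseEvent,
    times: Sequence[float],
    analyte: Analyte | str,
    n_subjects: int = 3,
    n_replicates: int = 1000,
    seed: int = 0,
    omega: Mapping[str, float] | None = None,
    sigma: float | None = None,
) -> PercentileBands:
    """Percentile bands of simulated observations, deterministic per seed.

    ``omega``/``sigma`` override the variability terms carried on
    ``params`` when given.
    """
    if n_replicates < 1:
        raise ParameterValidationError("n_replicates must be >= 1")
    analyte = Analyte(analyte)
    p = params
    if omega is not None:
        p = p.replace(omega=dict(omega))
    if sigma is not None:
        p = p.replace(sigma=float(sigma))
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_replicates * n_subjects, times.size))
    row = 0
    for _ in range(n_replicates):
        for _subj in range(n_subjects):
            eta = {name: rng.normal(0.0, sd) if sd > 0 else 0.0 for name, sd in p.omega.items()}
            rh2, ppd = simulate_individual(p, dose, times, iiv_draw=eta, residual_seed=rng)
            prof = rh2 if analyte == Analyte.RH2 else ppd
            sims[row] = prof.concentrations
            row += 1
    p05, p50, p95 = np.percentile(sims, [5.0, 50.0, 95.0], axis=0)
    return PercentileBands(analyte, dose, times, p05, p50, p95, n_replicates)


def coverage_fraction(
    bands: PercentileBands, dataset: pd.DataFrame, interpolate: bool = False
) -> CoverageResult:
    """Fraction of non-BLQ observations of the bands' analyte inside
    [p05, p95].

    Observation times must coincide with band times unless
    ``interpolate=True`` (linear interpolation of the band edges).
    """
    obs = dataset[(dataset["analyte"] == bands.analyte.value) & (~dataset["blq"].astype(bool))]
    if obs.empty:
        raise DataError("no quantifiable observations for coverage")
    t = obs["time_h"].to_numpy(dtype=float)
    y = obs["conc_nmol_per_L"].to_numpy(dtype=float)
    if interpolate:
        lo = np.interp(t, bands.times, bands.p05)
        hi = np.interp(t, bands.times, bands.p95)
    else:
        idx = np.searchsorted(bands.times, t)
        idx = np.clip(idx, 0, bands.times.size - 1)
        if not np.allclose(bands.times[idx], t):
            raise DataError("observation times not in band times; pass interpolate=True")
        lo, hi = bands.p05[idx], bands.p95[idx]
    inside = (y >= lo) & (y <= hi)
    frac = float(inside.mean())
    return CoverageResult(
        fraction=frac,
        n_observations=int(inside.size),
        majority_within=frac > 0.5,
        meets_090=frac >= 0.9,
    )


def plot_vpc(bands: PercentileBands, dataset: pd.DataFrame | None = None, ax=None):
    """Median line with shaded 90% interval, observations overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(bands.times, bands.p05, bands.p95, alpha=0.3, color="green", label="90% PI")
    ax.plot(bands.times, bands.p50, color="black", label="median")
    if dataset is not None:
        obs = dataset[
            (dataset["analyte"] == bands.analyte.value) & (~dataset["blq"].astype(bool))
        ]
        ax.plot(obs["time_h"], obs["conc_nmol_per_L"], "o", ms=4, label="observed")
    ax.set_xlabel("time (h)")
    ax.set_ylabel(f"{bands.analyte.value} concentration (nmol/L)")
    ax.legend()
    return ax
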