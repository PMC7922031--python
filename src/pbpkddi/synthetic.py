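"""Synthetic "observed" study datasets.

Emulates the structure of digitized clinical data: sparse sampling
schedules, plasma/saliva/urine-fraction observables, multiplicative
lognormal residual noise and per-study mean ± SD reporting, so every
downstream stage (evaluation, fitting, DDI ratios) is testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .drugs import DrugParameters, copy_drug
from .engine.system import SolverConfig
from .errors import ValidationError
from .fitting import set_parameter
from .physiology import Individual
from .trials import DDIProtocol, StudyProtocol, simulate_ddi, simulate_study


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal residual noise on sampled concentrations.

    ``sigma_log10`` is the spread of log10 residuals; values at or below
    ``loq`` are dropped from the observed table.  Reproducible given seed.
    """

    sigma_log10: float = 0.15
    loq: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_log10 < 0:
            raise ValidationError("sigma_log10 must be >= 0")


@dataclass
class SyntheticStudy:
    """A generated study: protocol, generating parameters, observed table.

    ``observed`` has columns ``study_id, analyte, matrix, time_h, value, sd``
    (sd only when n_subjects > 1), matching the observed-data CSV schema.
    """

    protocol: StudyProtocol
    true_parameters: dict[str, float]
    observed: pd.DataFrame
    n_subjects: int
    study_id: str = "synthetic"
    #: noise-free model prediction at the sampling schedule
    truth: Optional[pd.DataFrame] = None
    #: per-subject observation tables (before aggregation and LOQ filtering)
    subjects: list[pd.DataFrame] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.observed.to_csv(path, index=False)


#: sparse sampling templates of typical study designs (hours post dose)
SAMPLING_TEMPLATES: dict[str, tuple[float, ...]] = {
    "rich_day1": (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0),
    "rich_single_dose_96h": (
        0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0, 72.0, 96.0,
    ),
    "trough_maintenance": tuple(float(24 * d) for d in range(1, 15)),
}


def _subject_drugs(
    drugs: Mapping[str, DrugParameters],
    iiv: Optional[Mapping[str, float]],
    rng: np.random.Generator,
) -> dict[str, DrugParameters]:
    """Apply lognormal inter-individual factors to the listed parameters."""
    out = {name: copy_drug(d) for name, d in drugs.items()}
    if iiv:
        from .fitting import get_parameter

        for path, sigma in iiv.items():
            factor = 10.0 ** (sigma * rng.standard_normal())
            set_parameter(out, path, get_parameter(out, path) * factor)
    return out


def _observe(
    result,
    protocol: StudyProtocol,
    noise: NoiseModel,
    rng: Optional[np.random.Generator],
) -> pd.DataFrame:
    """Sample a simulation at the schedule; ``rng=None`` returns the truth."""
    times = np.asarray(protocol.sampling_times_h, dtype=float)
    rows = []
    for analyte, matrix in protocol.analytes:
        truth = result.sample(analyte, matrix, times)
        if rng is None:
            values = truth
        else:
            eps = rng.standard_normal(len(times))
            values = truth * 10.0 ** (noise.sigma_log10 * eps)
        rows.append(
            pd.DataFrame(
                {
                    "analyte": analyte,
                    "matrix": matrix,
                    "time_h": times,
                    "value": values,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _aggregate(
    tables: list[pd.DataFrame], noise: NoiseModel, study_id: str
) -> pd.DataFrame:
    stacked = pd.concat(tables, ignore_index=True)
    grouped = stacked.groupby(["analyte", "matrix", "time_h"], as_index=False)
    agg = grouped["value"].mean()
    if len(tables) > 1:
        agg["sd"] = grouped["value"].std(ddof=1)["value"].to_numpy()
    else:
        agg["sd"] = np.nan
    if noise.loq is not None:
        agg = agg[agg["value"] > noise.loq].reset_index(drop=True)
    agg.insert(0, "study_id", study_id)
    return agg[["study_id", "analyte", "matrix", "time_h", "value", "sd"]]


def generate_observed_dataset(
    protocol: StudyProtocol,
    drugs: Mapping[str, DrugParameters],
    noise: NoiseModel,
    n_subjects: int = 1,
    iiv: Optional[Mapping[str, float]] = None,
    individual: Optional[Individual] = None,
    solver: Optional[SolverConfig] = None,
    study_id: str = "synthetic",
    true_parameters: Optional[dict[str, float]] = None,
) -> SyntheticStudy:
    """Simulate the truth, optionally perturb per-subject parameters with
    lognormal factors (``iiv`` maps parameter path to sigma_log10), sample at
    the protocol schedule with residual noise, and report means ± SD."""
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    rng = np.random.default_rng(noise.seed)
    solver = solver or SolverConfig(rtol=1e-6, atol=1e-9)

    tables = []
    truth_frame = None
    base_result = None
    for _ in range(n_subjects):
        if iiv:
            subject = _subject_drugs(drugs, iiv, rng)
            result = simulate_study(
                protocol, subject, individual=individual, config=solver
            )
        else:
            if base_result is None:
                base_result = simulate_study(
                    protocol, dict(drugs), individual=individual, config=solver
                )
            result = base_result
        if truth_frame is None and not iiv:
            truth_frame = _observe(result, protocol, noise, None)
        tables.append(_observe(result, protocol, noise, rng))

    observed = _aggregate(tables, noise, study_id)
    return SyntheticStudy(
        protocol=protocol,
        true_parameters=dict(true_parameters or {}),
        observed=observed,
        n_subjects=n_subjects,
        study_id=study_id,
        truth=truth_frame,
        subjects=tables,
    )


def generate_ddi_dataset(
    ddi: DDIProtocol,
    drugs: Mapping[str, DrugParameters],
    noise: NoiseModel,
    n_subjects: int = 1,
    individual: Optional[Individual] = None,
    solver: Optional[SolverConfig] = None,
    study_id: str = "synthetic-ddi",
) -> tuple[SyntheticStudy, SyntheticStudy]:
    """Paired synthetic arms (victim alone, victim + perpetrator) sharing the
    subjects' residual-noise draws per arm stream."""
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    solver = solver or SolverConfig(rtol=1e-6, atol=1e-9)
    alone, together = simulate_ddi(ddi, dict(drugs), individual=individual,
                                   config=solver)

    studies = []
    for arm, result in (("alone", alone), ("with-perpetrator", together)):
        rng = np.random.default_rng(noise.seed)  # shared subjects across arms
        tables = [
            _observe(result, ddi.victim, noise, rng) for _ in range(n_subjects)
        ]
        observed = _aggregate(tables, noise, f"{study_id}/{arm}")
        studies.append(
            SyntheticStudy(
                protocol=ddi.victim,
                true_parameters={},
                observed=observed,
                n_subjects=n_subjects,
                study_id=f"{study_id}/{arm}",
            )
        )
    return studies[0], studies[1]
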