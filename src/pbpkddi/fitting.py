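"""Parameter estimation by log-scale least squares.

Strategy: Monte-Carlo multistart (uniform draws inside the bounds, fixed
seed) followed by local least-squares refinement, so rugged objectives are
explored globally and polished locally.  The objective is the sum of squared
log10 residuals between simulated and observed concentrations, appropriate
for profiles spanning orders of magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .drugs import DrugParameters, copy_drug
from .engine.processes import (
    HepaticClearance,
    RateLawMM,
    RateLawSpecificCL,
    RenalFiltration,
)
from .engine.system import SolverConfig
from .errors import ConfigurationError, ValidationError
from .physiology import Individual
from .trials import StudyProtocol, simulate_study


@dataclass(frozen=True)
class FreeParameter:
    """A fit parameter addressed by path into a drug model.

    Path grammar (segments joined by '/'):
      ``<drug>/lipophilicity`` and other scalar physchem fields,
      ``<drug>/process/<enzyme>/<field>`` (first process of that enzyme),
      ``<drug>/process/<enzyme>-><product>/<field>`` (linked pathway),
      ``<drug>/interaction/<enzyme>/<field>``,
      ``<drug>/cl_hep``, ``<drug>/gfr_fraction``.
    """

    path: str
    lower: float
    upper: float
    transform: str = "log"

    def __post_init__(self) -> None:
        if not np.isfinite(self.lower) or not np.isfinite(self.upper):
            raise ValidationError(f"{self.path}: bounds must be finite")
        if self.lower >= self.upper:
            raise ValidationError(f"{self.path}: bounds must be ordered")
        if self.transform not in ("log", "linear"):
            raise ValidationError(f"{self.path}: unknown transform")
        if self.transform == "log" and self.lower <= 0:
            raise ValidationError(f"{self.path}: log transform needs lower > 0")


@dataclass
class FitDataset:
    """One study: a protocol plus observed series (analyte, matrix, time_h,
    value)."""

    protocol: StudyProtocol
    observed: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"analyte", "matrix", "time_h", "value"} - set(
            self.observed.columns
        )
        if missing:
            raise ValidationError(f"observed frame lacks columns {sorted(missing)}")
        if len(self.observed) == 0:
            raise ValidationError("observed dataset is empty")


@dataclass
class FitSpec:
    parameters: list[FreeParameter]
    datasets: list[FitDataset]
    drugs: dict[str, DrugParameters]
    n_starts: int = 20
    seed: int = 0
    loq: Optional[float] = None
    individual: Optional[Individual] = None
    solver: Optional[SolverConfig] = None
    allow_joint_induction_fit: bool = False

    def __post_init__(self) -> None:
        if not self.parameters:
            raise ValidationError("fit spec declares no free parameters")
        if not self.datasets:
            raise ValidationError("fit spec declares no datasets")
        for p in self.parameters:
            get_parameter(self.drugs, p.path)  # resolvability check
        if not self.allow_joint_induction_fit:
            by_enzyme: dict[tuple[str, str], set[str]] = {}
            for p in self.parameters:
                parts = p.path.split("/")
                if len(parts) == 4 and parts[1] == "interaction":
                    by_enzyme.setdefault((parts[0], parts[2]), set()).add(parts[3])
            for (drug, enzyme), fields in by_enzyme.items():
                if {"E_max", "EC_50"} <= fields:
                    raise ValidationError(
                        f"jointly fitting E_max and EC_50 for {enzyme} of "
                        f"{drug} is not identifiable from single-arm data; "
                        f"set allow_joint_induction_fit=True to override"
                    )


@dataclass
class FitResult:
    estimates: dict[str, float]
    objective: float
    starts: list[dict]
    n_starts: int
    seed: int

    @property
    def success(self) -> bool:
        return any(s["converged"] for s in self.starts)


# ---------------------------------------------------------------------------
# Parameter paths
# ---------------------------------------------------------------------------

def _locate(drugs: dict[str, DrugParameters], path: str):
    parts = path.split("/")
    if parts[0] not in drugs:
        raise ConfigurationError(f"{path}: unknown drug {parts[0]!r}")
    drug = drugs[parts[0]]
    if len(parts) == 2:
        name = parts[1]
        if name == "cl_hep":
            for proc in drug.processes:
                if isinstance(proc, HepaticClearance):
                    return proc, "CL_spec"
            raise ConfigurationError(f"{path}: drug has no hepatic clearance")
        if name == "gfr_fraction":
            for proc in drug.processes:
                if isinstance(proc, RenalFiltration):
                    return proc, "gfr_fraction"
            raise ConfigurationError(f"{path}: drug has no renal filtration")
        if not hasattr(drug, name):
            raise ConfigurationError(f"{path}: unknown field {name!r}")
        return drug, name
    if len(parts) == 4 and parts[1] == "process":
        selector, fieldname = parts[2], parts[3]
        enzyme, _, product = selector.partition("->")
        for proc in drug.processes:
            if not isinstance(proc, (RateLawMM, RateLawSpecificCL)):
                continue
            if proc.enzyme != enzyme:
                continue
            if product and proc.product != product:
                continue
            if not hasattr(proc, fieldname):
                raise ConfigurationError(f"{path}: unknown field {fieldname!r}")
            return proc, fieldname
        raise ConfigurationError(f"{path}: no process matches {selector!r}")
    if len(parts) == 4 and parts[1] == "interaction":
        enzyme, fieldname = parts[2], parts[3]
        for action in drug.interactions:
            if action.target_enzyme == enzyme and hasattr(action, fieldname):
                return action, fieldname
        raise ConfigurationError(f"{path}: no interaction targets {enzyme!r}")
    raise ConfigurationError(f"cannot parse parameter path {path!r}")


def get_parameter(drugs: dict[str, DrugParameters], path: str) -> float:
    obj, fieldname = _locate(drugs, path)
    return float(getattr(obj, fieldname))


def set_parameter(drugs: dict[str, DrugParameters], path: str, value: float) -> None:
    obj, fieldname = _locate(drugs, path)
    setattr(obj, fieldname, float(value))


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

_FAILURE_PENALTY = 1e3


def _default_solver() -> SolverConfig:
    # fitting runs many simulations; moderate tolerances are sufficient for
    # a log-scale objective
    return SolverConfig(rtol=1e-6, atol=1e-9)


def residuals(values: Sequence[float], spec: FitSpec) -> np.ndarray:
    """Vector of log10(pred/obs) residuals over all datasets."""
    drugs = {name: copy_drug(d) for name, d in spec.drugs.items()}
    for p, v in zip(spec.parameters, values):
        set_parameter(drugs, p.path, v)
    solver = spec.solver or _default_solver()

    out: list[np.ndarray] = []
    for ds in spec.datasets:
        obs = ds.observed
        if spec.loq is not None:
            obs = obs[obs["value"] > spec.loq]
        if len(obs) == 0:
            raise ValidationError("dataset has no observations above the LOQ")
        try:
            result = simulate_study(
                ds.protocol, drugs, individual=spec.individual, config=solver
            )
        except Exception as exc:  # solver failures carry a large penalty
            warnings.warn(f"simulation failed during fit: {exc}", stacklevel=2)
            out.append(np.full(len(obs), _FAILURE_PENALTY))
            continue
        for (analyte, matrix), group in obs.groupby(["analyte", "matrix"]):
            sim = result.sample(analyte, matrix, group["time_h"].to_numpy())
            sim = np.clip(sim, 1e-12, None)
            out.append(np.log10(sim / group["value"].to_numpy()))
    return np.concatenate(out)


def objective(values: Sequence[float], spec: FitSpec) -> float:
    """Sum of squared log10 residuals between simulated and observed
    concentrations."""
    res = residuals(values, spec)
    return float(np.sum(res**2))


# ---------------------------------------------------------------------------
# Multistart optimisation
# ---------------------------------------------------------------------------

def _to_internal(values: np.ndarray, spec: FitSpec) -> np.ndarray:
    return np.array(
        [
            np.log10(v) if p.transform == "log" else v
            for p, v in zip(spec.parameters, values)
        ]
    )


def _from_internal(x: np.ndarray, spec: FitSpec) -> np.ndarray:
    return np.array(
        [
            10.0**xi if p.transform == "log" else xi
            for p, xi in zip(spec.parameters, x)
        ]
    )


def fit_parameters(spec: FitSpec, x0: Optional[Sequence[float]] = None) -> FitResult:
    """Monte-Carlo multistart followed by local least-squares refinement.

    Deterministic for a fixed ``spec.seed``.  ``x0`` optionally replaces the
    first start (natural parameter scale).
    """
    rng = np.random.default_rng(spec.seed)
    lower = _to_internal(np.array([p.lower for p in spec.parameters]), spec)
    upper = _to_internal(np.array([p.upper for p in spec.parameters]), spec)

    starts = [lower + (upper - lower) * rng.random(len(lower))
              for _ in range(spec.n_starts)]
    if x0 is not None:
        starts[0] = _to_internal(np.asarray(x0, dtype=float), spec)

    def fun(x: np.ndarray) -> np.ndarray:
        return residuals(_from_internal(x, spec), spec)

    records: list[dict] = []
    best_x: Optional[np.ndarray] = None
    best_obj = np.inf
    for k, start in enumerate(starts):
        try:
            # diff_step well above the ODE-solver noise floor so numerical
            # gradients stay informative
            sol = least_squares(
                fun,
                start,
                bounds=(lower, upper),
                method="trf",
                diff_step=1e-3,
                xtol=1e-8,
                ftol=1e-10,
                gtol=1e-10,
            )
        except Exception as exc:
            warnings.warn(f"start {k} failed: {exc}", stacklevel=2)
            records.append(
                {"start": k, "converged": False, "objective": np.inf,
                 "x0": _from_internal(start, spec).tolist(), "error": str(exc)}
            )
            continue
        obj = float(2.0 * sol.cost)  # least_squares cost is 0.5 * sum r^2
        records.append(
            {
                "start": k,
                "converged": bool(sol.success),
                "objective": obj,
                "x0": _from_internal(start, spec).tolist(),
                "x": _from_internal(sol.x, spec).tolist(),
                "nfev": int(sol.nfev),
            }
        )
        if sol.success and obj < best_obj:
            best_obj = obj
            best_x = sol.x
    if best_x is None:
        raise ValidationError(
            f"no successful optimisation start out of {spec.n_starts}; "
            f"diagnostics: {records}"
        )

    values = _from_internal(best_x, spec)
    return FitResult(
        estimates={p.path: float(v) for p, v in zip(spec.parameters, values)},
        objective=best_obj,
        starts=records,
        n_starts=spec.n_starts,
        seed=spec.seed,
    )


# ---------------------------------------------------------------------------
# One-at-a-time sensitivity utility
# ---------------------------------------------------------------------------

def sensitivity_auc(
    drugs: dict[str, DrugParameters],
    protocol: StudyProtocol,
    analyte: str,
    paths: Sequence[str],
    perturbation: float = 10.0,
    individual: Optional[Individual] = None,
    solver: Optional[SolverConfig] = None,
) -> dict[str, float]:
    """Relative one-at-a-time AUC sensitivity: (dAUC/AUC) / (dp/p) for a
    multiplicative parameter perturbation."""
    from .trials import auc_last

    solver = solver or _default_solver()
    base = simulate_study(protocol, drugs, individual=individual, config=solver)
    auc0 = auc_last(base.time_h, base.observable(analyte, "plasma"))
    out = {}
    for path in paths:
        perturbed = {name: copy_drug(d) for name, d in drugs.items()}
        p0 = get_parameter(perturbed, path)
        set_parameter(perturbed, path, p0 * perturbation)
        result = simulate_study(
            protocol, perturbed, individual=individual, config=solver
        )
        auc1 = auc_last(result.time_h, result.observable(analyte, "plasma"))
        out[path] = ((auc1 - auc0) / auc0) / (perturbation - 1.0)
    return out
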