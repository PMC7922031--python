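"""Model-performance statistics: MRD, GMFE, 2-fold fraction and the
observed-ratio-dependent DDI prediction-success limits.

Conventions (stated, tested): MRD is 10^(root-mean-square of log10
pred/obs); GMFE is 10^(mean absolute log10 pred/obs); boundary-touching
values count as within limits everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

#: margin parameter of the prediction-success limits: 20% deviation is
#: allowed as the observed ratio approaches 1
GUEST_DELTA = 1.25


@dataclass(frozen=True)
class PredObsPair:
    predicted: float
    observed: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.predicted <= 0 or self.observed <= 0:
            raise ValidationError(
                f"predicted and observed must be > 0 (label={self.label!r})"
            )

    @property
    def log10_ratio(self) -> float:
        return float(np.log10(self.predicted / self.observed))


@dataclass(frozen=True)
class GuestVerdict:
    observed: float
    predicted: float
    lower: float
    upper: float
    within: bool
    delta: float = GUEST_DELTA


def _ratios(pairs: Iterable[PredObsPair]) -> np.ndarray:
    logs = np.array([p.log10_ratio for p in pairs])
    if logs.size == 0:
        raise ValidationError("at least one predicted/observed pair is required")
    return logs


def mrd(pairs: Iterable[PredObsPair]) -> float:
    """Mean relative deviation: 10^sqrt(mean of squared log10(pred/obs))."""
    logs = _ratios(pairs)
    return float(10.0 ** np.sqrt(np.mean(logs**2)))


def gmfe(pairs: Iterable[PredObsPair]) -> float:
    """Geometric mean fold error: 10^(mean of |log10(pred/obs)|)."""
    logs = _ratios(pairs)
    return float(10.0 ** np.mean(np.abs(logs)))


def two_fold_fraction(pairs: Iterable[PredObsPair]) -> float:
    """Share of pairs with pred/obs in [0.5, 2]; bounds are inclusive."""
    logs = _ratios(pairs)
    within = np.abs(logs) <= np.log10(2.0) + 1e-12
    return float(np.mean(within))


def guest_limits(observed_ratio: float, delta: float = GUEST_DELTA) -> tuple[float, float]:
    """Acceptance bounds on a predicted DDI ratio given the observed ratio.

    With R the observed ratio mapped above 1 (R = obs if obs >= 1, else
    1/obs), the allowed fold deviation is L = (delta + 2 (R - 1)) / R, which
    equals delta at no interaction and approaches 2 for strong interactions.
    The bounds are (obs / L, obs * L); they are symmetric under taking the
    reciprocal of both prediction and observation.
    """
    if observed_ratio <= 0:
        raise ValidationError("observed_ratio must be > 0")
    if delta < 1:
        raise ValidationError("delta must be >= 1")
    r = observed_ratio if observed_ratio >= 1.0 else 1.0 / observed_ratio
    limit = (delta + 2.0 * (r - 1.0)) / r
    return observed_ratio / limit, observed_ratio * limit


def guest_verdict(
    predicted: float, observed: float, delta: float = GUEST_DELTA
) -> GuestVerdict:
    lower, upper = guest_limits(observed, delta)
    eps = 1e-12
    within = lower * (1 - eps) <= predicted <= upper * (1 + eps)
    return GuestVerdict(
        observed=observed,
        predicted=predicted,
        lower=lower,
        upper=upper,
        within=bool(within),
        delta=delta,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-study and pooled performance metrics with optional DDI verdicts."""

    per_study: pd.DataFrame
    pooled: dict
    verdicts: list[GuestVerdict]

    def to_json(self) -> str:
        payload = {
            "pooled": self.pooled,
            "per_study": self.per_study.to_dict(orient="records"),
            "guest_verdicts": [
                {
                    "observed": v.observed,
                    "predicted": v.predicted,
                    "lower": v.lower,
                    "upper": v.upper,
                    "within": v.within,
                }
                for v in self.verdicts
            ],
        }
        return json.dumps(payload, indent=2)

    def __str__(self) -> str:
        lines = ["per-study metrics:", self.per_study.to_string(index=False)]
        lines.append(f"pooled: {self.pooled}")
        if self.verdicts:
            n_within = sum(v.within for v in self.verdicts)
            lines.append(
                f"DDI ratios within prediction-success limits: "
                f"{n_within}/{len(self.verdicts)}"
            )
        return "\n".join(lines)


_MATCH_KEYS = ["study_id", "analyte", "matrix", "time_h"]


def evaluation_report(
    predicted: pd.DataFrame,
    observed: pd.DataFrame,
    ratio_pairs: Optional[Iterable[PredObsPair]] = None,
    delta: float = GUEST_DELTA,
) -> EvaluationReport:
    """Match predicted to observed concentrations and compute MRD / GMFE /
    2-fold fractions per study and pooled.

    Both frames need columns ``study_id, analyte, matrix, time_h, value``.
    Rows are matched on the first four; unmatched observed rows raise an
    error listing the offending labels.  ``ratio_pairs`` (predicted vs
    observed DDI ratios) additionally yields prediction-success verdicts.
    Pooled metrics are computed on the pooled pairs, not averaged per study.
    """
    ratio_pairs = list(ratio_pairs) if ratio_pairs is not None else None
    for name, frame in (("predicted", predicted), ("observed", observed)):
        missing = set(_MATCH_KEYS + ["value"]) - set(frame.columns)
        if missing:
            raise ValidationError(f"{name} frame lacks columns {sorted(missing)}")

    merged = observed.merge(
        predicted, on=_MATCH_KEYS, how="left", suffixes=("_obs", "_pred")
    )
    unmatched = merged[merged["value_pred"].isna()]
    if len(unmatched) == len(merged):
        raise ValidationError("no observed record matches any prediction")
    if len(unmatched):
        labels = unmatched[_MATCH_KEYS].astype(str).agg("/".join, axis=1)
        raise ValidationError(
            f"unmatched observed records: {sorted(labels.tolist())}"
        )

    def pairs_of(frame: pd.DataFrame) -> list[PredObsPair]:
        return [
            PredObsPair(row.value_pred, row.value_obs, label=str(row.study_id))
            for row in frame.itertuples()
            if row.value_obs > 0 and row.value_pred > 0
        ]

    records = []
    for study_id, group in merged.groupby("study_id"):
        pairs = pairs_of(group)
        records.append(
            {
                "study_id": study_id,
                "n": len(pairs),
                "mrd": mrd(pairs),
                "gmfe": gmfe(pairs),
                "two_fold_fraction": two_fold_fraction(pairs),
            }
        )
    pooled_pairs = pairs_of(merged)
    pooled = {
        "n": len(pooled_pairs),
        "mrd": mrd(pooled_pairs),
        "gmfe": gmfe(pooled_pairs),
        "two_fold_fraction": two_fold_fraction(pooled_pairs),
    }

    verdicts = []
    if ratio_pairs is not None:
        verdicts = [
            guest_verdict(p.predicted, p.observed, delta) for p in ratio_pairs
        ]
        pooled["ddi_ratio_gmfe"] = gmfe(ratio_pairs) if verdicts else None
        pooled["ddi_within_guest"] = sum(v.within for v in verdicts)
        pooled["ddi_total"] = len(verdicts)

    return EvaluationReport(
        per_study=pd.DataFrame.from_records(records),
        pooled=pooled,
        verdicts=verdicts,
    )
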