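"""Model-evaluation arithmetic: fold errors, R², and surgery percent changes.

Predictions are judged against observed PK parameters with the fold-error
ratio (predicted/observed) against bioequivalence-style acceptance ranges
(1.25-, 1.5-, 2- or 2.5-fold), the coefficient of determination across all
paired values, and pre- vs. post-surgery percent change with the
convention that a positive change means a post-surgery *decrease*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationReport",
    "ScenarioDelta",
    "fold_error",
    "within_fold",
    "r_squared",
    "percent_change",
    "build_validation_report",
]


def fold_error(predicted: float, observed: float) -> float:
    """Ratio of predicted to observed; requires a positive observed value."""
    if observed <= 0:
        raise ValueError("observed value must be positive")
    if predicted <= 0:
        raise ValueError("predicted value must be positive")
    return predicted / observed


def within_fold(fe: float, criterion: float = 1.25) -> bool:
    """True iff the fold error lies in [1/criterion, criterion] (inclusive)."""
    if fe <= 0:
        raise ValueError("fold error must be positive")
    if criterion not in (1.25, 1.5, 2.0, 2.5):
        raise ValueError("criterion must be one of 1.25, 1.5, 2.0, 2.5")
    return 1.0 / criterion <= fe <= criterion


def r_squared(observed, predicted) -> float:
    """Squared Pearson correlation of paired observed/predicted values."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-D")
    if len(obs) < 3:
        raise ValueError("need at least three pairs")
    if np.std(obs) == 0 or np.std(pred) == 0:
        raise ValueError("zero variance in one of the vectors")
    return float(np.corrcoef(obs, pred)[0, 1] ** 2)


def percent_change(pre_value: float, post_value: float) -> float:
    """(pre − post) · 100 / pre; positive means a post-surgery decrease."""
    if pre_value == 0:
        raise ValueError("pre-surgery value must be nonzero")
    return (pre_value - post_value) * 100.0 / pre_value


@dataclass
class ScenarioDelta:
    """Pre- vs. post-surgery change of one PK parameter."""

    parameter: str
    pre_value: float
    post_value: float

    @property
    def percent_change(self) -> float:
        return percent_change(self.pre_value, self.post_value)


@dataclass
class ValidationReport:
    """Paired observed/predicted PK parameters with fold-error verdicts."""

    table: pd.DataFrame  # columns: parameter, observed, predicted, fold_error, within
    r_squared: float
    criterion: float = 1.25
    all_within: bool = field(init=False)

    def __post_init__(self) -> None:
        self.all_within = bool(self.table["within"].all())

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "r_squared": round(self.r_squared, 4),
            "all_within": self.all_within,
            "rows": self.table.to_dict(orient="records"),
        }


def build_validation_report(
    pairs: pd.DataFrame, criterion: float = 1.25
) -> ValidationReport:
    """Assemble the report from a frame with parameter/observed/predicted.

    Fold errors are rounded to two decimals (matching the presentation
    convention of the source data) before the range verdict is applied.
    """
    required = {"parameter", "observed", "predicted"}
    if not required.issubset(pairs.columns):
        raise ValueError(f"pairs must have columns {sorted(required)}")
    tab = pairs.copy()
    tab["fold_error"] = [
        round(fold_error(p, o), 2) for p, o in zip(tab["predicted"], tab["observed"])
    ]
    tab["within"] = [within_fold(fe, criterion) for fe in tab["fold_error"]]
    r2 = r_squared(tab["observed"].to_numpy(), tab["predicted"].to_numpy())
    return ValidationReport(tab, r2, criterion)
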