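"""Risk-score composition and interquartile-range scaling.

Each category's risk score is the weighted sum of its (standardized)
members, ``z_k = sum_j w_kj * x_kj``, computed in the test sample with
weights learned on the training sample.  Because the weights sum to one
the score is a weighted average of its members.  Scores are then divided
by their interquartile range so that a regression coefficient on the
scaled score reads as the change in the outcome per one-IQR increase of
the raw score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ridge import CategoryWeights


class DegenerateScoreError(ValueError):
    """Risk score has zero interquartile range; IQR scaling undefined."""


@dataclass
class RiskScoreVector:
    category: str
    raw: np.ndarray
    iqr: float

    @property
    def scaled(self) -> np.ndarray:
        return self.raw / self.iqr


def compute_risk_score(table: pd.DataFrame, weights: CategoryWeights) -> np.ndarray:
    """Raw score values: weighted sum of the member columns."""
    missing = [m for m in weights.members if m not in table.columns]
    if missing:
        raise KeyError(f"missing member columns: {missing}")
    return table[weights.members].to_numpy(float) @ weights.weights


def iqr(values: np.ndarray) -> float:
    """Interquartile range under the linear-interpolation (type 7)
    quantile convention — the one used repo-wide for all percentiles."""
    q1, q3 = np.quantile(np.asarray(values, float), [0.25, 0.75])
    return float(q3 - q1)


def iqr_scale(
    category: str, raw: np.ndarray, reference: np.ndarray | None = None
) -> RiskScoreVector:
    """Scale a raw score by its interquartile range.

    ``reference`` optionally supplies the sample on which the IQR is
    computed (defaults to the score values themselves).
    """
    raw = np.asarray(raw, float)
    ref = raw if reference is None else np.asarray(reference, float)
    if ref.size < 4:
        raise ValueError("need at least 4 values to estimate an IQR")
    width = iqr(ref)
    if width <= 0.0:
        raise DegenerateScoreError(f"risk score {category!r} has zero IQR")
    return RiskScoreVector(category=category, raw=raw, iqr=width)
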