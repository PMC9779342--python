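"""Standardization, bootstrap resampling and train/test splitting.

Predictors (except SNP allele counts) are standardized to mean zero and
unit standard deviation so that the ridge penalty treats all category
members comparably.  Standardization statistics are estimated on a
reference sample and *frozen*: applying them to any other sample uses the
reference mean and SD, never recomputed ones, which keeps training and
test transformations consistent and leakage-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StudyDesign

logger = logging.getLogger(__name__)


@dataclass
class StandardizationStats:
    """Frozen per-column location/scale estimated on a reference sample.

    Columns whose reference SD is zero (possible for rare binary
    indicators under resampling) are recorded in ``degenerate``;
    standardizing maps them to all-zeros so the downstream ridge fit can
    ignore them.
    """

    mean: dict[str, float]
    sd: dict[str, float]
    degenerate: list[str] = field(default_factory=list)

    @property
    def columns(self) -> list[str]:
        return list(self.mean)


def fit_standardization(table: pd.DataFrame, design: StudyDesign) -> StandardizationStats:
    """Estimate mean/SD (ddof=1) for every column flagged for standardization."""
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    degenerate: list[str] = []
    for v in design.variables:
        if v.role == "outcome" or not v.is_standardized:
            continue
        x = table[v.name].to_numpy(float)
        mean[v.name] = float(x.mean())
        s = float(x.std(ddof=1)) if len(x) > 1 else 0.0
        if s <= 0.0:
            degenerate.append(v.name)
            logger.debug("degenerate column %r: zero SD in reference sample", v.name)
            s = 0.0
        sd[v.name] = s
    return StandardizationStats(mean=mean, sd=sd, degenerate=degenerate)


def standardize(
    table: pd.DataFrame, design: StudyDesign, stats: StandardizationStats
) -> pd.DataFrame:
    """Apply frozen standardization statistics to a table.

    SNP columns and the outcome pass through untouched.  Degenerate
    columns (zero reference SD) become all-zeros, i.e. centered only.
    """
    out = table.copy()
    for col in stats.columns:
        x = out[col].to_numpy(float)
        if col in stats.degenerate:
            out[col] = np.zeros_like(x)
        else:
            out[col] = (x - stats.mean[col]) / stats.sd[col]
    return out


def bootstrap_resample(table: pd.DataFrame, b: int, seed: int) -> pd.DataFrame:
    """Replicate ``b`` of the bootstrap scheme.

    Replicate 0 is the original table itself; replicates ``b >= 1`` draw
    ``n`` rows with replacement, reproducibly from ``(seed, b)``.
    """
    if len(table) == 0:
        raise ValueError("cannot resample an empty table")
    if b < 0:
        raise ValueError("replicate index must be non-negative")
    if b == 0:
        return table.reset_index(drop=True)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(b, 0)))
    idx = rng.integers(0, len(table), size=len(table))
    return table.iloc[idx].reset_index(drop=True)


def split_train_test(
    table: pd.DataFrame, fraction: float, rng: np.random.Generator | int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random, unstratified partition into training and test samples.

    The training sample holds ``round(fraction * n)`` rows
    (round half away from zero); the two parts are disjoint and exhaustive.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be strictly between 0 and 1")
    n = len(table)
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n_train = int(np.floor(fraction * n + 0.5))
    if n_train == 0 or n_train == n:
        raise ValueError("split would leave an empty part")
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return (
        table.iloc[train_idx].reset_index(drop=True),
        table.iloc[test_idx].reset_index(drop=True),
    )
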