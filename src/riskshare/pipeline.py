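"""End-to-end bootstrap pipeline.

Each replicate b of B runs the full two-step method:

    resample (identity for b = 0) -> 60/40 train/test split ->
    standardize -> learn category weights on train (penalty-factor ridge,
    CV, repeat-averaged, normalized) -> risk scores + IQR scaling on test
    -> OLS + LMG decomposition on test.

Replicate 0 always analyses the original rows, so the bootstrap output
contains the original-data estimate plus B-1 resampled ones.  Replicates
are reproducible in isolation: every random draw of replicate b flows
from the master seed and b only, which also makes them parallelizable.

Degenerate replicates (zero-IQR score, rank-deficient test design) are
flagged and excluded from the summaries rather than silently poisoning
the medians; flag counts are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import AnalysisConfig, StudyDesign, validate_design
from .importance import (
    RankDeficiencyError,
    RegressorUnit,
    ReplicateFit,
    fit_linear_model,
    lmg,
)
from .preprocess import (
    bootstrap_resample,
    fit_standardization,
    split_train_test,
    standardize,
)
from .ridge import CategoryWeights, learn_category_weights
from .scores import DegenerateScoreError, compute_risk_score, iqr_scale

logger = logging.getLogger(__name__)


@dataclass
class BootstrapResult:
    replicates: list[ReplicateFit]
    weights: list[list[CategoryWeights]]
    design: StudyDesign
    config: AnalysisConfig

    @property
    def n_flagged(self) -> int:
        return sum(not r.ok for r in self.replicates)


@dataclass
class BootstrapSummary:
    """Medians, percentile CIs and bootstrap p-values over replicates.

    ``coefficients`` has one row per model column (median, lower, upper,
    p_value); ``contributions`` one row per regressor unit (median,
    lower, upper of the LMG share); ``r_squared`` summarizes the total
    explained variance.  The p-value is the sign-crossing interpretation
    of the percentile bootstrap, 2*min(frac >= 0, frac <= 0), floored at
    its minimum attainable value 2/B_effective.
    """

    coefficients: pd.DataFrame
    contributions: pd.DataFrame
    r_squared: dict[str, float]
    ci_level: float
    n_replicates: int
    n_flagged: int
    flag_counts: dict[str, int] = field(default_factory=dict)


def build_units(design: StudyDesign) -> list[RegressorUnit]:
    """Regressor units of the final model: each ungrouped single alone,
    each single group as one unit, each risk score as one unit."""
    col_group = {c: g for g, cols in design.single_groups.items() for c in cols}
    units: list[RegressorUnit] = []
    seen_groups: list[str] = []
    for s in design.singles:
        g = col_group.get(s)
        if g is None:
            units.append(RegressorUnit(s, [s]))
        elif g not in seen_groups:
            seen_groups.append(g)
            units.append(RegressorUnit(g, list(design.single_groups[g])))
    for cat in design.categories:
        units.append(RegressorUnit(cat, [cat]))
    return units


def _replicate_rng(seed: int, b: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(b, stream))
    )


def run_single_replicate(
    table: pd.DataFrame,
    design: StudyDesign,
    config: AnalysisConfig,
    b: int,
    full_stats=None,
) -> tuple[ReplicateFit, list[CategoryWeights]]:
    """Run the whole two-step analysis for one bootstrap replicate.

    ``full_stats`` carries precomputed standardization statistics when
    ``config.standardize_on == "full"``.
    """
    data = bootstrap_resample(table, b, config.seed)
    train, test = split_train_test(
        data, config.train_fraction, _replicate_rng(config.seed, b, 1)
    )
    if config.standardize_on == "full":
        stats = full_stats if full_stats is not None else fit_standardization(table, design)
    else:
        stats = fit_standardization(train, design)
    flags = [f"degenerate_column:{c}" for c in stats.degenerate]
    train_s = standardize(train, design, stats)
    test_s = standardize(test, design, stats)

    weights, wflags = learn_category_weights(
        train_s, design, config, _replicate_rng(config.seed, b, 2)
    )
    flags += wflags

    try:
        X = test_s[design.singles].copy()
        for w in weights:
            raw = compute_risk_score(test_s, w)
            if config.iqr_on == "replicate":
                ref = np.concatenate([compute_risk_score(train_s, w), raw])
            else:
                ref = None
            X[w.category] = iqr_scale(w.category, raw, reference=ref).scaled
        y = test_s[design.outcome].to_numpy(float)
        intercept, coefs, r2 = fit_linear_model(X, y)
        shares, _ = lmg(X, y, build_units(design))
    except (DegenerateScoreError, RankDeficiencyError) as e:
        flags.append(f"degenerate_replicate:{type(e).__name__}")
        logger.debug("replicate %d flagged: %s", b, e)
        fit = ReplicateFit(
            index=b, intercept=float("nan"), coefficients={},
            r_squared=float("nan"), shares={}, flags=flags, ok=False,
        )
        return fit, weights

    fit = ReplicateFit(
        index=b, intercept=intercept, coefficients=coefs,
        r_squared=r2, shares=shares, flags=flags, ok=True,
    )
    return fit, weights


def run_bootstrap(
    table: pd.DataFrame, design: StudyDesign, config: AnalysisConfig
) -> BootstrapResult:
    """Run all B replicates (replicate 0 = original data)."""
    validate_design(design, table)
    full_stats = (
        fit_standardization(table, design) if config.standardize_on == "full" else None
    )

    def one(b: int):
        return run_single_replicate(table, design, config, b, full_stats=full_stats)

    if config.n_jobs != 1:
        from joblib import Parallel, delayed

        pairs = Parallel(n_jobs=config.n_jobs)(
            delayed(one)(b) for b in range(config.n_bootstrap)
        )
    else:
        pairs = [one(b) for b in range(config.n_bootstrap)]
    fits = [p[0] for p in pairs]
    weights = [p[1] for p in pairs]
    result = BootstrapResult(replicates=fits, weights=weights, design=design, config=config)
    if result.n_flagged > config.n_bootstrap / 2:
        raise RuntimeError(
            f"{result.n_flagged} of {config.n_bootstrap} replicates degenerate; "
            "data too unstable for bootstrap summaries"
        )
    if result.n_flagged:
        logger.info("excluded %d flagged replicates from summaries", result.n_flagged)
    return result


def _pvalue(draws: np.ndarray) -> float:
    f_plus = float(np.mean(draws >= 0))
    f_minus = float(np.mean(draws <= 0))
    p = 2.0 * min(f_plus, f_minus)
    if p == 0.0:
        p = 2.0 / draws.size  # minimum attainable at this replicate count
    return min(p, 1.0)


def summarize(result: BootstrapResult, ci_level: float | None = None) -> BootstrapSummary:
    """Aggregate unflagged replicates into medians, percentile CIs and
    bootstrap p-values (linear-interpolation quantiles throughout)."""
    level = result.config.ci_level if ci_level is None else ci_level
    alpha = 1.0 - level
    ok = [r for r in result.replicates if r.ok]
    if not ok:
        raise ValueError("no unflagged replicates to summarize")

    def stats_row(vals: np.ndarray) -> tuple[float, float, float]:
        lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
        return float(np.median(vals)), float(lo), float(hi)

    coef_names = list(ok[0].coefficients)
    coef_rows = {}
    for name in coef_names:
        vals = np.array([r.coefficients[name] for r in ok])
        med, lo, hi = stats_row(vals)
        coef_rows[name] = {"median": med, "lower": lo, "upper": hi,
                           "p_value": _pvalue(vals)}
    unit_names = list(ok[0].shares)
    share_rows = {}
    for name in unit_names:
        med, lo, hi = stats_row(np.array([r.shares[name] for r in ok]))
        share_rows[name] = {"median": med, "lower": lo, "upper": hi}
    r2_med, r2_lo, r2_hi = stats_row(np.array([r.r_squared for r in ok]))

    flag_counts: dict[str, int] = {}
    for r in result.replicates:
        for f in r.flags:
            flag_counts[f.split(":")[0]] = flag_counts.get(f.split(":")[0], 0) + 1

    return BootstrapSummary(
        coefficients=pd.DataFrame.from_dict(coef_rows, orient="index"),
        contributions=pd.DataFrame.from_dict(share_rows, orient="index"),
        r_squared={"median": r2_med, "lower": r2_lo, "upper": r2_hi},
        ci_level=level,
        n_replicates=len(ok),
        n_flagged=result.n_flagged,
        flag_counts=flag_counts,
    )
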