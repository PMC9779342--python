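"""Test-sample linear model and LMG decomposition of its R².

The LMG (Lindeman–Merenda–Gold) measure attributes the coefficient of
determination of a linear model to *regressor units* — here each risk
score, each lone single predictor, and each declared dummy group as one
unit.  A unit's share is its sequential R² increment averaged over all
orderings in which units can enter the model.  That average is exactly
the Shapley value of the set function R²(S), so the production path
enumerates the 2^p unit subsets with combinatorial weights

    share(u) = sum_{T ⊆ U \\ {u}} |T|! (p-|T|-1)! / p! * [R²(T ∪ {u}) - R²(T)]

instead of the p! orderings; the literal all-orderings average is kept as
an independent test oracle (:func:`lmg_bruteforce`).  Shares are
nonnegative and sum to the full model's R².

Subset R²s are computed from one set of precomputed centered
cross-product matrices, so no pass over the raw data is needed per
subset.  Rank-deficient subsets fall back to minimum-norm solutions:
R² is a projection and remains well defined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
import scipy.linalg

logger = logging.getLogger(__name__)

MAX_UNITS_LMG = 20
MAX_UNITS_BRUTEFORCE = 7


class RankDeficiencyError(ValueError):
    """Full design matrix is rank deficient; OLS coefficients undefined."""


@dataclass
class RegressorUnit:
    """One unit of the importance decomposition (>= 1 model columns)."""

    name: str
    columns: list[str]

    def __post_init__(self) -> None:
        if not self.columns:
            raise ValueError(f"unit {self.name!r} has no columns")


@dataclass
class ReplicateFit:
    """Result of one replicate's test-sample analysis."""

    index: int
    intercept: float
    coefficients: dict[str, float]
    r_squared: float
    shares: dict[str, float]
    flags: list[str] = field(default_factory=list)
    ok: bool = True


# ---------------------------------------------------------------------------


def fit_linear_model(X: pd.DataFrame | np.ndarray, y: np.ndarray):
    """OLS with intercept; returns (intercept, coefficients, R²).

    ``coefficients`` is a dict when ``X`` is a DataFrame, else an array.
    Raises :class:`RankDeficiencyError` when the design (with intercept)
    is column-rank deficient.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = Xa.shape
    if n <= p + 1:
        raise ValueError("too few observations for the model size")
    M = np.column_stack([np.ones(n), Xa])
    beta, _, rank, _ = np.linalg.lstsq(M, y, rcond=None)
    if rank < p + 1:
        raise RankDeficiencyError(f"design matrix rank {rank} < {p + 1}")
    resid = y - M @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / tss
    coefs = dict(zip(names, beta[1:])) if names is not None else beta[1:]
    return float(beta[0]), coefs, r2


# ---------------------------------------------------------------------------
# subset-R² machinery shared by the empirical and population paths


def _r2_cache(A: np.ndarray, b: np.ndarray, tss: float, groups: list[np.ndarray]):
    """R²(S) for every subset mask of the unit list.

    ``A``/``b``/``tss`` are centered second moments (empirical
    cross-products or population covariances — the algebra is the same);
    ``groups[u]`` holds the column indices of unit u.
    """
    p = len(groups)
    r2 = np.empty(1 << p)
    r2[0] = 0.0
    warned = False
    for mask in range(1, 1 << p):
        cols = np.concatenate([groups[u] for u in range(p) if mask >> u & 1])
        As = A[np.ix_(cols, cols)]
        bs = b[cols]
        scale = float(np.linalg.norm(bs)) + 1e-300
        try:
            c, low = scipy.linalg.cho_factor(As, check_finite=False)
            sol = scipy.linalg.cho_solve((c, low), bs, check_finite=False)
            # a near-singular subset can pass the factorization with a tiny
            # pivot and return garbage: verify the solution
            if not np.all(np.isfinite(sol)) or (
                np.linalg.norm(As @ sol - bs) > 1e-8 * scale
            ):
                raise scipy.linalg.LinAlgError("ill-conditioned subset")
        except (scipy.linalg.LinAlgError, ValueError):
            if not warned:
                logger.warning("rank-deficient subset: minimum-norm fallback")
                warned = True
            sol, *_ = np.linalg.lstsq(As, bs, rcond=None)
        r2[mask] = float(bs @ sol) / tss
    return r2


def _moments(X: pd.DataFrame, y: np.ndarray, units: list[RegressorUnit]):
    cols: list[str] = []
    groups: list[np.ndarray] = []
    for u in units:
        groups.append(np.arange(len(cols), len(cols) + len(u.columns)))
        cols.extend(u.columns)
    if len(set(cols)) != len(cols):
        # duplicated columns across units are tolerated (pseudoinverse path)
        pass
    Xa = X[cols].to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(y, float)
    Xc = Xa - Xa.mean(axis=0)
    yc = y - y.mean()
    return Xc.T @ Xc, Xc.T @ yc, float(yc @ yc), groups


def lmg_from_moments(
    A: np.ndarray, b: np.ndarray, tss: float, groups: list[np.ndarray]
) -> tuple[np.ndarray, float]:
    """Shapley/LMG shares from centered second moments.

    Returns (shares per unit, full-model R²).  Works identically for
    sample cross-products and population covariance matrices.
    """
    p = len(groups)
    if p > MAX_UNITS_LMG:
        raise ValueError(f"too many units for subset enumeration ({p} > {MAX_UNITS_LMG})")
    r2 = _r2_cache(A, b, tss, groups)
    fact = [math.factorial(i) for i in range(p + 1)]
    wt = np.array([fact[t] * fact[p - t - 1] / fact[p] for t in range(p)])
    popcount = np.zeros(1 << p, dtype=int)
    for mask in range(1, 1 << p):
        popcount[mask] = popcount[mask >> 1] + (mask & 1)
    shares = np.zeros(p)
    for u in range(p):
        bit = 1 << u
        for mask in range(1 << p):
            if mask & bit:
                continue
            shares[u] += wt[popcount[mask]] * (r2[mask | bit] - r2[mask])
    return np.maximum(shares, 0.0), float(r2[-1])


def lmg(
    X: pd.DataFrame, y: np.ndarray, units: list[RegressorUnit]
) -> tuple[dict[str, float], float]:
    """LMG decomposition of the OLS R² over regressor units.

    Returns (unit name -> share, full-model R²); shares sum to R².
    """
    A, b, tss, groups = _moments(X, y, units)
    shares, r2 = lmg_from_moments(A, b, tss, groups)
    return {u.name: float(s) for u, s in zip(units, shares)}, r2


def lmg_bruteforce(
    X: pd.DataFrame, y: np.ndarray, units: list[RegressorUnit]
) -> tuple[dict[str, float], float]:
    """All-orderings average of sequential R² increments (test oracle).

    Enumerates every one of the p! unit orderings and averages each
    unit's R² increment when it enters.  Exponentially slower than
    :func:`lmg` but a literal transcription of the definition.
    """
    p = len(units)
    if p > MAX_UNITS_BRUTEFORCE:
        raise ValueError(f"too many units for ordering enumeration ({p})")
    A, b, tss, groups = _moments(X, y, units)
    r2 = _r2_cache(A, b, tss, groups)
    shares = np.zeros(p)
    for order in permutations(range(p)):
        mask = 0
        for u in order:
            new = mask | (1 << u)
            shares[u] += r2[new] - r2[mask]
            mask = new
    shares /= math.factorial(p)
    return {u.name: float(s) for u, s in zip(units, np.maximum(shares, 0.0))}, float(
        r2[-1]
    )
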