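"""Ridge regression with per-coefficient penalty factors and the
risk-score weight normalization.

Category weights are learned on the training sample by minimizing

    (1/(2n)) * sum_i (y_i - g0 - x_i' g)^2  +  lam * sum_j pf_j * g_j^2

where the penalty factor ``pf_j`` is exactly 0 for single predictors
(they stay unregularized) and exactly 1 for every category member.  The
minimizer solves the normal equations

    (Xc'Xc/n + 2*lam*diag(pf)) g = Xc'(y - ybar)/n

on column-centered data; the intercept is recovered from the means.  This
objective is the public contract of the solver — it is deliberately a
plain, closed-form ridge rather than an emulation of any particular
library's internal rescaling, so its solutions can be verified against a
generic numerical optimizer.

The penalty ``lam`` is picked per fit by k-fold cross-validation on a
descending log-spaced grid, the whole selection is repeated with fresh
fold randomizations, and the averaged coefficients of each category are
normalized into weights that sum to one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import AnalysisConfig, StudyDesign

logger = logging.getLogger(__name__)

#: coefficients with absolute value below this count as exactly zero when
#: deciding between the signed-sum normalization and the uniform fallback
ZERO_TOL = 1e-12
#: |sum(g)| < CANCEL_TOL * sum(|g|) triggers the near-cancellation guard
CANCEL_TOL = 1e-8


class NearCancellationError(ValueError):
    """Signed sum of a category's coefficients is numerically zero while
    individual coefficients are not: the weight normalization is unstable."""


@dataclass
class RidgeProblem:
    """Design matrix, response and 0/1 penalty factors for one fit."""

    X: np.ndarray
    y: np.ndarray
    penalized: np.ndarray  # boolean mask, True = regularized
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.y = np.asarray(self.y, float)
        self.penalized = np.asarray(self.penalized, bool)
        n, p = self.X.shape
        if self.y.shape != (n,) or self.penalized.shape != (p,):
            raise ValueError("inconsistent problem shapes")


@dataclass
class CategoryWeights:
    """Normalized weights of one risk-factor category.

    ``fallback`` records whether the uniform 1/m branch was used:
    None (regular signed-sum normalization), ``"all_zero"`` (every
    averaged coefficient was zero) or ``"near_cancellation"`` (the signed
    sum was numerically cancelled; see :func:`normalize_weights`).
    """

    category: str
    members: list[str]
    weights: np.ndarray
    lambdas: list[float] = field(default_factory=list)
    fallback: str | None = None


# ---------------------------------------------------------------------------
# cross-product cache


class _CrossProducts:
    """Uncentered sufficient statistics of a training design, from which
    centered normal equations of any row subset are formed in O(p^2)."""

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.X = X
        self.y = y
        self.n = X.shape[0]
        self.S = X.T @ X
        self.s = X.T @ y
        self.colsum = X.sum(axis=0)
        self.ysum = float(y.sum())

    def centered_full(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        xm = self.colsum / self.n
        ym = self.ysum / self.n
        A = self.S - self.n * np.outer(xm, xm)
        b = self.s - self.n * xm * ym
        return A, b, xm, ym

    def centered_without(self, idx: np.ndarray):
        """Centered cross-products of the sample with rows ``idx`` removed."""
        Xf = self.X[idx]
        yf = self.y[idx]
        n_tr = self.n - len(idx)
        xm = (self.colsum - Xf.sum(axis=0)) / n_tr
        ym = (self.ysum - yf.sum()) / n_tr
        A = (self.S - Xf.T @ Xf) - n_tr * np.outer(xm, xm)
        b = (self.s - Xf.T @ yf) - n_tr * xm * ym
        return A, b, xm, ym, n_tr


def _solve_path(
    A: np.ndarray, b: np.ndarray, penalized: np.ndarray, lams: np.ndarray, n: int
) -> np.ndarray:
    """Solve the centered normal equations for every lam in ``lams``.

    Columns with zero centered variance (constant in this subsample) are
    excluded from the system and receive coefficient exactly 0.  Returns
    an array of shape (p, len(lams)).
    """
    p = A.shape[0]
    diag = np.diag(A)
    keep = diag > 1e-9 * max(n, 1)
    k = int(keep.sum())
    G = np.zeros((p, len(lams)))
    if k == 0:
        return G
    Ak = A[np.ix_(keep, keep)] / n
    bk = b[keep] / n
    D = np.diag(penalized[keep].astype(float))
    M = Ak[None, :, :] + 2.0 * lams[:, None, None] * D[None, :, :]
    rhs = np.broadcast_to(bk[:, None], (len(lams), k, 1))
    sol = np.linalg.solve(M, rhs)[..., 0]
    G[keep] = sol.T
    return G


# ---------------------------------------------------------------------------
# public operations


def fit_ridge(problem: RidgeProblem, lam: float) -> tuple[float, np.ndarray]:
    """Closed-form penalty-factor ridge fit; returns (intercept, coefficients)."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    cp = _CrossProducts(problem.X, problem.y)
    A, b, xm, ym = cp.centered_full()
    G = _solve_path(A, b, problem.penalized, np.array([lam]), cp.n)
    g = G[:, 0]
    return ym - float(xm @ g), g


def lambda_grid(
    problem: RidgeProblem, n_lambda: int = 100, min_ratio: float = 1e-4
) -> np.ndarray:
    """Descending log-spaced penalty grid.

    Anchored at ``lam_max = max_j |xc_j'(y - ybar)| / n`` over penalized
    columns — the largest penalty at which any regularized coefficient is
    still visibly shrunk under this objective — down to
    ``lam_max * min_ratio``.  A response empirically orthogonal to all
    penalized columns yields a tiny but still positive grid.
    """
    if not problem.penalized.any():
        raise ValueError("no penalized predictors")
    cp = _CrossProducts(problem.X, problem.y)
    A, b, _, _ = cp.centered_full()
    diag = np.diag(A)[problem.penalized]
    if np.all(diag <= 1e-9 * max(cp.n, 1)):
        raise ValueError("all penalized predictors are constant")
    lam_max = float(np.max(np.abs(b[problem.penalized]))) / cp.n
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def cv_select_lambda(
    problem: RidgeProblem,
    folds: int,
    grid: np.ndarray,
    rng: np.random.Generator | int,
) -> float:
    """Pick the penalty minimizing mean out-of-fold squared error.

    Folds are a random permutation cut into ``folds`` near-equal parts.
    Ties resolve to the largest (first) penalty of the descending grid.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    cp = _CrossProducts(problem.X, problem.y)
    lam, _ = _cv_select(cp, problem.penalized, folds, np.asarray(grid, float), rng)
    return lam


def _cv_select(
    cp: _CrossProducts,
    penalized: np.ndarray,
    folds: int,
    grid: np.ndarray,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray]:
    n = cp.n
    if n < folds:
        raise ValueError("more folds than observations")
    if n // folds < 2:
        raise ValueError("a fold would contain fewer than 2 observations")
    perm = rng.permutation(n)
    errs = np.empty((folds, len(grid)))
    for f, idx in enumerate(np.array_split(perm, folds)):
        A, b, xm, ym, n_tr = cp.centered_without(idx)
        G = _solve_path(A, b, penalized, grid, n_tr)
        resid = (cp.y[idx] - ym)[:, None] - (cp.X[idx] - xm) @ G
        errs[f] = np.mean(resid**2, axis=0)
    mean_err = errs.mean(axis=0)
    return float(grid[int(np.argmin(mean_err))]), mean_err


def normalize_weights(gamma: np.ndarray) -> tuple[np.ndarray, str | None]:
    """Turn a category's averaged ridge coefficients into weights.

    If every coefficient is (numerically) zero, all members get the
    uniform weight 1/m.  Otherwise the weights are the coefficients
    divided by their signed sum, which makes them sum to one by
    construction; with sign-mixed coefficients individual weights can
    fall outside [-1, 1].  A signed sum that nearly cancels while the
    coefficients do not (|sum| < 1e-8 * sum|g|) would blow the weights
    up, so that case raises :class:`NearCancellationError` for the caller
    to fall back on.
    """
    gamma = np.asarray(gamma, float)
    m = gamma.size
    if m < 1:
        raise ValueError("empty category")
    if np.all(np.abs(gamma) <= ZERO_TOL):
        return np.full(m, 1.0 / m), "all_zero"
    total = float(gamma.sum())
    if abs(total) < CANCEL_TOL * float(np.abs(gamma).sum()):
        raise NearCancellationError(
            "signed sum of coefficients cancels; weights undefined"
        )
    return gamma / total, None


def learn_category_weights(
    train: pd.DataFrame,
    design: StudyDesign,
    config: AnalysisConfig,
    rng: np.random.Generator | int,
) -> tuple[list[CategoryWeights], list[str]]:
    """Learn normalized weights for every category on a (standardized)
    training sample.

    Runs ``config.cv_repeats`` rounds of cross-validated penalty choice
    plus a full-sample refit, averages the coefficient vectors
    elementwise, then normalizes each category's slice.  Near-cancelled
    categories fall back to uniform weights and are flagged.

    Returns (weights per category, flags).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    singles = design.singles
    cats = design.categories
    member_cols = [c for members in cats.values() for c in members]
    cols = singles + member_cols
    X = train[cols].to_numpy(float)
    y = train[design.outcome].to_numpy(float)
    penalized = np.array([False] * len(singles) + [True] * len(member_cols))
    problem = RidgeProblem(X, y, penalized, names=cols)
    grid = lambda_grid(problem, config.n_lambda, config.lambda_min_ratio)

    cp = _CrossProducts(X, y)
    A_full, b_full, _, _ = cp.centered_full()
    gammas = np.empty((config.cv_repeats, len(cols)))
    lambdas: list[float] = []
    for r in range(config.cv_repeats):
        lam, _ = _cv_select(cp, penalized, config.cv_folds, grid, rng)
        gammas[r] = _solve_path(A_full, b_full, penalized, np.array([lam]), cp.n)[:, 0]
        lambdas.append(lam)
    gamma_bar = gammas.mean(axis=0)

    flags: list[str] = []
    out: list[CategoryWeights] = []
    offset = len(singles)
    for cat, members in cats.items():
        m = len(members)
        sl = gamma_bar[offset : offset + m]
        offset += m
        try:
            w, fb = normalize_weights(sl)
        except NearCancellationError:
            w, fb = np.full(m, 1.0 / m), "near_cancellation"
            flags.append(f"near_cancellation:{cat}")
            logger.debug("category %r: near-cancelled signed sum, uniform fallback", cat)
        out.append(
            CategoryWeights(category=cat, members=list(members), weights=w,
                            lambdas=lambdas, fallback=fb)
        )
    return out, flags
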