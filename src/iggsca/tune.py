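"""Penalty selection by K-fold cross-validation.

The CV loss is the held-out residual sum of squares of the combined model
(measurement plus structural residual blocks), computed with the
training-fold parameters.  Held-out rows are standardized with the
training fold's centering and scaling, and interaction scores use the
training fold's rescaling factors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset, standardize
from .estimation import PenaltyConfig, WorkData, compute_scores, fit
from .model import ModelSpec, pattern_matrices

logger = logging.getLogger("iggsca")

__all__ = ["CVPlan", "default_grid", "make_folds", "select_lambda", "holdout_error"]


def default_grid(n: int = 30) -> np.ndarray:
    """0 plus ``n`` logarithmically spaced penalty values on 1e-2 … 1e4."""
    return np.concatenate([[0.0], np.logspace(-2, 4, n)])


@dataclass(frozen=True)
class CVPlan:
    """Fold count, candidate penalty grid and fold-assignment seed."""

    K: int = 5
    grid: tuple = field(default_factory=lambda: tuple(default_grid()))
    seed: int = 0

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("K must be at least 2")
        g = np.asarray(self.grid, float)
        if g.size == 0:
            raise ValueError("empty penalty grid")
        if (g < 0).any():
            raise ValueError("penalty grid must be non-negative")
        if not np.all(np.diff(g) > 0):
            raise ValueError("penalty grid must be strictly increasing")


def make_folds(N: int, K: int, seed: int) -> list:
    """Seeded partition into K held-out folds with sizes differing by <= 1."""
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(N), K)


def holdout_error(params, Z_holdout: np.ndarray) -> float:
    """Combined-model residual SS of new standardized rows at fixed params."""
    G = compute_scores(params, Z_holdout, use_stored_scales=True).to_numpy()
    spec = params.spec
    meas = Z_holdout - G @ params.C.T
    dep_ix = [spec.index(d) for d in spec.dependent()]
    struct = G[:, dep_ix] - G @ params.B[dep_ix].T
    return float(np.sum(meas * meas) + np.sum(struct * struct))


def select_lambda(
    dataset: Dataset | pd.DataFrame,
    spec: ModelSpec,
    tau: int = 2,
    plan: CVPlan = CVPlan(),
    **fit_kwargs,
) -> tuple[float, pd.DataFrame]:
    """Choose the penalty minimizing total held-out error over seeded folds.

    Returns ``(lambda_star, table)`` where the table has one row per grid
    value with per-fold errors and their total.  Grid values are visited in
    increasing order with warm-started refits; exact ties in total error
    resolve to the smaller penalty.  A fold fit that fails to converge has
    its cell excluded (NaN) and is logged.
    """
    if isinstance(dataset, pd.DataFrame):
        dataset = Dataset.from_dataframe(dataset)
    N = dataset.N
    if N < 2 * plan.K:
        raise ValueError(f"need at least {2 * plan.K} observations for {plan.K} folds")
    grid = np.asarray(plan.grid, float)
    folds = make_folds(N, plan.K, plan.seed)
    errors = np.full((grid.size, plan.K), np.nan)
    X = dataset.values
    for k, ho_idx in enumerate(folds):
        tr_idx = np.setdiff1d(np.arange(N), ho_idx)
        train = Dataset(X[tr_idx], dataset.column_names)
        if train.N < dataset.J:
            warnings.warn(
                f"fold {k}: training rows ({train.N}) fewer than observed variables "
                f"({dataset.J})",
                RuntimeWarning,
            )
        train_std = standardize(train)
        Z_ho = train_std.transform_rows(X[ho_idx])
        # precompute (and possibly compress) once per fold; every penalty
        # value reuses the same working rows and Gram blocks
        cols = pattern_matrices(spec, train_std.column_names).columns
        wd = WorkData.build(train_std, spec, cols)
        start = None
        for i, lam in enumerate(grid):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = fit(
                    train_std,
                    spec,
                    PenaltyConfig(lam, tau),
                    start=start,
                    sign_convention=False,
                    finalize=False,
                    _work_data=wd,
                    **fit_kwargs,
                )
            start = res.params
            if not res.converged:
                logger.warning("fold %d, lambda=%g: fit did not converge; excluded", k, lam)
                continue
            errors[i, k] = holdout_error(res.params, Z_ho)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        totals = np.nansum(errors, axis=1)
        totals[np.all(np.isnan(errors), axis=1)] = np.inf
    best = int(np.argmin(totals))
    table = pd.DataFrame(
        errors, index=pd.Index(grid, name="lambda"),
        columns=[f"fold_{k}" for k in range(plan.K)],
    )
    table["total"] = totals
    return float(grid[best]), table
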