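"""Replicated parameter-recovery study: bias, SD and RMSE by parameter group.

For each sample size, ``reps`` datasets are drawn from a design, each is fit
with ridge (or lasso) regularization and a cross-validated penalty, the
solution is sign-aligned to the generating values, and per-parameter
finite-sample properties are aggregated:

* bias  = mean(estimate) - truth            (signed)
* SD    = std of estimates across replicates (divisor reps - 1)
* RMSE  = sqrt(mean((estimate - truth)^2))

Group cells average the per-parameter values, so the per-parameter
inequality RMSE >= |bias| holds before averaging.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import PenaltyConfig, align_signs, fit
from .simulate import SimulationDesign, simulate_dataset, true_parameter_set
from .tune import CVPlan, select_lambda

logger = logging.getLogger("iggsca")

__all__ = [
    "RecoveryTable",
    "recovery_metrics",
    "run_recovery_study",
    "study_parameter_groups",
    "COARSE_GRID",
]

# coarse log-spaced candidate penalties used by the recovery study
COARSE_GRID = (0.0, 1.0, 10.0, 100.0, 1000.0)


@dataclass
class RecoveryTable:
    """Group-level summary plus per-parameter detail across sample sizes."""

    table: pd.DataFrame   # index (N, group): bias, sd, rmse, n_params
    detail: pd.DataFrame  # long: N, parameter, group, truth, bias, sd, rmse
    reps: int
    excluded: dict        # N -> non-convergent replicate count
    runs: pd.DataFrame    # per replicate: N, rep, lambda, iterations

    def cell(self, N: int, group: str, column: str) -> float:
        return float(self.table.loc[(N, group), column])


def recovery_metrics(
    estimates: pd.DataFrame, truth: pd.Series, groups: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate replicate estimates into group and per-parameter tables.

    ``estimates`` has one row per replicate and one column per parameter;
    NaN cells (missing replicate estimates) are excluded per parameter.
    """
    rows = []
    for name in estimates.columns:
        e = estimates[name].dropna().to_numpy()
        t = float(truth[name])
        if e.size == 0:
            logger.warning("parameter %s has no replicate estimates", name)
            continue
        bias = float(e.mean() - t)
        sd = float(e.std(ddof=1)) if e.size > 1 else 0.0
        rmse = float(np.sqrt(np.mean((e - t) ** 2)))
        rows.append((name, groups[name], t, bias, sd, rmse, e.size))
    detail = pd.DataFrame(
        rows, columns=["parameter", "group", "truth", "bias", "sd", "rmse", "n_reps"]
    )
    table = (
        detail.groupby("group")[["bias", "sd", "rmse"]]
        .mean()
        .join(detail.groupby("group").size().rename("n_params"))
    )
    return table, detail


def study_parameter_groups(
    design: SimulationDesign, labels: list
) -> pd.Series:
    """Map free-parameter labels of the study preset to summary groups."""
    genes = set(design.meta.get("genes", []))
    rois = set(design.meta.get("rois", []))
    env = design.meta.get("env", "env")
    outcome = design.meta.get("outcome", "outcome")
    spec = design.spec
    B = design.true_B
    out = {}
    for lab in labels:
        block, a, b = lab
        key = f"{block}|{a}|{b}"
        if block == "weight":
            continue
        if block == "loading":
            if a in genes:
                out[key] = "loadings (genes)"
            elif a in rois:
                out[key] = "loadings (ROIs)"
            else:
                out[key] = "loadings (other)"
            continue
        zero = B[spec.index(b), spec.index(a)] == 0.0
        suff = "zero" if zero else "nonzero"
        if b in rois and (a in genes or a == env):
            out[key] = f"gene/env -> ROI ({suff})"
        elif b in rois and " x " in a:
            out[key] = f"GxE -> ROI ({suff})"
        elif b == outcome and a in rois:
            out[key] = f"ROI -> outcome ({suff})"
        elif b == outcome and a == env:
            out[key] = f"env -> outcome ({suff})"
        else:
            out[key] = f"other paths ({suff})"
    return pd.Series(out)


def run_recovery_study(
    design: SimulationDesign,
    N_list=(250, 500, 1000, 2000),
    reps: int = 200,
    tau: int = 2,
    cv_plan: CVPlan | None = None,
    seed: int = 0,
    groups: pd.Series | None = None,
    tol: float = 1e-5,
    max_iter: int = 300,
    progress: bool = False,
) -> RecoveryTable:
    """Run the replicated study and summarize recovery per group and N.

    Each replicate draws a dataset, selects the penalty by K-fold CV
    (5 folds on a coarse grid by default), refits on the full replicate,
    aligns signs to the generating values, and contributes its free loading
    and path estimates.  Non-convergent replicates are excluded and counted.
    """
    if reps < 2:
        raise ValueError("reps must be at least 2")
    if cv_plan is None:
        cv_plan = CVPlan(K=5, grid=COARSE_GRID, seed=0)
    spec = design.spec
    truth_ps = true_parameter_set(design)
    labels = truth_ps.free_labels()
    keys = [f"{b}|{x}|{y}" for b, x, y in labels]
    truth = pd.Series(truth_ps.free_values(), index=keys)
    if groups is None:
        groups = study_parameter_groups(design, labels)
    keep = [k for k in keys if k in groups.index]

    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, size=(len(N_list), reps, 3))

    blocks, details, run_rows = [], [], []
    excluded = {}
    for iN, N in enumerate(N_list):
        est_rows = []
        n_bad = 0
        for rep in range(reps):
            s_data, s_init, s_cv = (int(s) for s in seeds[iN, rep])
            ds, _ = simulate_dataset(design, N, seed=s_data)
            plan = CVPlan(K=cv_plan.K, grid=cv_plan.grid, seed=s_cv)
            lam, _ = select_lambda(
                ds, spec, tau=tau, plan=plan,
                init_seed=s_init, tol=tol, max_iter=max_iter,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = fit(
                    ds, spec, PenaltyConfig(lam, tau),
                    init_seed=s_init, tol=tol, max_iter=max_iter,
                )
            run_rows.append((N, rep, lam, res.iterations, res.converged))
            if not res.converged:
                n_bad += 1
                est_rows.append(np.full(len(keys), np.nan))
                continue
            aligned = align_signs(res.params, truth_ps)
            est_rows.append(aligned.free_values())
            if progress and (rep + 1) % 25 == 0:
                logger.info("N=%d: %d/%d replicates done", N, rep + 1, reps)
        excluded[N] = n_bad
        if n_bad:
            logger.warning("N=%d: %d/%d replicates non-convergent", N, n_bad, reps)
        est = pd.DataFrame(est_rows, columns=keys)[keep]
        table, detail = recovery_metrics(est, truth[keep], groups)
        table["N"] = N
        detail["N"] = N
        blocks.append(table)
        details.append(detail)
    table = pd.concat(blocks).set_index("N", append=True).swaplevel()
    detail = pd.concat(details, ignore_index=True)
    runs = pd.DataFrame(
        run_rows, columns=["N", "rep", "lambda", "iterations", "converged"]
    )
    return RecoveryTable(table=table, detail=detail, reps=reps,
                         excluded=excluded, runs=runs)
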