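"""Bootstrap inference, conditional (simple-slope) effects and indirect effects.

Standard errors and 95% intervals come from a nonparametric bootstrap:
rows are resampled with replacement, the model is refit with the same
penalty, signs are aligned to the full-sample solution, and the empirical
2.5/97.5 percentiles of each parameter's resample distribution form its
interval.  The penalty value is *not* re-selected inside resamples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset
from .estimation import FitResult, PenaltyConfig, align_signs, fit
from .model import ModelSpec

logger = logging.getLogger("iggsca")

__all__ = [
    "BootstrapResult",
    "bootstrap",
    "conditional_effect",
    "indirect_effect",
    "IndirectEffect",
]


@dataclass
class BootstrapResult:
    """Per-parameter bootstrap summary plus the raw resample draws.

    ``table`` is laid out like a reporting-ready weights/loadings/paths
    table: one row per parameter with estimate, SE, percentile CI bounds and
    a significance flag (CI excludes 0).  Fixed single-indicator weights and
    loadings appear with estimate 1.00 and SE 0.00.  ``draws`` holds the
    sign-aligned free-parameter vectors of the convergent resamples (order
    given by ``labels``); ``scale_draws`` the interaction rescaling factors.
    """

    table: pd.DataFrame
    labels: list
    draws: np.ndarray
    scale_draws: np.ndarray
    B: int
    B_effective: int
    seed: int
    penalty: PenaltyConfig

    def index_of(self, block: str, component: str, name: str) -> int:
        try:
            return self.labels.index((block, component, name))
        except ValueError:
            raise KeyError(f"no free parameter ({block}, {component}, {name})")

    def draws_for(self, block: str, component: str, name: str) -> np.ndarray:
        return self.draws[:, self.index_of(block, component, name)]


def _percentile_ci(draws: np.ndarray, level: float = 95.0) -> tuple:
    lo = (100.0 - level) / 2.0
    return (
        np.percentile(draws, lo, axis=0),
        np.percentile(draws, 100.0 - lo, axis=0),
    )


def bootstrap(
    dataset: Dataset | pd.DataFrame,
    spec: ModelSpec,
    penalty: PenaltyConfig,
    B: int = 500,
    seed: int = 0,
    fit_result: FitResult | None = None,
    ci_level: float = 95.0,
    **fit_kwargs,
) -> BootstrapResult:
    """Seeded bootstrap of all free parameters at a fixed penalty.

    Resamples whose standardization degenerates (a zero-variance column) are
    redrawn; refits that do not converge are dropped from the effective
    count, with a warning when fewer than 90% survive.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    if isinstance(dataset, pd.DataFrame):
        dataset = Dataset.from_dataframe(dataset)
    if fit_result is None:
        fit_result = fit(dataset, spec, penalty, **fit_kwargs)
    full = fit_result.params
    labels = full.free_labels()
    rng = np.random.default_rng(seed)
    N = dataset.N
    X = dataset.values
    rows, scale_rows = [], []
    n_dropped = 0
    for _ in range(B):
        for _try in range(1000):
            idx = rng.integers(0, N, size=N)
            sub = X[idx]
            if (sub.std(axis=0) > 0).all():
                break
            logger.info("resample with a zero-variance column redrawn")
        else:
            raise RuntimeError("could not draw a non-degenerate resample")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = fit(
                Dataset(sub, dataset.column_names),
                spec,
                penalty,
                start=full,
                sign_convention=False,
                **fit_kwargs,
            )
        if not res.converged:
            n_dropped += 1
            continue
        aligned = align_signs(res.params, full)
        rows.append(aligned.free_values())
        scale_rows.append(aligned.interaction_scales.copy())
    B_eff = len(rows)
    if B_eff < 2:
        raise RuntimeError("fewer than two convergent bootstrap resamples")
    if B_eff < 0.9 * B:
        warnings.warn(
            f"only {B_eff}/{B} bootstrap resamples converged", RuntimeWarning
        )
    draws = np.array(rows)
    scale_draws = np.array(scale_rows)
    se = draws.std(axis=0, ddof=1)
    lo, hi = _percentile_ci(draws, ci_level)
    est = full.free_values()
    free_ix = {lab: i for i, lab in enumerate(labels)}

    def row(block, comp, name):
        lab = (block, comp, name)
        if lab in free_ix:
            i = free_ix[lab]
            return (block, comp, name, est[i], se[i], lo[i], hi[i],
                    not (lo[i] <= 0.0 <= hi[i]))
        # fixed single-indicator entry
        return (block, comp, name, 1.0, 0.0, 1.0, 1.0, True)

    records = []
    for comp in spec.components:
        for ind in comp.indicators:
            records.append(row("weight", comp.name, ind))
    for comp in spec.components:
        for ind in comp.indicators:
            records.append(row("loading", comp.name, ind))
    for src, tgt in spec.paths:
        records.append(row("path", src, tgt))
    table = pd.DataFrame(
        records,
        columns=["block", "component", "name", "estimate", "se",
                 "ci_low", "ci_high", "significant"],
    )
    return BootstrapResult(
        table=table,
        labels=labels,
        draws=draws,
        scale_draws=scale_draws,
        B=B,
        B_effective=B_eff,
        seed=seed,
        penalty=penalty,
    )


def _find_interaction(spec: ModelSpec, predictor: str, moderator: str) -> int:
    for m, it in enumerate(spec.interactions):
        if {it.first, it.second} == {predictor, moderator}:
            return m
    raise ValueError(
        f"model declares no interaction between {predictor!r} and {moderator!r}"
    )


def conditional_effect(
    fit_result: FitResult,
    predictor: str,
    moderator: str,
    target: str,
    moderator_levels,
    boot: BootstrapResult | None = None,
    levels_are_standardized: bool = False,
) -> pd.DataFrame:
    """Simple slopes of ``predictor`` on ``target`` at fixed moderator levels.

    The slope at moderator level m is ``b_main + b_int * s_int * s(m)``,
    where ``b_main`` is the predictor→target path, ``b_int`` the
    (predictor×moderator)→target path, ``s_int`` the interaction's
    unit-variance rescaling factor and ``s(m)`` the moderator's standardized
    score at raw level m.  With ``boot`` given, slope draws combine each
    resample's coefficients with its own rescaling factor (levels keep the
    full-sample standardization).
    """
    spec = fit_result.params.spec
    params = fit_result.params
    if not spec.has_path(predictor, target):
        raise ValueError(f"no free path {predictor!r} -> {target!r} in the model")
    m = _find_interaction(spec, predictor, moderator)
    int_name = spec.interactions[m].name
    if not spec.has_path(int_name, target):
        raise ValueError(f"no free path {int_name!r} -> {target!r} in the model")
    t = spec.index(target)
    b_main = params.B[t, spec.index(predictor)]
    b_int = params.B[t, spec.index(int_name)]
    s_int = params.interaction_scales[m]

    mod_comp = spec.component(moderator)
    levels = np.asarray(moderator_levels, float)
    if levels_are_standardized or not mod_comp.is_single:
        std_levels = levels
    else:
        j = params.columns.index(mod_comp.indicators[0])
        std_levels = (levels - fit_result.center[j]) / fit_result.scale[j]

    slopes = b_main + b_int * s_int * std_levels
    out = pd.DataFrame(
        {"level": levels, "level_std": std_levels, "slope": slopes}
    )
    if boot is not None:
        d_main = boot.draws_for("path", predictor, target)
        d_int = boot.draws_for("path", int_name, target)
        d_scale = boot.scale_draws[:, m]
        slope_draws = d_main[:, None] + (d_int * d_scale)[:, None] * std_levels[None, :]
        lo, hi = _percentile_ci(slope_draws)
        out["se"] = slope_draws.std(axis=0, ddof=1)
        out["ci_low"] = lo
        out["ci_high"] = hi
        out["significant"] = ~((lo <= 0.0) & (0.0 <= hi))
    return out


@dataclass(frozen=True)
class IndirectEffect:
    chain: tuple
    estimate: float
    se: float = None
    ci_low: float = None
    ci_high: float = None
    significant: bool = None


def indirect_effect(
    fit_result: FitResult,
    path_chain,
    boot: BootstrapResult | None = None,
) -> IndirectEffect:
    """Product-of-coefficients effect along a mediation chain.

    ``path_chain`` names components in order, e.g. ``("gene", "roi",
    "depression")``; every consecutive pair must be a free path.  The
    bootstrap interval, if requested, is the percentile interval of the
    elementwise product of the chained coefficient draws.
    """
    spec = fit_result.params.spec
    chain = tuple(path_chain)
    if len(chain) < 2:
        raise ValueError("path chain needs at least two components")
    links = list(zip(chain[:-1], chain[1:]))
    for src, tgt in links:
        if not spec.has_path(src, tgt):
            raise ValueError(f"missing link: no free path {src!r} -> {tgt!r}")
    B = fit_result.params.B
    est = float(np.prod([B[spec.index(t), spec.index(s)] for s, t in links]))
    if boot is None:
        return IndirectEffect(chain, est)
    prod = np.ones(boot.draws.shape[0])
    for src, tgt in links:
        prod = prod * boot.draws_for("path", src, tgt)
    lo, hi = _percentile_ci(prod)
    return IndirectEffect(
        chain, est,
        se=float(prod.std(ddof=1)),
        ci_low=float(lo), ci_high=float(hi),
        significant=not (lo <= 0.0 <= hi),
    )
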