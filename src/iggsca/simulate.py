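"""Synthetic data with the covariance structure the composite model assumes.

The generator draws exogenous component scores as independent standard
normals, forms interaction scores as rescaled products of exogenous
parents, builds endogenous scores recursively from the structural
coefficients with residual variances chosen so every score has population
variance 1, and emits indicators as

    z_j = c * gamma + (eta_j - mean(eta_block)),   sd(eta) chosen so that
                                                   var(z_j) = 1

i.e. measurement residuals have sd sqrt(1 - c^2) per indicator but sum to
zero within each block.  The block-centering makes the composite model hold
*exactly* in population — the component equals a weighted sum of its own
indicators — so weights, loadings and paths are all consistently estimable,
which is what a parameter-recovery study requires.  (With independent
residuals the composite would only approximate a common factor and loading
estimates would converge to attenuated/inflated values, not to the
generating ones.)

``study_design`` builds the study preset: nine gene components carrying one,
two or four SNP indicators (21 SNPs), sixty ROI components with two
indicators each, one single-indicator environment variable, one
single-indicator outcome, and nine gene-by-environment interactions; genes,
environment and interactions point at every ROI, ROIs and environment at
the outcome, with a seeded subset of path coefficients set to exactly zero.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset
from .model import ModelSpec, ParameterSet, build_model, pattern_matrices

__all__ = [
    "SimulationDesign",
    "study_design",
    "simulate_dataset",
    "implied_score_cov",
    "true_parameter_set",
]


@dataclass
class SimulationDesign:
    """A model spec plus the generating parameter values.

    ``true_C``/``true_B`` hold loadings and path coefficients in spec
    order (declared free paths with value 0 encode the null arrows of the
    design; they are still estimated when the model is fit).  True weights
    follow from the equal-loading blocks: w_j = 1/(k c) for a k-indicator
    block with loading c.  ``snp_freqs`` optionally maps indicator columns
    to genotype frequencies for discretization to codes {1, 2, 3}.
    """

    spec: ModelSpec
    true_C: np.ndarray
    true_B: np.ndarray
    snp_freqs: dict | None = None
    meta: dict = field(default_factory=dict)

    def zero_paths(self) -> list:
        """Declared (free) paths whose generating coefficient is zero."""
        out = []
        for src, tgt in self.spec.paths:
            if self.true_B[self.spec.index(tgt), self.spec.index(src)] == 0.0:
                out.append((src, tgt))
        return out

    def measurement_residual_sd(self) -> pd.Series:
        """Per indicator: sqrt(1 - loading^2)."""
        spec = self.spec
        vals, names = [], []
        for p, comp in enumerate(spec.components):
            for ind in comp.indicators:
                j = spec.observed.index(ind)
                vals.append(float(np.sqrt(max(0.0, 1.0 - self.true_C[j, p] ** 2))))
                names.append(ind)
        return pd.Series(vals, index=names)


def true_parameter_set(design: SimulationDesign) -> ParameterSet:
    """The generating values arranged as a ParameterSet (for alignment/truth)."""
    ps = pattern_matrices(design.spec)
    ps.C = design.true_C.copy()
    ps.B = design.true_B.copy()
    for p, comp in enumerate(design.spec.components):
        if comp.is_single:
            continue
        k = len(comp.indicators)
        j0 = design.spec.observed.index(comp.indicators[0])
        c = design.true_C[j0, p]
        cols = [ps.columns.index(i) for i in comp.indicators]
        ps.W[p, cols] = 1.0 / (k * c)
    return ps


def study_design(
    loading_value: float = 0.8,
    path_value: float = 0.3,
    seed: int = 0,
    sparsity: float = 0.5,
    snp_alloc: tuple = (1, 1, 1, 2, 2, 2, 4, 4, 4),
    n_roi: int = 60,
    roi_indicators: int = 2,
    outcome_nonzero_rois: int = 3,
    snp_freqs: tuple | None = None,
) -> SimulationDesign:
    """The recovery-study preset: genes, ROIs, environment, outcome, G×E.

    ``sparsity`` is the fraction of each ROI equation's declared incoming
    paths whose generating value is zero, drawn by ``seed``.  The outcome
    equation instead receives ``outcome_nonzero_rois`` nonzero ROI paths
    (plus the environment path): with sixty mutually correlated ROIs, half
    of them carrying coefficient 0.3 would imply an outcome variance far
    above 1, so the outcome stays at the handful of nonzero effects the
    method is meant to detect.  ``sparsity=0`` makes every declared path
    nonzero (the resulting design may then be infeasible to simulate).
    """
    if not (0.0 < loading_value <= 1.0):
        raise ValueError("loading_value must be in (0, 1]")
    if not (0.0 <= sparsity <= 1.0):
        raise ValueError("sparsity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i+1}" for i in range(len(snp_alloc))]
    comps = []
    for g, k in zip(genes, snp_alloc):
        comps.append((g, [f"{g}_snp{j+1}" for j in range(k)]))
    rois = [f"roi{r+1}" for r in range(n_roi)]
    for r in rois:
        comps.append((r, [f"{r}_x{j+1}" for j in range(roi_indicators)]))
    comps.append(("env", ["env"]))
    comps.append(("outcome", ["outcome"]))
    inters = [(g, "env") for g in genes]
    inter_names = [f"{g} x env" for g in genes]
    paths = []
    for r in rois:
        for g in genes:
            paths.append((g, r))
        paths.append(("env", r))
        for i in inter_names:
            paths.append((i, r))
    for r in rois:
        paths.append((r, "outcome"))
    paths.append(("env", "outcome"))
    spec = build_model(comps, inters, paths)

    J, P = spec.J, spec.P
    C = np.zeros((J, P))
    for p, comp in enumerate(spec.components):
        for ind in comp.indicators:
            j = spec.observed.index(ind)
            C[j, p] = 1.0 if comp.is_single else loading_value
    B = np.zeros((P, P))
    # ROI equations: balanced per-equation zero subsets
    for r in rois:
        t = spec.index(r)
        preds = [spec.index(s) for s in spec.predictors_of(r)]
        n_zero = int(round(len(preds) * sparsity))
        zero_ix = rng.choice(len(preds), size=n_zero, replace=False)
        vals = np.full(len(preds), path_value)
        vals[zero_ix] = 0.0
        B[t, preds] = vals
    # outcome equation
    t = spec.index("outcome")
    if sparsity == 0.0:
        nz = list(range(n_roi))
    else:
        nz = rng.choice(n_roi, size=min(outcome_nonzero_rois, n_roi), replace=False)
    for i in nz:
        B[t, spec.index(rois[i])] = path_value
    B[t, spec.index("env")] = path_value

    freqs = None
    if snp_freqs is not None:
        freqs = {f"{g}_snp{j+1}": tuple(snp_freqs)
                 for g, k in zip(genes, snp_alloc) for j in range(k)}
    return SimulationDesign(
        spec, C, B, snp_freqs=freqs,
        meta={"genes": genes, "rois": rois, "env": "env", "outcome": "outcome"},
    )


def _component_order(spec: ModelSpec) -> list:
    """Topological order of base components; raises on structural cycles."""
    ts = graphlib.TopologicalSorter()
    inter = {it.name for it in spec.interactions}
    for comp in spec.components:
        ts.add(comp.name)
    for src, tgt in spec.paths:
        if src not in inter:
            ts.add(tgt, src)
        else:
            it = next(i for i in spec.interactions if i.name == src)
            ts.add(tgt, it.first, it.second)
    try:
        return list(ts.static_order())
    except graphlib.CycleError as exc:
        raise ValueError(f"cyclic structural graph; cannot simulate: {exc}") from exc


def implied_score_cov(design: SimulationDesign) -> pd.DataFrame:
    """Population covariance of all component scores under the design."""
    spec = design.spec
    P = spec.P
    names = list(spec.names)
    n0 = spec.n_components
    targets = {t for _, t in spec.paths}
    exog = [c.name for c in spec.components if c.name not in targets]
    endo_order = [n for n in _component_order(spec) if n in targets]
    Sigma = np.zeros((P, P))
    for name in exog:
        Sigma[spec.index(name), spec.index(name)] = 1.0
    exog_set = set(exog)
    # interactions: products of exogenous parents (jointly normal)
    for m, it in enumerate(spec.interactions):
        if it.first not in exog_set or it.second not in exog_set:
            raise ValueError(
                f"interaction {it.name!r}: generation requires exogenous parents"
            )
    for m, it in enumerate(spec.interactions):
        a, b = spec.index(it.first), spec.index(it.second)
        i = n0 + m
        var_raw = 1.0 + Sigma[a, b] ** 2
        Sigma[i, i] = 1.0
        for m2 in range(m):
            it2 = spec.interactions[m2]
            a2, b2 = spec.index(it2.first), spec.index(it2.second)
            var_raw2 = 1.0 + Sigma[a2, b2] ** 2
            cov = (Sigma[a, a2] * Sigma[b, b2] + Sigma[a, b2] * Sigma[b, a2])
            cov /= np.sqrt(var_raw * var_raw2)
            Sigma[i, n0 + m2] = Sigma[n0 + m2, i] = cov
    for name in endo_order:
        t = spec.index(name)
        brow = design.true_B[t]
        cov_t = Sigma @ brow
        var_pred = float(brow @ cov_t)
        if var_pred >= 1.0:
            raise ValueError(
                f"implied explained variance of {name!r} is {var_pred:.3f} >= 1; "
                "reduce path magnitudes or sparsify"
            )
        Sigma[t, :] = cov_t
        Sigma[:, t] = cov_t
        Sigma[t, t] = 1.0
    return pd.DataFrame(Sigma, index=names, columns=names)


def simulate_dataset(
    design: SimulationDesign, N: int, seed: int = 0
) -> tuple[Dataset, pd.DataFrame]:
    """Draw N observations; returns ``(dataset, true component scores)``.

    Exogenous scores are iid standard normal; interaction scores are
    products of exogenous parents divided by their population sd; endogenous
    scores follow the structural equations with residual sd chosen so every
    population variance is 1.  Raises on cyclic structural graphs or when a
    dependent equation's implied explained variance reaches 1.
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    spec = design.spec
    Sigma = implied_score_cov(design).to_numpy()  # also validates feasibility
    rng = np.random.default_rng(seed)
    n0 = spec.n_components
    targets = {t for _, t in spec.paths}
    G = np.zeros((N, spec.P))
    for comp in spec.components:
        if comp.name not in targets:
            G[:, spec.index(comp.name)] = rng.standard_normal(N)
    for m, it in enumerate(spec.interactions):
        a, b = spec.index(it.first), spec.index(it.second)
        var_raw = 1.0 + Sigma[a, b] ** 2
        G[:, n0 + m] = G[:, a] * G[:, b] / np.sqrt(var_raw)
    for name in [n for n in _component_order(spec) if n in targets]:
        t = spec.index(name)
        brow = design.true_B[t]
        var_pred = float(brow @ Sigma @ brow)
        sd = np.sqrt(1.0 - var_pred)
        G[:, t] = G @ brow + sd * rng.standard_normal(N)

    cols = spec.observed
    Z = np.zeros((N, len(cols)))
    for p, comp in enumerate(spec.components):
        js = [cols.index(i) for i in comp.indicators]
        k = len(js)
        gam = G[:, p]
        if k == 1:
            Z[:, js[0]] = gam
            continue
        cvals = design.true_C[js, p]
        if not np.allclose(cvals, cvals[0]):
            raise NotImplementedError(
                "unequal loadings within a block are not supported by the "
                "composite-consistent generator"
            )
        c = float(cvals[0])
        sd_eta = np.sqrt((1.0 - c * c) * k / (k - 1.0))
        eta = rng.normal(0.0, sd_eta, size=(N, k))
        eps = eta - eta.mean(axis=1, keepdims=True)
        Z[:, js] = c * gam[:, None] + eps

    if design.snp_freqs:
        for col, (f1, f2, _f3) in design.snp_freqs.items():
            j = cols.index(col)
            q1, q2 = np.quantile(Z[:, j], [f1, f1 + f2])
            codes = np.ones(N)
            codes[Z[:, j] > q1] = 2.0
            codes[Z[:, j] > q2] = 3.0
            Z[:, j] = codes

    scores = pd.DataFrame(G, columns=list(spec.names))
    return Dataset(Z, cols), scores
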