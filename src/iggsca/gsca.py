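"""Model / Results front end.

``GSCAModel`` binds an observations table to a model specification;
``fit`` (fixed penalty) or ``fit_cv`` (cross-validated penalty) return a
``GSCAResults`` carrying estimates, component scores, fit diagnostics and
inference methods.

Example
-------
>>> spec = build_model([("gene", ["snp1", "snp2"]), ("dep", ["score"])],
...                    paths=[("gene", "dep")])
>>> res = GSCAModel(df, spec).fit(lam=10.0, tau=2)
>>> res.paths
>>> res.bootstrap(B=500, seed=1).table
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import infer as _infer
from .data import Dataset
from .estimation import FitResult, PenaltyConfig, fit as _fit
from .model import ModelSpec, load_model_config, pattern_matrices
from .tune import CVPlan, select_lambda

__all__ = ["GSCAModel", "GSCAResults"]


class GSCAModel:
    """A composite-based structural model bound to data.

    Parameters
    ----------
    data : DataFrame or Dataset
        Observations (rows = subjects); columns must match the spec's
        indicators exactly (order free).
    spec : ModelSpec
        Components, interactions and free paths.
    """

    def __init__(self, data, spec: ModelSpec):
        if isinstance(data, pd.DataFrame):
            data = Dataset.from_dataframe(data)
        pattern_matrices(spec, data.column_names)  # validates column/indicator match
        self.data = data
        self.spec = spec

    @classmethod
    def from_config(cls, data, config_path) -> "GSCAModel":
        return cls(data, load_model_config(config_path))

    def fit(
        self,
        lam: float = 0.0,
        tau: int = 2,
        penalty: PenaltyConfig | None = None,
        init_seed: int = 0,
        tol: float = 1e-5,
        max_iter: int = 300,
        **kwargs,
    ) -> "GSCAResults":
        pen = penalty if penalty is not None else PenaltyConfig(lam, tau)
        res = _fit(self.data, self.spec, pen, init_seed=init_seed,
                   tol=tol, max_iter=max_iter, **kwargs)
        return GSCAResults(self, res)

    def select_lambda(self, tau: int = 2, plan: CVPlan | None = None,
                      **fit_kwargs):
        return select_lambda(self.data, self.spec, tau=tau,
                             plan=plan or CVPlan(), **fit_kwargs)

    def fit_cv(self, tau: int = 2, plan: CVPlan | None = None,
               init_seed: int = 0, **fit_kwargs) -> "GSCAResults":
        """Cross-validate the penalty, then fit at the selected value."""
        lam, table = self.select_lambda(tau=tau, plan=plan,
                                        init_seed=init_seed, **fit_kwargs)
        out = self.fit(lam=lam, tau=tau, init_seed=init_seed, **fit_kwargs)
        out.cv_table = table
        return out


class GSCAResults:
    """Estimates, scores and inference for a fitted model."""

    def __init__(self, model: GSCAModel, result: FitResult):
        self.model = model
        self.result = result
        self.cv_table: pd.DataFrame | None = None
        self._boot: _infer.BootstrapResult | None = None

    # -- delegated basics ------------------------------------------------

    @property
    def params(self):
        return self.result.params

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def scores(self) -> pd.DataFrame:
        return self.result.scores

    @property
    def criterion(self) -> float:
        return self.result.criterion

    @property
    def converged(self) -> bool:
        return self.result.converged

    @property
    def penalty(self) -> PenaltyConfig:
        return self.result.penalty

    @property
    def r2(self) -> pd.Series:
        return pd.Series(self.result.r2, name="r2")

    @property
    def r2_mean(self) -> float:
        return self.result.r2_mean

    # -- tabular views ---------------------------------------------------

    def _measurement_table(self, block: str) -> pd.DataFrame:
        par = self.params
        M = par.W if block == "weight" else par.C.T
        rows = []
        for p, comp in enumerate(self.spec.components):
            for ind in comp.indicators:
                j = par.columns.index(ind)
                rows.append((comp.name, ind, float(M[p, j])))
        return pd.DataFrame(rows, columns=["component", "indicator", "estimate"])

    @property
    def weights(self) -> pd.DataFrame:
        return self._measurement_table("weight")

    @property
    def loadings(self) -> pd.DataFrame:
        return self._measurement_table("loading")

    @property
    def paths(self) -> pd.DataFrame:
        par = self.params
        spec = self.spec
        rows = [
            (s, t, float(par.B[spec.index(t), spec.index(s)]))
            for s, t in spec.paths
        ]
        return pd.DataFrame(rows, columns=["source", "target", "estimate"])

    # -- inference -------------------------------------------------------

    def bootstrap(self, B: int = 500, seed: int = 0, **kwargs) -> "_infer.BootstrapResult":
        self._boot = _infer.bootstrap(
            self.model.data, self.spec, self.penalty, B=B, seed=seed,
            fit_result=self.result, **kwargs,
        )
        return self._boot

    def conditional_effect(self, predictor: str, moderator: str, target: str,
                           levels=None, **kwargs) -> pd.DataFrame:
        if levels is None:
            comp = self.spec.component(moderator)
            if comp.is_single:
                j = self.params.columns.index(comp.indicators[0])
                raw = self.model.data.values[:, j]
                levels = np.unique(raw)
            else:
                levels = np.array([-1.0, 1.0])
        return _infer.conditional_effect(
            self.result, predictor, moderator, target, levels,
            boot=self._boot, **kwargs,
        )

    def indirect_effect(self, *chain) -> "_infer.IndirectEffect":
        if len(chain) == 1:  # accept a single sequence too
            chain = tuple(chain[0])
        return _infer.indirect_effect(self.result, chain, boot=self._boot)

    # -- reporting -------------------------------------------------------

    def summary(self) -> str:
        res = self.result
        lines = [
            "Generalized structured component analysis (imaging genetics)",
            "=" * 62,
            f"observations: {res.N}    observed variables: {len(res.params.columns)}",
            f"components:   {self.spec.P} ({len(self.spec.interactions)} interactions)",
            f"penalty:      lambda={res.penalty.lam:g}, tau={res.penalty.tau} "
            f"({'ridge' if res.penalty.tau == 2 else 'lasso'})",
            f"criterion:    {res.criterion:.6g} after {res.iterations} iterations "
            f"(converged={res.converged})",
            "",
            "Weights / loadings",
            "-" * 62,
        ]
        wl = self.weights.merge(
            self.loadings, on=["component", "indicator"], suffixes=("_w", "_l")
        ).rename(columns={"estimate_w": "weight", "estimate_l": "loading"})
        if self._boot is not None:
            bt = self._boot.table
            for blk, col in (("weight", "weight"), ("loading", "loading")):
                sub = bt[bt.block == blk][["component", "name", "se", "ci_low", "ci_high"]]
                sub = sub.rename(columns={
                    "name": "indicator", "se": f"{col}_se",
                    "ci_low": f"{col}_ci_low", "ci_high": f"{col}_ci_high"})
                wl = wl.merge(sub, on=["component", "indicator"], how="left")
        lines.append(wl.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        lines += ["", "Path coefficients", "-" * 62]
        pt = self.paths
        if self._boot is not None:
            bt = self._boot.table
            sub = bt[bt.block == "path"].rename(
                columns={"component": "source", "name": "target"}
            )[["source", "target", "se", "ci_low", "ci_high", "significant"]]
            pt = pt.merge(sub, on=["source", "target"], how="left")
        lines.append(pt.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        lines += ["", "R^2 of dependent components", "-" * 62]
        r2 = self.r2
        lines.append(r2.to_string(float_format=lambda v: f"{v:.3f}"))
        lines.append(f"average R^2: {self.r2_mean:.3f}")
        return "\n".join(lines)

    def __repr__(self):
        return (f"<GSCAResults: P={self.spec.P}, N={self.result.N}, "
                f"lambda={self.penalty.lam:g}, tau={self.penalty.tau}, "
                f"converged={self.converged}>")
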