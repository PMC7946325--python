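"""Penalized alternating least-squares estimation.

The estimator minimizes

    phi = sum_i || V z_i - A W z_i ||^2  +  lambda * sum |b|^tau

over weights W, loadings C and path coefficients B, subject to every
component score having unit variance (divisor N), where ``V = [I; W]`` and
``A = [C; B]`` stack the measurement and structural parts of the combined
model.  tau = 2 gives a ridge penalty on the free path coefficients,
tau = 1 the lasso; weights and loadings are never penalized.

Three blocks are updated in turn until the criterion stabilizes:

* **weights** — each composite component's free weights solve a
  norm-constrained least-squares problem exactly (secular equation), so the
  criterion cannot increase at this step;
* **loadings** — closed-form regression of each indicator on its own
  component score;
* **paths** — per dependent component, closed-form ridge or coordinate-
  descent lasso on the component scores.

Interaction components score as the elementwise product of their two parent
scores rescaled to unit variance; they share their parents' weights, which
the weight step handles by treating the partner score (and the rescaling
factor) as fixed within the update and refreshing both afterwards.

When every interaction has at most one composite parent, the alternating
updates depend on the data only through cross-products of the columns of
``[Z, partner ⊙ Z_parent-blocks]``, so the solver runs on the triangular QR
factor of that matrix instead of the raw rows — numerically identical
results at a cost independent of the sample size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .data import Dataset, standardize
from .model import ModelSpec, ParameterSet, pattern_matrices

logger = logging.getLogger("iggsca")

__all__ = [
    "PenaltyConfig",
    "FitResult",
    "fit",
    "compute_scores",
    "evaluate_criterion",
    "update_paths",
    "update_loadings",
    "update_weights",
    "compute_r2",
    "align_signs",
    "apply_sign_flips",
]


@dataclass(frozen=True)
class PenaltyConfig:
    """Penalty on the free path coefficients: lam * sum |b|**tau."""

    lam: float = 0.0
    tau: int = 2

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.tau not in (1, 2):
            raise ValueError("tau must be 1 (lasso) or 2 (ridge)")


@dataclass
class FitResult:
    """Converged (or stopped) estimates and derived quantities."""

    params: ParameterSet
    scores: pd.DataFrame                 # N x P component scores
    criterion: float
    criterion_path: np.ndarray
    measurement_residuals: pd.DataFrame  # N x J
    structural_residuals: pd.DataFrame   # N x n_dependent
    r2: dict
    iterations: int
    converged: bool
    penalty: PenaltyConfig
    N: int
    center: np.ndarray = None            # standardization of the fitted data
    scale: np.ndarray = None

    @property
    def r2_mean(self) -> float:
        return float(np.mean(list(self.r2.values()))) if self.r2 else float("nan")


# ---------------------------------------------------------------------------
# score computation on real data
# ---------------------------------------------------------------------------

def _base_scores(params: ParameterSet, Z: np.ndarray) -> np.ndarray:
    spec = params.spec
    P = spec.P
    G = np.empty((Z.shape[0], P))
    G[:, : spec.n_components] = Z @ params.W[: spec.n_components].T
    return G


def compute_scores(
    params: ParameterSet,
    dataset: Dataset | np.ndarray,
    use_stored_scales: bool = False,
) -> pd.DataFrame:
    """Component scores gamma = W z, interaction columns as rescaled products.

    Expects standardized data in the parameter set's column order.  With
    ``use_stored_scales`` the interaction rescaling factors stored in
    ``params`` are applied (out-of-sample scoring); otherwise each
    interaction column is rescaled to unit variance on the given data and
    the factors are written back into ``params``.
    """
    spec = params.spec
    Z = dataset.values if isinstance(dataset, Dataset) else np.asarray(dataset, float)
    if Z.shape[1] != len(params.columns):
        raise ValueError("data width does not match parameter columns")
    G = _base_scores(params, Z)
    n0 = spec.n_components
    N = Z.shape[0]
    for m, it in enumerate(spec.interactions):
        u = G[:, spec.index(it.first)] * G[:, spec.index(it.second)]
        if use_stored_scales:
            s = params.interaction_scales[m]
        else:
            nrm = np.linalg.norm(u)
            s = np.sqrt(N) / nrm if nrm > 0 else 1.0
            params.interaction_scales[m] = s
        G[:, n0 + m] = s * u
    return pd.DataFrame(G, columns=list(spec.names))


@dataclass
class CriterionValue:
    phi: float
    measurement_residuals: np.ndarray
    structural_residuals: np.ndarray  # columns = dependent components
    penalty_term: float
    dependent: tuple


def evaluate_criterion(
    params: ParameterSet,
    dataset: Dataset | np.ndarray,
    penalty: PenaltyConfig = PenaltyConfig(),
    scores: np.ndarray | None = None,
) -> CriterionValue:
    """Evaluate phi and its residual blocks at fixed parameter values.

    The structural block sums over dependent components (those receiving at
    least one free path); components with no incoming paths contribute no
    structural residual.
    """
    spec = params.spec
    Z = dataset.values if isinstance(dataset, Dataset) else np.asarray(dataset, float)
    if scores is None:
        scores = compute_scores(params, Z, use_stored_scales=False).to_numpy()
    G = np.asarray(scores, float)
    meas = Z - G @ params.C.T
    dep = spec.dependent()
    dep_ix = [spec.index(d) for d in dep]
    struct = G[:, dep_ix] - G @ params.B[dep_ix].T
    pen = penalty.lam * float(np.sum(np.abs(params.B[params.b_free]) ** penalty.tau))
    phi = float(np.sum(meas * meas) + np.sum(struct * struct) + pen)
    return CriterionValue(phi, meas, struct, pen, dep)


# ---------------------------------------------------------------------------
# block updates on fixed scores (public forms)
# ---------------------------------------------------------------------------

def _solve_path_row(G, cxy, free_ix, b_start, penalty, N):
    """Minimize ||y - X b||^2 + lam*sum|b|^tau given Gram G = X'X, cxy = X'y."""
    lam, tau = penalty.lam, penalty.tau
    q = G.shape[0]
    if lam == 0.0 or tau == 2:
        A = G + lam * np.eye(q) if lam > 0 else G
        try:
            c, low = sla.cho_factor(A, check_finite=False)
            return sla.cho_solve((c, low), cxy, check_finite=False)
        except (np.linalg.LinAlgError, sla.LinAlgError):
            logger.warning("collinear predictors at lambda=0; minimum-norm solution used")
            return np.linalg.pinv(A) @ cxy
    # lasso: coordinate descent in covariance form
    b = np.array(b_start, dtype=float)
    Gd = np.diag(G).copy()
    thr = lam / 2.0
    tol = 1e-12 * max(N, 1)
    for _ in range(10000):
        delta = 0.0
        for j in range(q):
            rho = cxy[j] - G[j] @ b + Gd[j] * b[j]
            bj = np.sign(rho) * max(abs(rho) - thr, 0.0) / Gd[j]
            delta = max(delta, abs(bj - b[j]))
            b[j] = bj
        if delta < tol:
            break
    return b


def update_paths(
    scores: np.ndarray | pd.DataFrame,
    params: ParameterSet,
    penalty: PenaltyConfig = PenaltyConfig(),
) -> np.ndarray:
    """Per-dependent-component penalized regression on fixed scores -> B.

    Ridge rows are solved in closed form; lasso rows by coordinate descent.
    Dependent components sharing the same predictor set share one Gram
    matrix.
    """
    spec = params.spec
    G = np.asarray(scores, float)
    N = G.shape[0]
    B = params.B.copy()
    B[params.b_free] = 0.0
    groups: dict[tuple, list[int]] = {}
    for d in spec.dependent():
        t = spec.index(d)
        preds = tuple(sorted(spec.index(s) for s in spec.predictors_of(d)))
        groups.setdefault(preds, []).append(t)
    for preds, targets in groups.items():
        X = G[:, list(preds)]
        Gram = X.T @ X
        Cxy = X.T @ G[:, targets]
        for k, t in enumerate(targets):
            b = _solve_path_row(
                Gram, Cxy[:, k], preds, params.B[t, list(preds)], penalty, N
            )
            B[t, list(preds)] = b
    return B


def update_loadings(
    scores: np.ndarray | pd.DataFrame,
    dataset: Dataset | np.ndarray,
    params: ParameterSet,
) -> np.ndarray:
    """Closed-form loading update: C[j, p] = z_j' gamma_p / N for free entries."""
    spec = params.spec
    Z = dataset.values if isinstance(dataset, Dataset) else np.asarray(dataset, float)
    G = np.asarray(scores, float)
    N = Z.shape[0]
    C = params.C.copy()
    for p, comp in enumerate(spec.components):
        if comp.is_single:
            continue
        js = [params.columns.index(i) for i in comp.indicators]
        C[js, p] = Z[:, js].T @ G[:, p] / N
    return C


def update_weights(
    params: ParameterSet,
    dataset: Dataset | np.ndarray,
    penalty: PenaltyConfig = PenaltyConfig(),
) -> ParameterSet:
    """One full pass of exact norm-constrained weight updates.

    Returns an updated copy of ``params`` (loadings and paths untouched);
    every composite score column has unit variance afterwards.
    """
    Z = dataset.values if isinstance(dataset, Dataset) else np.asarray(dataset, float)
    ds = dataset if isinstance(dataset, Dataset) else Dataset(Z, params.columns)
    wd = WorkData(Z, Z.shape[0], params.spec, params.columns)
    work = _Work(params.copy(), wd, penalty)
    work.normalize_weights()
    work.update_weights_pass()
    return work.par


def compute_r2(fit_result: "FitResult") -> dict:
    """R^2 = 1 - RSS/N per dependent component (unit-variance scores)."""
    return dict(fit_result.r2)


# ---------------------------------------------------------------------------
# norm-constrained least squares:  min w'Hw - 2g'w  s.t.  w'Sw = N
# ---------------------------------------------------------------------------

def _whitener(S: np.ndarray) -> np.ndarray | None:
    """T with T'ST = I on the numerical range of S (columns may be dropped)."""
    ds, E = np.linalg.eigh(S)
    keep = ds > 1e-12 * max(ds[-1], 1e-300)
    if not keep.any():
        return None
    return E[:, keep] / np.sqrt(ds[keep])


def _secular_root(lam: np.ndarray, c: np.ndarray, N: float, scale: float) -> np.ndarray:
    """Solve sum c_i^2/(lam_i+mu)^2 = N for the global sphere minimizer u.

    Safeguarded Newton on the reciprocal-norm form (Moré–Sorensen style);
    converges monotonically from mu0 = ||c||/sqrt(N) - lam_min.
    """
    lam_min = lam[0]
    rootN = np.sqrt(N)
    cnorm = np.sqrt(c @ c)
    lo = -lam_min + 1e-14 * scale
    mu = max(cnorm / rootN - lam_min, lo)
    inv_rootN = 1.0 / rootN
    for _ in range(100):
        d = lam + mu
        r = c / d
        f = float(r @ r)
        if abs(f - N) <= 1e-13 * N:
            break
        fp = -2.0 * float((r * r / d).sum())
        # Newton on f^{-1/2} - N^{-1/2}
        h = f**-0.5 - inv_rootN
        hp = -0.5 * f**-1.5 * fp
        step = h / hp
        mu_new = mu - step
        if mu_new <= lo or not np.isfinite(mu_new):
            mu_new = 0.5 * (mu + lo)
        mu = mu_new
    return c / (lam + mu)


def _eigh_small(A: np.ndarray):
    """eigh specialized for the tiny (k<=2) matrices of the weight step."""
    k = A.shape[0]
    if k == 1:
        return A[0].copy(), np.ones((1, 1))
    if k == 2:
        a, b, d = A[0, 0], A[0, 1], A[1, 1]
        t = 0.5 * (a + d)
        r = float(np.hypot(0.5 * (a - d), b))
        l1, l2 = t - r, t + r
        if abs(b) > 1e-300:
            v1 = np.array([l1 - d, b])
            v1 /= np.sqrt(v1 @ v1)
        elif a <= d:
            v1 = np.array([1.0, 0.0])
        else:
            v1 = np.array([0.0, 1.0])
        Q = np.array([[v1[0], -v1[1]], [v1[1], v1[0]]])
        return np.array([l1, l2]), Q
    return np.linalg.eigh(A)


def _solve_norm_constrained(H, g, S, N, w_fallback, T=None):
    """Global minimizer of  w'Hw - 2g'w  subject to  w'Sw = N.

    Whitens by S (``T`` may be precomputed), reduces to a sphere-constrained
    quadratic and solves its secular equation; handles the degenerate (hard)
    case where the gradient has no component on the smallest eigenspace.
    """
    if T is None:
        T = _whitener(S)
    if T is None:
        return np.array(w_fallback, float)
    Ht = T.T @ H @ T
    Ht = 0.5 * (Ht + Ht.T)
    gt = T.T @ g
    lam, Q = _eigh_small(Ht)
    c = Q.T @ gt
    scale = max(abs(lam[0]), abs(lam[-1]), 1.0)
    rootN = np.sqrt(N)
    cnorm = np.sqrt(c @ c)
    if cnorm < 1e-14 * scale * rootN:
        # objective is (nearly) pure quadratic: smallest-eigenvalue direction
        w = T @ (Q[:, 0] * rootN)
        if w @ np.asarray(w_fallback, float) < 0:  # continuity with iterate
            w = -w
        return w
    lam_min = lam[0]
    on_min = np.abs(lam - lam_min) < 1e-12 * scale
    c_min_norm = np.sqrt(c[on_min] @ c[on_min])
    u = None
    if c_min_norm <= 1e-13 * scale * rootN:
        # possible hard case: gradient orthogonal to smallest eigenspace
        mask = ~on_min
        denom = lam[mask] - lam_min
        val = float(np.sum((c[mask] / denom) ** 2)) if mask.any() else 0.0
        if val < N:
            u = np.zeros_like(c)
            if mask.any():
                u[mask] = c[mask] / denom
            u[int(np.nonzero(on_min)[0][0])] = np.sqrt(N - val)
    if u is None:
        u = _secular_root(lam, c, N, scale)
    w = T @ (Q @ u)
    # exact feasibility polish
    nrm = np.sqrt(w @ S @ w)
    if nrm > 0:
        w *= rootN / nrm
    return w


# ---------------------------------------------------------------------------
# internal working state for the ALS loop
# ---------------------------------------------------------------------------

class WorkData:
    """Spec- and data-dependent precomputations, shareable across fits.

    Holds the working rows (raw or QR-compressed), per-component indicator
    Gram matrices and their whiteners, dependent/interaction bookkeeping.
    Everything here is invariant over penalty values and starting points,
    so cross-validation reuses one instance per training fold.
    """

    def __init__(self, Z: np.ndarray, N: int, spec: ModelSpec, columns,
                 U_fixed: list | None = None):
        self.Z = Z
        self.N = N
        self.spec = spec
        self.columns = tuple(columns)
        self.col_ix = {c: j for j, c in enumerate(self.columns)}
        self.comp_cols = [
            np.array([self.col_ix[i] for i in comp.indicators])
            for comp in spec.components
        ]
        self.n0 = spec.n_components
        # per-column ownership for fast measurement fit
        self.col_comp = np.empty(len(self.columns), dtype=int)
        for p, cols in enumerate(self.comp_cols):
            self.col_comp[cols] = p
        # dependent bookkeeping
        self.dep = [spec.index(d) for d in spec.dependent()]
        self.dep_pos = {t: i for i, t in enumerate(self.dep)}
        self.preds = {t: np.array([spec.index(s) for s in
                                   spec.predictors_of(spec.names[t])])
                      for t in self.dep}
        # interaction bookkeeping
        self.int_parents = [
            (spec.index(it.first), spec.index(it.second))
            for it in spec.interactions
        ]
        # which interactions involve composite parent p (for weight updates)
        self.int_of_parent: dict[int, list[int]] = {}
        for m, (a, b) in enumerate(self.int_parents):
            for p in (a, b):
                if not spec.components[p].is_single:
                    self.int_of_parent.setdefault(p, []).append(m)
        self.U_fixed = U_fixed  # compressed-mode linear maps, or None
        self.S_blocks = [Z[:, cols].T @ Z[:, cols] for cols in self.comp_cols]
        self.T_blocks = [
            None if comp.is_single else _whitener(self.S_blocks[p])
            for p, comp in enumerate(spec.components)
        ]

    @classmethod
    def build(cls, dataset: Dataset, spec: ModelSpec, columns,
              compress: str = "auto") -> "WorkData":
        Z = dataset.values
        N = Z.shape[0]
        ok = _compressible(spec)
        use = compress == "always" or (compress == "auto" and ok and N > 2 * Z.shape[1])
        if compress == "always" and not ok:
            raise ValueError(
                "model has a two-composite interaction; compression unavailable"
            )
        if use:
            col_ix = {c: j for j, c in enumerate(columns)}
            Zc, U_fixed = _compress(Z, spec, columns, col_ix)
            return cls(Zc, N, spec, columns, U_fixed=U_fixed)
        return cls(Z, N, spec, columns)


_WD_FIELDS = ("Z", "N", "col_ix", "comp_cols", "n0", "col_comp", "dep",
              "dep_pos", "preds", "int_parents", "int_of_parent", "U_fixed",
              "S_blocks", "T_blocks")


class _Work:
    """Mutable estimation state: parameters plus scores/residuals."""

    def __init__(self, params: ParameterSet, wd: WorkData,
                 penalty: PenaltyConfig):
        self.par = params
        self.spec = params.spec
        self.pen = penalty
        for name in _WD_FIELDS:
            setattr(self, name, getattr(wd, name))
        self.G = None      # (R, P) scores on working rows
        self.u = None      # list of raw interaction products (R,)
        self.Rs = None     # (R, n_dep) structural residuals

    def normalize_weights(self):
        """Rescale composite weight rows so every score has unit variance."""
        par = self.par
        for p, comp in enumerate(self.spec.components):
            if comp.is_single:
                continue
            cols = self.comp_cols[p]
            w = par.W[p, cols]
            nrm2 = float(w @ self.S_blocks[p] @ w)
            if nrm2 <= 1e-300:
                w = np.ones(len(cols))
                nrm2 = float(w @ self.S_blocks[p] @ w)
            par.W[p, cols] = w * np.sqrt(self.N / nrm2)

    # -- score / residual maintenance -----------------------------------

    def _U(self, m: int, parent: int) -> np.ndarray:
        """Matrix with u_m = U @ w_parent (partner score held fixed)."""
        if self.U_fixed is not None:
            U, lin_parent = self.U_fixed[m]
            if lin_parent != parent:
                raise RuntimeError("compressed mode cannot relinearize this parent")
            return U
        a, b = self.int_parents[m]
        partner = b if parent == a else a
        return self.G[:, partner][:, None] * self.Z[:, self.comp_cols[parent]]

    def refresh_scores(self):
        spec, Z = self.spec, self.Z
        R = Z.shape[0]
        G = np.empty((R, spec.P))
        for p, cols in enumerate(self.comp_cols):
            G[:, p] = Z[:, cols] @ self.par.W[p, cols]
        self.G = G
        self.u = []
        for m, (a, b) in enumerate(self.int_parents):
            if self.U_fixed is not None:
                U, lin_parent = self.U_fixed[m]
                if U.shape[1] == 1 and lin_parent is None:
                    u = U[:, 0].copy()
                else:
                    u = U @ self.par.W[lin_parent, self.comp_cols[lin_parent]]
            else:
                u = G[:, a] * G[:, b]
            self.u.append(u)
            nrm = np.sqrt(u @ u)
            s = np.sqrt(self.N) / nrm if nrm > 0 else 1.0
            self.par.interaction_scales[m] = s
            G[:, self.n0 + m] = s * u

    def refresh_struct(self):
        G, B = self.G, self.par.B
        self.Rs = G[:, self.dep] - G @ B[self.dep].T

    def criterion(self) -> float:
        fitted = self.G[:, self.col_comp] * self.par.C[
            np.arange(len(self.par.columns)), self.col_comp
        ]
        meas = self.Z - fitted
        pen = self.pen.lam * float(
            np.sum(np.abs(self.par.B[self.par.b_free]) ** self.pen.tau)
        )
        return float(np.sum(meas * meas) + np.sum(self.Rs * self.Rs) + pen)

    # -- block updates ---------------------------------------------------

    def update_loadings_pass(self):
        par, G = self.par, self.G
        for p, comp in enumerate(self.spec.components):
            if comp.is_single:
                continue
            cols = self.comp_cols[p]
            par.C[cols, p] = self.Z[:, cols].T @ G[:, p] / self.N

    def update_paths_pass(self):
        par, G = self.par, self.G
        groups: dict[tuple, list[int]] = {}
        for t in self.dep:
            groups.setdefault(tuple(self.preds[t]), []).append(t)
        for preds, targets in groups.items():
            pl = list(preds)
            X = G[:, pl]
            Gram = X.T @ X
            Cxy = X.T @ G[:, targets]
            if self.pen.tau == 2 or self.pen.lam == 0.0:
                A = Gram + self.pen.lam * np.eye(len(pl))
                try:
                    cf = sla.cho_factor(A, check_finite=False)
                    sol = sla.cho_solve(cf, Cxy, check_finite=False)
                except (np.linalg.LinAlgError, sla.LinAlgError):
                    logger.warning(
                        "collinear predictors at lambda=0; minimum-norm solution used"
                    )
                    sol = np.linalg.pinv(A) @ Cxy
                for k, t in enumerate(targets):
                    par.B[t, pl] = sol[:, k]
            else:
                for k, t in enumerate(targets):
                    par.B[t, pl] = _solve_path_row(
                        Gram, Cxy[:, k], pl, par.B[t, pl], self.pen, self.N
                    )
        self.refresh_struct()

    def update_weights_pass(self):
        if self.G is None:
            self.refresh_scores()
        if self.Rs is None:
            self.refresh_struct()
        par, spec = self.par, self.spec
        G, Rs = self.G, self.Rs
        dep = self.dep
        B = par.B
        for p, comp in enumerate(spec.components):
            if comp.is_single:
                continue
            cols = self.comp_cols[p]
            Zp = self.Z[:, cols]
            S_pp = self.S_blocks[p]
            cvec = par.C[cols, p]
            H = (cvec @ cvec) * S_pp
            g = S_pp @ cvec
            ms = self.int_of_parent.get(p, [])
            # alpha_t = [t==p] - B[t,p];  beta_{m,t} = -B[t, m] * s_m
            alpha = -B[dep, p]
            if p in self.dep_pos:
                alpha[self.dep_pos[p]] += 1.0
            betas, Us = [], []
            for m in ms:
                s_m = par.interaction_scales[m]
                betas.append(-B[dep, self.n0 + m] * s_m)
                Us.append(self._U(m, p))
            # linear maps whose combination gives every residual term in w
            mats = [Zp] + Us
            coefs = [alpha] + betas
            cur = [G[:, p]] + [Us[i] @ par.W[p, cols] for i in range(len(ms))]
            nterm = len(mats)
            gram = [[None] * nterm for _ in range(nterm)]
            for i in range(nterm):
                for j in range(i, nterm):
                    Gij = S_pp if (i == 0 and j == 0) else mats[i].T @ mats[j]
                    gram[i][j] = Gij
                    if i != j:
                        gram[j][i] = Gij.T
            for i in range(nterm):
                for j in range(nterm):
                    cc = float(coefs[i] @ coefs[j])
                    if cc != 0.0:
                        H = H + cc * gram[i][j]
            # linear term: g_struct = -sum_t A_t' a_t,  a_t = r_t - A_t w_cur
            for i in range(nterm):
                v = Rs @ coefs[i]
                for j in range(nterm):
                    cc = float(coefs[i] @ coefs[j])
                    if cc != 0.0:
                        v = v - cc * cur[j]
                g = g - mats[i].T @ v
            w_old = par.W[p, cols].copy()
            w_new = _solve_norm_constrained(H, g, S_pp, self.N, w_old,
                                            T=self.T_blocks[p])
            dw = w_new - w_old
            if not np.any(dw):
                continue
            par.W[p, cols] = w_new
            gp_new = Zp @ w_new
            d_gp = gp_new - G[:, p]
            G[:, p] = gp_new
            # structural residuals move linearly while s_m is held fixed
            Rs += d_gp[:, None] * alpha
            for i, m in enumerate(ms):
                du = Us[i] @ dw
                Rs += du[:, None] * betas[i]
                self.u[m] = self.u[m] + du
                # now refresh the unit-variance rescaling of the product
                nrm = np.sqrt(self.u[m] @ self.u[m])
                s_new = np.sqrt(self.N) / nrm if nrm > 0 else 1.0
                gm_new = s_new * self.u[m]
                d_gm = gm_new - G[:, self.n0 + m]
                G[:, self.n0 + m] = gm_new
                par.interaction_scales[m] = s_new
                Rs -= d_gm[:, None] * B[dep, self.n0 + m]

    # -- driver ----------------------------------------------------------

    def run(self, tol: float, max_iter: int):
        self.refresh_scores()
        self.refresh_struct()
        path = [self.criterion()]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            self.update_weights_pass()
            self.update_loadings_pass()
            self.update_paths_pass()
            phi = self.criterion()
            path.append(phi)
            prev = path[-2]
            if abs(prev - phi) < tol * max(abs(prev), 1e-12):
                converged = True
                break
        return np.array(path), it, converged


# ---------------------------------------------------------------------------
# row compression
# ---------------------------------------------------------------------------

def _compressible(spec: ModelSpec) -> bool:
    for it in spec.interactions:
        a = spec.component(it.first)
        b = spec.component(it.second)
        if not (a.is_single or b.is_single):
            return False
    return True


def _compress(Z: np.ndarray, spec: ModelSpec, columns, col_ix) -> tuple:
    """QR row compression preserving all cross-products the ALS uses."""
    blocks = [Z]
    meta = []  # (slice into D, lin_parent or None)
    offset = Z.shape[1]
    base_scores = {}
    for it in spec.interactions:
        a, b = spec.component(it.first), spec.component(it.second)
        ia, ib = spec.index(it.first), spec.index(it.second)

        def single_col(comp, idx):
            if idx not in base_scores:
                base_scores[idx] = Z[:, col_ix[comp.indicators[0]]]
            return base_scores[idx]

        if a.is_single and b.is_single:
            col = single_col(a, ia) * single_col(b, ib)
            blocks.append(col[:, None])
            meta.append((slice(offset, offset + 1), None))
            offset += 1
        else:
            comp_par, single_par = (a, b) if not a.is_single else (b, a)
            ip = spec.index(comp_par.name)
            isg = spec.index(single_par.name)
            cols = [col_ix[i] for i in comp_par.indicators]
            Ub = single_col(single_par, isg)[:, None] * Z[:, cols]
            blocks.append(Ub)
            meta.append((slice(offset, offset + len(cols)), ip))
            offset += len(cols)
    D = np.hstack(blocks)
    R = np.linalg.qr(D, mode="r")
    Zc = np.ascontiguousarray(R[:, : Z.shape[1]])
    U_fixed = [(np.ascontiguousarray(R[:, sl]), lin) for sl, lin in meta]
    return Zc, U_fixed


# ---------------------------------------------------------------------------
# sign conventions
# ---------------------------------------------------------------------------

def _interaction_flips(spec: ModelSpec, flips: np.ndarray) -> np.ndarray:
    out = flips.copy()
    n0 = spec.n_components
    for m, it in enumerate(spec.interactions):
        out[n0 + m] = flips[spec.index(it.first)] * flips[spec.index(it.second)]
    return out


def apply_sign_flips(params: ParameterSet, flips: np.ndarray) -> ParameterSet:
    """Flip component signs coherently (weights, loadings, both B axes).

    ``flips`` gives ±1 per non-interaction component; interaction signs
    follow as the product of their parents' flips.  The fitted model is
    invariant under any such flip.
    """
    f = _interaction_flips(params.spec, np.asarray(flips, float))
    out = params.copy()
    out.W *= f[:, None]
    out.C *= f[None, :]
    out.B = f[:, None] * out.B * f[None, :]
    return out


def _convention_flips(params: ParameterSet) -> np.ndarray:
    """Positive loading-sum convention; ties broken by the first weight."""
    spec = params.spec
    flips = np.ones(spec.P)
    for p, comp in enumerate(spec.components):
        if comp.is_single:
            continue
        csum = params.C[:, p].sum()
        if abs(csum) > 1e-12:
            flips[p] = np.sign(csum)
        else:
            w0 = params.W[p][np.abs(params.W[p]) > 0]
            flips[p] = np.sign(w0[0]) if w0.size and w0[0] != 0 else 1.0
    return flips


def align_signs(params: ParameterSet, reference: ParameterSet) -> ParameterSet:
    """Flip composite components to best agree with a reference solution."""
    spec = params.spec
    flips = np.ones(spec.P)
    for p, comp in enumerate(spec.components):
        if comp.is_single:
            continue
        d = params.W[p] @ reference.W[p] + params.C[:, p] @ reference.C[:, p]
        if d < 0:
            flips[p] = -1.0
    return apply_sign_flips(params, flips)


# ---------------------------------------------------------------------------
# top-level fit
# ---------------------------------------------------------------------------

def _init_params(spec, dataset, penalty, rng, start):
    params = pattern_matrices(spec, dataset.column_names)
    if start is not None:
        params.W = start.W.copy()
        params.C = start.C.copy()
        params.B = start.B.copy()
        params.interaction_scales = start.interaction_scales.copy()
    else:
        for p, comp in enumerate(spec.components):
            if comp.is_single:
                continue
            cols = [params.columns.index(i) for i in comp.indicators]
            params.W[p, cols] = rng.uniform(-1.0, 1.0, size=len(cols))
    return params


def fit(
    dataset: Dataset | pd.DataFrame,
    spec: ModelSpec,
    penalty: PenaltyConfig = PenaltyConfig(),
    init_seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 300,
    start: ParameterSet | None = None,
    compress: str = "auto",
    sign_convention: bool = True,
    finalize: bool = True,
    _work_data: WorkData | None = None,
) -> FitResult:
    """Fit the model by alternating regularized least squares.

    ``dataset`` is standardized internally if it is not already.  ``start``
    warm-starts from a previous solution (e.g. the fit at the preceding
    penalty value); otherwise free weights are drawn uniform(-1, 1) from
    ``init_seed`` and normalized, followed by one closed-form pass for
    loadings and paths.  The criterion value is recorded after every full
    weights→loadings→paths cycle; iteration stops when its relative decrease
    falls below ``tol``.
    """
    if isinstance(dataset, pd.DataFrame):
        dataset = Dataset.from_dataframe(dataset)
    if not dataset.is_standardized:
        dataset = standardize(dataset)
    if dataset.N < 2:
        raise ValueError("at least two observations required")
    rng = np.random.default_rng(init_seed)
    params = _init_params(spec, dataset, penalty, rng, start)
    N = dataset.N

    wd = _work_data if _work_data is not None else WorkData.build(
        dataset, spec, params.columns, compress
    )
    work = _Work(params, wd, penalty)

    # closed-form initialization pass for loadings and paths
    work.normalize_weights()
    work.refresh_scores()
    work.refresh_struct()
    if start is None:
        work.update_loadings_pass()
        work.update_paths_pass()

    path, iterations, converged = work.run(tol, max_iter)
    if not converged:
        warnings.warn(
            f"ALS did not converge in {max_iter} iterations "
            f"(last relative change {abs(path[-2]-path[-1])/max(abs(path[-2]),1e-12):.2e})",
            RuntimeWarning,
        )
    params = work.par
    if sign_convention:
        params = apply_sign_flips(params, _convention_flips(params))

    if not finalize:
        # cross-validation inner fits need only the parameters
        return FitResult(
            params=params, scores=None, criterion=float(path[-1]),
            criterion_path=path, measurement_residuals=None,
            structural_residuals=None, r2={}, iterations=iterations,
            converged=converged, penalty=penalty, N=N,
            center=dataset.center, scale=dataset.scale,
        )

    # final quantities on the real rows
    scores = compute_scores(params, dataset, use_stored_scales=False)
    crit = evaluate_criterion(params, dataset, penalty, scores=scores.to_numpy())
    dep = crit.dependent
    rss = np.sum(crit.structural_residuals**2, axis=0)
    r2 = {d: float(1.0 - rss[i] / N) for i, d in enumerate(dep)}
    return FitResult(
        params=params,
        scores=scores,
        criterion=crit.phi,
        criterion_path=path,
        measurement_residuals=pd.DataFrame(
            crit.measurement_residuals, columns=list(params.columns)
        ),
        structural_residuals=pd.DataFrame(
            crit.structural_residuals, columns=list(dep)
        ),
        r2=r2,
        iterations=iterations,
        converged=converged,
        penalty=penalty,
        N=N,
        center=dataset.center,
        scale=dataset.scale,
    )
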