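"""Alternating penalized least squares: block oracles, convergence, limits."""

import numpy as np
import pytest
from scipy.optimize import minimize

from iggsca.data import Dataset, standardize
from iggsca.estimation import (
    PenaltyConfig,
    apply_sign_flips,
    compute_scores,
    evaluate_criterion,
    fit,
    update_loadings,
    update_paths,
    update_weights,
)
from iggsca.model import build_model, pattern_matrices


def _orthonormal_columns(N, k, rng):
    """k exactly orthonormal, exactly mean-zero columns scaled to var 1."""
    M = rng.normal(size=(N, k))
    M -= M.mean(axis=0)
    Q, _ = np.linalg.qr(M)
    return Q * np.sqrt(N)


def exact_prototype(N=80, c=0.8, seed=3):
    """Prototype data where the composite model holds exactly in sample.

    Every residual (measurement and structural) is exactly orthogonal to
    every score in the sample, so the generating parameters are the exact
    criterion minimizer; the outcome is a noiseless combination of the two
    ROI scores.  Returns (dataset, spec, true ParameterSet).
    """
    rng = np.random.default_rng(seed)
    Q = _orthonormal_columns(N, 11, rng)
    g1, g2 = Q[:, 0], Q[:, 1]
    q3, q4 = Q[:, 9], Q[:, 10]  # exactly orthogonal structural residuals

    def combine(coef, cols, n_pred=None):
        """Exact-unit-variance combination; returns (score, path coefs)."""
        raw = sum(b * col for b, col in zip(coef, cols))
        scale = np.sqrt(raw @ raw / N)
        n_pred = len(coef) if n_pred is None else n_pred
        return raw / scale, [b / scale for b in coef[:n_pred]]

    r1, b_r1 = combine([0.6, 0.5, 0.5], [g1, g2, q3], n_pred=2)
    r2, b_r2 = combine([0.4, 0.3, 0.5, 0.5], [g1, g2, r1, q4], n_pred=3)
    y, b_y = combine([0.6, 0.4], [r1, r2])
    scores = [g1, g2, r1, r2, y]

    spec = build_model(
        [("gene1", ["z1", "z2"]), ("gene2", ["z3", "z4"]),
         ("roi1", ["z5", "z6"]), ("roi2", ["z7", "z8"]),
         ("behavior", ["z9"])],
        [],
        [("gene1", "roi1"), ("gene2", "roi1"),
         ("gene1", "roi2"), ("gene2", "roi2"), ("roi1", "roi2"),
         ("roi1", "behavior"), ("roi2", "behavior")],
    )
    Z = np.empty((N, 9))
    s = np.sqrt(1 - c * c)
    for p in range(4):
        eps = Q[:, 5 + p] * s
        Z[:, 2 * p] = c * scores[p] + eps
        Z[:, 2 * p + 1] = c * scores[p] - eps
    Z[:, 8] = y

    ps = pattern_matrices(spec)
    for p in range(4):
        ps.W[p, [2 * p, 2 * p + 1]] = 1.0 / (2 * c)
        ps.C[[2 * p, 2 * p + 1], p] = c
    t = spec.index
    ps.B[t("roi1"), [t("gene1"), t("gene2")]] = b_r1
    ps.B[t("roi2"), [t("gene1"), t("gene2"), t("roi1")]] = b_r2
    ps.B[t("behavior"), [t("roi1"), t("roi2")]] = b_y
    return Dataset(Z, spec.observed), spec, ps


class TestScores:
    def test_selector_weight(self):
        spec = build_model([("c", ["x", "y"])])
        ps = pattern_matrices(spec)
        ps.W[0, 0] = 1.0
        Z = np.array([[1.0, 5.0], [2.0, 6.0], [-3.0, 7.0]])
        G = compute_scores(ps, Z, use_stored_scales=True)
        np.testing.assert_array_equal(G["c"], Z[:, 0])

    def test_brute_force_product(self, rng):
        spec = build_model([("a", ["x1", "x2"]), ("b", ["x3", "x4"])])
        ps = pattern_matrices(spec)
        W = rng.normal(size=(2, 4))
        W[0, 2:] = W[1, :2] = 0.0
        ps.W = W
        Z = rng.normal(size=(6, 4))
        G = compute_scores(ps, Z, use_stored_scales=True).to_numpy()
        # independent elementwise oracle
        for i in range(6):
            for p in range(2):
                assert G[i, p] == pytest.approx(sum(W[p, j] * Z[i, j] for j in range(4)))

    def test_interaction_product_and_rescale(self, rng):
        # all parent weights 1: raw interaction score (z1+z2)(z3+z4)
        spec = build_model(
            [("a", ["z1", "z2"]), ("b", ["z3", "z4"])], [("a", "b")]
        )
        ps = pattern_matrices(spec)
        ps.W[0, :2] = 1.0
        ps.W[1, 2:] = 1.0
        Z = rng.normal(size=(40, 4))
        G = compute_scores(ps, Z).to_numpy()
        raw = (Z[:, 0] + Z[:, 1]) * (Z[:, 2] + Z[:, 3])
        s = np.sqrt(40) / np.linalg.norm(raw)
        np.testing.assert_allclose(G[:, 2], s * raw, atol=1e-12)
        assert ps.interaction_scales[0] == pytest.approx(s)
        assert (G[:, 2] ** 2).sum() / 40 == pytest.approx(1.0)


class TestCriterion:
    def test_perfect_fit_is_zero(self):
        spec = build_model([("a", ["x"]), ("b", ["y"])], paths=[("a", "b")])
        x = np.array([1.0, -1.0, 2.0, -2.0])
        ds = standardize(Dataset(np.column_stack([x, x]), ("x", "y")))
        ps = pattern_matrices(spec)
        ps.B[1, 0] = 1.0
        G = compute_scores(ps, ds).to_numpy()
        cv = evaluate_criterion(ps, ds, PenaltyConfig(0.0, 2), scores=G)
        assert cv.phi == pytest.approx(0.0, abs=1e-20)

    def test_zero_paths_value(self, prototype_spec, prototype_data):
        # B = 0: no penalty, and each dependent score contributes ||gamma||^2 = N
        ps = pattern_matrices(prototype_spec, prototype_data.column_names)
        rng = np.random.default_rng(0)
        ps.W[ps.w_free] = rng.normal(size=ps.w_free.sum())
        G = compute_scores(ps, prototype_data).to_numpy()
        # normalize scores so the constraint holds
        G_norm = G / np.sqrt((G**2).mean(axis=0))
        cv = evaluate_criterion(ps, prototype_data, PenaltyConfig(5.0, 2), scores=G_norm)
        meas = np.sum((prototype_data.values - G_norm @ ps.C.T) ** 2)
        n_dep = len(prototype_spec.dependent())
        assert cv.penalty_term == 0.0
        assert cv.phi == pytest.approx(meas + n_dep * prototype_data.N)

    def test_brute_force_sum(self, rng):
        # 2 components over 4 variables, fixed parameters: compare against an
        # independent per-observation loop over the combined-model residual
        spec = build_model(
            [("a", ["x1", "x2"]), ("b", ["x3", "x4"])], paths=[("a", "b")]
        )
        ds = standardize(Dataset(rng.normal(size=(15, 4)), spec.observed))
        ps = pattern_matrices(spec)
        ps.W[0, :2] = [0.7, 0.4]
        ps.W[1, 2:] = [0.5, 0.6]
        ps.C[:2, 0] = [0.8, 0.9]
        ps.C[2:, 1] = [0.7, 0.6]
        ps.B[1, 0] = 0.3
        pen = PenaltyConfig(2.5, 1)
        G = compute_scores(ps, ds, use_stored_scales=True).to_numpy()
        cv = evaluate_criterion(ps, ds, pen, scores=G)
        total = 0.0
        for i in range(ds.N):
            z = ds.values[i]
            gam = ps.W @ z
            e_meas = z - ps.C @ gam
            e_b = gam[1] - ps.B[1] @ gam  # only 'b' is dependent
            total += e_meas @ e_meas + e_b * e_b
        total += pen.lam * abs(ps.B[1, 0]) ** pen.tau
        assert cv.phi == pytest.approx(total, rel=1e-12)


class TestPathUpdate:
    def _setup(self, rng, n_pred=3, N=60):
        comps = [(f"p{i}", [f"x{i}"]) for i in range(n_pred)] + [("t", ["y"])]
        spec = build_model(comps, paths=[(f"p{i}", "t") for i in range(n_pred)])
        ds = standardize(Dataset(rng.normal(size=(N, n_pred + 1)), spec.observed))
        ps = pattern_matrices(spec, ds.column_names)
        G = compute_scores(ps, ds, use_stored_scales=True).to_numpy()
        return spec, ds, ps, G

    def test_lambda_zero_is_ols(self, rng):
        spec, ds, ps, G = self._setup(rng)
        B = update_paths(G, ps, PenaltyConfig(0.0, 2))
        X, y = G[:, :3], G[:, 3]
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(B[3, :3], ols, atol=1e-10)

    def test_ridge_shrinks_monotonically(self, rng):
        spec, ds, ps, G = self._setup(rng)
        norms = [
            np.linalg.norm(update_paths(G, ps, PenaltyConfig(lam, 2))[3, :3])
            for lam in (0.0, 1.0, 10.0, 100.0, 1000.0, 1e6)
        ]
        assert all(a >= b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-3 * norms[0]

    def test_lasso_matches_numeric_minimizer(self, rng):
        spec, ds, ps, G = self._setup(rng)
        lam = 25.0
        B = update_paths(G, ps, PenaltyConfig(lam, 1))
        b_cd = B[3, :3]
        X, y = G[:, :3], G[:, 3]

        def obj(b):
            r = y - X @ b
            return r @ r + lam * np.abs(b).sum()

        res = minimize(obj, b_cd + 0.05, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        assert obj(b_cd) <= res.fun + 1e-8


class TestLoadingUpdate:
    def test_perfect_and_orthogonal_indicator(self, rng):
        spec = build_model([("c", ["x", "y"])])
        N = 50
        g = rng.normal(size=N)
        g = (g - g.mean()) / g.std()
        orth = rng.normal(size=N)
        orth -= orth @ g / (g @ g) * g
        orth -= orth.mean()
        Z = np.column_stack([g, orth])
        ps = pattern_matrices(spec)
        G = g[:, None]
        C = update_loadings(G, Z, ps)
        assert C[0, 0] == pytest.approx(1.0, abs=1e-10)   # indicator == score
        assert C[1, 0] == pytest.approx(0.0, abs=1e-10)   # orthogonal

    def test_covariance_oracle(self, rng):
        spec = build_model([("a", ["x1", "x2", "x3"])])
        ds = standardize(Dataset(rng.normal(size=(30, 3)), spec.observed))
        ps = pattern_matrices(spec)
        ps.W[0] = rng.normal(size=3)
        G = compute_scores(ps, ds, use_stored_scales=True).to_numpy()
        G /= G.std(axis=0)
        C = update_loadings(G, ds, ps)
        for j in range(3):
            expected = np.mean(ds.values[:, j] * G[:, 0])
            assert C[j, 0] == pytest.approx(expected, rel=1e-10)


class TestWeightUpdate:
    def test_single_indicator_fixed(self, rng):
        spec = build_model([("s", ["x"]), ("t", ["y"])], paths=[("s", "t")])
        ds = standardize(Dataset(rng.normal(size=(40, 2)), spec.observed))
        ps = pattern_matrices(spec, ds.column_names)
        ps.B[1, 0] = 0.4
        out = update_weights(ps, ds)
        assert out.W[0, 0] == 1.0 and out.W[1, 1] == 1.0

    def test_principal_axis_without_paths(self, rng):
        # with no structural paths the converged weights are the leading
        # eigenvector direction of the indicator block covariance
        spec = build_model([("c", ["x1", "x2", "x3"])])
        X = rng.normal(size=(200, 3)) @ np.diag([2.0, 1.0, 0.5])
        ds = standardize(Dataset(X @ np.array([[1, .5, 0], [0, 1, .3], [0, 0, 1.0]]),
                                 spec.observed))
        res = fit(ds, spec, PenaltyConfig(0.0, 2), tol=1e-12, max_iter=500)
        S = ds.values.T @ ds.values / ds.N
        evals, evecs = np.linalg.eigh(S)
        v = evecs[:, -1]
        w = res.params.W[0]
        cos = abs(w @ v) / np.linalg.norm(w)
        assert cos == pytest.approx(1.0, abs=1e-7)

    def test_unit_variance_after_update(self, interaction_spec, interaction_data, rng):
        ps = pattern_matrices(interaction_spec, interaction_data.column_names)
        ps.W[ps.w_free] = rng.normal(size=int(ps.w_free.sum()))
        ps.C[ps.c_free] = 0.5
        ps.B[ps.b_free] = 0.2
        out = update_weights(ps, interaction_data, PenaltyConfig(1.0, 2))
        G = compute_scores(out, interaction_data).to_numpy()
        np.testing.assert_allclose((G**2).sum(axis=0) / interaction_data.N,
                                   np.ones(G.shape[1]), atol=1e-10)


class TestFit:
    def test_exact_data_recovers_truth(self):
        ds, spec, truth = exact_prototype()
        res = fit(ds, spec, PenaltyConfig(0.0, 2), init_seed=11,
                  tol=1e-14, max_iter=2000)
        assert res.converged
        np.testing.assert_allclose(res.params.W, truth.W, atol=1e-6)
        np.testing.assert_allclose(res.params.C, truth.C, atol=1e-6)
        np.testing.assert_allclose(res.params.B, truth.B, atol=1e-6)

    def test_exact_data_r2(self):
        # the outcome is a noiseless combination of its ROI predictors, so
        # its R^2 is exactly 1; the first ROI equation carries a structural
        # residual of variance (0.5/scale)^2 on an exactly orthogonal
        # direction, with scale^2 = 0.6^2 + 0.5^2 + 0.5^2
        ds, spec, _ = exact_prototype()
        res = fit(ds, spec, PenaltyConfig(0.0, 2), tol=1e-12, max_iter=2000)
        assert res.r2["behavior"] == pytest.approx(1.0, abs=1e-8)
        assert res.r2["roi1"] == pytest.approx(1.0 - 0.25 / 0.86, abs=1e-6)

    def test_r2_near_zero_for_unrelated_predictors(self, rng):
        spec = build_model([("a", ["x"]), ("b", ["y"])], paths=[("a", "b")])
        N = 4000
        ds = standardize(Dataset(rng.normal(size=(N, 2)), spec.observed))
        res = fit(ds, spec)
        assert abs(res.r2["b"]) < 0.01

    def test_r2_matches_variance_ratio(self, prototype_spec, prototype_data):
        res = fit(prototype_data, prototype_spec, PenaltyConfig(3.0, 2))
        resid = res.structural_residuals
        for name in res.r2:
            direct = 1.0 - (resid[name] ** 2).sum() / res.N
            assert res.r2[name] == pytest.approx(direct, rel=1e-10)

    def test_all_single_indicator_equals_ols(self, rng):
        comps = [(f"c{i}", [f"x{i}"]) for i in range(5)]
        paths = [(f"c{i}", "c4") for i in range(3)] + [("c0", "c3")]
        spec = build_model(comps, paths=paths)
        ds = standardize(Dataset(rng.normal(size=(80, 5)), spec.observed))
        res = fit(ds, spec, PenaltyConfig(0.0, 2), tol=1e-12)
        Z = ds.values
        b4 = np.linalg.lstsq(Z[:, :3], Z[:, 4], rcond=None)[0]
        b3 = np.linalg.lstsq(Z[:, :1], Z[:, 3], rcond=None)[0]
        np.testing.assert_allclose(res.params.B[4, :3], b4, atol=1e-8)
        np.testing.assert_allclose(res.params.B[3, :1], b3, atol=1e-8)

    def test_criterion_path_non_increasing(self, interaction_spec, interaction_data):
        res = fit(interaction_data, interaction_spec, PenaltyConfig(2.0, 2),
                  init_seed=4)
        diffs = np.diff(res.criterion_path)
        assert (diffs <= 1e-8 * max(1.0, res.criterion_path[0])).all()

    def test_compressed_equals_uncompressed(self, interaction_spec, rng):
        X = rng.normal(size=(400, 7))
        ds = Dataset(X, interaction_spec.observed)
        a = fit(ds, interaction_spec, PenaltyConfig(3.0, 2), init_seed=5,
                compress="never")
        b = fit(ds, interaction_spec, PenaltyConfig(3.0, 2), init_seed=5,
                compress="always")
        assert a.criterion == pytest.approx(b.criterion, rel=1e-12)
        np.testing.assert_allclose(a.params.W, b.params.W, atol=1e-10)
        np.testing.assert_allclose(a.params.B, b.params.B, atol=1e-10)
        np.testing.assert_allclose(a.scores.to_numpy(), b.scores.to_numpy(),
                                   atol=1e-9)

    def test_non_convergence_flagged(self, prototype_spec, prototype_data):
        with pytest.warns(RuntimeWarning, match="did not converge"):
            res = fit(prototype_data, prototype_spec, tol=0.0, max_iter=2)
        assert not res.converged

    def test_sign_convention_positive_loading_sum(self, prototype_spec,
                                                  prototype_data):
        res = fit(prototype_data, prototype_spec, init_seed=9)
        for p, comp in enumerate(prototype_spec.components):
            if not comp.is_single:
                assert res.params.C[:, p].sum() > 0

    def test_sign_flip_is_involution(self, prototype_spec, prototype_data):
        res = fit(prototype_data, prototype_spec, init_seed=9)
        flips = np.array([1.0, -1.0, -1.0, 1.0, 1.0])
        flipped = apply_sign_flips(res.params, flips)
        back = apply_sign_flips(flipped, flips)
        np.testing.assert_allclose(back.W, res.params.W, atol=1e-14)
        np.testing.assert_allclose(back.B, res.params.B, atol=1e-14)
        # flipping leaves the criterion invariant
        a = evaluate_criterion(res.params, prototype_data, res.penalty)
        b = evaluate_criterion(flipped, prototype_data, res.penalty)
        assert a.phi == pytest.approx(b.phi, rel=1e-12)
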