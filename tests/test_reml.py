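"""REML correctness against closed forms and independent likelihood oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from epiarm.kinship import KinshipMatrix
from epiarm.reml import FitOptions, ModelSpec, blup_product, build_design, fit

import pandas as pd


def _genomic_kernel(n, n_markers, rng):
    calls = rng.integers(0, 2, size=(n, n_markers)) * 2.0
    p = calls.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    W = calls[:, poly] - 2 * p[poly]
    K = W @ W.T / (2 * np.sum(p[poly] * (1 - p[poly])))
    ids = tuple(f"L{i}" for i in range(n))
    return KinshipMatrix(ids, K, {"label": "g"})


def profiled_restricted_loglik_oracle(y, X, K):
    """Independent 1-D oracle: profile the restricted likelihood over the
    variance ratio via the eigendecomposition of K (one observation per line)."""
    n, p = X.shape
    w, U = np.linalg.eigh(K)
    yt, Xt = U.T @ y, U.T @ X

    def negll(lam):
        d = lam * w + 1.0
        inv = 1.0 / d
        B = Xt.T @ (inv[:, None] * Xt)
        beta = np.linalg.solve(B, Xt.T @ (inv * yt))
        r = yt - Xt @ beta
        Q = float(r @ (inv * r))
        s2 = Q / (n - p)
        return 0.5 * (
            (n - p) * np.log(2 * np.pi)
            + (n - p) * np.log(s2)
            + np.sum(np.log(d))
            + np.linalg.slogdet(B)[1]
            + (n - p)
        )

    res = minimize_scalar(negll, bounds=(1e-10, 1e4), method="bounded", options={"xatol": 1e-12})
    return -res.fun, res.x


class TestClosedForms:
    def test_fixed_effects_only_matches_ols_reml(self):
        rng = np.random.default_rng(0)
        n, p = 60, 3
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = X @ np.array([1.0, 2.0, -1.0]) + rng.standard_normal(n)
        ids = tuple(f"L{i}" for i in range(12))
        m = ModelSpec(y=y, X=X, line_index=np.arange(n) % 12, line_ids=ids, kernels={})
        f = fit(m)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        s2 = rss / (n - p)
        ll = -0.5 * (
            (n - p) * np.log(2 * np.pi)
            + (n - p) * np.log(s2)
            + np.linalg.slogdet(X.T @ X)[1]
            + (n - p)
        )
        assert f.variance_components["residual"] == pytest.approx(s2, rel=1e-8)
        assert f.logREML == pytest.approx(ll, abs=1e-8)

    def test_balanced_one_way_anova_oracle(self):
        """Identity kernel with r replicates per line: REML equals the
        classic mean-squares solution sigma_e = MSW, sigma_a = (MSB - MSW)/r."""
        rng = np.random.default_rng(1)
        m, r = 40, 4
        line_eff = rng.standard_normal(m) * 1.5
        y = np.repeat(line_eff, r) + rng.standard_normal(m * r)
        li = np.repeat(np.arange(m), r)
        ids = tuple(f"L{i}" for i in range(m))
        km = KinshipMatrix(ids, np.eye(m), {"label": "I"})
        f = fit(ModelSpec(y=y, X=np.ones((m * r, 1)), line_index=li, line_ids=ids, kernels={"a": km}))
        means = y.reshape(m, r).mean(axis=1)
        msw = float(np.sum((y.reshape(m, r) - means[:, None]) ** 2)) / (m * (r - 1))
        msb = r * float(np.sum((means - means.mean()) ** 2)) / (m - 1)
        assert f.variance_components["residual"] == pytest.approx(msw, rel=1e-5)
        assert f.variance_components["a"] == pytest.approx((msb - msw) / r, rel=1e-4)

    def test_single_genomic_kernel_matches_profiled_oracle(self):
        rng = np.random.default_rng(2)
        n = 100
        km = _genomic_kernel(n, 80, rng)
        w, U = np.linalg.eigh(km.values)
        g = U @ (np.sqrt(np.clip(w, 0, None)) * rng.standard_normal(n))
        y = 2.0 + g + rng.standard_normal(n)
        X = np.ones((n, 1))
        f = fit(ModelSpec(y=y, X=X, line_index=np.arange(n), line_ids=km.line_ids, kernels={"g": km}))
        ll_star, lam_star = profiled_restricted_loglik_oracle(y, X, km.values)
        assert f.logREML == pytest.approx(ll_star, abs=1e-5)
        ratio = f.variance_components["g"] / f.variance_components["residual"]
        assert ratio == pytest.approx(lam_star, rel=1e-3)


class TestOptimizerProperties:
    def _toy_model(self, seed, n=80):
        rng = np.random.default_rng(seed)
        km = _genomic_kernel(n, 50, rng)
        w, U = np.linalg.eigh(km.values)
        g = U @ (np.sqrt(np.clip(w, 0, None)) * rng.standard_normal(n))
        y = g + rng.standard_normal(n)
        return ModelSpec(
            y=y, X=np.ones((n, 1)), line_index=np.arange(n), line_ids=km.line_ids,
            kernels={"g": km},
        )

    def test_em_iterations_never_decrease_loglik(self):
        f = fit(self._toy_model(3), FitOptions(use_ai=False, max_iter=300))
        h = np.asarray(f.history)
        assert np.all(np.diff(h) >= -1e-7)

    def test_accelerated_path_is_also_monotone(self):
        f = fit(self._toy_model(4))
        h = np.asarray(f.history)
        assert np.all(np.diff(h) >= -1e-7)

    def test_permutation_invariance(self):
        m = self._toy_model(5)
        f1 = fit(m)
        rng = np.random.default_rng(6)
        perm = rng.permutation(m.n_obs)
        m2 = ModelSpec(
            y=m.y[perm], X=m.X[perm], line_index=m.line_index[perm],
            line_ids=m.line_ids, kernels=m.kernels,
        )
        f2 = fit(m2)
        for k in f1.variance_components:
            assert f2.variance_components[k] == pytest.approx(
                f1.variance_components[k], abs=1e-8 * (1 + f1.variance_components[k])
            )

    def test_nested_model_never_fits_worse(self):
        rng = np.random.default_rng(7)
        n = 80
        k1 = _genomic_kernel(n, 50, rng)
        k2 = _genomic_kernel(n, 50, rng)
        w, U = np.linalg.eigh(k1.values)
        y = U @ (np.sqrt(np.clip(w, 0, None)) * rng.standard_normal(n)) + rng.standard_normal(n)
        X = np.ones((n, 1))
        base = dict(y=y, X=X, line_index=np.arange(n), line_ids=k1.line_ids)
        f_null = fit(ModelSpec(kernels={"a": k1}, **base))
        f_alt = fit(
            ModelSpec(kernels={"a": k1, "b": k2}, **base),
            FitOptions(init=f_null.variance_components),
        )
        assert f_alt.logREML >= f_null.logREML - 1e-6

    def test_null_genetic_variance_hits_boundary_with_zero_blups(self):
        rng = np.random.default_rng(8)
        n = 120
        km = _genomic_kernel(n, 60, rng)
        boundary_seen = 0
        for s in range(5):
            y = np.random.default_rng(100 + s).standard_normal(n)  # pure noise
            f = fit(ModelSpec(y=y, X=np.ones((n, 1)), line_index=np.arange(n),
                              line_ids=km.line_ids, kernels={"g": km}))
            if f.boundary_flags["g"]:
                boundary_seen += 1
                assert np.all(f.blups["g"] == 0.0)
                assert f.variance_components["g"] == 0.0
        assert boundary_seen >= 2  # boundary estimates are the common outcome

    def test_nonfinite_phenotype_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            ModelSpec(
                y=np.array([1.0, np.nan, 2.0]), X=np.ones((3, 1)),
                line_index=np.array([0, 1, 2]), line_ids=("a", "b", "c"), kernels={},
            )

    def test_mismatched_kernel_order_rejected(self):
        km = KinshipMatrix(("b", "a"), np.eye(2), {})
        with pytest.raises(ValueError, match="line ids"):
            ModelSpec(
                y=np.zeros(4), X=np.ones((4, 1)), line_index=np.array([0, 1, 0, 1]),
                line_ids=("a", "b"), kernels={"k": km},
            )


class TestDesignAndBlups:
    def test_build_design_environment_contrasts(self):
        pheno = pd.DataFrame(
            {
                "line_id": ["a", "b", "a", "c"],
                "env_id": ["E2", "E1", "E1", "E2"],
                "value": [1.0, 2.0, 3.0, 4.0],
            }
        )
        y, X, li = build_design(pheno, ["a", "b", "c"])
        assert X.shape == (4, 2)  # intercept + one contrast for E2
        np.testing.assert_array_equal(X[:, 1], [1.0, 0.0, 0.0, 1.0])
        np.testing.assert_array_equal(li, [0, 1, 0, 2])

    def test_blup_product_elementwise(self):
        from epiarm.reml import MixedModelFit

        f = MixedModelFit(
            variance_components={}, logREML=0.0,
            blups={"A:x": np.array([1.0, -2.0, 0.0]), "A:y": np.array([2.0, 1.0, 5.0])},
            converged=True, boundary_flags={}, n_iter=0,
            fixed_effects=np.zeros(1), line_ids=("a", "b", "c"),
        )
        np.testing.assert_array_equal(blup_product(f, "A:x", "A:y"), [2.0, -2.0, 0.0])
        rng = np.random.default_rng(0)
        u, v = rng.standard_normal(50), rng.standard_normal(50)
        f.blups = {"u": u, "v": v}
        loop = np.array([u[i] * v[i] for i in range(50)])
        np.testing.assert_allclose(blup_product(f, "u", "v"), loop)
        with pytest.raises(KeyError, match="no BLUP term"):
            blup_product(f, "u", "w")
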