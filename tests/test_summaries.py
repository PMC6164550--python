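"""Posterior summaries: HPD intervals, the dissimilarity surface, rate
profiles (including the Bray–Curtis contrast), depth-integrated
compositions and PCA of observation scores."""

import numpy as np
import pytest

from gradcoda.curves import PolySimplexCurve, rate_minimiser
from gradcoda.model import still_scores
from gradcoda.simplex import build_ilr_basis, closure
from gradcoda.summaries import (
    GridSummary,
    adjacent_dissimilarity_profile,
    bray_curtis,
    dissimilarity_surface,
    hpd_interval,
    integrated_composition,
    pca_scores,
    rate_profile,
)


class TestHpdInterval:
    def test_uniform_grid(self):
        lo, hi = hpd_interval(np.arange(1, 101, dtype=float), 0.95)
        assert hi - lo == 94.0  # 95 consecutive values

    def test_level_one_limit(self):
        x = np.random.default_rng(0).normal(size=200)
        lo, hi = hpd_interval(x, 0.9999)
        assert lo == x.min() and hi == x.max()

    def test_symmetric_unimodal_close_to_equal_tailed(self):
        x = np.random.default_rng(1).standard_normal(100_000)
        lo, hi = hpd_interval(x, 0.95)
        qlo, qhi = np.quantile(x, [0.025, 0.975])
        assert abs(lo - qlo) < 0.05 and abs(hi - qhi) < 0.05

    def test_shorter_than_equal_tailed_when_skewed(self):
        x = np.random.default_rng(2).exponential(size=50_000)
        lo, hi = hpd_interval(x, 0.9)
        qlo, qhi = np.quantile(x, [0.05, 0.95])
        assert (hi - lo) < (qhi - qlo)
        assert lo < qlo  # mass shifts toward the mode at zero

    def test_matches_arviz(self):
        import arviz as az

        x = np.random.default_rng(3).normal(size=5000)
        lo, hi = hpd_interval(x, 0.95)
        ref = az.hdi(x, hdi_prob=0.95)
        assert abs(lo - ref[0]) < 0.01 and abs(hi - ref[1]) < 0.01

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            hpd_interval([1.0, 2.0], 0.9)


def _curve_set(seed, n_curves=200, s=4, degree=2, center=1.9, scale=1.05):
    r = np.random.default_rng(seed)
    basis = build_ilr_basis(s)
    mean = r.standard_normal((degree + 1, s - 1))
    return [
        PolySimplexCurve(
            mean + 0.1 * r.standard_normal(mean.shape), basis, center, scale
        )
        for _ in range(n_curves)
    ]


class TestDissimilaritySurface:
    def test_diagonal_exactly_zero_and_symmetric(self):
        curves = _curve_set(0)
        grid = np.linspace(0.11, 3.72, 30)
        surf = dissimilarity_surface(curves, grid)
        assert np.all(np.diag(surf["mean"]) == 0.0)
        assert np.allclose(surf["mean"], surf["mean"].T)
        assert np.allclose(surf["hpd_width"], surf["hpd_width"].T)

    def test_factorized_identity_per_draw(self):
        # surface entries satisfy |z1-z2|·||b1+(z1+z2)b2|| for each draw
        curves = _curve_set(1, n_curves=20)
        grid = np.linspace(0.5, 3.5, 10)
        surf = dissimilarity_surface(curves, grid)
        c = curves[0]
        zg = c.to_z(grid)
        manual = np.zeros((10, 10))
        for cur in curves:
            for i in range(10):
                for j in range(10):
                    manual[i, j] += abs(zg[i] - zg[j]) * np.linalg.norm(
                        cur.beta[1] + (zg[i] + zg[j]) * cur.beta[2]
                    )
        manual /= len(curves)
        assert np.allclose(surf["mean"], manual, atol=1e-10)

    def test_local_monotonicity_near_diagonal(self):
        curves = _curve_set(2)
        grid = np.linspace(0.11, 3.72, 40)
        mean = dissimilarity_surface(curves, grid)["mean"]
        # moving one step further from the diagonal increases dissimilarity
        for i in range(5, 35):
            assert mean[i, i + 1] < mean[i, i + 2] < mean[i, i + 3]

    def test_collinear_truth_zero_counterdiagonal(self):
        basis = build_ilr_basis(4)
        r = np.random.default_rng(3)
        b1 = np.array([1.0, -0.6, 0.4])
        c = -0.45
        curves = [
            PolySimplexCurve(
                np.vstack([r.normal(0, 0.1, 3), b1, c * b1]), basis, 0.0, 1.0
            )
            for _ in range(50)
        ]
        z1 = 0.7
        z2 = -1.0 / c - z1
        surf_val = [
            abs(z1 - z2)
            * np.linalg.norm(cur.beta[1] + (z1 + z2) * cur.beta[2])
            for cur in curves
        ]
        assert max(surf_val) < 1e-12


class TestRateProfile:
    def test_flat_for_linear_curves(self):
        curves = _curve_set(4, degree=1)
        grid = np.linspace(0.11, 3.72, 20)
        prof = rate_profile(curves, grid)
        traces = prof["traces"]
        assert np.allclose(traces, traces[:, :1])
        assert np.all(traces >= 0)

    def test_quadratic_minimiser_closed_form(self):
        curves = _curve_set(5, n_curves=50)
        grid = np.linspace(0.11, 3.72, 200)
        prof = rate_profile(curves, grid)
        for m in (0, 17, 33):
            c = curves[m]
            zstar = rate_minimiser(c)
            expect_depth = zstar * c.z_scale + c.z_center
            assert np.isclose(prof["minimiser_depths"][m], expect_depth, atol=1e-9)

    def test_per_metre_chain_rule(self):
        curves = _curve_set(6)
        grid = np.linspace(0.11, 3.72, 10)
        per_m = rate_profile(curves, grid, per_metre=True)["traces"]
        per_z = rate_profile(curves, grid, per_metre=False)["traces"]
        assert np.allclose(per_m * curves[0].z_scale, per_z)

    def test_summary_bounds_contain_mean(self):
        curves = _curve_set(7)
        grid = np.linspace(0.11, 3.72, 15)
        s = rate_profile(curves, grid)["summary"]
        assert isinstance(s, GridSummary)
        assert np.all(s.hpd_lower <= s.mean) and np.all(s.mean <= s.hpd_upper)


class TestIntegratedComposition:
    def test_constant_truth_recovers_intercept(self):
        basis = build_ilr_basis(4)
        beta = np.vstack([[0.5, -0.3, 0.2], [0, 0, 0], [0, 0, 0]])
        curves = [PolySimplexCurve(beta, basis, 1.9, 1.0)] * 20
        res = integrated_composition(curves, 0.11, 3.72)
        from gradcoda.simplex import ilr_inv

        assert np.allclose(res["mean"], ilr_inv(beta[0], basis).parts, atol=1e-12)

    def test_parts_sum_to_one(self):
        curves = _curve_set(8)
        res = integrated_composition(curves, 0.11, 3.72)
        assert np.allclose(res["draws"].sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(res["mean"].sum(), 1.0, atol=1e-10)

    def test_quadrature_oracle_per_draw(self):
        from scipy.integrate import simpson

        curves = _curve_set(9, n_curves=5)
        S, D = 0.3, 3.5
        res = integrated_composition(curves, S, D)
        zs = np.linspace(S, D, 1001)
        for m, c in enumerate(curves):
            coords = np.stack([c.coords(c.to_z(d)) for d in zs])
            mean_coords = simpson(coords, x=zs, axis=0) / (D - S)
            from gradcoda.simplex import ilr_inv

            expect = ilr_inv(mean_coords, c.basis).parts
            assert np.allclose(res["draws"][m], expect, atol=1e-8)

    def test_bad_interval(self):
        with pytest.raises(ValueError):
            integrated_composition(_curve_set(0, n_curves=2), 3.0, 1.0)


class TestBrayCurtis:
    def test_identity_and_direct_value(self):
        a = closure([2, 1, 1])
        b = closure([1, 1, 2])
        assert bray_curtis(a, a) == 0.0
        assert np.isclose(bray_curtis(a, b), 0.25)

    def test_disjoint_support_limit(self):
        a = closure([1 - 2e-9, 1e-9, 1e-9])
        b = closure([1e-9, 1 - 2e-9, 1e-9])
        assert bray_curtis(a, b) > 0.999

    def test_not_perturbation_invariant(self):
        from gradcoda.simplex import perturb

        a, b, p = closure([2, 1, 1]), closure([1, 1, 2]), closure([10, 1, 1])
        assert not np.isclose(
            bray_curtis(a, b), bray_curtis(perturb(p, a), perturb(p, b))
        )


class TestAdjacentProfile:
    def test_quadratic_profile_equals_rate_at_midpoints(self):
        # for quadratic curves the chord between consecutive grid points
        # equals the spacing times the derivative at the midpoint, exactly
        curves = _curve_set(10, n_curves=30)
        lo, hi = 0.11, 3.72
        prof = adjacent_dissimilarity_profile(curves, np.linspace(lo, hi, 100))
        spacing = (hi - lo) / 99
        rate = rate_profile(curves, prof.grid, per_metre=True)
        assert np.allclose(prof.mean / spacing, rate["summary"].mean, atol=1e-10)

    def test_cubic_profile_converges_to_rate(self):
        curves = _curve_set(12, n_curves=20, degree=3)
        lo, hi = 0.11, 3.72
        errs = []
        for G in (100, 1000):
            prof = adjacent_dissimilarity_profile(curves, np.linspace(lo, hi, G))
            spacing = (hi - lo) / (G - 1)
            rate = rate_profile(curves, prof.grid, per_metre=True)
            errs.append(np.abs(prof.mean / spacing - rate["summary"].mean).max())
        assert errs[1] < errs[0] / 5  # refining the grid shrinks the gap

    def test_constant_truth_zero_under_both_metrics(self):
        basis = build_ilr_basis(3)
        curves = [
            PolySimplexCurve(np.vstack([[0.4, 0.1], [0, 0], [0, 0]]), basis)
        ] * 15
        grid = np.linspace(0.11, 3.72, 30)
        for metric in ("aitchison", "bray_curtis"):
            prof = adjacent_dissimilarity_profile(curves, grid, metric=metric)
            assert np.allclose(prof.mean, 0.0, atol=1e-14)

    def test_metrics_can_disagree_on_ranking(self):
        # a rare part changing fast dominates the Aitchison rate but barely
        # moves Bray-Curtis; an abundant slow part does the opposite
        basis = build_ilr_basis(3)
        beta = np.vstack([[3.0, 0.0], [0.0, 2.0], [0.0, 0.0]])
        curves = [PolySimplexCurve(beta, basis, 0.0, 1.0)] * 10
        grid = np.linspace(-2.0, 2.0, 50)
        ait = adjacent_dissimilarity_profile(curves, grid, metric="aitchison")
        bc = adjacent_dissimilarity_profile(curves, grid, metric="bray_curtis")
        assert np.argmax(ait.mean) != np.argmax(bc.mean)


class TestPcaScores:
    def test_collinear_rows_one_component(self):
        t = np.linspace(0, 1, 30)
        X = np.outer(t, [1.0, 2.0, -1.0])
        res = pca_scores(X)
        assert res["explained_variance_ratio"][0] > 0.999

    def test_rotation_invariance_of_explained_variance(self, rng):
        X = rng.standard_normal((40, 5))
        Q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        r1 = pca_scores(X)["explained_variance_ratio"]
        r2 = pca_scores(X @ Q)["explained_variance_ratio"]
        assert np.allclose(r1, r2, atol=1e-10)

    def test_sign_convention_deterministic(self, rng):
        X = rng.standard_normal((30, 4))
        res = pca_scores(X)
        comps = res["loadings"]
        for row in comps:
            assert row[np.argmax(np.abs(row))] > 0

    def test_depth_gradient_shows_on_pc1(self, dock_fit):
        scores = still_scores(dock_fit["draws"])
        res = pca_scores(scores)
        r = np.corrcoef(res["scores"][:, 0], dock_fit["table"].covariate)[0, 1]
        assert abs(r) > 0.9


class TestBasisInvarianceOfSummaries:
    def test_rotated_basis_same_summaries(self):
        from gradcoda.simplex import random_orthonormal_basis

        curves = _curve_set(11, n_curves=40, s=5)
        other = random_orthonormal_basis(5, np.random.default_rng(0))
        R = other.contrast_matrix.T @ curves[0].basis.contrast_matrix
        rotated = [
            PolySimplexCurve(c.beta @ R.T, other, c.z_center, c.z_scale)
            for c in curves
        ]
        grid = np.linspace(0.11, 3.72, 25)
        s1 = dissimilarity_surface(curves, grid)
        s2 = dissimilarity_surface(rotated, grid)
        assert np.allclose(s1["mean"], s2["mean"], atol=1e-8)
        assert np.allclose(s1["hpd_width"], s2["hpd_width"], atol=1e-8)
        r1 = rate_profile(curves, grid)["summary"]
        r2 = rate_profile(rotated, grid)["summary"]
        assert np.allclose(r1.mean, r2.mean, atol=1e-8)
        i1 = integrated_composition(curves, 0.11, 3.72)
        i2 = integrated_composition(rotated, 0.11, 3.72)
        assert np.allclose(i1["mean"], i2["mean"], atol=1e-8)
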