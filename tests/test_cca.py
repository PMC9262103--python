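import numpy as np
import pytest
from scipy import linalg as sla

from ddrcca import (
    DomainSpec,
    ReducedData,
    SubjectTable,
    canonical_loadings,
    fit_cca,
    make_domain_block,
    permutation_test,
    reduce_block_pca,
    run_cca_pipeline,
    varimax_rotate,
)
from ddrcca.cca import BlockPCA


def cca_oracle_correlations(X, Y):
    """Canonical correlations via the generalized eigenproblem."""
    N = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sxx = Xc.T @ Xc / (N - 1)
    Syy = Yc.T @ Yc / (N - 1)
    Sxy = Xc.T @ Yc / (N - 1)
    M = Sxy @ np.linalg.solve(Syy, Sxy.T)
    w = sla.eigh(M, Sxx, eigvals_only=True)
    rho = np.sqrt(np.clip(w, 0.0, 1.0))[::-1]
    return rho[: min(X.shape[1], Y.shape[1])]


def random_reduced(rng, n, k, label="blk"):
    comps = rng.standard_normal((n, k))
    return ReducedData(
        components=comps,
        factor_labels=[f"{label}::factor_{i + 1}" for i in range(k)],
        source=[],
    )


class TestFitCCA:
    def test_identical_blocks_give_unit_correlations(self, rng):
        X = rng.standard_normal((40, 3))
        model = fit_cca(X, X.copy())
        np.testing.assert_allclose(model.correlations, 1.0, atol=1e-8)

    def test_univariate_equals_pearson(self, rng):
        x = rng.standard_normal((100, 1))
        y = 0.5 * x + rng.standard_normal((100, 1))
        model = fit_cca(x, y)
        r = abs(np.corrcoef(x[:, 0], y[:, 0])[0, 1])
        assert model.correlations[0] == pytest.approx(r, abs=1e-10)

    def test_matches_generalized_eigen_oracle(self, rng):
        X = rng.standard_normal((50, 3))
        Y = rng.standard_normal((50, 4))
        model = fit_cca(X, Y)
        np.testing.assert_allclose(
            model.correlations, cca_oracle_correlations(X, Y), atol=1e-8
        )

    def test_canonical_variable_properties(self, rng):
        X = rng.standard_normal((60, 3))
        Y = rng.standard_normal((60, 4))
        model = fit_cca(X, Y)
        for i in range(model.m):
            r = np.corrcoef(model.variables_P[:, i], model.variables_Q[:, i])[0, 1]
            assert r == pytest.approx(model.correlations[i], abs=1e-8)
        # within-block canonical variables mutually uncorrelated
        cp = np.corrcoef(model.variables_P, rowvar=False)
        assert np.abs(cp - np.eye(model.m)).max() < 1e-6
        assert np.all(np.diff(model.correlations) <= 1e-12)

    def test_rank_deficient_block_advises_reduction(self, rng):
        X = rng.standard_normal((30, 3))
        X = np.column_stack([X, X[:, 0]])  # exact collinearity
        with pytest.raises(np.linalg.LinAlgError, match="reduce its dimension"):
            fit_cca(X, rng.standard_normal((30, 2)))

    def test_block_swap_symmetry(self, rng):
        X = rng.standard_normal((50, 3))
        Y = rng.standard_normal((50, 4))
        np.testing.assert_allclose(
            fit_cca(X, Y).correlations, fit_cca(Y, X).correlations, atol=1e-10
        )


class TestReduceBlockPCA:
    def test_full_dimension_is_invariant_reexpression(self, rng):
        red = random_reduced(rng, 60, 4)
        Y = rng.standard_normal((60, 3))
        scores = reduce_block_pca(red, 4)
        r1 = fit_cca(red.components, Y).correlations
        r2 = fit_cca(scores, Y).correlations
        np.testing.assert_allclose(r1, r2, atol=1e-8)

    def test_exact_rank_reconstruction(self, rng):
        basis = rng.standard_normal((2, 5))
        comps = rng.standard_normal((40, 2)) @ basis
        red = ReducedData(comps, [f"f{i}" for i in range(5)], [])
        pca = BlockPCA(2).fit(comps)
        back = pca.transform(comps) @ pca.components_.T + pca.mean_
        np.testing.assert_allclose(back, comps, atol=1e-8)

    def test_variance_ordering(self, rng):
        red = random_reduced(rng, 80, 6)
        pca = BlockPCA(6).fit(red.components)
        assert np.all(np.diff(pca.singular_values_) <= 1e-12)


class TestCanonicalLoadings:
    def test_perfect_loading_is_one(self, rng):
        X = rng.standard_normal((80, 2))
        Y = np.column_stack([X[:, 0] * 2.0, rng.standard_normal(80)])
        model = fit_cca(X, Y)
        obs = SubjectTable(Y, ["match", "noise"],
                           [f"s{i}" for i in range(80)])
        ls = canonical_loadings(model, obs, Y, side="y")
        assert abs(ls.observed_loadings[0, 0]) > 0.99

    def test_sign_flip_flips_only_that_row(self, rng):
        X = rng.standard_normal((60, 2))
        Y = rng.standard_normal((60, 3))
        model = fit_cca(X, Y)
        obs = SubjectTable(Y.copy(), ["a", "b", "c"],
                           [f"s{i}" for i in range(60)])
        ls = canonical_loadings(model, obs, Y, side="y")
        flipped = SubjectTable(Y * np.array([1.0, -1.0, 1.0]), ["a", "b", "c"],
                               [f"s{i}" for i in range(60)])
        ls2 = canonical_loadings(model, flipped, Y, side="y")
        np.testing.assert_allclose(ls2.observed_loadings[1],
                                   -ls.observed_loadings[1], atol=1e-12)
        np.testing.assert_allclose(ls2.observed_loadings[0],
                                   ls.observed_loadings[0], atol=1e-12)

    def test_ve_limit_one_informative_variable(self, rng):
        # variable 1 equals the canonical variable; P-1 orthogonal noise
        # variables: VE -> 100/P as N grows
        N, P = 5000, 8
        X = rng.standard_normal((N, 2))
        Y = rng.standard_normal((N, 2))
        Y[:, 0] = X[:, 0] + 0.05 * rng.standard_normal(N)
        model = fit_cca(X, Y)
        obs_vals = np.column_stack(
            [model.variables_Q[:, 0], rng.standard_normal((N, P - 1))]
        )
        obs = SubjectTable(obs_vals, [f"v{i}" for i in range(P)],
                           [f"s{i}" for i in range(N)])
        ls = canonical_loadings(model, obs, Y, side="y")
        assert ls.ve_pct[0] == pytest.approx(100.0 / P, rel=0.15)

    def test_zero_variance_variable_warns_and_zeroes(self, rng):
        X = rng.standard_normal((40, 2))
        Y = rng.standard_normal((40, 2))
        model = fit_cca(X, Y)
        obs_vals = np.column_stack([np.full(40, 3.0), Y[:, 0]])
        obs = SubjectTable(obs_vals, ["flat", "ok"],
                           [f"s{i}" for i in range(40)])
        with pytest.warns(UserWarning, match="zero-variance"):
            ls = canonical_loadings(model, obs, Y, side="y")
        np.testing.assert_array_equal(ls.observed_loadings[0], 0.0)


class TestPermutationTest:
    def test_pvalue_lower_bound(self, rng):
        X = rng.standard_normal((50, 2))
        res = permutation_test(X, X.copy(), n_perm=99, rng_seed=0)
        assert np.all(res.p_values >= 1.0 / 100.0)
        assert res.p_values[0] == pytest.approx(1.0 / 100.0)
        assert res.n_significant >= 1

    def test_pvalues_non_decreasing(self, rng):
        X = rng.standard_normal((80, 3))
        Y = 0.5 * X + rng.standard_normal((80, 3))
        res = permutation_test(X, Y, n_perm=99, rng_seed=1)
        assert np.all(np.diff(res.p_values) >= 0)

    def test_unequal_blocks_need_within_scheme(self, rng):
        X = rng.standard_normal((30, 2))
        Y = rng.standard_normal((30, 2))
        blocks = np.array([0] * 10 + [1] * 20)
        with pytest.raises(ValueError, match="within"):
            permutation_test(X, Y, n_perm=19, blocks=blocks, rng_seed=0)
        res = permutation_test(X, Y, n_perm=19, blocks=blocks, scheme="within",
                               rng_seed=0)
        assert res.n_perm == 19

    def test_block_exchange_keeps_blocks_whole(self, rng):
        X = rng.standard_normal((20, 2))
        Y = rng.standard_normal((20, 2))
        blocks = np.repeat(np.arange(5), 4)
        res = permutation_test(X, Y, n_perm=39, blocks=blocks, rng_seed=0)
        assert res.null_max_corr.shape == (39,)

    def test_independent_blocks_rarely_significant(self):
        rej = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            res = permutation_test(
                rng.standard_normal((100, 3)),
                rng.standard_normal((100, 3)),
                n_perm=99, alpha=0.05, rng_seed=seed,
            )
            rej += res.n_significant > 0
        assert rej <= 8  # ~5% expected


class TestRunCCAPipeline:
    def test_varimax_rotation_invariance(self, rng):
        spec = DomainSpec("d", 8, 3, signal_sd=(4.0, 3.0, 2.0), noise_sd=0.4)
        block, _ = make_domain_block(spec, 120, rng_seed=0)
        _, _, V = np.linalg.svd(block)
        scores = block @ V.T[:, :3]
        rotated_loadings, _ = varimax_rotate(V.T[:, :3])
        scores_rot = block @ rotated_loadings
        Y = rng.standard_normal((120, 4))
        r_plain = fit_cca(scores, Y).correlations
        r_rot = fit_cca(scores_rot, Y).correlations
        np.testing.assert_allclose(r_plain, r_rot, atol=1e-10)

    def test_invertible_transform_invariance(self, rng):
        X = rng.standard_normal((70, 3))
        Y = rng.standard_normal((70, 4))
        T = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        np.testing.assert_allclose(
            fit_cca(X, Y).correlations, fit_cca(X @ T, Y).correlations,
            atol=1e-10,
        )

    def test_nested_reduction_weakens_correlations(self, rng):
        red = random_reduced(rng, 100, 6)
        Y = rng.standard_normal((100, 4))
        r_full = fit_cca(reduce_block_pca(red, 6), Y).correlations
        r_small = fit_cca(reduce_block_pca(red, 3), Y).correlations
        # PCA-nested subspace: correlations weakly decrease per index
        assert np.all(r_small <= r_full[: r_small.size] + 1e-10)

    def test_pipeline_returns_consistent_objects(self, rng):
        red_x = random_reduced(rng, 90, 3, "sm")
        red_y = random_reduced(rng, 90, 5, "bm")
        model, loadings, perm = run_cca_pipeline(
            red_x, red_y, bm_target_dim=4, n_perm=49, rng_seed=0
        )
        assert model.m == 3
        assert loadings["sm"].factor_loadings.shape == (3, 3)
        assert loadings["bm"].factor_loadings.shape == (5, 3)
        assert perm.p_values.shape == (3,)
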