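import numpy as np
import pytest

import ddrcca.ddr as ddr_mod
from ddrcca import (
    DomainPartition,
    DomainSpec,
    SubjectTable,
    estimate_dimension,
    loo_reconstruct,
    make_domain_block,
    naive_press,
    null_eigenspectrum,
    project_heldout,
    run_ddr,
    svd_decompose,
    two_way_press,
    varimax_rotate,
)


def pinv_by_svd(M):
    """Independent pseudo-inverse for oracle checks."""
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    tol = max(M.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    inv = np.where(s > tol, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    return Vt.T @ np.diag(inv) @ U.T


def loo_oracle(X_out, V, k, j):
    """Brute-force leave-one-variable-out reconstruction, built from scratch."""
    Vk = V[:, :k]
    V_mj = np.delete(Vk, j, axis=0)
    X_mj = np.delete(X_out, j, axis=1)
    X_tilde = X_mj @ pinv_by_svd(V_mj.T) @ Vk.T
    return X_tilde[:, j]


class TestSVDDecompose:
    def test_identity_singular_values(self):
        U_pc, s, V = svd_decompose(np.eye(3))
        np.testing.assert_allclose(s, [1.0, 1.0, 1.0], atol=1e-12)

    def test_rank_one_closed_form(self, rng):
        u = rng.standard_normal(6)
        v = rng.standard_normal(4)
        _, s, _ = svd_decompose(np.outer(u, v))
        assert s[0] == pytest.approx(np.linalg.norm(u) * np.linalg.norm(v))
        assert np.all(s[1:] < 1e-10)

    def test_reconstruction_identity(self, rng):
        block = rng.standard_normal((6, 4))
        U_pc, s, V = svd_decompose(block)
        assert np.linalg.norm(block - U_pc @ V.T) < 1e-8
        # U_PC = block @ V and V has orthonormal columns
        np.testing.assert_allclose(U_pc, block @ V, atol=1e-10)
        np.testing.assert_allclose(V.T @ V, np.eye(4), atol=1e-10)


class TestNaivePress:
    def test_full_basis_reconstructs_exactly(self, rng):
        X = rng.standard_normal((5, 3))
        _, _, V = svd_decompose(rng.standard_normal((10, 3)))
        assert naive_press(X, V) == pytest.approx(0.0, abs=1e-16)

    def test_rows_in_span_give_zero(self, rng):
        V1 = np.array([[1.0], [0.0]])
        X = np.array([[2.0, 0.0], [-3.0, 0.0]])
        assert naive_press(X, V1) == pytest.approx(0.0)

    def test_hand_example(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        V1 = np.array([[1.0], [0.0]])
        assert naive_press(X, V1) == pytest.approx(1.0)

    def test_projection_first_k_identity_columns(self, rng):
        X = rng.standard_normal((4, 5))
        Vk = np.eye(5)[:, :2]
        np.testing.assert_allclose(project_heldout(X, Vk), X[:, :2])


class TestLooReconstruct:
    def test_noiseless_low_rank_recovered(self, rng):
        k = 2
        scores = rng.standard_normal((8, k))
        V = np.linalg.qr(rng.standard_normal((5, 5)))[0]
        X_out = scores @ V[:, :k].T
        for j in range(5):
            pred = loo_reconstruct(X_out, V, k, j)
            np.testing.assert_allclose(pred, X_out[:, j], atol=1e-6)

    def test_hand_pseudo_inverse_p2(self):
        V = np.array([[1 / np.sqrt(2)], [1 / np.sqrt(2)]])
        X_out = np.array([[1.0, 1.0]])
        pred = loo_reconstruct(X_out, V, 1, 0)
        assert pred[0] == pytest.approx(1.0)

    def test_prediction_ignores_own_column(self, rng):
        X_out = rng.standard_normal((6, 5))
        V = np.linalg.qr(rng.standard_normal((5, 5)))[0]
        base = loo_reconstruct(X_out, V, 2, 3)
        X_mod = X_out.copy()
        X_mod[:, 3] = 999.0
        np.testing.assert_array_equal(loo_reconstruct(X_mod, V, 2, 3), base)

    def test_k_equal_p_rejected(self, rng):
        X = rng.standard_normal((4, 3))
        V = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        with pytest.raises(ValueError, match="k must be"):
            loo_reconstruct(X, V, 3, 0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            X_out = rng.standard_normal((10, 5))
            V = np.linalg.qr(rng.standard_normal((5, 5)))[0]
            k = int(rng.integers(1, 5))
            j = int(rng.integers(0, 5))
            np.testing.assert_allclose(
                loo_reconstruct(X_out, V, k, j),
                loo_oracle(X_out, V, k, j),
                atol=1e-10,
            )


class TestTwoWayPress:
    def test_noiseless_rank_one_chooses_one(self, rng):
        scores = rng.standard_normal((60, 1))
        V = np.linalg.qr(rng.standard_normal((6, 1)))[0]
        block = scores @ V.T
        curve = two_way_press(block, n_folds=5, rng_seed=0)
        assert curve.chosen_k == 1

    def test_pure_noise_mostly_chooses_one(self):
        hits = 0
        for seed in range(20):
            block = np.random.default_rng(seed).standard_normal((60, 6))
            curve = two_way_press(block, n_folds=5, rng_seed=seed)
            hits += curve.chosen_k == 1
        assert hits > 10

    def test_naive_curve_non_increasing(self, rng):
        spec = DomainSpec("d", 8, 2, signal_sd=(3.0, 2.0), noise_sd=0.5)
        block, _ = make_domain_block(spec, 50, rng_seed=3)
        curve = two_way_press(block, n_folds=5, rng_seed=1)
        assert np.all(np.diff(curve.naive_press) <= 1e-9)

    def test_press_interior_minimum_on_signal(self):
        spec = DomainSpec("d", 10, 3, signal_sd=(4.0, 3.0, 2.0), noise_sd=0.5)
        block, _ = make_domain_block(spec, 200, rng_seed=5)
        curve = two_way_press(block, n_folds=5, rng_seed=2)
        assert curve.chosen_k == 3
        assert curve.press[-1] > curve.press[curve.chosen_k - 1]

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            two_way_press(rng.standard_normal((8, 4)), n_folds=5)

    def test_column_sign_flips_leave_curve_unchanged(self):
        spec = DomainSpec("d", 8, 2, signal_sd=(3.0, 2.0), noise_sd=0.5)
        block, _ = make_domain_block(spec, 80, rng_seed=9)
        flipped = block * np.array([1, -1, 1, -1, -1, 1, 1, -1])
        c1 = two_way_press(block, n_folds=5, rng_seed=4)
        c2 = two_way_press(flipped, n_folds=5, rng_seed=4)
        np.testing.assert_allclose(c1.press, c2.press, rtol=1e-9)
        assert c1.chosen_k == c2.chosen_k


class TestEstimateDimension:
    def test_single_repeat_matches_single_run(self):
        spec = DomainSpec("d", 8, 2, signal_sd=(3.0, 2.0), noise_sd=0.5)
        block, _ = make_domain_block(spec, 100, rng_seed=1)
        k, votes = estimate_dimension(block, n_folds=5, n_repeats=1, rng_seed=42)
        assert k == two_way_press(block, n_folds=5, rng_seed=42).chosen_k
        assert votes == {k: 1}

    def test_unanimous_votes(self):
        spec = DomainSpec("d", 8, 2, signal_sd=(5.0, 4.0), noise_sd=0.3)
        block, _ = make_domain_block(spec, 150, rng_seed=2)
        k, votes = estimate_dimension(block, n_folds=5, n_repeats=6, rng_seed=0)
        assert sum(votes.values()) == 6
        assert votes.get(k, 0) == max(votes.values())

    def test_tie_breaks_to_smallest(self, monkeypatch):
        results = iter([2, 3, 3, 2])

        class FakeCurve:
            def __init__(self, k):
                self.chosen_k = k

        monkeypatch.setattr(
            ddr_mod, "two_way_press", lambda *a, **kw: FakeCurve(next(results))
        )
        k, votes = ddr_mod.estimate_dimension(np.zeros((20, 4)), n_repeats=4)
        assert votes == {2: 2, 3: 2}
        assert k == 2


class TestVarimax:
    @staticmethod
    def normalized_criterion(L):
        h = np.sqrt((L**2).sum(axis=1))
        A = L / np.where(h > 0, h, 1.0)[:, None]
        return float((A**2).var(axis=0).sum())

    def test_simple_structure_preserved(self):
        L = np.array([[0.9, 0.0], [0.8, 0.0], [0.0, 0.7], [0.0, 0.6]])
        rotated, R = varimax_rotate(L)
        # already maximally simple: rotation is a signed permutation
        perm = np.abs(R).argmax(axis=0)
        assert sorted(perm.tolist()) == [0, 1]
        for c, i in enumerate(perm):
            np.testing.assert_allclose(np.abs(rotated[:, c]), np.abs(L[:, i]),
                                       atol=1e-6)

    def test_k1_sign_rule(self):
        L = np.array([[-0.9], [0.2]])
        rotated, R = varimax_rotate(L)
        assert R[0, 0] == -1.0
        assert rotated[0, 0] == 0.9

    def test_criterion_not_decreased_and_R_orthogonal(self, rng):
        L = rng.standard_normal((8, 3))
        rotated, R = varimax_rotate(L)
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-8)
        np.testing.assert_allclose(rotated, L @ R, atol=1e-12)
        assert self.normalized_criterion(rotated) >= (
            self.normalized_criterion(L) - 1e-10
        )

    def test_matches_grid_search_oracle_k2(self, rng):
        L = rng.standard_normal((8, 2))
        rotated, _ = varimax_rotate(L)
        best = -np.inf
        h = np.sqrt((L**2).sum(axis=1))
        A = L / h[:, None]
        for theta in np.arange(0.0, 90.0, 0.1) * np.pi / 180.0:
            Rt = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            best = max(best, float(((A @ Rt) ** 2).var(axis=0).sum()))
        assert self.normalized_criterion(rotated) >= best - 1e-4

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            varimax_rotate(np.array([[np.nan], [1.0]]))


class TestRunDDR:
    def make_table(self, blocks, labels):
        values = np.hstack(blocks)
        names, mapping = [], {}
        for b, (block, label) in enumerate(zip(blocks, labels)):
            for v in range(block.shape[1]):
                name = f"{label}_v{v}"
                names.append(name)
                mapping[name] = label
        table = SubjectTable(values, names,
                             [f"s{i}" for i in range(values.shape[0])])
        return table, DomainPartition(mapping)

    def test_two_rank_one_domains_give_two_factors(self, rng):
        blocks = []
        for seed in (1, 2):
            spec = DomainSpec("d", 6, 1, signal_sd=(4.0,), noise_sd=0.3)
            block, _ = make_domain_block(spec, 120, rng_seed=seed)
            blocks.append(block)
        table, part = self.make_table(blocks, ["a", "b"])
        reduced = run_ddr(table, part, n_repeats=3, rng_seed=0)
        assert reduced.components.shape == (120, 2)
        assert reduced.factor_labels == ["a::factor_1", "b::factor_1"]

    def test_single_variable_domain_passthrough(self, rng):
        col = rng.standard_normal((50, 1))
        other = rng.standard_normal((50, 4))
        table, part = self.make_table([col, other], ["solo", "grp"])
        reduced = run_ddr(table, part, n_repeats=2, rng_seed=0)
        solo = reduced.source[0]
        assert solo.chosen_k == 1
        np.testing.assert_allclose(
            np.abs(reduced.components[:, 0]), np.abs(col[:, 0]), atol=1e-12
        )

    def test_rotated_components_span_unrotated_scores(self, rng):
        spec = DomainSpec("d", 8, 3, signal_sd=(4.0, 3.0, 2.0), noise_sd=0.4)
        block, _ = make_domain_block(spec, 150, rng_seed=4)
        table, part = self.make_table([block], ["dom"])
        reduced = run_ddr(table, part, n_repeats=3, rng_seed=0)
        red = reduced.source[0]
        scores = block @ red.loadings  # unrotated first-k scores
        # projection of rotated components onto unrotated score space is exact
        proj = scores @ np.linalg.lstsq(scores, red.rotated_components,
                                        rcond=None)[0]
        assert np.linalg.norm(proj - red.rotated_components) < 1e-8
        np.testing.assert_allclose(red.rotated_loadings,
                                   red.loadings @ red.rotation, atol=1e-10)
        np.testing.assert_allclose(red.rotation.T @ red.rotation, np.eye(red.chosen_k),
                                   atol=1e-8)

    def test_variance_explained_bounds(self, rng):
        spec = DomainSpec("d", 6, 2, signal_sd=(4.0, 2.0), noise_sd=0.5)
        block, _ = make_domain_block(spec, 100, rng_seed=8)
        table, part = self.make_table([block], ["dom"])
        reduced = run_ddr(table, part, n_repeats=3, rng_seed=0)
        assert 0 < reduced.source[0].variance_explained_pct <= 100

    def test_missing_values_rejected(self):
        table = SubjectTable(np.array([[1.0, np.nan], [2.0, 3.0]]),
                             ["a", "b"], ["s1", "s2"])
        with pytest.raises(ValueError, match="missing"):
            run_ddr(table, DomainPartition({"a": "d", "b": "d"}))


class TestNullEigenspectrum:
    def test_total_variance_preserved(self, rng):
        block = rng.standard_normal((60, 5))
        eig, null, _ = null_eigenspectrum(block, n_shuffles=20, rng_seed=0)
        assert eig.sum() == pytest.approx(null.sum(), abs=1e-8)

    def test_pure_noise_crosses_early(self):
        early = 0
        for seed in range(10):
            block = np.random.default_rng(seed).standard_normal((100, 6))
            _, _, crossing = null_eigenspectrum(block, n_shuffles=30,
                                                rng_seed=seed)
            early += crossing in (1, 2)
        assert early >= 7

    def test_strong_signal_crossing_near_rank(self):
        spec = DomainSpec("d", 10, 3, signal_sd=(5.0, 4.0, 3.0), noise_sd=0.5)
        block, _ = make_domain_block(spec, 250, rng_seed=0)
        _, _, crossing = null_eigenspectrum(block, n_shuffles=50, rng_seed=0)
        assert crossing is not None and abs(crossing - 3) <= 1
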