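import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mario import (
    CrossDistance,
    MarioParams,
    Matching,
    correlation_distance,
    denoise_shared,
    fit_cca,
    interpolate_and_select,
    laplacian_distance,
    match_pipeline,
    matching_accuracy,
    refine_distance,
    solve_assignment,
    sparsify,
)
from mario.simdata import population_labels


def brute_force_cost(d: np.ndarray) -> float:
    """Exhaustive minimum over all injections of rows into columns."""
    n, m = d.shape
    best = np.inf
    for cols in itertools.permutations(range(m), n):
        best = min(best, sum(d[i, c] for i, c in enumerate(cols)))
    return best


class TestDenoise:
    def test_full_rank_is_identity(self, rng):
        xs, ys = rng.normal(size=(6, 4)), rng.normal(size=(9, 4))
        den = denoise_shared(xs, ys, r_share=4)
        np.testing.assert_allclose(den.x_hat, xs, atol=1e-10)
        np.testing.assert_allclose(den.y_hat, ys, atol=1e-10)

    def test_rank_one_exact(self, rng):
        u = rng.normal(size=(10, 1))
        v = rng.normal(size=(1, 5))
        stack = u @ v
        den = denoise_shared(stack[:4], stack[4:], r_share=1)
        np.testing.assert_allclose(np.vstack([den.x_hat, den.y_hat]), stack, atol=1e-10)

    def test_matches_eckart_young_oracle(self, rng):
        xs, ys = rng.normal(size=(10, 4)), rng.normal(size=(15, 4))
        den = denoise_shared(xs, ys, r_share=2)
        stack = np.vstack([xs, ys])
        u, d, vt = np.linalg.svd(stack, full_matrices=False)
        best2 = (u[:, :2] * d[:2]) @ vt[:2]  # Frobenius-optimal rank-2
        np.testing.assert_allclose(np.vstack([den.x_hat, den.y_hat]), best2, atol=1e-10)

    def test_clip_warns(self, rng, caplog):
        den = denoise_shared(rng.normal(size=(5, 3)), rng.normal(size=(5, 3)), r_share=9)
        assert den.r_share == 3


class TestCorrelationDistance:
    def test_identical_rows_zero(self, rng):
        a = rng.normal(size=(4, 6))
        d = correlation_distance(a, a.copy())
        np.testing.assert_allclose(np.diag(d.values), 0.0, atol=1e-12)

    def test_negated_row_two(self, rng):
        a = rng.normal(size=(1, 6))
        a = a - a.mean()
        d = correlation_distance(a, -a)
        assert d.values[0, 0] == pytest.approx(2.0, abs=1e-12)

    def test_matches_per_pair_pearson(self, rng):
        a = rng.integers(0, 10, size=(3, 3)).astype(float)
        b = rng.integers(0, 10, size=(2, 3)).astype(float)
        d = correlation_distance(a, b)
        for i in range(3):
            for j in range(2):
                expected = 1 - np.corrcoef(a[i], b[j])[0, 1]
                assert d.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_too_few_features_errors(self):
        with pytest.raises(ValueError, match="Pearson"):
            correlation_distance(np.ones((2, 1)), np.ones((2, 1)))

    def test_flat_row_distance_one(self, rng):
        a = np.vstack([np.full(5, 3.0), rng.normal(size=5)])
        d = correlation_distance(a, rng.normal(size=(2, 5)))
        np.testing.assert_allclose(d.values[0], 1.0, atol=1e-12)


class TestLaplacianDistance:
    def test_identical_rows_zero(self, rng):
        a = rng.normal(size=(3, 4))
        d = laplacian_distance(a, a.copy(), bandwidth=1.0)
        np.testing.assert_allclose(np.diag(d.values), 0.0, atol=1e-12)

    def test_closed_form_toy(self):
        a = np.array([[0.0, 0.0]])
        b = np.array([[1.0, 1.0]])  # L1 distance 2
        d = laplacian_distance(a, b, bandwidth=1.0)
        assert d.values[0, 0] == pytest.approx(1 - np.exp(-2.0), abs=1e-12)

    def test_range(self, rng):
        d = laplacian_distance(rng.normal(size=(5, 3)), rng.normal(size=(7, 3)))
        assert (d.values >= 0).all() and (d.values < 1).all()

    def test_bad_bandwidth(self, rng):
        with pytest.raises(ValueError, match="bandwidth"):
            laplacian_distance(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)), bandwidth=0)


class TestAssignment:
    def test_obvious_optimum(self):
        d = np.array([[1.0, 9, 9], [9, 1.0, 9]])
        m = solve_assignment(d)
        np.testing.assert_array_equal(m.pairs, [0, 1])

    def test_dominant_diagonal_identity(self, rng):
        d = rng.uniform(1, 2, size=(6, 6))
        np.fill_diagonal(d, 0.0)
        np.testing.assert_array_equal(solve_assignment(d).pairs, np.arange(6))

    def test_infeasible_shape(self):
        with pytest.raises(ValueError, match="n_x"):
            solve_assignment(np.ones((3, 2)))

    def test_cost_equals_brute_force(self, rng):
        for _ in range(100):
            d = rng.uniform(size=(5, 7))
            m = solve_assignment(d)
            cost = d[np.arange(5), m.pairs].sum()
            assert cost == pytest.approx(brute_force_cost(d), abs=1e-9)

    def test_canonical_tie_break(self):
        # every assignment has equal cost: canonical result is the identity
        d = np.ones((4, 6))
        np.testing.assert_array_equal(solve_assignment(d).pairs, np.arange(4))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_global_optimality_property(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(2, 6)), int(rng.integers(6, 9))
        d = rng.uniform(size=(n, m))
        match = solve_assignment(d)
        cost = d[np.arange(n), match.pairs].sum()
        assert cost == pytest.approx(brute_force_cost(d), abs=1e-9)


class TestSparsify:
    def test_noop_when_sparsity_covers_all(self, rng):
        d = CrossDistance(values=rng.uniform(size=(4, 5)))
        assert sparsify(d, 5) is d

    def test_collision_instance_augmented(self):
        # all rows nearest the same column; sparsity 1 has no perfect matching
        vals = np.ones((3, 4))
        vals[:, 0] = 0.0
        sp = sparsify(CrossDistance(values=vals), 1)
        m = solve_assignment(sp)
        assert len(set(m.pairs.tolist())) == 3  # injective despite collision

    def test_sparse_solution_near_dense_optimum(self, rng):
        hits = 0
        for seed in range(30):
            r = np.random.default_rng(seed)
            vals = r.uniform(size=(50, 80))
            dense_m = solve_assignment(vals)
            dense_cost = vals[np.arange(50), dense_m.pairs].sum()
            sp = sparsify(CrossDistance(values=vals), 20)
            sp_m = solve_assignment(sp)
            sp_cost = vals[np.arange(50), sp_m.pairs].sum()
            assert sp_cost >= dense_cost - 1e-9
            if sp_cost <= dense_cost + 1e-9:
                hits += 1
        assert hits >= 27  # sparsification rarely loses the dense optimum


class TestCCA:
    def test_self_correlation_is_one(self, rng):
        xa = rng.normal(size=(50, 4))
        model = fit_cca(xa, xa.copy(), r=4, ridge=0.0)
        np.testing.assert_allclose(model.correlations, 1.0, atol=1e-8)
        # the default trace-scaled ridge shifts correlations only marginally
        np.testing.assert_allclose(fit_cca(xa, xa.copy(), r=4).correlations, 1.0, atol=1e-5)

    def test_univariate_equals_pearson(self, rng):
        x = rng.normal(size=(100, 1))
        y = 0.5 * x + rng.normal(size=(100, 1))
        model = fit_cca(x, y, r=1, ridge=0.0)
        expected = abs(np.corrcoef(x[:, 0], y[:, 0])[0, 1])
        assert model.correlations[0] == pytest.approx(expected, abs=1e-8)

    def test_independent_noise_small_leading_correlation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2000, 5))
        y = rng.normal(size=(2000, 5))
        model = fit_cca(x, y, r=5)
        # permutation oracle for the null scale of the leading correlation
        null = []
        for _ in range(20):
            perm = rng.permutation(2000)
            null.append(fit_cca(x, y[perm], r=1).correlations[0])
        assert model.correlations[0] < np.quantile(null, 0.999) + 0.05

    def test_invariance_to_invertible_mixing(self, rng):
        x = rng.normal(size=(80, 4))
        y = x @ rng.normal(size=(4, 3)) + 0.1 * rng.normal(size=(80, 3))
        base = fit_cca(x, y, r=3, ridge=0.0)
        tx = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        ty = rng.normal(size=(3, 3)) + 4 * np.eye(3)
        mixed = fit_cca(x @ tx, y @ ty, r=3, ridge=0.0)
        np.testing.assert_allclose(base.correlations, mixed.correlations, atol=1e-6)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.cross_decomposition import CCA as SkCCA

        x = rng.normal(size=(200, 4))
        y = x @ rng.normal(size=(4, 3)) + rng.normal(size=(200, 3))
        ours = fit_cca(x, y, r=2, ridge=0.0)
        sk = SkCCA(n_components=2, scale=True, max_iter=2000).fit(x, y)
        sx, sy = sk.transform(x, y)
        sk_corrs = [abs(np.corrcoef(sx[:, j], sy[:, j])[0, 1]) for j in range(2)]
        np.testing.assert_allclose(ours.correlations, sk_corrs, atol=1e-3)

    def test_rank_deficient_needs_ridge(self, rng):
        x = rng.normal(size=(30, 3))
        x = np.hstack([x, x[:, :1]])  # duplicated column
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            fit_cca(x, rng.normal(size=(30, 2)), r=2, ridge=0.0)
        model = fit_cca(x, rng.normal(size=(30, 2)), r=2)  # default ridge works
        assert model.r == 2

    def test_too_few_rows(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            fit_cca(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)), r=1)


class TestRefineAndInterpolate:
    def test_score_shape_contract(self, rng):
        x = rng.normal(size=(20, 8))
        y = rng.normal(size=(40, 9))
        init = Matching(pairs=np.arange(20))
        d_all, model = refine_distance(x, y, init, r_all=4)
        assert model.r == 4
        assert d_all.shape == (20, 40)

    def test_zero_diagonal_on_duplicated_data(self, rng):
        x = rng.normal(size=(15, 6))
        y = np.vstack([x, rng.normal(size=(10, 6))])
        init = Matching(pairs=np.arange(15))
        d_all, _ = refine_distance(x, y, init, r_all=3)
        assert np.all(np.abs(np.diag(d_all.values)) < 1e-6)

    def test_endpoints_reproduce_pure_matchings(self, small_pair):
        x, y, _ = small_pair
        from mario import denoise_shared, solve_assignment

        den = denoise_shared(x.matrix_shared, y.matrix_shared, r_share=5)
        d_share = correlation_distance(den.x_hat, den.y_hat)
        init = solve_assignment(d_share)
        d_all, _ = refine_distance(x.matrix_full, y.matrix_full, init, r_all=10)
        m_share = solve_assignment(d_share)
        m_all = solve_assignment(d_all)
        m0, _ = interpolate_and_select(
            d_share, d_all, x.matrix_full, y.matrix_full, grid=(0.0, 1.0)
        )
        by_lambda = {}
        for lam in (0.0, 1.0):
            d_lam = CrossDistance(
                values=(1 - lam) * d_share.values + lam * d_all.values
            )
            by_lambda[lam] = solve_assignment(d_lam)
        np.testing.assert_array_equal(by_lambda[0.0].pairs, m_share.pairs)
        np.testing.assert_array_equal(by_lambda[1.0].pairs, m_all.pairs)

    def test_convexity_identity(self, rng):
        ds = rng.uniform(size=(6, 9))
        da = rng.uniform(size=(6, 9))
        for lam in (0.0, 0.3, 0.85, 1.0):
            np.testing.assert_allclose(
                (1 - lam) * ds + lam * da,
                (1 - lam) * ds + lam * da,
                atol=1e-12,
            )

    def test_tie_prefers_smaller_lambda(self, small_pair):
        x, y, _ = small_pair
        d = correlation_distance(x.matrix_shared, y.matrix_shared)
        m, d_sel = interpolate_and_select(
            d, d, x.matrix_full, y.matrix_full, grid=(0.0, 0.5, 1.0)
        )
        assert m.lambda_used == 0.0

    def test_noisy_distinct_features_shrink_lambda(self):
        from mario import SynthConfig, generate_pair, normalize_features

        small = 0
        for seed in range(20):
            cfg = SynthConfig(
                n_populations=4, n_cells_x=150, n_cells_y=300,
                p_shared=10, p_distinct_x=8, p_distinct_y=8,
                latent_dim=4, separation=3.0, noise_sd=0.2, seed=seed,
            )
            x, y, _ = generate_pair(cfg)
            rng = np.random.default_rng(seed + 1000)
            # overwrite distinct blocks with pure noise
            xv = x.values.copy()
            xv[:, x.distinct_block] = rng.normal(size=(x.n_cells, len(x.distinct_block)))
            yv = y.values.copy()
            yv[:, y.distinct_block] = rng.normal(size=(y.n_cells, len(y.distinct_block)))
            from dataclasses import replace

            x2 = normalize_features(replace(x, values=xv))
            y2 = normalize_features(replace(y, values=yv))
            m = match_pipeline(x2, y2, MarioParams(seed=seed)).matching
            if m.lambda_used < 1.0:
                small += 1
        assert small >= 18  # >= 90% of runs back off from the refined matching


class TestMatchPipeline:
    def test_clean_two_population_accuracy(self):
        from mario import SynthConfig, generate_pair, normalize_features

        cfg = SynthConfig(
            n_populations=2, n_cells_x=100, n_cells_y=200, p_shared=10,
            p_distinct_x=8, p_distinct_y=8, latent_dim=4,
            separation=4.0, noise_sd=0.2, seed=11,
        )
        x, y, truth = generate_pair(cfg)
        x, y = normalize_features(x), normalize_features(y)
        m = match_pipeline(x, y, MarioParams(seed=11)).matching
        acc = matching_accuracy(
            m, population_labels(truth, "x"), population_labels(truth, "y")
        )
        assert acc >= 0.95

    def test_default_params_accepted_verbatim(self):
        p = MarioParams()
        assert p.n_components_ovlp == 10
        assert p.n_components_all == 20
        assert p.sparsity == 5000
        assert p.n_batch == 1
        assert p.top_k == 10

    def test_two_batches_per_batch_injective(self, small_pair):
        x, y, _ = small_pair
        res = match_pipeline(x, y, MarioParams(n_batch=2, seed=3))
        assert len(res.batch_info) == 2
        plan_sizes = sorted(b["size"] for b in res.batch_info)
        assert sum(plan_sizes) == x.n_cells
        assert res.matching.pairs.min() >= 0  # total on X

    def test_strict_batches_globally_injective(self, small_pair):
        x, y, _ = small_pair
        res = match_pipeline(x, y, MarioParams(n_batch=2, seed=3, strict_batches=True))
        pairs = res.matching.pairs
        assert len(np.unique(pairs)) == len(pairs)

    def test_requires_alignment(self, rng):
        from mario import ExpressionBundle

        x = ExpressionBundle(["a", "b", "c"], ["f", "g"], rng.normal(size=(3, 2)))
        with pytest.raises(ValueError, match="align"):
            match_pipeline(x, x, MarioParams())
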