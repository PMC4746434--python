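"""Tests of the quadrature, EM steps, full calibration, and standard errors."""

import itertools

import numpy as np
import pytest
from scipy import optimize
from scipy.stats import multivariate_normal

from mgrm.calibrate import (
    BankStructure,
    CalibrationConfig,
    ConfigError,
    _ab_to_eta,
    _eta_to_ab,
    _item_neg_ll_grad,
    build_quadrature,
    calibrate,
    compute_standard_errors,
    e_step,
    flag_failed_calibration,
    m_step_item,
    update_latent_correlation,
)
from mgrm.model import (
    ItemBank,
    ItemParameters,
    LatentCorrelation,
    category_probabilities,
    marginal_log_likelihood,
)
from mgrm.synthetic import (
    GenerationConfig,
    generate_responses,
    replication_rng,
    sample_item_bank,
    sample_thetas,
)

from conftest import tiny_bank


class TestQuadrature:
    def test_univariate_geometry_and_symmetry(self):
        corr = LatentCorrelation(np.eye(1))
        grid = build_quadrature(21, (-3.5, 3.5), corr)
        assert grid.Q == 21
        np.testing.assert_allclose(np.diff(grid.univariate), 0.35, atol=1e-12)
        np.testing.assert_allclose(grid.univariate, -grid.univariate[::-1], atol=1e-12)
        np.testing.assert_allclose(grid.weights, grid.weights[::-1], atol=1e-14)
        assert grid.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(grid.weights >= 0)

    def test_weights_sum_for_correlated_prior(self):
        corr = LatentCorrelation.exchangeable(3, 0.7)
        grid = build_quadrature(7, (-3.5, 3.5), corr)
        assert grid.Q == 343
        assert grid.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_correlated_weights_match_density_ratio(self):
        corr = LatentCorrelation.exchangeable(2, 0.7)
        grid = build_quadrature(15, (-3.5, 3.5), corr)
        node_pp = np.argmin(np.abs(grid.nodes - [1.0, 1.0]).sum(axis=1))
        node_pm = np.argmin(np.abs(grid.nodes - [1.0, -1.0]).sum(axis=1))
        assert grid.weights[node_pp] > grid.weights[node_pm]
        mvn = multivariate_normal(mean=[0, 0], cov=corr.matrix)
        expected = mvn.pdf([1.0, 1.0]) / mvn.pdf([1.0, -1.0])
        got = grid.weights[node_pp] / grid.weights[node_pm]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_node_count_guard(self):
        corr = LatentCorrelation.exchangeable(3, 0.2)
        with pytest.raises(ConfigError):
            build_quadrature(500, (-3.5, 3.5), corr)


class TestEStep:
    def test_masses_sum_to_sample_size_and_counts_telescope(self, rng):
        bank = tiny_bank(H=2, K=2, L=4, seed=21)
        corr = LatentCorrelation.exchangeable(2, 0.3)
        grid = build_quadrature(7, (-3.5, 3.5), corr)
        X = rng.integers(0, 3, size=(40, 4))
        counts = e_step(X, bank, corr, grid)
        assert counts.n_bar.sum() == pytest.approx(40, abs=1e-8)
        for j in range(bank.L):
            np.testing.assert_allclose(
                counts.r_bar[j].sum(axis=0), counts.n_bar, atol=1e-8
            )

    def test_matches_brute_force_bayes_table(self):
        # N=2, L=2, H=1, Q=3: posterior worked out with explicit loops
        bank = tiny_bank(H=1, K=2, L=2, seed=33)
        corr = LatentCorrelation(np.eye(1))
        grid = build_quadrature(3, (-3.0, 3.0), corr)
        X = np.array([[0, 2], [1, 1]])
        counts = e_step(X, bank, corr, grid)

        w = grid.weights_for(corr)
        n_bar = np.zeros(3)
        r_bar = np.zeros((2, 3, 3))
        for i in range(2):
            joint = np.array(
                [
                    w[q]
                    * category_probabilities(grid.nodes[q], bank.items[0])[X[i, 0]]
                    * category_probabilities(grid.nodes[q], bank.items[1])[X[i, 1]]
                    for q in range(3)
                ]
            )
            post = joint / joint.sum()
            n_bar += post
            for j in range(2):
                r_bar[j, X[i, j]] += post
        np.testing.assert_allclose(counts.n_bar, n_bar, atol=1e-12)
        np.testing.assert_allclose(counts.r_bar, r_bar, atol=1e-12)
        # the marginal loglik reported by the E-step matches the direct one
        assert counts.loglik == pytest.approx(
            marginal_log_likelihood(X, bank, corr, grid), abs=1e-10
        )


def _expected_complete_ll(item, r_collapsed, t):
    from mgrm.calibrate import _item_neg_ll_grad

    eta = _ab_to_eta(item.a_loading, item.b)
    return -_item_neg_ll_grad(eta, r_collapsed, t, item.D, 1e-10)[0]


class TestMStep:
    def _counts_and_item(self, seed=3, N=300):
        bank = tiny_bank(H=1, K=3, L=4, seed=seed)
        corr = LatentCorrelation(np.eye(1))
        grid = build_quadrature(11, (-3.5, 3.5), corr)
        rng = np.random.default_rng(seed)
        th = sample_thetas(N, corr, rng)
        X = generate_responses(th, bank, rng)
        counts = e_step(X, bank, corr, grid)
        return bank, grid, counts

    def test_ascent_property(self):
        bank, grid, counts = self._counts_and_item()
        from mgrm.calibrate import _collapse_full_r

        for j, item in enumerate(bank.items):
            r = _collapse_full_r(counts.r_bar[j], grid, item.loading_dim)
            before = _expected_complete_ll(item, r, grid.univariate)
            updated = m_step_item(counts, item, grid, item_index=j)
            after = _expected_complete_ll(updated, r, grid.univariate)
            assert after >= before - 1e-10

    def test_agrees_with_generic_optimizer(self):
        bank, grid, counts = self._counts_and_item(seed=9)
        from mgrm.calibrate import _collapse_full_r

        item = bank.items[1]
        r = _collapse_full_r(counts.r_bar[1], grid, item.loading_dim)
        updated = m_step_item(counts, item, grid, item_index=1)
        res = optimize.minimize(
            lambda e: _item_neg_ll_grad(e, r, grid.univariate, item.D, 1e-10)[0],
            _ab_to_eta(item.a_loading, item.b),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
        )
        a_ref, b_ref = _eta_to_ab(res.x)
        assert updated.a_loading == pytest.approx(a_ref, abs=1e-5)
        np.testing.assert_allclose(updated.b, b_ref, atol=1e-5)

    def test_self_consistent_at_population_counts(self):
        # expected counts at the true parameters: n_bar = N w, r_bar = N w P
        bank = tiny_bank(H=1, K=3, L=1, seed=14)
        corr = LatentCorrelation(np.eye(1))
        grid = build_quadrature(41, (-4.5, 4.5), corr)
        item = bank.items[0]
        N = 1e7
        w = grid.weights_for(corr)
        P = np.stack(
            [category_probabilities(grid.nodes[q], item) for q in range(grid.Q)]
        ).T  # (K+1, Q)
        from mgrm.calibrate import ExpectedCounts

        counts = ExpectedCounts(
            n_bar=N * w, r_bar=(N * w * P)[None, :, :], loglik=0.0
        )
        updated = m_step_item(counts, item, grid, item_index=0)
        assert updated.a_loading == pytest.approx(item.a_loading, abs=1e-3)
        np.testing.assert_allclose(updated.b, item.b, atol=1e-3)


class TestLatentCorrelationUpdate:
    def test_unit_diagonal_and_symmetry(self, rng):
        bank = tiny_bank(H=2, K=2, L=6, seed=17)
        corr = LatentCorrelation.exchangeable(2, 0.4)
        grid = build_quadrature(9, (-3.5, 3.5), corr)
        th = sample_thetas(300, corr, rng)
        X = generate_responses(th, bank, rng)
        out = update_latent_correlation(X, bank, corr, grid)
        np.testing.assert_array_equal(np.diag(out.matrix), 1.0)
        np.testing.assert_allclose(out.matrix, out.matrix.T, atol=1e-14)

    def test_single_dimension_returns_identity(self, rng):
        bank = tiny_bank(H=1, K=2, L=4, seed=18)
        corr = LatentCorrelation(np.eye(1))
        grid = build_quadrature(9, (-3.5, 3.5), corr)
        X = rng.integers(0, 3, size=(30, 4))
        out = update_latent_correlation(X, bank, corr, grid)
        np.testing.assert_array_equal(out.matrix, np.eye(1))


def _simulated_fit(L=30, N=2000, r=0.5, seed=101, nodes=15, **cfg_kwargs):
    gen = GenerationConfig(L=L, H=3, K=3, N=N, r=r)
    rng = replication_rng(seed, (L, N, int(r * 1000)), 0)
    bank = sample_item_bank(gen, rng)
    th = sample_thetas(N, gen.corr, rng)
    X = generate_responses(th, bank, rng)
    cfg = CalibrationConfig(nodes_per_dim=nodes, **cfg_kwargs)
    return bank, X, calibrate(X, bank, cfg)


@pytest.fixture(scope="module")
def medium_fit():
    return _simulated_fit(L=30, N=2000, r=0.5, seed=101)


class TestCalibrate:

    def test_zero_cycles_returns_start_values(self):
        bank = tiny_bank(H=1, K=2, L=4, seed=23)
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(60, 4))
        res = calibrate(X, bank, CalibrationConfig(max_cycles=0, nodes_per_dim=5))
        assert not res.converged
        assert res.n_cycles == 0
        np.testing.assert_allclose(
            [it.a_loading for it in res.bank_hat.items], 1.5
        )

    def test_loglik_trace_non_decreasing(self, medium_fit):
        _, _, res = medium_fit
        assert np.all(np.diff(res.loglik_trace) >= -1e-6)

    def test_discrimination_recovery_at_large_sample(self, medium_fit):
        bank, _, res = medium_fit
        for h in (1, 2, 3):
            t = [it.a_loading for it in bank.items if it.loading_dim == h]
            e = [
                it.a_loading
                for it in res.bank_hat.items
                if it.loading_dim == h
            ]
            assert np.corrcoef(t, e)[0, 1] > 0.95

    def test_latent_correlation_recovery(self, medium_fit):
        _, _, res = medium_fit
        off = res.corr_hat.matrix[np.triu_indices(3, 1)]
        assert np.all(np.abs(off - 0.5) < 0.05)

    def test_confirmatory_zero_pattern_preserved(self, medium_fit):
        bank, _, res = medium_fit
        np.testing.assert_array_equal(
            res.bank_hat.a_matrix() == 0, bank.a_matrix() == 0
        )

    def test_item_order_equivariance(self):
        bank = tiny_bank(H=2, K=2, L=6, seed=31)
        corr = LatentCorrelation.exchangeable(2, 0.3)
        rng = np.random.default_rng(8)
        th = sample_thetas(250, corr, rng)
        X = generate_responses(th, bank, rng)
        cfg = CalibrationConfig(nodes_per_dim=7, max_cycles=40, compute_se=False)
        res = calibrate(X, bank, cfg)
        perm = [3, 0, 5, 1, 4, 2]
        bank_p = ItemBank(items=tuple(bank.items[j] for j in perm))
        res_p = calibrate(X[:, perm], bank_p, cfg)
        for jj, j in enumerate(perm):
            # bit-exact: the canonical item-id ordering makes accumulation
            # order independent of the column permutation
            np.testing.assert_array_equal(
                res_p.bank_hat.items[jj].b, res.bank_hat.items[j].b
            )
            assert res_p.bank_hat.items[jj].a_loading == res.bank_hat.items[j].a_loading

    def test_out_of_range_categories_rejected(self):
        bank = tiny_bank(H=1, K=2, L=4)
        X = np.full((10, 4), 5)
        with pytest.raises(ValueError):
            calibrate(X, bank, CalibrationConfig(nodes_per_dim=5))

    def test_empty_observed_category_noted_not_fatal(self):
        bank = tiny_bank(H=1, K=2, L=4, seed=23)
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(80, 4))  # category 2 never observed
        res = calibrate(
            X, bank, CalibrationConfig(nodes_per_dim=5, max_cycles=30, compute_se=False)
        )
        assert any("empty observed category" in n for n in res.notes)

    def test_em_reaches_generic_optimizer_optimum(self):
        # N=150, L=6, H=2 fixture: EM loglik within 1e-3 of a direct
        # numerical maximization over all free parameters
        gen = GenerationConfig(
            L=6, H=2, K=2, N=150, r=0.5,
            b_intervals=((-2.0, -0.3), (0.3, 2.0)),
        )
        rng = replication_rng(55, (6, 150, 500), 0)
        bank = sample_item_bank(gen, rng)
        th = sample_thetas(150, gen.corr, rng)
        X = generate_responses(th, bank, rng)
        cfg = CalibrationConfig(
            nodes_per_dim=11, param_tol=1e-6, compute_se=False
        )
        res = calibrate(X, bank, cfg)
        grid = build_quadrature(11, (-3.5, 3.5), LatentCorrelation.exchangeable(2, 0.0))

        structure = BankStructure.from_bank(bank)

        def unpack(v):
            items = []
            for j in range(6):
                block = v[j * 3 : (j + 1) * 3]
                a = np.zeros(2)
                a[structure.loading_dims[j] - 1] = np.exp(block[0])
                b = np.array([block[1], block[1] + np.exp(block[2])])
                items.append(
                    ItemParameters(
                        item_id=j + 1,
                        loading_dim=structure.loading_dims[j],
                        a=a,
                        b=b,
                    )
                )
            rho = 0.99 * np.tanh(v[-1])
            return ItemBank(items=tuple(items)), LatentCorrelation.exchangeable(2, rho)

        def neg_ll(v):
            try:
                bk, cr = unpack(v)
                return -marginal_log_likelihood(X, bk, cr, grid)
            except (ValueError, np.linalg.LinAlgError):
                return 1e12

        v0 = []
        for it in calibrate(X, bank, CalibrationConfig(max_cycles=0, nodes_per_dim=11)).bank_hat.items:
            v0 += [np.log(it.a_loading), it.b[0], np.log(it.b[1] - it.b[0])]
        v0.append(0.0)
        opt = optimize.minimize(
            neg_ll, np.array(v0), method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-9},
        )
        em_ll = res.loglik_trace[-1]
        assert -opt.fun - em_ll < 1e-3

    def test_rmse_improves_with_sample_size(self):
        # paired replications: discrimination RMSE shrinks from N=500 to N=2000
        from mgrm.recovery import indices_for_replication

        deltas = []
        for rep in range(5):
            rmse = {}
            for N in (500, 2000):
                gen = GenerationConfig(L=12, H=3, K=3, N=N, r=0.5)
                rng = replication_rng(77, (12, N, 500), rep)
                bank = sample_item_bank(gen, rng)
                th = sample_thetas(N, gen.corr, rng)
                X = generate_responses(th, bank, rng)
                res = calibrate(
                    X, bank, CalibrationConfig(nodes_per_dim=11, compute_se=False)
                )
                idx = indices_for_replication(bank, res)
                rmse[N] = idx[idx["class"].str.startswith("a")]["rmse"].mean()
            deltas.append(rmse[500] - rmse[2000])
        assert np.mean(deltas) > 0


class TestStandardErrors:
    def test_positive_on_successful_fit(self):
        _, _, res = _simulated_fit(L=12, N=400, r=0.2, seed=201, nodes=9)
        assert res.se is not None
        assert np.all(res.se > 0)
        assert np.all(np.isfinite(res.se))

    def test_matches_exact_expected_information(self):
        # K=1 items reduce to the two-parameter logistic model; with L=4
        # binary items all 16 response patterns can be enumerated, giving
        # the exact per-respondent expected information by numeric
        # integration over the latent density.  OPG standard errors on a
        # large simulated sample must approach its inverse square root.
        rng = np.random.default_rng(6)
        items = []
        for j, (a, b) in enumerate([(1.4, -0.8), (2.0, 0.3), (1.1, 1.0), (1.7, -0.2)]):
            items.append(
                ItemParameters(
                    item_id=j + 1, loading_dim=1, a=np.array([a]), b=np.array([b])
                )
            )
        bank = ItemBank(items=tuple(items))
        corr = LatentCorrelation(np.eye(1))
        grid = build_quadrature(41, (-5.0, 5.0), corr)
        w = grid.weights_for(corr)
        probs = np.stack(
            [
                [category_probabilities(grid.nodes[q], it)[1] for q in range(grid.Q)]
                for it in bank.items
            ]
        )  # (L, Q) probability of a correct/endorsed response

        def pattern_prob_and_score(pattern, eps=1e-6):
            def logp(v):
                pr = np.ones(grid.Q)
                for j, x in enumerate(pattern):
                    a, b = v[2 * j], v[2 * j + 1]
                    p1 = 1 / (1 + np.exp(-a * (grid.nodes[:, 0] - b)))
                    pr = pr * (p1 if x == 1 else 1 - p1)
                return np.log((w * pr).sum())

            v0 = np.array([[it.a_loading, it.b[0]] for it in bank.items]).ravel()
            base = logp(v0)
            score = np.zeros(8)
            for p in range(8):
                vp = v0.copy()
                vp[p] += eps
                vm = v0.copy()
                vm[p] -= eps
                score[p] = (logp(vp) - logp(vm)) / (2 * eps)
            return np.exp(base), score

        info = np.zeros((8, 8))
        for pattern in itertools.product([0, 1], repeat=4):
            p, s = pattern_prob_and_score(pattern)
            info += p * np.outer(s, s)
        N = 20_000
        se_exact = np.sqrt(np.diag(np.linalg.inv(N * info)))

        th = sample_thetas(N, corr, rng)
        X = generate_responses(th, bank, rng)
        result = calibrate(
            X, bank, CalibrationConfig(nodes_per_dim=41, quad_range=(-5.0, 5.0))
        )
        se_fit = result.se.ravel()  # columns (a, b1) per item, same order
        np.testing.assert_allclose(se_fit, se_exact, rtol=0.05)

    def test_root_n_scaling(self):
        # same bank, refreshed simulees: quadrupling N halves the median SE
        gen = GenerationConfig(L=12, H=3, K=3, N=400, r=0.2)
        rng = replication_rng(301, (12,), 0)
        bank = sample_item_bank(gen, rng)
        meds = {}
        for N in (400, 1600):
            th = sample_thetas(N, gen.corr, rng)
            X = generate_responses(th, bank, rng)
            res = calibrate(X, bank, CalibrationConfig(nodes_per_dim=9))
            meds[N] = np.median(res.se)
        ratio = meds[400] / meds[1600]
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_failure_flag_rules(self):
        _, _, res = _simulated_fit(L=12, N=400, r=0.2, seed=201, nodes=9)
        assert not flag_failed_calibration(res, se_threshold=1.0)
        assert flag_failed_calibration(res, se_threshold=1e-6)
        assert "unusually large" not in res.failure_reason  # reason is quantitative
        res.se = np.full_like(res.se, np.inf)
        assert flag_failed_calibration(res, se_threshold=1.0)
        assert "singular" in res.failure_reason
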