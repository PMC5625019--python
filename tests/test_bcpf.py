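"""Tests for the variational Bayesian CP factorization."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import gamma as gamma_dist
from scipy.stats import multivariate_normal

import tffusion as tfn
from tffusion import bcpf
from cp_als_oracle import cp_als, compose


def elbo_is_monotone(trace, rtol=1e-8):
    trace = np.asarray(trace)
    return bool(np.all(np.diff(trace) >= -rtol * np.abs(trace[:-1])))


class TestInitState:
    def test_shape_contract(self):
        tensor, _ = tfn.gen_cp_tensor((20, 20, 3), 2, 10.0, 0.0, seed=0)
        state = bcpf.init_state(tensor, tfn.PriorConfig(r_init=10, seed=0))
        assert [m.shape for m in state.factor_means] == [
            (20, 10), (20, 10), (3, 10)
        ]
        assert state.rank == 10

    def test_deterministic(self):
        tensor, _ = tfn.gen_cp_tensor((8, 8, 3), 2, 10.0, 0.1, seed=1)
        cfg = tfn.PriorConfig(r_init=6, seed=4)
        s1 = bcpf.init_state(tensor, cfg)
        s2 = bcpf.init_state(tensor, cfg)
        for a, b in zip(s1.factor_means, s2.factor_means):
            np.testing.assert_array_equal(a, b)

    def test_overcomplete_start_warns_but_accepted(self):
        tensor, _ = tfn.gen_cp_tensor((6, 6, 3), 2, 10.0, 0.0, seed=2)
        with pytest.warns(UserWarning, match="overcomplete"):
            state = bcpf.init_state(tensor, tfn.PriorConfig(r_init=8, seed=0))
        assert state.rank == 8

    def test_all_masked_rejected(self):
        tensor = tfn.ObservedTensor(
            np.zeros((3, 3, 2)), np.zeros((3, 3, 2), dtype=bool)
        )
        with pytest.raises(ValueError, match="no observed"):
            bcpf.init_state(tensor, tfn.PriorConfig(r_init=2))


class TestFactorUpdate:
    def test_row_without_data_falls_back_to_prior(self):
        tensor, _ = tfn.gen_cp_tensor((6, 6, 3), 2, 10.0, 0.0, seed=0)
        tensor.mask[2, :, :] = False  # mode-0 row 2 unobserved everywhere
        cfg = tfn.PriorConfig(r_init=3, seed=0)
        state = bcpf.init_state(tensor, cfg)
        state = bcpf.update_factor_mode(state, tensor, 0)
        np.testing.assert_allclose(state.factor_means[0][2], 0.0, atol=1e-12)
        np.testing.assert_allclose(
            state.factor_row_covariances[0][2],
            np.diag(1.0 / state.e_lambda),
            rtol=1e-6,
        )

    def test_update_matches_numerical_block_maximization(self):
        """The conjugate update of one mode's block is the exact maximizer
        of the lower bound over that block (checked numerically on 2x2x2)."""
        tensor, _ = tfn.gen_cp_tensor((2, 2, 2), 1, 5.0, 0.0, seed=3)
        cfg = tfn.PriorConfig(r_init=2, seed=3)
        state = bcpf.init_state(tensor, cfg)
        for mode in range(3):
            bcpf.update_factor_mode(state, tensor, mode)
        bcpf.update_lambda(state, cfg)
        bcpf.update_tau(state, tensor, cfg)
        state = bcpf.update_factor_mode(state, tensor, 0)
        lb_conjugate = bcpf.lower_bound(state, tensor, cfg)

        r = state.rank

        def set_block(x):
            s = state.copy()
            means = x[: 2 * r].reshape(2, r)
            s.factor_means[0] = means
            covs = []
            for i in range(2):
                tri = np.zeros((r, r))
                tri[np.tril_indices(r)] = x[2 * r + i * (r * (r + 1) // 2):
                                            2 * r + (i + 1) * (r * (r + 1) // 2)]
                tri[np.diag_indices(r)] = np.exp(tri[np.diag_indices(r)])
                covs.append(tri @ tri.T + 1e-12 * np.eye(r))
            s.factor_row_covariances[0] = np.stack(covs)
            return s

        def neg_bound(x):
            try:
                return -bcpf.lower_bound(set_block(x), tensor, cfg)
            except FloatingPointError:
                return np.inf

        # start from the conjugate solution and search for an improvement
        x0 = np.concatenate(
            [state.factor_means[0].ravel()]
            + [
                np.linalg.cholesky(c)[np.tril_indices(r)]
                for c in state.factor_row_covariances[0]
            ]
        )
        # cholesky diag is log-parametrized in set_block
        ntri = r * (r + 1) // 2
        for i in range(2):
            tri = np.zeros((r, r))
            tri[np.tril_indices(r)] = x0[2 * r + i * ntri: 2 * r + (i + 1) * ntri]
            tri[np.diag_indices(r)] = np.log(tri[np.diag_indices(r)])
            x0[2 * r + i * ntri: 2 * r + (i + 1) * ntri] = tri[np.tril_indices(r)]
        res = minimize(neg_bound, x0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
        assert -res.fun <= lb_conjugate + 1e-6

    def test_noiseless_rank1_exact_fixed_point(self):
        tensor, truth = tfn.gen_cp_tensor((6, 6, 3), 1, None, 0.0, seed=1)
        cfg = tfn.PriorConfig(r_init=1, seed=1)
        state = bcpf.init_state(tensor, cfg)
        for _ in range(50):
            for mode in range(3):
                bcpf.update_factor_mode(state, tensor, mode)
            bcpf.update_tau(state, tensor, cfg)
        err = np.linalg.norm(bcpf.reconstruct(state) - truth.latent_tensor)
        assert err / np.linalg.norm(truth.latent_tensor) < 1e-6

    def test_invalid_mode_rejected(self):
        tensor, _ = tfn.gen_cp_tensor((4, 4, 3), 1, 10.0, 0.0, seed=0)
        state = bcpf.init_state(tensor, tfn.PriorConfig(r_init=2, seed=0))
        with pytest.raises(ValueError, match="mode"):
            bcpf.update_factor_mode(state, tensor, 3)


class TestLambdaUpdate:
    def test_dead_component_conjugate_by_hand(self):
        tensor, _ = tfn.gen_cp_tensor((5, 5, 3), 2, 10.0, 0.0, seed=0)
        cfg = tfn.PriorConfig(r_init=2, seed=0)
        state = bcpf.init_state(tensor, cfg)
        # plant an exactly-dead component: zero columns, zero covariance
        for n in range(3):
            state.factor_means[n][:, 1] = 0.0
            state.factor_row_covariances[n][:, 1, :] = 0.0
            state.factor_row_covariances[n][:, :, 1] = 0.0
        bcpf.update_lambda(state, cfg)
        dims = 5 + 5 + 3
        assert state.e_lambda[1] == pytest.approx(
            (cfg.c0 + dims / 2) / cfg.d0
        )

    def test_symmetric_components_identical_posteriors(self):
        tensor, _ = tfn.gen_cp_tensor((5, 5, 3), 1, 10.0, 0.0, seed=1)
        cfg = tfn.PriorConfig(r_init=2, seed=1)
        state = bcpf.init_state(tensor, cfg)
        for n in range(3):
            state.factor_means[n][:, 1] = state.factor_means[n][:, 0]
            state.factor_row_covariances[n][:] = np.eye(2)
        bcpf.update_lambda(state, cfg)
        assert state.lambda_rate[0] == pytest.approx(state.lambda_rate[1])

    def test_monotone_over_random_states(self):
        # conjugate lambda update never decreases the bound
        for seed in range(20):
            tensor, _ = tfn.gen_cp_tensor((6, 6, 3), 2, 10.0, 0.2, seed=seed)
            cfg = tfn.PriorConfig(r_init=3, seed=seed)
            state = bcpf.init_state(tensor, cfg)
            for mode in range(3):
                bcpf.update_factor_mode(state, tensor, mode)
            before = bcpf.lower_bound(state, tensor, cfg)
            bcpf.update_lambda(state, cfg)
            after = bcpf.lower_bound(state, tensor, cfg)
            assert after >= before - 1e-8 * abs(before)


class TestTauUpdate:
    def test_zero_residual_rate_is_prior(self):
        tensor, truth = tfn.gen_cp_tensor((4, 4, 3), 1, None, 0.0, seed=0)
        cfg = tfn.PriorConfig(r_init=1, seed=0)
        state = bcpf.init_state(tensor, cfg)
        # place the posterior exactly on the truth with zero uncertainty
        state.factor_means = [f.copy() for f in truth.factor_matrices]
        for n in range(3):
            state.factor_row_covariances[n][:] = 0.0
        bcpf.update_tau(state, tensor, cfg)
        assert state.tau_rate == pytest.approx(cfg.b0)
        assert state.tau_shape == pytest.approx(cfg.a0 + tensor.n_observed / 2)

    def test_fixed_point_unchanged(self):
        tensor, _ = tfn.gen_cp_tensor((5, 5, 3), 1, 10.0, 0.0, seed=1)
        cfg = tfn.PriorConfig(r_init=2, seed=1)
        state = tfn.fit(tensor, cfg)
        shape, rate = state.tau_shape, state.tau_rate
        bcpf.update_tau(state, tensor, cfg)
        assert state.tau_shape == pytest.approx(shape)
        assert state.tau_rate == pytest.approx(rate, rel=1e-9)

    def test_posterior_mean_scale_free_in_observation_count(self):
        # doubling the observation count at fixed residual-per-entry leaves
        # E[tau] approximately unchanged
        means = {}
        for n, seed in ((6, 0), (12, 0)):
            tensor, truth = tfn.gen_cp_tensor((n, n, 3), 1, 25.0, 0.0, seed=seed)
            cfg = tfn.PriorConfig(r_init=1, seed=seed)
            state = bcpf.init_state(tensor, cfg)
            state.factor_means = [f.copy() for f in truth.factor_matrices]
            for m in range(3):
                state.factor_row_covariances[m][:] = 0.0
            bcpf.update_tau(state, tensor, cfg)
            means[n] = state.e_tau
        assert means[12] == pytest.approx(means[6], rel=0.5)


class TestPruneRank:
    def test_no_component_below_threshold_is_noop(self):
        tensor, _ = tfn.gen_cp_tensor((6, 6, 3), 2, 10.0, 0.0, seed=0)
        cfg = tfn.PriorConfig(r_init=2, seed=0)
        state = tfn.fit(tensor, cfg)
        rank = state.rank
        bcpf.prune_rank(state, cfg)
        assert state.rank == rank

    def test_planted_dead_component_removed(self):
        tensor, _ = tfn.gen_cp_tensor((6, 6, 3), 2, 10.0, 0.0, seed=1)
        cfg = tfn.PriorConfig(r_init=3, seed=1)
        state = bcpf.init_state(tensor, cfg)
        for n in range(3):
            state.factor_means[n][:, 2] = 0.0
        bcpf.prune_rank(state, cfg)
        assert state.rank == 2
        assert all(m.shape[1] == 2 for m in state.factor_means)
        assert state.lambda_shape.shape == (2,)

    def test_never_prunes_to_zero(self):
        tensor, _ = tfn.gen_cp_tensor((5, 5, 3), 1, 10.0, 0.0, seed=2)
        cfg = tfn.PriorConfig(r_init=2, seed=2)
        state = bcpf.init_state(tensor, cfg)
        for n in range(3):
            state.factor_means[n][:, 0] = 1e-8  # weak but largest
            state.factor_means[n][:, 1] = 0.0
        bcpf.prune_rank(state, cfg)
        assert state.rank == 1


class TestLowerBound:
    def test_pure_function(self):
        tensor, _ = tfn.gen_cp_tensor((5, 5, 3), 2, 10.0, 0.1, seed=0)
        cfg = tfn.PriorConfig(r_init=3, seed=0)
        state = tfn.fit(tensor, cfg)
        assert bcpf.lower_bound(state, tensor, cfg) == bcpf.lower_bound(
            state, tensor, cfg
        )

    def test_monte_carlo_oracle(self):
        """L(q) = E_q[ln p(Y,Theta) - ln q(Theta)]: compare the analytic
        bound with a seeded Monte-Carlo estimate on a 2x2x2 instance."""
        tensor, _ = tfn.gen_cp_tensor((2, 2, 2), 1, 5.0, 0.0, seed=5)
        cfg = tfn.PriorConfig(r_init=1, seed=5)
        state = bcpf.init_state(tensor, cfg)
        for _ in range(3):
            for mode in range(3):
                bcpf.update_factor_mode(state, tensor, mode)
            bcpf.update_lambda(state, cfg)
            bcpf.update_tau(state, tensor, cfg)
        analytic = bcpf.lower_bound(state, tensor, cfg)

        rng = np.random.default_rng(0)
        n_samples = 200_000
        r = state.rank
        log_p = np.zeros(n_samples)
        log_q = np.zeros(n_samples)
        # sample factor rows
        rows = []
        for n in range(3):
            mode_rows = []
            for i in range(2):
                mean = state.factor_means[n][i]
                cov = state.factor_row_covariances[n][i]
                draws = rng.multivariate_normal(mean, cov, size=n_samples)
                log_q += multivariate_normal.logpdf(draws, mean, cov)
                mode_rows.append(draws)
            rows.append(mode_rows)
        lam = rng.gamma(
            state.lambda_shape, 1.0 / state.lambda_rate, size=(n_samples, r)
        )
        log_q += gamma_dist.logpdf(
            lam, state.lambda_shape, scale=1.0 / state.lambda_rate
        ).sum(axis=1)
        tau = rng.gamma(state.tau_shape, 1.0 / state.tau_rate, size=n_samples)
        log_q += gamma_dist.logpdf(tau, state.tau_shape, scale=1.0 / state.tau_rate)

        # log joint
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    pred = (rows[0][i] * rows[1][j] * rows[2][k]).sum(axis=1)
                    y = tensor.values[i, j, k]
                    log_p += 0.5 * np.log(tau / (2 * np.pi)) - 0.5 * tau * (
                        y - pred
                    ) ** 2
        for n in range(3):
            for i in range(2):
                a = rows[n][i]
                log_p += (
                    0.5 * np.log(lam / (2 * np.pi)) - 0.5 * lam * a ** 2
                ).sum(axis=1)
        log_p += gamma_dist.logpdf(lam, cfg.c0, scale=1.0 / cfg.d0).sum(axis=1)
        log_p += gamma_dist.logpdf(tau, cfg.a0, scale=1.0 / cfg.b0)

        diffs = log_p - log_q
        mc = diffs.mean()
        stderr = diffs.std(ddof=1) / np.sqrt(n_samples)
        assert analytic == pytest.approx(mc, abs=6 * stderr + 1e-9)

    def test_increases_over_sweeps(self):
        for seed in range(5):
            tensor, _ = tfn.gen_cp_tensor((8, 8, 3), 2, 10.0, 0.2, seed=seed)
            state = tfn.fit(tensor, tfn.PriorConfig(r_init=4, seed=seed))
            assert elbo_is_monotone(state.lower_bound_trace)


class TestFit:
    def test_noiseless_rank1_exact(self):
        tensor, truth = tfn.gen_cp_tensor((10, 10, 3), 1, None, 0.0, seed=3)
        state = tfn.fit(tensor, tfn.PriorConfig(r_init=5, seed=3))
        rec = tfn.reconstruct(state)
        rel = np.linalg.norm(rec - truth.latent_tensor) / np.linalg.norm(
            truth.latent_tensor
        )
        assert rel < 1e-6

    def test_heldout_rmse_bounded_by_noise(self):
        tensor, truth = tfn.gen_cp_tensor((40, 40, 5), 4, 100.0, 0.3, seed=0)
        state = tfn.fit(tensor, tfn.PriorConfig(r_init=10, seed=0))
        held = ~tensor.mask
        rmse = np.sqrt(
            np.mean((tfn.reconstruct(state)[held] - truth.latent_tensor[held]) ** 2)
        )
        assert rmse <= 1.5 * 0.1

    def test_nonconvergence_flagged_not_raised(self):
        tensor, _ = tfn.gen_cp_tensor((10, 10, 3), 2, 10.0, 0.1, seed=4)
        with pytest.warns(UserWarning, match="converge"):
            state = tfn.fit(tensor, tfn.PriorConfig(r_init=5, max_iter=2, seed=4))
        assert state.converged is False

    def test_deterministic(self):
        tensor, _ = tfn.gen_cp_tensor((8, 8, 3), 2, 10.0, 0.1, seed=5)
        s1 = tfn.fit(tensor, tfn.PriorConfig(r_init=4, seed=5))
        s2 = tfn.fit(tensor, tfn.PriorConfig(r_init=4, seed=5))
        for a, b in zip(s1.factor_means, s2.factor_means):
            np.testing.assert_array_equal(a, b)

    def test_completion_improves_with_noise_precision(self):
        # held-out RMSE decreases (in expectation over seeds) as tau grows
        by_tau = {}
        for tau in (1.0, 10.0, 100.0):
            errs = []
            for seed in range(10):
                tensor, truth = tfn.gen_cp_tensor(
                    (15, 15, 3), 2, tau, 0.2, seed=seed
                )
                state = tfn.fit(tensor, tfn.PriorConfig(r_init=6, seed=seed))
                held = ~tensor.mask
                errs.append(
                    np.sqrt(np.mean(
                        (tfn.reconstruct(state)[held]
                         - truth.latent_tensor[held]) ** 2
                    ))
                )
            by_tau[tau] = np.mean(errs)
        assert by_tau[10.0] < by_tau[1.0]
        assert by_tau[100.0] < by_tau[10.0]

    def test_matches_als_oracle_on_full_data(self):
        # at fixed known rank on fully observed data the variational fit's
        # reconstruction error is within 10% of a CP-ALS oracle's
        tensor, _ = tfn.gen_cp_tensor((15, 15, 4), 3, 25.0, 0.0, seed=6)
        state = tfn.fit(tensor, tfn.PriorConfig(r_init=3, seed=6))
        vb_err = np.linalg.norm(tfn.reconstruct(state) - tensor.values)
        factors = cp_als(tensor.values, tensor.mask, rank=3, seed=6)
        als_err = np.linalg.norm(compose(factors) - tensor.values)
        assert vb_err == pytest.approx(als_err, rel=0.1)


class TestPredictReconstruct:
    def test_reconstruct_matches_triple_loop_oracle(self):
        tensor, _ = tfn.gen_cp_tensor((6, 6, 3), 2, 10.0, 0.0, seed=0)
        state = tfn.fit(tensor, tfn.PriorConfig(r_init=3, seed=0))
        rec = tfn.reconstruct(state)
        m0, m1, m2 = state.factor_means
        for i in range(6):
            for j in range(6):
                for k in range(3):
                    expected = sum(
                        m0[i, r] * m1[j, r] * m2[k, r]
                        for r in range(state.rank)
                    )
                    assert rec[i, j, k] == pytest.approx(expected, abs=1e-10)

    def test_rank1_unit_factors_all_ones(self):
        tensor, _ = tfn.gen_cp_tensor((2, 2, 2), 1, 10.0, 0.0, seed=0)
        cfg = tfn.PriorConfig(r_init=1, seed=0)
        state = bcpf.init_state(tensor, cfg)
        state.factor_means = [np.ones((2, 1)) for _ in range(3)]
        for n in range(3):
            state.factor_row_covariances[n][:] = 1e-12
        np.testing.assert_allclose(tfn.reconstruct(state), 1.0)
        assert tfn.predict(state, (0, 1, 1)).mean == pytest.approx(1.0)

    def test_permutation_and_scale_indifference(self):
        tensor, _ = tfn.gen_cp_tensor((5, 5, 3), 2, 10.0, 0.0, seed=1)
        state = tfn.fit(tensor, tfn.PriorConfig(r_init=3, seed=1))
        rec = tfn.reconstruct(state)
        perm = np.random.default_rng(0).permutation(state.rank)
        state.factor_means = [m[:, perm] for m in state.factor_means]
        np.testing.assert_allclose(tfn.reconstruct(state), rec, atol=1e-12)
        state.factor_means[0] *= 2.0
        state.factor_means[1] *= 0.5
        np.testing.assert_allclose(tfn.reconstruct(state), rec, atol=1e-12)

    def test_exact_fit_predicts_observed_values(self):
        tensor, _ = tfn.gen_cp_tensor((6, 6, 3), 1, None, 0.0, seed=2)
        state = tfn.fit(tensor, tfn.PriorConfig(r_init=2, seed=2))
        for idx in [(0, 0, 0), (3, 4, 1), (5, 5, 2)]:
            pred = tfn.predict(state, idx)
            assert pred.mean == pytest.approx(tensor.values[idx], abs=1e-6)
            assert pred.variance > 0

    def test_masked_entry_has_larger_variance(self):
        values = np.ones((6, 6, 3)) + 0.05 * np.random.default_rng(0).standard_normal((6, 6, 3))
        mask = np.ones((6, 6, 3), dtype=bool)
        mask[0, 1, :] = False  # hold out one fiber
        tensor = tfn.ObservedTensor(values, mask)
        state = tfn.fit(tensor, tfn.PriorConfig(r_init=2, seed=0))
        var_masked = tfn.predict(state, (0, 1, 0)).variance
        var_observed = tfn.predict(state, (1, 0, 0)).variance
        assert var_masked > var_observed
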