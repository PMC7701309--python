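import numpy as np
import pytest

import tvgnet as tv
from tvgnet.core import (
    ConvergenceError,
    NeighborhoodIndex,
    blockwise_partition,
    fit_admm,
    fit_joint,
    fit_pseudo,
    fit_series,
    kernel_covariance,
    lambda_max,
    loggle_objective,
    refit_support,
    support_of,
)
from tvgnet.kernels import KernelSpec, kernel_weights

from _oracles import objective as oracle_objective
from _oracles import prox_gradient_minimize, weighted_covariance_loop


class TestKernelWeights:
    def test_single_sample_gets_weight_one(self):
        w = kernel_weights(np.array([0.3]), 0.5, KernelSpec("epanechnikov", 0.5))
        assert w == pytest.approx([1.0])

    def test_epanechnikov_three_point_example(self):
        w = kernel_weights(np.array([0.0, 0.5, 1.0]), 0.5, KernelSpec("epanechnikov", 1.0))
        assert w == pytest.approx([0.3, 0.4, 0.3])

    def test_symmetric_layout_gives_symmetric_weights(self, rng):
        offs = rng.uniform(0.01, 0.2, 5)
        times = np.concatenate([0.5 - offs, 0.5 + offs])
        for fam in ("epanechnikov", "gaussian"):
            w = kernel_weights(times, 0.5, KernelSpec(fam, 0.3))
            assert w[:5] == pytest.approx(w[5:])
            assert w.sum() == pytest.approx(1.0)
            assert (w >= 0).all()


class TestKernelCovariance:
    def _xc(self, values, times):
        return tv.ExpressionMatrix(
            gene_ids=[f"g{i}" for i in range(values.shape[0])],
            sample_ids=[f"s{j}" for j in range(values.shape[1])],
            values=values,
            times=times,
        )

    def test_weight_concentrated_on_one_sample_is_outer_product(self):
        # only the sample at t=0.5 is inside the kernel support
        values = np.array([[1.0, 9.0], [2.0, -9.0]])
        Xc = self._xc(values, np.array([0.5, 1.0]))
        s = kernel_covariance(Xc, 0.5, KernelSpec("epanechnikov", 0.1))
        assert s == pytest.approx(np.array([[1.0, 2.0], [2.0, 4.0]]))

    def test_identical_samples_give_same_outer_product_for_any_bandwidth(self):
        x = np.array([1.5, -0.5])
        values = np.tile(x[:, None], (1, 7))
        Xc = self._xc(values, np.linspace(0, 1, 7))
        for h in (0.2, 0.5, 2.0):
            s = kernel_covariance(Xc, 0.4, KernelSpec("gaussian", h))
            assert s == pytest.approx(np.outer(x, x))

    def test_matches_entrywise_brute_force(self, rng):
        values = rng.standard_normal((4, 30))
        times = rng.uniform(0, 1, 30)
        spec = KernelSpec("gaussian", 0.25)
        Xc = self._xc(values, times)
        s = kernel_covariance(Xc, 0.37, spec)
        w = kernel_weights(times, 0.37, spec)
        assert s == pytest.approx(weighted_covariance_loop(values, w))

    def test_result_is_positive_semidefinite(self, rng):
        values = rng.standard_normal((5, 12))
        Xc = self._xc(values, rng.uniform(0, 1, 12))
        s = kernel_covariance(Xc, 0.5, KernelSpec("gaussian", 0.3))
        assert np.linalg.eigvalsh(s).min() >= -1e-12


class TestLoggleObjective:
    def test_identity_case(self):
        assert loggle_objective([np.eye(2)], [np.eye(2)], lam=5.0) == pytest.approx(2.0)

    def test_closed_form_with_off_diagonal(self):
        om = np.array([[1.0, 0.5], [0.5, 1.0]])
        val0 = loggle_objective([om], [np.eye(2)], lam=0.0)
        assert val0 == pytest.approx(2.0 - np.log(0.75))
        val1 = loggle_objective([om], [np.eye(2)], lam=1.0)
        assert val1 == pytest.approx(2.0 - np.log(0.75) + 1.0)  # ordered-pair sum

    def test_non_positive_definite_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            loggle_objective([bad], [np.eye(2)], lam=0.1)


class TestFitAdmm:
    def test_unpenalized_single_time_returns_inverse(self, random_cov_factory):
        s = random_cov_factory(3)[0]
        om = fit_admm([s], lam=0.0, tol=1e-8, max_iter=5000)[0]
        assert np.abs(om - np.linalg.inv(s)).max() < 1e-6

    def test_empty_support_at_and_above_lambda_max(self, rng):
        for _ in range(10):
            a = rng.standard_normal((4, 40))
            covs = [np.cov(a), np.cov(a + 0.1 * rng.standard_normal(a.shape))]
            lam = lambda_max(covs) * (1.0 + 1e-9)
            for om in fit_admm(covs, lam):
                assert support_of(om, tol=0.0) == frozenset()

    def test_support_nonempty_just_below_lambda_max(self, random_cov_factory):
        covs = random_cov_factory(4, m=2)
        lam = 0.95 * lambda_max(covs)
        sups = [support_of(om) for om in fit_admm(covs, lam)]
        assert any(sups)

    def test_matches_proximal_gradient_oracle(self, random_cov_factory):
        s = random_cov_factory(3)[0]
        lam = 0.1
        ours = fit_admm([s], lam, tol=1e-9, max_iter=20000)[0]
        ref = prox_gradient_minimize([s], lam)[0]
        assert oracle_objective([ours], [s], lam) <= oracle_objective([ref], [s], lam) + 1e-6
        assert np.abs(ours - ref).max() < 1e-4

    def test_optimal_objective_monotone_in_lambda(self, random_cov_factory):
        covs = random_cov_factory(4, m=3)
        lams = [0.0, 0.05, 0.1, 0.3]
        vals = []
        for lam in lams:
            oms = fit_admm(covs, lam, tol=1e-8, max_iter=5000)
            # evaluate at lam to compare optima of the same objective family
            vals.append(loggle_objective(oms, covs, lam))
        assert all(vals[i] <= vals[i + 1] + 1e-8 for i in range(len(vals) - 1))

    def test_outputs_symmetric_positive_definite(self, random_cov_factory):
        covs = random_cov_factory(5, m=3)
        for om in fit_admm(covs, 0.08):
            assert np.allclose(om, om.T)
            assert np.linalg.eigvalsh(om).min() > 0

    def test_non_convergence_carries_residuals(self, random_cov_factory):
        s = random_cov_factory(4)[0]
        with pytest.raises(ConvergenceError) as err:
            fit_admm([s], 0.05, tol=1e-14, max_iter=2)
        assert err.value.primal > 0 or err.value.dual > 0
        assert err.value.n_iter == 2


class TestBlockwise:
    def test_lambda_zero_gives_single_block(self, random_cov_factory):
        covs = random_cov_factory(5, m=2)
        blocks = blockwise_partition(covs, 0.0)
        assert len(blocks) == 1 and len(blocks[0]) == 5

    def test_block_diagonal_covariance_recovers_blocks(self, rng):
        s = np.zeros((4, 4))
        s[:2, :2] = [[2.0, 0.9], [0.9, 1.5]]
        s[2:, 2:] = [[1.0, 0.4], [0.4, 1.0]]
        blocks = blockwise_partition([s], 0.01)
        assert sorted(tuple(b) for b in blocks) == [(0, 1), (2, 3)]

    @pytest.mark.parametrize("lam_frac", [0.2, 0.5, 0.8])
    def test_assembled_blocks_match_full_admm_support(self, random_cov_factory, lam_frac):
        covs = random_cov_factory(6, m=2, n=12)  # noisy: nontrivial block structure
        lam = lam_frac * lambda_max(covs)
        full = fit_admm(covs, lam, tol=1e-7, max_iter=3000)
        assembled = fit_joint(covs, lam, blockwise=True, tol=1e-7, max_iter=3000)
        for f, a in zip(full, assembled):
            assert support_of(f) == support_of(a)


class TestRefitSupport:
    def test_full_support_is_plain_inverse(self, random_cov_factory):
        s = random_cov_factory(4)[0]
        full = frozenset((u, v) for u in range(4) for v in range(u + 1, 4))
        om = refit_support(s, full)
        assert np.abs(om - np.linalg.inv(s)).max() < 1e-5

    def test_empty_support_is_diagonal_mle(self, random_cov_factory):
        s = random_cov_factory(3)[0]
        om = refit_support(s, frozenset())
        assert om == pytest.approx(np.diag(1.0 / np.diag(s)))

    def test_support_from_tiny_lambda_refits_to_inverse(self, random_cov_factory):
        s = random_cov_factory(4)[0]
        sup = support_of(fit_admm([s], 1e-6, tol=1e-8, max_iter=5000)[0])
        om = refit_support(s, sup)
        assert np.abs(om - np.linalg.inv(s)).max() < 1e-3

    def test_off_support_entries_exactly_zero(self, random_cov_factory):
        s = random_cov_factory(4)[0]
        sup = frozenset({(0, 1), (2, 3)})
        om = refit_support(s, sup)
        assert om[0, 2] == 0.0 and om[1, 3] == 0.0 and om[0, 3] == 0.0
        assert np.linalg.eigvalsh(om).min() > 0


class TestFitPseudo:
    def test_huge_lambda_gives_empty_support(self, random_cov_factory):
        covs = random_cov_factory(4, m=2)
        sup, om = fit_pseudo(covs, 0, lam=100.0)
        assert sup == frozenset()
        assert om == pytest.approx(np.diag(1.0 / np.diag(covs[0])))

    def test_support_is_symmetric_by_construction(self, random_cov_factory):
        covs = random_cov_factory(6, m=3, n=15)
        sup, om = fit_pseudo(covs, 1, lam=0.05)
        assert np.allclose(om, om.T)
        for u, v in sup:
            assert u < v  # stored as unordered pairs

    def test_agrees_with_exact_mode_on_strong_edges(self):
        traj = tv.generate_graph_trajectory(p=10, n_grid=9, base_edges=8, n_changing=0, seed=5)
        ds = tv.sample_dataset(traj, [200] * 9, seed=6)
        X = tv.ExpressionMatrix(
            [f"g{i}" for i in range(10)],
            [f"s{j}" for j in range(ds.n_samples)],
            ds.values,
            times=ds.times,
        )
        spec = KernelSpec("epanechnikov", 0.15)
        Xc = tv.center_expressions(X, spec)
        covs = tv.covariance_series(Xc, traj.grid, spec)
        sub = covs.subset((3, 4, 5))
        lam = 0.15
        exact = support_of(fit_joint(sub, lam)[1])
        pseudo, _ = fit_pseudo(sub, 1, lam)
        n_pairs = 45
        agree = n_pairs - len(exact ^ pseudo)
        assert agree / n_pairs >= 0.9


class TestFitSeries:
    def test_kernel_method_equals_loggle_with_d_zero(self, small_dataset):
        traj, _, X = small_dataset
        spec = KernelSpec("epanechnikov", 0.2)
        Xc = tv.center_expressions(X, spec)
        a = fit_series(Xc, traj.grid, spec, d=0.0, lam=0.2, method="loggle")
        b = fit_series(Xc, traj.grid, spec, d=0.7, lam=0.2, method="kernel")
        assert a.supports == b.supports
        for ma, mb in zip(a.matrices, b.matrices):
            assert np.abs(ma - mb).max() < 1e-8

    def test_invar_method_yields_identical_supports(self, small_dataset):
        traj, _, X = small_dataset
        spec = KernelSpec("epanechnikov", 0.2)
        Xc = tv.center_expressions(X, spec)
        series = fit_series(Xc, traj.grid, spec, d=0.0, lam=0.15, method="invar")
        assert len(set(series.supports)) == 1

    def test_d_zero_matches_independent_graphical_lasso(self, small_dataset):
        from sklearn.covariance import graphical_lasso

        traj, _, X = small_dataset
        spec = KernelSpec("epanechnikov", 0.2)
        Xc = tv.center_expressions(X.take_genes([0, 1, 2, 3]), spec)
        covs = tv.covariance_series(Xc, traj.grid, spec)
        lam = 0.1
        for k in (0, 4, 8):
            corr, _ = tv.standardize_covariance(covs.matrices[k])
            ours = fit_admm([corr], lam, tol=1e-9, max_iter=20000)[0]
            _, ref = graphical_lasso(corr, alpha=lam, tol=1e-12, max_iter=2000)
            assert np.abs(ours - ref).max() < 1e-4

    def test_parameter_length_mismatch_rejected(self, small_dataset):
        traj, _, X = small_dataset
        spec = KernelSpec("epanechnikov", 0.2)
        Xc = tv.center_expressions(X, spec)
        with pytest.raises(ValueError):
            fit_series(Xc, traj.grid, spec, d=[0.1, 0.2], lam=0.1)

    def test_invar_requires_shared_lambda(self, small_dataset):
        traj, _, X = small_dataset
        spec = KernelSpec("epanechnikov", 0.2)
        Xc = tv.center_expressions(X, spec)
        with pytest.raises(ValueError, match="shared"):
            fit_series(Xc, traj.grid, spec, d=1.0, lam=np.linspace(0.1, 0.5, 9), method="invar")


class TestNeighborhoodIndex:
    def test_d_zero_is_singleton_and_d_one_is_everything(self):
        grid = np.linspace(0, 1, 9)
        assert NeighborhoodIndex.build(grid, 4, 0.0).members == (4,)
        assert NeighborhoodIndex.build(grid, 0, 1.0).members == tuple(range(9))

    def test_center_position(self):
        grid = np.linspace(0, 1, 9)
        nb = NeighborhoodIndex.build(grid, 3, 0.125)
        assert nb.members == (2, 3, 4)
        assert nb.center_pos == 1
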