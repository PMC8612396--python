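"""ECM building blocks and the constrained mixture estimator."""

import numpy as np
import pytest

from parsimix import (
    ConstraintSpec,
    ConstrainedGaussianMixture,
    MixtureParameters,
    check_constraints,
    e_step,
    initialize_parameters,
    m_step_weights_means,
    make_design_A,
    relative_change,
    rotation_change,
    update_rotation_common,
    update_scatters,
    update_shapes,
    update_volumes,
)
from parsimix.mixture import _scatter_objective


def _rot2(alpha):
    c, s = np.cos(alpha), np.sin(alpha)
    return np.array([[c, -s], [s, c]])


class TestConvergenceMonitors:
    def test_zero_for_identical(self, rng):
        x = rng.standard_normal((3, 4))
        assert relative_change(x, x.copy()) == 0.0
        assert rotation_change(np.eye(3), np.eye(3)) == 0.0

    def test_zero_norm_previous_forces_iteration(self):
        assert relative_change(np.zeros((2, 2)), np.ones((2, 2))) == np.inf
        assert relative_change(np.zeros((2, 2)), np.zeros((2, 2))) == 0.0

    def test_rotation_change_quarter_turn(self):
        """For a 2-D rotation by alpha vs the identity the monitor equals
        1 - cos(2 alpha); at alpha = pi/2 this evaluates to 2."""
        assert rotation_change(np.eye(2), _rot2(np.pi / 2)) == pytest.approx(2.0)
        alpha = 0.3
        assert rotation_change(np.eye(2), _rot2(alpha)) == pytest.approx(
            1 - np.cos(2 * alpha)
        )


class TestInitialization:
    def test_reproducible_under_seed(self, rng):
        X = rng.standard_normal((40, 3))
        a = initialize_parameters(X, 3, np.random.default_rng(7))
        b = initialize_parameters(X, 3, np.random.default_rng(7))
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.covariances, b.covariances)
        assert np.allclose(a.weights, 1 / 3)

    def test_single_component_from_p_plus_one_points(self, rng):
        X = rng.standard_normal((30, 2))
        params = initialize_parameters(X, 1, np.random.default_rng(0))
        assert params.means.shape == (1, 2)
        # covariance of p+1 = 3 points is generically nonsingular
        assert np.linalg.det(params.covariances[0]) > 0

    def test_too_few_observations_falls_back_to_replacement(self, rng):
        X = rng.standard_normal((5, 2))  # k(p+1) = 6 > n
        params = initialize_parameters(X, 2, np.random.default_rng(1))
        assert params.means.shape == (2, 2)
        for C in params.covariances:
            assert np.all(np.linalg.eigvalsh(C) > 0)

    def test_collinear_draw_gets_ridge(self):
        # all points on a line: every group covariance is singular
        t = np.linspace(0, 1, 20)
        X = np.column_stack([t, 2 * t])
        params = initialize_parameters(X, 2, np.random.default_rng(3))
        for C in params.covariances:
            assert np.linalg.det(C) > 0  # ridge applied, fit can proceed


class TestESterp:
    def test_identical_components_uniform_responsibilities(self, rng):
        cov = np.eye(2)
        params = MixtureParameters(
            weights=[0.5, 0.5],
            means=np.zeros((2, 2)),
            covariances=np.stack([cov, cov]),
        )
        tau, _ = e_step(rng.standard_normal((10, 2)), params, "em")
        assert np.allclose(tau, 0.5)

    def test_cem_tie_goes_to_lowest_index(self):
        params = MixtureParameters(
            weights=[0.5, 0.5],
            means=np.zeros((2, 2)),
            covariances=np.stack([np.eye(2), np.eye(2)]),
        )
        tau, _ = e_step(np.zeros((4, 2)), params, "cem")
        assert np.array_equal(tau.argmax(axis=1), np.zeros(4, dtype=int))

    def test_rows_normalize_and_cem_matches_em_argmax(self, rng, mixture_factory):
        params = mixture_factory(rng, 3, 4)
        X = rng.standard_normal((50, 4)) * 3
        tau_em, lw = e_step(X, params, "em")
        tau_cem, _ = e_step(X, params, "cem")
        assert np.allclose(tau_em.sum(axis=1), 1.0, atol=1e-12)
        assert np.array_equal(tau_cem.argmax(axis=1), lw.argmax(axis=1))


class TestMStep:
    def test_single_component_sample_moments(self, rng):
        X = rng.standard_normal((25, 3))
        tau = np.ones((25, 1))
        pi, mu, nj, S = m_step_weights_means(X, tau)
        assert np.allclose(mu[0], X.mean(axis=0))
        assert np.allclose(S[0], np.cov(X.T, bias=True))
        assert nj[0] == pytest.approx(25)

    def test_hard_labels_match_groupwise_moments(self, rng):
        X = rng.standard_normal((30, 2))
        labels = rng.integers(0, 3, size=30)
        tau = np.zeros((30, 3))
        tau[np.arange(30), labels] = 1.0
        pi, mu, nj, S = m_step_weights_means(X, tau)
        for j in range(3):
            G = X[labels == j]
            assert np.allclose(mu[j], G.mean(axis=0))
            assert np.allclose(S[j], np.cov(G.T, bias=True))

    def test_uniform_responsibilities_give_global_mean(self, rng):
        X = rng.standard_normal((40, 3))
        tau = np.full((40, 2), 0.5)
        _, mu, _, _ = m_step_weights_means(X, tau)
        assert np.allclose(mu[0], mu[1])
        assert np.allclose(mu[0], X.mean(axis=0))


def _random_moments(rng, k, p, spd_factory):
    nj = rng.uniform(5, 30, size=k)
    S = np.stack([spd_factory(rng, p) for _ in range(k)])
    return S, nj


class TestShapeUpdate:
    def test_spherical_limit(self, rng, spd_factory):
        S, nj = _random_moments(rng, 3, 4, spd_factory)
        d = np.ones(3)
        R = np.stack([np.eye(4)] * 3)
        spec = ConstraintSpec(c_shw=1, c_shb=1, rotation="I")
        D = update_shapes(S, nj, d, R, spec)
        assert np.allclose(D, 1.0)

    def test_common_shape_closed_form(self, rng):
        """With free within-shape, common shape and axis-aligned rotations a
        single pass gives the weighted mean of the per-component diagonals,
        renormalized to unit determinant."""
        k, p = 3, 3
        nj = np.array([10.0, 20.0, 5.0])
        diags = np.abs(rng.standard_normal((k, p))) + 0.5
        S = np.stack([np.diag(v) for v in diags])
        d = np.ones(k)
        R = np.stack([np.eye(p)] * k)
        spec = ConstraintSpec(c_shw=np.inf, c_shb=1, rotation="I")
        D = update_shapes(S, nj, d, R, spec)
        mean = (nj[:, None] * diags).sum(axis=0) / nj.sum()
        expected = mean / np.exp(np.mean(np.log(mean)))
        assert np.allclose(D, expected, rtol=1e-10)
        assert np.allclose(D[0], D[1]) and np.allclose(D[1], D[2])

    def test_output_satisfies_ratio_constraints(self, rng, spd_factory):
        for _ in range(20):
            k = int(rng.integers(2, 5))
            p = int(rng.integers(2, 5))
            S, nj = _random_moments(rng, k, p, spd_factory)
            rot = rng.choice(["I", "V"])
            c_shw = float(rng.choice([1.5, 4.0, 16.0]))
            spec = ConstraintSpec(
                c_shw=c_shw,
                c_shb=float(rng.uniform(1.0, c_shw ** ((p - 1) / p))),
                rotation=rot,
            )
            d = np.exp(rng.standard_normal(k))
            if rot == "V":
                R = np.stack([np.linalg.qr(rng.standard_normal((p, p)))[0] for _ in range(k)])
            else:
                R = np.stack([np.eye(p)] * k)
            D = update_shapes(S, nj, d, R, spec, max_iter=200, tol=1e-12)
            assert np.allclose(np.prod(D, axis=1), 1.0, atol=1e-8)
            assert np.all(D.max(axis=1) / D.min(axis=1) <= spec.c_shw * (1 + 1e-8))
            if rot == "V":
                Ds = -np.sort(-D, axis=1)
            else:
                Ds = D
            assert np.all(Ds.max(axis=0) / Ds.min(axis=0) <= spec.c_shb * (1 + 1e-6))


class TestVolumeUpdate:
    def test_equal_volume_limit_weighted_mean(self, rng, spd_factory):
        S, nj = _random_moments(rng, 3, 3, spd_factory)
        D = np.ones((3, 3))
        R = np.stack([np.eye(3)] * 3)
        d = update_volumes(S, nj, D, R, c_det=1.0)
        nu = np.array([np.trace(S[j]) / 3 for j in range(3)])
        assert np.allclose(d, np.sum(nj * nu) / nj.sum())

    def test_unbinding_constraint_returns_proxies(self, rng, spd_factory):
        S, nj = _random_moments(rng, 2, 2, spd_factory)
        D = np.ones((2, 2))
        R = np.stack([np.eye(2)] * 2)
        d = update_volumes(S, nj, D, R, c_det=1e12)
        nu = np.array([np.trace(S[j]) / 2 for j in range(2)])
        assert np.allclose(d, nu)

    def test_single_component_trace_over_p(self):
        S = np.array([[[4.0, 1.0], [1.0, 2.0]]])
        d = update_volumes(S, np.array([7.0]), np.ones((1, 2)), np.eye(2)[None], np.inf)
        assert d[0] == pytest.approx((4.0 + 2.0) / 2)


class TestRotationUpdate:
    def test_fixed_point_at_common_eigenvectors(self, rng, spd_factory):
        """When all scatters and shapes agree, the eigenvector basis of the
        common scatter (eigenvalues decreasing) is a fixed point."""
        p = 3
        S0 = spd_factory(rng, p)
        evals, evecs = np.linalg.eigh(S0)
        R0 = evecs[:, ::-1]
        S = np.stack([S0] * 2)
        nj = np.array([8.0, 12.0])
        D = np.tile(np.sort(evals)[::-1] / np.exp(np.mean(np.log(evals))), (2, 1))
        d = np.full(2, np.exp(np.mean(np.log(evals))))
        R, converged = update_rotation_common(S, nj, d, D, R0, max_iter=50, tol=1e-12)
        assert converged
        assert np.allclose(np.abs(R.T @ R0), np.eye(p), atol=1e-8)

    def test_objective_monotone_along_iterations(self, rng, spd_factory):
        """Each accepted majorization iterate does not increase the
        complete-data trace objective."""
        for _ in range(100):
            k = int(rng.integers(1, 4))
            p = int(rng.integers(2, 5))
            S = np.stack([spd_factory(rng, p) for _ in range(k)])
            nj = rng.uniform(2, 20, size=k)
            d = np.exp(rng.standard_normal(k))
            D = np.exp(rng.standard_normal((k, p)))
            D /= np.exp(np.mean(np.log(D), axis=1))[:, None]
            R0, _ = np.linalg.qr(rng.standard_normal((p, p)))
            Rs = np.broadcast_to(R0, (k, p, p)).copy()
            prev = _scatter_objective(S, nj, d, D, Rs)
            R = R0
            for _ in range(5):
                R, _ = update_rotation_common(S, nj, d, D, R, max_iter=1, tol=0)
                Rk = np.broadcast_to(R, (k, p, p)).copy()
                curr = _scatter_objective(S, nj, d, D, Rk)
                assert curr <= prev + 1e-9 * max(1, abs(prev))
                prev = curr


class TestScatterUpdate:
    def test_unconstrained_returns_weighted_scatters(self, rng, spd_factory):
        S, nj = _random_moments(rng, 3, 3, spd_factory)
        spec = ConstraintSpec(rotation="V")  # all infinite
        d, D, R, Sigma = update_scatters(S, nj, spec)
        assert np.allclose(Sigma, S, rtol=1e-8)

    def test_fully_constrained_pooled_spherical(self, rng, spd_factory):
        S, nj = _random_moments(rng, 3, 3, spd_factory)
        spec = ConstraintSpec(c_det=1, c_shw=1, c_shb=1, rotation="I")
        d, D, R, Sigma = update_scatters(S, nj, spec)
        sigma2 = np.sum(nj * np.trace(S, axis1=1, axis2=2) / 3) / nj.sum()
        for j in range(3):
            assert np.allclose(Sigma[j], sigma2 * np.eye(3), rtol=1e-10)

    def test_random_specs_satisfy_constraints(self, rng, spd_factory):
        for _ in range(15):
            k = int(rng.integers(2, 5))
            p = int(rng.integers(2, 5))
            S, nj = _random_moments(rng, k, p, spd_factory)
            c_shw = float(rng.choice([1.0, 2.0, 8.0, np.inf]))
            spec = ConstraintSpec(
                c_det=float(rng.choice([1.0, 4.0, np.inf])),
                c_shw=c_shw,
                c_shb=1.0 if c_shw == 1.0 else float(rng.choice([1.0, 2.0])),
                rotation=str(rng.choice(["I", "E", "V"])),
            ).effective(p)
            d, D, R, Sigma = update_scatters(
                S, nj, spec, max_iter_scatter=100, tol_scatter=1e-10
            )
            params = MixtureParameters(
                weights=nj / nj.sum(),
                means=np.zeros((k, p)),
                covariances=Sigma,
                volumes=d,
                shapes=D,
                rotations=R,
            )
            assert check_constraints(params, spec, tol=1e-6).satisfied


class TestFit:
    def test_single_component_unconstrained_mle(self, rng):
        X = rng.standard_normal((40, 3)) @ np.diag([1.0, 2.0, 0.5]) + 1.0
        est = ConstrainedGaussianMixture(1, n_init=1, random_state=0).fit(X)
        assert np.allclose(est.means_[0], X.mean(axis=0), atol=1e-6)
        assert np.allclose(est.covariances_[0], np.cov(X.T, bias=True), rtol=1e-5)

    def test_em_target_history_non_decreasing(self):
        X, _, _ = make_design_A(seed=3)
        est = ConstrainedGaussianMixture(
            3, c_det=4, c_shw=16, c_shb=2, rotation="V", n_init=5, random_state=1
        ).fit(X)
        # the history starts at the random (possibly infeasible) initializer;
        # monotonicity holds from the first constrained iterate onward
        assert np.all(np.diff(est.target_history_[1:]) >= -1e-8)

    def test_fitted_result_satisfies_constraints(self):
        X, _, _ = make_design_A(seed=5)
        est = ConstrainedGaussianMixture(
            3, c_det=2, c_shw=8, c_shb=2, rotation="E", n_init=5, random_state=2
        ).fit(X)
        assert est.constraint_report_.satisfied
        # common rotation regime: all rotations coincide
        for j in range(1, 3):
            assert np.allclose(est.rotations_[0], est.rotations_[j])

    def test_engines_agree(self):
        """The numba fast path reproduces the reference numpy trajectory."""
        X, _, _ = make_design_A(seed=9)
        kwargs = dict(
            n_components=3, c_det=2, c_shw=100, c_shb=2, rotation="V",
            n_init=4, random_state=42,
        )
        a = ConstrainedGaussianMixture(**kwargs, engine="numpy").fit(X)
        b = ConstrainedGaussianMixture(**kwargs, engine="numba").fit(X)
        assert a.log_likelihood_ == pytest.approx(b.log_likelihood_, rel=1e-9)
        assert np.array_equal(a.labels_, b.labels_)
        assert np.allclose(a.covariances_, b.covariances_, rtol=1e-7)

    def test_cem_equal_spherical_partition_locally_optimal(self, rng):
        """Under the fully constrained spherical CEM limit, no single-point
        reassignment improves the classification likelihood."""
        X, _, _ = make_design_A(seed=11)
        est = ConstrainedGaussianMixture(
            3, c_det=1, c_shw=1, c_shb=1, rotation="I", mode="cem",
            n_init=5, random_state=3,
        ).fit(X)
        from parsimix import classification_loglik

        base = est.log_likelihood_
        labels = est.labels_.copy()
        assert base == pytest.approx(classification_loglik(X, est.params_, labels))
        # one-step reassignment oracle at the fitted parameters
        for i in range(0, X.shape[0], 7):
            for j in range(3):
                if j == labels[i]:
                    continue
                alt = labels.copy()
                alt[i] = j
                assert classification_loglik(X, est.params_, alt) <= base + 1e-9

    def test_constrained_beats_unconstrained_on_noisy_design(self):
        """With the true-ratio constants the fit recovers the partition far
        better than the unconstrained fit on identical starts."""
        from parsimix import adjusted_rand_index

        X, y, truth = make_design_A(seed=13)
        rep = check_constraints(truth.with_decomposition("V"), ConstraintSpec())
        constrained = ConstrainedGaussianMixture(
            3,
            c_det=rep.deter_ratio,
            c_shw=float(rep.shw_ratios.max()),
            c_shb=float(rep.shb_ratios.max()),
            rotation="V",
            n_init=10,
            random_state=4,
        ).fit(X)
        unconstrained = ConstrainedGaussianMixture(
            3, rotation="V", n_init=10, random_state=4
        ).fit(X)
        ari_c = adjusted_rand_index(y, constrained.labels_)
        ari_u = adjusted_rand_index(y, unconstrained.labels_)
        assert ari_c > ari_u + 0.1

    def test_predict_matches_training_labels(self):
        X, _, _ = make_design_A(seed=17)
        est = ConstrainedGaussianMixture(
            3, c_det=2, c_shw=100, c_shb=2, n_init=5, random_state=5
        ).fit(X)
        assert np.array_equal(est.predict(X), est.labels_)
        proba = est.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert np.array_equal(proba.argmax(axis=1), est.labels_)

    def test_best_target_nested_in_constraint_constants(self):
        """Loosening the constraints enlarges the feasible set, so the best
        achieved target is non-decreasing along a chain of constants."""
        X, _, _ = make_design_A(seed=29)
        targets = []
        for c in [1.0, 2.0, 4.0, 16.0, 256.0, np.inf]:
            cshb = c ** (2 / 3) if np.isfinite(c) else np.inf
            est = ConstrainedGaussianMixture(
                3, c_det=c, c_shw=c, c_shb=cshb, rotation="V",
                n_init=10, random_state=77,
            ).fit(X)
            targets.append(est.log_likelihood_)
        assert np.all(np.diff(targets) >= -1e-6)

    def test_sklearn_param_interface(self):
        est = ConstrainedGaussianMixture(3, c_det=2.0)
        params = est.get_params()
        assert params["n_components"] == 3 and params["c_det"] == 2.0
        est.set_params(c_det=4.0)
        assert est.c_det == 4.0
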