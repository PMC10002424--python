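import numpy as np
import pytest

from cropcal.smoothers import (ILUESConfig, MDASchedule, es_update,
                               esmda_run, ilues_objective, ilues_run,
                               kalman_gain, reflect_into_bounds)


class TestKalmanGain:
    def test_scalar_identity_model_matches_hand_algebra(self):
        # f(m) = m, members {1,2,3}: sample var v=1, obs var r=0.5
        M = np.array([[1.0], [2.0], [3.0]])
        K = kalman_gain(M, M, np.array([[0.5]]))
        assert K[0, 0] == pytest.approx(1.0 / 1.5, rel=1e-6)

    def test_collapsed_ensemble_has_zero_gain(self):
        M = np.ones((5, 2))
        D = np.ones((5, 3))
        K = kalman_gain(M, D, np.eye(3))
        np.testing.assert_allclose(K, 0.0)

    def test_infinite_noise_limit(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(50, 2))
        D = rng.normal(size=(50, 3))
        K = kalman_gain(M, D, 1e6 * np.eye(3))
        assert np.abs(K).max() < 1e-4

    def test_too_few_members_rejected(self):
        with pytest.raises(ValueError):
            kalman_gain(np.ones((1, 2)), np.ones((1, 3)), np.eye(3))


class TestMDASchedule:
    def test_constant_schedule_satisfies_consistency(self):
        s = MDASchedule.constant(3)
        assert s.factors == (3.0, 3.0, 3.0)
        assert sum(1 / a for a in s.factors) == pytest.approx(1.0)

    def test_squared_variant(self):
        s = MDASchedule.constant(4, squared_constraint=True)
        assert s.factors[0] == pytest.approx(2.0)
        assert sum(1 / a**2 for a in s.factors) == pytest.approx(1.0)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            MDASchedule((2.0, 3.0))  # sum 1/alpha != 1
        with pytest.raises(ValueError):
            MDASchedule((0.5, 1.0))  # factor < 1


class TestBoundsReflection:
    def test_reflection_folds_back_symmetrically(self):
        bounds = np.array([[0.0, 1.0]])
        assert reflect_into_bounds(np.array([1.2]), bounds)[0] == \
            pytest.approx(0.8)
        assert reflect_into_bounds(np.array([-0.3]), bounds)[0] == \
            pytest.approx(0.3)
        assert reflect_into_bounds(np.array([0.4]), bounds)[0] == 0.4

    def test_far_overshoots_still_land_inside(self):
        bounds = np.array([[-1.0, 2.0], [0.0, 0.5]])
        rng = np.random.default_rng(1)
        X = rng.normal(0, 50, size=(200, 2))
        Y = reflect_into_bounds(X, bounds)
        assert (Y >= bounds[:, 0]).all() and (Y <= bounds[:, 1]).all()


class TestESUpdate:
    def test_linear_gaussian_posterior_recovered(self, linear_gaussian):
        lg = linear_gaussian
        rng = np.random.default_rng(3)
        mu0 = np.zeros(2)
        C0 = np.array([[1.0, 0.3], [0.3, 0.8]])
        ne = 2000
        M0 = rng.multivariate_normal(mu0, C0, ne)
        # analytic posterior with the Gaussian prior actually sampled
        Ri = np.linalg.inv(lg["R"])
        Cp = np.linalg.inv(np.linalg.inv(C0) + lg["H"].T @ Ri @ lg["H"])
        mp = Cp @ (np.linalg.inv(C0) @ mu0 + lg["H"].T @ Ri @ lg["d_obs"])
        M1, _ = es_update(lg["model"], M0, lg["model"](M0), lg["d_obs"],
                          lg["R"], rng=4)
        se = np.sqrt(np.diag(Cp) / ne)
        assert np.all(np.abs(M1.mean(axis=0) - mp) < 3 * se)
        np.testing.assert_allclose(np.cov(M1.T), Cp, rtol=0.2, atol=0.01)

    def test_identical_members_are_not_moved(self):
        M = np.tile([1.0, 2.0], (10, 1))
        model = lambda X: X @ np.array([[1.0], [1.0]])
        M1, _ = es_update(model, M, model(M), np.array([5.0]),
                          np.array([[0.1]]), rng=0)
        np.testing.assert_allclose(M1, M)

    def test_zero_residual_members_unchanged(self):
        # members differ but all predict the data exactly: C_MD = 0
        M = np.array([[0.0], [1.0], [2.0]])
        model = lambda X: np.full((len(np.atleast_2d(X)), 1), 5.0)
        M1, _ = es_update(model, M, model(M), np.array([5.0]),
                          np.array([[0.1]]), rng=0)
        np.testing.assert_allclose(M1, M)


class TestESMDA:
    def test_single_unit_factor_equals_plain_es_update(self, linear_gaussian):
        lg = linear_gaussian
        rng = np.random.default_rng(8)
        M0 = rng.uniform(-3, 3, size=(40, 2))
        res = esmda_run(lg["model"], M0, lg["d_obs"], lg["R"],
                        MDASchedule((1.0,)), seed=21)
        M_ref, _ = es_update(lg["model"], M0, lg["model"](M0), lg["d_obs"],
                             lg["R"], rng=np.random.default_rng(21))
        np.testing.assert_array_equal(res.samples, M_ref)

    def test_two_step_schedule_matches_single_step_moments(self,
                                                           linear_gaussian):
        lg = linear_gaussian
        rng = np.random.default_rng(9)
        mu0, C0 = np.zeros(2), np.eye(2)
        ne = 2000
        M0 = rng.multivariate_normal(mu0, C0, ne)
        Ri = np.linalg.inv(lg["R"])
        Cp = np.linalg.inv(np.linalg.inv(C0) + lg["H"].T @ Ri @ lg["H"])
        mp = Cp @ lg["H"].T @ Ri @ lg["d_obs"]
        r1 = esmda_run(lg["model"], M0, lg["d_obs"], lg["R"],
                       MDASchedule((1.0,)), seed=1)
        r2 = esmda_run(lg["model"], M0, lg["d_obs"], lg["R"],
                       MDASchedule.constant(2), seed=2)
        se = 3 * np.sqrt(np.diag(Cp) / ne)
        for res in (r1, r2):
            assert np.all(np.abs(res.samples.mean(axis=0) - mp) < se)

    def test_history_and_map_bookkeeping(self, linear_gaussian):
        lg = linear_gaussian
        M0 = np.random.default_rng(2).uniform(-2, 2, size=(30, 2))
        res = esmda_run(lg["model"], M0, lg["d_obs"], lg["R"],
                        MDASchedule.constant(3), seed=5,
                        bounds=lg["bounds"])
        assert len(res.history["iterations"]) == 4  # prior + 3 updates
        assert res.map_index == int(np.argmax(res.log_likelihoods))
        assert (res.samples >= lg["bounds"][:, 0]).all()
        assert (res.samples <= lg["bounds"][:, 1]).all()


class TestILUESObjective:
    def test_hand_computed_three_member_toy(self):
        # f(m)=m, d=1, CD=1, m_ref=0, CMM=1:
        # J1 = (1-m)^2 = [1,0,1]; J2 = m^2 = [0,1,4]
        # J = J1/1 + J2/4 = [1.0, 0.25, 2.0]
        M = np.array([[0.0], [1.0], [2.0]])
        J = ilues_objective(M, M.copy(), np.array([1.0]), np.eye(1),
                            np.array([0.0]), np.eye(1))
        np.testing.assert_allclose(J, [1.0, 0.25, 2.0], atol=1e-9)
        assert list(np.argsort(J)) == [1, 0, 2]

    def test_reference_member_has_zero_distance_term(self):
        M = np.array([[0.5], [1.0], [2.0]])
        J = ilues_objective(M, M.copy(), np.array([9.0]), np.eye(1),
                            np.array([0.5]), np.eye(1), a=0.0, b=1.0)
        assert J[0] == 0.0

    def test_exact_fit_has_zero_misfit_term(self):
        M = np.array([[0.5], [1.0], [2.0]])
        D = np.array([[9.0], [1.0], [4.0]])
        J = ilues_objective(M, D, np.array([9.0]), np.eye(1),
                            np.array([0.0]), np.eye(1), a=1.0, b=0.0)
        assert J[0] == 0.0


class TestILUESRun:
    def test_local_ensemble_size_from_fraction(self):
        assert ILUESConfig(ensemble_size=500, local_fraction=0.1).n_local \
            == 50
        assert ILUESConfig(ensemble_size=50, local_fraction=1.0).n_local \
            == 50
        with pytest.raises(ValueError):
            ILUESConfig(ensemble_size=10, local_fraction=0.05)

    def test_bimodal_posterior_modes_both_kept(self):
        # forward f(m)=m^2, obs 4: posterior modes at -2 and +2
        model = lambda M: np.atleast_2d(M)**2
        CD = np.array([[0.25]])
        bounds = np.array([[-5.0, 5.0]])
        rng = np.random.default_rng(12)
        prior = rng.uniform(-5, 5, size=(100, 1))
        res = ilues_run(model, prior, np.array([4.0]), CD,
                        ILUESConfig(ensemble_size=100, n_iterations=4,
                                    seed=12),
                        bounds=bounds)
        S = res.samples[:, 0]
        assert (np.abs(S - 2) < 0.5).mean() >= 0.2
        assert (np.abs(S + 2) < 0.5).mean() >= 0.2

    def test_global_limit_runs_and_respects_bounds(self, linear_gaussian):
        lg = linear_gaussian
        M0 = np.random.default_rng(4).uniform(-2, 2, size=(30, 2))
        res = ilues_run(lg["model"], M0, lg["d_obs"], lg["R"],
                        ILUESConfig(ensemble_size=30, n_iterations=2,
                                    local_fraction=1.0, a=1.0, b=0.0,
                                    seed=3),
                        bounds=lg["bounds"])
        assert res.samples.shape == (30, 2)
        assert np.isfinite(res.samples).all()
        assert (res.samples >= lg["bounds"][:, 0]).all()
        assert (res.samples <= lg["bounds"][:, 1]).all()

    def test_linear_gaussian_mean_recovered(self, linear_gaussian):
        # with alpha=1 the local set is global; ILUES should land near
        # the analytic posterior mean even with random member adoption
        lg = linear_gaussian
        rng = np.random.default_rng(6)
        M0 = rng.multivariate_normal(np.zeros(2), np.eye(2), 400)
        Ri = np.linalg.inv(lg["R"])
        Cp = np.linalg.inv(np.eye(2) + lg["H"].T @ Ri @ lg["H"])
        mp = Cp @ lg["H"].T @ Ri @ lg["d_obs"]
        res = ilues_run(lg["model"], M0, lg["d_obs"], lg["R"],
                        ILUESConfig(ensemble_size=400, n_iterations=1,
                                    local_fraction=1.0, seed=7))
        assert np.all(np.abs(res.samples.mean(axis=0) - mp)
                      < 6 * np.sqrt(np.diag(Cp) / 400))
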