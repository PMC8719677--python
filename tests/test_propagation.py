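"""Centered ridge activity model: oracle equivalence, CV, FOV, permutation
null, propagator calling, and recovery on generator truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from conftest import direct_noise_matrix, network_frame
from noiseprop import propagation, synth
from noiseprop.propagation import ActivityEstimates, CenteredModel


def brute_force_ridge(X, y, lam):
    """Independent oracle: numeric minimizer of ||y - Xa||^2 + lam*||a||^2."""

    def objective(a):
        r = y - X @ a
        return float(r @ r + lam * a @ a)

    def grad(a):
        return -2 * X.T @ (y - X @ a) + 2 * lam * a

    res = optimize.minimize(
        objective, np.zeros(X.shape[1]), jac=grad, method="BFGS",
        options={"gtol": 1e-14, "maxiter": 10_000},
    )
    return res.x


def make_model(X, Y, conds=None):
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    return CenteredModel(
        X=Xc, Y=Yc,
        promoter_ids=[f"p{i}" for i in range(X.shape[0])],
        regulator_ids=[f"tf{j}" for j in range(X.shape[1])],
        condition_ids=conds or [f"c{k}" for k in range(Y.shape[1])],
    )


class TestCentering:
    def _frames(self, n_promoters=100, n_network=80, seed=0):
        rng = np.random.default_rng(seed)
        pids = [f"p{i:03d}" for i in range(n_promoters)]
        N = pd.DataFrame(rng.normal(size=(n_promoters, 3)), index=pids,
                         columns=["c1", "c2", "c3"])
        S = pd.DataFrame(
            rng.integers(0, 2, size=(n_network, 4)), index=pids[:n_network],
            columns=[f"tf{j}" for j in range(4)],
        )
        return N, S

    def test_constant_noise_column_centers_to_zero(self):
        N, S = self._frames()
        N["c1"] = 0.7
        model = propagation.center_model_inputs(N, S)
        np.testing.assert_allclose(model.Y[:, 0], 0.0, atol=1e-12)

    def test_design_column_means_vanish(self):
        N, S = self._frames()
        model = propagation.center_model_inputs(N, S)
        assert np.abs(model.X.mean(axis=0)).max() < 1e-12

    def test_unannotated_drop_vs_zero_row_modes(self):
        N, S = self._frames()
        dropped = propagation.center_model_inputs(N, S, unannotated="drop")
        zeroed = propagation.center_model_inputs(N, S, unannotated="zero")
        assert len(dropped.promoter_ids) == 80
        assert dropped.n_unannotated == 20
        assert len(zeroed.promoter_ids) == 100
        assert zeroed.n_unannotated == 20

    def test_empty_intersection_rejected(self):
        N, S = self._frames()
        S.index = [f"x{i}" for i in range(len(S))]
        with pytest.raises(ValueError):
            propagation.center_model_inputs(N, S, unannotated="drop")


class TestRidgeSolution:
    def test_three_promoter_toy_matches_bruteforce(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        y = np.array([0.1, 0.2, 0.3])
        model = make_model(X, y)
        est = propagation.infer_activities(model, lam=1.0)
        expected = brute_force_ridge(model.X, model.Y[:, 0], 1.0)
        np.testing.assert_allclose(est.A.to_numpy()[:, 0], expected, atol=1e-8)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_small_instances_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n, r = rng.integers(3, 6), rng.integers(1, 6)
        X = rng.normal(size=(n, r))
        y = rng.normal(size=n)
        lam = float(rng.uniform(0.1, 5.0))
        model = make_model(X, y)
        est = propagation.infer_activities(model, lam)
        expected = brute_force_ridge(model.X, model.Y[:, 0], lam)
        np.testing.assert_allclose(est.A.to_numpy()[:, 0], expected, atol=1e-8)

    def test_zero_response_gives_zero_activities(self):
        model = make_model(np.eye(4), np.zeros(4))
        est = propagation.infer_activities(model, 1.0)
        np.testing.assert_allclose(est.A.to_numpy(), 0.0, atol=1e-15)

    def test_huge_prior_shrinks_to_zero(self):
        rng = np.random.default_rng(1)
        model = make_model(rng.normal(size=(50, 5)), rng.normal(size=50))
        est = propagation.infer_activities(model, 1e12)
        assert np.abs(est.A.to_numpy()).max() < 1e-6

    def test_singular_unpenalized_system_rejected(self):
        X = np.ones((6, 2))  # duplicated columns
        rng = np.random.default_rng(2)
        model = make_model(X * rng.normal(size=(6, 1)), rng.normal(size=6))
        model.X[:, 1] = model.X[:, 0]
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            propagation.infer_activities(model, 0.0)

    def test_error_bars_positive(self):
        rng = np.random.default_rng(3)
        model = make_model(rng.integers(0, 2, (80, 6)), rng.normal(size=(80, 3)))
        est = propagation.infer_activities(model, 1.0)
        assert (est.delta_A.to_numpy() > 0).all()


class TestPriorSelection:
    def _signal_data(self, seed=0, resid_sd=0.001):
        rng = np.random.default_rng(seed)
        P, R, C = 400, 10, 3
        pids = [f"p{i}" for i in range(P)]
        S = pd.DataFrame(rng.integers(0, 2, (P, R)), index=pids,
                         columns=[f"tf{j}" for j in range(R)])
        A = rng.uniform(0.02, 0.08, (R, C))
        N = pd.DataFrame(S.to_numpy() @ A + rng.normal(0, resid_sd, (P, C)),
                         index=pids, columns=[f"c{k}" for k in range(C)])
        return N, S

    def test_single_element_grid_returned(self):
        N, S = self._signal_data()
        lam, _ = propagation.select_prior_strength(N, S, [3.0], k_folds=4, seed=0)
        assert lam == 3.0

    def test_strong_signal_prefers_weak_prior(self):
        N, S = self._signal_data()
        grid = [0.01, 1.0, 100.0, 10_000.0]
        lam, table = propagation.select_prior_strength(N, S, grid, k_folds=5, seed=0)
        assert lam <= 1.0
        # out-of-fold FOV degrades as the prior overwhelms the signal
        assert table["mean_fov"].iloc[0] > table["mean_fov"].iloc[-1]

    def test_pure_noise_yields_nonpositive_out_of_fold_fov(self):
        rng = np.random.default_rng(4)
        P = 400
        pids = [f"p{i}" for i in range(P)]
        S = pd.DataFrame(rng.integers(0, 2, (P, 10)), index=pids,
                         columns=[f"tf{j}" for j in range(10)])
        N = pd.DataFrame(rng.normal(size=(P, 3)), index=pids,
                         columns=["c1", "c2", "c3"])
        _, table = propagation.select_prior_strength(
            N, S, [0.1, 10.0, 1000.0], k_folds=5, seed=0
        )
        assert (table["mean_fov"] <= 0.005).all()


class TestExplainedVariance:
    def test_perfect_reconstruction_is_one(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 2, (60, 4)).astype(float)
        A = rng.uniform(0, 0.1, (4, 2))
        model = make_model(X, X @ A)
        fov = propagation.explained_variance(model, A)
        np.testing.assert_allclose(fov, 1.0, atol=1e-12)

    def test_zero_activities_explain_nothing(self):
        rng = np.random.default_rng(6)
        model = make_model(rng.integers(0, 2, (60, 4)), rng.normal(size=60))
        fov = propagation.explained_variance(model, np.zeros((4, 1)))
        np.testing.assert_allclose(fov, 0.0, atol=1e-12)

    def test_in_sample_fov_nonincreasing_in_lambda(self):
        rng = np.random.default_rng(7)
        model = make_model(rng.integers(0, 2, (100, 6)),
                           rng.normal(size=(100, 2)))
        fovs = [
            propagation.infer_activities(model, lam).fov.mean()
            for lam in (0.1, 1.0, 10.0, 100.0, 1000.0)
        ]
        assert (np.diff(fovs) <= 1e-12).all()

    def test_fitted_fov_tracks_plugin_truth(self, default_truth_direct):
        truth = default_truth_direct["truth"]
        N, S = default_truth_direct["N"], default_truth_direct["S"]
        model = propagation.center_model_inputs(N, S)
        fov_true = propagation.explained_variance(model, truth.activities)
        est = propagation.infer_activities(model, 0.1)
        assert np.abs(est.fov.to_numpy() - fov_true).max() <= 0.05


class TestPermutationNull:
    def test_fixed_seed_reproducible(self, default_truth_direct):
        N, S = default_truth_direct["N"], default_truth_direct["S"]
        a = propagation.randomized_fov(N, S, n_shuffles=5, lam=0.1, seed=42)
        b = propagation.randomized_fov(N, S, n_shuffles=5, lam=0.1, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_signal_far_exceeds_null(self, default_truth_direct):
        N, S = default_truth_direct["N"], default_truth_direct["S"]
        est = propagation.infer_activities(
            propagation.center_model_inputs(N, S), 0.1
        )
        null = propagation.randomized_fov(N, S, n_shuffles=50, lam=0.1, seed=1)
        z = (est.fov.to_numpy() - null["fov_mean"].to_numpy()) / null[
            "fov_se"
        ].to_numpy()
        assert z.min() >= 5

    def test_signal_free_data_within_null_scatter(self):
        truth = synth.simulate_ground_truth(
            P=800, n_condition_specific=0, n_global=0, seed=21
        )
        N, _ = direct_noise_matrix(truth, residual_sd=0.006, seed=22)
        S = network_frame(truth)
        est = propagation.infer_activities(
            propagation.center_model_inputs(N, S), 0.1
        )
        null = propagation.randomized_fov(N, S, n_shuffles=100, lam=0.1, seed=2)
        z = (est.fov.to_numpy() - null["fov_mean"].to_numpy()) / null[
            "fov_sd"
        ].to_numpy()
        assert np.abs(z).max() <= 3


def crafted_estimates(A, dA, conds=None):
    regs = [f"tf{i}" for i in range(A.shape[0])]
    conds = conds or [f"c{j}" for j in range(A.shape[1])]
    model = CenteredModel(
        X=np.zeros((1, len(regs))), Y=np.zeros((1, len(conds))),
        promoter_ids=["p0"], regulator_ids=regs, condition_ids=conds,
    )
    return ActivityEstimates(
        A=pd.DataFrame(A, index=regs, columns=conds),
        delta_A=pd.DataFrame(dA, index=regs, columns=conds),
        lam=1.0,
        sigma2=pd.Series(1.0, index=conds),
        fov=pd.Series(0.5, index=conds),
        n_promoters=1,
        model=model,
    )


class TestPropagatorCalling:
    def test_all_zero_activities_give_empty_lists(self):
        est = crafted_estimates(np.zeros((4, 3)), np.ones((4, 3)))
        table, per_cond = propagation.condition_specific_propagators(est)
        assert table.empty
        assert all(len(v) == 0 for v in per_cond.values())

    def test_two_condition_regulator_excluded_from_specific_list(self):
        A = np.array([[0.5, 0.5, 0.0], [0.5, 0.0, 0.0], [0.0, 0.0, 0.0]])
        est = crafted_estimates(A, np.full((3, 3), 0.1))
        table, per_cond = propagation.condition_specific_propagators(est)
        assert list(table["regulator_id"]) == ["tf1"]
        assert per_cond["c0"] == ["tf0", "tf1"] and per_cond["c1"] == ["tf0"]

    def test_single_condition_averages_passthrough(self):
        est = crafted_estimates(np.array([[0.5], [0.05]]),
                                np.array([[0.1], [0.1]]))
        avg = propagation.average_activities(est)
        assert list(avg["regulator_id"]) == ["tf0"]  # tf1 below its error bar
        assert avg["A_bar"].iloc[0] == pytest.approx(0.5)
        assert avg["delta_A_bar"].iloc[0] == pytest.approx(0.1)

    def test_global_propagators_fill_top_slots(self, default_truth_direct):
        truth = default_truth_direct["truth"]
        N, S = default_truth_direct["N"], default_truth_direct["S"]
        est = propagation.infer_activities(
            propagation.center_model_inputs(N, S), 0.1
        )
        avg = propagation.average_activities(est)
        expect = {
            truth.regulator_ids[i]
            for i in synth.globally_active_rows(truth.activities)
        }
        assert set(avg[avg["top"]]["regulator_id"]) == expect


class TestRecovery:
    def test_inferred_activities_track_truth(self, default_truth_direct):
        truth = default_truth_direct["truth"]
        N, S = default_truth_direct["N"], default_truth_direct["S"]
        est = propagation.infer_activities(
            propagation.center_model_inputs(N, S), 0.1
        )
        A_hat = est.A.loc[truth.regulator_ids, truth.condition_ids].to_numpy()
        r = np.corrcoef(truth.activities.ravel(), A_hat.ravel())[0, 1]
        assert r >= 0.8
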