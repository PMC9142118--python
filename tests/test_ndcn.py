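import numpy as np
import pytest

import dynbrain as db
from dynbrain.ndcn import (
    CouplingGraph,
    NdcnConfig,
    NdcnModel,
    _init_params,
    _loss_and_grads,
    _normalized_operator,
    load_model,
    save_model,
    training_loss,
)
from dynbrain.snapshots import Snapshot, SnapshotSequence


def _identity_model(m=1, solver="rk4", step=0.2, W_h=None):
    """Linear model with identity codec: dynamics fully hand-specified."""
    cfg = NdcnConfig(ode_solver=solver, step_size=step,
                     activation="linear", encoder_activation="linear")
    params = {
        "W_e": np.eye(m), "b_e": np.zeros(m),
        "W_h": -np.eye(m) if W_h is None else W_h, "b_h": np.zeros(m),
        "W_d": np.eye(m), "b_d": np.zeros(m),
    }
    return NdcnModel(params=params,
                     coupling=CouplingGraph(np.zeros((m, m)), np.eye(m)),
                     config=cfg)


class TestCouplingGraph:
    def test_single_snapshot_thresholds_itself(self, symmetric_matrix):
        X = symmetric_matrix(5, seed=3)
        seq = SnapshotSequence("s", [Snapshot(0.0, np.clip(X, -1, 1))])
        g = db.build_coupling_graph(seq, density=0.3)
        iu = np.triu_indices(5, k=1)
        kept = np.count_nonzero(g.adjacency[iu])
        assert kept == round(0.3 * 10)
        # kept weights are the largest |entries|
        w = np.abs(np.clip(X, -1, 1))[iu]
        assert g.adjacency[iu].max() == pytest.approx(w.max())

    def test_mean_idempotent_for_identical_snapshots(self, symmetric_matrix):
        X = np.clip(symmetric_matrix(5, seed=4), -1, 1)
        one = db.build_coupling_graph(
            SnapshotSequence("s", [Snapshot(0.0, X)]), density=0.4)
        two = db.build_coupling_graph(
            SnapshotSequence("s", [Snapshot(0.0, X), Snapshot(1.0, X)]),
            density=0.4)
        assert np.allclose(one.adjacency, two.adjacency)
        assert np.allclose(one.operator, two.operator)

    def test_operator_matches_hand_computation(self):
        # 3-node chain with unit weights
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        op = _normalized_operator(A)
        A_hat = A + np.eye(3)
        d = A_hat.sum(axis=1)
        expected = A_hat / np.sqrt(np.outer(d, d))
        assert np.allclose(op, expected)
        assert np.linalg.norm(op, 2) <= 1.0 + 1e-9

    def test_operator_spectral_norm_bounded(self, toy_series):
        seq = db.build_observed_snapshots(toy_series, db.WindowScheme(6, 5))
        g = db.build_coupling_graph(seq, density=0.3)
        assert np.linalg.norm(g.operator, 2) <= 1.0 + 1e-9

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            db.build_coupling_graph(SnapshotSequence("s", []), 0.2)


class TestDynamicsRhs:
    def test_zero_weights_stationary(self):
        model = _identity_model(3, W_h=np.zeros((3, 3)))
        H = np.ones((3, 3))
        assert np.array_equal(db.dynamics_rhs(model, H), np.zeros((3, 3)))

    def test_negative_identity_gives_decay_field(self):
        model = _identity_model(2)
        H = np.array([[1.0, -2.0], [0.5, 3.0]])
        assert np.allclose(db.dynamics_rhs(model, H), -H)

    def test_matches_dense_arithmetic_oracle(self):
        rng = np.random.default_rng(5)
        m, d = 4, 3
        A = rng.random((m, m))
        A = (A + A.T) / 2
        op = _normalized_operator(A)
        cfg = NdcnConfig(hidden_dim=d)
        params = _init_params(m, d, rng)
        model = NdcnModel(params=params, coupling=CouplingGraph(A, op), config=cfg)
        H = rng.normal(size=(m, d))
        expected = np.tanh(op @ H @ params["W_h"] + params["b_h"])
        assert np.allclose(db.dynamics_rhs(model, H), expected)

    def test_shape_mismatch_rejected(self):
        model = _identity_model(2)
        with pytest.raises(ValueError, match="shape"):
            db.dynamics_rhs(model, np.ones((3, 2)))


class TestIntegrate:
    def test_zero_dynamics_is_exact_identity(self, symmetric_matrix):
        model = _identity_model(4, W_h=np.zeros((4, 4)))
        x0 = symmetric_matrix(4)
        out = db.integrate(model, x0, np.array([0.5, 1.0, 7.3]))
        for X in out:
            assert np.array_equal(X, x0)

    @pytest.mark.parametrize("solver,tol", [("rk4", 1e-3), ("adaptive", 1e-3)])
    def test_scalar_decay_closed_form(self, solver, tol):
        model = _identity_model(1, solver=solver)
        out = db.integrate(model, np.array([[1.0]]), np.array([1.0]))
        assert out[0][0, 0] == pytest.approx(np.exp(-1.0), abs=tol)

    def test_two_node_diffusion_closed_form(self):
        # dX/dt = -L X on a single edge: eigenmodes give
        # x1(t) = (1+e^{-2t})/2, x2(t) = (1-e^{-2t})/2
        L = np.array([[1.0, -1.0], [-1.0, 1.0]])
        model = _identity_model(2, W_h=None)
        model.params["W_h"] = np.eye(2)
        model.coupling = CouplingGraph(np.zeros((2, 2)), -L)
        x0 = np.array([[1.0, 1.0], [0.0, 0.0]])  # each column starts at [1, 0]
        t = 0.8   # a grid point of the default 0.2 step
        out = db.integrate(model, x0, np.array([t]))[0]
        expected_1 = (1 + np.exp(-2 * t)) / 2
        expected_2 = (1 - np.exp(-2 * t)) / 2
        assert out[0, 0] == pytest.approx(expected_1, abs=1e-4)
        assert out[1, 0] == pytest.approx(expected_2, abs=1e-4)

    def test_euler_first_order_convergence(self):
        errs = []
        for h in (0.1, 0.05, 0.025, 0.0125):
            model = _identity_model(1, solver="euler", step=h)
            out = db.integrate(model, np.array([[1.0]]), np.array([1.0]))
            errs.append(abs(out[0][0, 0] - np.exp(-1.0)))
        ratios = [errs[i] / errs[i + 1] for i in range(3)]
        assert all(1.8 <= r <= 2.2 for r in ratios)

    def test_invalid_times_rejected(self, symmetric_matrix):
        model = _identity_model(3, W_h=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            db.integrate(model, symmetric_matrix(3), np.array([1.0, 0.5]))


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        m, d = 4, 3
        A = rng.random((m, m))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        for loss_norm in ("l2", "l1"):
            cfg = NdcnConfig(ode_solver="rk4", step_size=0.25,
                             loss_norm=loss_norm, hidden_dim=d, seed=1)
            model = NdcnModel(params=_init_params(m, d, rng),
                              coupling=CouplingGraph(A, _normalized_operator(A)),
                              config=cfg)
            model.params["W_h"] = rng.normal(0, 0.3, (d, d))
            x0 = rng.normal(size=(m, m))
            x0 = (x0 + x0.T) / 2
            rel = np.array([0.0, 1.0, 2.0])
            obs = [x0] + [rng.normal(size=(m, m)) for _ in range(2)]
            _, grads = _loss_and_grads(model, x0, rel, obs)
            eps = 1e-6
            for k in ("W_h", "W_e", "W_d", "b_h"):
                p = model.params[k]
                idx = (0,) * p.ndim
                p[idx] += eps
                lp, _ = _loss_and_grads(model, x0, rel, obs)
                p[idx] -= 2 * eps
                lm, _ = _loss_and_grads(model, x0, rel, obs)
                p[idx] += eps
                num = (lp - lm) / (2 * eps)
                assert grads[k][idx] == pytest.approx(num, rel=1e-4, abs=1e-9)


class TestFit:
    def test_stationary_sequence_fits_to_small_loss(self, symmetric_matrix):
        X = np.clip(symmetric_matrix(8, seed=0), -1, 1)
        np.fill_diagonal(X, 1.0)
        seq = SnapshotSequence(
            "s", [Snapshot(float(t), X) for t in (0, 2, 4, 6, 8)])
        coupling = db.build_coupling_graph(seq, 0.5)
        model = db.fit(seq, coupling,
                       NdcnConfig(epochs=400, step_size=0.5, seed=0))
        assert model.final_loss < 0.05
        preds = db.predict_in_snapshots(model, np.array([1.0, 5.0]))
        for p in preds:
            assert np.mean(np.abs(p.matrix - X)) < 0.05

    def test_interpolates_graph_diffusion(self, fitted_diffusion_model,
                                          diffusion_truth):
        _, evaluate = diffusion_truth
        held = np.array([0.5, 2.5, 3.5, 5.5, 6.5, 8.5])
        preds = db.predict_in_snapshots(fitted_diffusion_model, held)
        mae = np.mean([np.mean(np.abs(p.matrix - evaluate(p.time_index)))
                       for p in preds])
        assert mae < 0.05

    def test_seed_robustness_of_final_loss(self, diffusion_truth):
        seq, _ = diffusion_truth
        coupling = db.build_coupling_graph(seq, 0.5)
        losses = [
            db.fit(seq, coupling,
                   NdcnConfig(step_size=0.25, epochs=200, seed=s)).final_loss
            for s in (0, 1)
        ]
        assert abs(losses[0] - losses[1]) < 0.05

    def test_needs_three_snapshots(self, symmetric_matrix):
        X = np.clip(symmetric_matrix(4), -1, 1)
        np.fill_diagonal(X, 1.0)
        seq = SnapshotSequence("s", [Snapshot(0.0, X), Snapshot(1.0, X)])
        with pytest.raises(ValueError, match="at least 3"):
            db.fit(seq, db.build_coupling_graph(seq, 0.5), NdcnConfig())

    def test_step_must_resolve_snapshot_spacing(self, diffusion_truth):
        seq, _ = diffusion_truth
        coupling = db.build_coupling_graph(seq, 0.5)
        with pytest.raises(ValueError, match="step_size"):
            db.fit(seq, coupling, NdcnConfig(step_size=1.5))

    def test_adaptive_solver_rejected_for_training(self, diffusion_truth):
        seq, _ = diffusion_truth
        coupling = db.build_coupling_graph(seq, 0.5)
        with pytest.raises(ValueError, match="fixed-step"):
            db.fit(seq, coupling, NdcnConfig(ode_solver="adaptive"))

    def test_prediction_at_training_times_reproduces_loss(
            self, fitted_diffusion_model, diffusion_truth):
        seq, _ = diffusion_truth
        recomputed = training_loss(fitted_diffusion_model, seq)
        assert recomputed == pytest.approx(fitted_diffusion_model.final_loss,
                                           abs=1e-12)


class TestPrediction:
    def test_in_snapshot_counts_per_volume_default(self, fitted_diffusion_model):
        model = fitted_diffusion_model
        seq = db.predict_in_snapshots(model)
        assert len(seq) == int(model.span[1]) + 1
        assert all(s.provenance == "in" for s in seq)

    def test_empty_request_empty_sequence(self, fitted_diffusion_model):
        assert len(db.predict_in_snapshots(fitted_diffusion_model,
                                           np.array([]))) == 0
        assert len(db.predict_out_snapshots(fitted_diffusion_model, 0)) == 0

    def test_out_of_span_redirects_to_extrapolation(self, fitted_diffusion_model):
        hi = fitted_diffusion_model.span[1]
        with pytest.raises(ValueError, match="extrapolation"):
            db.predict_in_snapshots(fitted_diffusion_model,
                                    np.array([hi + 5.0]))

    def test_out_snapshots_count_tag_and_range(self, fitted_diffusion_model):
        out = db.predict_out_snapshots(fitted_diffusion_model, 7)
        assert len(out) == 7
        assert all(s.provenance == "out" for s in out)
        assert all(np.all(np.abs(s.matrix) <= 1.0) for s in out)
        assert out.times[0] > fitted_diffusion_model.span[1]

    def test_predictions_symmetric(self, fitted_diffusion_model):
        for s in db.predict_in_snapshots(fitted_diffusion_model,
                                         np.array([1.3, 4.7])):
            assert np.allclose(s.matrix, s.matrix.T)


def test_checkpoint_round_trip(tmp_path, fitted_diffusion_model):
    p = save_model(fitted_diffusion_model, tmp_path / "model.npz")
    back = load_model(p)
    for k, v in fitted_diffusion_model.params.items():
        assert np.array_equal(back.params[k], v)
    assert back.span == fitted_diffusion_model.span
    assert back.config == fitted_diffusion_model.config
    a = db.predict_in_snapshots(fitted_diffusion_model, np.array([3.5]))[0]
    b = db.predict_in_snapshots(back, np.array([3.5]))[0]
    assert np.array_equal(a.matrix, b.matrix)
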