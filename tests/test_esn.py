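"""Echo state network core: initialization invariants, the leaky-integrator
update against scalar oracles, ridge readout against normal equations, and
the fading-memory property."""

import math

import numpy as np
import pytest

from esnmort import esn as E


def _manual_weights(w_in, w, config=None, w_out=None):
    cfg = config or E.ESNConfig(reservoir_size=w.shape[0], seed=0)
    return E.ESNWeights(w_in=np.asarray(w_in, dtype=float),
                        w=np.asarray(w, dtype=float), config=cfg,
                        w_out=w_out)


def _scalar_loop_update(w_in, w, x, u, alpha):
    """Independent pure-python evaluation of the state update."""
    n = len(x)
    out = []
    for i in range(n):
        drive = w_in[i][0]
        for k, uk in enumerate(u):
            drive += w_in[i][1 + k] * uk
        for j in range(n):
            drive += w[i][j] * x[j]
        out.append((1.0 - alpha) * x[i] + alpha * math.tanh(drive))
    return out


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        dict(reservoir_size=0),
        dict(leakage=0.0),
        dict(leakage=1.5),
        dict(connectivity=-0.1),
        dict(connectivity=1.1),
        dict(ridge_lambda=-1e-9),
        dict(spectral_radius=0.0),
        dict(washout=-1),
    ])
    def test_invalid_hyperparameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            E.ESNConfig(**kwargs)


class TestInitialization:
    def test_deterministic_given_seed(self):
        cfg = E.ESNConfig(reservoir_size=60, seed=42)
        a, b = E.init_esn(cfg, 10), E.init_esn(cfg, 10)
        np.testing.assert_array_equal(a.w_in, b.w_in)
        np.testing.assert_array_equal(a.w, b.w)

    def test_input_weights_uniform_in_half_interval(self):
        w = E.init_esn(E.ESNConfig(reservoir_size=200, seed=0), 30)
        assert w.w_in.shape == (200, 31)
        assert np.abs(w.w_in).max() <= 0.5

    def test_spectral_radius_rescaled_exactly(self):
        cfg = E.ESNConfig(reservoir_size=300, seed=1)
        w = E.init_esn(cfg, 5)
        rho = E.spectral_radius(w.w)
        assert rho == pytest.approx(cfg.spectral_radius, rel=1e-6)

    def test_zero_fraction_matches_connectivity(self):
        cfg = E.ESNConfig(reservoir_size=1000, connectivity=0.5, seed=3)
        w = E.init_esn(cfg, 5)
        frac_zero = np.mean(w.w == 0.0)
        sd = math.sqrt(0.25 / w.w.size)
        assert abs(frac_zero - 0.5) <= 3 * sd

    def test_zero_connectivity_skips_rescaling_with_warning(self, caplog):
        cfg = E.ESNConfig(reservoir_size=20, connectivity=0.0, seed=0)
        with caplog.at_level("WARNING", logger="esnmort.esn"):
            w = E.init_esn(cfg, 4)
        np.testing.assert_array_equal(w.w, 0.0)
        assert "rescaling skipped" in caplog.text

    def test_untrained_network_has_no_readout(self, tiny_config):
        assert not E.init_esn(tiny_config, 8).is_trained


class TestStateUpdate:
    def test_zero_weights_give_zero_state(self):
        w = _manual_weights(np.zeros((3, 4)), np.zeros((3, 3)))
        state = E.ReservoirState(np.array([0.3, -0.8, 0.1]))
        out = E.update_state(w, state, np.ones(3), alpha=1.0)
        np.testing.assert_array_equal(out.x, 0.0)

    def test_full_leakage_drops_previous_state_linearly(self, rng):
        w = _manual_weights(rng.uniform(-0.5, 0.5, (4, 3)),
                            rng.uniform(-0.5, 0.5, (4, 4)))
        x0 = rng.uniform(-1, 1, 4)
        u = rng.uniform(0, 1, 2)
        out = E.update_state(w, E.ReservoirState(x0), u, alpha=1.0)
        expected = np.tanh(w.w_in @ np.concatenate([[1.0], u]) + w.w @ x0)
        np.testing.assert_allclose(out.x, expected, rtol=0, atol=1e-15)

    @pytest.mark.parametrize("alpha", [0.3, 0.5, 1.0])
    def test_matches_scalar_loop_oracle_over_two_steps(self, alpha, rng):
        w_in = rng.uniform(-0.5, 0.5, (3, 3))
        w = rng.uniform(-0.5, 0.5, (3, 3))
        weights = _manual_weights(w_in, w)
        x = [0.0, 0.0, 0.0]
        state = E.ReservoirState(np.array(x))
        for step in range(2):
            u = [0.2 + 0.1 * step, 0.7]
            x = _scalar_loop_update(w_in.tolist(), w.tolist(), x, u, alpha)
            state = E.update_state(weights, state, np.array(u), alpha=alpha)
        np.testing.assert_allclose(state.x, x, rtol=0, atol=1e-12)

    def test_dimension_mismatch_names_the_matrix(self, tiny_config):
        w = E.init_esn(tiny_config, 8)
        with pytest.raises(ValueError, match="W_in"):
            E.update_state(w, E.ReservoirState.zeros(40), np.ones(5))
        with pytest.raises(ValueError, match="match W"):
            E.update_state(w, E.ReservoirState.zeros(7), np.ones(8))

    def test_bounded_state_with_full_leakage(self, tiny_config, rng):
        w = E.init_esn(tiny_config, 8)
        state = E.update_state(w, E.ReservoirState.zeros(40),
                               rng.uniform(0, 1, 8), alpha=1.0)
        assert np.all(np.abs(state.x) < 1.0)


class TestRunReservoir:
    def test_single_input_equals_one_update(self, tiny_config, rng):
        w = E.init_esn(tiny_config, 8)
        u = rng.uniform(0, 1, (1, 8))
        acts = E.run_reservoir(w, u)
        single = E.update_state(w, E.ReservoirState.zeros(40), u[0])
        np.testing.assert_array_equal(acts[:, 0], single.x)

    def test_split_and_chain_equals_one_pass(self, tiny_config, rng):
        w = E.init_esn(tiny_config, 8)
        u = rng.uniform(0, 1, (12, 8))
        full = E.run_reservoir(w, u)
        first = E.run_reservoir(w, u[:5])
        second = E.run_reservoir(w, u[5:],
                                 x0=E.ReservoirState(first[:, -1], n=5))
        np.testing.assert_allclose(np.hstack([first, second]), full,
                                   rtol=0, atol=1e-14)

    def test_matches_step_by_step_oracle(self, rng):
        w_in = rng.uniform(-0.5, 0.5, (4, 3))
        w_mat = rng.uniform(-0.5, 0.5, (4, 4))
        weights = _manual_weights(w_in, w_mat,
                                  config=E.ESNConfig(reservoir_size=4,
                                                     leakage=0.5, seed=0))
        u = rng.uniform(0, 1, (6, 2))
        acts = E.run_reservoir(weights, u)
        x = [0.0] * 4
        for t in range(6):
            x = _scalar_loop_update(w_in.tolist(), w_mat.tolist(), x,
                                    u[t].tolist(), 0.5)
            np.testing.assert_allclose(acts[:, t], x, rtol=0, atol=1e-12)

    def test_empty_sequence_rejected(self, tiny_config):
        w = E.init_esn(tiny_config, 8)
        with pytest.raises(ValueError, match="empty"):
            E.run_reservoir(w, np.empty((0, 8)))


class TestRidgeReadout:
    def test_zero_targets_give_zero_readout(self, tiny_config, rng):
        w = E.init_esn(tiny_config, 8)
        u = rng.uniform(0, 1, (15, 8))
        acts = E.run_reservoir(w, u)
        trained = E.train_readout(w, u, acts, np.zeros(15),
                                  ridge_lambda=1e-6, washout=0)
        np.testing.assert_allclose(trained.w_out, 0.0, atol=1e-12)

    @pytest.mark.parametrize("lam", [1e-8, 1e-2])
    def test_matches_normal_equation_oracle(self, lam, rng):
        """Small dense problem: the solver agrees with the explicit
        (D'D + lam I)^-1 D'y solution."""
        n_samples, n_inputs, n_res = 5, 2, 1
        u = rng.uniform(0, 1, (n_samples, n_inputs))
        acts = rng.uniform(-1, 1, (n_res, n_samples))
        y = rng.normal(size=n_samples)
        cfg = E.ESNConfig(reservoir_size=n_res, seed=0)
        w = _manual_weights(np.zeros((n_res, 1 + n_inputs)),
                            np.zeros((n_res, n_res)), config=cfg)
        trained = E.train_readout(w, u, acts, y, ridge_lambda=lam, washout=0)
        design = np.hstack([np.ones((n_samples, 1)), u, acts.T])
        oracle = np.linalg.solve(
            design.T @ design + lam * np.eye(design.shape[1]),
            design.T @ y)
        np.testing.assert_allclose(trained.w_out[0], oracle, atol=1e-8)

    @pytest.mark.parametrize("lam", [1e-8, 1e-2])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_primal_and_dual_forms_agree(self, lam, seed):
        """Overparameterized problems (features > samples) solved via the
        dual system agree with the explicit feature-space normal equations."""
        rng = np.random.default_rng(seed)
        n_samples, n_inputs, n_res = 12, 14, 30  # features 45 > samples
        u = rng.uniform(0, 1, (n_samples, n_inputs))
        acts = rng.uniform(-1, 1, (n_res, n_samples))
        y = rng.normal(size=n_samples)
        cfg = E.ESNConfig(reservoir_size=n_res, seed=0)
        w = _manual_weights(np.zeros((n_res, 1 + n_inputs)),
                            np.zeros((n_res, n_res)), config=cfg)
        trained = E.train_readout(w, u, acts, y, ridge_lambda=lam, washout=0)
        design = np.hstack([np.ones((n_samples, 1)), u, acts.T])
        primal = np.linalg.solve(
            design.T @ design + lam * np.eye(design.shape[1]),
            design.T @ y)
        np.testing.assert_allclose(trained.w_out[0], primal, atol=1e-6)

    def test_washout_excludes_leading_samples(self, tiny_config, rng):
        w = E.init_esn(tiny_config, 8)
        u = rng.uniform(0, 1, (20, 8))
        acts = E.run_reservoir(w, u)
        y = rng.normal(size=20)
        a = E.train_readout(w, u, acts, y, washout=6)
        b = E.train_readout(w, u[6:], acts[:, 6:], y[6:], washout=0)
        np.testing.assert_allclose(a.w_out, b.w_out, rtol=0, atol=1e-9)

    def test_negative_penalty_rejected(self, tiny_config, rng):
        w = E.init_esn(tiny_config, 8)
        u = rng.uniform(0, 1, (10, 8))
        acts = E.run_reservoir(w, u)
        with pytest.raises(ValueError):
            E.train_readout(w, u, acts, np.zeros(10), ridge_lambda=-1.0)

    def test_washout_longer_than_series_rejected(self, tiny_config, rng):
        w = E.init_esn(tiny_config, 8)
        u = rng.uniform(0, 1, (5, 8))
        acts = E.run_reservoir(w, u)
        with pytest.raises(ValueError, match="washout"):
            E.train_readout(w, u, acts, np.zeros(5), washout=5)

    def test_degenerate_design_warns_and_falls_back(self):
        cfg = E.ESNConfig(reservoir_size=2, seed=0)
        w = _manual_weights(np.zeros((2, 3)), np.zeros((2, 2)), config=cfg)
        u = np.zeros((4, 2))
        acts = np.zeros((2, 4))
        with pytest.warns(UserWarning, match="degenerate"):
            trained = E.train_readout(w, u, acts, np.full(4, 2.0),
                                      washout=0)
        assert trained.w_out is not None


class TestPredict:
    def test_zero_readout_gives_zero_outputs(self, tiny_config, rng):
        w = E.init_esn(tiny_config, 8)
        w.w_out = np.zeros((1, 1 + 8 + 40))
        out = E.predict(w, rng.uniform(0, 1, (6, 8)))
        np.testing.assert_array_equal(out, 0.0)

    def test_untrained_network_rejected(self, tiny_config, rng):
        w = E.init_esn(tiny_config, 8)
        with pytest.raises(ValueError, match="untrained"):
            E.predict(w, rng.uniform(0, 1, (6, 8)))

    def test_matches_hand_evaluation_of_output_equation(self, rng):
        cfg = E.ESNConfig(reservoir_size=3, leakage=1.0, seed=0)
        w_in = rng.uniform(-0.5, 0.5, (3, 3))
        w_mat = rng.uniform(-0.5, 0.5, (3, 3))
        w_out = rng.normal(size=(1, 1 + 2 + 3))
        w = _manual_weights(w_in, w_mat, config=cfg, w_out=w_out)
        u = rng.uniform(0, 1, (4, 2))
        out = E.predict(w, u)
        x = np.zeros(3)
        for t in range(4):
            x = np.tanh(w_in @ np.concatenate([[1.0], u[t]]) + w_mat @ x)
            d = np.concatenate([[1.0], u[t], x])
            assert out[t] == pytest.approx(float((w_out @ d)[0]), abs=1e-12)

    def test_interpolation_regime_reproduces_training_targets(self, rng):
        """With features >> samples and lambda -> 0 the readout
        interpolates: predicting on the training inputs returns the targets
        beyond the washout to near machine precision."""
        cfg = E.ESNConfig(reservoir_size=80, seed=2, washout=3,
                          ridge_lambda=1e-12)
        w = E.init_esn(cfg, 6)
        u = rng.uniform(0, 1, (20, 6))
        y = rng.normal(90.0, 5.0, size=20)
        acts = E.run_reservoir(w, u)
        trained = E.train_readout(w, u, acts, y)
        preds = E.predict(trained, u, activations=acts)
        np.testing.assert_allclose(preds[3:], y[3:], atol=1e-5)


class TestErrorMetric:
    def test_perfect_prediction_has_zero_error(self):
        m = E.rms_error([1.0, 2.0], [1.0, 2.0])
        assert m.rms == 0.0 and m.rms_relative == 0.0

    def test_three_four_residual_pair(self):
        m = E.rms_error([3.0, 4.0], [0.0, 0.0])
        assert m.rms == pytest.approx(math.sqrt(12.5), abs=1e-15)

    def test_relative_error_is_percent_of_mean_target(self):
        m = E.rms_error([91.2], [89.5])
        assert m.rms_relative == pytest.approx(1.7 / 89.5 * 100, abs=1e-9)

    def test_empty_or_mismatched_rejected(self):
        with pytest.raises(ValueError):
            E.rms_error([], [])
        with pytest.raises(ValueError):
            E.rms_error([1.0], [1.0, 2.0])


class TestDynamics:
    def test_fading_memory_below_unit_spectral_radius(self):
        """Two trajectories from different initial states converge under a
        common input sequence at spectral radius 0.8 (checked for the pure
        tanh update, alpha = 1; leakage < 1 slows the same geometric
        convergence)."""
        cfg = E.ESNConfig(reservoir_size=100, spectral_radius=0.8,
                          leakage=1.0, seed=8)
        w = E.init_esn(cfg, 5)
        rng = np.random.default_rng(21)
        inputs = rng.uniform(0, 1, (50, 5))
        a = E.ReservoirState(rng.uniform(-1, 1, 100))
        b = E.ReservoirState(rng.uniform(-1, 1, 100))
        dist = None
        for t in range(50):
            a = E.update_state(w, a, inputs[t])
            b = E.update_state(w, b, inputs[t])
            dist = float(np.linalg.norm(a.x - b.x))
        assert dist < 1e-6

    def test_outputs_continuous_in_leakage(self, tiny_config, rng):
        w = E.init_esn(tiny_config, 8)
        u = rng.uniform(0, 1, (10, 8))
        x0 = E.ReservoirState.zeros(40)
        base, bumped = x0, x0
        for t in range(10):
            base = E.update_state(w, base, u[t], alpha=0.5)
            bumped = E.update_state(w, bumped, u[t], alpha=0.5 + 1e-8)
        assert float(np.abs(base.x - bumped.x).max()) < 1e-5


class TestSerialization:
    def test_round_trip_preserves_weights_and_config(self, tiny_config, rng,
                                                     tmp_path):
        w = E.init_esn(tiny_config, 8)
        u = rng.uniform(0, 1, (12, 8))
        acts = E.run_reservoir(w, u)
        trained = E.train_readout(w, u, acts, rng.normal(size=12), washout=2)
        path = tmp_path / "esn.npz"
        E.save_esn(trained, path)
        back = E.load_esn(path)
        assert back.config == trained.config
        np.testing.assert_array_equal(back.w_in, trained.w_in)
        np.testing.assert_array_equal(back.w, trained.w)
        np.testing.assert_array_equal(back.w_out, trained.w_out)
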