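"""State-model contracts: architecture, Cox loss, multitask aggregation,
training behaviour, export round trip and random search."""

import numpy as np
import pytest

from metastate.state_model import (StateModelConfig,
                                   TrainedStateModel, build_model,
                                   cox_ph_loss, cox_ph_loss_grad, export_model,
                                   hyperparameter_search, load_model,
                                   multitask_loss, train_state_model)

TINY = dict(n_markers=20, n_endpoints=3, shared_widths=(12, 12, 16),
            head_mlp_widths=(8, 6, 4), skip_widths=(6, 6, 4),
            post_merge_widths=(8, 8))


def brute_force_breslow(s, t, d):
    total, k = 0.0, 0
    for i in range(len(s)):
        if d[i]:
            k += 1
            total -= s[i] - np.log(
                sum(np.exp(s[j]) for j in range(len(s)) if t[j] >= t[i]))
    return total / k


class TestArchitecture:
    @pytest.mark.parametrize("cfg_kwargs", [
        TINY,
        dict(TINY, shared_widths=(10, 14), head_mlp_widths=(6, 4),
             skip_widths=(8, 4), post_merge_widths=(6,)),
        dict(n_markers=7, n_endpoints=2, linear=True),
    ])
    def test_parameter_count_matches_closed_form(self, cfg_kwargs):
        cfg = StateModelConfig(**cfg_kwargs)
        net = build_model(cfg)
        actual = sum(p.value.size for p in net.params())
        assert actual == cfg.n_parameters()

    def test_forward_shape_and_inference_determinism(self, rng):
        cfg = StateModelConfig(**TINY, seed=1)
        net = build_model(cfg)
        x = rng.normal(size=(11, 20))
        out = net.forward(x)
        assert out.shape == (11, 3)
        np.testing.assert_array_equal(out, net.forward(x))

    def test_identical_rows_identical_outputs(self, rng):
        net = build_model(StateModelConfig(**TINY, seed=2))
        row = rng.normal(size=(1, 20))
        x = np.vstack([row, rng.normal(size=(4, 20)), row])
        out = net.forward(x)
        np.testing.assert_allclose(out[0], out[-1], atol=1e-12)

    def test_row_order_invariance_at_inference(self, rng):
        net = build_model(StateModelConfig(**TINY, seed=3))
        x = rng.normal(size=(9, 20))
        perm = rng.permutation(9)
        np.testing.assert_allclose(net.forward(x)[perm], net.forward(x[perm]),
                                   atol=1e-12)

    def test_mismatched_terminal_widths_error(self):
        with pytest.raises(ValueError, match="residual addition"):
            StateModelConfig(**dict(TINY, skip_widths=(6, 6, 5)))

    def test_wrong_input_width_error(self, rng):
        net = build_model(StateModelConfig(**TINY))
        with pytest.raises(ValueError, match="shape"):
            net.forward(rng.normal(size=(3, 21)))


class TestCoxLoss:
    def test_symmetric_two_member_risk_set(self):
        assert cox_ph_loss([0.5, 0.5], [1.0, 2.0], [1, 0]) == pytest.approx(
            np.log(2), abs=1e-12)

    def test_singleton_risk_set_after_exclusion(self):
        assert cox_ph_loss([0.5, 1.3], [1.0, 2.0], [1, 0],
                           [True, False]) == pytest.approx(0.0, abs=1e-12)

    def test_zero_eligible_events_flagged_zero(self):
        loss, grad, k = cox_ph_loss_grad([1.0, 2.0], [1.0, 2.0], [0, 0])
        assert loss == 0.0 and k == 0 and not grad.any()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(5, 31))
            s = rng.normal(size=n)
            t = np.round(rng.random(n) * 10, 1)  # ties possible
            d = rng.random(n) < 0.6
            if not d.any():
                d[0] = True
            assert cox_ph_loss(s, t, d) == pytest.approx(
                brute_force_breslow(s, t, d), abs=1e-10)

    def test_translation_invariance(self, rng):
        s = rng.normal(size=40)
        t = rng.random(40) * 5
        d = rng.random(40) < 0.5
        d[0] = True
        assert cox_ph_loss(s, t, d) == pytest.approx(
            cox_ph_loss(s + 7.3, t, d), abs=1e-9)

    def test_ineligible_rows_outside_risk_sets(self):
        s = np.array([0.2, 1.5, -0.3])
        t = np.array([2.0, 3.0, 4.0])
        d = np.array([True, False, False])
        with_row = cox_ph_loss(s, t, d)
        masked = cox_ph_loss(s, t, d, [True, False, True])
        manual = -(s[0] - np.log(np.exp(s[0]) + np.exp(s[2])))
        assert masked == pytest.approx(manual, abs=1e-12)
        assert masked != pytest.approx(with_row, abs=1e-6)

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            cox_ph_loss([1.0], [1.0, 2.0], [1, 0])

    def test_gradient_matches_finite_differences(self, rng):
        n = 15
        s = rng.normal(size=n)
        t = rng.random(n) * 5
        d = rng.random(n) < 0.5
        d[:2] = True
        _, grad, _ = cox_ph_loss_grad(s, t, d)
        eps = 1e-6
        for i in range(n):
            e = np.zeros(n)
            e[i] = eps
            num = (cox_ph_loss(s + e, t, d) - cox_ph_loss(s - e, t, d)) / (2 * eps)
            assert grad[i] == pytest.approx(num, abs=1e-7)


class TestMultitaskLoss:
    def test_sum_of_means(self):
        assert multitask_loss([1.0, 2.0], [True, True]) == 3.0

    def test_single_endpoint_equals_its_loss(self):
        assert multitask_loss([0.42], [True]) == pytest.approx(0.42)

    def test_invalid_endpoint_contributes_nothing(self):
        assert multitask_loss([1.0, 99.0], [True, False]) == 1.0

    def test_all_invalid_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert multitask_loss([1.0], [False]) == 0.0


def _toy_training_data(rng, n=900, d=20, n_endpoints=3):
    X = rng.normal(size=(n, d))
    beta = np.zeros(d)
    beta[:4] = [0.7, -0.5, 0.4, 0.3]
    times = np.empty((n, n_endpoints))
    events = np.empty((n, n_endpoints), dtype=bool)
    for e in range(n_endpoints):
        eta = X @ beta if e == 0 else np.zeros(n)
        t = -np.log(rng.random(n)) / (0.03 * np.exp(eta))
        events[:, e] = t <= 12
        times[:, e] = np.minimum(t, 12)
    eligible = np.ones((n, n_endpoints), dtype=bool)
    return X, times, events, eligible


class TestTraining:
    def test_respects_max_epochs_and_records_history(self, rng):
        X, t, d, m = _toy_training_data(rng)
        cfg = StateModelConfig(**TINY, batch_size=256, max_epochs=4,
                               early_stopping_patience=10, seed=4,
                               weight_averaging=False)
        tm = train_state_model(build_model(cfg),
                               (X[:700], t[:700], d[:700], m[:700]),
                               (X[700:], t[700:], d[700:], m[700:]), cfg)
        assert len(tm.history) <= 4
        assert all(np.isfinite(h["valid_loss"]) for h in tm.history)
        assert tm.history[0]["epoch"] == 1

    def test_training_improves_signal_endpoint(self, rng):
        X, t, d, m = _toy_training_data(rng, n=1500)
        cfg = StateModelConfig(n_markers=20, n_endpoints=3,
                               shared_widths=(16, 16, 24),
                               head_mlp_widths=(12, 8, 6),
                               skip_widths=(8, 8, 6), post_merge_widths=(8, 8),
                               shared_dropout=0.05, head_dropout=0.1,
                               batch_size=256, learning_rate=5e-3,
                               max_epochs=20, schedule_steps=(12, 16, 18),
                               swa_start_epoch=10, early_stopping_patience=8,
                               seed=5)
        tm = train_state_model(build_model(cfg),
                               (X[:1200], t[:1200], d[:1200], m[:1200]),
                               (X[1200:], t[1200:], d[1200:], m[1200:]), cfg)
        from metastate.evaluation import harrell_c
        s = tm.predict_states(X[1200:])[:, 0]
        assert harrell_c(t[1200:, 0], d[1200:, 0], s) > 0.6

    def test_empty_validation_errors(self, rng):
        X, t, d, m = _toy_training_data(rng, n=100)
        cfg = StateModelConfig(**TINY, max_epochs=1)
        with pytest.raises(ValueError):
            train_state_model(build_model(cfg), (X, t, d, m),
                              (X[:0], t[:0], d[:0], m[:0]), cfg)


class TestExport:
    def _trained(self, rng):
        cfg = StateModelConfig(**TINY, seed=6)
        net = build_model(cfg)
        net.forward(rng.normal(size=(64, 20)), training=True)  # warm BN stats
        return TrainedStateModel(
            net=net, marker_mean=rng.normal(size=20),
            marker_sd=np.abs(rng.normal(size=20)) + 0.5, config=cfg,
            endpoints=["a", "b", "c"],
            history=[{"epoch": 1, "train_loss": 1.0, "valid_loss": 1.0, "lr": 1e-3}])

    def test_round_trip_reproduces_states(self, tmp_path, rng):
        tm = self._trained(rng)
        export_model(tm, tmp_path / "bundle")
        back = load_model(tmp_path / "bundle")
        X = rng.normal(size=(1000, 20))
        np.testing.assert_allclose(back.predict_states(X),
                                   tm.predict_states(X), atol=1e-5)

    def test_bundle_contains_normalization_statistics(self, tmp_path, rng):
        import json
        tm = self._trained(rng)
        export_model(tm, tmp_path / "bundle")
        meta = json.loads((tmp_path / "bundle" / "metadata.json").read_text())
        np.testing.assert_allclose(meta["marker_mean"], tm.marker_mean)
        np.testing.assert_allclose(meta["marker_sd"], tm.marker_sd)

    def test_wrong_marker_count_raises_shape_error(self, tmp_path, rng):
        tm = self._trained(rng)
        export_model(tm, tmp_path / "bundle")
        back = load_model(tmp_path / "bundle")
        with pytest.raises(ValueError, match="shape"):
            back.predict_states(rng.normal(size=(5, 21)))


class TestHyperparameterSearch:
    def _data(self, rng):
        X, t, d, m = _toy_training_data(rng, n=400, n_endpoints=1)
        return ((X[:300], t[:300], d[:300], m[:300]),
                (X[300:], t[300:], d[300:], m[300:]))

    def test_budget_one_returns_sampled_config(self, rng):
        train, valid = self._data(rng)
        base = StateModelConfig(n_markers=20, n_endpoints=1, linear=True,
                                max_epochs=2, batch_size=128,
                                early_stopping_patience=2)
        best, trials = hyperparameter_search(
            {"learning_rate": [1e-3, 1e-2]}, budget=1, seed=0,
            train=train, valid=valid, base_config=base)
        assert len(trials) == 1
        assert best.learning_rate == trials[0]["overrides"]["learning_rate"]

    def test_same_seed_identical_trials_and_argmin(self, rng):
        train, valid = self._data(rng)
        base = StateModelConfig(n_markers=20, n_endpoints=1, linear=True,
                                max_epochs=2, batch_size=128,
                                early_stopping_patience=2)
        space = {"learning_rate": [1e-3, 3e-3, 1e-2], "batch_size": [64, 128]}
        b1, t1 = hyperparameter_search(space, 3, 9, train, valid, base)
        b2, t2 = hyperparameter_search(space, 3, 9, train, valid, base)
        assert [t["overrides"] for t in t1] == [t["overrides"] for t in t2]
        best_val = min(t["valid_loss"] for t in t1)
        assert all(best_val <= t["valid_loss"] for t in t1)

    def test_empty_space_errors(self, rng):
        train, valid = self._data(rng)
        base = StateModelConfig(n_markers=20, n_endpoints=1, linear=True)
        with pytest.raises(ValueError):
            hyperparameter_search({}, 1, 0, train, valid, base)
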