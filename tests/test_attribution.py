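"""Attribution contracts: additivity, closed forms, aggregation, percentile
profiles, high-impact flags and the 2-D embedding."""

import numpy as np
import pytest

from metastate.attribution import (additivity_residuals, compute_attributions,
                                   embed_attributions, global_importance,
                                   high_impact_mask, percentile_profile)
from metastate.state_model import (StateModelConfig, TrainedStateModel,
                                   build_model)

TINY = dict(n_markers=15, n_endpoints=2, shared_widths=(10, 10, 12),
            head_mlp_widths=(8, 6, 4), skip_widths=(6, 6, 4),
            post_merge_widths=(8, 8))


def _trained(rng, **kwargs):
    cfg = StateModelConfig(**{**TINY, **kwargs}, seed=11)
    net = build_model(cfg)
    if not cfg.linear:
        net.forward(rng.normal(size=(128, cfg.n_markers)), training=True)
    return TrainedStateModel(net=net, marker_mean=np.zeros(cfg.n_markers),
                             marker_sd=np.ones(cfg.n_markers), config=cfg,
                             endpoints=["a", "b"])


class TestComputeAttributions:
    def test_additivity_to_background_expectation(self, rng):
        model = _trained(rng)
        X = rng.normal(size=(300, 15))
        bg = rng.normal(size=(32, 15))
        res = compute_attributions(model, X, bg, "a")
        # the rescale rule is exactly additive for this layer family
        np.testing.assert_allclose(res.phi.sum(axis=1),
                                   res.f_x - res.f_background.mean(),
                                   atol=1e-10)
        assert (additivity_residuals(res) < 0.05).mean() >= 0.99

    def test_linear_model_closed_form(self, rng):
        model = _trained(rng, linear=True)
        X = rng.normal(size=(40, 15))
        bg = rng.normal(size=(16, 15))
        res = compute_attributions(model, X, bg, "b")
        w = model.net.heads_linear[1].W.value[:, 0]
        np.testing.assert_allclose(res.phi, w * (X - bg.mean(axis=0)),
                                   atol=1e-12)

    def test_sample_equal_to_background_gets_zero_attributions(self, rng):
        model = _trained(rng)
        x = rng.normal(size=(1, 15))
        res = compute_attributions(model, x, x.copy(), "a")
        np.testing.assert_allclose(res.phi, 0.0, atol=1e-12)

    def test_dimension_mismatch_errors(self, rng):
        model = _trained(rng)
        with pytest.raises(ValueError, match="dimension"):
            compute_attributions(model, rng.normal(size=(5, 15)),
                                 rng.normal(size=(4, 14)), "a")
        with pytest.raises(ValueError):
            compute_attributions(model, rng.normal(size=(5, 15)),
                                 np.empty((0, 15)), "a")

    def test_unknown_endpoint(self, rng):
        model = _trained(rng)
        with pytest.raises(KeyError):
            compute_attributions(model, rng.normal(size=(2, 15)),
                                 rng.normal(size=(2, 15)), "zzz")


class TestGlobalImportance:
    def test_toy_sum_of_absolutes(self):
        phi = np.array([[-1.0], [2.0]])
        gi = global_importance({"a": phi}, ["m0"])
        assert gi.loc["m0", "a"] == 3.0

    def test_zero_attributions_zero_matrix(self):
        gi = global_importance({"a": np.zeros((4, 3))})
        assert (gi.to_numpy() == 0).all()

    def test_matches_double_loop_on_small_tensor(self, rng):
        phi_a = rng.normal(size=(10, 5))
        phi_b = rng.normal(size=(10, 5))
        gi = global_importance({"a": phi_a, "b": phi_b})
        for ep, phi in (("a", phi_a), ("b", phi_b)):
            for j in range(5):
                expected = sum(abs(phi[i, j]) for i in range(10))
                assert gi.iloc[j][ep] == pytest.approx(expected)


class TestPercentileProfile:
    def test_constant_attributions_flat_profile(self):
        phi = np.full((200, 2), 0.7)
        vals = np.random.default_rng(0).normal(size=(200, 2))
        prof = percentile_profile(phi, vals, n_bins=10)
        np.testing.assert_allclose(prof["mean_attribution"], 0.7)

    def test_bin_means_average_to_overall_mean(self, rng):
        phi = rng.normal(size=(500, 3))
        vals = rng.normal(size=(500, 3))
        prof = percentile_profile(phi, vals, n_bins=100)
        np.testing.assert_allclose(prof["mean_attribution"].mean(axis=1),
                                   phi.mean(axis=0), atol=1e-10)

    def test_monotone_attribution_gives_monotone_profile(self, rng):
        vals = rng.normal(size=(400, 1))
        phi = 2.0 * vals + 1.0  # strictly increasing in the marker
        prof = percentile_profile(phi, vals, n_bins=20)
        assert np.all(np.diff(prof["mean_attribution"][0]) > 0)
        assert np.all(np.diff(prof["mean_marker_value"][0]) > 0)

    def test_too_few_rows_errors(self, rng):
        with pytest.raises(ValueError):
            percentile_profile(rng.normal(size=(5, 2)),
                               rng.normal(size=(5, 2)), n_bins=10)


class TestHighImpactMask:
    def test_flagged_fraction_near_two_percent(self, rng):
        phi = rng.normal(size=(1000, 100))
        mask = high_impact_mask(phi)
        assert abs(mask.mean() - 0.02) < 0.003

    def test_values_inside_wider_reference_unflagged(self, rng):
        phi = rng.normal(size=(100, 10)) * 0.01
        ref = rng.normal(size=100000)  # much wider distribution
        mask = high_impact_mask(phi, reference=ref)
        assert not mask.any()

    def test_fixed_interval_variant(self, rng):
        phi = rng.normal(size=(50, 4))
        mask = high_impact_mask(phi, fixed_interval=(-0.2, 0.2))
        np.testing.assert_array_equal(mask, (phi < -0.2) | (phi > 0.2))

    def test_percentiles_at_interval_bounds_equivalent(self, rng):
        # distribution built so its 1%/99% percentiles are exactly -0.2/0.2
        base = np.linspace(-0.2, 0.2, 99)
        phi = np.concatenate([[-10.0], base, [10.0]]).reshape(1, -1)
        mask = high_impact_mask(phi)
        np.testing.assert_array_equal(
            mask, ~((phi >= -0.2) & (phi <= 0.2)))

    def test_degenerate_distribution_errors(self):
        with pytest.raises(ValueError):
            high_impact_mask(np.full((10, 3), 1.0))


class TestSignalVsNullAttributions:
    def test_discriminative_endpoint_dominates_global_importance(self, rng):
        """A trained model's attributions concentrate on the endpoint with
        real marker signal; the null endpoint's attributions are near zero
        (mean |phi| under 10% of the strong endpoint's)."""
        from metastate.state_model import train_state_model

        n, d = 4000, 20
        X = rng.normal(size=(n, d))
        beta = np.zeros(d)
        beta[:4] = [0.8, -0.6, 0.5, 0.4]
        times = np.empty((n, 2))
        events = np.empty((n, 2), dtype=bool)
        for e, eta in enumerate((X @ beta, np.zeros(n))):
            t = -np.log(rng.random(n)) / (0.05 * np.exp(eta))
            events[:, e] = t <= 10
            times[:, e] = np.minimum(t, 10)
        elig = np.ones((n, 2), dtype=bool)
        cfg = StateModelConfig(n_markers=d, n_endpoints=2,
                               shared_widths=(16, 16, 16),
                               head_mlp_widths=(8, 8, 8),
                               skip_widths=(8, 8, 8), post_merge_widths=(8, 8),
                               shared_dropout=0.05, head_dropout=0.05,
                               weight_decay=0.15, batch_size=512,
                               learning_rate=5e-3, max_epochs=120,
                               schedule_steps=(60, 90, 110),
                               weight_averaging=False,
                               checkpoint_selection="per_endpoint",
                               early_stopping_patience=60, seed=7)
        model = train_state_model(build_model(cfg),
                                  (X[:3200], times[:3200], events[:3200], elig[:3200]),
                                  (X[3200:], times[3200:], events[3200:], elig[3200:]),
                                  cfg, ["signal", "null"])
        bg = X[:64]
        samp = X[3200:3600]
        phi = {e: compute_attributions(model, samp, bg, e).phi
               for e in ("signal", "null")}
        gi = global_importance(phi)
        assert gi["signal"].sum() > gi["null"].sum()
        assert np.abs(phi["null"]).mean() < 0.10 * np.abs(phi["signal"]).mean()


class TestEmbedding:
    def test_shape_and_seed_determinism(self, rng):
        phi = rng.normal(size=(80, 12))
        a = embed_attributions(phi, seed=4, n_neighbors=10)
        b = embed_attributions(phi, seed=4, n_neighbors=10)
        assert a.shape == (80, 2)
        np.testing.assert_allclose(a, b)

    def test_disjoint_clusters_separate(self, rng):
        from sklearn.metrics import silhouette_score
        c1 = rng.normal(size=(40, 8))
        c2 = rng.normal(size=(40, 8)) + 12.0
        phi = np.vstack([c1, c2])
        labels = np.r_[np.zeros(40), np.ones(40)]
        emb = embed_attributions(phi, seed=0, n_neighbors=10)
        assert silhouette_score(emb, labels) > 0

    def test_too_few_rows_errors(self, rng):
        with pytest.raises(ValueError):
            embed_attributions(rng.normal(size=(5, 3)), seed=0)
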