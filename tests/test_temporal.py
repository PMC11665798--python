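"""Temporal RSD model: context features, losses, training mechanics, causality."""

import numpy as np
import pytest

from surgrsd import make_embedding_config, sample_cohort, sample_frame_embeddings
from surgrsd import temporal as tm
from surgrsd.simulate import FrameFeatureTrack
from surgrsd.temporal.nn import smooth_l1, weighted_cross_entropy

from conftest import tiny_step_config


def _tiny_setup(seed=0, n_train=2, n_val=1, n_test=1, noise_sd=0.05, dim=6):
    cfg = tiny_step_config(seed=seed)
    timelines, split = sample_cohort(cfg, n_train, n_val, n_test)
    emb = make_embedding_config(cfg.all_codes, dim=dim, noise_sd=noise_sd, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    tracks = {v: sample_frame_embeddings(timelines[v], emb, rng) for v in timelines}
    return cfg, timelines, split, tracks


def _fast_tcfg(**overrides):
    defaults = dict(
        feature_dim=6,
        n_steps=5,
        hidden_size=12,
        epochs=2,
        lr_schedule=((2, 1e-3),),
        tbptt_window=128,
        seed=0,
    )
    defaults.update(overrides)
    return tm.TemporalModelConfig(**defaults)


class TestContextFeature:
    def test_dimensional_bookkeeping(self):
        cfg = tm.TemporalModelConfig(feature_dim=768, n_steps=14, use_prior_context=True)
        state = tm.ContextState(14, cfg.context_window)
        out = tm.build_context_feature(np.zeros(768), 0, state, cfg)
        assert out.shape == (797,)  # 768 + 1 + 14 + 14

    def test_cold_start_blocks_are_uniform(self):
        cfg = _fast_tcfg(use_prior_context=True)
        state = tm.ContextState(5, cfg.context_window)
        out = tm.build_context_feature(np.zeros(6), 0, state, cfg)
        assert np.allclose(out[7:12], 1 / 5)
        assert np.allclose(out[12:17], 1 / 5)

    def test_context_off_length_d_plus_one(self):
        cfg = _fast_tcfg(use_prior_context=False)
        state = tm.ContextState(5, cfg.context_window)
        out = tm.build_context_feature(np.ones(6), 3600, state, cfg)
        assert out.shape == (7,)
        assert out[-1] == 1.0  # elapsed hour normalised

    def test_dimension_mismatch_rejected(self):
        cfg = _fast_tcfg()
        state = tm.ContextState(5, cfg.context_window)
        with pytest.raises(ValueError):
            tm.build_context_feature(np.zeros(5), 0, state, cfg)

    def test_buffer_mean_tracks_recent_probabilities(self):
        state = tm.ContextState(2, window=3)
        for p in ([1.0, 0.0], [0.0, 1.0], [0.0, 1.0], [0.0, 1.0]):
            state.update(np.asarray(p))
        assert np.allclose(state.mean_recent(), [0.0, 1.0])  # oldest evicted


class TestNormalisationAndLoss:
    def test_normalize_rsd_factor_ten(self):
        assert tm.normalize_rsd(45.0, 10.0) == 4.5
        assert tm.normalize_rsd(0.0, 10.0) == 0.0

    def test_round_trip_exact_to_machine_precision(self):
        # x/10*10 can differ from x by one ulp (10 is not a power of two)
        vals = np.linspace(0, 123.4, 50)
        back = tm.denormalize_rsd(tm.normalize_rsd(vals, 10.0), 10.0)
        np.testing.assert_allclose(back, vals, rtol=np.finfo(float).eps, atol=0.0)

    @pytest.mark.parametrize("residual, expected", [(0.5, 0.125), (2.0, 1.5)])
    def test_smooth_l1_branches(self, residual, expected):
        loss, _ = smooth_l1(np.array([residual]), np.array([0.0]), beta=1.0)
        assert loss == pytest.approx(expected)

    def test_class_weights_formula(self):
        w = tm.class_weights([0, 0, 0, 1], 2)
        assert w == pytest.approx([4 / 6, 2.0])

    def test_class_weights_balanced_and_single(self):
        assert tm.class_weights([0, 0, 1, 1], 2) == pytest.approx([1.0, 1.0])
        assert tm.class_weights([1, 1], 3) == pytest.approx([0.0, 1.0, 0.0])

    def test_class_weights_empty_rejected(self):
        with pytest.raises(ValueError):
            tm.class_weights([], 3)

    def test_unobserved_class_excluded_from_loss(self):
        logits = np.array([[5.0, 0.0, -5.0], [0.0, 5.0, -5.0]])
        w = np.array([1.0, 1.0, 0.0])
        loss_with, _ = weighted_cross_entropy(logits, np.array([0, 1]), w)
        # adding a sample of the zero-weight class changes nothing
        logits2 = np.vstack([logits, [[0.0, 0.0, 9.0]]])
        loss_without, _ = weighted_cross_entropy(logits2, np.array([0, 1, 2]), w)
        assert loss_with == pytest.approx(loss_without)

    def test_perfect_prediction_gives_zero_loss(self):
        cfg = _fast_tcfg(use_step_head=True)
        step_true = np.array([0, 1])
        step_logits = np.array([[500.0, 0.0, 0, 0, 0], [0.0, 500.0, 0, 0, 0]])
        rsd = np.array([1.2, 3.4])
        loss = tm.multitask_loss(
            step_logits, step_true, None, None, rsd, rsd, np.ones(5), cfg
        )
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_nan_inputs_rejected(self):
        cfg = _fast_tcfg()
        with pytest.raises(FloatingPointError):
            tm.multitask_loss(
                None, None, None, None, np.array([np.nan]), np.array([0.0]), None, cfg
            )


class TestConfig:
    def test_context_requires_step_head(self):
        with pytest.raises(ValueError):
            _fast_tcfg(use_step_head=False, use_prior_context=True)

    def test_variant_flags(self):
        v = tm.variant_config("rsd", feature_dim=4, n_steps=3)
        assert not v.use_step_head and not v.use_prior_context
        v = tm.variant_config("s_rsd", feature_dim=4, n_steps=3)
        assert v.use_step_head and not v.use_prior_context
        v = tm.variant_config("full", feature_dim=4, n_steps=3)
        assert v.use_step_head and v.use_prior_context
        with pytest.raises(ValueError):
            tm.variant_config("nope", feature_dim=4, n_steps=3)


class TestTraining:
    def test_loss_decreases_on_tiny_cohort(self):
        _, timelines, split, tracks = _tiny_setup(seed=1)
        cfg = _fast_tcfg(epochs=4, lr_schedule=((4, 1e-3),))
        model = tm.train(tracks, timelines, split, cfg)
        losses = [e["train_loss"] for e in model.training_log]
        assert losses[-1] < losses[0]

    def test_deterministic_given_seed(self):
        _, timelines, split, tracks = _tiny_setup(seed=2)
        cfg = _fast_tcfg(seed=7)
        m1 = tm.train(tracks, timelines, split, cfg)
        m2 = tm.train(tracks, timelines, split, cfg)
        for k, v in m1.parameters().items():
            assert np.array_equal(v, m2.parameters()[k]), k

    def test_rsd_head_frozen_when_rsd_loss_weight_zero(self):
        _, timelines, split, tracks = _tiny_setup(seed=3)
        cfg = _fast_tcfg(loss_weights=(1.0, 0.0, 0.0), epochs=1, lr_schedule=((1, 1e-3),))
        model = tm.TemporalRSDModel(cfg, [1, 2, 3, 4, 5])
        before = model.head_rsd.W.copy()
        trained = tm.train(tracks, timelines, split, cfg)
        assert np.array_equal(trained.head_rsd.W, before)

    def test_step_head_frozen_when_step_loss_weight_zero(self):
        _, timelines, split, tracks = _tiny_setup(seed=3)
        cfg = _fast_tcfg(loss_weights=(0.0, 0.0, 1.0), epochs=1, lr_schedule=((1, 1e-3),))
        model = tm.TemporalRSDModel(cfg, [1, 2, 3, 4, 5])
        before = model.head_step.W.copy()
        trained = tm.train(tracks, timelines, split, cfg)
        assert np.array_equal(trained.head_step.W, before)

    def test_misaligned_track_rejected(self):
        _, timelines, split, tracks = _tiny_setup(seed=4)
        vid = split.train[0]
        bad = FrameFeatureTrack(
            vid, tracks[vid].features[:-5], tracks[vid].elapsed_sec[:-5]
        )
        tracks = dict(tracks, **{vid: bad})
        with pytest.raises(ValueError, match="track length"):
            tm.train(tracks, timelines, split, _fast_tcfg())

    def test_context_variant_trains_and_predicts(self):
        _, timelines, split, tracks = _tiny_setup(seed=5)
        cfg = _fast_tcfg(use_prior_context=True, epochs=1, lr_schedule=((1, 1e-3),))
        model = tm.train(tracks, timelines, split, cfg)
        series, probs = tm.predict_online(model, tracks[split.test[0]])
        assert len(series) == tracks[split.test[0]].T
        assert np.allclose(probs.probs.sum(axis=1), 1.0)

    def test_save_load_round_trip(self, tmp_path):
        _, timelines, split, tracks = _tiny_setup(seed=6)
        model = tm.train(tracks, timelines, split, _fast_tcfg(epochs=1, lr_schedule=((1, 1e-3),)))
        model.save(tmp_path / "m")
        loaded = tm.TemporalRSDModel.load(tmp_path / "m")
        vid = split.test[0]
        a, _ = tm.predict_online(model, tracks[vid])
        b, _ = tm.predict_online(loaded, tracks[vid])
        assert a.rsd_pred_min == b.rsd_pred_min


class TestPredictOnline:
    def test_outputs_causal_under_future_perturbation(self):
        _, timelines, split, tracks = _tiny_setup(seed=7)
        cfg = _fast_tcfg(use_prior_context=True)
        model = tm.TemporalRSDModel(cfg, [1, 2, 3, 4, 5])
        track = tracks[split.test[0]]
        base_series, base_probs = tm.predict_online(model, track)
        t_cut = track.T // 2
        rng = np.random.default_rng(0)
        perturbed = track.features.copy()
        perturbed[t_cut + 1 :] += rng.normal(size=perturbed[t_cut + 1 :].shape)
        p_series, p_probs = tm.predict_online(
            model, FrameFeatureTrack(track.video_id, perturbed, track.elapsed_sec)
        )
        assert base_series.rsd_pred_min[: t_cut + 1] == p_series.rsd_pred_min[: t_cut + 1]
        assert np.array_equal(base_probs.probs[: t_cut + 1], p_probs.probs[: t_cut + 1])

    def test_zero_length_track_gives_empty_series(self):
        cfg = _fast_tcfg()
        model = tm.TemporalRSDModel(cfg, [1, 2, 3, 4, 5])
        track = FrameFeatureTrack("empty", np.zeros((0, 6)), np.zeros(0))
        series, probs = tm.predict_online(model, track)
        assert len(series) == 0 and len(probs.probs) == 0

    def test_dimension_mismatch_rejected(self):
        cfg = _fast_tcfg()
        model = tm.TemporalRSDModel(cfg, [1, 2, 3, 4, 5])
        track = FrameFeatureTrack("bad", np.zeros((10, 9)), np.arange(10))
        with pytest.raises(ValueError, match="dimension"):
            tm.predict_online(model, track)

    def test_predictions_nonnegative(self):
        _, timelines, split, tracks = _tiny_setup(seed=8)
        model = tm.TemporalRSDModel(_fast_tcfg(), [1, 2, 3, 4, 5])
        series, _ = tm.predict_online(model, tracks[split.test[0]])
        assert min(series.rsd_pred_min) >= 0.0


def test_lstm_gradients_match_finite_differences():
    """Analytic backward pass against central finite differences."""
    from surgrsd.temporal.nn import LSTMLayer

    rng = np.random.default_rng(0)
    layer = LSTMLayer(3, 4, rng)
    X = rng.normal(size=(6, 3))
    dH = rng.normal(size=(6, 4))
    h0, c0 = layer.init_state()

    def loss_fn():
        H, _, _ = layer.forward_sequence(X, h0, c0)
        return float((H * dH).sum())

    _, _, cache = layer.forward_sequence(X, h0, c0)
    grads, dX = layer.backward_sequence(cache, dH)
    eps = 1e-6
    for name, param, grad in [
        ("Wx", layer.Wx, grads["Wx"]),
        ("Wh", layer.Wh, grads["Wh"]),
        ("b", layer.b, grads["b"]),
    ]:
        flat = param.reshape(-1)
        for idx in rng.choice(flat.size, size=5, replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            up = loss_fn()
            flat[idx] = orig - eps
            down = loss_fn()
            flat[idx] = orig
            fd = (up - down) / (2 * eps)
            assert grad.reshape(-1)[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7), name
    # input gradient
    for idx in rng.choice(X.size, size=5, replace=False):
        flat = X.reshape(-1)
        orig = flat[idx]
        flat[idx] = orig + eps
        up = loss_fn()
        flat[idx] = orig - eps
        down = loss_fn()
        flat[idx] = orig
        assert dX.reshape(-1)[idx] == pytest.approx((up - down) / (2 * eps), rel=1e-4, abs=1e-7)
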