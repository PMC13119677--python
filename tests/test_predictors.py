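"""Predictor architectures, label generation and training mechanics.

The expensive end-to-end training properties live in the acceptance tests;
here the models are exercised untrained or on tiny corpora.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from predisp import nn
from predisp.inversion import InversionConfig
from predisp.predictors import (
    PredictorState,
    TrainConfig,
    build_label_dataset,
    build_predictor,
    latent_mse,
    load_checkpoint,
    map_features,
    predict_init,
    save_checkpoint,
    train_predictor,
)
from predisp.scene import SceneConfig, default_generator, render_sequence


def test_temporal_predictor_stabilises_after_warmup(benchmark_run):
    """The first frame has no history (zero start for the recurrent state);
    prediction error from frame 4 onward is no worse than at frame 1,
    averaged over held-out sequences."""
    first, later = [], []
    for res in benchmark_run["results"]["gru"]:
        errs = [latent_mse(t.w_init, t.w_opt) for t in res.traces]
        first.append(errs[0])
        later.append(np.mean(errs[3:]))
    assert np.mean(later) <= np.mean(first)


class TestLatentMSE:
    def test_identity_is_zero(self):
        v = np.arange(64.0)
        assert latent_mse(v, v) == 0.0

    def test_unit_offset_in_every_coordinate_is_one(self):
        w = np.zeros(64)
        assert latent_mse(w, w + 1.0) == 1.0

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_bruteforce_sum(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.standard_normal(16)
        v = rng.standard_normal(16)
        acc = 0.0
        for i in range(16):
            acc += (w[i] - v[i]) ** 2
        assert latent_mse(w, v) == pytest.approx(acc / 16, rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            latent_mse(np.zeros(3), np.zeros(4))


@pytest.fixture(scope="module")
def models():
    return {kind: build_predictor(kind, 64, 64, 64, seed=1)
            for kind in ("gru", "mapping", "siamese")}


@pytest.fixture(scope="module")
def tiny_pair():
    rng = np.random.default_rng(0)
    return rng.random((64, 64)), rng.random((64, 64))


class TestArchitectureContracts:
    def test_feature_and_output_dimensions(self, models, tiny_pair):
        """Eq-style dimension contract: K+N numbers in, K out."""
        left, right = tiny_pair
        for kind, model in models.items():
            feats = map_features(model, left, right)
            assert feats.shape == (256,) and np.all(np.isfinite(feats))
            state = PredictorState.initial(64)
            w, _ = predict_init(model, state, feats)
            assert w.shape == (64,) and np.all(np.isfinite(w))

    def test_feedforward_kinds_ignore_state(self, models, tiny_pair):
        left, right = tiny_pair
        feats = map_features(models["mapping"], left, right)
        s1 = PredictorState.initial(64)
        s2 = PredictorState(hidden=np.ones(64), w_prev=np.full(64, 0.3), frame=7)
        w1, _ = predict_init(models["mapping"], s1, feats)
        w2, _ = predict_init(models["mapping"], s2, feats)
        assert np.array_equal(w1, w2)

    def test_temporal_kind_is_deterministic_and_updates_state(self, models, tiny_pair):
        left, right = tiny_pair
        feats = map_features(models["gru"], left, right)
        state = PredictorState(hidden=np.full(64, 0.1), w_prev=np.full(64, 0.2))
        wa, sa = predict_init(models["gru"], state, feats)
        wb, sb = predict_init(models["gru"], state, feats)
        assert np.array_equal(wa, wb)
        assert np.array_equal(sa.hidden, sb.hidden)
        assert sa.frame == state.frame + 1
        with pytest.raises(ValueError):
            predict_init(models["gru"], None, feats)

    def test_untrained_temporal_model_passes_previous_latent_through(self, models, tiny_pair):
        """The passthrough initialisation makes the fresh temporal predictor
        approximate the previous-optimum warm start."""
        left, right = tiny_pair
        feats = map_features(models["gru"], left, right)
        w_prev = np.full(64, 0.3)
        state = PredictorState(hidden=np.zeros(64), w_prev=w_prev)
        w, _ = predict_init(models["gru"], state, feats)
        assert latent_mse(w, w_prev) < latent_mse(np.zeros(64), w_prev)

    def test_image_size_mismatch_rejected(self, models):
        with pytest.raises(ValueError):
            map_features(models["mapping"], np.zeros((32, 32)), np.zeros((32, 32)))

    def test_correlation_volume_peaks_at_true_shift(self):
        """The cost-volume primitive: correlating a feature map with a
        shifted copy peaks at the shifting offset, matching a brute-force
        correlation oracle on a toy input."""
        rng = np.random.default_rng(5)
        base = rng.standard_normal((1, 4, 16, 16))
        for true_k in (0, 2, 4):
            # positive disparity: the left view is the right view shifted
            # rightward, left(x) = right(x - k)
            left = np.zeros_like(base)
            left[..., true_k:] = base[..., : 16 - true_k]
            fl = nn.Tensor(left)
            fr = nn.Tensor(base)
            cost = [float((fl.shift_left(k) * fr).mean_axis(1).mean().data)
                    for k in range(5)]
            # oracle: plain numpy correlation over integer shifts
            oracle = []
            for k in range(5):
                s = np.zeros_like(left)
                s[..., : 16 - k] = left[..., k:]
                oracle.append(float((s * base).mean()))
            assert np.allclose(cost, oracle, rtol=1e-12)
            assert int(np.argmax(cost)) == true_k


@pytest.fixture(scope="module")
def tiny_labels():
    cfg = SceneConfig(n_frames=12, seed=2)
    g = default_generator(cfg)
    seqs = [render_sequence(cfg, g)]
    inv = InversionConfig(epsilon=25.0, max_steps=40)
    records, report = build_label_dataset(seqs, g, inv)
    return records, report, g


class TestLabelDataset:
    def test_cardinality(self, tiny_labels):
        records, report, _ = tiny_labels
        assert len(records) == 12
        assert report["n_records"] - report["n_excluded"] == sum(
            1 for r in records if not r.excluded)

    def test_reproducible_under_fixed_seeds(self, tiny_labels):
        records, _, g = tiny_labels
        cfg = SceneConfig(n_frames=12, seed=2)
        again, _ = build_label_dataset([render_sequence(cfg, g)], g,
                                       InversionConfig(epsilon=25.0, max_steps=40))
        assert np.array_equal(records[5].w_train, again[5].w_train)

    def test_outlier_frames_are_flagged(self, tiny_labels):
        _, _, g = tiny_labels
        cfg = SceneConfig(n_frames=12, seed=2)
        out, report = build_label_dataset([render_sequence(cfg, g)], g,
                                          InversionConfig(epsilon=25.0, max_steps=40),
                                          loss_bound=0.0)
        assert report["n_excluded"] == len(out)
        assert all(r.excluded for r in out)


class TestTraining:
    def test_degenerate_fit_reaches_zero_loss(self, tiny_labels):
        """Labels equal to a constant are fitted exactly (loss -> ~0)."""
        records, _, _ = tiny_labels
        import copy
        recs = copy.deepcopy(records)
        for r in recs:
            r.w_train = np.zeros_like(r.w_train)
        cfg = TrainConfig.for_kind("siamese", epochs=60, seed=0)
        with pytest.warns(UserWarning):
            # the static baseline is also perfect here, hence the warning
            model, curve = train_predictor(cfg, recs)
        assert curve["val_mse"].min() < 1e-3

    def test_training_recipes_differ_per_family(self):
        gru = TrainConfig.for_kind("gru")
        ff = TrainConfig.for_kind("mapping")
        assert (gru.batch_size, gru.shuffle) == (1, False)
        assert (ff.batch_size, ff.shuffle) == (5, True)
        assert gru.weight_decay == ff.weight_decay == 0.0

    def test_training_is_reproducible(self, tiny_labels):
        records, _, _ = tiny_labels
        import warnings
        curves = []
        for _ in range(2):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, curve = train_predictor(
                    TrainConfig.for_kind("mapping", epochs=2, seed=3), records)
            curves.append(curve)
        assert np.array_equal(curves[0]["val_mse"].values,
                              curves[1]["val_mse"].values)


def test_noiseless_labels_reach_the_interpolation_floor(scene_cfg, gen, eps_interp):
    """On noiseless frames every label optimum explains its frame to within
    the calibrated interpolation bound."""
    cfg = SceneConfig(**{**scene_cfg.__dict__, "n_frames": 6})
    records, report = build_label_dataset(
        [render_sequence(cfg, gen)], gen,
        InversionConfig(epsilon=1.0, patience=30, min_rel_improvement=1e-5,
                        max_steps=300))
    assert report["n_excluded"] == 0
    assert all(r.final_loss < 2.0 * eps_interp for r in records)


def test_shuffling_the_temporal_model_degrades_validation():
    """The temporal predictor needs ordered sequences: forcing shuffled,
    stateless updates on the same seeds never validates better."""
    import warnings

    cfg = SceneConfig(n_frames=50, seed=2)
    g = default_generator(cfg)
    label_cfg = InversionConfig(epsilon=1.0, patience=30,
                                min_rel_improvement=1e-5, max_steps=300)
    seqs = [render_sequence(SceneConfig(n_frames=50, seed=s), g) for s in (2, 3)]
    records, _ = build_label_dataset(seqs, g, label_cfg)
    best = {}
    for shuffle in (False, True):
        tc = TrainConfig.for_kind("gru", epochs=8, seed=0)
        tc.shuffle = shuffle
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, curve = train_predictor(tc, records)
        best[shuffle] = curve["val_mse"].min()
    assert best[True] >= best[False]


def test_checkpoint_roundtrip_preserves_predictions(tmp_path, models, tiny_pair):
    left, right = tiny_pair
    for kind, model in models.items():
        path = tmp_path / f"{kind}.npz"
        save_checkpoint(model, path)
        clone = load_checkpoint(path)
        assert np.array_equal(map_features(model, left, right),
                              map_features(clone, left, right))
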