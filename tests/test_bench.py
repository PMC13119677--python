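"""Benchmark harness pieces: frame ops, surface export, embedding, tables."""

import numpy as np
import pytest

from predisp import SceneConfig, crop_roi, embed_latents, export_surface, split_sbs_frame
from predisp.bench import BenchConfig, run_benchmark


class TestCropRoi:
    def test_standard_endoscopic_crop(self):
        frame = np.zeros((288, 360))
        assert crop_roi(frame, 256).shape == (256, 256)

    def test_full_size_crop_is_identity(self):
        frame = np.random.default_rng(0).random((64, 64))
        assert np.array_equal(crop_roi(frame, 64), frame)

    def test_crop_of_crop_equals_single_crop(self):
        frame = np.random.default_rng(1).random((100, 120))
        assert np.array_equal(crop_roi(crop_roi(frame, 80), 40),
                              crop_roi(frame, 40))

    def test_oversized_crop_rejected(self):
        with pytest.raises(ValueError):
            crop_roi(np.zeros((32, 32)), 64)


class TestSplitSbs:
    def test_standard_720_wide_frame(self):
        frame = np.zeros((288, 720))
        left, right = split_sbs_frame(frame)
        assert left.shape == right.shape == (288, 360)

    def test_reconcatenation_recovers_input(self):
        frame = np.random.default_rng(2).random((16, 40))
        left, right = split_sbs_frame(frame)
        assert np.array_equal(np.concatenate([left, right], axis=1), frame)

    def test_constant_frame_gives_identical_halves(self):
        left, right = split_sbs_frame(np.full((8, 12), 0.5))
        assert np.array_equal(left, right)

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError):
            split_sbs_frame(np.zeros((8, 13)))


class TestExportSurface:
    def test_constant_depth_plane_and_cardinality(self, tmp_path):
        trimesh = pytest.importorskip("trimesh")
        depth = np.full((8, 10), 25.0)
        img = np.random.default_rng(3).random((8, 10))
        path = tmp_path / "plane.ply"
        n = export_surface(depth, img, path, focal=100.0)
        assert n == 80
        cloud = trimesh.load(path)
        assert cloud.vertices.shape == (80, 3)
        assert np.allclose(cloud.vertices[:, 2], 25.0)

    def test_roundtrip_through_independent_parser(self, tmp_path):
        trimesh = pytest.importorskip("trimesh")
        rng = np.random.default_rng(4)
        depth = rng.uniform(10.0, 50.0, size=(12, 9))
        img = rng.random((12, 9))
        path = tmp_path / "cloud.ply"
        export_surface(depth, img, path, focal=80.0)
        cloud = trimesh.load(path)
        h, w = depth.shape
        yy, xx = np.mgrid[0:h, 0:w]
        z = depth.ravel()
        x = (xx.ravel() - (w - 1) / 2) * z / 80.0
        y = (yy.ravel() - (h - 1) / 2) * z / 80.0
        expected = np.stack([x, y, z], axis=1).astype(np.float32)
        assert np.allclose(np.asarray(cloud.vertices, dtype=np.float32),
                           expected, atol=1e-6)

    def test_nonpositive_depth_pixels_skipped(self, tmp_path):
        depth = np.full((4, 4), 10.0)
        depth[0, 0] = 0.0
        depth[1, 1] = -3.0
        n = export_surface(depth, np.zeros((4, 4)), tmp_path / "s.ply", focal=50.0)
        assert n == 14


class TestEmbedLatents:
    def test_collinear_inputs_collapse_to_one_axis(self):
        base = np.arange(6.0)
        pts = embed_latents([t * base for t in np.linspace(-1, 1, 7)])
        assert pts.shape == (7, 2)
        assert np.allclose(pts[:, 1], 0.0, atol=1e-9)

    def test_two_components_reconstruct_no_worse_than_one(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((30, 8))
        from sklearn.decomposition import PCA
        err = []
        for k in (1, 2):
            p = PCA(n_components=k, svd_solver="full").fit(data)
            rec = p.inverse_transform(p.transform(data))
            err.append(np.sum((rec - data) ** 2))
        assert err[1] <= err[0]
        assert embed_latents(data).shape == (30, 2)

    def test_too_few_vectors_rejected(self):
        with pytest.raises(ValueError):
            embed_latents(np.zeros((2, 5)))


def test_plot_helpers_write_figures(tmp_path):
    import pandas as pd

    from predisp.plots import plot_latent_embedding, plot_validation_curves

    curves = {"gru": pd.DataFrame({"epoch": [0, 1, 2], "val_mse": [0.02, 0.01, 0.008]})}
    p1 = plot_validation_curves(curves, {"last_opt": 0.014}, tmp_path / "c.png")
    emb = np.random.default_rng(0).standard_normal((12, 2))
    p2 = plot_latent_embedding(emb, tmp_path / "e.png")
    assert p1.stat().st_size > 0 and p2.stat().st_size > 0


@pytest.fixture(scope="module")
def quick():
    cfg = BenchConfig(
        scene=SceneConfig(),
        strategies=("zero", "last_opt"),
        base_seed=5,
        n_train_sequences=1, train_frames=8, eval_frames=8,
        eval_seeds=(105,),
    )
    return cfg, run_benchmark(cfg)


class TestQuickBenchmark:
    """A miniature protocol run: table shape, accounting, determinism."""

    def test_one_row_per_strategy_with_metric_columns(self, quick):
        _, (table, _, _, failures) = quick
        assert not failures
        assert list(table["strategy"]) == ["zero", "last_opt"]
        for col in ("loss_pho", "iterations", "single_frame_time_s"):
            assert col in table.columns
            assert table[f"best_{col}"].sum() >= 1

    def test_summary_means_match_frame_records(self, quick):
        _, (table, results, _, _) = quick
        for name, rs in results.items():
            per_seed = [r.frame_table().iloc[r.warmup:]["n_steps"].mean() for r in rs]
            row = table[table["strategy"] == name].iloc[0]
            assert row["iterations"] == pytest.approx(np.mean(per_seed))

    def test_rerun_is_deterministic_in_steps_and_losses(self, quick):
        cfg, (table, _, _, _) = quick
        table2, _, _, _ = run_benchmark(cfg)
        assert np.array_equal(table["iterations"].values, table2["iterations"].values)
        assert np.array_equal(table["loss_pho"].values, table2["loss_pho"].values)
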