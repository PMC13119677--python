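"""Per-frame inversion behaviour and initializer strategies."""

import numpy as np
import pytest

from predisp import (
    InitStrategy,
    InversionConfig,
    SceneConfig,
    default_generator,
    make_initial,
    optimize_latent,
    render_sequence,
    run_sequence,
)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"lr": 0.0}, {"max_steps": 0}, {"epsilon": -1.0},
    ])
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            InversionConfig(**kwargs)


class TestOptimizeLatent:
    def test_start_below_threshold_converges_with_zero_steps(
            self, gen, noiseless_ds, inv_cfg):
        trace = optimize_latent(noiseless_ds.latents[0], noiseless_ds.pairs[0],
                                gen, inv_cfg)
        assert trace.converged and trace.n_steps == 0
        assert len(trace.losses) == 1

    def test_trace_bookkeeping_invariants(self, gen, noiseless_ds, inv_cfg):
        trace = optimize_latent(np.zeros(gen.latent_dim), noiseless_ds.pairs[1],
                                gen, inv_cfg)
        assert len(trace.losses) == trace.n_steps + 1
        assert trace.final_loss == min(trace.losses)
        assert trace.final_loss <= trace.losses[0] or trace.n_steps == inv_cfg.max_steps
        # reported optimum reproduces the reported best loss
        from predisp.photometric import total_loss
        assert total_loss(trace.w_opt, noiseless_ds.pairs[1], gen) == pytest.approx(
            trace.final_loss, rel=1e-12)

    def test_time_decomposition_identity(self, gen, noiseless_ds, inv_cfg):
        trace = optimize_latent(np.zeros(gen.latent_dim), noiseless_ds.pairs[2],
                                gen, inv_cfg, t_p=0.0123)
        assert trace.t_all == trace.t_p + trace.n_steps * trace.t_g_per_step

    def test_zero_init_recovers_noiseless_frames(self, gen, noiseless_ds, inv_cfg):
        for t in range(6):
            trace = optimize_latent(np.zeros(gen.latent_dim),
                                    noiseless_ds.pairs[t], gen, inv_cfg)
            assert trace.converged and trace.n_steps <= inv_cfg.max_steps

    def test_wrong_latent_dimension_rejected(self, gen, noiseless_ds, inv_cfg):
        with pytest.raises(ValueError):
            optimize_latent(np.zeros(3), noiseless_ds.pairs[0], gen, inv_cfg)

    def test_steps_shrink_as_init_approaches_truth(self, gen, noiseless_ds, inv_cfg):
        """Monte-Carlo ordering: a 4x closer start never needs more steps on
        average."""
        rng = np.random.default_rng(21)
        amp = noiseless_ds.config.amplitude
        means = []
        for radius in (amp, amp / 4):
            steps = []
            for t in range(10):
                delta = radius * rng.standard_normal(gen.latent_dim)
                trace = optimize_latent(noiseless_ds.latents[t] + delta,
                                        noiseless_ds.pairs[t], gen, inv_cfg)
                steps.append(trace.n_steps)
            means.append(np.mean(steps))
        assert means[1] <= means[0]


class TestMakeInitial:
    def test_zero_kind(self, noiseless_ds):
        w, t_p = make_initial(InitStrategy("zero"), noiseless_ds.pairs[0], 64)
        assert np.array_equal(w, np.zeros(64)) and t_p == 0.0

    def test_mean_train_kind_passes_centre_through(self, noiseless_ds):
        v = np.arange(64.0)
        strat = InitStrategy("mean_train", mean=v)
        w, t_p = make_initial(strat, noiseless_ds.pairs[0], 64)
        assert np.array_equal(w, v) and t_p == 0.0

    def test_last_opt_kind_feeds_back_previous_optimum(self, noiseless_ds):
        strat = InitStrategy("last_opt")
        strat.reset(64)
        w, _ = make_initial(strat, noiseless_ds.pairs[0], 64)
        assert np.array_equal(w, np.zeros(64))  # first frame falls back to zero
        strat.observe(np.full(64, 0.25))
        w, _ = make_initial(strat, noiseless_ds.pairs[1], 64)
        assert np.array_equal(w, np.full(64, 0.25))

    def test_misconfigured_strategies_rejected(self):
        with pytest.raises(ValueError):
            InitStrategy("warp")
        with pytest.raises(ValueError):
            InitStrategy("mean_train")
        with pytest.raises(ValueError):
            InitStrategy("predicted")


class TestRunSequence:
    def test_constant_sequence_needs_no_steps_after_first_frame(self, inv_cfg):
        cfg = SceneConfig(sigma=0.0, rho=1.0, n_frames=5, seed=3)
        g = default_generator(cfg)
        ds = render_sequence(cfg, g)
        res = run_sequence(ds, InitStrategy("last_opt"), g, inv_cfg)
        assert all(t.converged for t in res.traces)
        assert all(t.n_steps == 0 for t in res.traces[1:])

    def test_summary_cells_are_means_of_frame_records(self, gen, noiseless_ds, inv_cfg):
        res = run_sequence(noiseless_ds, InitStrategy("zero"), gen, inv_cfg, warmup=3)
        tab = res.frame_table().iloc[3:]
        s = res.summary()
        assert s["mean_n_steps"] == pytest.approx(tab["n_steps"].mean())
        assert s["mean_final_loss"] == pytest.approx(tab["final_loss"].mean())
        assert s["mean_t_all"] == pytest.approx(tab["t_all"].mean())
        assert s["n_frames"] == len(noiseless_ds) - 3

    def test_temporal_coherence_makes_last_opt_cheaper_than_zero(self, inv_cfg):
        """On a strongly coherent sequence the previous optimum is on average
        a closer start than the origin."""
        steps = {}
        for name in ("zero", "last_opt"):
            totals = []
            for seed in (31, 32, 33):
                cfg = SceneConfig(sigma=0.0, rho=0.95, n_frames=12, seed=seed)
                g = default_generator(cfg)
                ds = render_sequence(cfg, g)
                res = run_sequence(ds, InitStrategy(name), g, inv_cfg, warmup=1)
                totals.append(res.summary()["mean_n_steps"])
            steps[name] = np.mean(totals)
        assert steps["last_opt"] <= steps["zero"]

    def test_deterministic_across_runs(self, gen, inv_cfg):
        cfg = SceneConfig(n_frames=6, seed=44)
        ds = render_sequence(cfg, gen)
        r1 = run_sequence(ds, InitStrategy("zero"), gen, inv_cfg)
        r2 = run_sequence(ds, InitStrategy("zero"), gen, inv_cfg)
        assert [t.n_steps for t in r1.traces] == [t.n_steps for t in r2.traces]
        assert np.array_equal(np.stack([t.w_opt for t in r1.traces]),
                              np.stack([t.w_opt for t in r2.traces]))
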