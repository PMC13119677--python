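"""Stage-2 self-supervised training of a warm-start predictor (miniature).

Labels are produced by inverting every frame of a short corpus with the
fixed generator; a mapping-network predictor then regresses them from the
stereo pairs.  A real run uses the benchmark protocol's corpus (4 x 150
frames) and more epochs — this miniature just shows the moving parts.  The
printed validation MSE is comparable against the two static baselines: a
useful predictor must undercut them.
"""

import warnings

from predisp import SceneConfig, default_generator, render_sequence
from predisp.bench import BenchConfig
from predisp.predictors import (
    TrainConfig, build_label_dataset, static_baseline_val_mse, train_predictor,
)

scene = SceneConfig(n_frames=40, seed=0)
gen = default_generator(scene)
seqs = [render_sequence(SceneConfig(n_frames=40, seed=s), gen) for s in (0, 1)]

label_cfg = BenchConfig(scene=scene).label_inversion()
records, report = build_label_dataset(seqs, gen, label_cfg)
print(f"labels: {report['n_records']} frames, {report['n_excluded']} excluded, "
      f"median final loss {report['median_label_loss']:.2f} px^2")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # miniature run may not beat the baselines
    model, curve = train_predictor(TrainConfig.for_kind("mapping", epochs=8), records)

base = static_baseline_val_mse(records)
print(f"validation latent-MSE: trained mapping {curve['val_mse'].min():.5f} | "
      f"static mean-train {base['mean_train']:.5f}, last-opt {base['last_opt']:.5f}")
print("(lower than both statics = the learned warm start is worth having)")
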