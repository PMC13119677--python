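# predisp

Prediction-guided generative disparity estimation for stereo endoscopy.

## The problem

Minimally invasive surgery needs dense depth from stereo-endoscopic video,
but pixel-wise disparity supervision is unobtainable in the operating room.
A self-supervised generative approach sidesteps labels: a fixed generator
G decodes a compact latent code w ∈ R^K into a disparity map, and each
frame is explained by *latent inversion* — gradient descent on the
photometric loss between the observed right view I_r and the right view
reconstructed by warping the left view through G(w):

    w* = argmin_w  L_pho( Interp(G(w), I_l), I_r ),     depth = b·f / G(w*)

The catch is latency: inverting every frame from a cold start takes many
Adam iterations (fixed lr 5·10⁻³, up to 150 per frame).  Endoscopic video
is temporally coherent, though — consecutive optima are close — so a
*warm start* predicted from the current stereo pair and the previous
frame's optimum can cut the iteration count substantially while converging
to the same solution:

    w_init^t = P( w_opt^{t−1}, M(I_l^t), M(I_r^t) )        (K+N ↦ K)

`predisp` implements the whole pipeline on seeded synthetic stereo
sequences with known ground truth: the differentiable generator and warp,
the per-frame inversion loop, three learned warm-start predictors (a
stereo mapping network with spatial pyramid pooling and a correlation cost
volume; the same network fused with the previous optimum by a single-step
GRU; a siamese baseline), their self-supervised Stage-2 training
(labels = inversion optima of the fixed generator, MSE loss), and the
benchmark protocol comparing five initializer strategies on held-out
sequences by final photometric loss (px²), iteration count and per-frame
time t_all = t_p + N_step·t_g.

It is a research codebase for studying *how much* informed initialisation
buys under controlled conditions, aimed at people working on
self-supervised stereo, GAN/generator inversion, or surgical 3-D
reconstruction.  See `docs/methods.md` for the model, assumptions and
design choices.

## A worked example

```python
import numpy as np
from predisp import (SceneConfig, default_generator, render_sequence,
                     InversionConfig, measure_interp_bound, optimize_latent,
                     latent_mse, disparity_to_depth)

cfg = SceneConfig(n_frames=5, sigma=0.0, seed=7)      # 64x64, K=64
gen = default_generator(cfg)
ds  = render_sequence(cfg, gen)                       # ground truth attached
inv = InversionConfig(epsilon=2.0 * measure_interp_bound(cfg, gen))

tr = optimize_latent(np.zeros(64), ds.pairs[2], gen, inv)
print(tr.converged, tr.n_steps, round(tr.final_loss, 2))
print(round(latent_mse(tr.w_opt, ds.latents[2]), 5))
```

prints (seeded, reproducible):

```
True 39 18.63
0.0225
```

— the cold-started inversion needed 39 Adam steps to push the photometric
loss to 18.63 px², below the calibrated threshold (twice the fixture's
interpolation floor, 19.0 px² here).  The recovered code sits at
latent-MSE 0.0225 from the ground-truth trajectory point (whose marginal
variance is 0.04): the threshold stop accepts any code inside the wide
low-loss basin, leaving slack along latent directions the texture barely
observes — exactly why the *final loss*, not latent distance, is the
fidelity metric.  A warm start cuts those 39 steps: run
`python examples/04_benchmark_strategies.py` (or the
full `predisp benchmark --seed 0 --out out/`) to see the per-strategy
table.  The `examples/` directory walks every capability: scene synthesis,
single-frame inversion, predictor training, the strategy benchmark, and
PLY surface export with the 2-D latent embedding.

There is also a thin CLI:

```sh
predisp simulate --seed 3 --frames 50 --out seq/
predisp infer --sequence seq/ --strategy last_opt --out out/
predisp export-surface --sequence seq/ --frame 0 --out surf.ply
predisp benchmark --seed 0 --out bench/        # trains all predictors
```

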