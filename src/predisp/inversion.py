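"""Online latent inversion: per-frame optimisation and initializer strategies.

Each frame of a stereo sequence is explained by gradient descent on the
photometric loss over the generator's latent code.  The optimiser is Adam
with a fixed learning rate of 5e-3 (beta1=0.9, beta2=0.999), capped at 150
iterations per frame.  Descent stops at the first of:

* loss <= epsilon (converged: the reconstruction explains the frame to
  within the calibrated interpolation/noise floor),
* a plateau (no relative improvement beyond 1e-4 for ``patience`` steps --
  with observation noise the epsilon threshold alone may never fire, but the
  loss still stabilises), or
* the iteration cap.

The whole point of the package is that *where the descent starts* dominates
its cost: the initializer strategies range from the cold zero vector through
static warm starts (previous frame's optimum, centre of the training optima)
to a learned temporal predictor.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .photometric import total_loss_and_grad

__all__ = [
    "InversionConfig",
    "OptimizationTrace",
    "InitStrategy",
    "SequenceResult",
    "optimize_latent",
    "make_initial",
    "run_sequence",
]


@dataclass
class InversionConfig:
    """Per-frame optimisation settings.

    ``epsilon`` (pixel^2) is the convergence threshold on the photometric
    loss; calibrate it from the fixture's interpolation floor, e.g.
    ``2 * measure_interp_bound(...)``.  Left as ``None``, no threshold is
    applied and descent stops only on plateau or the iteration cap (the
    trace then never reports ``converged``).
    """

    lr: float = 5e-3
    max_steps: int = 150
    epsilon: float | None = None
    patience: int = 10
    min_rel_improvement: float = 1e-4
    lam: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class OptimizationTrace:
    """Record of one frame's inversion."""

    w_init: np.ndarray
    w_opt: np.ndarray
    losses: list[float]       # length n_steps + 1, losses[0] is at w_init
    n_steps: int
    converged: bool
    t_p: float                # seconds spent producing the initial latent
    t_g_per_step: float       # mean seconds per optimisation step

    @property
    def final_loss(self) -> float:
        return min(self.losses)

    @property
    def t_all(self) -> float:
        """Per-frame time decomposition: prediction plus iteration cost."""
        return self.t_p + self.n_steps * self.t_g_per_step


class InversionError(RuntimeError):
    def __init__(self, step: int, msg: str):
        super().__init__(f"step {step}: {msg}")
        self.step = step


def optimize_latent(w_init, pair, gen, cfg: InversionConfig,
                    t_p: float = 0.0) -> OptimizationTrace:
    """Invert one frame by Adam descent on the photometric loss.

    Counts gradient updates only: a start already below ``epsilon`` converges
    with ``n_steps == 0``.  Returns the best latent seen (not necessarily the
    last iterate) together with the full loss history and timing components.
    """
    w = np.array(w_init, dtype=np.float64)
    if w.shape != (gen.latent_dim,):
        raise ValueError(f"w_init has shape {w.shape}, expected ({gen.latent_dim},)")
    eps = -np.inf if cfg.epsilon is None else cfg.epsilon
    t0 = time.perf_counter()
    loss, grad = total_loss_and_grad(w, pair, gen, lam=cfg.lam)
    if not np.isfinite(loss):
        raise InversionError(0, "non-finite loss at the initial latent")
    losses = [loss]
    best_loss, best_w = loss, w.copy()
    m = np.zeros_like(w)
    v = np.zeros_like(w)
    n_steps = 0
    stall = 0
    converged = loss <= eps
    while not converged and n_steps < cfg.max_steps:
        if not np.all(np.isfinite(grad)):
            raise InversionError(n_steps, "non-finite gradient")
        n_steps += 1
        m = 0.9 * m + 0.1 * grad
        v = 0.999 * v + 0.001 * grad * grad
        mh = m / (1.0 - 0.9**n_steps)
        vh = v / (1.0 - 0.999**n_steps)
        w -= cfg.lr * mh / (np.sqrt(vh) + 1e-8)
        loss, grad = total_loss_and_grad(w, pair, gen, lam=cfg.lam)
        if not np.isfinite(loss):
            raise InversionError(n_steps, "non-finite loss")
        losses.append(loss)
        if loss < best_loss * (1.0 - cfg.min_rel_improvement):
            stall = 0
        else:
            stall += 1
        if loss < best_loss:
            best_loss, best_w = loss, w.copy()
        if best_loss <= eps:
            converged = True
        elif stall >= cfg.patience:
            break
    elapsed = time.perf_counter() - t0
    return OptimizationTrace(
        w_init=np.array(w_init, dtype=np.float64),
        w_opt=best_w,
        losses=losses,
        n_steps=n_steps,
        converged=converged,
        t_p=t_p,
        t_g_per_step=elapsed / max(n_steps, 1),
    )


@dataclass
class InitStrategy:
    """How to choose each frame's starting latent.

    kinds:
      * ``zero``       -- the cold start: a zero vector every frame.
      * ``mean_train`` -- centre of the training optima (``mean`` payload).
      * ``last_opt``   -- previous frame's optimum (autoregressive; zero at
                          the first frame).
      * ``predicted``  -- a learned temporal predictor (``predictor`` payload,
                          an object with ``reset(K)`` and
                          ``predict(pair, w_prev) -> w_init``).
    """

    kind: str
    mean: np.ndarray | None = None
    predictor: object | None = None
    # mutable per-sequence context
    prev_opt: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.kind not in ("zero", "mean_train", "last_opt", "predicted"):
            raise ValueError(f"unknown initializer kind {self.kind!r}")
        if self.kind == "mean_train" and self.mean is None:
            raise ValueError("mean_train strategy requires the mean latent")
        if self.kind == "predicted" and self.predictor is None:
            raise ValueError("predicted strategy requires a predictor handle")

    def reset(self, latent_dim: int) -> None:
        self.prev_opt = None
        if self.kind == "predicted":
            self.predictor.reset(latent_dim)

    def observe(self, w_opt: np.ndarray) -> None:
        """Feed back a frame's optimisation result (autoregressive loop)."""
        self.prev_opt = np.array(w_opt, dtype=np.float64)


def make_initial(strategy: InitStrategy, pair, latent_dim: int):
    """Produce (w_init, t_p) for one frame.

    Static strategies report t_p = 0 by convention; the learned predictor's
    forward pass is timed.  Temporal strategies fall back to the zero vector
    at the first frame, where no history exists.
    """
    if strategy.kind == "zero":
        return np.zeros(latent_dim), 0.0
    if strategy.kind == "mean_train":
        return np.array(strategy.mean, dtype=np.float64), 0.0
    if strategy.kind == "last_opt":
        if strategy.prev_opt is None:
            return np.zeros(latent_dim), 0.0
        return strategy.prev_opt.copy(), 0.0
    # predicted
    t0 = time.perf_counter()
    w_prev = strategy.prev_opt if strategy.prev_opt is not None else np.zeros(latent_dim)
    w_init = strategy.predictor.predict(pair, w_prev)
    return np.asarray(w_init, dtype=np.float64), time.perf_counter() - t0


@dataclass
class SequenceResult:
    """All traces of one strategy over one sequence, plus summary means."""

    strategy: str
    traces: list[OptimizationTrace]
    warmup: int = 0  # leading frames excluded from the summary means

    def frame_table(self) -> pd.DataFrame:
        rows = [
            {
                "frame": i,
                "strategy": self.strategy,
                "n_steps": tr.n_steps,
                "final_loss": tr.final_loss,
                "converged": tr.converged,
                "t_p": tr.t_p,
                "t_g": tr.t_g_per_step,
                "t_all": tr.t_all,
            }
            for i, tr in enumerate(self.traces)
        ]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        tab = self.frame_table().iloc[self.warmup:]
        return {
            "strategy": self.strategy,
            "mean_final_loss": float(tab["final_loss"].mean()),
            "mean_n_steps": float(tab["n_steps"].mean()),
            "mean_t_all": float(tab["t_all"].mean()),
            "n_frames": int(len(tab)),
        }


def run_sequence(dataset, strategy: InitStrategy, gen, cfg: InversionConfig,
                 warmup: int = 0) -> SequenceResult:
    """Invert every frame of a sequence under one initializer strategy.

    The previous frame's optimum is fed back into the strategy after each
    frame, closing the autoregressive loop for the temporal strategies.
    Optimiser state is reset at every frame: each frame is an independent
    inversion, only the starting point carries history.
    """
    strategy.reset(gen.latent_dim)
    traces: list[OptimizationTrace] = []
    for pair in dataset.pairs:
        try:
            w_init, t_p = make_initial(strategy, pair, gen.latent_dim)
            trace = optimize_latent(w_init, pair, gen, cfg, t_p=t_p)
        except Exception as exc:
            raise RuntimeError(f"frame {pair.frame_index}: {exc}") from exc
        strategy.observe(trace.w_opt)
        traces.append(trace)
    return SequenceResult(strategy=strategy.kind, traces=traces, warmup=warmup)
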