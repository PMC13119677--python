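"""Disk formats: PNG frame directories, ground-truth archives, tables.

A sequence directory holds 8-bit PNG frames named ``frame_%05d_L.png`` /
``frame_%05d_R.png``, a compressed ``ground_truth.npz`` with the latent
trajectory and disparity stack, and a ``scene.yaml`` sidecar with the full
scene configuration.  Images quantise to 1/255 on write; everything else
round-trips losslessly.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .scene import SceneConfig, StereoPair, SequenceDataset

__all__ = [
    "write_sequence",
    "read_sequence",
    "write_results",
    "read_results",
    "write_config_snapshot",
]


def _to_uint8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)


def write_sequence(ds: SequenceDataset, out_dir) -> Path:
    """Write a rendered sequence as PNGs + ground-truth archive + YAML sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pair in ds.pairs:
        iio.imwrite(out / f"frame_{pair.frame_index:05d}_L.png", _to_uint8(pair.left))
        iio.imwrite(out / f"frame_{pair.frame_index:05d}_R.png", _to_uint8(pair.right))
    np.savez_compressed(out / "ground_truth.npz",
                        latents=ds.latents, disparities=ds.disparities)
    with open(out / "scene.yaml", "w") as fh:
        yaml.safe_dump(asdict(ds.config), fh)
    return out


def read_sequence(seq_dir) -> SequenceDataset:
    """Read a sequence directory written by :func:`write_sequence`."""
    seq = Path(seq_dir)
    with open(seq / "scene.yaml") as fh:
        cfg = SceneConfig(**yaml.safe_load(fh))
    with np.load(seq / "ground_truth.npz") as z:
        latents = z["latents"]
        disparities = z["disparities"]
    pairs = []
    for t in range(cfg.n_frames):
        left = iio.imread(seq / f"frame_{t:05d}_L.png").astype(np.float64) / 255.0
        right = iio.imread(seq / f"frame_{t:05d}_R.png").astype(np.float64) / 255.0
        pairs.append(StereoPair(left=left, right=right, baseline=cfg.baseline,
                                focal=cfg.focal, frame_index=t))
    return SequenceDataset(config=cfg, pairs=pairs, latents=latents,
                           disparities=disparities)


def write_results(results, out_dir) -> Path:
    """Write per-frame CSV traces and a JSON summary for each strategy."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = pd.concat([r.frame_table() for r in results], ignore_index=True)
    frames.to_csv(out / "frames.csv", index=False)
    summaries = [r.summary() for r in results]
    with open(out / "summary.json", "w") as fh:
        json.dump(summaries, fh, indent=2)
    return out


def read_results(out_dir):
    out = Path(out_dir)
    frames = pd.read_csv(out / "frames.csv")
    with open(out / "summary.json") as fh:
        summaries = json.load(fh)
    return frames, summaries


def write_config_snapshot(path, **sections) -> None:
    """Resolved-configuration snapshot for provenance of a run."""
    snap = {}
    for name, obj in sections.items():
        if hasattr(obj, "__dataclass_fields__"):
            d = asdict(obj)
            d = {k: v for k, v in d.items() if not isinstance(v, np.ndarray)}
            snap[name] = d
        else:
            snap[name] = obj
    with open(path, "w") as fh:
        yaml.safe_dump(snap, fh)
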