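"""Differentiable stereo warping and the photometric self-supervision loss.

Convention (rectified stereo, positive disparity): a scene point imaged at
column ``x`` in the right view appears at column ``x + d`` in the left view,
so the right image is reconstructed by sampling the left image:

    rec(x, y) = left(x + d(x, y), y)        (bilinear in x)

Pixels whose source coordinate falls outside the left image are masked out
and excluded from the loss.  Intensities are stored in [0, 1] but the loss is
computed on the 0-255 scale, so its magnitude is directly interpretable in
pixel-squared intensity units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WarpResult", "reconstruct_right", "photometric_loss", "total_loss"]

INTENSITY_SCALE = 255.0


@dataclass
class WarpResult:
    """Reconstructed right view plus the validity mask of the warp."""

    image: np.ndarray  # (H, W) in [0, 1]
    mask: np.ndarray   # (H, W) bool, True where the sample was in-bounds
    # horizontal derivative of the reconstruction w.r.t. disparity, needed by
    # the analytic inversion gradient; same shape as image
    d_image_d_disp: np.ndarray


def reconstruct_right(left: np.ndarray, disparity: np.ndarray) -> WarpResult:
    """Warp the left image by the disparity map to reconstruct the right view."""
    left = np.asarray(left, dtype=np.float64)
    disparity = np.asarray(disparity, dtype=np.float64)
    if left.shape != disparity.shape:
        raise ValueError(
            f"left image {left.shape} and disparity {disparity.shape} differ in size"
        )
    H, W = left.shape
    xs = np.arange(W)[None, :] + disparity  # source column per pixel
    mask = (xs >= 0.0) & (xs <= W - 1)
    x0 = np.floor(xs).astype(np.int64)
    frac = xs - x0
    x0c = np.clip(x0, 0, W - 1)
    x1c = np.clip(x0 + 1, 0, W - 1)
    rows = np.arange(H)[:, None]
    a = left[rows, x0c]
    b = left[rows, x1c]
    rec = (1.0 - frac) * a + frac * b
    return WarpResult(image=rec, mask=mask, d_image_d_disp=b - a)


def photometric_loss(rec: np.ndarray, target: np.ndarray, mask: np.ndarray) -> float:
    """Mean squared intensity difference over masked pixels, 0-255 scale (pixel^2)."""
    rec = np.asarray(rec, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if rec.shape != target.shape or rec.shape != mask.shape:
        raise ValueError("image/mask shapes differ")
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValueError("photometric loss undefined: empty validity mask")
    diff = (rec - target)[mask] * INTENSITY_SCALE
    return float(np.mean(diff * diff))


def total_loss(w, pair, gen, lam: float = 0.0, d_ref=None) -> float:
    """Objective minimised during inversion.

    With ``lam == 0`` (the default) this is exactly the masked photometric
    loss of the warp through G(w).  With ``lam > 0`` a quadratic disparity
    regulariser ``lam/N * ||G(w) - d_ref||^2`` is added, pulling the decoded
    map toward a reference disparity (the generator's base level d0 when no
    reference is supplied).
    """
    loss, _ = total_loss_and_grad(w, pair, gen, lam=lam, d_ref=d_ref, need_grad=False)
    return loss


def total_loss_and_grad(w, pair, gen, lam: float = 0.0, d_ref=None, need_grad: bool = True):
    """Loss and its analytic gradient with respect to the latent.

    Chain: latent -> disparity (generator VJP) -> warped image (bilinear,
    derivative ``b - a`` per pixel) -> masked squared-error loss.
    """
    if lam < 0:
        raise ValueError("regulariser weight lam must be nonnegative")
    w = np.asarray(w, dtype=np.float64)
    disp, vjp = gen.generate_with_vjp(w)
    warp = reconstruct_right(pair.left, disp)
    n = int(np.count_nonzero(warp.mask))
    if n == 0:
        raise ValueError("photometric loss undefined: empty validity mask")
    resid = np.where(warp.mask, warp.image - pair.right, 0.0)
    loss = float(np.sum(resid * resid) * INTENSITY_SCALE**2 / n)
    g_disp = None
    if lam > 0.0:
        ref = np.full_like(disp, gen.d0) if d_ref is None else np.asarray(d_ref)
        dres = disp - ref
        loss += lam * float(np.sum(dres * dres)) / disp.size
        if need_grad:
            g_disp = (2.0 * lam / disp.size) * dres
    if not need_grad:
        return loss, None
    g_img = (2.0 * INTENSITY_SCALE**2 / n) * resid
    g_d = g_img * warp.d_image_d_disp
    if g_disp is not None:
        g_d = g_d + g_disp
    return loss, vjp(g_d)
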