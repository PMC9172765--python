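"""Native coarse-to-fine dense Lucas-Kanade optical flow.

A self-contained pyramidal implementation of the classic local method:
at each pyramid level the current flow estimate warps the moving frame
toward the reference, and per-pixel 2x2 normal equations over a square
window are re-solved for the total flow (linearized around the current
estimate, using the warped frame's gradients).  Pixels whose structure
tensor is ill-conditioned (textureless regions) keep the flow inherited
from the coarser level instead of an unstable local solution.

The displacement convention matches the rest of the package: the returned
field ``u`` satisfies ``reference(x, y) ~ frame(x + u_x, y + u_y)``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .model import _check_odd

__all__ = ["pyramidal_lk_dense"]

#: pixels whose (window-averaged) structure tensor has a smaller eigenvalue
#: below this keep the incoming flow rather than the local solution
EIGENVALUE_THRESHOLD = 1e-4

_MIN_LEVEL_SIZE = 32


def _as_float_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D frame, got shape {image.shape}")
    if image.max() > 1.5:  # integer-valued input: put gradients on unit scale
        image = image / 255.0 if image.max() <= 255 else image / image.max()
    return image


def _pyramid(image: np.ndarray, levels: int) -> list:
    """Factor-2 Gaussian pyramid, finest level first."""
    out = [image]
    for _ in range(levels - 1):
        blurred = ndimage.gaussian_filter(out[-1], sigma=1.0, mode="nearest")
        out.append(blurred[::2, ::2])
    return out


def _warp_bilinear(image: np.ndarray, flow: np.ndarray) -> np.ndarray:
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w]
    coords = np.stack([yy + flow[..., 1], xx + flow[..., 0]])
    return ndimage.map_coordinates(image, coords, order=1, mode="nearest")


def _upsample_flow(flow: np.ndarray, shape) -> np.ndarray:
    """Upsample a flow field x2 (bilinear) and double its magnitudes."""
    h, w = shape
    zoom = (h / flow.shape[0], w / flow.shape[1], 1.0)
    up = ndimage.zoom(flow, zoom, order=1, mode="nearest", grid_mode=True)
    return 2.0 * up


def pyramidal_lk_dense(
    reference: np.ndarray,
    frame: np.ndarray,
    levels: int = 3,
    window: int = 15,
    iterations: int = 5,
) -> np.ndarray:
    """Estimate dense flow from ``reference`` to ``frame``.

    Parameters
    ----------
    reference, frame : ndarray, shape (H, W)
        Grayscale frames (integer frames are rescaled to ``[0, 1]``).
    levels : int
        Requested number of pyramid levels; capped so the coarsest level
        stays at least 32 px on its short side.
    window : odd int >= 5
        Side length of the square integration window.
    iterations : int
        Warp/solve passes per pyramid level.

    Returns
    -------
    flow : ndarray, shape (H, W, 2)
        Components ``(u_x, u_y)`` in pixels, sub-pixel precision.
    """
    _check_odd(window, "window")
    if window < 5:
        raise ValueError("window must be >= 5")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    ref = _as_float_image(reference)
    frm = _as_float_image(frame)
    if ref.shape != frm.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {frm.shape}")

    max_levels = int(np.floor(np.log2(min(ref.shape) / _MIN_LEVEL_SIZE))) + 1
    levels = max(1, min(levels, max_levels))
    ref_pyramid = _pyramid(ref, levels)
    frm_pyramid = _pyramid(frm, levels)

    flow = np.zeros(ref_pyramid[-1].shape + (2,))
    for level in range(levels - 1, -1, -1):
        ref_l = ref_pyramid[level]
        frm_l = frm_pyramid[level]
        if flow.shape[:2] != ref_l.shape:
            flow = _upsample_flow(flow, ref_l.shape)
        mean = lambda a: ndimage.uniform_filter(a, size=window, mode="nearest")
        for _ in range(iterations):
            warped = _warp_bilinear(frm_l, flow)
            # gradients of the WARPED moving frame: the linearization is then
            # consistent at the current estimate, which keeps the iteration
            # stable (reference-frame gradients diverge off large residuals)
            gy, gx = np.gradient(warped)
            sxx, sxy, syy = mean(gx * gx), mean(gx * gy), mean(gy * gy)
            trace = sxx + syy
            det = sxx * syy - sxy * sxy
            lambda_min = trace / 2 - np.sqrt(np.maximum(trace**2 / 4 - det, 0.0))
            solvable = (lambda_min >= EIGENVALUE_THRESHOLD) & (np.abs(det) > 1e-12)
            safe_det = np.where(solvable, det, 1.0)
            it = warped - ref_l
            # solve for the TOTAL flow each pass (linearized around the
            # current estimate) — accumulating raw increments is unstable
            err = gx * flow[..., 0] + gy * flow[..., 1] - it
            bx = mean(gx * err)
            by = mean(gy * err)
            u = (syy * bx - sxy * by) / safe_det
            v = (sxx * by - sxy * bx) / safe_det
            flow = np.where(
                solvable[..., None], np.stack([u, v], axis=-1), flow
            )
    return flow
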