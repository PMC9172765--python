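"""Dense optical flow by polynomial expansion (Farnebäck's method).

Each image is locally approximated by a quadratic polynomial
``f(x) ≈ xᵀ A x + bᵀ x + c`` fitted over a small Gaussian-weighted
neighborhood (the *polynomial expansion*).  Under a local translation ``d``
of the signal, the expansion coefficients of the two images are related by
``A2 = A1`` and ``b2 = b1 - 2 A1 d``, which turns flow estimation into a
per-pixel linear problem.  Robustness comes from averaging the normal
equations over a larger window and from an iterative coarse-to-fine scheme
that handles displacements larger than the expansion neighborhood.

Because the local model is affine-in-space rather than constant, the method
tolerates the smoothly varying contractile deformations and the moderate
image noise typical of optical mapping recordings better than plain
Lucas-Kanade windows.

The displacement convention matches the rest of the package:
``reference(x, y) ≈ frame(x + u_x, y + u_y)``.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import ndimage

__all__ = ["farneback_flow", "polynomial_expansion"]

_MIN_LEVEL_SIZE = 16


def _applicability(n: int, sigma: float) -> np.ndarray:
    x = np.arange(n) - (n - 1) / 2
    w = np.exp(-(x**2) / (2.0 * sigma**2))
    return w


def polynomial_expansion(
    image: np.ndarray, n: int = 5, sigma: float = 1.1
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit ``f(x) ≈ xᵀ A x + bᵀ x + c`` around every pixel.

    Parameters
    ----------
    image : ndarray, shape (H, W)
        Grayscale image (floats).
    n : odd int
        Side length of the expansion neighborhood.
    sigma : float
        Width of the Gaussian applicability weighting the fit.

    Returns
    -------
    a : ndarray, shape (H, W, 2, 2)
        Symmetric quadratic coefficient per pixel (x-then-y component order).
    b : ndarray, shape (H, W, 2)
        Linear coefficients ``(b_x, b_y)``.
    c : ndarray, shape (H, W)
        Constant coefficients.
    """
    image = np.asarray(image, dtype=float)
    w = _applicability(n, sigma)
    x = np.arange(n) - (n - 1) / 2

    # separable correlation kernels for the moments  m_ab = Σ w x^a y^b I
    k0, k1, k2 = w, w * x, w * x * x
    def corr(img, ky, kx):
        tmp = ndimage.correlate1d(img, ky, axis=0, mode="nearest")
        return ndimage.correlate1d(tmp, kx, axis=1, mode="nearest")

    m00 = corr(image, k0, k0)
    m10 = corr(image, k0, k1)  # x moment
    m01 = corr(image, k1, k0)  # y moment
    m20 = corr(image, k0, k2)
    m02 = corr(image, k2, k0)
    m11 = corr(image, k1, k1)

    # normal-equations matrix G = Σ w B Bᵀ for basis B = (1, x, y, x², y², xy);
    # uniform certainty makes it constant across the image
    s0 = w.sum()
    s2 = (w * x * x).sum()
    s4 = (w * x**4).sum()
    G = np.zeros((6, 6))
    G[0, 0] = s0 * s0
    G[1, 1] = s2 * s0
    G[2, 2] = s0 * s2
    G[3, 3] = s4 * s0
    G[4, 4] = s0 * s4
    G[5, 5] = s2 * s2
    G[0, 3] = G[3, 0] = s2 * s0
    G[0, 4] = G[4, 0] = s0 * s2
    G[3, 4] = G[4, 3] = s2 * s2
    Ginv = np.linalg.inv(G)

    moments = np.stack([m00, m10, m01, m20, m02, m11], axis=-1)
    coeffs = moments @ Ginv.T

    c = coeffs[..., 0]
    b = coeffs[..., 1:3]
    a = np.empty(image.shape + (2, 2))
    a[..., 0, 0] = coeffs[..., 3]
    a[..., 1, 1] = coeffs[..., 4]
    a[..., 0, 1] = a[..., 1, 0] = coeffs[..., 5] / 2.0
    return a, b, c


def _sample_fields(a, b, flow):
    """Sample expansion coefficients of the moving frame at x + flow."""
    h, w = flow.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    coords = np.stack([yy + flow[..., 1], xx + flow[..., 0]])
    kw = dict(order=1, mode="nearest")
    a_s = np.empty_like(a)
    a_s[..., 0, 0] = ndimage.map_coordinates(a[..., 0, 0], coords, **kw)
    a_s[..., 1, 1] = ndimage.map_coordinates(a[..., 1, 1], coords, **kw)
    off = ndimage.map_coordinates(a[..., 0, 1], coords, **kw)
    a_s[..., 0, 1] = a_s[..., 1, 0] = off
    b_s = np.empty_like(b)
    b_s[..., 0] = ndimage.map_coordinates(b[..., 0], coords, **kw)
    b_s[..., 1] = ndimage.map_coordinates(b[..., 1], coords, **kw)
    return a_s, b_s


def _flow_level(ref, frm, flow, winsize, iterations, poly_n, poly_sigma):
    a1, b1, _ = polynomial_expansion(ref, poly_n, poly_sigma)
    a2, b2, _ = polynomial_expansion(frm, poly_n, poly_sigma)
    mean = lambda arr: ndimage.uniform_filter(arr, size=winsize, mode="nearest")
    for _ in range(iterations):
        a2_w, b2_w = _sample_fields(a2, b2, flow)
        a_mid = 0.5 * (a1 + a2_w)
        # Δb = -(b2 - b1)/2 + A d0 ;  solving A d = Δb recovers the total flow
        db = -0.5 * (b2_w - b1) + np.einsum("...ij,...j->...i", a_mid, flow)
        g11 = mean(a_mid[..., 0, 0] ** 2 + a_mid[..., 0, 1] ** 2)
        g12 = mean(
            a_mid[..., 0, 0] * a_mid[..., 0, 1]
            + a_mid[..., 0, 1] * a_mid[..., 1, 1]
        )
        g22 = mean(a_mid[..., 0, 1] ** 2 + a_mid[..., 1, 1] ** 2)
        h1 = mean(a_mid[..., 0, 0] * db[..., 0] + a_mid[..., 0, 1] * db[..., 1])
        h2 = mean(a_mid[..., 0, 1] * db[..., 0] + a_mid[..., 1, 1] * db[..., 1])
        det = g11 * g22 - g12 * g12
        ok = np.abs(det) > 1e-14
        safe_det = np.where(ok, det, 1.0)
        u = np.where(ok, (g22 * h1 - g12 * h2) / safe_det, flow[..., 0])
        v = np.where(ok, (g11 * h2 - g12 * h1) / safe_det, flow[..., 1])
        flow = np.stack([u, v], axis=-1)
    return flow


def _downsample(image: np.ndarray) -> np.ndarray:
    return ndimage.gaussian_filter(image, sigma=1.0, mode="nearest")[::2, ::2]


def farneback_flow(
    reference: np.ndarray,
    frame: np.ndarray,
    levels: int = 5,
    winsize: int = 13,
    iterations: int = 3,
    poly_n: int = 5,
    poly_sigma: float = 1.1,
) -> np.ndarray:
    """Estimate dense flow from ``reference`` to ``frame``.

    Parameters
    ----------
    reference, frame : ndarray, shape (H, W)
        Grayscale frames (integer frames are rescaled to ``[0, 1]``).
    levels : int
        Pyramid levels (factor 2), capped so the coarsest level keeps at
        least 16 px on its short side.
    winsize : int
        Side length of the box window averaging the normal equations.
    iterations : int
        Solve/warp passes per level.
    poly_n, poly_sigma : int, float
        Neighborhood size and Gaussian width of the polynomial expansion.

    Returns
    -------
    flow : ndarray, shape (H, W, 2), components ``(u_x, u_y)`` in pixels.
    """
    ref = np.asarray(reference, dtype=float)
    frm = np.asarray(frame, dtype=float)
    if ref.shape != frm.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {frm.shape}")
    if ref.max() > 1.5:
        scale = 255.0 if ref.max() <= 255 else float(max(ref.max(), frm.max()))
        ref = ref / scale
        frm = frm / scale

    max_levels = int(np.floor(np.log2(min(ref.shape) / _MIN_LEVEL_SIZE))) + 1
    levels = max(1, min(levels, max_levels))
    ref_pyr, frm_pyr = [ref], [frm]
    for _ in range(levels - 1):
        ref_pyr.append(_downsample(ref_pyr[-1]))
        frm_pyr.append(_downsample(frm_pyr[-1]))

    flow = np.zeros(ref_pyr[-1].shape + (2,))
    for level in range(levels - 1, -1, -1):
        target = ref_pyr[level].shape
        if flow.shape[:2] != target:
            zoom = (target[0] / flow.shape[0], target[1] / flow.shape[1], 1.0)
            flow = 2.0 * ndimage.zoom(flow, zoom, order=1, mode="nearest", grid_mode=True)
        flow = _flow_level(
            ref_pyr[level], frm_pyr[level], flow, winsize, iterations,
            poly_n, poly_sigma,
        )
    return flow
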