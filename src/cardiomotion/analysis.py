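"""Measurement outputs: normalized optical maps, ROI traces, tracking error.

:func:`pixelwise_normalize` renders optical maps of wave propagation by
rescaling each pixel's time trace inside a sliding window — short windows
(tens of ms) also suppress slow illumination-related baseline drift.
:func:`extract_trace` averages a small ROI box per frame, the standard way
optical action potential traces are read out.  :func:`compute_epe` is the
accuracy metric for flow benchmarks: the mean Euclidean distance between
estimated and reference displacement vectors (end-point error).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .model import ROI, VideoStack

__all__ = ["pixelwise_normalize", "extract_trace", "compute_epe", "BenchmarkRecord"]


@dataclass
class BenchmarkRecord:
    """One cell of an accuracy benchmark sweep.

    ``f_percent`` is the unsigned fluorescence strength |ΔF/F| in percent
    (the signed fractional value is kept in ``f_signed``); ``sigma`` is the
    added Gaussian noise standard deviation on unit intensities.
    ``seconds_per_pair`` is wall-clock and therefore hardware-dependent:
    report-only.
    """

    backend: str
    f_percent: float
    sigma: float
    contrast_enhanced: bool
    mean_epe_px: float
    n_pairs: int
    seconds_per_pair: float
    epe_stderr: float = 0.0
    f_signed: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean_epe_px) or self.mean_epe_px < 0:
            raise ValueError("mean_epe_px must be finite and >= 0")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


def pixelwise_normalize(stack: VideoStack, window_ms: float = 20.0) -> VideoStack:
    """Sliding-window min/max normalization of every pixel's time trace.

    The window length is ``L = max(2, round(window_ms / frame_interval_ms))``
    frames, centered on each frame (centered rather than trailing windows
    avoid phase lag in upstroke timing) and truncated at the video ends.
    Pixels whose windowed range is flat map to 0.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    interval = stack.frame_interval_ms
    if interval <= 0:
        raise ValueError("unknown frame interval")
    length = max(2, int(round(window_ms / interval)))
    frames = np.asarray(stack.frames, dtype=float)
    n = frames.shape[0]
    # centered window [t - L//2, t - L//2 + L - 1]; clamped temporal indices
    # stay inside the truncated window, so mode="nearest" matches truncation
    lo = ndimage.minimum_filter1d(frames, size=length, axis=0, mode="nearest")
    hi = ndimage.maximum_filter1d(frames, size=length, axis=0, mode="nearest")
    span = hi - lo
    flat = span < 1e-12
    span[flat] = 1.0
    out = (frames - lo) / span
    out[flat] = 0.0
    return stack.with_frames(np.clip(out, 0.0, 1.0), bit_depth="unit")


def extract_trace(stack: VideoStack, roi: ROI) -> np.ndarray:
    """Mean intensity over the ROI box per frame (length-T time series)."""
    h, w = stack.frame_shape
    y0, y1, x0, x1 = roi.bounds(h, w)
    box = np.asarray(stack.frames, dtype=float)[:, y0:y1, x0:x1]
    return box.mean(axis=(1, 2))


def compute_epe(
    estimated: np.ndarray,
    truth: np.ndarray,
    mask: Optional[np.ndarray] = None,
) -> float:
    """Mean end-point error between two displacement fields, in pixels.

    The Euclidean distance ``sqrt((û_x - u_x)² + (û_y - u_y)²)`` is averaged
    over all pixels, or over the mask's True pixels if one is given.
    """
    estimated = np.asarray(estimated, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimated.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: {estimated.shape} vs {truth.shape}"
        )
    dist = np.sqrt(((estimated - truth) ** 2).sum(axis=-1))
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != dist.shape:
            raise ValueError("mask shape does not match the fields")
        if not mask.any():
            raise ValueError("mask excludes every pixel")
        dist = dist[mask]
    return float(dist.mean())
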