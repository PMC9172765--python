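"""Core data model for optical mapping video analysis.

The central containers are :class:`VideoStack` — a time-ordered stack of
grayscale frames ``I(x, y, t)`` as acquired by a high-speed optical mapping
camera — and :class:`FlowSequence` — per-frame dense displacement fields
``u(x, y, t)`` measured with respect to a fixed reference frame.

Conventions
-----------
* Coordinates are 0-based with origin at the top-left; ``x`` is the column
  index and ``y`` the row index.  Arrays are indexed ``(t, y, x)``.
* Flow components are stored in the order ``(u_x, u_y)`` on the last axis.
* Displacements follow the fixed "ref-to-frame" convention: tissue content
  located at ``(x, y)`` in the reference frame appears at
  ``(x + u_x, y + u_y)`` in frame ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple, Union

import numpy as np

__all__ = [
    "VideoStack",
    "FlowSequence",
    "ROI",
    "PipelineConfig",
    "FLOW_CONVENTION",
    "to_unit_range",
    "quantize_8bit",
]

#: The single displacement convention used throughout the package.
FLOW_CONVENTION = "ref-to-frame"

_VALID_BIT_DEPTHS = (8, 12, 14, 16)


@dataclass
class VideoStack:
    """A grayscale video: frames indexed ``(t, y, x)`` plus acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Pixel intensities.  Integer-valued for camera data, floats in
        ``[0, 1]`` for ``bit_depth="unit"`` stacks.
    bit_depth : {8, 12, 14, 16} or "unit"
        Sensor bit depth; ``"unit"`` marks normalized floating-point data.
    frame_interval_ms : float
        Time between consecutive frames in milliseconds (e.g. 2.0 at 500 fps).
    mask : ndarray of bool, shape (H, W), optional
        Tissue mask (True = tissue).
    name : str
        Free-text identifier, carried through processing steps.
    """

    frames: np.ndarray
    bit_depth: Union[int, str] = "unit"
    frame_interval_ms: float = 1.0
    mask: Optional[np.ndarray] = None
    name: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (T, H, W) array, got shape {self.frames.shape}"
            )
        if min(self.frames.shape) < 1:
            raise ValueError("empty video: T, H and W must all be >= 1")
        if self.bit_depth == "unit":
            if not np.all(np.isfinite(self.frames)):
                raise ValueError("unit-range stack contains non-finite values")
        elif self.bit_depth in _VALID_BIT_DEPTHS:
            lo, hi = self.frames.min(), self.frames.max()
            if lo < 0 or hi > 2**self.bit_depth - 1:
                raise ValueError(
                    f"values [{lo}, {hi}] outside the {self.bit_depth}-bit range"
                )
        else:
            raise ValueError(f"unsupported bit depth: {self.bit_depth!r}")
        if self.frame_interval_ms <= 0:
            raise ValueError("frame_interval_ms must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.frame_shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != frame shape {self.frame_shape}"
                )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return self.frames.shape[1:3]

    def with_frames(self, frames: np.ndarray, bit_depth=None) -> "VideoStack":
        """Copy of this stack with new pixel data (metadata propagated)."""
        return replace(
            self,
            frames=frames,
            bit_depth=self.bit_depth if bit_depth is None else bit_depth,
        )


@dataclass
class FlowSequence:
    """Per-frame dense displacement fields relative to a reference frame.

    ``fields`` has shape ``(T, H, W, 2)`` with components ``(u_x, u_y)`` in
    pixel units; the field at ``reference_index`` is identically zero.
    """

    fields: np.ndarray
    reference_index: int = 0
    convention: str = FLOW_CONVENTION

    def __post_init__(self) -> None:
        self.fields = np.asarray(self.fields, dtype=float)
        if self.fields.ndim != 4 or self.fields.shape[-1] != 2:
            raise ValueError(
                f"fields must have shape (T, H, W, 2), got {self.fields.shape}"
            )
        if not np.all(np.isfinite(self.fields)):
            raise ValueError("flow fields contain non-finite values")
        if not 0 <= self.reference_index < self.fields.shape[0]:
            raise ValueError("reference_index out of range")
        if self.convention != FLOW_CONVENTION:
            raise ValueError(
                f"unknown flow convention {self.convention!r}; "
                f"expected {FLOW_CONVENTION!r}"
            )

    @property
    def n_frames(self) -> int:
        return self.fields.shape[0]


@dataclass
class ROI:
    """A square region of interest whose per-frame mean gives an optical trace.

    ``size`` is the box side length in pixels (6 px is a typical choice for
    whole-heart recordings); the box is clipped at image borders.
    """

    center_x: int
    center_y: int
    size: int = 6
    aggregation: str = "mean"

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("ROI size must be >= 1")
        if self.aggregation != "mean":
            raise ValueError("only 'mean' aggregation is supported")

    def bounds(self, height: int, width: int) -> Tuple[int, int, int, int]:
        """Box bounds ``(y0, y1, x0, x1)`` (half-open) clipped to the image."""
        x0 = int(round(self.center_x)) - self.size // 2
        y0 = int(round(self.center_y)) - self.size // 2
        x1, y1 = x0 + self.size, y0 + self.size
        x0, x1 = max(x0, 0), min(x1, width)
        y0, y1 = max(y0, 0), min(y1, height)
        if x0 >= x1 or y0 >= y1:
            raise ValueError("ROI lies entirely outside the image")
        return y0, y1, x0, x1


def _check_odd(value: int, label: str) -> None:
    if value < 1 or value % 2 == 0:
        raise ValueError(f"{label} must be an odd integer >= 1, got {value}")


@dataclass
class PipelineConfig:
    """Tunable parameters of the motion-compensation pipeline.

    Kernel entries are diameters (pixels for the spatial axes, frames for the
    temporal axis) and must be odd so that kernels are centered.
    """

    pre_smooth: Tuple[int, int, int] = (3, 3, 3)
    contrast_kernel: int = 7
    flow_smooth: Tuple[int, int, int] = (3, 3, 3)
    backend: str = "farneback"
    reference_index: int = 0
    norm_window_ms: float = 20.0
    epsilon_flat: float = 1e-6

    def __post_init__(self) -> None:
        for k, label in zip(self.pre_smooth, ("pre_smooth k_x", "pre_smooth k_y", "pre_smooth k_t")):
            _check_odd(k, label)
        for k, label in zip(self.flow_smooth, ("flow_smooth k_x", "flow_smooth k_y", "flow_smooth k_t")):
            _check_odd(k, label)
        _check_odd(self.contrast_kernel, "contrast_kernel")
        if self.reference_index < 0:
            raise ValueError("reference_index must be >= 0")
        if self.norm_window_ms <= 0:
            raise ValueError("norm_window_ms must be positive")
        if self.epsilon_flat <= 0:
            raise ValueError("epsilon_flat must be positive")


def to_unit_range(stack: VideoStack, epsilon_flat: float = 1e-6) -> VideoStack:
    """Rescale a video to ``[0, 1]`` using the global min/max of the whole stack.

    A single global affine map is used (rather than per-frame scaling) so that
    temporal signals are not distorted.  If the stack is flat (max - min below
    ``epsilon_flat``) an all-zero stack is returned.
    """
    frames = np.asarray(stack.frames, dtype=float)
    lo = frames.min()
    hi = frames.max()
    if hi - lo < epsilon_flat:
        unit = np.zeros_like(frames)
    else:
        unit = (frames - lo) / (hi - lo)
    out = stack.with_frames(unit, bit_depth="unit")
    return out


def quantize_8bit(stack: VideoStack) -> VideoStack:
    """Reduce a video to the 8-bit range ``[0, 255]``.

    Unit-range values ``m`` map to ``round_half_up(m * 255)`` clipped to
    ``[0, 255]``; integer stacks are first normalized to the unit range.
    Round-half-up (rather than banker's rounding) keeps the mapping
    reproducible across platforms.
    """
    if stack.bit_depth == "unit":
        unit = np.asarray(stack.frames, dtype=float)
    else:
        unit = to_unit_range(stack).frames
    scaled = np.floor(unit * 255.0 + 0.5)  # round half up
    clipped = np.clip(scaled, 0, 255).astype(np.uint8)
    return stack.with_frames(clipped, bit_depth=8)
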