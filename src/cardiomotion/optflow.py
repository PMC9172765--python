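"""Dense optical flow estimation through a named-backend registry.

Backends estimate the displacement field between a reference frame and a
moving frame under the package-wide "ref-to-frame" convention:
``reference(x, y) ≈ frame(x + u_x, y + u_y)``.

Registered backends:

``lucas_kanade``
    Coarse-to-fine iterative dense Lucas-Kanade
    (:func:`skimage.registration.optical_flow_ilk`), default parameters.
``tvl1``
    Coarse-to-fine TV-L1 variational flow
    (:func:`skimage.registration.optical_flow_tvl1`), default parameters.
``farneback``
    Native polynomial-expansion flow (:mod:`cardiomotion.farneback`).
``lucas_kanade_native``
    Native pyramidal Lucas-Kanade tracker (:mod:`cardiomotion.lk`), kept so
    the toolkit remains testable without any external vision dependency.

All backends consume 8-bit input (the common contract of classic flow
implementations); a backend may declare ``input_bit_depth=16`` to receive
16-bit frames instead, and a minimum image size below which inputs are
bilinearly upscaled (the resulting flow is downscaled and divided by the
scale factor).  Third-party algorithms (e.g. a variational Brox solver or a
hardware flow engine) can be attached at runtime with
:func:`register_backend`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional

import numpy as np
from scipy import ndimage
from skimage.registration import optical_flow_ilk, optical_flow_tvl1

from .farneback import farneback_flow
from .lk import pyramidal_lk_dense
from .model import FlowSequence, VideoStack, _check_odd
from .preprocess import smooth_spatiotemporal

__all__ = [
    "FlowBackendSpec",
    "register_backend",
    "get_backend",
    "available_backends",
    "estimate_flow_pair",
    "estimate_flow_video",
    "smooth_flow",
]


@dataclass
class FlowBackendSpec:
    """A named flow backend plus optional parameter overrides."""

    name: str
    params: Dict = field(default_factory=dict)


@dataclass
class _Backend:
    name: str
    func: Callable[..., np.ndarray]  # (ref, frame, **params) -> (H, W, 2)
    input_bit_depth: int = 8
    min_size: Optional[int] = None


_REGISTRY: Dict[str, _Backend] = {}


def register_backend(
    name: str,
    func: Callable[..., np.ndarray],
    input_bit_depth: int = 8,
    min_size: Optional[int] = None,
) -> None:
    """Register (or replace) a flow backend.

    ``func(reference, frame, **params)`` must return an ``(H, W, 2)`` float
    array with components ``(u_x, u_y)`` in pixels, following the
    ref-to-frame convention.
    """
    _REGISTRY[name] = _Backend(name, func, input_bit_depth, min_size)


def available_backends() -> list:
    """Names of all registered backends, sorted."""
    return sorted(_REGISTRY)


def get_backend(name: str) -> _Backend:
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown flow backend {name!r}; registered: {available_backends()}"
        )
    return _REGISTRY[name]


def _skimage_flow(solver):
    def run(reference, frame, **params):
        flow = solver(reference, frame, **params)  # (2, H, W), (row, col)
        return np.ascontiguousarray(np.moveaxis(flow[::-1], 0, -1), dtype=float)

    return run


register_backend("lucas_kanade", _skimage_flow(optical_flow_ilk))
register_backend("tvl1", _skimage_flow(optical_flow_tvl1))
register_backend("farneback", farneback_flow)
register_backend("lucas_kanade_native", pyramidal_lk_dense)


def _prepare_frame(frame: np.ndarray, bit_depth: int) -> np.ndarray:
    """Quantize a frame to the backend's input bit depth.

    Unit-range floats are scaled to the full integer range (values outside
    ``[0, 1]``, e.g. from additive noise, are clipped); integer frames with
    matching depth pass through untouched.
    """
    frame = np.asarray(frame)
    if bit_depth == 8 and frame.dtype == np.uint8:
        return frame
    if bit_depth == 16 and frame.dtype == np.uint16:
        return frame
    if np.issubdtype(frame.dtype, np.integer):
        frame = frame / float(frame.max() if frame.max() > 0 else 1)
    top = 2**bit_depth - 1
    scaled = np.floor(np.clip(frame, 0.0, 1.0) * top + 0.5)
    return scaled.astype(np.uint8 if bit_depth == 8 else np.uint16)


def estimate_flow_pair(
    reference: np.ndarray, frame: np.ndarray, backend: "FlowBackendSpec | str"
) -> np.ndarray:
    """Estimate the dense displacement field between two frames.

    Frames are quantized to the backend's input bit depth before estimation.
    Returns an ``(H, W, 2)`` array ``(u_x, u_y)`` in pixels such that content
    at ``(x, y)`` in ``reference`` appears at ``(x + u_x, y + u_y)`` in
    ``frame``.  Non-finite backend output (e.g. from textureless regions) is
    replaced by zero so that flow fields are always finite.
    """
    if isinstance(backend, str):
        backend = FlowBackendSpec(backend)
    spec = get_backend(backend.name)
    reference = np.asarray(reference)
    frame = np.asarray(frame)
    if reference.shape != frame.shape:
        raise ValueError(
            f"shape mismatch: reference {reference.shape} vs frame {frame.shape}"
        )
    ref_q = _prepare_frame(reference, spec.input_bit_depth)
    frm_q = _prepare_frame(frame, spec.input_bit_depth)

    scale = 1
    if spec.min_size is not None and min(ref_q.shape) < spec.min_size:
        scale = int(np.ceil(spec.min_size / min(ref_q.shape)))
        ref_q = ndimage.zoom(ref_q.astype(float), scale, order=1, mode="nearest")
        frm_q = ndimage.zoom(frm_q.astype(float), scale, order=1, mode="nearest")
        ref_q = _prepare_frame(ref_q / ref_q.max(), spec.input_bit_depth)
        frm_q = _prepare_frame(frm_q / frm_q.max(), spec.input_bit_depth)

    flow = np.asarray(spec.func(ref_q, frm_q, **backend.params), dtype=float)
    if flow.shape != ref_q.shape + (2,):
        raise ValueError(
            f"backend {spec.name!r} returned shape {flow.shape}, "
            f"expected {ref_q.shape + (2,)}"
        )
    if scale != 1:
        zoom = (frame.shape[0] / flow.shape[0], frame.shape[1] / flow.shape[1], 1)
        flow = ndimage.zoom(flow, zoom, order=1, mode="nearest", grid_mode=True)
        flow /= scale
    return np.nan_to_num(flow, nan=0.0, posinf=0.0, neginf=0.0)


def estimate_flow_video(
    stack: VideoStack, reference_index: int, backend: "FlowBackendSpec | str"
) -> FlowSequence:
    """Estimate flow from a reference frame to every frame of a video.

    Every frame is matched directly against the reference (no temporal
    chaining, so errors do not accumulate along the sequence); the field at
    ``reference_index`` is exactly zero.
    """
    if not 0 <= reference_index < stack.n_frames:
        raise IndexError(
            f"reference_index {reference_index} out of range for "
            f"{stack.n_frames} frames"
        )
    frames = stack.frames
    fields = np.zeros((stack.n_frames,) + stack.frame_shape + (2,))
    reference = frames[reference_index]
    for t in range(stack.n_frames):
        if t == reference_index:
            continue
        fields[t] = estimate_flow_pair(reference, frames[t], backend)
    return FlowSequence(fields=fields, reference_index=reference_index)


def smooth_flow(flow: FlowSequence, k_x: int = 3, k_y: int = 3, k_t: int = 3) -> FlowSequence:
    """Spatio-temporal box smoothing of a displacement field sequence.

    Each component is smoothed independently with the same box-mean operator
    used for video pre-smoothing; the reference-frame field is re-zeroed
    afterwards so the stabilized reference frame stays untouched.
    """
    smoothed = np.empty_like(flow.fields)
    for c in range(2):
        component = VideoStack(flow.fields[..., c], bit_depth="unit")
        smoothed[..., c] = smooth_spatiotemporal(component, k_x, k_y, k_t).frames
    smoothed[flow.reference_index] = 0.0
    return FlowSequence(fields=smoothed, reference_index=flow.reference_index)
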