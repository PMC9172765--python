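"""Motion compensation: warping raw frames into the co-moving reference frame.

Stabilization samples each deformed frame at ``reference position + u``,
with ``u`` defined ref-to-frame.  Under this "output looks up source"
convention, estimating flow and warping form a closed loop with no field
inversion: the warped frame shows every material point at the position it
occupies in the reference frame.

Warping is always applied to the ORIGINAL raw frames — never to the
contrast-enhanced frames, which exist only to feed the flow estimator.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .model import FlowSequence, VideoStack

__all__ = ["warp_frame", "compensate_video"]

_INTERP_ORDER = {"bilinear": 1, "nearest": 0}


def warp_frame(
    frame: np.ndarray, field: np.ndarray, interpolation: str = "bilinear"
) -> np.ndarray:
    """Warp one frame by a displacement field.

    ``output(x, y) = frame(x + u_x(x, y), y + u_y(x, y))``, sampled with the
    chosen interpolation; positions outside the image use clamp-to-edge
    values.  Bilinear interpolation is the default because sub-pixel shifts
    matter: nearest-neighbor resampling reintroduces up to half a pixel of
    apparent motion.
    """
    frame = np.asarray(frame, dtype=float)
    field = np.asarray(field, dtype=float)
    if field.shape != frame.shape + (2,):
        raise ValueError(
            f"field shape {field.shape} does not match frame {frame.shape}"
        )
    if interpolation not in _INTERP_ORDER:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    h, w = frame.shape
    yy, xx = np.mgrid[0:h, 0:w]
    coords = np.stack([yy + field[..., 1], xx + field[..., 0]])
    return ndimage.map_coordinates(
        frame, coords, order=_INTERP_ORDER[interpolation], mode="nearest"
    )


def compensate_video(
    stack: VideoStack, flow: FlowSequence, interpolation: str = "bilinear"
) -> VideoStack:
    """Warp every raw frame by its displacement field.

    Frame ``t`` of the output is ``warp_frame(raw frame t, flow field t)``;
    the reference frame is returned unchanged.  The output is float-valued
    (bit depth "unit" metadata), with the frame interval propagated.
    """
    if flow.n_frames != stack.n_frames:
        raise ValueError(
            f"flow has {flow.n_frames} fields but video has "
            f"{stack.n_frames} frames"
        )
    frames = np.asarray(stack.frames, dtype=float)
    out = np.empty_like(frames)
    for t in range(stack.n_frames):
        if t == flow.reference_index:
            out[t] = frames[t]
        else:
            out[t] = warp_frame(frames[t], flow.fields[t], interpolation)
    return stack.with_frames(out, bit_depth="unit")
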