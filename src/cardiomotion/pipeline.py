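"""End-to-end motion compensation: raw video in, stabilized video out.

The processing order is fixed and matters:

1. spatio-temporal smoothing of the raw video (noise suppression);
2. local contrast enhancement (restores brightness constancy);
3. dense optical flow of the contrast-enhanced video against a reference
   frame;
4. spatio-temporal smoothing of the displacement fields;
5. warping of the ORIGINAL raw frames by the smoothed fields.

Only the flow estimator ever sees the pre-processed frames; the stabilized
output is resampled from the untouched raw data, so no intensity precision
is lost to the pre-processing.
"""

from __future__ import annotations

from typing import Optional, Tuple

from .compensate import compensate_video
from .model import FlowSequence, PipelineConfig, VideoStack
from .optflow import FlowBackendSpec, estimate_flow_video, smooth_flow
from .preprocess import contrast_enhance, smooth_spatiotemporal

__all__ = ["run_pipeline"]


def run_pipeline(
    stack: VideoStack,
    config: Optional[PipelineConfig] = None,
    backend_params: Optional[dict] = None,
) -> Tuple[VideoStack, FlowSequence]:
    """Motion-compensate a video; returns (stabilized video, smoothed flow)."""
    if config is None:
        config = PipelineConfig()
    k_x, k_y, k_t = config.pre_smooth
    smoothed = smooth_spatiotemporal(stack, k_x, k_y, k_t)
    enhanced = contrast_enhance(smoothed, config.contrast_kernel, config.epsilon_flat)
    backend = FlowBackendSpec(config.backend, backend_params or {})
    flow = estimate_flow_video(enhanced, config.reference_index, backend)
    fx, fy, ft = config.flow_smooth
    flow = smooth_flow(flow, fx, fy, ft)
    stabilized = compensate_video(stack, flow)
    return stabilized, flow
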