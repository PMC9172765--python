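"""Stabilize a contracting synthetic recording and check it against truth.

Generates a 128 x 128 synthetic optical mapping video (planar action
potential wave, contractile deformation up to 5 px, 5% fluorescence
darkening), runs the full pipeline — smoothing, contrast enhancement,
Farnebäck flow, flow smoothing, warping — and reports how close the
estimated flow comes to the generator's exact ground truth.
"""

import numpy as np

from cardiomotion import (
    PipelineConfig,
    SyntheticScene,
    compute_epe,
    make_video,
    run_pipeline,
)

scene = SyntheticScene(f=-0.05, sigma=0.0)
video, truth = make_video(scene, 80)
print(f"video: {video.n_frames} frames, {video.frame_shape}, "
      f"{video.frame_interval_ms} ms/frame")

config = PipelineConfig(backend="farneback", contrast_kernel=7)
stabilized, flow = run_pipeline(video, config)

epe = np.mean([
    compute_epe(flow.fields[t], truth.fields[t]) for t in range(1, video.n_frames)
])
motion = np.hypot(truth.fields[..., 0], truth.fields[..., 1]).mean()
print(f"mean tissue displacement: {motion:.2f} px")
print(f"mean end-point error of estimated flow: {epe:.3f} px")

# pixels the wave never reaches move only because of contraction; after
# stabilization their temporal fluctuation should collapse
quiet = scene.mask & (scene._excitation_series[:80].max(axis=0) < 0.01)
std_raw = video.frames[:, quiet].std(axis=0).mean()
std_stab = stabilized.frames[:, quiet].std(axis=0).mean()
print(f"temporal std in quiet tissue: raw {std_raw:.4f} -> "
      f"stabilized {std_stab:.4f}  ({std_raw / std_stab:.1f}x reduction)")
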