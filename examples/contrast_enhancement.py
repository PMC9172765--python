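"""Why contrast enhancement makes tracking robust to fluorescence.

A voltage-sensitive dye modulates brightness as (1 + f*v(t)) * texture —
a violation of the brightness-constancy assumption every optical flow
method relies on.  Local min/max renormalization removes exactly this
multiplicative modulation wherever the excitation v is smooth at the
scale of the kernel: the enhanced frames become independent of the
fluorescence level, and only the thin wavefront (where v itself has
spatial structure) leaves a residual.
"""

import numpy as np

from cardiomotion import SyntheticScene, VideoStack, contrast_enhance, render_frame

scene = SyntheticScene(f=-0.10)

# 1) spatially uniform excitation: a 10% whole-tissue darkening
uniform = [
    render_frame(scene.texture, np.full((128, 128), v), scene.f, scene.mask)
    for v in (0.0, 0.5, 1.0)
]
stack = VideoStack(np.stack(uniform), bit_depth="unit")
enhanced = contrast_enhance(stack, k=7)
tissue = scene.mask
raw_change = np.abs(uniform[2][tissue] - uniform[0][tissue]).mean()
ce_change = np.abs(
    enhanced.frames[2][tissue] - enhanced.frames[0][tissue]
).mean()
print("uniform 10% fluorescence darkening across the tissue:")
print(f"  mean |brightness change|: raw {raw_change:.4f}, "
      f"contrast-enhanced {ce_change:.6f}")

# 2) a propagating wave: the suppression is confined to smooth-v regions
frames = np.stack([scene.rendered(t) for t in (10, 100)])
enhanced = contrast_enhance(VideoStack(frames, bit_depth="unit"), k=7)
v = scene.excitation(100)
gy, gx = np.gradient(v)
smooth_v = tissue & (v > 0.1) & (np.hypot(gx, gy) < 0.02)
raw_change = np.abs(frames[1][smooth_v] - frames[0][smooth_v]).mean()
ce_change = np.abs(
    enhanced.frames[1][smooth_v] - enhanced.frames[0][smooth_v]
).mean()
print("propagating wave, excited pixels away from the sharp front:")
print(f"  mean |brightness change|: raw {raw_change:.4f}, "
      f"contrast-enhanced {ce_change:.4f}")
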