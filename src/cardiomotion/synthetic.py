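"""Synthetic optical mapping videos with exact ground-truth displacements.

The generator renders a fluorescing, contracting tissue as the product of a
static texture and a propagating excitation wave,

    I~(x, y, t) = (1 + f * v(x, y, t)) * I_texture(x, y),

where ``v ∈ [0, 1]`` is the local action-potential amplitude and ``f`` is
the signed fractional change in fluorescence ΔF/F (negative for dyes such
as Di-4-ANEPPS behind a long-pass filter).  The rendered frames are then
deformed by a smooth displacement field ``d(x, y, t)`` that mimics the
tissue contracting in response to the wave, and independent Gaussian noise
may be added.  Because the deformation is analytic, the displacement
between any two time points, ``u = d(t2) - d(t1)``, is known exactly at
every pixel — the ground truth against which flow backends are scored.

This is a parametric stand-in for an electromechanical tissue simulation:
it reproduces the two properties that matter for evaluating motion tracking
(brightness change coupled to motion, smooth contractile deformation), not
cardiac electromechanics itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .model import FlowSequence, VideoStack

__all__ = [
    "WaveModel",
    "DeformationModel",
    "SyntheticScene",
    "ellipse_mask",
    "make_texture",
    "action_potential_shape",
    "wave_field",
    "deformation_field",
    "render_frame",
    "add_noise",
    "make_pair",
    "make_dataset",
    "make_video",
]


@dataclass
class WaveModel:
    """Parametric excitation wave ``v(x, y, t) ∈ [0, 1]``.

    The local time course is an action-potential-like pulse
    ``A(s) = N (1 - exp(-s/tau_rise)) exp(-s/tau_decay)`` (peak normalized
    to 1) evaluated at ``s = t - arrival(x, y)`` and repeated with period
    ``period``.  ``kind="planar"`` propagates a plane wave with speed
    ``speed`` px/frame along ``direction``; ``kind="spiral"`` rotates an
    Archimedean spiral with angular frequency ``omega`` rad/frame and pitch
    ``pitch`` px/rad around ``origin``.
    """

    kind: str = "planar"
    speed: float = 0.5
    direction: float = 0.0
    omega: float = 0.05
    pitch: float = 8.0
    period: float = 150.0
    tau_rise: float = 3.0
    tau_decay: float = 25.0
    origin: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("planar", "spiral"):
            raise ValueError(f"unknown wave kind {self.kind!r}")
        for value, label in (
            (self.period, "period"),
            (self.tau_rise, "tau_rise"),
            (self.tau_decay, "tau_decay"),
        ):
            if value <= 0:
                raise ValueError(f"{label} must be positive")


@dataclass
class DeformationModel:
    """Smooth tissue deformation ``d(x, y, t)`` with ``max |d| <= amplitude``.

    ``kind="contractile"`` couples the deformation to the wave: the
    excitation is low-pass filtered with time constant ``tau_em`` frames
    (excitation-contraction delay) and the displacement is the negative
    gradient of its Gaussian-smoothed field (width ``sigma_d`` px) —
    tissue is pulled toward currently excited regions.  ``kind="bulk"``
    applies a static smooth random vector profile (seeded) oscillating
    sinusoidally with the wave period, emulating rigid-ish bulk motion.
    """

    kind: str = "contractile"
    amplitude: float = 5.0
    tau_em: float = 10.0
    sigma_d: float = 12.0
    profile_seed: int = 7

    def __post_init__(self) -> None:
        if self.kind not in ("contractile", "bulk"):
            raise ValueError(f"unknown deformation kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.tau_em <= 0 or self.sigma_d <= 0:
            raise ValueError("tau_em and sigma_d must be positive")


def ellipse_mask(height: int, width: int, margin: int = 4) -> np.ndarray:
    """Elliptical tissue mask inset ``margin`` pixels from the image border."""
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    ry, rx = height / 2.0 - margin, width / 2.0 - margin
    yy, xx = np.mgrid[0:height, 0:width]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def make_texture(
    height: int,
    width: int,
    correlation_length: float = 3.0,
    seed: int = 0,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Seeded random tissue texture with a controlled correlation length.

    White noise is smoothed with a Gaussian of width ``correlation_length``
    and affinely rescaled so tissue pixels span ``[0.2, 1.0]``; pixels
    outside the mask are set to the flat background level 0.05.
    """
    if correlation_length < 1:
        raise ValueError("correlation_length must be >= 1")
    if mask is None:
        mask = ellipse_mask(height, width)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((height, width))
    smooth = ndimage.gaussian_filter(noise, sigma=correlation_length, mode="wrap")
    tissue = smooth[mask]
    lo, hi = tissue.min(), tissue.max()
    texture = np.full((height, width), 0.05)
    texture[mask] = 0.2 + 0.8 * (smooth[mask] - lo) / (hi - lo)
    return texture


def action_potential_shape(
    s: np.ndarray, tau_rise: float, tau_decay: float
) -> np.ndarray:
    """Pulse ``N (1 - exp(-s/tau_rise)) exp(-s/tau_decay)``, peak 1 at s*."""
    s = np.asarray(s, dtype=float)
    s_peak = tau_rise * np.log1p(tau_decay / tau_rise)
    peak = (1.0 - np.exp(-s_peak / tau_rise)) * np.exp(-s_peak / tau_decay)
    out = (1.0 - np.exp(-s / tau_rise)) * np.exp(-s / tau_decay) / peak
    return np.where(s >= 0, out, 0.0)


def _arrival_time(model: WaveModel, shape: Tuple[int, int]) -> np.ndarray:
    height, width = shape
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    cx, cy = model.origin
    if model.kind == "planar":
        if model.speed <= 0:
            raise ValueError("planar wave speed must be positive")
        return (
            (xx - cx) * np.cos(model.direction) + (yy - cy) * np.sin(model.direction)
        ) / model.speed
    radius = np.hypot(yy - cy, xx - cx)
    if model.omega <= 0:
        raise ValueError("spiral angular frequency must be positive")
    chi = np.arctan2(yy - cy, xx - cx) - radius / model.pitch
    return chi / model.omega


def wave_field(model: WaveModel, shape: Tuple[int, int], t: float) -> np.ndarray:
    """Excitation ``v(x, y, t) ∈ [0, 1]`` on a grid of the given shape.

    Before the wave first arrives at a pixel the excitation is zero; after
    arrival the pulse repeats with the wave period.
    """
    s = t - _arrival_time(model, shape)
    phase = np.mod(s, model.period)
    v = action_potential_shape(phase, model.tau_rise, model.tau_decay)
    return np.where(s >= 0, v, 0.0)


def render_frame(
    texture: np.ndarray,
    v_field: np.ndarray,
    f: float,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Apply the fluorescence model ``(1 + f v) * texture`` on tissue pixels."""
    if np.max(np.abs(f * v_field)) >= 1.0:
        raise ValueError("|f * v| must stay below 1")
    out = np.array(texture, dtype=float)
    if mask is None:
        out = (1.0 + f * v_field) * out
    else:
        out[mask] = (1.0 + f * v_field[mask]) * out[mask]
    return out


def add_noise(frames: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Add seeded i.i.d. Gaussian noise on the unit-intensity scale.

    Values are deliberately NOT clipped; quantization clamps later if 8-bit
    conversion is requested.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    frames = np.asarray(frames, dtype=float)
    if sigma == 0:
        return frames.copy()
    rng = np.random.default_rng(seed)
    return frames + rng.normal(0.0, sigma, size=frames.shape)


@dataclass(eq=False)
class SyntheticScene:
    """Full configuration of a synthetic optical mapping recording.

    The default scene — 128 x 128 pixels, a planar wave at 0.5 px/frame with
    a 150-frame period, contractile deformation of 5 px amplitude and a
    3 px-correlation-length texture — mirrors the low-resolution format
    commonly used in whole-heart optical mapping.  ``f`` and ``sigma`` are
    the two controlled dials the benchmarks sweep; the geometry underneath
    is cached and independent of them.
    """

    width: int = 128
    height: int = 128
    texture_correlation: float = 3.0
    wave: WaveModel = field(default_factory=WaveModel)
    deformation: DeformationModel = field(default_factory=DeformationModel)
    f: float = -0.05
    sigma: float = 0.0
    seed: int = 42
    duration: int = 150
    frame_interval_ms: float = 2.0

    def __post_init__(self) -> None:
        if abs(self.f) > 0.5:
            raise ValueError("|f| must be <= 0.5")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.duration < 2:
            raise ValueError("duration must be >= 2 frames")

    # -- cached geometry (independent of f and sigma) --------------------

    @cached_property
    def mask(self) -> np.ndarray:
        return ellipse_mask(self.height, self.width)

    @cached_property
    def texture(self) -> np.ndarray:
        return make_texture(
            self.height, self.width, self.texture_correlation, self.seed, self.mask
        )

    @cached_property
    def _excitation_series(self) -> np.ndarray:
        """v(x, y, t) for t = 0 .. duration-1, float32 (T, H, W)."""
        out = np.empty((self.duration, self.height, self.width), dtype=np.float32)
        for t in range(self.duration):
            out[t] = wave_field(self.wave, (self.height, self.width), float(t))
        return out

    @cached_property
    def _deformation_series(self) -> np.ndarray:
        """d(x, y, t) for t = 0 .. duration-1, float32 (T, H, W, 2)."""
        model = self.deformation
        shape = (self.height, self.width)
        out = np.empty((self.duration,) + shape + (2,), dtype=np.float32)
        if model.kind == "bulk":
            rng = np.random.default_rng(model.profile_seed)
            g = ndimage.gaussian_filter(
                rng.standard_normal((2,) + shape), sigma=(0, model.sigma_d, model.sigma_d)
            )
            g /= np.hypot(g[0], g[1]).max()
            for t in range(self.duration):
                s_t = np.sin(2.0 * np.pi * t / self.wave.period)
                out[t, ..., 0] = model.amplitude * s_t * g[1]
                out[t, ..., 1] = model.amplitude * s_t * g[0]
            return out
        # contractile: low-pass the masked excitation, then pull tissue
        # toward excited regions along the smoothed gradient
        masked_v = self._excitation_series * self.mask
        state = np.zeros(shape, dtype=float)
        raw = np.empty_like(out)
        peak = 0.0
        for t in range(self.duration):
            state = state + (masked_v[t] - state) / model.tau_em
            phi = ndimage.gaussian_filter(state, sigma=model.sigma_d, mode="nearest")
            gy, gx = np.gradient(phi)
            raw[t, ..., 0] = -gx
            raw[t, ..., 1] = -gy
            peak = max(peak, float(np.hypot(gx, gy).max()))
        if peak > 0:
            raw *= model.amplitude / peak
        return raw

    # -- per-frame evaluations -------------------------------------------

    def excitation(self, t: int) -> np.ndarray:
        return np.asarray(self._excitation_series[self._index(t)], dtype=float)

    def displacement(self, t: int) -> np.ndarray:
        """Ground-truth deformation d(x, y, t) relative to the rest state."""
        return np.asarray(self._deformation_series[self._index(t)], dtype=float)

    def rendered(self, t: int) -> np.ndarray:
        """Undeformed, noise-free frame I~(x, y, t)."""
        return render_frame(self.texture, self.excitation(t), self.f, self.mask)

    def _index(self, t: int) -> int:
        t = int(t)
        if not 0 <= t < self.duration:
            raise IndexError(f"time {t} outside scene duration {self.duration}")
        return t


def deformation_field(scene: SyntheticScene, t: int) -> np.ndarray:
    """Deformation ``d(x, y, t)`` of the scene at integer frame ``t``."""
    return scene.displacement(t)


def _deform_image(
    image: np.ndarray,
    u: np.ndarray,
    max_iter: int = 40,
    tol: float = 1e-3,
) -> np.ndarray:
    """Deform ``image`` so that output(x + u(x)) == image(x).

    The required inverse mapping is found by fixed-point iteration
    ``u_inv <- -u`` evaluated at the displaced point (a contraction whenever
    the displacement gradient stays below 1); iterations stop early once the
    residual falls below ``tol`` pixels.  Deformations too steep to invert
    raise instead of returning garbage.
    """
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    inv_x = -u[..., 0]
    inv_y = -u[..., 1]
    for _ in range(max_iter):
        coords = np.stack([yy + inv_y, xx + inv_x])
        sampled_x = ndimage.map_coordinates(u[..., 0], coords, order=1, mode="nearest")
        sampled_y = ndimage.map_coordinates(u[..., 1], coords, order=1, mode="nearest")
        delta = max(
            np.abs(inv_x + sampled_x).max(), np.abs(inv_y + sampled_y).max()
        )
        inv_x, inv_y = -sampled_x, -sampled_y
        if delta < tol:
            break
    if delta > 0.05:
        raise RuntimeError(
            f"displacement inversion did not converge (residual {delta:.3g} px); "
            "deformation amplitude or gradient too large"
        )
    coords = np.stack([yy + inv_y, xx + inv_x])
    return ndimage.map_coordinates(image, coords, order=1, mode="nearest")


def make_pair(
    scene: SyntheticScene,
    t1: int,
    t2: int,
    noise_seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One evaluation pair ``(A, B, u)`` with exact ground truth.

    ``A`` is the rendered frame at ``t1``; ``u = d(t2) - d(t1)`` is the
    relative displacement; ``B`` is the rendered frame at ``t2`` deformed by
    ``u`` (so that ``B(x + u(x)) == I~(x, t2)``).  Noise of the scene's
    ``sigma`` is then added independently to A and B; the returned ``u`` is
    noise-free and exact.
    """
    if t1 == t2:
        raise ValueError("t1 and t2 must differ")
    image_a = scene.rendered(t1)
    image_b0 = scene.rendered(t2)
    u = scene.displacement(t2) - scene.displacement(t1)
    image_b = _deform_image(image_b0, u)
    image_a = add_noise(image_a, scene.sigma, noise_seed)
    image_b = add_noise(image_b, scene.sigma, noise_seed + 1)
    return image_a, image_b, u


def make_dataset(
    scene: SyntheticScene, n_pairs: int, seed: int = 1
) -> List[Tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """A reproducible dataset of evaluation pairs.

    Time points ``(t1, t2)`` are drawn uniformly at random over the scene
    duration; per-pair noise seeds are derived as ``seed + index`` so the
    dataset is fully determined by the master seed.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_pairs):
        t1 = int(rng.integers(scene.duration))
        t2 = int(rng.integers(scene.duration))
        while t2 == t1:
            t2 = int(rng.integers(scene.duration))
        pairs.append(make_pair(scene, t1, t2, noise_seed=2 * (seed + i)))
    return pairs


def make_video(
    scene: SyntheticScene, n_frames: int
) -> Tuple[VideoStack, FlowSequence]:
    """Render a T-frame video plus its ground-truth flow (reference frame 0).

    Frame ``t`` is the rendered frame at ``t`` deformed by the relative
    displacement ``u_t = d(t) - d(0)``, with noise added; the returned
    flow holds the exact ``u_t`` (zero at the reference).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if n_frames > scene.duration:
        raise ValueError(
            f"n_frames {n_frames} exceeds scene duration {scene.duration}"
        )
    frames = np.empty((n_frames, scene.height, scene.width))
    fields = np.zeros((n_frames, scene.height, scene.width, 2))
    d0 = scene.displacement(0)
    for t in range(n_frames):
        rendered = scene.rendered(t)
        if t == 0:
            frames[t] = rendered
        else:
            fields[t] = scene.displacement(t) - d0
            frames[t] = _deform_image(rendered, fields[t])
    frames = add_noise(frames, scene.sigma, scene.seed)
    stack = VideoStack(
        frames=frames,
        bit_depth="unit",
        frame_interval_ms=scene.frame_interval_ms,
        mask=scene.mask,
        name="synthetic",
    )
    return stack, FlowSequence(fields=fields, reference_index=0)
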