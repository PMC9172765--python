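# Methods

This note documents the models, algorithms and parameter choices behind
`cardiomotion`, and what the synthetic benchmark does and does not show.

## Processing pipeline

A raw optical mapping video `I(x, y, t)` is processed in a fixed order:
spatio-temporal smoothing → local contrast enhancement → dense optical
flow against a reference frame → spatio-temporal smoothing of the flow →
warping of the **original raw** frames.  Only the flow estimator sees the
pre-processed frames; the stabilized video is resampled from untouched raw
data, so pre-processing costs no intensity precision.

**Smoothing** is an unweighted box mean over a `k_x × k_y × k_t`
neighborhood (defaults 3 × 3 × 3) with replicate padding.  A box rather
than a Gaussian kernel is a declared convention: it is the simplest
operator parameterized purely by a diameter, and it makes oracle tests
exact.  Replicate padding avoids dark rims at borders that a flow
estimator would latch onto as features.

**Contrast enhancement** renormalizes each pixel by the min/max over a
disc of diameter `k` (Euclidean radius `(k−1)/2`, clipped at borders):
`I_c = (I − min S)/(max S − min S)`, with a flat-guard output of 0 where
the local range is below `epsilon_flat = 1e-6` (flat regions carry no
trackable contrast; zero marks them inert).  The operator is invariant
under any positive affine rescaling of the frame, which is why a
multiplicative fluorescence modulation `(1 + f·v)` disappears wherever
`v` is smooth at the kernel scale.  The kernel should match the texture
grain: ≈ 9–11 px for 320 × 440 recordings, ≈ 7 px at 256 × 256, 3–5 px at
128 × 128; too small amplifies noise, too large flattens local contrast.
The package default is 7 px.

**Flow convention.**  All displacements are "ref-to-frame": content at
`(x, y)` in the reference frame appears at `(x + u_x, y + u_y)` in frame
`t`; components are stored `(u_x, u_y)` with 0-based, top-left-origin
coordinates.  Stabilization samples frame `t` at `x + u(x)` ("output looks
up source"), so estimate → warp is a closed loop needing no field
inversion.  Each frame is matched directly against the reference — never
chained through intermediate frames — so tracking errors do not accumulate
along the sequence.  Bilinear interpolation with clamp-to-edge boundaries
is the default; nearest-neighbor resampling would reintroduce up to half a
pixel of apparent motion.

## Flow backends

* `lucas_kanade` — scikit-image's coarse-to-fine iterative dense
  Lucas–Kanade (`optical_flow_ilk`), library defaults.
* `tvl1` — scikit-image's coarse-to-fine TV-L1 variational flow
  (`optical_flow_tvl1`, the Zach/Pock/Bischof formulation), library
  defaults.
* `farneback` — native implementation of flow by polynomial expansion:
  each image is locally fitted with a quadratic `xᵀAx + bᵀx + c` over a
  Gaussian-weighted 5 × 5 neighborhood (σ = 1.1); under a translation `d`
  the coefficients satisfy `b₂ = b₁ − 2A d`, and the per-pixel normal
  equations are averaged over a 13 × 13 box window and solved inside an
  iterative (3 passes/level) coarse-to-fine pyramid (up to 5 levels,
  factor 2, coarsest level ≥ 16 px).  The affine-in-space local model
  tolerates smooth contractile deformation and noise better than
  constant-flow windows.
* `lucas_kanade_native` — a self-contained pyramidal dense Lucas–Kanade
  tracker (window 15, 5 iterations/level, coarsest level ≥ 32 px) kept so
  the toolkit works and is testable without any external vision library.
  Design notes: the per-pixel 2 × 2 system is re-solved for the *total*
  flow each pass, linearized around the current estimate using gradients
  of the *warped moving frame*.  Both choices are deliberate: accumulating
  raw increments, or linearizing with static reference-frame gradients,
  is unstable on deforming fluorescence imagery (errors in misconverged
  regions feed back through the warp and grow with iteration count).
  Pixels whose window-averaged structure tensor has smaller eigenvalue
  below 1e-4 (on unit-scaled intensities) keep the flow inherited from the
  coarser level instead of an ill-conditioned local solution.

All backends consume 8-bit input; unit-range frames are quantized
(round-half-up, clipped) immediately before estimation, mirroring the
integer-input contract of classic flow implementations.  A backend may
declare a 16-bit preference or a minimum image size (inputs below it are
bilinearly upscaled and the flow rescaled back).  Third-party algorithms —
e.g. a variational Brox solver or a vendor's hardware flow engine, neither
of which has an implementation in the scientific Python stack — can be
attached at runtime with `register_backend`; benchmarks iterate over
whatever is registered.

## Synthetic benchmark

The generator renders fluorescing, contracting tissue as
`Ĩ(x,y,t) = (1 + f·v(x,y,t)) · I_texture(x,y)` and deforms it with a
smooth displacement field `d(x,y,t)`:

* **Texture** — Gaussian-smoothed white noise (correlation length 3 px by
  default), rescaled so tissue pixels span [0.2, 1.0] inside an elliptical
  mask (4 px inset); background is flat 0.05.
* **Wave** `v ∈ [0, 1]` — an action-potential-like pulse
  `N(1 − e^{−s/τ_r})e^{−s/τ_d}` (peak normalized to 1, `τ_r = 3`,
  `τ_d = 25` frames) evaluated at `s = t − arrival(x,y)` and repeated with
  period 150 frames; the default is a planar wave at 0.5 px/frame, a
  spiral mode is available.
* **Deformation** — "contractile": the masked excitation is low-pass
  filtered with time constant `τ_em = 10` frames
  (excitation–contraction delay), Gaussian-smoothed with `σ_d = 12` px,
  and the displacement is the negative gradient of that field, peak
  magnitude normalized to the amplitude `A = 5` px.  Tissue is thus pulled
  toward currently excited regions, and the motion is temporally coupled
  to the wave — the same confound present in real recordings.  A "bulk"
  mode (seeded smooth random profile oscillating at the wave period)
  provides motion uncorrelated with the wave.
* **Evaluation pairs** — two times `t₁ ≠ t₂` drawn uniformly over the
  150-frame scene; `A = Ĩ(t₁)`, ground truth `u = d(t₂) − d(t₁)`, and `B`
  is `Ĩ(t₂)` deformed so that `B(x + u(x)) = Ĩ(x, t₂)`.  The required
  inverse mapping is found by fixed-point iteration (`u_inv ← −u` at the
  displaced point), which contracts because `|∇u| < 1`; with the default
  amplitude the residual passes 1e-3 px within ~40 iterations, and the
  constructor raises if the residual stays above 0.05 px rather than
  return an inconsistent pair.  Generator self-consistency (resampling `B`
  at `x + u` reproduces `Ĩ(t₂)` to ≤ 1e-2 mean absolute unit intensity) is
  asserted in the test suite.  Gaussian noise of standard deviation σ is
  added independently to both images on the unit intensity scale, *not*
  clipped (quantization clamps later); the returned `u` is exact and
  noise-free.  Everything is deterministic under the master seed.

`f` (signed fractional change in fluorescence, negative for
Di-4-ANEPPS-like darkening) and σ are the two controlled dials; with
`f = 0` and σ = 0 brightness constancy holds exactly.

**Benchmark protocol.**  For each (backend, f, σ, contrast-enhancement)
cell, pairs are optionally contrast-enhanced, quantized to 8 bits,
tracked, and scored by mean EPE over all pixels (a tissue mask is
supported but off by default) — always on unsmoothed fields.  The default
Monte-Carlo size is 200 pairs per cell, two orders of magnitude below an
exhaustive sweep but enough that cell standard errors (reported alongside
every mean) are a few hundredths of a pixel; the acceptance script uses
this size.

## What the benchmark does and does not show

The synthetic scene reproduces the *mechanisms* that make optical mapping
hard to track — brightness modulation coupled to motion, sharp moving
wavefront edges, sensor quantization, additive noise — and the qualitative
results expected from them: EPE grows monotonically with both f and σ for
every backend, contrast enhancement removes the fluorescence sensitivity
(all backends stay sub-pixel through |ΔF/F| = 20 %), and the Farnebäck
backend is the most noise-robust, remaining sub-pixel through σ = 0.12 at
|ΔF/F| = 3 %.

It does **not** reproduce the absolute fluorescence-sensitivity thresholds
reported for GPU flow implementations on simulation-driven imagery of real
hearts, for two reasons.  First, the synthetic texture is far more
trackable than an experimental heart image: Gaussian noise at 3 px
correlation has strong, dense gradients everywhere, so a 10–15 %
brightness modulation displaces the apparent match by only a fraction of a
pixel, whereas real tissue texture has large low-contrast regions where
the same modulation masquerades as multi-pixel motion.  Second, flow
implementations differ sharply in their failure behavior even within one
algorithm family; the solvers used here (scikit-image's iLK and TV-L1, and
the native Farnebäck) degrade gracefully where some GPU implementations
fail outright.  Under the default scene the local and variational
backends reach ≈ 0.45–0.5 px mean EPE at |ΔF/F| = 10–15 % without contrast
enhancement — clearly degraded relative to their ≈ 0.2–0.4 px baselines,
but not past the 1 px mark.  Conclusions about *absolute* tolerable signal
strengths for a given camera/dye combination should therefore come from
data with realistic texture statistics, not from this generator.

Other simplifications: no photobleaching, no shot noise or camera PSF, no
illumination inhomogeneity (so the residual illumination-related artifacts
seen in stabilized experimental traces have no counterpart here), 2-D
in-plane deformation only, and physiologically schematic wave and
contraction models.

## Numerical conventions worth knowing

* Unit normalization uses the global video min/max (per-frame scaling
  would distort temporal signals); flat videos map to zero.
* Quantization rounds half up — reproducible across platforms.
* The pixel-wise normalization window is centered (trailing windows lag
  the upstroke) and truncated at the video ends; its length is
  `max(2, round(window_ms / frame_interval_ms))` frames.
* ROI traces are plain box means, clipped at image borders.
* Flow archives store the convention tag and refuse to load fields written
  under any other convention.
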