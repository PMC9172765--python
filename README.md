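# cardiomotion

Numerical motion tracking and motion-artifact compensation for optical
mapping videos of contracting cardiac tissue.

## The problem

Voltage- and calcium-sensitive optical mapping resolves electrical wave
phenomena (action potentials, calcium transients) on the heart surface at
high spatial and temporal resolution — but the measurement is exquisitely
sensitive to motion.  When the tissue contracts, each camera pixel sees
different material points over time, and the resulting *motion artifacts*
can completely mask the physiological signal.  The classic workaround is to
paralyze the tissue pharmacologically; the numerical alternative is to
track the tissue densely with optical flow and warp every frame into a
co-moving reference frame, so each pixel follows one material point.

Tracking fluorescing tissue is harder than ordinary motion tracking because
the fluorescence signal *deliberately* violates brightness constancy: a
voltage-sensitive dye darkens the tissue by a fraction ΔF/F at full
excitation, and flow algorithms can mistake that darkening for motion and
inadvertently track the action potential wave instead of the tissue.

`cardiomotion` implements the full processing chain and a synthetic
benchmark that quantifies exactly this failure mode:

1. **Pre-processing** — spatio-temporal box smoothing and local contrast
   enhancement, `I_c = (I − min S) / (max S − min S)` over a small circular
   neighborhood `S`, which amplifies tissue texture and suppresses the
   fluorescence modulation;
2. **Dense optical flow** `u(x, y, t)` of the contrast-enhanced video
   against a reference frame, through a backend registry
   (`lucas_kanade` — coarse-to-fine iterative dense Lucas–Kanade,
   `tvl1` — TV-L1 variational flow, both via scikit-image;
   `farneback` — a native polynomial-expansion implementation;
   `lucas_kanade_native` — a native pyramidal tracker);
3. **Post-processing** — spatio-temporal smoothing of the flow and warping
   of the *original raw* frames to produce the stabilized video;
4. **Analysis** — pixel-wise sliding-window normalized optical maps, ROI
   traces, and the mean end-point error (EPE)
   `⟨‖û − u‖₂⟩` against ground truth;
5. **Synthetic benchmark** — `Ĩ(x,y,t) = (1 + f·v(x,y,t))·I_texture(x,y)`
   rendered with a parametric action-potential wave `v`, deformed by a
   smooth contractile displacement field `d(x,y,t)` with exact analytic
   ground truth `u = d(t₂) − d(t₁)`, plus additive Gaussian noise σ.

## Worked example

`examples/motion_compensation.py` generates a 128×128 synthetic recording
(planar wave, contractile deformation up to 5 px, 5 % fluorescence
darkening), runs the full pipeline with the Farnebäck backend and compares
against the generator's exact ground truth:

```
video: 80 frames, (128, 128), 2.0 ms/frame
mean tissue displacement: 0.55 px
mean end-point error of estimated flow: 0.205 px
temporal std in quiet tissue: raw 0.0065 -> stabilized 0.0012  (5.4x reduction)
```

The estimated flow tracks the true deformation to a fraction of a pixel,
and in tissue the wave has not reached (where any intensity fluctuation is
pure motion artifact) stabilization collapses the temporal fluctuation
5-fold.  `examples/contrast_enhancement.py` shows the mechanism that makes
this safe with strong fluorescence:

```
uniform 10% fluorescence darkening across the tissue:
  mean |brightness change|: raw 0.0634, contrast-enhanced 0.000117
```

A spatially smooth 10 % signal — which a flow algorithm would otherwise
misread as motion — is suppressed by three orders of magnitude.
`examples/benchmark_sweep.py` runs a small fluorescence sweep over all
backends and prints an EPE table; `examples/roi_traces.py` extracts
6×6-pixel ROI traces before and after stabilization.

A thin CLI mirrors the library: `cardiomotion synth | compensate | trace |
bench` (see `cardiomotion --help`).

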