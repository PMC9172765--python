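"""Accuracy and speed benchmarks for flow backends on synthetic data.

The two accuracy sweeps mirror the standard evaluation protocol for motion
tracking in optical mapping: generate image pairs with exact ground-truth
displacements, vary one nuisance dial — fluorescence strength |ΔF/F| or
noise standard deviation σ — and score each backend by mean end-point
error.  EPE is always computed on raw, UNsmoothed flow fields (smoothing
would hide backend error), and contrast enhancement, when enabled, is
applied before quantization to the backend's input bit depth.

Each sweep cell carries a Monte-Carlo standard error over pairs so that
trend comparisons can be tolerance-aware.
"""

from __future__ import annotations

import time
from dataclasses import asdict, fields as dataclass_fields
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .analysis import BenchmarkRecord, compute_epe
from .model import VideoStack
from .optflow import FlowBackendSpec, estimate_flow_pair
from .preprocess import contrast_enhance
from .synthetic import SyntheticScene, make_dataset, make_video

__all__ = [
    "sweep_fluorescence",
    "sweep_noise",
    "measure_speed",
    "write_report",
    "read_report",
]

_DEFAULT_CONTRAST_KERNEL = 7


def _enhance(frame: np.ndarray, kernel: int) -> np.ndarray:
    stack = VideoStack(frame[np.newaxis], bit_depth="unit")
    return contrast_enhance(stack, kernel).frames[0]


def _bench_cell(
    dataset,
    backend: str,
    ce: bool,
    f: float,
    sigma: float,
    contrast_kernel: int,
) -> BenchmarkRecord:
    spec = FlowBackendSpec(backend)
    epes = []
    start = time.perf_counter()
    for image_a, image_b, truth in dataset:
        if ce:
            image_a = _enhance(image_a, contrast_kernel)
            image_b = _enhance(image_b, contrast_kernel)
        flow = estimate_flow_pair(image_a, image_b, spec)
        epes.append(compute_epe(flow, truth))
    elapsed = time.perf_counter() - start
    epes = np.asarray(epes)
    return BenchmarkRecord(
        backend=backend,
        f_percent=abs(f) * 100.0,
        sigma=sigma,
        contrast_enhanced=ce,
        mean_epe_px=float(epes.mean()),
        n_pairs=len(epes),
        seconds_per_pair=elapsed / len(epes),
        epe_stderr=float(epes.std(ddof=1) / np.sqrt(len(epes))) if len(epes) > 1 else 0.0,
        f_signed=f,
    )


def sweep_fluorescence(
    backends: Sequence[str],
    f_values: Sequence[float],
    ce_modes: Sequence[bool] = (False, True),
    scene: Optional[SyntheticScene] = None,
    n_pairs: int = 200,
    seed: int = 1,
    contrast_kernel: int = _DEFAULT_CONTRAST_KERNEL,
) -> List[BenchmarkRecord]:
    """EPE of each backend over fluorescence strengths (σ = 0).

    ``f_values`` are unsigned |ΔF/F| percentages (e.g. ``[0, 5, 10]``); the
    rendered signal is a fluorescence *decrease*, as for Di-4-ANEPPS.  One
    record per (backend, f, contrast-enhancement) cell; the same dataset is
    shared across backends within a cell so comparisons are paired.
    """
    if scene is None:
        scene = SyntheticScene()
    records = []
    for f_percent in f_values:
        if not 0 <= f_percent <= 50:
            raise ValueError("fluorescence strength must be in [0, 50] percent")
        scene.f = -f_percent / 100.0
        scene.sigma = 0.0
        dataset = make_dataset(scene, n_pairs, seed)
        for ce in ce_modes:
            for backend in backends:
                records.append(
                    _bench_cell(dataset, backend, ce, scene.f, 0.0, contrast_kernel)
                )
    return records


def sweep_noise(
    backends: Sequence[str],
    sigma_values: Sequence[float],
    scene: Optional[SyntheticScene] = None,
    f_percent: float = 0.0,
    n_pairs: int = 200,
    seed: int = 1,
    contrast_enhanced: bool = False,
    contrast_kernel: int = _DEFAULT_CONTRAST_KERNEL,
) -> List[BenchmarkRecord]:
    """EPE of each backend over noise levels at fixed fluorescence strength."""
    if scene is None:
        scene = SyntheticScene()
    records = []
    for sigma in sigma_values:
        scene.f = -f_percent / 100.0
        scene.sigma = float(sigma)
        dataset = make_dataset(scene, n_pairs, seed)
        for backend in backends:
            records.append(
                _bench_cell(
                    dataset, backend, contrast_enhanced, scene.f, float(sigma),
                    contrast_kernel,
                )
            )
    return records


def measure_speed(
    backend: str,
    image_size: int = 128,
    n_frames: int = 50,
    include_prepost: bool = False,
    seed: int = 1,
) -> dict:
    """Steady-state wall-clock throughput of a backend (report-only).

    The first 5 pairs are warm-up and excluded; timings are per frame pair
    and exclude disk I/O.  Hardware-dependent by nature — never part of an
    accuracy comparison.
    """
    if n_frames < 10:
        raise ValueError("n_frames must be >= 10")
    scene = SyntheticScene(width=image_size, height=image_size)
    video, _ = make_video(scene, min(n_frames + 1, scene.duration))
    frames = video.frames
    reference = frames[0]
    times = []
    for t in range(1, len(frames)):
        start = time.perf_counter()
        if include_prepost:
            ref_in = _enhance(reference, _DEFAULT_CONTRAST_KERNEL)
            frm_in = _enhance(frames[t], _DEFAULT_CONTRAST_KERNEL)
        else:
            ref_in, frm_in = reference, frames[t]
        estimate_flow_pair(ref_in, frm_in, backend)
        times.append(time.perf_counter() - start)
    steady = np.asarray(times[5:]) if len(times) > 5 else np.asarray(times)
    return {
        "backend": backend,
        "image_size": image_size,
        "include_prepost": include_prepost,
        "seconds_per_pair": float(steady.mean()),
        "seconds_per_pair_std": float(steady.std(ddof=1)) if len(steady) > 1 else 0.0,
        "fps": float(1.0 / steady.mean()),
        "n_pairs": int(len(steady)),
    }


_REPORT_COLUMNS = [
    "backend",
    "f_percent",
    "sigma",
    "contrast_enhanced",
    "mean_epe_px",
    "n_pairs",
    "seconds_per_pair",
    "epe_stderr",
    "f_signed",
]


def write_report(records: Iterable[BenchmarkRecord], path: str) -> None:
    """Write benchmark records to CSV (stable column order, round-trippable)."""
    rows = [asdict(record) for record in records]
    frame = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    frame.to_csv(path, index=False)


def read_report(path: str) -> List[BenchmarkRecord]:
    """Read a CSV written by :func:`write_report` back into records."""
    frame = pd.read_csv(path)
    names = [f.name for f in dataclass_fields(BenchmarkRecord)]
    records = []
    for _, row in frame.iterrows():
        kwargs = {name: row[name] for name in names if name in frame.columns}
        kwargs["backend"] = str(kwargs["backend"])
        kwargs["contrast_enhanced"] = bool(kwargs["contrast_enhanced"])
        kwargs["n_pairs"] = int(kwargs["n_pairs"])
        records.append(BenchmarkRecord(**kwargs))
    return records
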