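"""Reading and writing the on-disk formats the toolkit touches.

Supported formats:

* multi-page TIFF (8/16-bit integer or 32-bit float, one page per frame) —
  metadata is embedded as JSON in the ImageDescription tag so that
  ``write_video``/``read_video`` round-trip bit depth and frame interval;
* raw binary stacks with an INI-style sidecar (keys ``width``, ``height``,
  ``frames``, ``bit_depth``, ``frame_interval_ms``, ``dtype``) — one explicit
  dialect, since camera vendors all differ;
* NumPy ``.npz`` archives for flow fields (lossless);
* CSV tables for optical traces.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import tifffile

from .model import FLOW_CONVENTION, FlowSequence, VideoStack

__all__ = [
    "read_video",
    "write_video",
    "read_flow",
    "write_flow",
    "write_traces",
]

_RAW_DTYPES = {8: np.uint8, 12: np.uint16, 14: np.uint16, 16: np.uint16}


def _read_sidecar(path: str) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", ";", "[")):
                continue
            if "=" not in line:
                raise ValueError(f"malformed sidecar line: {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            meta[key.lower()] = value
    return meta


def _read_raw(path: str) -> VideoStack:
    sidecar = os.path.splitext(path)[0] + ".ini"
    if not os.path.exists(sidecar):
        raise FileNotFoundError(f"raw stack sidecar not found: {sidecar}")
    meta = _read_sidecar(sidecar)
    try:
        width = int(meta["width"])
        height = int(meta["height"])
        n_frames = int(meta["frames"])
        bit_depth = meta["bit_depth"]
        interval = float(meta.get("frame_interval_ms", 1.0))
    except KeyError as exc:
        raise ValueError(f"sidecar missing required key: {exc}") from exc
    if bit_depth == "unit":
        dtype = np.float32
    else:
        bit_depth = int(bit_depth)
        if bit_depth not in _RAW_DTYPES:
            raise ValueError(f"unsupported bit depth: {bit_depth}")
        dtype = _RAW_DTYPES[bit_depth]
    data = np.fromfile(path, dtype=dtype)
    expected = n_frames * height * width
    if data.size != expected:
        raise ValueError(
            f"raw stack size {data.size} does not match sidecar "
            f"({n_frames}x{height}x{width}={expected})"
        )
    frames = data.reshape(n_frames, height, width)
    return VideoStack(
        frames=frames,
        bit_depth=bit_depth,
        frame_interval_ms=interval,
        name=os.path.basename(path),
    )


def read_video(path: str, format_hint: Optional[str] = None) -> VideoStack:
    """Read a video stack from a multi-page TIFF or raw binary file.

    The format is chosen from ``format_hint`` ("tiff" or "raw") or inferred
    from the file extension.  Pixel values are returned untouched.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"video file not found: {path}")
    ext = os.path.splitext(path)[1].lower()
    fmt = format_hint or ("raw" if ext in (".raw", ".bin", ".dat") else "tiff")
    if fmt == "raw":
        return _read_raw(path)
    try:
        with tifffile.TiffFile(path) as tif:
            frames = tif.asarray()
            description = tif.pages[0].description or ""
    except Exception as exc:
        raise ValueError(f"unreadable video: {path} ({exc})") from exc
    if frames.ndim == 2:
        frames = frames[np.newaxis]
    if frames.ndim != 3:
        raise ValueError(
            f"expected single-channel frames; TIFF has shape {frames.shape}"
        )
    meta = {}
    if description:
        try:
            parsed = json.loads(description)
            if isinstance(parsed, dict):
                meta = parsed
        except ValueError:
            pass
    if "bit_depth" in meta:
        bit_depth = meta["bit_depth"]
    elif frames.dtype == np.uint8:
        bit_depth = 8
    elif frames.dtype == np.uint16:
        bit_depth = 16
    elif np.issubdtype(frames.dtype, np.floating):
        bit_depth = "unit"
    else:
        raise ValueError(f"unsupported TIFF pixel type: {frames.dtype}")
    return VideoStack(
        frames=frames,
        bit_depth=bit_depth,
        frame_interval_ms=float(meta.get("frame_interval_ms", 1.0)),
        name=meta.get("name", os.path.basename(path)),
    )


def write_video(stack: VideoStack, path: str) -> None:
    """Write a video stack as a multi-page TIFF, one page per frame.

    Integer stacks keep their storage dtype (8-bit data as uint8, deeper
    sensors as uint16); unit-range stacks are written as 32-bit float pages.
    Metadata is stored as JSON in the ImageDescription tag.
    """
    if stack.bit_depth == "unit":
        frames = np.asarray(stack.frames, dtype=np.float32)
    elif stack.bit_depth == 8:
        frames = np.asarray(stack.frames).astype(np.uint8)
    else:
        frames = np.asarray(stack.frames).astype(np.uint16)
    meta = {
        "bit_depth": stack.bit_depth,
        "frame_interval_ms": stack.frame_interval_ms,
        "name": stack.name,
    }
    tifffile.imwrite(
        path, frames, photometric="minisblack", description=json.dumps(meta)
    )


def write_flow(flow: FlowSequence, path: str) -> None:
    """Write a flow sequence to a lossless ``.npz`` archive."""
    np.savez_compressed(
        path,
        fields=flow.fields,
        reference_index=np.int64(flow.reference_index),
        convention=np.bytes_(flow.convention.encode()),
    )


def read_flow(path: str) -> FlowSequence:
    """Read a flow sequence written by :func:`write_flow` (bit-exact)."""
    try:
        with np.load(path) as archive:
            if "convention" not in archive:
                raise ValueError("flow archive missing convention tag")
            convention = bytes(archive["convention"]).decode()
            if convention != FLOW_CONVENTION:
                raise ValueError(
                    f"flow convention mismatch: {convention!r} != {FLOW_CONVENTION!r}"
                )
            fields = archive["fields"]
            reference_index = int(archive["reference_index"])
    except (OSError, KeyError) as exc:
        raise ValueError(f"corrupt flow archive: {path} ({exc})") from exc
    return FlowSequence(fields=fields, reference_index=reference_index)


def write_traces(
    traces: Sequence[Tuple[str, Iterable[float]]],
    frame_interval_ms: float,
    path: str,
) -> None:
    """Write labelled optical traces as a CSV table.

    The first column is time in milliseconds (``t * frame_interval_ms``),
    followed by one column per trace.  All traces must have equal length.
    """
    labels: List[str] = [label for label, _ in traces]
    series = [np.asarray(list(values), dtype=float) for _, values in traces]
    lengths = {len(s) for s in series}
    if len(lengths) > 1:
        raise ValueError(f"traces have unequal lengths: {sorted(lengths)}")
    n = lengths.pop() if lengths else 0
    with open(path, "w") as fh:
        fh.write(",".join(["time_ms"] + labels) + "\n")
        for t in range(n):
            row = [repr(t * frame_interval_ms)] + [repr(s[t]) for s in series]
            fh.write(",".join(row) + "\n")
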