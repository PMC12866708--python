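"""File I/O: grayscale TIFF images/stacks and CSV traces/tables.

Physical units (pixel size, frame interval, sampling rate) always come from
the caller or config; TIFF resolution tags are not trusted as anything more
than defaults.  CSV outputs are UTF-8, '.' decimal, RFC-4180; an optional
provenance header of ``#``-prefixed lines (package version, config hash,
seed) precedes the body and is skipped on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .calcium import FluorescenceTrace, RatiometricTrace
from .motion import MotionVideo
from .sarcomere import StriationImage

__all__ = [
    "read_tiff_stack",
    "write_tiff",
    "quantize_u16",
    "read_trace_csv",
    "write_trace_csv",
    "write_csv",
    "read_csv",
    "config_hash",
    "provenance_lines",
]


def quantize_u16(array: np.ndarray) -> np.ndarray:
    """Round and clip a float intensity grid to uint16."""
    return np.clip(np.round(array), 0, 65535).astype(np.uint16)


def write_tiff(path: str | Path, data: np.ndarray | StriationImage | MotionVideo) -> Path:
    """Write a grayscale 16-bit TIFF (single- or multi-page).

    Float inputs are rounded/clipped to uint16; integer inputs are written
    as-is when they fit.
    """
    if isinstance(data, StriationImage):
        arr = data.pixels
    elif isinstance(data, MotionVideo):
        arr = data.frames
    else:
        arr = np.asarray(data)
    if arr.dtype not in (np.uint8, np.uint16):
        arr = quantize_u16(arr)
    path = Path(path)
    tifffile.imwrite(path, arr)
    return path


def read_tiff_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
    allow_float: bool = False,
) -> StriationImage | MotionVideo:
    """Read a grayscale TIFF: one page gives a :class:`StriationImage`
    (requires ``pixel_size_um``), several give a :class:`MotionVideo`
    (requires ``pixel_size_um`` and ``frame_interval_s``).

    RGB pages are rejected; float pages are rejected unless
    ``allow_float=True``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such TIFF: {path}")
    arr = tifffile.imread(path)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:2]):
        raise ValueError(f"{path}: RGB(A) TIFF not supported; provide grayscale")
    if np.issubdtype(arr.dtype, np.floating) and not allow_float:
        raise ValueError(f"{path}: float TIFF needs allow_float=True")
    if arr.ndim == 2:
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required for a single-page image")
        return StriationImage(pixels=arr.astype(float), pixel_size_um=pixel_size_um)
    if arr.ndim == 3:
        if pixel_size_um is None or frame_interval_s is None:
            raise ValueError("pixel_size_um and frame_interval_s required for a stack")
        return MotionVideo(
            frames=arr.astype(float),
            pixel_size_um=pixel_size_um,
            frame_interval_s=frame_interval_s,
        )
    raise ValueError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def config_hash(config: dict) -> str:
    """SHA-256 of the canonical JSON form of a config dict."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def provenance_lines(config: dict | None = None, seed: int | None = None) -> list[str]:
    lines = [f"# cardiofunc {__version__}"]
    if config is not None:
        lines.append(f"# config_sha256={config_hash(config)}")
    if seed is not None:
        lines.append(f"# seed={seed}")
    return lines


def write_csv(
    df: pd.DataFrame, path: str | Path,
    config: dict | None = None, seed: int | None = None,
) -> Path:
    """Write a DataFrame as CSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in provenance_lines(config, seed):
            fh.write(line + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_trace_csv(
    trace: FluorescenceTrace | RatiometricTrace, path: str | Path, **prov
) -> Path:
    if isinstance(trace, RatiometricTrace):
        df = pd.DataFrame(
            {"time_s": trace.time_s, "f340": trace.f340, "f380": trace.f380}
        )
    else:
        df = pd.DataFrame({"time_s": trace.time_s, "f": trace.values})
    return write_csv(df, path, **prov)


def read_trace_csv(
    path: str | Path, sampling_hz: float | None = None
) -> FluorescenceTrace | RatiometricTrace:
    """Read ``time_s,f`` or ``time_s,f340,f380`` CSV; the sampling rate is
    inferred from the time axis unless given."""
    df = read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing time_s column")
    t = df["time_s"].to_numpy(dtype=float)
    if sampling_hz is None:
        if len(t) < 2:
            raise ValueError(f"{path}: cannot infer sampling rate from < 2 samples")
        sampling_hz = 1.0 / float(np.median(np.diff(t)))
    if {"f340", "f380"} <= set(df.columns):
        return RatiometricTrace(
            time_s=t, f340=df["f340"].to_numpy(float),
            f380=df["f380"].to_numpy(float), sampling_hz=sampling_hz,
        )
    if "f" in df.columns:
        return FluorescenceTrace(
            time_s=t, values=df["f"].to_numpy(float), sampling_hz=sampling_hz
        )
    raise ValueError(f"{path}: expected columns time_s,f or time_s,f340,f380")
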