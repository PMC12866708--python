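"""Beating-monolayer motion analysis by block matching.

Frame-to-frame pixel displacement of a beating cardiomyocyte monolayer is
estimated per tiled block by maximizing normalized cross-correlation over
an integer search window, refined to sub-pixel precision by separable
3-point parabolic interpolation.  The mean displacement magnitude over
textured (valid) blocks, scaled to um/s, gives a displacement-velocity
trace with one contraction-speed peak and one relaxation-speed peak per
beat; per-beat kinetics (peak velocities, half-prominence durations) and
the beating-area fraction are derived from it.

This is the displacement-velocity readout of video-based contractility
systems; no substrate-traction force inversion is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "MotionVideo",
    "DisplacementField",
    "VelocityTrace",
    "BeatKinetics",
    "block_displacement",
    "velocity_trace",
    "beat_kinetics",
]


@dataclass
class MotionVideo:
    """Time-lapse frame stack with physical pixel size and frame interval."""

    frames: np.ndarray  # (n_frames, ny, nx)
    pixel_size_um: float
    frame_interval_s: float
    truth: object | None = None
    truth_mean_velocity_um_s: np.ndarray | None = None  # signed; + = contraction
    truth_area_fraction: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 3:
            raise ValueError("frames must be a stack of >= 3 equally shaped 2D frames")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be > 0")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass
class DisplacementField:
    """Per-block displacement between two frames, in pixels.

    The block grid is inset from the frame border by ``search_px`` so every
    block's full search window (including the +/-1 bins the sub-pixel
    parabola needs) lies inside the frame.
    """

    dy: np.ndarray  # (n_by, n_bx)
    dx: np.ndarray
    valid: np.ndarray  # bool
    block_px: int
    origin: tuple[int, int] = (0, 0)  # top-left pixel of block (0, 0)
    dy_int: np.ndarray | None = None  # integer NCC argmax shift (pre-refinement)
    dx_int: np.ndarray | None = None

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dy, self.dx)

    @property
    def magnitude_int(self) -> np.ndarray:
        """Magnitude of the dominant (integer-bin) motion; partial-coverage
        blocks report the majority shift, not a coverage-weighted blend."""
        if self.dy_int is None:
            return self.magnitude
        return np.hypot(self.dy_int, self.dx_int)


@dataclass
class VelocityTrace:
    """Per-frame-pair mean displacement speed, um/s.

    ``time_s`` are the midpoints of each frame pair; ``fields`` retains the
    per-pair block displacement fields; pairs with no valid block are NaN
    and listed in ``gaps``.
    """

    time_s: np.ndarray
    mean_speed_um_s: np.ndarray
    fields: list[DisplacementField] = field(repr=False, default_factory=list)
    gaps: list[int] = field(default_factory=list)


@dataclass
class BeatKinetics:
    """Per-video beat summary (means over complete beat episodes)."""

    contraction_peak_um_s: float
    relaxation_peak_um_s: float
    contraction_duration_s: float
    relaxation_duration_s: float
    beating_area_fraction: float
    n_beats: int
    missing_reason: str | None = None


def _shift_order(search_px: int) -> np.ndarray:
    """Candidate shifts sorted by magnitude, then row, then col (the
    tie-break order: first maximum in this order wins)."""
    shifts = [(dv, du) for dv in range(-search_px, search_px + 1)
              for du in range(-search_px, search_px + 1)]
    shifts.sort(key=lambda s: (s[0] * s[0] + s[1] * s[1], s[0], s[1]))
    return np.array(shifts, dtype=int)


def block_displacement(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    block_px: int = 16,
    search_px: int = 7,
    texture_floor: float = 1e-3,
    subpixel: bool = True,
) -> DisplacementField:
    """Displacement of each tiled block of ``frame_a`` into ``frame_b``.

    For every block with intensity variance >= ``texture_floor`` the integer
    shift in ``[-search_px, search_px]^2`` maximizing zero-mean normalized
    cross-correlation is found (ties toward smaller magnitude, then
    lexicographic), then refined along each axis by 3-point parabolic
    interpolation of the correlation surface.  Low-texture blocks are
    masked invalid.  Exact for pure integer translations of the interior.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"frames differ in shape: {a.shape} vs {b.shape}")
    if block_px < 8:
        raise ValueError("block_px must be >= 8")
    if search_px < 1:
        raise ValueError("search_px must be >= 1")
    ny, nx = a.shape
    s = search_px + 1  # +1 so the parabola's neighbor bins are also in-frame
    n_by, n_bx = (ny - 2 * s) // block_px, (nx - 2 * s) // block_px
    if n_by <= 0 or n_bx <= 0:
        raise ValueError(
            f"frame {a.shape} too small for block_px={block_px} with a "
            f"{s}-px search margin"
        )
    H, W = n_by * block_px, n_bx * block_px
    oy = s + (ny - 2 * s - H) // 2
    ox = s + (nx - 2 * s - W) // 2

    ab = a[oy : oy + H, ox : ox + W].reshape(n_by, block_px, n_bx, block_px).transpose(0, 2, 1, 3)
    a_mean = ab.mean(axis=(2, 3), keepdims=True)
    a0 = ab - a_mean
    a_norm = np.sqrt((a0**2).sum(axis=(2, 3)))
    texture_ok = ab.var(axis=(2, 3)) >= texture_floor

    # correlations computed one bin beyond the search range so the parabola
    # has neighbors even when the best integer shift sits on the boundary
    shifts = _shift_order(search_px + 1)
    n_shift = len(shifts)
    corr = np.full((n_shift, n_by, n_bx), -np.inf)
    for k, (dv, du) in enumerate(shifts):
        bw = b[oy + dv : oy + dv + H, ox + du : ox + du + W]
        bb = bw.reshape(n_by, block_px, n_bx, block_px).transpose(0, 2, 1, 3)
        b0 = bb - bb.mean(axis=(2, 3), keepdims=True)
        b_norm = np.sqrt((b0**2).sum(axis=(2, 3)))
        num = (a0 * b0).sum(axis=(2, 3))
        with np.errstate(invalid="ignore", divide="ignore"):
            c = num / (a_norm * b_norm)
        c[~np.isfinite(c)] = -np.inf
        corr[k] = c

    allowed = np.max(np.abs(shifts), axis=1) <= search_px
    corr_search = np.where(allowed[:, None, None], corr, -np.inf)
    best = corr_search.argmax(axis=0)  # first max in (magnitude, row, col) order
    dy = shifts[best, 0].astype(float)
    dx = shifts[best, 1].astype(float)
    dy_int, dx_int = dy.copy(), dx.copy()
    best_corr = np.take_along_axis(corr_search, best[None], axis=0)[0]
    valid = texture_ok & np.isfinite(best_corr)

    if subpixel:
        # index correlation by shift for parabolic refinement
        lut = {(int(dv), int(du)): k for k, (dv, du) in enumerate(shifts)}
        for i in range(n_by):
            for j in range(n_bx):
                if not valid[i, j]:
                    continue
                dv, du = int(dy[i, j]), int(dx[i, j])
                c0 = corr[lut[(dv, du)], i, j]
                if c0 >= 1.0 - 1e-12:
                    continue  # exact match: integer shift is already exact
                for axis, (lo, hi) in (("y", ((dv - 1, du), (dv + 1, du))),
                                       ("x", ((dv, du - 1), (dv, du + 1)))):
                    if lo not in lut or hi not in lut:
                        continue
                    cm = corr[lut[lo], i, j]
                    cp = corr[lut[hi], i, j]
                    if not (np.isfinite(cm) and np.isfinite(cp)):
                        continue
                    denom = cm - 2.0 * c0 + cp
                    if denom >= 0:
                        continue
                    off = 0.5 * (cm - cp) / denom
                    off = min(max(off, -0.5), 0.5)
                    if axis == "y":
                        dy[i, j] += off
                    else:
                        dx[i, j] += off

    dy[~valid] = np.nan
    dx[~valid] = np.nan
    dy_int[~valid] = np.nan
    dx_int[~valid] = np.nan
    return DisplacementField(
        dy=dy, dx=dx, valid=valid, block_px=block_px, origin=(oy, ox),
        dy_int=dy_int, dx_int=dx_int,
    )


def velocity_trace(
    video: MotionVideo,
    block_px: int = 16,
    search_px: int = 7,
    texture_floor: float = 1e-3,
) -> VelocityTrace:
    """Mean displacement speed over valid blocks for each adjacent frame
    pair, scaled by pixel size / frame interval to um/s."""
    n = video.n_frames
    speeds = np.empty(n - 1)
    fields: list[DisplacementField] = []
    gaps: list[int] = []
    scale = video.pixel_size_um / video.frame_interval_s
    for i in range(n - 1):
        fld = block_displacement(
            video.frames[i], video.frames[i + 1],
            block_px=block_px, search_px=search_px, texture_floor=texture_floor,
        )
        fields.append(fld)
        if fld.valid.any():
            speeds[i] = float(np.nanmean(fld.magnitude[fld.valid])) * scale
        else:
            speeds[i] = np.nan
            gaps.append(i)
    time_s = (np.arange(n - 1) + 0.5) * video.frame_interval_s
    return VelocityTrace(time_s=time_s, mean_speed_um_s=speeds, fields=fields, gaps=gaps)


def _merge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    merged = [runs[0]]
    for lo, hi in runs[1:]:
        if lo - merged[-1][1] <= max_gap:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))
    return merged


def beat_kinetics(
    vel: VelocityTrace,
    quiescence_fraction: float = 0.1,
    merge_gap_s: float = 0.25,
    area_threshold_px: float = 0.2,
) -> BeatKinetics:
    """Segment the speed trace into beats and summarize each.

    Beat episodes are supra-threshold runs (speed >= ``quiescence_fraction``
    of the global max), with sub-threshold gaps shorter than ``merge_gap_s``
    merged so the brief mid-beat pause between the contraction and
    relaxation peaks does not split a beat.  Episodes touching the trace
    boundary are dropped as partial.  Within each episode the first
    prominent peak is the contraction peak and the last the relaxation
    peak; durations are widths at half prominence.  The beating-area
    fraction is the fraction of valid blocks whose within-episode maximum
    displacement exceeds ``area_threshold_px``, averaged over episodes.
    """
    v = vel.mean_speed_um_s
    dt = float(vel.time_s[1] - vel.time_s[0]) if len(vel.time_s) > 1 else 1.0
    finite = np.isfinite(v)
    if not finite.any() or np.nanmax(v) <= 0:
        return BeatKinetics(
            math.nan, math.nan, math.nan, math.nan, math.nan, 0,
            missing_reason="no motion detected",
        )
    vmax = float(np.nanmax(v))
    thr = quiescence_fraction * vmax
    above = finite & (v >= thr)

    runs: list[tuple[int, int]] = []
    i = 0
    n = len(v)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    if not runs:
        return BeatKinetics(
            math.nan, math.nan, math.nan, math.nan, math.nan, 0,
            missing_reason="no supra-threshold episodes",
        )
    runs = _merge_runs(runs, max(1, int(round(merge_gap_s / dt))))
    episodes = [(lo, hi) for lo, hi in runs if lo > 0 and hi < n]

    con_peaks, rel_peaks = [], []
    con_dur, rel_dur, area = [], [], []
    vv = np.where(finite, v, 0.0)
    for lo, hi in episodes:
        seg = vv[lo:hi]
        pk, props = signal.find_peaks(seg, prominence=0.05 * vmax)
        if pk.size < 2:
            continue
        c_idx, r_idx = lo + pk[0], lo + pk[-1]
        con_peaks.append(v[c_idx])
        rel_peaks.append(v[r_idx])
        widths = signal.peak_widths(vv, [c_idx, r_idx], rel_height=0.5)[0]
        con_dur.append(widths[0] * dt)
        rel_dur.append(widths[1] * dt)
        if vel.fields:
            mags = np.stack([f.magnitude_int for f in vel.fields[lo:hi]])
            valid_any = np.stack([f.valid for f in vel.fields[lo:hi]]).any(axis=0)
            if valid_any.any():
                peak_disp = np.nanmax(np.where(np.isnan(mags), 0.0, mags), axis=0)
                area.append(float((peak_disp[valid_any] >= area_threshold_px).mean()))

    if not con_peaks:
        return BeatKinetics(
            math.nan, math.nan, math.nan, math.nan, math.nan, 0,
            missing_reason="no complete beat episode with two peaks",
        )
    return BeatKinetics(
        contraction_peak_um_s=float(np.mean(con_peaks)),
        relaxation_peak_um_s=float(np.mean(rel_peaks)),
        contraction_duration_s=float(np.mean(con_dur)),
        relaxation_duration_s=float(np.mean(rel_dur)),
        beating_area_fraction=float(np.mean(area)) if area else math.nan,
        n_beats=len(con_peaks),
    )
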