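"""Sarcomere organization scoring by spatial frequency analysis.

An immunofluorescence image of striated myofibrils (alpha-actinin or TNNT2
staining) shows a quasi-periodic banding pattern with spacing around
1.6-2.2 um.  The image is Hann-windowed, mean-subtracted and Fourier
transformed; the primary peak of the 2D power spectrum inside a period
search band gives the mean sarcomere length ("period"), and the fraction
of off-DC spectral energy pooled around that peak gives an organization
score ("power") in [0, 1].  Higher power means a more regular striation
pattern; disorder (positional jitter of the Z-discs) spreads spectral
energy away from the fundamental and lowers the score.

The annular (all-orientation) peak search makes the score rotation
invariant, and the off-DC normalization makes it invariant to intensity
scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

__all__ = [
    "StriationImage",
    "PowerSpectrum2D",
    "SpectralPeak",
    "SarcomereScore",
    "power_spectrum_2d",
    "find_primary_peak",
    "score_sarcomere",
    "DEFAULT_BAND_UM",
]

DEFAULT_BAND_UM: tuple[float, float] = (1.2, 3.0)
MIN_IMAGE_PX = 32


@dataclass
class StriationImage:
    """Single-channel intensity image with physical pixel size.

    ``roi`` is an optional half-open rectangle ``(row0, row1, col0, col1)``
    (0-based, origin top-left); scoring uses only that sub-region.
    ``truth`` carries the generative record when the image is synthetic.
    """

    pixels: np.ndarray
    pixel_size_um: float
    roi: tuple[int, int, int, int] | None = None
    truth: object | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D grid")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.roi is not None:
            r0, r1, c0, c1 = self.roi
            ny, nx = self.pixels.shape
            if not (0 <= r0 < r1 <= ny and 0 <= c0 < c1 <= nx):
                raise ValueError(f"roi {self.roi} outside image bounds {self.pixels.shape}")

    @property
    def data(self) -> np.ndarray:
        if self.roi is None:
            return self.pixels
        r0, r1, c0, c1 = self.roi
        return self.pixels[r0:r1, c0:c1]


@dataclass
class PowerSpectrum2D:
    """Squared-magnitude DFT of the windowed, mean-subtracted image.

    ``power`` is in unshifted FFT layout; ``fy``/``fx`` are the matching
    cycle/um axes (``np.fft.fftfreq`` order).  The DC bin is retained but
    flagged; all scoring excludes it.
    """

    power: np.ndarray
    fy: np.ndarray
    fx: np.ndarray
    windowed: np.ndarray  # mean-subtracted, Hann-windowed image (for refinement)
    pixel_size_um: float
    dc_power: float
    total_offdc: float
    no_signal: bool


@dataclass
class SpectralPeak:
    frequency_cyc_per_um: float
    orientation_deg: float
    power_fraction: float
    no_signal: bool = False


@dataclass
class SarcomereScore:
    """Organization score of one striation image (or ROI).

    ``power`` in [0, 1]; ``period_um = 1 / peak_frequency_cyc_per_um``;
    ``orientation_deg`` is the band-normal angle in [0, 180).
    """

    power: float
    period_um: float
    orientation_deg: float
    peak_frequency_cyc_per_um: float
    no_signal: bool = False


def power_spectrum_2d(image: StriationImage) -> PowerSpectrum2D:
    """Windowed 2D power spectrum with frequency axes in cycles/um.

    The ROI is mean-subtracted and multiplied by a separable periodic Hann
    window before the transform, suppressing edge-discontinuity leakage.
    A constant image yields an all-zero off-DC spectrum flagged 'no signal'.
    """
    data = image.data
    ny, nx = data.shape
    if ny < MIN_IMAGE_PX or nx < MIN_IMAGE_PX:
        raise ValueError(f"image must be >= {MIN_IMAGE_PX}x{MIN_IMAGE_PX} px, got {data.shape}")
    win = np.outer(windows.hann(ny, sym=False), windows.hann(nx, sym=False))
    g = (data - data.mean()) * win
    spec = np.fft.fft2(g)
    power = np.abs(spec) ** 2
    fy = np.fft.fftfreq(ny, d=image.pixel_size_um)
    fx = np.fft.fftfreq(nx, d=image.pixel_size_um)
    dc = float(power[0, 0])
    total_offdc = float(power.sum() - dc)
    scale = float(np.abs(g).max()) ** 2 * g.size
    no_signal = total_offdc <= 1e-18 * max(scale, 1.0)
    return PowerSpectrum2D(
        power=power, fy=fy, fx=fx, windowed=g,
        pixel_size_um=image.pixel_size_um, dc_power=dc,
        total_offdc=total_offdc, no_signal=no_signal,
    )


def _dtft_power(g: np.ndarray, fy: float, fx: float, pixel_size_um: float) -> float:
    """|DTFT|^2 of the windowed image at an arbitrary (fy, fx) in cycles/um."""
    ny, nx = g.shape
    y = np.arange(ny) * pixel_size_um
    x = np.arange(nx) * pixel_size_um
    ey = np.exp(-2j * math.pi * fy * y)
    ex = np.exp(-2j * math.pi * fx * x)
    return float(np.abs(ey @ g @ ex) ** 2)


def _refine_radial(
    spec: PowerSpectrum2D, r0: float, ey: float, ex: float, delta: float, iters: int = 2
) -> float:
    """Sub-bin peak frequency by 3-point parabolic interpolation along the
    radial direction, on log magnitudes of the exact windowed transform.

    A second pass at delta/8 around the first vertex tightens the estimate
    well below a tenth of a frequency bin.
    """
    r = r0
    step = delta
    for _ in range(iters):
        vals = []
        for rr in (r - step, r, r + step):
            if rr <= 0:
                return r
            vals.append(_dtft_power(spec.windowed, rr * ey, rr * ex, spec.pixel_size_um))
        a, b, c = (math.log(max(v, 1e-300)) for v in vals)
        denom = a - 2.0 * b + c
        if denom >= 0:  # not locally concave; keep current estimate
            return r
        off = 0.5 * (a - c) / denom
        off = min(max(off, -1.0), 1.0)
        r = r + off * step
        step /= 8.0
    return r


def find_primary_peak(
    spec: PowerSpectrum2D, band_um: tuple[float, float] = DEFAULT_BAND_UM
) -> SpectralPeak:
    """Locate the dominant spatial frequency within a period search band.

    Searches all orientations in the annulus of radii
    ``[1/max_period, 1/min_period]`` (canonical half-plane, so Hermitian
    mirrors are not double-counted); ties break toward lower frequency then
    smaller angle.  ``power_fraction`` pools the 3x3 bin neighborhood of the
    peak plus its Hermitian mirror and normalizes by total off-DC energy.
    """
    min_period, max_period = band_um
    if not 0 < min_period < max_period:
        raise ValueError("band_um must satisfy 0 < min_period < max_period")
    f_lo, f_hi = 1.0 / max_period, 1.0 / min_period
    nyq = 1.0 / (2.0 * spec.pixel_size_um)
    if f_lo > nyq:
        raise ValueError(
            f"period band {band_um} um lies entirely above Nyquist "
            f"({nyq:.3f} cyc/um); empty annulus"
        )

    FY, FX = np.meshgrid(spec.fy, spec.fx, indexing="ij")
    FR = np.hypot(FY, FX)
    half = (FY > 0) | ((FY == 0) & (FX > 0))
    annulus = half & (FR >= f_lo) & (FR <= f_hi)
    if not annulus.any():
        raise ValueError(f"no spectral bins inside the period band {band_um} um")
    if spec.no_signal:
        return SpectralPeak(math.nan, math.nan, 0.0, no_signal=True)

    pw = np.where(annulus, spec.power, -np.inf)
    pmax = pw.max()
    cand = np.argwhere(pw == pmax)
    if len(cand) > 1:  # lower frequency, then smaller angle
        fr = FR[cand[:, 0], cand[:, 1]]
        ang = np.degrees(np.arctan2(FY[cand[:, 0], cand[:, 1]], FX[cand[:, 0], cand[:, 1]])) % 180.0
        order = np.lexsort((ang, fr))
        cand = cand[order]
    i0, j0 = (int(v) for v in cand[0])

    fy0, fx0 = float(spec.fy[i0]), float(spec.fx[j0])
    r0 = math.hypot(fy0, fx0)
    ey, ex = fy0 / r0, fx0 / r0
    ny, nx = spec.power.shape
    delta = min(1.0 / (ny * spec.pixel_size_um), 1.0 / (nx * spec.pixel_size_um))
    r_ref = _refine_radial(spec, r0, ey, ex, delta)

    # energy pooled over the peak's 3x3 neighborhood plus its Hermitian mirror
    neigh = set()
    mi, mj = (-i0) % ny, (-j0) % nx
    for ci, cj in ((i0, j0), (mi, mj)):
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                neigh.add(((ci + di) % ny, (cj + dj) % nx))
    neigh.discard((0, 0))
    energy = float(sum(spec.power[i, j] for i, j in neigh))
    frac = min(max(energy / spec.total_offdc, 0.0), 1.0) if spec.total_offdc > 0 else 0.0

    orientation = math.degrees(math.atan2(fy0, fx0)) % 180.0
    return SpectralPeak(
        frequency_cyc_per_um=r_ref, orientation_deg=orientation, power_fraction=frac
    )


def score_sarcomere(
    image: StriationImage, band_um: tuple[float, float] = DEFAULT_BAND_UM
) -> SarcomereScore:
    """Score one image (or its ROI): power, period and orientation."""
    spec = power_spectrum_2d(image)
    peak = find_primary_peak(spec, band_um)
    period = math.nan if peak.no_signal else 1.0 / peak.frequency_cyc_per_um
    return SarcomereScore(
        power=peak.power_fraction,
        period_um=period,
        orientation_deg=peak.orientation_deg,
        peak_frequency_cyc_per_um=peak.frequency_cyc_per_um,
        no_signal=peak.no_signal,
    )
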