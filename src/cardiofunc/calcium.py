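"""Calcium-transient kinetics extraction.

Handles both spontaneous single-channel recordings (e.g. Fluo-4 at 50 fps,
normalized to dF/F0) and field-paced ratiometric Fura-2 recordings captured
as F340/F380 excitation ratio pairs (higher ratio = higher cytosolic
calcium).  Per cell the pipeline is: (optionally) form the ratio, detect
beats, then summarize kinetics -- beat rate, transient amplitude, rise time
(10%-amplitude onset to peak), mono-exponential decay tau, and diastolic
level.

Decay tau is the time constant of an ``A*exp(-t/tau) + C`` least-squares
fit to each peak-to-next-onset segment; it is the standard proxy for
SERCA-mediated calcium reuptake ("recycling") rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

__all__ = [
    "FluorescenceTrace",
    "RatiometricTrace",
    "Beats",
    "TransientFeatures",
    "compute_ratio",
    "detect_transients",
    "extract_features",
    "analyze_trace",
]


def _check_uniform(time_s: np.ndarray, sampling_hz: float) -> None:
    if len(time_s) > 1:
        dt = np.diff(time_s)
        if np.max(np.abs(dt - 1.0 / sampling_hz)) > 1e-6:
            raise ValueError("time axis must be uniformly sampled at sampling_hz (<=1e-6 s)")


@dataclass
class FluorescenceTrace:
    """Uniformly sampled single-channel fluorescence (or ratio) time series."""

    time_s: np.ndarray
    values: np.ndarray
    sampling_hz: float
    units: str = "au"
    truth: object | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_s.shape != self.values.shape:
            raise ValueError("time_s and values must have the same length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        _check_uniform(self.time_s, self.sampling_hz)


@dataclass
class RatiometricTrace:
    """Paired 340/380 nm excitation channels sampled as ratio pairs."""

    time_s: np.ndarray
    f340: np.ndarray
    f380: np.ndarray
    sampling_hz: float
    truth: object | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f340 = np.asarray(self.f340, dtype=float)
        self.f380 = np.asarray(self.f380, dtype=float)
        if not (self.time_s.shape == self.f340.shape == self.f380.shape):
            raise ValueError("time_s, f340 and f380 must have the same length")
        _check_uniform(self.time_s, self.sampling_hz)


@dataclass
class Beats:
    """Detected beat landmarks (sample indices into the trace)."""

    peaks: np.ndarray
    onsets: np.ndarray
    empty_reason: str | None = None

    @property
    def n_beats(self) -> int:
        return int(len(self.peaks))


@dataclass
class TransientFeatures:
    """Per-cell calcium-handling summary.

    Units: amplitude and diastolic_level are dF/F0 for single-channel input
    (F0 = 10th percentile of the raw trace) and ratio units for ratiometric
    input (ratios are already concentration-calibrated up to a constant, so
    they are not renormalized).
    """

    beat_rate_bpm: float
    amplitude: float
    rise_time_s: float
    decay_tau_s: float
    diastolic_level: float
    n_beats: int
    fit_r2: float
    missing_reason: str | None = None
    excluded_decay_fits: int = 0


def compute_ratio(trace: RatiometricTrace, f380_floor: float = 1e-9) -> FluorescenceTrace:
    """Elementwise F340/F380 ratio trace.

    Raises if the denominator channel dips to or below ``f380_floor``
    anywhere, naming the first offending sample.
    """
    bad = np.nonzero(trace.f380 <= f380_floor)[0]
    if bad.size:
        raise ValueError(
            f"f380 <= floor ({f380_floor}) first at index {int(bad[0])} "
            f"(t = {trace.time_s[bad[0]]:.4f} s)"
        )
    return FluorescenceTrace(
        time_s=trace.time_s,
        values=trace.f340 / trace.f380,
        sampling_hz=trace.sampling_hz,
        units="ratio",
        truth=trace.truth,
    )


def _robust_noise_sd(values: np.ndarray) -> float:
    """Noise SD from the scaled median absolute deviation of the first
    difference (differencing suppresses the slow transient component)."""
    d = np.diff(values)
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / math.sqrt(2.0))


def detect_transients(
    trace: FluorescenceTrace,
    rhythm: str = "spontaneous",
    pacing_hz: float | None = None,
    prominence_k: float = 5.0,
    refractory_fraction: float = 0.25,
) -> Beats:
    """Locate beat peaks and their 10%-amplitude onsets.

    Peaks must exceed a prominence floor of ``prominence_k`` robust noise
    SDs (with a small range-relative floor so noiseless traces still
    detect), and peaks closer than ``refractory_fraction / expected_rate``
    are never both kept.  In paced mode the search keeps at most one peak
    per pacing window ``[k/f, (k+1)/f)``.  An empty result is allowed and
    flagged, never an error.
    """
    if rhythm not in ("spontaneous", "paced"):
        raise ValueError(f"unknown rhythm {rhythm!r}")
    if rhythm == "paced" and not pacing_hz:
        raise ValueError("paced rhythm requires pacing_hz")
    v = trace.values
    fs = trace.sampling_hz
    noise_sd = _robust_noise_sd(v)
    vrange = float(np.percentile(v, 99.5) - np.percentile(v, 0.5))
    prominence = max(prominence_k * noise_sd, 0.1 * vrange)
    if prominence <= 0:
        return Beats(np.array([], int), np.array([], int), empty_reason="flat trace")

    if rhythm == "paced":
        rate = pacing_hz
        distance = max(1, int(round(refractory_fraction / rate * fs)))
        peaks, _ = signal.find_peaks(v, prominence=prominence, distance=distance)
        # one peak per pacing window: keep the tallest
        kept = []
        period = 1.0 / rate
        for k in range(int(math.ceil(trace.time_s[-1] / period)) + 1):
            inwin = peaks[(trace.time_s[peaks] >= k * period) & (trace.time_s[peaks] < (k + 1) * period)]
            if inwin.size:
                kept.append(int(inwin[np.argmax(v[inwin])]))
        peaks = np.array(sorted(kept), dtype=int)
    else:
        peaks, _ = signal.find_peaks(v, prominence=prominence)
        if peaks.size >= 2:
            est_period = float(np.median(np.diff(trace.time_s[peaks])))
            distance = max(1, int(round(refractory_fraction * est_period * fs)))
            peaks, _ = signal.find_peaks(v, prominence=prominence, distance=distance)

    if peaks.size == 0:
        return Beats(np.array([], int), np.array([], int), empty_reason="no peaks above floor")

    onsets = np.empty(peaks.size, dtype=int)
    prev = 0
    for i, p in enumerate(peaks):
        seg = v[prev:p] if p > prev else v[max(p - 1, 0):p + 1]
        dia = float(np.percentile(seg, 10)) if seg.size else float(v[p])
        thr = dia + 0.1 * (v[p] - dia)
        below = np.nonzero(v[prev:p] <= thr)[0]
        onsets[i] = prev + int(below[-1]) if below.size else prev
        prev = p
    return Beats(peaks=peaks, onsets=onsets)


def _fit_decay(t: np.ndarray, y: np.ndarray, dia: float) -> tuple[float, float]:
    """Fit A*exp(-t/tau) + C to one decay segment; return (tau, r2)."""
    if len(t) < 4:
        return math.nan, 0.0
    a0 = max(float(y[0] - dia), 1e-9)
    # log-linear initial tau from the early decay
    yy = np.clip(y - dia, 1e-9 * a0, None)
    k = max(4, len(t) // 2)
    slope = np.polyfit(t[:k], np.log(yy[:k]), 1)[0]
    tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3.0

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=[a0, max(tau0, 1e-3), dia],
            bounds=([0.0, 1e-4, -np.inf], [np.inf, 100.0 * (t[-1] - t[0] + 1e-9), np.inf]),
            maxfev=2000,
        )
    except RuntimeError:
        return math.nan, 0.0
    resid = y - model(t, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return float(popt[1]), max(min(r2, 1.0), 0.0)


def extract_features(
    trace: FluorescenceTrace,
    beats: Beats,
    normalize: bool | None = None,
    r2_min: float = 0.8,
) -> TransientFeatures:
    """Summarize kinetics over detected beats.

    ``normalize=None`` auto-detects: ratio-valued traces are left alone,
    anything else is converted to dF/F0 with F0 the 10th percentile.
    Diastolic level is the median of pooled inter-beat baseline segments
    (last 25% of each previous-peak-to-onset interval); amplitude the mean
    peak-minus-preceding-diastolic; decay tau the mean over per-beat
    exponential fits with r2 >= ``r2_min`` (poor fits are excluded and
    counted).
    """
    if normalize is None:
        normalize = trace.units != "ratio"
    v = trace.values
    if normalize:
        f0 = float(np.percentile(v, 10))
        if f0 <= 0:
            raise ValueError("cannot form dF/F0: 10th-percentile baseline is <= 0")
        v = (v - f0) / f0
    t = trace.time_s

    if beats.n_beats < 2:
        reason = beats.empty_reason or f"only {beats.n_beats} beat(s) detected; need >= 2"
        return TransientFeatures(
            beat_rate_bpm=math.nan, amplitude=math.nan, rise_time_s=math.nan,
            decay_tau_s=math.nan, diastolic_level=math.nan,
            n_beats=beats.n_beats, fit_r2=math.nan, missing_reason=reason,
        )

    peaks, onsets = beats.peaks, beats.onsets

    # pooled baseline: last quarter of each previous-peak -> onset interval
    base_samples = []
    per_beat_dia = np.full(peaks.size, math.nan)
    for i in range(1, peaks.size):
        lo, hi = peaks[i - 1], onsets[i]
        if hi <= lo:
            continue
        start = hi - max(1, (hi - lo) // 4)
        seg = v[start:hi]
        base_samples.append(seg)
        per_beat_dia[i] = float(np.median(seg))
    diastolic = float(np.median(np.concatenate(base_samples))) if base_samples else math.nan

    amps = [float(v[peaks[i]] - per_beat_dia[i]) for i in range(1, peaks.size)
            if np.isfinite(per_beat_dia[i])]
    amplitude = float(np.mean(amps)) if amps else math.nan
    rise_time = float(np.mean(t[peaks] - t[onsets]))
    beat_rate = 60.0 * (peaks.size - 1) / float(t[peaks[-1]] - t[peaks[0]])

    taus, r2s, excluded = [], [], 0
    for i, p in enumerate(peaks):
        end = onsets[i + 1] if i + 1 < peaks.size else len(v)
        seg_t = t[p:end] - t[p]
        seg_v = v[p:end]
        dia = per_beat_dia[i] if np.isfinite(per_beat_dia[i]) else diastolic
        tau, r2 = _fit_decay(seg_t, seg_v, dia if np.isfinite(dia) else 0.0)
        if np.isfinite(tau) and r2 >= r2_min:
            taus.append(tau)
            r2s.append(r2)
        else:
            excluded += 1
    decay_tau = float(np.mean(taus)) if taus else math.nan
    fit_r2 = float(np.mean(r2s)) if r2s else math.nan

    return TransientFeatures(
        beat_rate_bpm=beat_rate, amplitude=amplitude, rise_time_s=rise_time,
        decay_tau_s=decay_tau, diastolic_level=diastolic,
        n_beats=int(peaks.size), fit_r2=fit_r2, excluded_decay_fits=excluded,
    )


def analyze_trace(
    trace: FluorescenceTrace | RatiometricTrace,
    rhythm: str = "spontaneous",
    pacing_hz: float | None = None,
    **kwargs,
) -> TransientFeatures:
    """Convenience wrapper: ratio (if needed) -> detect -> extract."""
    if isinstance(trace, RatiometricTrace):
        trace = compute_ratio(trace)
    beats = detect_transients(trace, rhythm=rhythm, pacing_hz=pacing_hz)
    return extract_features(trace, beats, **kwargs)
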