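"""Synthetic microscopy and trace generators with recorded ground truth.

Every generator here is the measurement model run forwards: quasi-periodic
striation images (Z-disc-like Gaussian ridges with positional jitter),
calcium transients (linear rise, mono-exponential decay) in single-channel
or ratiometric F340/F380 form, and beating-monolayer videos whose texture is
warped by a pulsatile displacement field.  Each output carries its truth
record so downstream estimators can be validated by parameter recovery.

All randomness flows from an explicit integer seed; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .sarcomere import StriationImage
from .calcium import FluorescenceTrace, RatiometricTrace
from .motion import MotionVideo

__all__ = [
    "StriationTruth",
    "TransientTruth",
    "MotionTruth",
    "GroupSpec",
    "GroupDesign",
    "GroupBundle",
    "CellRecord",
    "generate_striation_image",
    "generate_calcium_trace",
    "generate_motion_video",
    "generate_group_dataset",
]

MIN_PERIODS_SPANNED = 10


# ---------------------------------------------------------------------------
# Truth records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StriationTruth:
    """Generative parameters of a striation image.

    ``period_um`` is the sarcomere spacing, ``jitter_sigma_um`` the SD of
    band-center positional noise (the disorder that degrades spectral
    "power"), ``orientation_deg`` the band-normal angle (counterclockwise
    from the image x-axis), ``band_sigma_um`` the Gaussian ridge width.
    """

    period_um: float = 1.8
    jitter_sigma_um: float = 0.0
    orientation_deg: float = 0.0
    band_sigma_um: float = 0.25
    amplitude: float = 1000.0
    baseline: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.period_um > 0:
            raise ValueError("period_um must be > 0")
        if self.jitter_sigma_um < 0:
            raise ValueError("jitter_sigma_um must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class TransientTruth:
    """Generative parameters of a calcium transient trace.

    ``amplitude`` and ``diastolic_level`` are in ΔF/F0-compatible trace units
    for ``mode='single_channel'`` (diastolic defaults to 1 so the additive
    amplitude is directly a ΔF/F0) and in ratio units for ``'ratiometric'``.
    Kinetics must resolve between beats: rise + 3·tau < one beat period.
    """

    mode: str = "ratiometric"  # 'single_channel' | 'ratiometric'
    rhythm: str = "paced"  # 'spontaneous' | 'paced'
    beat_rate_hz: float = 0.5
    amplitude: float = 0.6
    rise_time_s: float = 0.1
    decay_tau_s: float = 0.4
    diastolic_level: float = 0.5
    noise_sd: float = 0.0
    duration_s: float = 20.0
    sampling_hz: float = 50.0
    interbeat_cv: float = 0.05  # spontaneous rhythm only
    f380_level: float = 1000.0  # ratiometric denominator channel mean
    f380_noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("single_channel", "ratiometric"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.rhythm not in ("spontaneous", "paced"):
            raise ValueError(f"unknown rhythm {self.rhythm!r}")
        if self.beat_rate_hz <= 0:
            raise ValueError("beat_rate_hz must be > 0")
        period = 1.0 / self.beat_rate_hz
        if not self.rise_time_s + 3.0 * self.decay_tau_s < period:
            raise ValueError(
                "kinetic invariant violated: rise_time_s + 3*decay_tau_s = "
                f"{self.rise_time_s + 3 * self.decay_tau_s:.3f} s must be < "
                f"beat period {period:.3f} s"
            )
        if self.sampling_hz < 20.0 * self.beat_rate_hz:
            raise ValueError("sampling_hz must be >= 20 * beat_rate_hz")
        if self.noise_sd < 0 or self.f380_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class MotionTruth:
    """Generative parameters of a beating-monolayer video.

    The displacement field is ``d(x, t) = m(x) * s(t) * u`` with a smooth
    mask ``m`` covering ``beating_area_fraction`` of the frame, a uniform
    in-plane direction ``u`` at ``direction_deg``, and a per-beat raised-
    cosine pulse ``s(t)`` whose derivative attains +peak contraction and
    −peak relaxation velocity (asymmetric when the two differ).
    """

    peak_contraction_velocity_um_s: float = 10.0
    peak_relaxation_velocity_um_s: float = 8.0
    beat_rate_hz: float = 1.0
    beating_area_fraction: float = 1.0
    pixel_size_um: float = 0.5
    frame_interval_s: float = 0.05
    direction_deg: float = 30.0
    active_fraction: float = 0.5  # fraction of the beat period spent moving
    start_offset_s: float = 0.3  # first beat onset (keeps beats off the edges)
    seed: int = 0

    def validate(self) -> None:
        if self.peak_contraction_velocity_um_s < 0 or self.peak_relaxation_velocity_um_s < 0:
            raise ValueError("peak velocities must be >= 0")
        if not 0.0 <= self.beating_area_fraction <= 1.0:
            raise ValueError("beating_area_fraction must be in [0, 1]")
        if self.beat_rate_hz <= 0 or self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("beat rate, pixel size and frame interval must be > 0")
        if not 0 < self.active_fraction < 1:
            raise ValueError("active_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# Striation images
# ---------------------------------------------------------------------------

def generate_striation_image(
    truth: StriationTruth,
    shape: tuple[int, int] = (256, 256),
    pixel_size_um: float = 0.1,
) -> StriationImage:
    """Render a quasi-periodic striation image from its truth record.

    Gaussian-profile ridges are placed at ``k*period + eps_k`` along the
    band-normal axis, ``eps_k ~ N(0, jitter_sigma^2)``, on a constant
    baseline, with i.i.d. Gaussian pixel noise on top.  The image must span
    at least 10 periods along the band normal.
    """
    truth.validate()
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    ny, nx = shape
    rng = np.random.default_rng(truth.seed)

    theta = math.radians(truth.orientation_deg)
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    # coordinate along the band normal, in micrometres
    u = (xx * math.cos(theta) + yy * math.sin(theta)) * pixel_size_um
    extent = float(u.max() - u.min())
    n_req = MIN_PERIODS_SPANNED * truth.period_um
    if extent < n_req:
        min_px = math.ceil(n_req / pixel_size_um)
        raise ValueError(
            f"image spans {extent:.2f} um along the band normal; need >= "
            f"{n_req:.2f} um ({MIN_PERIODS_SPANNED} periods), i.e. at least "
            f"{min_px} px at {pixel_size_um} um/px"
        )

    k_lo = math.floor(u.min() / truth.period_um) - 3
    k_hi = math.ceil(u.max() / truth.period_um) + 3
    ks = np.arange(k_lo, k_hi + 1)
    centers = ks * truth.period_um
    if truth.jitter_sigma_um > 0:
        centers = centers + rng.normal(0.0, truth.jitter_sigma_um, size=ks.size)
    else:
        rng.normal(0.0, 1.0, size=ks.size)  # keep the noise stream aligned

    img = np.full(shape, float(truth.baseline))
    two_s2 = 2.0 * truth.band_sigma_um**2
    for c in centers:
        img += truth.amplitude * np.exp(-((u - c) ** 2) / two_s2)
    if truth.noise_sd > 0:
        img += rng.normal(0.0, truth.noise_sd, size=shape)
    return StriationImage(pixels=img, pixel_size_um=pixel_size_um, truth=truth)


# ---------------------------------------------------------------------------
# Calcium traces
# ---------------------------------------------------------------------------

def _transient_kernel(s: np.ndarray, amplitude: float, rise: float, tau: float) -> np.ndarray:
    """Linear rise over ``rise`` seconds to ``amplitude``, then exp decay."""
    out = np.zeros_like(s)
    on = s >= 0
    rising = on & (s < rise)
    if rise > 0:
        out[rising] = amplitude * s[rising] / rise
    falling = s >= rise
    out[falling] = amplitude * np.exp(-(s[falling] - rise) / tau)
    return out


def beat_onsets(truth: TransientTruth, rng: np.random.Generator | None = None) -> np.ndarray:
    """Beat onset times.  Paced: exact multiples of the pacing period.
    Spontaneous: intervals jittered with CV ``interbeat_cv``."""
    period = 1.0 / truth.beat_rate_hz
    if truth.rhythm == "paced":
        return np.arange(0.0, truth.duration_s, period)
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    n_max = int(math.ceil(truth.duration_s / period)) + 2
    intervals = rng.normal(period, truth.interbeat_cv * period, size=n_max)
    intervals = np.clip(intervals, 0.5 * period, 1.5 * period)
    onsets = np.concatenate([[0.0], np.cumsum(intervals)])
    return onsets[onsets < truth.duration_s]


def generate_calcium_trace(truth: TransientTruth) -> FluorescenceTrace | RatiometricTrace:
    """Synthesize a calcium transient trace from its truth record.

    Single-channel mode returns a :class:`FluorescenceTrace`; ratiometric
    mode returns a :class:`RatiometricTrace` in which all calcium dynamics
    sit in F340 (``F340 = R(t) * F380``) and F380 fluctuates about a
    constant mean, so F340/F380 reconstructs the ratio signal exactly.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    n = int(round(truth.duration_s * truth.sampling_hz))
    t = np.arange(n) / truth.sampling_hz

    onsets = beat_onsets(truth, rng)
    signal = np.full(n, float(truth.diastolic_level))
    for i, onset in enumerate(onsets):
        k = _transient_kernel(
            t - onset, truth.amplitude, truth.rise_time_s, truth.decay_tau_s
        )
        if i + 1 < len(onsets):  # each beat's kernel ends at the next onset
            k[t >= onsets[i + 1]] = 0.0
        signal += k

    if truth.mode == "single_channel":
        values = signal.copy()
        if truth.noise_sd > 0:
            values += rng.normal(0.0, truth.noise_sd, size=n)
        return FluorescenceTrace(
            time_s=t, values=values, sampling_hz=truth.sampling_hz, truth=truth
        )

    ratio = signal.copy()
    if truth.noise_sd > 0:
        ratio += rng.normal(0.0, truth.noise_sd, size=n)
    f380 = np.full(n, float(truth.f380_level))
    if truth.f380_noise_sd > 0:
        f380 += rng.normal(0.0, truth.f380_noise_sd, size=n)
    f340 = ratio * f380
    return RatiometricTrace(
        time_s=t, f340=f340, f380=f380, sampling_hz=truth.sampling_hz, truth=truth
    )


# ---------------------------------------------------------------------------
# Beating videos
# ---------------------------------------------------------------------------

def _pulse_displacement(t: np.ndarray, truth: MotionTruth) -> np.ndarray:
    """Per-beat displacement pulse s(t) in micrometres.

    Raised-cosine rise over t1 then raised-cosine return over t2, with
    t1, t2 chosen so the derivative peaks equal the requested contraction
    and relaxation velocities and t1 + t2 fills ``active_fraction`` of the
    beat period.  Zero outside the active window; zero net displacement
    per beat.
    """
    vc = truth.peak_contraction_velocity_um_s
    vr = truth.peak_relaxation_velocity_um_s
    period = 1.0 / truth.beat_rate_hz
    if vc == 0.0 or vr == 0.0:
        return np.zeros_like(t)
    t_active = truth.active_fraction * period
    amp = 2.0 * t_active / (math.pi * (1.0 / vc + 1.0 / vr))
    t1 = math.pi * amp / (2.0 * vc)
    t2 = math.pi * amp / (2.0 * vr)

    phase = np.mod(t - truth.start_offset_s, period)
    phase[t < truth.start_offset_s] = t_active  # quiescent before first beat
    s = np.zeros_like(t)
    rising = phase < t1
    s[rising] = 0.5 * amp * (1.0 - np.cos(math.pi * phase[rising] / t1))
    falling = (phase >= t1) & (phase < t1 + t2)
    s[falling] = 0.5 * amp * (1.0 + np.cos(math.pi * (phase[falling] - t1) / t2))
    return s


def pulse_amplitude_um(truth: MotionTruth) -> float:
    """Peak displacement amplitude of the beat pulse, micrometres."""
    vc = truth.peak_contraction_velocity_um_s
    vr = truth.peak_relaxation_velocity_um_s
    if vc == 0.0 or vr == 0.0:
        return 0.0
    t_active = truth.active_fraction / truth.beat_rate_hz
    return 2.0 * t_active / (math.pi * (1.0 / vc + 1.0 / vr))


def _beating_mask(shape: tuple[int, int], fraction: float, smooth_px: float = 3.0) -> np.ndarray:
    """Smooth mask whose >0.5 support covers ~``fraction`` of the frame."""
    ny, nx = shape
    if fraction <= 0:
        return np.zeros(shape)
    if fraction >= 1:
        return np.ones(shape)
    hy = math.sqrt(fraction) * ny
    hx = math.sqrt(fraction) * nx
    yy, xx = np.mgrid[0:ny, 0:nx]
    rect = (
        (np.abs(yy - (ny - 1) / 2.0) <= hy / 2.0)
        & (np.abs(xx - (nx - 1) / 2.0) <= hx / 2.0)
    ).astype(float)
    return ndimage.gaussian_filter(rect, smooth_px, mode="nearest")


def _bandpass_texture(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Seeded band-pass noise texture (correlation length ~4 px)."""
    white = rng.normal(size=shape)
    tex = ndimage.gaussian_filter(white, 1.0) - ndimage.gaussian_filter(white, 4.0)
    tex = (tex - tex.mean()) / tex.std()
    return 500.0 + 100.0 * tex


def generate_motion_video(
    truth: MotionTruth,
    shape: tuple[int, int] = (64, 64),
    n_frames: int = 60,
) -> MotionVideo:
    """Render a beating-monolayer video from its truth record.

    A static band-pass-noise texture is warped by the time-varying
    displacement field; the returned video carries the truth record plus
    the signed ground-truth mean-velocity series (um/s, positive during
    contraction) whose per-beat trapezoidal integral is zero.
    """
    truth.validate()
    duration = n_frames * truth.frame_interval_s
    needed = 2.0 / truth.beat_rate_hz + truth.start_offset_s
    if duration < needed:
        raise ValueError(
            f"n_frames={n_frames} covers {duration:.2f} s; need >= {needed:.2f} s "
            "(two beats after the start offset)"
        )
    amp_px = pulse_amplitude_um(truth) / truth.pixel_size_um
    if amp_px > min(shape) / 4.0:
        raise ValueError(
            f"peak displacement {amp_px:.1f} px exceeds 1/4 of the frame size "
            f"({min(shape) / 4:.1f} px)"
        )

    rng = np.random.default_rng(truth.seed)
    texture = _bandpass_texture(shape, rng)
    mask = _beating_mask(shape, truth.beating_area_fraction)
    theta = math.radians(truth.direction_deg)
    uy, ux = math.sin(theta), math.cos(theta)

    t = np.arange(n_frames) * truth.frame_interval_s
    s_um = _pulse_displacement(t, truth)
    s_px = s_um / truth.pixel_size_um

    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    frames = np.empty((n_frames,) + shape)
    for i in range(n_frames):
        dy = mask * s_px[i] * uy
        dx = mask * s_px[i] * ux
        if s_px[i] == 0.0:
            frames[i] = texture
        else:
            frames[i] = ndimage.map_coordinates(
                texture, [yy - dy, xx - dx], order=3, mode="reflect"
            )

    mean_mask = float(mask.mean())
    truth_velocity = mean_mask * np.diff(s_um) / truth.frame_interval_s
    return MotionVideo(
        frames=frames,
        pixel_size_um=truth.pixel_size_um,
        frame_interval_s=truth.frame_interval_s,
        truth=truth,
        truth_mean_velocity_um_s=truth_velocity,
        truth_area_fraction=float((mask > 0.5).mean()),
    )


# ---------------------------------------------------------------------------
# Grouped datasets
# ---------------------------------------------------------------------------

# physical truncation bounds for per-cell parameter draws
_PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "period_um": (0.5, np.inf),
    "jitter_sigma_um": (0.0, np.inf),
    "band_sigma_um": (0.05, np.inf),
    "amplitude": (1e-3, np.inf),
    "baseline": (0.0, np.inf),
    "noise_sd": (0.0, np.inf),
    "beat_rate_hz": (0.05, np.inf),
    "rise_time_s": (0.02, np.inf),
    "decay_tau_s": (0.05, np.inf),
    "diastolic_level": (1e-3, np.inf),
    "peak_contraction_velocity_um_s": (0.1, np.inf),
    "peak_relaxation_velocity_um_s": (0.1, np.inf),
    "beating_area_fraction": (0.0, 1.0),
}


@dataclass(frozen=True)
class GroupSpec:
    """Per-factor-combination parameter distributions.

    Each dict maps a truth-field name to ``(mean, sd)``; parameters not
    listed stay at the base-truth value.  SDs must be strictly positive.
    """

    transient: dict[str, tuple[float, float]] = field(default_factory=dict)
    striation: dict[str, tuple[float, float]] = field(default_factory=dict)
    motion: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class GroupDesign:
    """Two-factor (genotype x treatment) synthetic study design."""

    genotypes: tuple[str, ...]
    treatments: tuple[str, ...]
    groups: dict[tuple[str, str], GroupSpec]
    n_per_group: int
    seed: int
    transient_base: TransientTruth = TransientTruth()
    striation_base: StriationTruth = StriationTruth()
    motion_base: MotionTruth = MotionTruth()
    image_shape: tuple[int, int] = (256, 256)
    image_pixel_size_um: float = 0.1
    video_shape: tuple[int, int] = (64, 64)
    video_n_frames: int = 60

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for g in self.genotypes:
            for tr in self.treatments:
                if (g, tr) not in self.groups:
                    raise ValueError(f"missing parameter set for group {(g, tr)}")
        for key, spec in self.groups.items():
            for modality in ("transient", "striation", "motion"):
                for name, (_, sd) in getattr(spec, modality).items():
                    if not sd > 0:
                        raise ValueError(
                            f"non-positive SD for {modality}.{name} in group {key}"
                        )


@dataclass
class CellRecord:
    cell_id: str
    genotype: str
    treatment: str
    trace: FluorescenceTrace | RatiometricTrace | None = None
    image: StriationImage | None = None
    video: MotionVideo | None = None


@dataclass
class GroupBundle:
    """Raw per-cell data plus the (analysis-blind) ground-truth table."""

    design: GroupDesign
    cells: list[CellRecord]
    truth: pd.DataFrame  # columns: cell_id, genotype, treatment, modality, param, value


def _draw_params(
    base,
    dists: dict[str, tuple[float, float]],
    rng: np.random.Generator,
    extra_bounds: dict[str, tuple[float, float]] | None = None,
):
    """Draw a truth record from truncated-Normal per-parameter distributions."""
    updates = {}
    for name in sorted(dists):
        mean, sd = dists[name]
        lo, hi = _PARAM_BOUNDS.get(name, (-np.inf, np.inf))
        if extra_bounds and name in extra_bounds:
            lo = max(lo, extra_bounds[name][0])
            hi = min(hi, extra_bounds[name][1])
        a, b = (lo - mean) / sd, (hi - mean) / sd
        updates[name] = float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))
    return replace(base, **updates)


def generate_group_dataset(
    design: GroupDesign,
    modalities: tuple[str, ...] = ("transient", "striation", "motion"),
) -> GroupBundle:
    """Materialize raw per-cell data for a two-factor design.

    For each factor combination, ``n_per_group`` per-cell parameter sets are
    drawn from the group's truncated-Normal distributions and rendered with
    the generators above.  The returned truth table is for validation only;
    the analysis pipeline never reads it.
    """
    design.validate()
    seed_seq = np.random.SeedSequence(design.seed)
    cells: list[CellRecord] = []
    truth_rows: list[dict] = []

    idx = 0
    for genotype in design.genotypes:
        for treatment in design.treatments:
            spec = design.groups[(genotype, treatment)]
            for _ in range(design.n_per_group):
                child = seed_seq.spawn(1)[0]
                rng = np.random.default_rng(child)
                cell_seed = int(child.generate_state(1)[0] % (2**31))
                cell_id = f"cell{idx:04d}"
                rec = CellRecord(cell_id=cell_id, genotype=genotype, treatment=treatment)

                if "transient" in modalities:
                    base = design.transient_base
                    # keep drawn kinetics inside the between-beat window
                    rate = spec.transient.get("beat_rate_hz", (base.beat_rate_hz, None))[0]
                    rise = spec.transient.get("rise_time_s", (base.rise_time_s, None))[0]
                    tau_hi = 0.95 * (1.0 / rate - rise) / 3.0
                    tt = _draw_params(
                        base, spec.transient, rng,
                        extra_bounds={"decay_tau_s": (-np.inf, tau_hi)},
                    )
                    tt = replace(tt, seed=cell_seed)
                    rec.trace = generate_calcium_trace(tt)
                    for name, val in _truth_fields(tt):
                        truth_rows.append(
                            dict(cell_id=cell_id, genotype=genotype, treatment=treatment,
                                 modality="transient", param=name, value=val)
                        )
                if "striation" in modalities:
                    st = _draw_params(design.striation_base, spec.striation, rng)
                    st = replace(st, seed=cell_seed + 1)
                    rec.image = generate_striation_image(
                        st, design.image_shape, design.image_pixel_size_um
                    )
                    for name, val in _truth_fields(st):
                        truth_rows.append(
                            dict(cell_id=cell_id, genotype=genotype, treatment=treatment,
                                 modality="striation", param=name, value=val)
                        )
                if "motion" in modalities:
                    mt = _draw_params(design.motion_base, spec.motion, rng)
                    mt = replace(mt, seed=cell_seed + 2)
                    rec.video = generate_motion_video(
                        mt, design.video_shape, design.video_n_frames
                    )
                    for name, val in _truth_fields(mt):
                        truth_rows.append(
                            dict(cell_id=cell_id, genotype=genotype, treatment=treatment,
                                 modality="motion", param=name, value=val)
                        )
                cells.append(rec)
                idx += 1

    truth = pd.DataFrame(truth_rows)
    return GroupBundle(design=design, cells=cells, truth=truth)


def _truth_fields(truth) -> list[tuple[str, float]]:
    out = []
    for name, val in vars(truth).items():
        if isinstance(val, (int, float)) and name != "seed":
            out.append((name, float(val)))
    return out
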