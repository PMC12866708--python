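# Methods

`cardiofunc` re-implements, as a tested library, the quantitative
phenotyping computations used to characterize iPSC-derived cardiomyocytes
(iPSC-CMs) in genotype × treatment designs: sarcomere organization scoring
from immunofluorescence images, calcium-transient kinetics from
single-channel and ratiometric recordings, displacement-velocity
contractility from beating-monolayer videos, and the group-comparison
statistics downstream of all three. Because the raw microscopy of such
studies is rarely deposited, every stage is validated by parameter
recovery on synthetic data whose generative model is stated below.

## Sarcomere organization ("power" and "period")

A striated myofibril image (α-actinin or TNNT2 staining) is modeled as a
quasi-periodic pattern of Z-disc bands ~1.6–2.2 µm apart. The image (or a
rectangular ROI; 0-based, half-open, origin top-left) is mean-subtracted,
multiplied by a separable periodic Hann window, and Fourier transformed.
Mean subtraction and windowing suppress the DC pedestal and
edge-discontinuity leakage that would otherwise contaminate the band
around the fundamental.

- **Period.** The primary peak is the largest squared-magnitude bin inside
  the annulus of spatial frequencies corresponding to periods in the
  search band (default 1.2–3.0 µm, bracketing physiological sarcomere
  lengths; configurable). The search covers all orientations (canonical
  half-plane, so Hermitian mirrors are not double-counted), making the
  score rotation invariant; ties break toward lower frequency, then
  smaller angle. The peak frequency is refined along the radial direction
  by 3-point parabolic interpolation on log magnitudes of the exact
  windowed transform sampled at ±1 frequency bin, iterated once at 1/8
  bin. Log-domain interpolation is used because the windowed mainlobe is
  close to Gaussian, for which a log-parabola is exact; the iterated
  refinement keeps the peak estimate well inside a tenth of a bin, which a
  dense direct-DFT oracle confirms on 32×32 instances.
- **Power.** The organization score is the energy in the 3×3 bin
  neighborhood of the peak (plus its Hermitian mirror) divided by total
  off-DC energy, clipped to [0, 1]. The 3×3 pool captures the window's
  leakage of the fundamental without absorbing harmonics. The
  normalization makes the score invariant to intensity scaling and, to
  <1%, to translation. The original instrument software's normalization
  is not public; this normalized fraction is this package's operational
  definition and preserves the ordering semantics (more regular → higher
  power).
- Constant (no-signal) images return power 0 with a `no_signal` flag
  rather than an error. Multiple ROIs are scored independently; averaging
  happens only at the statistics layer.

## Calcium transient kinetics

Input is either a single-channel fluorescence trace (e.g. Fluo-4 at
50 frames/s, spontaneous rhythm) or a ratiometric pair captured with
340/380 nm excitation (field-paced at 0.5 Hz in the emulated protocol).
Ratio traces are formed elementwise as F340/F380 after checking the
denominator against a floor; they are *not* renormalized, since the ratio
is already concentration-calibrated up to a constant. Single-channel
traces are converted to ΔF/F0 with F0 the 10th percentile of the trace
(robust to transient occupancy), which makes every feature invariant to
affine intensity scaling.

- **Beat detection.** Peaks must exceed a prominence floor of 5 robust
  noise SDs (noise SD estimated as 1.4826·MAD of the first difference
  divided by √2; a small range-relative floor keeps noiseless traces
  detectable), and peaks closer than 0.25 of the expected beat period are
  never both kept. Paced mode keeps at most one peak per pacing window;
  spontaneous mode estimates the period from a first detection pass.
  Onsets sit at the last crossing of baseline + 10% amplitude before each
  peak. An empty result is flagged, never an error.
- **Features.** Diastolic level = median of pooled baseline segments (the
  last 25% of each previous-peak→onset interval). Amplitude = mean of
  peak minus preceding per-beat diastolic. Rise time = mean onset→peak
  time; with the generator's linear ramp the 10% onset makes the measured
  rise ≈0.9× the ramp duration (documented, and accounted for in
  recovery tests). Decay tau comes from per-beat least-squares fits of
  A·exp(−t/τ)+C over peak→next-onset segments; fits with r² < 0.8 are
  excluded from the cell mean and counted. Beat rate uses the
  peak-to-peak span, 60·(n−1)/(t_last−t_first), unbiased for partial
  first/last cycles. Cells with <2 beats report missing features with a
  reason.
- The late-interval baseline window still contains a small exponential
  tail, biasing diastolic (and hence amplitude) by <2% at the default
  kinetics; this is inherent to the stated definition and is covered by
  the recovery tolerances.

## Monolayer motion and contractility

The contractility readout is displacement velocity, as in video-based
commercial cell-motion systems; no substrate-traction force inversion is
attempted. For each adjacent frame pair, tiled blocks (default 16 px,
≥8 px) are matched by maximizing zero-mean normalized cross-correlation
over integer shifts within ±`search_px` (default 7), with sub-pixel
refinement by separable 3-point parabolic interpolation of the
correlation surface. The block grid is inset from the frame border by
`search_px`+1 so every block's full search window is in-frame —
boundary blocks cannot be refined and would otherwise bias the mean
speed. Correlations are evaluated one bin beyond the search range so
boundary-of-search maxima can still be refined. Low-texture blocks
(variance below `texture_floor`) are masked invalid. Integer translations
are recovered exactly (refinement is skipped at perfect correlation);
NCC is insensitive to global intensity drift.

The velocity trace is the mean displacement magnitude over valid blocks ×
pixel size / frame interval. Beats are supra-threshold episodes (speed ≥
10% of the trace maximum), with sub-threshold gaps shorter than
`merge_gap_s` (default 0.25 s) merged so the brief mid-beat pause between
the contraction and relaxation speed peaks does not split a beat;
episodes touching the trace boundary are dropped as partial. Within each
episode the first prominent peak is the contraction peak and the last the
relaxation peak; durations are widths at half prominence. The
beating-area fraction counts blocks whose within-episode maximum
displacement exceeds `area_threshold_px` (default 0.2 px), averaged over
episodes; the count uses the *integer* (pre-refinement) match, because
the dominant motion of a partially covered block is what classifies it as
beating — sub-pixel refinement on mixed blocks reports a
coverage-weighted blend that would inflate the area.

## Group statistics

Measurements live in long-format tables (`unit_id, factor_a, factor_b,
measurement, value`). Two-way crossed fixed-effects ANOVA uses the
classical sum-of-squares partition when the design is balanced (the
partition identity SS_A+SS_B+SS_AB+SS_err = SS_total is tested to 1e-8)
and Type-II sums of squares via statsmodels OLS otherwise — imaging cell
counts are rarely balanced, and Type-II is the conventional default when
no interaction priority is stated. Degenerate zero-variance designs
report F as undefined with p = 1 instead of raising, keeping batch runs
alive.

Post hoc comparisons default to all pairwise cell means using the pooled
error MS (Welch per-pair tests are an option), adjusted by the step-down
Šidák (Holm–Šidák) procedure: sort p ascending, adj_(i) =
1−(1−p_(i))^(m−i+1), enforce monotonicity by running maximum, report in
input order. Adjusted values never fall below raw ones and never exceed
Bonferroni. The comparison family is explicit in the output rather than
implicit in the code.

qPCR relative expression uses 2^−ΔΔCT: replicate CTs are averaged per
sample and gene, ΔCT = CT(target) − CT(reference), ΔΔCT subtracts the
calibrator group's mean ΔCT. The calibrator group's *geometric* mean fold
is exactly 1 (the arithmetic mean exceeds 1 whenever CTs vary).
Summaries are mean ± SEM (SD/√n; undefined at n = 1).

## Synthetic data generators

All generators are seed-deterministic (bit-identical reruns) and attach
their truth records; noiseless outputs match the closed-form construction
pointwise.

- **Striation images**: Gaussian-profile ridges (σ 0.25 µm — the
  diffraction-blurred appearance of Z-discs, and a clean spectral
  fundamental, unlike square waves) at positions k·period + ε_k,
  ε_k ~ N(0, jitter²), any orientation, plus baseline and i.i.d. Gaussian
  noise. The frame must span ≥10 periods along the band normal.
- **Calcium traces**: per-beat kernel with linear rise (default 0.1 s)
  to the amplitude then exponential decay (default τ 0.4 s), on a
  diastolic baseline; each kernel ends at the next onset (the stated
  invariant rise+3τ < period means <1% of the amplitude is truncated).
  Paced onsets are exact multiples of the pacing period; spontaneous
  onsets jitter with 5% inter-beat CV (rhythm variability is not reported
  for the emulated lines; 5% keeps beats separable). Ratiometric mode
  puts all dynamics into F340 = R(t)·F380 with F380 fluctuating about a
  constant mean — any factorization with the correct ratio is
  observationally equivalent downstream. Default diastolic ratio 0.5 and
  amplitude 0.6 mirror the emulated Fura-2 protocol's reference level.
- **Videos**: a seeded band-pass-noise texture (correlation length ≈4 px,
  so block matching has texture everywhere) warped by
  d(x,t) = m(x)·s(t)·û, with a smooth mask m covering the beating-area
  fraction, a *uniform* direction û, and a per-beat raised-cosine pulse
  whose rise and fall slopes hit the requested contraction and relaxation
  peak velocities within an active window (default half the beat period).
  A uniform direction is used instead of radial convergence because block
  matching estimates local translation; a radial field makes blocks near
  the convergence center compress rather than translate, which would test
  the toy field, not the estimator. The attached truth series is the
  signed mean velocity (trapezoid-integrating to zero per beat). Peak
  displacement is rejected above ¼ of the frame size.
- **Group datasets**: per-cell parameters drawn from truncated-Normal
  distributions (truncation at physical bounds, e.g. τ > 0.05 s and below
  the between-beat window) per factor combination, then rendered with the
  generators above. The truth table is returned for validation only; the
  analysis pipeline is tested to never consult it.

What the generators do *not* emulate: optical point-spread functions,
photobleaching, motion artifacts in calcium recordings, arrhythmia or
alternans, cell segmentation errors, and non-Gaussian camera noise.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to every property of
real recordings.

## Validation conditions and problem sizes

The test suite and `scripts/acceptance.py` use: 256×256 px images at
0.1 µm/px (32×32 at 0.5 µm/px for the dense-DFT oracle, where the direct
transform is affordable); 20 s ratiometric traces at 50 Hz, paced at
0.5 Hz, SNR 20 dB, 50 cells for recovery; 64×64 px videos (60 frames at
20 fps, 0.5 µm/px) for velocity recovery and 128×128 for beating-area
recovery; 1000 replicate null tables (2×2, n = 30/group) for the type-I
error check; and the bundled two-factor phenotype design at n = 50
cells/group per modality for the end-to-end directional check. These
sizes keep the full validation run within a few minutes on one core while
leaving every recovery tolerance comfortably met.

## Known limitations

- The sarcomere score needs a dominant striation orientation within the
  scored ROI; heavily curved or multi-directional myofibril fields share
  spectral energy across angles and lower the power of all of them.
- The decay fit assumes a mono-exponential with offset; biphasic decays
  are summarized by an effective τ with reduced r².
- Block matching reports translation only; rotation or strain within a
  block biases the estimate toward the dominant translation.
- The beating-area estimate is quantized at block resolution and excludes
  the search margin at the frame border.
- Paced-mode detection assumes capture on every pacing pulse; skipped
  beats reduce the count rather than being flagged as capture failure.
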