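"""Generators: closed-form construction, seed determinism, error contracts."""

import numpy as np
import pytest

import cardiofunc as cf
from cardiofunc.synth import (
    GroupDesign, GroupSpec, beat_onsets, generate_group_dataset,
    pulse_amplitude_um,
)


class TestStriationGenerator:
    def test_noiseless_comb_is_periodic_along_x(self):
        truth = cf.StriationTruth(period_um=1.8, jitter_sigma_um=0.0, noise_sd=0.0)
        img = cf.generate_striation_image(truth, shape=(64, 256), pixel_size_um=0.1)
        profile = img.pixels[32]
        lag = int(round(1.8 / 0.1))  # 18 px
        # exact periodicity away from the band bookkeeping margins
        np.testing.assert_allclose(profile[: 256 - lag], profile[lag:], rtol=1e-9)

    def test_autocorrelation_peak_at_period_lag(self):
        # period 2.0 um at 0.1 um/px: first non-zero-lag autocorrelation
        # maximum of the band-normal profile must sit at lag 20 px
        truth = cf.StriationTruth(period_um=2.0, jitter_sigma_um=0.0, noise_sd=0.0)
        img = cf.generate_striation_image(truth, shape=(64, 256), pixel_size_um=0.1)
        p = img.pixels[10] - img.pixels[10].mean()
        ac = np.correlate(p, p, mode="full")[p.size - 1 :]
        interior = ac[5:40]  # skip the zero-lag peak
        assert 5 + int(np.argmax(interior)) == 20

    def test_seed_determinism(self):
        truth = cf.StriationTruth(jitter_sigma_um=0.3, noise_sd=50.0, seed=7)
        a = cf.generate_striation_image(truth)
        b = cf.generate_striation_image(truth)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_too_small_image_names_minimum(self):
        with pytest.raises(ValueError, match="at least"):
            cf.generate_striation_image(
                cf.StriationTruth(period_um=2.0), shape=(64, 64), pixel_size_um=0.1
            )

    def test_orientation_rotates_bands(self):
        truth = cf.StriationTruth(period_um=1.8, orientation_deg=90.0)
        img = cf.generate_striation_image(truth, shape=(256, 64), pixel_size_um=0.1)
        # bands normal to y: columns constant along x
        np.testing.assert_allclose(img.pixels[:, 0], img.pixels[:, -1], rtol=1e-9)


class TestCalciumGenerator:
    def test_zero_amplitude_gives_constant_plus_noise(self):
        truth = cf.TransientTruth(amplitude=0.0, noise_sd=0.0)
        trace = cf.compute_ratio(cf.generate_calcium_trace(truth))
        np.testing.assert_allclose(trace.values, 0.5, rtol=1e-12)

    def test_paced_onsets_exact_grid(self):
        truth = cf.TransientTruth(rhythm="paced", beat_rate_hz=0.5, duration_s=20.0)
        onsets = beat_onsets(truth)
        np.testing.assert_array_equal(onsets, np.arange(0.0, 20.0, 2.0))
        assert len(onsets) == 10

    def test_ratiometric_peak_ratio(self):
        # diastolic 0.5 + amplitude 0.6, no noise: max F340/F380 = 1.1
        truth = cf.TransientTruth(diastolic_level=0.5, amplitude=0.6, noise_sd=0.0)
        trace = cf.generate_calcium_trace(truth)
        ratio = trace.f340 / trace.f380
        assert np.max(ratio) == pytest.approx(1.1, abs=1e-9)

    def test_seed_determinism(self):
        truth = cf.TransientTruth(rhythm="spontaneous", noise_sd=0.05, seed=11)
        a = cf.generate_calcium_trace(truth)
        b = cf.generate_calcium_trace(truth)
        np.testing.assert_array_equal(a.f340, b.f340)
        np.testing.assert_array_equal(a.f380, b.f380)

    def test_kinetic_invariant_enforced(self):
        with pytest.raises(ValueError, match="kinetic invariant"):
            cf.TransientTruth(beat_rate_hz=1.0, decay_tau_s=0.5).validate()

    def test_single_channel_mode(self):
        truth = cf.TransientTruth(
            mode="single_channel", diastolic_level=1.0, amplitude=0.6, noise_sd=0.0
        )
        trace = cf.generate_calcium_trace(truth)
        assert isinstance(trace, cf.FluorescenceTrace)
        assert np.max(trace.values) == pytest.approx(1.6, abs=1e-9)
        assert np.min(trace.values) == pytest.approx(1.0, abs=1e-6)


class TestMotionGenerator:
    def test_zero_velocity_gives_static_frames(self):
        truth = cf.MotionTruth(
            peak_contraction_velocity_um_s=0.0, peak_relaxation_velocity_um_s=0.0
        )
        video = cf.generate_motion_video(truth)
        for frame in video.frames[1:]:
            np.testing.assert_array_equal(frame, video.frames[0])

    def test_seed_determinism(self):
        truth = cf.MotionTruth(seed=5)
        a = cf.generate_motion_video(truth)
        b = cf.generate_motion_video(truth)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_truth_velocity_integrates_to_zero_per_beat(self):
        # signed mean-velocity series: trapezoidal integral over one full
        # beat equals the net displacement, which is zero by construction
        truth = cf.MotionTruth(beat_rate_hz=1.0, frame_interval_s=0.05, seed=2)
        video = cf.generate_motion_video(truth, n_frames=60)
        v = video.truth_mean_velocity_um_s
        dt = truth.frame_interval_s
        # beat window: one full period starting at the first onset
        i0 = int(round(truth.start_offset_s / dt))
        i1 = i0 + int(round(1.0 / truth.beat_rate_hz / dt))
        net = np.trapezoid(v[i0 - 1 : i1], dx=dt)
        assert abs(net) < 1e-9

    def test_displacement_amplitude_guard(self):
        truth = cf.MotionTruth(
            peak_contraction_velocity_um_s=200.0,
            peak_relaxation_velocity_um_s=200.0,
        )
        assert pulse_amplitude_um(truth) / truth.pixel_size_um > 16
        with pytest.raises(ValueError, match="1/4 of the frame"):
            cf.generate_motion_video(truth, shape=(64, 64), n_frames=60)

    def test_too_few_frames(self):
        with pytest.raises(ValueError, match="two beats"):
            cf.generate_motion_video(cf.MotionTruth(), n_frames=10)


class TestGroupDataset:
    @staticmethod
    def _design(n=10, seed=0, amp_shift=None):
        base = dict(amplitude=(0.6, 0.06), decay_tau_s=(0.4, 0.04))
        mut = dict(base)
        if amp_shift is not None:
            mut["amplitude"] = amp_shift
        groups = {
            ("Corr", "Base"): GroupSpec(transient=base),
            ("Corr", "MM"): GroupSpec(transient=base),
            ("PA", "Base"): GroupSpec(transient=base),
            ("PA", "MM"): GroupSpec(transient=mut),
        }
        return GroupDesign(
            genotypes=("Corr", "PA"), treatments=("Base", "MM"),
            groups=groups, n_per_group=n, seed=seed,
        )

    def test_null_design_means_within_sampling_error(self):
        bundle = generate_group_dataset(self._design(n=50), modalities=("transient",))
        amp = bundle.truth.query("param == 'amplitude'")
        means = amp.groupby(["genotype", "treatment"])["value"].mean()
        se = 0.06 / np.sqrt(50)
        assert np.all(np.abs(means - 0.6) < 3 * se)

    def test_programmed_shift_reflected_in_truth(self):
        bundle = generate_group_dataset(
            self._design(n=80, amp_shift=(0.42, 0.042)), modalities=("transient",)
        )
        amp = bundle.truth.query("param == 'amplitude'")
        means = amp.groupby(["genotype", "treatment"])["value"].mean()
        assert means[("PA", "MM")] == pytest.approx(0.42, abs=3 * 0.042 / np.sqrt(80))
        assert means[("Corr", "MM")] == pytest.approx(0.6, abs=3 * 0.06 / np.sqrt(80))

    def test_identical_seeds_identical_bundles(self):
        a = generate_group_dataset(self._design(n=3, seed=9), modalities=("transient",))
        b = generate_group_dataset(self._design(n=3, seed=9), modalities=("transient",))
        for ca, cb in zip(a.cells, b.cells):
            np.testing.assert_array_equal(ca.trace.f340, cb.trace.f340)
        assert a.truth.equals(b.truth)

    def test_non_positive_sd_rejected(self):
        design = self._design(amp_shift=(0.42, 0.0))
        with pytest.raises(ValueError, match="non-positive SD"):
            generate_group_dataset(design, modalities=("transient",))

    def test_missing_group_rejected(self):
        design = self._design()
        design.groups.pop(("PA", "MM"))
        with pytest.raises(ValueError, match="missing parameter set"):
            generate_group_dataset(design)
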