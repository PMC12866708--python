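"""Contractility analysis of a synthetic beating-monolayer video.

Warps a textured frame with an asymmetric per-beat displacement pulse
(contraction faster than relaxation), then recovers the displacement-
velocity trace by block matching and summarizes per-beat kinetics.
"""

import numpy as np

import cardiofunc as cf

truth = cf.MotionTruth(
    peak_contraction_velocity_um_s=12.0,
    peak_relaxation_velocity_um_s=6.0,
    beat_rate_hz=1.0, beating_area_fraction=1.0,
    pixel_size_um=0.5, frame_interval_s=0.05, seed=7,
)
video = cf.generate_motion_video(truth, shape=(64, 64), n_frames=60)
vel = cf.velocity_trace(video, block_px=16, search_px=4)
kin = cf.beat_kinetics(vel)

print(f"frames analyzed     : {video.n_frames} ({video.n_frames * 0.05:.1f} s)")
print(f"max mean speed      : {np.nanmax(vel.mean_speed_um_s):.2f} um/s "
      f"(ground truth {np.max(np.abs(video.truth_mean_velocity_um_s)):.2f})")
print(f"beats found         : {kin.n_beats}")
print(f"contraction peak    : {kin.contraction_peak_um_s:.2f} um/s (true 12.0)")
print(f"relaxation peak     : {kin.relaxation_peak_um_s:.2f} um/s (true 6.0)")
print(f"contraction duration: {kin.contraction_duration_s:.3f} s")
print(f"relaxation duration : {kin.relaxation_duration_s:.3f} s")
print(f"beating area        : {kin.beating_area_fraction:.2f} (true 1.0)")
print("\nEach beat shows two speed peaks -- shortening then re-lengthening; "
      "the slower\nrelaxation produces the lower, wider second peak.")
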