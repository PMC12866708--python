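"""Extract calcium-handling kinetics from a paced ratiometric trace.

Simulates a Fura-2 recording (F340/F380 ratio pairs at 50 Hz, field-paced
at 0.5 Hz) with known kinetics, then recovers beat rate, transient
amplitude, rise time, decay tau and diastolic level from the raw channels.
"""

import cardiofunc as cf

truth = cf.TransientTruth(
    mode="ratiometric", rhythm="paced", beat_rate_hz=0.5,
    amplitude=0.6, rise_time_s=0.1, decay_tau_s=0.4, diastolic_level=0.5,
    noise_sd=0.06, duration_s=20.0, sampling_hz=50.0, seed=7,
)
trace = cf.generate_calcium_trace(truth)
features = cf.analyze_trace(trace, rhythm="paced", pacing_hz=0.5)

print("true vs estimated (ratio units / seconds):")
print(f"  beats detected : {features.n_beats} (expected {int(20 * 0.5)})")
print(f"  beat rate      : {features.beat_rate_bpm:.1f} bpm (true 30.0)")
print(f"  amplitude      : {features.amplitude:.3f} (true 0.600)")
print(f"  diastolic ratio: {features.diastolic_level:.3f} (true 0.500)")
print(f"  decay tau      : {features.decay_tau_s:.3f} s (true 0.400)")
print(f"  rise time      : {features.rise_time_s:.3f} s (~0.9x the 0.100 s ramp)")
print(f"  decay fit r^2  : {features.fit_r2:.3f}")
print("\nDecay tau is the time constant of the per-beat exponential fit "
      "(calcium reuptake);\nthe rise time is measured from the 10%-amplitude "
      "onset, hence ~0.9x the linear ramp.")
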