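"""Score sarcomere organization of synthetic striation images.

Generates two alpha-actinin-like striation images -- one well organized,
one with jittered Z-disc positions -- and scores both.  "Power" is the
fraction of off-DC spectral energy at the primary peak (higher = more
regular striations); "period" is the recovered sarcomere length in um.
"""

import cardiofunc as cf

for label, jitter in (("organized", 0.05), ("disarrayed", 0.35)):
    truth = cf.StriationTruth(
        period_um=1.8, jitter_sigma_um=jitter, noise_sd=100.0, seed=42
    )
    image = cf.generate_striation_image(truth, shape=(256, 256), pixel_size_um=0.1)
    score = cf.score_sarcomere(image, band_um=(1.2, 3.0))
    print(f"{label:>11}: power={score.power:.3f}  period={score.period_um:.3f} um  "
          f"orientation={score.orientation_deg:.1f} deg")

print("\nThe disarrayed image keeps the same period (the mean spacing is "
      "unchanged)\nbut loses spectral power: positional disorder spreads "
      "energy off the peak.")
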