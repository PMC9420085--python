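"""Synthetic pseudo-micrographs and analysis robustness under disorder.

Generates noisy filament images (site jitter, blur, additive noise),
measures the javelin striation tilt through blur, and traces how meridional
detection degrades as disorder grows.
"""

from myohelix import (
    NoiseModel,
    degradation_curve,
    detect_layer_lines,
    generate_micrograph,
    measure_tilt,
    power_spectrum,
)

noise = NoiseModel(jitter_nm=1.0, blur_nm=1.0, additive_sigma=0.2, seed=7)
mask = generate_micrograph("filament", noise=noise, size=(1032, 64))
lines = detect_layer_lines(power_spectrum(mask), repeat_nm=172.0)
meridionals = [l.spacing for l in lines if l.meridional]
print(f"noisy filament (jitter 1 nm, blur 1 nm, noise 0.2): meridionals {meridionals}")

javelin = generate_micrograph(
    "javelin", noise=NoiseModel(blur_nm=2.0, seed=1), size=(512, 512), tilt_deg=6.5
)
tilt = measure_tilt(power_spectrum(javelin, window="hann"), 7.15)
print(f"javelin rendered at 6.5 degrees, blurred 2 nm: measured tilt {tilt:.2f} degrees")

grid = [NoiseModel(), NoiseModel(jitter_nm=2.0), NoiseModel(jitter_nm=4.0),
        NoiseModel(jitter_nm=4.0, additive_sigma=2.0)]
table = degradation_curve("meridional_detected", grid, n_seeds=4)
print("\nmeridional detection vs disorder:")
print(table[["jitter_nm", "additive_sigma", "mean", "sd"]].to_string(index=False))
# Detection probability falls as jitter and noise grow; the 14.3 nm crown
# reflection is the most disorder-tolerant feature, as in real micrographs.
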