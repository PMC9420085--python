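"""Derive the helical parameters of the smooth-muscle myosin filament.

Three strands, a subunit translation of two crown spacings (2 x 172/12 nm)
and a 20 degree twist per subunit fix the whole lattice: the pitch, the
translational repeat, and the layer-line spacings the repeat predicts.
"""

from myohelix import CROWN_SPACING_NM, derive_params, predicted_layer_lines, rod_coverage

params = derive_params(3, 2.0 * CROWN_SPACING_NM, 20.0)
print(f"strands:            {params.n_strands}")
print(f"subunit translation {params.residue_translation:.2f} nm")
print(f"pitch:              {params.pitch:.1f} nm   (one 360-degree turn of a strand)")
print(f"repeat:             {params.repeat:.1f} nm   (lattice maps onto itself)")
print(f"crown spacing:      {params.crown_spacing:.2f} nm  ({params.crowns_per_repeat} crowns per repeat)")

print("\npredicted layer lines (order, spacing nm):")
for order, spacing in predicted_layer_lines(params.repeat, 7):
    print(f"  l={order}:  {spacing:6.1f}")

print(f"\na 150 nm rod covers {rod_coverage(150.0, 14.3)} crown repeats")
# The 516 nm pitch equals 3 x 172 nm: one strand completes a turn in
# exactly three repeats, and the 86/57.3/34.4/24.6 nm lines are the
# repeat's 2nd, 3rd, 5th and 7th orders.
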