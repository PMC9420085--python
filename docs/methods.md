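# Methods

## The lattice model

The filament surface is treated as an unrolled cylinder of circumference
`C` (default 60 nm — a rendering choice, not a structural datum) carrying
transverse crowns of cross-bridges every `Δz` nm. A lattice is specified by
the strand count `n`, the axial subunit translation `t` and the azimuthal
twist per subunit `ω`; the pitch follows as `P = 360°·t/ω` and the repeat
`c` is the smallest `k·t` for which `k·ω` is a multiple of the strand phase
`360°/n` (the translated lattice maps onto itself with the strands
permuted). The repeat search runs over integer subunit counts through
exact rational arithmetic on `ω·n/360`, so bin-exact lattices carry no
floating-point drift.

Crown spacing is tied to the subunit translation through
`crowns_per_subunit`: the default smooth-muscle lattice places **two** head
crowns per subunit translation (`t = 2·Δz`, the "2 × 14.3 nm" stagger of
the building units), giving `Δz = 172/12` nm exactly. The historical
short-repeat lattice uses one crown per subunit; it is provided as
`OLD_MODEL_72` with `Δz = 72/5 = 14.4` nm so that it, too, is exact on its
own grid (the printed value 14.3 nm does not divide 72). All printed unit
lengths (258, 344, 516 nm) are integer multiples of the default
`Δz = 172/12`, which is why the grid is defined as the fraction rather than
the rounded 14.3.

Bridge sites sit at azimuth `s·(360°/n) + k·ω·Δz/t` for strand `s` and
crown `k`. Handedness (a free boolean; the data do not determine it) sets
the sign of the per-crown twist. Under the trv scheme the polarity of a
site is `+1` when its azimuthal row index (azimuth divided by the row step,
the gcd of per-crown twist and strand phase) is even — adjacent rows are
then oppositely polarized; the phase convention (which row is "+") is
arbitrary and fixed to even-row-positive. Crowns occupy the half-open
interval `[0, L)`, which makes counts per repeat exact (12 crowns, 36
sites, 2 × 18 azimuthal rows per 172 nm).

## Building units

The 150 nm myosin rod spans 11 crowns; a polar trimer staggers three
molecules by 3 crowns (~43 nm) and spans 17 crowns. These two integers are
the unique small-integer reconstruction consistent with the printed hexamer
lengths: variant A (inter-trimer offset 1 crown) spans 18 crowns = 258 nm
with a 16-crown ≈ 229.3 nm overlap (printed as 230 nm), variant B (offset
7) spans 24 crowns = 344 nm. Heads are placed at the *inboard* end of each
molecule, so the two head groups of a hexamer interlock head-to-head inside
the unit and the terminal crowns carry bare rod. The alternative
(outboard) placement would put heads on the terminal crowns and leave no
smooth ends, contradicting the observed cross-bridge-free end segments, and
was rejected. Elongation appends units alternately at the two ends on a
deterministic schedule (odd-numbered units high, even low); the `seed`
argument is reserved for a future stochastic growth mode. Growth per unit
is `span − overlap`, occupancy is gap-free, and every assembled strand ends
in two rod-only smooth segments.

The cross-section packs 18 rod circles as six trimer triangles on a ring
with exact six-fold symmetry. The tight variant relocates each trimer's
innermost rod (its SF2 neck) onto an inner ring and pulls the outer pair
inward, shrinking the bounding circle by ~11 % (bounded above by the
reported 20 %).

## Rendering and polarity

Masks are binary (background 0, foreground 1, film-mask contrast), stamped
analytically at pixel centres so renders are bit-reproducible, with
overlaps saturating at 1. The "bunny-ears L 90°" motif is concretized as
two 6 × 3 nm elliptical lobes at right angles — one axial, one lateral —
with the inner corner anchored on the lattice node; the lobe dimensions are
free parameters (no source geometry exists). The lateral lobe makes the
motif chiral, which is what lets polarity reach the diffraction pattern.
The strip is cylindrically periodic: stamps crossing the seam wrap to the
other side, so the lateral structure carries exact lattice combs and no
seam artefacts.

Polarity −1 mirrors the motif about the vertical axis *in place* (the head
pair points the other way on its node). Reversing the polarity of *every*
bridge is a mirror operation on the whole filament, so the uniformly
left-polarized filament is rendered as the mirror enantiomorph — handedness
reversed along with the motifs. Two exact consequences, both tested: the
left mask is the pixel-exact mirror image of the right mask (hence exactly
mirrored power spectra and `S_left = S_right` to machine precision), and
the trv lattice, where rows share one handedness and only motifs alternate,
doubles the lateral period of the polarity decoration. An early variant
that mirrored the *placement* of −1 sites instead was discarded: it
restores the uniform lateral comb at the crown frequency and therefore
erases the satellite that distinguishes mixed from uniform polarity.

The default diffraction canvas is 1032 × 120 px at 1 nm/px: the height is
2 × 516 nm, so every order of the 172 nm repeat falls exactly on an FFT
bin and the printed spacings are read off without interpolation (the 72 nm
lattice uses 1008 px = 14 repeats the same way). Widths of 60 or 120 px
are laterally commensurate with the lattice combs; satellite detection
assumes such a canvas.

## Spectra and observables

Power spectra are mean-subtracted 2D DFTs, squared modulus, DC-centred,
calibrated in cycles/nm. No window is applied on bin-exact canvases;
a Hann window is used otherwise (tilt measurement on paracrystals), since
windows trade peak sharpness for leakage control.

Layer-line detection integrates power laterally — the meridian band is the
3 central columns, everything else is off-meridional — and finds peaks on
the positive-frequency axial profile with prominence ≥ 2 % of the maximum
non-DC profile power. Spacings are `1/frequency` with 3-point parabolic
sub-bin refinement (exactly zero shift on bin-exact peaks), reported to
0.1 nm half-up (the field's printed precision); equal rounded spacings keep
the stronger peak. A reflection is meridional when the lateral centroid of
its contiguous peak (bins ≥ 10 % of the row maximum around the row argmax)
lies within one bin of the meridian; the contiguous-run restriction stops
satellite columns and the noise floor from dragging the centroid. Orders
are assigned as `round(repeat/spacing)` against a stated repeat and capped
at 24 (beyond the interpreted range); assignment plays no role in detection.

Tilt is the signed angle between the meridian and the line from the origin
to the reflection nearest the target spacing, refined by a 5 × 5
power-weighted centroid; an annulus whose maximum does not stand 5× above
its mean raises a not-found error rather than returning a number.

The symmetry index `S = 1 − Σ|I_L − I_R|/Σ(I_L + I_R)` sums off-meridional
intensity on either side of the meridian band (the unpaired most-negative
frequency column of even-width canvases is excluded so mirrored spectra
give exactly swapped sums). It is undefined (raises) when only meridional
reflections exist.

Satellite detection: uniform polarity samples lateral frequency in columns
spaced `1/d_row` (`d_row` = azimuthal row spacing × circumference / 360°);
trv decoration doubles the lateral period and populates the half-way column
at `0.5/d_row` — the first column beside the 14.3 nm meridional. Only the
bin(s) nearest `±0.5/d_row` are measured, which keeps the principal columns
and their sampling aliases out of the window; presence requires power
≥ 10⁻⁴ of the meridional peak, four orders of magnitude above rasterization
residue in the uniform schemes and ~6× below the trv satellite. The crown
meridional itself must be a local peak carrying ≥ 1 % of the meridional
profile maximum, otherwise the result is "not applicable".

## Indexing

Residuals are computed in reciprocal space, `Σ (1/d − l/c)²` with
`l = round(c/d) ≥ 1`, because FFT bin error is uniform in frequency.
Observations assigned `l > 24` are excluded for that candidate. Candidates
are ranked by the **mean** residual over the observations they index — a
summed residual would reward the candidate that excludes the most
observations — with ties broken to the candidate indexing more lines, then
to the smaller repeat. On noiseless synthetic observations the generating
repeat scores zero.

## Synthetic micrographs

The generator emulates negative-stain/section pseudo-micrographs:
lattice-preserving per-site positional jitter (σ in nm) and orientation
jitter (σ in degrees) before rasterization — matching the 2D mask
abstraction, not per-molecule elastic deformation — then Gaussian blur
(point-spread σ in nm), an optional linear background gradient, and
additive Gaussian pixel noise. One seed expands into fixed per-stage
substreams so stages re-run independently and outputs are byte-identical
across runs. Pixel values are not clipped after additive noise, so the
requested σ is preserved exactly (image writers normalize at export).
What the generator does **not** model: contrast transfer function, stain
granularity, front/back superposition of the cylinder, or bending
flexibility — so passing tests show robustness of the analysis to
site-level disorder and detector noise, not to every failure mode of real
micrographs.

Degradation curves run the full pipeline per noise level and seed on a
single-repeat-scale canvas (516 × 64 px) so a grid completes in seconds;
detection probability falls with disorder as a trend, which is asserted as
such rather than as strict monotonicity.

## Problem sizes and numerical choices

Default problem sizes: diffraction canvases of 1032 × 120 px (six repeats),
1008 px for the short lattice, 512² for tilt work, and 1000 trials for the
repeat-recovery experiment (spacing jitter σ = 0.5 nm on each lattice's
observable orders, including order 1, which both source patterns show).
These complete in seconds while keeping every reported quantity bin-exact.
Ties, tolerances and degenerate inputs: half-up rounding at 0.1 nm;
1 × 10⁻⁹ nm tolerance on crown-boundary inclusion; constant images yield a
flagged all-zero spectrum and an empty line list rather than an error.

## Known limitations

The 2D model cannot express the "long trimer" unit with simultaneous
14.3 nm and 86 nm overlap regions (its geometry is under-determined by a
single offset parameter), does not model Bessel-order amplitudes of true
helical diffraction, and treats the hexamer as one strand segment — whether
its two trimers share an azimuth is left open. The row count is reported
both ways (36 distinct azimuths; 18 per polarity class) since the "2 × 18"
bookkeeping convention is ambiguous. The near-coincidence of the 72 nm and
172 nm head positions around 430 nm (2.5 × 172 = 430 vs 6 × 72 = 432) is
not an exact common multiple and no operation asserts it.
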