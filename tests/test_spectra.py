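"""Power spectra and the observables read from them: layer lines,
meridionals, tilt, symmetry index and the polarity satellite."""

import numpy as np
import pytest

from myohelix import (
    DEFAULT_PARAMS,
    BridgeSite,
    MaskImage,
    ParameterError,
    PeakNotFoundError,
    detect_layer_lines,
    detect_satellite,
    measure_tilt,
    power_spectrum,
    render_mask,
    render_paracrystal,
    symmetry_index,
)

CS = DEFAULT_PARAMS.crown_spacing


class TestPowerSpectrum:
    def test_vertical_grating_peaks_at_expected_frequency(self):
        mask = render_paracrystal(0.0, 8.0, width_px=64, height_px=64)
        ps = power_spectrum(mask)
        r, c = np.unravel_index(np.argmax(ps.power), ps.power.shape)
        assert abs(ps.freq_axial[r]) == pytest.approx(1.0 / 8.0, abs=1e-9)
        assert ps.freq_lateral[c] == pytest.approx(0.0, abs=1e-9)

    def test_parseval_identity(self, scheme_masks):
        mask = scheme_masks["trv"]
        img = mask.pixels - mask.pixels.mean()
        ps = power_spectrum(mask)
        assert ps.power.sum() == pytest.approx(
            img.size * (img**2).sum(), rel=1e-6
        )

    def test_friedel_symmetry(self, scheme_spectra):
        p = scheme_spectra["trv"].power
        inverted = np.roll(np.roll(p[::-1, ::-1], 1, axis=0), 1, axis=1)
        assert np.allclose(p, inverted, rtol=1e-9, atol=p.max() * 1e-12)

    def test_mirrored_image_gives_mirrored_spectrum(self, scheme_masks):
        mask = scheme_masks["trv"]
        mirrored = MaskImage(mask.pixels[:, ::-1].copy(), mask.nm_per_px)
        p = power_spectrum(mask).power
        q = power_spectrum(mirrored).power
        assert np.allclose(q, np.roll(p[:, ::-1], 1, axis=1), rtol=1e-9,
                           atol=p.max() * 1e-12)

    def test_degenerate_image_flagged(self):
        ps = power_spectrum(MaskImage(np.ones((16, 16)), 1.0))
        assert ps.metadata["degenerate"]
        assert not ps.power.any()
        assert detect_layer_lines(ps) == []

    def test_too_small_image_rejected(self):
        with pytest.raises(ParameterError):
            power_spectrum(MaskImage(np.zeros((4, 4)), 1.0))


class TestDetectLayerLines:
    def test_default_lattice_printed_spacings(self, scheme_spectra):
        spacings = {
            l.spacing for l in detect_layer_lines(scheme_spectra["trv"], repeat_nm=172.0)
        }
        assert {86.0, 57.3, 34.4, 24.6} <= spacings

    def test_old_lattice_spacings(self, old_lattice_spectrum):
        spacings = {
            l.spacing
            for l in detect_layer_lines(old_lattice_spectrum, repeat_nm=72.0)
        }
        assert {36.0, 24.0} <= spacings

    def test_crown_only_mask_dominant_meridional(self):
        """Crowns without helical offsets give only meridional reflections,
        dominated by the crown spacing."""
        from myohelix import Motif

        sites = [
            BridgeSite(c * CS, 20.0 * s, 120.0 * s, s, c, +1)
            for c in range(72)
            for s in range(3)
        ]
        mask = render_mask(sites, Motif(shape="dot"), height_px=1032, width_px=120)
        lines = detect_layer_lines(power_spectrum(mask), repeat_nm=172.0)
        assert lines, "no reflections found"
        dominant = max(lines, key=lambda l: l.power)
        assert dominant.meridional
        assert dominant.spacing == pytest.approx(14.3, abs=0.05)

    def test_intensity_scaling_invariance(self, scheme_masks):
        mask = scheme_masks["trv"]
        scaled = MaskImage(mask.pixels * 7.5, mask.nm_per_px, dict(mask.metadata))
        a = detect_layer_lines(power_spectrum(mask), repeat_nm=172.0)
        b = detect_layer_lines(power_spectrum(scaled), repeat_nm=172.0)
        assert [(l.order, l.spacing, l.meridional) for l in a] == [
            (l.order, l.spacing, l.meridional) for l in b
        ]

    def test_oracle_equivalence_with_predicted_lines(self, scheme_spectra):
        """On a bin-exact canvas every detected spacing equals repeat/l after
        0.1 nm rounding, for its assigned order."""
        from myohelix import predicted_layer_lines

        predicted = dict(predicted_layer_lines(172.0, 24))
        for line in detect_layer_lines(scheme_spectra["trv"], repeat_nm=172.0):
            assert line.spacing == predicted[line.order]


class TestMeasureTilt:
    def test_zero_tilt_paracrystal(self):
        mask = render_paracrystal(0.0, 7.15, width_px=512, height_px=512)
        tilt = measure_tilt(power_spectrum(mask, window="hann"), 7.15)
        assert abs(tilt) < 0.5

    @pytest.mark.parametrize("angle", [6.5, -6.5])
    def test_javelin_tilt_recovered(self, angle):
        mask = render_paracrystal(angle, 7.15, width_px=512, height_px=512)
        tilt = measure_tilt(power_spectrum(mask, window="hann"), 7.15)
        assert tilt == pytest.approx(angle, abs=0.5)

    def test_antisymmetry(self):
        pos = render_paracrystal(4.0, 14.3, width_px=256, height_px=256)
        neg = render_paracrystal(-4.0, 14.3, width_px=256, height_px=256)
        t_pos = measure_tilt(power_spectrum(pos, window="hann"), 14.3)
        t_neg = measure_tilt(power_spectrum(neg, window="hann"), 14.3)
        assert t_pos == pytest.approx(-t_neg, abs=0.05)

    def test_missing_reflection_raises(self):
        mask = render_paracrystal(0.0, 7.15, width_px=128, height_px=128)
        with pytest.raises(PeakNotFoundError):
            measure_tilt(power_spectrum(mask), target_spacing=40.0, tolerance=2.0)


class TestSymmetryIndex:
    def test_trv_more_balanced_than_uniform(self, scheme_spectra):
        S = {
            s: symmetry_index(detect_layer_lines(ps, repeat_nm=172.0))
            for s, ps in scheme_spectra.items()
        }
        assert S["trv"] > S["left"]
        assert S["trv"] > S["right"]

    def test_left_equals_right_exactly(self, scheme_spectra):
        S_left = symmetry_index(detect_layer_lines(scheme_spectra["left"], repeat_nm=172.0))
        S_right = symmetry_index(detect_layer_lines(scheme_spectra["right"], repeat_nm=172.0))
        assert S_left == pytest.approx(S_right, abs=1e-6)

    def test_perfectly_mirrored_spectrum_gives_one(self):
        from myohelix.spectra import LayerLine

        lines = [
            LayerLine(2, 86.0, 5.0, 5.0, False, 0.0, 10.0, 1 / 86.0),
            LayerLine(3, 57.3, 2.0, 2.0, False, 0.0, 4.0, 1 / 57.3),
        ]
        assert symmetry_index(lines) == pytest.approx(1.0)

    def test_meridional_only_undefined(self):
        from myohelix.spectra import LayerLine

        lines = [LayerLine(12, 14.3, 1.0, 1.0, True, 0.0, 2.0, 1 / 14.3)]
        with pytest.raises(ValueError):
            symmetry_index(lines)


class TestSatellite:
    def test_present_only_under_trv(self, scheme_spectra):
        flags = {s: detect_satellite(ps) for s, ps in scheme_spectra.items()}
        assert flags["trv"].present
        assert not flags["left"].present
        assert not flags["right"].present
        assert all(f.applicable for f in flags.values())

    def test_satellite_sits_beside_meridional(self, scheme_spectra):
        sat = detect_satellite(scheme_spectra["trv"])
        # first off-meridional column: half the principal column frequency
        row_spacing = 60.0 * 10.0 / 360.0
        assert sat.lateral_offset == pytest.approx(0.5 / row_spacing, abs=1e-6)

    def test_not_applicable_without_meridional(self):
        mask = render_paracrystal(0.0, 40.0, width_px=64, height_px=64)
        result = detect_satellite(
            power_spectrum(mask), crown_spacing_nm=CS, row_spacing_nm=5 / 3
        )
        assert not result.applicable
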