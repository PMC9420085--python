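"""Building-unit hierarchy: trimer/hexamer spans, filament elongation and
cross-sectional packing."""

import math

import numpy as np
import pytest

from myohelix import (
    CROWN_SPACING_NM,
    ParameterError,
    assemble_filament,
    build_hexamer,
    build_trimer,
    cross_section_layout,
)


class TestTrimer:
    def test_default_span_matches_printed_geometry(self):
        # oracle: (258 + 230) / 2 = 244 nm from the printed hexamer span and
        # overlap; the 17-crown trimer is 243.7 nm on the exact grid
        t = build_trimer(stagger_crowns=3)
        assert t.span_crowns == 17
        assert t.span_nm == pytest.approx((258.0 + 230.0) / 2.0, abs=0.5)

    @pytest.mark.parametrize("stagger,span", [(0, 11), (1, 13), (3, 17)])
    def test_span_arithmetic(self, stagger, span):
        assert build_trimer(stagger_crowns=stagger).span_crowns == span

    def test_head_crowns_polarity(self):
        low = build_trimer(polarity=-1)
        high = build_trimer(polarity=+1)
        assert low.head_crowns() == [0, 3, 6]
        assert high.head_crowns() == [10, 13, 16]


class TestHexamer:
    def test_variant_a_span_258(self):
        assert build_hexamer("A").span_nm == pytest.approx(258.0)

    def test_variant_b_span_344(self):
        assert build_hexamer("B").span_nm == pytest.approx(344.0)

    def test_variant_a_overlap(self):
        h = build_hexamer("A")
        assert h.overlap_crowns == 16
        # printed as "230 nm overlap"; exact grid value is 229.3
        assert h.overlap_nm == pytest.approx(229.33, abs=0.01)
        assert 229.0 <= h.overlap_nm <= 230.0

    def test_span_overlap_identity(self):
        for variant in ("A", "B"):
            h = build_hexamer(variant)
            assert h.span_crowns + h.overlap_crowns == 2 * h.trimer.span_crowns

    def test_spans_are_crown_multiples(self):
        for variant in ("A", "B"):
            h = build_hexamer(variant)
            for value in (h.span_nm, h.overlap_nm):
                assert value / CROWN_SPACING_NM == pytest.approx(
                    round(value / CROWN_SPACING_NM), abs=1e-9
                )

    def test_antiparallel_heads(self):
        heads = build_hexamer("A").head_crowns()
        assert sum(heads.values()) == 0

    def test_unknown_variant(self):
        with pytest.raises(ParameterError):
            build_hexamer("C")


class TestAssembly:
    def test_single_unit_lengths(self):
        assert assemble_filament(1, "A").total_length == pytest.approx(258.0)
        assert assemble_filament(1, "B").total_length == pytest.approx(344.0)

    @pytest.mark.parametrize("variant", ["A", "B"])
    @pytest.mark.parametrize("n", [1, 2, 3, 7, 12])
    def test_length_formula_matches_occupancy(self, variant, n):
        """Total length follows span + (n-1)(span - overlap), and equals the
        brute-force extent of the union of unit intervals."""
        h = build_hexamer(variant)
        strand = assemble_filament(n, variant)
        expected = (h.span_crowns + (n - 1) * (h.span_crowns - h.overlap_crowns)) * CROWN_SPACING_NM
        assert strand.total_length == pytest.approx(expected)
        occupied = sorted(strand.rod_cover)
        assert (occupied[-1] - occupied[0] + 1) * CROWN_SPACING_NM == pytest.approx(expected)

    @pytest.mark.parametrize("n", [1, 2, 5, 10])
    def test_no_interior_bare_zone(self, n):
        assert not assemble_filament(n, "A").has_interior_gap()

    @pytest.mark.parametrize("variant", ["A", "B"])
    def test_smooth_ends_at_both_ends(self, variant):
        for n in (1, 3, 6):
            strand = assemble_filament(n, variant)
            low, high = strand.smooth_end_lengths
            assert low > 0 and high > 0

    def test_deterministic_and_monotone(self):
        lengths = [assemble_filament(n, "A", seed=5).total_length for n in range(1, 8)]
        again = [assemble_filament(n, "A", seed=5).total_length for n in range(1, 8)]
        assert lengths == again
        assert all(b > a for a, b in zip(lengths, lengths[1:]))

    def test_every_unit_is_bipolar(self):
        strand = assemble_filament(4, "A")
        assert sum(sum(v) for v in strand.heads.values()) == 0


class TestCrossSection:
    def test_loose_layout_counts(self):
        cs = cross_section_layout(tight=False)
        assert cs.coords.shape == (18, 2)
        assert len(np.unique(cs.trimer_index)) == 6

    def test_sixfold_rotation_symmetry(self):
        cs = cross_section_layout(tight=False)
        theta = math.radians(60.0)
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        rotated = cs.coords @ rot.T
        orig = {tuple(np.round(p, 9)) for p in cs.coords}
        assert {tuple(np.round(p, 9)) for p in rotated} == orig

    def test_tight_reduces_diameter_at_most_20_percent(self):
        loose = cross_section_layout(tight=False).bounding_diameter
        tight = cross_section_layout(tight=True).bounding_diameter
        reduction = (loose - tight) / loose
        assert 0.0 < reduction <= 0.20
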