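"""Closed-form lattice geometry: derived parameters, predicted layer lines,
site generation and row counting."""

import math

import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from myohelix import (
    CROWN_SPACING_NM,
    DEFAULT_PARAMS,
    OLD_MODEL_72,
    HelixParams,
    ParameterError,
    derive_params,
    generate_sites,
    predicted_layer_lines,
    rod_coverage,
    rows_per_repeat,
    sites_to_dataframe,
)


class TestDeriveParams:
    @pytest.mark.parametrize(
        "n,translation,twist,pitch,repeat",
        [
            (3, 2 * CROWN_SPACING_NM, 20.0, 516.0, 172.0),
            (1, 40.0, 360.0 - 1e-9, 40.0, 40.0),
            (3, 14.4, 48.0, 108.0, 72.0),
        ],
    )
    def test_pitch_and_repeat(self, n, translation, twist, pitch, repeat):
        p = derive_params(n, translation, twist)
        assert p.pitch == pytest.approx(pitch, abs=1e-6)
        assert p.repeat == pytest.approx(repeat, abs=1e-6)

    def test_old_model_pitch(self):
        # the historical short-repeat lattice: ~14.3 nm translation, 108 pitch
        p = derive_params(3, 14.3, 47.67, crowns_per_subunit=1)
        assert p.pitch == pytest.approx(108.0, rel=1e-3)

    def test_twist_round_trip(self):
        p = derive_params(3, 2 * CROWN_SPACING_NM, 20.0)
        twist_back = 360.0 * p.residue_translation / p.pitch
        assert twist_back == pytest.approx(p.twist_per_subunit, rel=1e-9)

    @pytest.mark.parametrize("bad", [(0, 10.0, 20.0), (3, -1.0, 20.0), (3, 10.0, 0.0)])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ParameterError):
            derive_params(*bad)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        translation=st.floats(1.0, 100.0),
        k=st.integers(1, 24),
        n=st.sampled_from([1, 2, 3, 6]),
    )
    def test_round_trip_property(self, translation, k, n):
        """Recomputing twist from the derived pitch returns the input."""
        assume(n * k >= 2)
        twist = 360.0 / (n * k)  # guarantees a k-subunit repeat
        p = derive_params(n, translation, twist)
        assert 360.0 * translation / p.pitch == pytest.approx(twist, rel=1e-9)
        assert p.repeat == pytest.approx(k * translation, rel=1e-9)


class TestPredictedLayerLines:
    def test_printed_spacings_172(self):
        spacings = [s for _, s in predicted_layer_lines(172.0, 7)]
        assert spacings == [172.0, 86.0, 57.3, 43.0, 34.4, 28.7, 24.6]

    def test_printed_spacings_72(self):
        assert [s for _, s in predicted_layer_lines(72.0, 3)] == [72.0, 36.0, 24.0]

    def test_first_order_is_repeat(self):
        assert predicted_layer_lines(123.4, 1) == [(1, 123.4)]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(repeat=st.floats(61.0, 500.0), max_order=st.integers(2, 24))
    def test_strictly_decreasing(self, repeat, max_order):
        # repeat large enough that 0.1 nm rounding cannot merge neighbours
        spacings = [s for _, s in predicted_layer_lines(repeat, max_order)]
        assert all(a > b for a, b in zip(spacings, spacings[1:]))


class TestGenerateSites:
    def test_default_repeat_counts(self):
        sites = generate_sites(DEFAULT_PARAMS, 172.0, "trv")
        assert len(sites) == 36
        assert len({s.crown_index for s in sites}) == 12

    def test_zero_length_empty(self):
        assert generate_sites(DEFAULT_PARAMS, 0.0, "left") == []

    def test_left_is_right_with_flipped_polarity(self):
        left = generate_sites(DEFAULT_PARAMS, 172.0, "left")
        right = generate_sites(DEFAULT_PARAMS, 172.0, "right")
        assert [(s.axial, s.azimuth, -s.polarity) for s in left] == [
            (s.axial, s.azimuth, s.polarity) for s in right
        ]

    def test_unknown_scheme(self):
        with pytest.raises(ParameterError):
            generate_sites(DEFAULT_PARAMS, 172.0, "sideways")

    @pytest.mark.parametrize("length", [10.0, 14.4, 100.0, 172.0, 516.0])
    def test_count_matches_brute_force(self, length):
        """Site count equals the brute-force crown enumeration on [0, length)."""
        cs = DEFAULT_PARAMS.crown_spacing
        crowns = sum(1 for c in range(1000) if c * cs < length - 1e-9)
        sites = generate_sites(DEFAULT_PARAMS, length, "trv")
        assert len(sites) == DEFAULT_PARAMS.bridges_per_crown * crowns

    def test_axial_positions_on_crown_grid(self):
        cs = DEFAULT_PARAMS.crown_spacing
        for s in generate_sites(DEFAULT_PARAMS, 516.0, "right"):
            assert s.axial == pytest.approx(s.crown_index * cs, abs=1e-9)

    def test_repeat_translation_invariance(self):
        """Translating the default lattice by one repeat maps it onto itself."""
        sites = generate_sites(DEFAULT_PARAMS, 2 * 172.0, "trv")
        first = {
            (round(s.axial, 6), round(s.azimuth, 6), s.polarity)
            for s in sites
            if s.axial < 172.0 - 1e-9
        }
        second = {
            (round(s.axial - 172.0, 6), round(s.azimuth, 6), s.polarity)
            for s in sites
            if s.axial >= 172.0 - 1e-9
        }
        assert first == second

    def test_trv_adjacent_rows_alternate(self):
        sites = generate_sites(DEFAULT_PARAMS, 172.0, "trv")
        by_azimuth = {}
        for s in sites:
            by_azimuth.setdefault(round(s.azimuth, 6), set()).add(s.polarity)
        azimuths = sorted(by_azimuth)
        assert all(len(v) == 1 for v in by_azimuth.values())
        pols = [by_azimuth[a].pop() for a in azimuths]
        assert all(a * b == -1 for a, b in zip(pols, pols[1:]))


class TestRowsPerRepeat:
    def test_default_lattice_two_times_eighteen(self):
        rc = rows_per_repeat(DEFAULT_PARAMS)
        assert rc.per_polarity == {+1: 18, -1: 18}
        assert rc.total == 36

    def test_single_untwisted_strand_one_row(self):
        p = HelixParams(
            n_strands=1,
            residue_translation=14.4,
            twist_per_subunit=360.0 - 1e-12,
            repeat=14.4,
            pitch=14.4,
            crowns_per_repeat=1,
            bridges_per_crown=1,
            strand_phase=360.0,
        )
        assert rows_per_repeat(p).total == 1

    @pytest.mark.parametrize("params", [DEFAULT_PARAMS, OLD_MODEL_72])
    def test_matches_brute_force_enumeration(self, params):
        sites = generate_sites(params, params.repeat, "trv")
        brute = len({round(s.azimuth, 6) for s in sites})
        assert rows_per_repeat(params).total == brute


class TestRodCoverage:
    @pytest.mark.parametrize(
        "rod,cs,expected",
        [(150.0, 14.3, 10.5), (14.3, 14.3, 1.0), (143.0, 14.3, 10.0)],
    )
    def test_examples(self, rod, cs, expected):
        assert rod_coverage(rod, cs) == expected

    def test_invalid(self):
        with pytest.raises(ParameterError):
            rod_coverage(-1.0, 14.3)


class TestSerialization:
    def test_params_dict_round_trip(self):
        d = DEFAULT_PARAMS.to_dict()
        assert HelixParams.from_dict(d) == DEFAULT_PARAMS

    def test_unknown_key_rejected(self):
        with pytest.raises(ParameterError):
            HelixParams.from_dict({"n_strands": 3, "colour": "red"})

    def test_sites_dataframe_columns(self):
        frame = sites_to_dataframe(generate_sites(DEFAULT_PARAMS, 172.0, "trv"))
        assert list(frame.columns) == [
            "crown_index",
            "strand_index",
            "axial_nm",
            "azimuth_deg",
            "lateral_nm",
            "polarity",
            "orientation_deg",
        ]
        assert len(frame) == 36
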