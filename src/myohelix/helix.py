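"""Helical lattice parameterization of the smooth-muscle myosin thick filament.

The filament surface is modelled as an unrolled cylinder carrying transverse
*crowns* of myosin-head pairs every ``crown_spacing`` nanometres.  The default
parameterization is a three-strand helix with a 172 nm translational repeat,
a 516 nm single-strand pitch and a subunit (building-unit) axial translation
of twice the crown spacing, i.e. 2 x 172/12 ~ 28.7 nm.  Crown spacing is held
at exactly 172/12 nm so that every printed unit length (258, 344, 516 nm) is
exact on the crown grid.

All closed-form geometry lives here: derived pitch/repeat, predicted
layer-line spacings (``repeat / l``), bridge-site enumeration with polarity
schemes, azimuthal row counting and rod-coverage arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CROWN_SPACING_NM",
    "DEFAULT_PARAMS",
    "OLD_MODEL_72",
    "BridgeSite",
    "HelixParams",
    "ParameterError",
    "RowCount",
    "derive_params",
    "generate_sites",
    "predicted_layer_lines",
    "rod_coverage",
    "rows_per_repeat",
    "round_spacing",
    "sites_to_dataframe",
]

#: Exact crown spacing of the default lattice (printed as 14.3 nm).
CROWN_SPACING_NM = 172.0 / 12.0

PolarityScheme = Literal["left", "right", "trv"]
SCHEMES: tuple[str, ...] = ("left", "right", "trv")

_TOL = 1e-9


class ParameterError(ValueError):
    """Raised for invalid helical parameters or scheme identifiers."""


def round_spacing(value: float, decimals: int = 1) -> float:
    """Round half-up to the given number of decimals (reporting convention).

    Python's builtin ``round`` rounds half-to-even; printed spacings in the
    field round half-up (172/7 = 24.57 -> 24.6).
    """
    factor = 10.0**decimals
    return math.floor(value * factor + 0.5) / factor


@dataclass(frozen=True)
class HelixParams:
    """Parameterization of the helical cross-bridge lattice.

    Parameters
    ----------
    n_strands
        Number of coaxial helical strands (3 in the proposed model; 6 is the
        historical alternative).
    residue_translation
        Axial rise per subunit along one strand, nm.  For the default model a
        subunit spans two head crowns (the 2 x 14.3 nm stagger), hence
        2 x 172/12 nm.
    twist_per_subunit
        Azimuthal rotation per subunit, degrees.  Tied to the pitch through
        ``pitch * twist_per_subunit = 360 * residue_translation``.
    repeat
        Smallest axial translation mapping the lattice onto itself, nm.
    pitch
        Axial rise for one full 360 degree turn of a single strand, nm.
    crowns_per_repeat
        Number of head crowns inside one repeat.
    bridges_per_crown
        Cross-bridges per crown (one per strand in the default model).
    strand_phase
        Azimuthal separation of neighbouring strands, degrees.
    circumference
        Circumference of the unrolled filament surface, nm.  A rendering
        choice, not a structural datum.
    handedness
        +1 right-handed (default), -1 left-handed.  The source data do not
        determine handedness.
    """

    n_strands: int = 3
    residue_translation: float = 2 * CROWN_SPACING_NM
    twist_per_subunit: float = 20.0
    repeat: float = 172.0
    pitch: float = 516.0
    crowns_per_repeat: int = 12
    bridges_per_crown: int = 3
    strand_phase: float = 120.0
    circumference: float = 60.0
    handedness: int = 1

    def __post_init__(self) -> None:
        if self.n_strands < 1:
            raise ParameterError("n_strands must be >= 1")
        for name in ("residue_translation", "repeat", "pitch", "circumference"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0 < self.twist_per_subunit < 360:
            raise ParameterError("twist_per_subunit must lie in (0, 360)")
        if self.handedness not in (-1, 1):
            raise ParameterError("handedness must be +1 or -1")
        if not math.isclose(
            self.pitch * self.twist_per_subunit,
            360.0 * self.residue_translation,
            rel_tol=1e-6,
        ):
            raise ParameterError(
                "pitch * twist_per_subunit must equal 360 * residue_translation"
            )
        if not math.isclose(
            self.n_strands * self.strand_phase, 360.0, rel_tol=1e-9
        ):
            raise ParameterError("n_strands * strand_phase must equal 360")

    # -- derived geometry ------------------------------------------------

    @property
    def crown_spacing(self) -> float:
        """Axial distance between successive crowns, nm."""
        return self.repeat / self.crowns_per_repeat

    @property
    def per_crown_twist(self) -> float:
        """Azimuthal step between successive crowns, degrees (signed)."""
        step = (
            self.twist_per_subunit
            * self.crown_spacing
            / self.residue_translation
        )
        return self.handedness * step

    @property
    def azimuthal_row_step(self) -> float:
        """Angular spacing between adjacent cross-bridge rows, degrees.

        The greatest common divisor of the per-crown twist and the strand
        phase; every site azimuth is an integer multiple of it.
        """
        step = abs(self.per_crown_twist)
        if step < _TOL:
            return self.strand_phase
        a = Fraction(step).limit_denominator(10**6)
        b = Fraction(self.strand_phase).limit_denominator(10**6)
        g = Fraction(math.gcd(a.numerator, b.numerator), math.lcm(a.denominator, b.denominator))
        return float(g)

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_strands": self.n_strands,
            "residue_translation": self.residue_translation,
            "twist_per_subunit": self.twist_per_subunit,
            "repeat": self.repeat,
            "pitch": self.pitch,
            "crowns_per_repeat": self.crowns_per_repeat,
            "bridges_per_crown": self.bridges_per_crown,
            "strand_phase": self.strand_phase,
            "circumference": self.circumference,
            "handedness": self.handedness,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "HelixParams":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown helix keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class BridgeSite:
    """One cross-bridge position on the unrolled lattice."""

    axial: float
    lateral: float
    azimuth: float
    strand_index: int
    crown_index: int
    polarity: int
    orientation: float = 0.0


def derive_params(
    n_strands: int,
    residue_translation: float,
    twist_per_subunit: float,
    *,
    crowns_per_subunit: int = 2,
    bridges_per_crown: int = 3,
    circumference: float = 60.0,
    handedness: int = 1,
    max_subunits: int = 10**6,
) -> HelixParams:
    """Derive the full lattice parameterization from strand count, subunit
    translation and twist.

    ``pitch = 360 * translation / twist``.  The repeat is the smallest axial
    translation by an integer number of subunits that maps the infinite site
    set onto itself, allowing the strands to permute: ``k`` subunits close the
    lattice when ``k * twist`` is a multiple of the strand phase
    ``360 / n_strands``.

    ``crowns_per_subunit`` sets how many head crowns one subunit translation
    spans: 2 for the default smooth-muscle model (the 2 x 14.3 nm stagger),
    1 for the historical short-repeat lattice.
    """
    if n_strands < 1:
        raise ParameterError("n_strands must be >= 1")
    if residue_translation <= 0:
        raise ParameterError("residue_translation must be positive")
    if not 0 < twist_per_subunit < 360:
        raise ParameterError("twist_per_subunit must lie in (0, 360)")
    if crowns_per_subunit < 1:
        raise ParameterError("crowns_per_subunit must be >= 1")

    pitch = 360.0 * residue_translation / twist_per_subunit

    # smallest k with k * twist = 0 (mod 360 / n_strands)
    ratio = twist_per_subunit * n_strands / 360.0
    frac = Fraction(ratio).limit_denominator(max_subunits)
    if not math.isclose(float(frac), ratio, rel_tol=1e-9, abs_tol=1e-12):
        raise ParameterError(
            "no translational repeat within "
            f"{max_subunits} subunits for twist {twist_per_subunit}"
        )
    k = frac.denominator
    repeat = k * residue_translation

    return HelixParams(
        n_strands=n_strands,
        residue_translation=residue_translation,
        twist_per_subunit=twist_per_subunit,
        repeat=repeat,
        pitch=pitch,
        crowns_per_repeat=k * crowns_per_subunit,
        bridges_per_crown=bridges_per_crown,
        strand_phase=360.0 / n_strands,
        circumference=circumference,
        handedness=handedness,
    )


#: Default lattice: 3 strands, 172 nm repeat, 516 nm pitch, 12 crowns/repeat.
DEFAULT_PARAMS = HelixParams()

#: The historical short-repeat lattice (72 nm repeat, 108 nm pitch).  The
#: crown spacing is 72/5 = 14.4 nm so the lattice is exact on its own grid.
OLD_MODEL_72 = derive_params(3, 14.4, 48.0, crowns_per_subunit=1)


def predicted_layer_lines(
    repeat: float, max_order: int
) -> list[tuple[int, float]]:
    """Predicted layer-line spacings ``repeat / l`` for orders 1..max_order.

    Spacings are reported to 0.1 nm (half-up), matching printed precision.
    """
    if repeat <= 0:
        raise ParameterError("repeat must be positive")
    if max_order < 1:
        raise ParameterError("max_order must be >= 1")
    return [(l, round_spacing(repeat / l)) for l in range(1, max_order + 1)]


def _polarity(scheme: str, azimuth: float, row_step: float) -> int:
    if scheme == "left":
        return -1
    if scheme == "right":
        return +1
    if scheme == "trv":
        row = round(azimuth / row_step)
        return +1 if row % 2 == 0 else -1
    raise ParameterError(f"unknown polarity scheme {scheme!r}")


def generate_sites(
    params: HelixParams,
    length: float,
    scheme: PolarityScheme = "trv",
) -> list[BridgeSite]:
    """Enumerate the cross-bridge sites of a noiseless lattice of the given
    axial length (crowns on the half-open interval ``[0, length)``).

    Each crown carries ``bridges_per_crown`` sites at azimuths
    ``strand * strand_phase + crown * per_crown_twist`` (mod 360).  Polarity:
    ``left`` all -1, ``right`` all +1, ``trv`` alternates with the parity of
    the azimuthal row index (adjacent rows oppositely polarized).
    """
    if length < 0:
        raise ParameterError("length must be >= 0")
    if scheme not in SCHEMES:
        raise ParameterError(f"unknown polarity scheme {scheme!r}")
    cs = params.crown_spacing
    n_crowns = 0 if length <= _TOL else int(math.floor((length - _TOL) / cs)) + 1
    row_step = params.azimuthal_row_step
    sites: list[BridgeSite] = []
    for c in range(n_crowns):
        for s in range(params.bridges_per_crown):
            azimuth = (s * params.strand_phase + c * params.per_crown_twist) % 360.0
            # kill numeric noise so azimuths of equivalent rows compare equal
            azimuth = round(azimuth / row_step) * row_step % 360.0
            sites.append(
                BridgeSite(
                    axial=c * cs,
                    lateral=azimuth / 360.0 * params.circumference,
                    azimuth=azimuth,
                    strand_index=s,
                    crown_index=c,
                    polarity=_polarity(scheme, azimuth, row_step),
                )
            )
    return sites


@dataclass(frozen=True)
class RowCount:
    """Distinct azimuthal cross-bridge rows within one repeat.

    The total counts every distinct azimuth; ``per_polarity`` partitions the
    rows by their polarity class under the trv scheme.  For the default
    lattice this is 36 rows total, 18 per polarity class (reported in the
    field as "2 x 18 adjacent rows").
    """

    total: int
    per_polarity: dict[int, int]


def rows_per_repeat(params: HelixParams) -> RowCount:
    """Count distinct azimuthal rows in one repeat, split by trv polarity."""
    sites = generate_sites(params, params.repeat, scheme="trv")
    seen: dict[float, int] = {}
    for site in sites:
        key = round(site.azimuth, 6) % 360.0
        seen[key] = site.polarity
    per: dict[int, int] = {+1: 0, -1: 0}
    for pol in seen.values():
        per[pol] += 1
    return RowCount(total=len(seen), per_polarity=per)


def rod_coverage(rod_length: float, crown_spacing: float) -> float:
    """Number of crown repeats covered by a rod, to the nearest half repeat.

    A 150 nm rod on the 14.3 nm crown grid covers 10.5 repeats.
    """
    if rod_length <= 0 or crown_spacing <= 0:
        raise ParameterError("rod_length and crown_spacing must be positive")
    x = rod_length / crown_spacing
    return math.floor(2.0 * x + 0.5) / 2.0


def sites_to_dataframe(sites: Sequence[BridgeSite]) -> pd.DataFrame:
    """Export sites as a DataFrame (CSV-ready, one row per cross-bridge)."""
    return pd.DataFrame(
        {
            "crown_index": [s.crown_index for s in sites],
            "strand_index": [s.strand_index for s in sites],
            "axial_nm": [s.axial for s in sites],
            "azimuth_deg": [s.azimuth for s in sites],
            "lateral_nm": [s.lateral for s in sites],
            "polarity": [s.polarity for s in sites],
            "orientation_deg": [s.orientation for s in sites],
        }
    )
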