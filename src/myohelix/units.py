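"""Building-unit hierarchy on the crown grid: molecule -> trimer -> hexamer.

The myosin molecule's 150 nm rod spans 11 crowns of the 172/12 nm grid.  A
polar trimer staggers three molecules by 3 crowns (~43 nm), spanning 17
crowns.  Two antiparallel trimers clasp head-to-head into a bipolar hexamer;
the inter-trimer offset distinguishes the long-overlap variant A (1 crown
offset, 258 nm span, ~230 nm overlap) from the short-overlap variant B
(7 crowns, 344 nm span).  Filaments elongate by appending hexamers
alternately at the two ends, which leaves a rod-only (cross-bridge free)
smooth segment at each end and no interior bare zone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .helix import CROWN_SPACING_NM, ParameterError

__all__ = [
    "AssembledStrand",
    "CrossSection",
    "Hexamer",
    "MoleculeGeom",
    "Trimer",
    "assemble_filament",
    "build_hexamer",
    "build_trimer",
    "cross_section_layout",
]

HexamerVariant = Literal["A", "B"]

#: Inter-trimer offsets (in crowns) of the two hexamer variants.
HEXAMER_OFFSETS: dict[str, int] = {"A": 1, "B": 7}


@dataclass(frozen=True)
class MoleculeGeom:
    """One myosin molecule on the crown grid.

    ``head_end`` is the end (+1 high / -1 low) at which the pair of heads
    sits; the remaining crowns carry bare rod.
    """

    rod_length: float = 150.0
    span_crowns: int = 11
    head_end: int = +1

    def __post_init__(self) -> None:
        if self.span_crowns * CROWN_SPACING_NM < self.rod_length - 1e-9:
            raise ParameterError(
                "span_crowns * crown_spacing must cover the rod length"
            )
        if self.head_end not in (-1, +1):
            raise ParameterError("head_end must be +1 or -1")


@dataclass(frozen=True)
class Trimer:
    """Three staggered parallel molecules forming a polar trimer."""

    molecules: tuple[MoleculeGeom, MoleculeGeom, MoleculeGeom]
    intra_stagger_crowns: int = 3
    polarity: int = +1

    @property
    def span_crowns(self) -> int:
        return self.molecules[0].span_crowns + 2 * self.intra_stagger_crowns

    @property
    def span_nm(self) -> float:
        return self.span_crowns * CROWN_SPACING_NM

    def head_crowns(self) -> list[int]:
        """Crown offsets (within the trimer span) bearing head pairs.

        Heads sit at the ``polarity`` end of each molecule: at the high end
        of each rod for polarity +1, at the low end for -1.
        """
        offsets = []
        for i, mol in enumerate(self.molecules):
            start = i * self.intra_stagger_crowns
            if self.polarity > 0:
                offsets.append(start + mol.span_crowns - 1)
            else:
                offsets.append(start)
        return sorted(offsets)


def build_trimer(
    molecule: MoleculeGeom | None = None,
    stagger_crowns: int = 3,
    polarity: int = +1,
) -> Trimer:
    """Assemble a polar trimer with the given intra-trimer stagger."""
    if stagger_crowns < 0:
        raise ParameterError("stagger_crowns must be >= 0")
    mol = molecule or MoleculeGeom(head_end=polarity)
    return Trimer(
        molecules=(mol, mol, mol),
        intra_stagger_crowns=stagger_crowns,
        polarity=polarity,
    )


@dataclass(frozen=True)
class Hexamer:
    """Bipolar building unit: two antiparallel trimers, offset axially."""

    variant: str
    trimer: Trimer
    inter_trimer_offset_crowns: int

    @property
    def span_crowns(self) -> int:
        return self.trimer.span_crowns + self.inter_trimer_offset_crowns

    @property
    def overlap_crowns(self) -> int:
        return self.trimer.span_crowns - self.inter_trimer_offset_crowns

    @property
    def span_nm(self) -> float:
        return self.span_crowns * CROWN_SPACING_NM

    @property
    def overlap_nm(self) -> float:
        return self.overlap_crowns * CROWN_SPACING_NM

    def head_crowns(self) -> dict[int, int]:
        """Map of crown offset (within the span) -> head polarity.

        The low trimer points its heads up (+1), the high trimer points
        down (-1): the two head groups interlock head-to-head inside the
        unit, leaving the two terminal crowns rod-only (smooth).
        """
        heads: dict[int, int] = {}
        low = build_trimer(polarity=+1, stagger_crowns=self.trimer.intra_stagger_crowns)
        high = build_trimer(polarity=-1, stagger_crowns=self.trimer.intra_stagger_crowns)
        for off in low.head_crowns():
            heads[off] = +1
        for off in high.head_crowns():
            heads[self.inter_trimer_offset_crowns + off] = -1
        return heads


def build_hexamer(variant: HexamerVariant = "A", trimer: Trimer | None = None) -> Hexamer:
    """Build hexamer variant A (long overlap, 258 nm) or B (short, 344 nm)."""
    if variant not in HEXAMER_OFFSETS:
        raise ParameterError(f"unknown hexamer variant {variant!r}")
    t = trimer or build_trimer()
    return Hexamer(
        variant=variant,
        trimer=t,
        inter_trimer_offset_crowns=HEXAMER_OFFSETS[variant],
    )


@dataclass
class AssembledStrand:
    """Crown-occupancy map of one supra-coiled-coil strand."""

    start_crown: int
    end_crown: int  # exclusive
    rod_cover: dict[int, int] = field(default_factory=dict)
    heads: dict[int, list[int]] = field(default_factory=dict)
    crown_spacing: float = CROWN_SPACING_NM

    @property
    def total_length(self) -> float:
        return (self.end_crown - self.start_crown) * self.crown_spacing

    @property
    def head_crown_count(self) -> int:
        return len(self.heads)

    @property
    def smooth_end_lengths(self) -> tuple[float, float]:
        """Lengths (nm) of the rod-only terminal segments at the two ends."""
        low = 0
        c = self.start_crown
        while c < self.end_crown and c not in self.heads:
            low += 1
            c += 1
        high = 0
        c = self.end_crown - 1
        while c >= self.start_crown and c not in self.heads:
            high += 1
            c -= 1
        return (low * self.crown_spacing, high * self.crown_spacing)

    def has_interior_gap(self) -> bool:
        return any(
            c not in self.rod_cover
            for c in range(self.start_crown, self.end_crown)
        )

    def occupancy_frame(self) -> pd.DataFrame:
        rows = []
        for c in range(self.start_crown, self.end_crown):
            pols = self.heads.get(c, [])
            rows.append(
                {
                    "crown_index": c,
                    "axial_nm": c * self.crown_spacing,
                    "n_rods": self.rod_cover.get(c, 0),
                    "n_heads": len(pols),
                    "polarity_sum": sum(pols),
                }
            )
        return pd.DataFrame(rows)


def assemble_filament(
    n_units: int,
    variant: HexamerVariant = "A",
    seed: int = 0,
) -> AssembledStrand:
    """Elongate a strand by head-to-head attachment of hexamer units.

    Units append alternately at the two ends (unit 1 at the high end, unit 2
    at the low end, ...), each overlapping the strand by the hexamer overlap
    so the total length grows by ``span - overlap`` per added unit.  The
    schedule is deterministic; ``seed`` is accepted for interface stability
    and reserved for a future stochastic growth mode.
    """
    if n_units < 1:
        raise ParameterError("n_units must be >= 1")
    hexamer = build_hexamer(variant)
    span = hexamer.span_crowns
    overlap = hexamer.overlap_crowns
    unit_heads = hexamer.head_crowns()

    strand = AssembledStrand(start_crown=0, end_crown=span)

    def _place(unit_start: int) -> None:
        for c in range(unit_start, unit_start + span):
            strand.rod_cover[c] = strand.rod_cover.get(c, 0) + 1
        for off, pol in unit_heads.items():
            strand.heads.setdefault(unit_start + off, []).append(pol)

    _place(0)
    lo, hi = 0, span
    for k in range(1, n_units):
        if k % 2 == 1:  # attach at the high end
            ustart = hi - overlap
            _place(ustart)
            hi = ustart + span
        else:  # attach at the low end
            ustart = lo + overlap - span
            _place(ustart)
            lo = ustart
    strand.start_crown, strand.end_crown = lo, hi
    return strand


@dataclass(frozen=True)
class CrossSection:
    """Cross-sectional rod packing: 18 coiled-coil rods in 6 trimer triangles."""

    coords: np.ndarray  # (18, 2) rod centres, nm
    trimer_index: np.ndarray  # (18,) which trimer each rod belongs to
    rod_radius: float
    tight: bool

    @property
    def bounding_diameter(self) -> float:
        return 2.0 * (float(np.hypot(*self.coords.T).max()) + self.rod_radius)


def cross_section_layout(
    tight: bool = False,
    rod_radius: float = 1.0,
    ring_radius: float = 4.5,
    inner_ring_radius: float = 1.6,
    tighten_shift: float = 0.7,
) -> CrossSection:
    """Lay out the 18 rod centres of the dodecagonal backbone packing.

    Six trimer triangles (three hexamer pairs) sit on a ring with exact
    six-fold symmetry.  ``tight=True`` relocates each trimer's innermost rod
    (its SF2 neck) onto an inner ring and pulls the outer pair radially
    inward, shrinking the bounding circle by at most 20 %.
    """
    a = 2.0 * rod_radius / math.sqrt(3.0)  # triangle circumradius
    coords = []
    groups = []
    for k in range(6):
        phi = math.radians(60.0 * k)
        u = np.array([math.cos(phi), math.sin(phi)])
        centre = ring_radius * u
        # vertex directions: one pointing inward (SF2), two outward
        verts = []
        for ang in (180.0, 60.0, -60.0):
            t = phi + math.radians(ang)
            verts.append(centre + a * np.array([math.cos(t), math.sin(t)]))
        if tight:
            verts[0] = inner_ring_radius * u
            verts[1] = verts[1] - tighten_shift * u
            verts[2] = verts[2] - tighten_shift * u
        coords.extend(verts)
        groups.extend([k] * 3)
    return CrossSection(
        coords=np.array(coords),
        trimer_index=np.array(groups),
        rod_radius=rod_radius,
        tight=tight,
    )
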