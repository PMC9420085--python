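"""Rasterization of lattices and paracrystals into calibrated mask images.

This is the digital analogue of the film masks used on a bench
diffractometer: binary foreground motifs ("dots" or L-shaped "bunny ears")
stamped at the cross-bridge lattice nodes of an unrolled filament surface,
plus striation patterns for LMM paracrystals (0 degree tilt) and rod
javelins (6-7 degree tilt).

Polarity convention: a polarity +1 site is stamped as drawn; a polarity -1
site is stamped with the motif mirrored in place about the vertical
(meridian) axis -- the head pair points the other way but stays on its
lattice node.  Reversing the pulling direction of *every* cross-bridge is a
mirror operation on the whole filament, so the uniformly left-polarized
filament is rendered as the mirror enantiomorph (handedness reversed along
with the motifs; see :func:`render_scheme_mask`), making the left mask,
pixel for pixel, the mirror image of the right mask.  Under the trv scheme
the rows share a single lattice and only the motifs alternate, which doubles
the lateral period of the polarity decoration -- the origin of the satellite
reflection beside the 14.3 nm meridional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .helix import BridgeSite, HelixParams, ParameterError, generate_sites

__all__ = [
    "MaskImage",
    "Motif",
    "NyquistError",
    "render_mask",
    "render_paracrystal",
    "render_scheme_mask",
    "scheme_render_params",
]


class NyquistError(ValueError):
    """Striation period too fine for the requested pixel size."""


def scheme_render_params(params: HelixParams, scheme: str) -> HelixParams:
    """Lattice parameters used to *render* a polarity scheme.

    The uniformly left-polarized filament is the mirror image of the
    right-polarized one, so its lattice handedness is reversed; the right
    and trv schemes render on the base lattice.
    """
    if scheme == "left":
        return replace(params, handedness=-params.handedness)
    return params


@dataclass
class MaskImage:
    """Calibrated 2D intensity grid.  The filament axis is image-vertical
    (axial position increases with the row index); ``nm_per_px`` calibrates
    both axes.  ``metadata`` fully determines a noiseless render."""

    pixels: np.ndarray
    nm_per_px: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.nm_per_px <= 0:
            raise ParameterError("nm_per_px must be positive")
        self.pixels = np.asarray(self.pixels, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def height_nm(self) -> float:
        return self.pixels.shape[0] * self.nm_per_px

    @property
    def width_nm(self) -> float:
        return self.pixels.shape[1] * self.nm_per_px


@dataclass(frozen=True)
class Motif:
    """Cross-bridge stamp shape.

    ``bunny_ears``: two elliptical lobes of ``lobe_length x lobe_width`` nm
    joined at right angle (``separation_deg``), the inner corner anchored at
    the lattice node -- one lobe runs along the axis, the other sideways, so
    the motif is chiral and polarity is visible.  ``dot``: a disk of
    ``dot_radius`` nm (achiral).
    """

    shape: Literal["dot", "bunny_ears"] = "bunny_ears"
    lobe_length: float = 6.0
    lobe_width: float = 3.0
    separation_deg: float = 90.0
    dot_radius: float = 2.0

    @property
    def footprint_nm(self) -> float:
        if self.shape == "dot":
            return 2.0 * self.dot_radius
        return self.lobe_length + self.lobe_width

    def __post_init__(self) -> None:
        if self.shape not in ("dot", "bunny_ears"):
            raise ParameterError(f"unknown motif shape {self.shape!r}")


def _stamp(
    motif: Motif,
    d_ax: np.ndarray,
    d_lat: np.ndarray,
    orientation_deg: float,
    mirror: bool,
) -> np.ndarray:
    """Evaluate the binary motif on offsets (nm) from the anchor point."""
    if mirror:
        d_lat = -d_lat
    d_ax, d_lat = np.broadcast_arrays(d_ax, d_lat)
    if motif.shape == "dot":
        return (d_ax**2 + d_lat**2 <= motif.dot_radius**2).astype(float)
    out = np.zeros(d_ax.shape)
    half_l = motif.lobe_length / 2.0
    half_w = motif.lobe_width / 2.0
    for lobe_angle in (0.0, motif.separation_deg):
        theta = math.radians(orientation_deg + lobe_angle)
        # unit vectors along / across the lobe (axial, lateral components)
        ua, ul = math.cos(theta), math.sin(theta)
        along = d_ax * ua + d_lat * ul
        across = -d_ax * ul + d_lat * ua
        inside = ((along - half_l) / half_l) ** 2 + (across / half_w) ** 2 <= 1.0
        out[inside] = 1.0
    return out


def render_mask(
    sites: Sequence[BridgeSite],
    motif: Motif = Motif(),
    nm_per_px: float = 1.0,
    width_px: int = 120,
    height_px: int = 1032,
    circumference_nm: float = 60.0,
    metadata: dict | None = None,
) -> MaskImage:
    """Stamp every site onto a calibrated canvas.

    The lattice strip of width ``circumference_nm`` is centred laterally and
    is cylindrically periodic: stamps crossing the strip seam wrap around to
    the other side, as they do on the filament surface.  Polarity -1 sites
    are stamped with the motif mirrored in place about the vertical axis;
    overlapping stamps saturate at 1.  Sites falling outside the canvas
    axially are clipped and counted in ``metadata['clipped_sites']``.
    """
    if nm_per_px <= 0:
        raise ParameterError("nm_per_px must be positive")
    canvas = np.zeros((height_px, width_px))
    width_nm = width_px * nm_per_px
    height_nm = height_px * nm_per_px
    if circumference_nm > width_nm:
        raise ParameterError("canvas narrower than the lattice circumference")
    x0 = (width_nm - circumference_nm) / 2.0
    pad = motif.footprint_nm + nm_per_px
    clipped = 0

    # strip columns (pixel centres inside [x0, x0 + circumference))
    centres = (np.arange(width_px) + 0.5) * nm_per_px
    strip = np.flatnonzero((centres >= x0) & (centres < x0 + circumference_nm))
    s_lo, s_hi = (int(strip[0]), int(strip[-1]) + 1) if strip.size else (0, 0)

    for site in sites:
        y = site.axial
        if not (-pad < y < height_nm + pad):
            clipped += 1
            continue
        if y < pad or y > height_nm - pad:
            clipped += 1
        r_lo = max(int((y - pad) / nm_per_px), 0)
        r_hi = min(int((y + pad) / nm_per_px) + 1, height_px)
        if r_lo >= r_hi:
            continue
        rows = (np.arange(r_lo, r_hi) + 0.5) * nm_per_px
        d_ax = rows[:, None] - y
        mirror = site.polarity < 0
        x_base = x0 + site.lateral % circumference_nm
        for shift in (-circumference_nm, 0.0, circumference_nm):
            x = x_base + shift
            c_lo = max(int((x - pad) / nm_per_px), s_lo)
            c_hi = min(int((x + pad) / nm_per_px) + 1, s_hi)
            if c_lo >= c_hi:
                continue
            d_lat = centres[c_lo:c_hi][None, :] - x
            patch = _stamp(motif, d_ax, d_lat, site.orientation, mirror)
            region = canvas[r_lo:r_hi, c_lo:c_hi]
            np.maximum(region, patch, out=region)

    meta = dict(metadata or {})
    meta.update(
        {
            "kind": "lattice_mask",
            "motif": {
                "shape": motif.shape,
                "lobe_length": motif.lobe_length,
                "lobe_width": motif.lobe_width,
                "separation_deg": motif.separation_deg,
                "dot_radius": motif.dot_radius,
            },
            "nm_per_px": nm_per_px,
            "circumference_nm": circumference_nm,
            "n_sites": len(sites),
            "clipped_sites": clipped,
        }
    )
    return MaskImage(pixels=canvas, nm_per_px=nm_per_px, metadata=meta)


def render_scheme_mask(
    params: HelixParams,
    scheme: str = "trv",
    motif: Motif = Motif(),
    nm_per_px: float = 1.0,
    width_px: int = 120,
    height_px: int = 1032,
) -> MaskImage:
    """Generate the lattice sites for the full canvas height and render
    them, recording the helix parameters in the metadata.

    For the uniformly left-polarized scheme the whole filament is the mirror
    image of the right-polarized one, so the lattice handedness is reversed
    along with the motifs; the trv scheme keeps the base handedness and only
    alternates motif orientation between adjacent rows.
    """
    length = height_px * nm_per_px
    sites = generate_sites(scheme_render_params(params, scheme), length, scheme)
    mask = render_mask(
        sites,
        motif=motif,
        nm_per_px=nm_per_px,
        width_px=width_px,
        height_px=height_px,
        circumference_nm=params.circumference,
        metadata={"helix": params.to_dict(), "scheme": scheme},
    )
    return mask


def render_paracrystal(
    tilt_deg: float,
    striation_period: float,
    nm_per_px: float = 1.0,
    width_px: int = 512,
    height_px: int = 512,
    waveform: Literal["sin", "bars"] = "sin",
) -> MaskImage:
    """Render striations of the given period, with the striation normal
    rotated ``tilt_deg`` from the long (vertical) axis.

    Tilt 0 models an LMM paracrystal (striations perpendicular to the axis);
    6-7 degrees models a rod javelin.  Raises :class:`NyquistError` when the
    period is not resolvable at the requested pixel size.
    """
    if striation_period <= 2.0 * nm_per_px:
        raise NyquistError(
            f"striation period {striation_period} nm needs nm_per_px < "
            f"{striation_period / 2.0}"
        )
    theta = math.radians(tilt_deg)
    rows = (np.arange(height_px) + 0.5) * nm_per_px
    cols = (np.arange(width_px) + 0.5) * nm_per_px
    phase = (
        rows[:, None] * math.cos(theta) + cols[None, :] * math.sin(theta)
    ) / striation_period
    if waveform == "sin":
        img = 0.5 * (1.0 + np.cos(2.0 * math.pi * phase))
    elif waveform == "bars":
        img = ((phase % 1.0) < 0.5).astype(float)
    else:
        raise ParameterError(f"unknown waveform {waveform!r}")
    meta = {
        "kind": "paracrystal",
        "tilt_deg": tilt_deg,
        "striation_period": striation_period,
        "nm_per_px": nm_per_px,
        "waveform": waveform,
    }
    return MaskImage(pixels=img, nm_per_px=nm_per_px, metadata=meta)
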