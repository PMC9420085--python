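"""File I/O: calibrated images (TIFF/PNG + JSON sidecar), layer-line CSVs
and YAML/JSON configuration files."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .helix import ParameterError
from .render import MaskImage
from .spectra import LayerLine

__all__ = [
    "FormatError",
    "LL_COLUMNS",
    "read_config_file",
    "read_image",
    "read_ll_csv",
    "write_config_file",
    "write_image",
    "write_ll_csv",
]

LL_COLUMNS = (
    "order",
    "spacing_nm",
    "intensity_left",
    "intensity_right",
    "meridional",
    "tilt_deg",
)


class FormatError(ValueError):
    """Malformed input file."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(mask: MaskImage, path: str | Path) -> Path:
    """Write a mask as 16-bit TIFF or 8-bit PNG plus a JSON metadata sidecar.

    Pixels are linearly rescaled to the full dtype range; the sidecar
    records ``nm_per_px``, the scaling, and the render metadata so the image
    round-trips through :func:`read_image`.
    """
    path = Path(path)
    img = np.asarray(mask.pixels, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    scale = hi - lo if hi > lo else 1.0
    norm = (img - lo) / scale
    if path.suffix.lower() in (".tif", ".tiff"):
        data = np.round(norm * 65535).astype(np.uint16)
        tifffile.imwrite(path, data)
        depth = 65535
    elif path.suffix.lower() == ".png":
        data = np.round(norm * 255).astype(np.uint8)
        Image.fromarray(data, mode="L").save(path)
        depth = 255
    else:
        raise FormatError(f"unsupported image format {path.suffix!r}")
    sidecar = {
        "nm_per_px": mask.nm_per_px,
        "intensity_offset": lo,
        "intensity_scale": scale,
        "depth": depth,
        "metadata": mask.metadata,
    }
    _sidecar(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_image(path: str | Path, nm_per_px: float | None = None) -> MaskImage:
    """Read TIFF/PNG back into a :class:`MaskImage`.

    Uses the JSON sidecar for calibration and intensity scaling when
    present; otherwise ``nm_per_px`` must be supplied and intensities are
    scaled to [0, 1].
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path).astype(float)
        depth = 65535.0
    elif path.suffix.lower() == ".png":
        data = np.asarray(Image.open(path).convert("L"), dtype=float)
        depth = 255.0
    else:
        raise FormatError(f"unsupported image format {path.suffix!r}")
    sidecar_path = _sidecar(path)
    metadata: dict = {}
    if sidecar_path.exists():
        side = json.loads(sidecar_path.read_text())
        nm_per_px = side["nm_per_px"]
        pixels = data / side["depth"] * side["intensity_scale"] + side[
            "intensity_offset"
        ]
        metadata = side.get("metadata", {})
    else:
        if nm_per_px is None:
            raise FormatError(
                f"no sidecar for {path.name}; nm_per_px must be given"
            )
        pixels = data / depth
    return MaskImage(pixels=pixels, nm_per_px=nm_per_px, metadata=metadata)


def write_ll_csv(lines: Sequence[LayerLine], path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        {
            "order": [l.order for l in lines],
            "spacing_nm": [l.spacing for l in lines],
            "intensity_left": [l.intensity_left for l in lines],
            "intensity_right": [l.intensity_right for l in lines],
            "meridional": [l.meridional for l in lines],
            "tilt_deg": [l.tilt for l in lines],
        }
    )
    frame.to_csv(path, index=False)
    return path


def read_ll_csv(path: str | Path) -> pd.DataFrame:
    """Read a layer-line CSV, checking the declared header."""
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in LL_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(
            f"{Path(path).name}: missing column(s) {', '.join(missing)}"
        )
    return frame


def read_config_file(path: str | Path) -> dict:
    """Read a YAML or JSON configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise FormatError(f"cannot parse {path.name}: {exc}") from exc
    if not isinstance(data, dict):
        raise FormatError(f"{path.name}: expected a mapping at top level")
    return data


def write_config_file(data: dict, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path
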