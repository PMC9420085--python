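"""End-to-end pipeline: simulate masks -> power spectra -> layer lines ->
symmetry / satellite -> repeat indexing, in one call.

Reproduces the polarity experiment: the same lattice is rendered under the
three polarity schemes (left, right, trv), their spectra are compared for
left/right balance and the 14.3 nm satellite, and the trv layer lines are
indexed against the candidate repeats.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import io as mio
from . import spectra
from .config import ConfigError, RunConfig
from .helix import SCHEMES
from .indexing import index_repeats
from .synth import generate_micrograph

__all__ = ["run_pipeline"]

log = logging.getLogger("myohelix")


def _sig(x: float, digits: int = 4) -> float:
    return float(f"{x:.{digits}g}")


def run_pipeline(config: RunConfig, write_artifacts: bool = True) -> dict:
    """Execute the full simulate -> diffract -> index experiment.

    Returns the report dict (also written as ``report.json`` alongside mask
    images and layer-line CSVs under ``config.output_dir`` unless
    ``write_artifacts`` is false).  On error, partial artifacts are removed.
    """
    if not isinstance(config, RunConfig):
        raise ConfigError("run_pipeline expects a RunConfig")
    outdir = Path(config.output_dir)
    written: list[Path] = []
    try:
        report: dict = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "schemes": {},
        }
        motif = config.mask.to_motif()
        observed: list[float] = []
        for scheme in SCHEMES:
            log.info("rendering %s-scheme mask (%d x %d px)", scheme,
                     config.mask.height_px, config.mask.width_px)
            mask = generate_micrograph(
                "filament",
                helix=config.helix,
                scheme=scheme,
                noise=config.noise,
                nm_per_px=config.mask.nm_per_px,
                size=(config.mask.height_px, config.mask.width_px),
                motif=motif,
            )
            ps = spectra.power_spectrum(mask, window=config.diffraction.window)  # type: ignore[arg-type]
            lines = spectra.detect_layer_lines(
                ps,
                min_prominence=config.diffraction.min_prominence,
                max_order=config.diffraction.max_order,
                repeat_nm=config.helix.repeat,
            )
            try:
                sym = spectra.symmetry_index(lines)
            except ValueError:
                sym = None
            satellite = spectra.detect_satellite(ps)
            report["schemes"][scheme] = {
                "spacings_nm": [l.spacing for l in lines],
                "meridional_spacings_nm": [
                    l.spacing for l in lines if l.meridional
                ],
                "symmetry_index": None if sym is None else _sig(sym),
                "satellite_present": satellite.present
                if satellite.applicable
                else None,
            }
            if scheme == "trv":
                observed = [l.spacing for l in lines if not l.meridional]
            if write_artifacts:
                outdir.mkdir(parents=True, exist_ok=True)
                img = outdir / f"mask_{scheme}.png"
                mio.write_image(mask, img)
                written.extend([img, img.with_suffix(".png.json")])
                csv = outdir / f"layer_lines_{scheme}.csv"
                mio.write_ll_csv(lines, csv)
                written.append(csv)

        if observed:
            result = index_repeats(observed, config.indexing.candidates)
            report["indexing"] = {
                "observed_spacings_nm": observed,
                "candidates": [
                    {
                        "repeat_nm": c.repeat,
                        "residual": _sig(c.residual),
                        "n_indexed": c.n_indexed,
                    }
                    for c in result.candidates
                ],
                "best_repeat": result.best_repeat,
                "margin": _sig(result.margin),
            }
            report["best_repeat"] = result.best_repeat
        else:
            report["indexing"] = None
            report["best_repeat"] = None

        if write_artifacts:
            outdir.mkdir(parents=True, exist_ok=True)
            rpt = outdir / "report.json"
            rpt.write_text(json.dumps(report, indent=2))
            written.append(rpt)
        log.info("pipeline complete: best repeat %s nm", report["best_repeat"])
        return report
    except Exception:
        for path in written:
            try:
                path.unlink(missing_ok=True)
            except OSError:  # pragma: no cover
                pass
        raise
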