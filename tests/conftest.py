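"""Shared fixtures: scheme masks and spectra are expensive enough to cache
per session; everything is generated programmatically."""

import pytest

from myohelix import DEFAULT_PARAMS, OLD_MODEL_72, power_spectrum
from myohelix.render import render_scheme_mask


@pytest.fixture(scope="session")
def scheme_masks():
    """Noiseless default-lattice masks for the three polarity schemes on the
    bin-exact 1032 x 120 px canvas."""
    return {
        scheme: render_scheme_mask(DEFAULT_PARAMS, scheme)
        for scheme in ("left", "right", "trv")
    }


@pytest.fixture(scope="session")
def scheme_spectra(scheme_masks):
    return {s: power_spectrum(m) for s, m in scheme_masks.items()}


@pytest.fixture(scope="session")
def old_lattice_spectrum():
    """Spectrum of the historical 72 nm lattice on a 14-repeat canvas."""
    mask = render_scheme_mask(OLD_MODEL_72, "trv", height_px=1008)
    return power_spectrum(mask)
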