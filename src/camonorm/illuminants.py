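"""Illuminant spectra for visual modelling.

The default viewing light is the CIE standard illuminant D65 ("idealised
daylight"); an ideal flat white is available for sensitivity checks.  Only
relative spectral shape matters: discriminability metrics are built from
log catch *ratios* and are invariant to the illuminant's overall scale.
"""

from __future__ import annotations

import numpy as np

from .spectra import Spectrum, StandardGrid

__all__ = ["d65", "ideal_white", "get_illuminant"]

# CIE standard illuminant D65, relative spectral power, 10 nm tabulation
# (300-700 nm), normalised to 100 at 560 nm.
_D65_WL = np.arange(300.0, 701.0, 10.0)
_D65_SPD = np.array([
    0.0341, 3.2945, 20.2360, 37.0535, 39.9488,
    44.9117, 46.6383, 52.0891, 49.9755, 54.6482,
    82.7549, 91.4860, 93.4318, 86.6823, 104.8650,
    117.0080, 117.8120, 114.8610, 115.9230, 108.8110,
    109.3540, 107.8020, 104.7900, 107.6890, 104.4050,
    104.0460, 100.0000, 96.3342, 95.7880, 88.6856,
    90.0062, 89.5991, 87.6987, 83.2886, 83.6992,
    80.0268, 80.2146, 82.2778, 78.2842, 69.7213,
    71.6091,
])


def d65(grid: StandardGrid | None = None) -> Spectrum:
    """D65 relative spectral power on the canonical grid (linear interpolation)."""
    grid = grid or StandardGrid()
    wl = grid.wavelengths
    return Spectrum(wl, np.interp(wl, _D65_WL, _D65_SPD), name="D65")


def ideal_white(grid: StandardGrid | None = None) -> Spectrum:
    """Spectrally flat illuminant (equal energy) on the canonical grid."""
    grid = grid or StandardGrid()
    return Spectrum(grid.wavelengths, np.ones(len(grid)), name="ideal_white")


def get_illuminant(name: str, grid: StandardGrid | None = None) -> Spectrum:
    if name.lower() in ("d65",):
        return d65(grid)
    if name.lower() in ("white", "ideal_white", "flat", "equal_energy"):
        return ideal_white(grid)
    raise ValueError(f"unknown illuminant '{name}' (use 'd65' or 'ideal_white')")
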