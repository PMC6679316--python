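"""Wavelength axis of the imaging spectrograph.

The camera samples 254 bands across roughly 866-1701 nm, but the leading and
trailing bands are noise-dominated and analyses run on the 220-band window
931.8-1653.8 nm.  We anchor the grid so that this analysis window is exactly
linear (bands ``n_lead .. n_lead + n_analysis - 1`` span it with constant
spacing) and extrapolate the same spacing outwards to the noisy edge bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WavelengthGrid", "make_wavelength_grid"]


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength values (nm), one per band."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        # >= 1: band subsetting (trim to one wavelength, single selected
        # band) must stay representable; full sensor grids have >= 2
        if values.ndim != 1 or values.size < 1:
            raise ValueError("grid needs at least 1 band in a 1-D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("grid values must be finite")
        if not np.all(np.diff(values) > 0):
            raise ValueError("grid values must be strictly increasing")
        object.__setattr__(self, "values", values)

    @property
    def n_bands(self) -> int:
        return int(self.values.size)

    def band_range(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Indices of bands with lo_nm <= wavelength <= hi_nm (inclusive)."""
        if lo_nm > hi_nm:
            raise ValueError(f"lo_nm={lo_nm} exceeds hi_nm={hi_nm}")
        idx = np.nonzero((self.values >= lo_nm) & (self.values <= hi_nm))[0]
        return idx

    def subset(self, indices: np.ndarray) -> "WavelengthGrid":
        return WavelengthGrid(self.values[np.asarray(indices)])


def make_wavelength_grid(
    n_bands: int = 254,
    analysis_lo_nm: float = 931.8,
    analysis_hi_nm: float = 1653.8,
    n_lead: int = 20,
    n_trail: int = 14,
) -> WavelengthGrid:
    """Build the sensor grid with a linear analysis window.

    ``n_lead`` noisy bands precede the analysis window and ``n_trail`` follow
    it; the analysis window holds the remaining ``n_bands - n_lead - n_trail``
    bands and spans [analysis_lo_nm, analysis_hi_nm] with constant spacing,
    which is extrapolated to the edge bands.  The defaults give 254 bands of
    which 220 fall in 931.8-1653.8 nm.
    """
    n_analysis = n_bands - n_lead - n_trail
    if n_lead < 0 or n_trail < 0 or n_analysis < 2:
        raise ValueError(
            f"inconsistent band counts: n_bands={n_bands}, n_lead={n_lead}, "
            f"n_trail={n_trail} leaves {n_analysis} analysis bands (need >= 2)"
        )
    if analysis_lo_nm >= analysis_hi_nm:
        raise ValueError("analysis_lo_nm must be < analysis_hi_nm")
    spacing = (analysis_hi_nm - analysis_lo_nm) / (n_analysis - 1)
    first = analysis_lo_nm - n_lead * spacing
    values = first + spacing * np.arange(n_bands)
    # pin the window endpoints exactly despite float accumulation
    values[n_lead] = analysis_lo_nm
    values[n_lead + n_analysis - 1] = analysis_hi_nm
    return WavelengthGrid(values)
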