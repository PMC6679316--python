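"""Hyperspectral cube container, black/white reflectance correction, band trim.

A push-broom NIR camera delivers a rows x cols x bands cube of digital
numbers (DN).  Conversion to relative reflectance uses a dark-current frame B
(lens capped, light off) and a white-reference frame W (standard white board):

    R = (I - B) / (W - B)

Reference frames may be full-size or a single line broadcast along the scan
axis, which matches how push-broom systems average their reference scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .grid import WavelengthGrid
from .table import SpectraTable

__all__ = [
    "Hypercube",
    "ReferenceFrames",
    "reflectance_correct",
    "trim_bands",
]

logger = logging.getLogger(__name__)

#: validity floor for the W - B denominator, in DN units
DENOM_EPS = 1e-9


@dataclass
class Hypercube:
    """rows x cols x bands array with its wavelength axis.

    ``kind`` is ``"raw"`` for DN straight off the sensor and ``"reflectance"``
    after black/white correction.  ``meta`` carries bookkeeping such as
    invalid-denominator counts from the correction step.
    """

    data: np.ndarray
    grid: WavelengthGrid
    kind: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (rows x cols x bands)")
        if self.data.shape[2] != self.grid.n_bands:
            raise ValueError(
                f"cube has {self.data.shape[2]} bands, grid has {self.grid.n_bands}"
            )
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.values


@dataclass
class ReferenceFrames:
    """Dark (B) and white (W) calibration frames.

    Each is rows x cols x bands or 1 x cols x bands (one averaged reference
    line broadcast over the scan direction).
    """

    dark: np.ndarray
    white: np.ndarray
    min_valid: float = 0.99

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark)
        self.white = np.asarray(self.white)
        if self.dark.ndim != 3 or self.white.ndim != 3:
            raise ValueError("reference frames must be 3-D")
        frac_valid = float(np.mean(self.white - self.dark > DENOM_EPS))
        if frac_valid < self.min_valid:
            raise ValueError(
                f"white exceeds dark on only {frac_valid:.1%} of entries "
                f"(need >= {self.min_valid:.0%}); check the reference pair"
            )


def reflectance_correct(
    raw: Hypercube,
    refs: ReferenceFrames,
    invalid_policy: str = "zero",
    clip_negative: bool = False,
) -> Hypercube:
    """Black/white correction R = (I - B) / (W - B).

    Entries whose denominator W - B falls below a small validity floor are
    handled per ``invalid_policy``: ``"zero"`` (default) masks them to 0 and
    counts them; ``"nan"`` would not produce a valid cube, so it is rejected;
    ``"error"`` raises.  Negative reflectance from noise (I < B) is kept by
    default to preserve linearity for scatter correction; ``clip_negative``
    clips to 0 and records the clipped count.
    """
    if raw.kind != "raw":
        raise ValueError("reflectance_correct expects a raw-DN cube")
    if invalid_policy not in ("zero", "error"):
        raise ValueError(f"unknown invalid_policy {invalid_policy!r}")
    I = raw.data.astype(np.float64, copy=False)
    B = refs.dark.astype(np.float64, copy=False)
    W = refs.white.astype(np.float64, copy=False)
    denom = W - B
    invalid = denom <= DENOM_EPS
    n_invalid = int(np.count_nonzero(invalid & np.ones(raw.shape, bool)))
    if n_invalid and invalid_policy == "error":
        raise ValueError(f"{n_invalid} cube entries have invalid W - B <= {DENOM_EPS}")
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (I - B) / denom
    if n_invalid:
        R = np.where(np.broadcast_to(invalid, R.shape), 0.0, R)
        logger.warning("masked %d entries with invalid reference denominator", n_invalid)
    n_negative = int(np.count_nonzero(R < 0))
    if n_negative:
        logger.info("%d corrected entries are negative (I < B)", n_negative)
        if clip_negative:
            R = np.clip(R, 0.0, None)
    meta = {"n_invalid": n_invalid, "n_negative": n_negative, "clipped": clip_negative}
    return Hypercube(R, raw.grid, kind="reflectance", meta=meta)


def trim_bands(
    x: Union[Hypercube, SpectraTable], lo_nm: float, hi_nm: float
) -> Union[Hypercube, SpectraTable]:
    """Keep exactly the bands with lo_nm <= wavelength <= hi_nm (inclusive).

    Drops the noise-dominated leading/trailing bands of the sensor; with the
    default 254-band grid and the 931.8-1653.8 nm window this retains 220
    bands.  Idempotent.
    """
    if lo_nm >= hi_nm and lo_nm != hi_nm:
        raise ValueError("lo_nm must be <= hi_nm")
    idx = x.grid.band_range(lo_nm, hi_nm)
    if idx.size == 0:
        raise ValueError(
            f"no bands retained in [{lo_nm}, {hi_nm}] nm "
            f"(grid spans {x.grid.values[0]:.1f}-{x.grid.values[-1]:.1f} nm)"
        )
    if isinstance(x, Hypercube):
        return Hypercube(x.data[:, :, idx], x.grid.subset(idx), x.kind, dict(x.meta))
    return x.take_bands(idx)
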