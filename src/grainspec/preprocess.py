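"""Row-wise spectral pretreatments: SNV, MSC, Savitzky-Golay first derivative.

All three operate per spectrum (per table row):

* SNV   x -> (x - mean(x)) / sd(x), sd with the n-1 denominator;
* MSC   regress x on a reference spectrum, x ~ a + b*ref, return (x - a)/b.
  The reference is the column-wise mean of the *calibration* rows and is
  reused unchanged for prediction rows — never refit, to avoid leakage;
* SG1   first derivative with respect to band index via local polynomial
  fits (window 11, order 2 by default); boundary values come from one-sided
  polynomial fits so the output keeps its length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.signal import savgol_filter

from .table import SpectraTable

__all__ = ["MscReference", "snv", "msc_fit", "msc_apply", "sg1", "make_preprocessor"]

TableLike = Union[SpectraTable, np.ndarray]


def _rows(x: TableLike) -> np.ndarray:
    if isinstance(x, SpectraTable):
        return x.x
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D samples x bands array")
    return arr


def _rewrap(x: TableLike, out: np.ndarray) -> TableLike:
    return x.with_x(out) if isinstance(x, SpectraTable) else out


def _row_name(x: TableLike, i: int) -> str:
    if isinstance(x, SpectraTable):
        return f"id {x.ids[i]} (row {i})"
    return f"row {i}"


def snv(x: TableLike) -> TableLike:
    """Standard normal variate: center and scale each row to mean 0, sd 1."""
    arr = _rows(x)
    if arr.shape[1] < 2:
        raise ValueError("SNV needs at least 2 bands")
    sd = arr.std(axis=1, ddof=1)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(f"SNV undefined for constant spectrum {_row_name(x, bad[0])}")
    out = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
    return _rewrap(x, out)


@dataclass(frozen=True)
class MscReference:
    """Frozen MSC reference spectrum (mean of the calibration rows)."""

    spectrum: np.ndarray

    def __post_init__(self) -> None:
        spec = np.asarray(self.spectrum, dtype=float)
        if spec.ndim != 1 or not np.all(np.isfinite(spec)):
            raise ValueError("MSC reference must be a finite 1-D spectrum")
        object.__setattr__(self, "spectrum", spec)

    @property
    def n_bands(self) -> int:
        return int(self.spectrum.size)


def msc_fit(calibration: TableLike) -> MscReference:
    """Fit the MSC reference: the column-wise mean of calibration rows."""
    arr = _rows(calibration)
    if arr.shape[0] < 2:
        raise ValueError("MSC reference needs at least 2 calibration rows")
    return MscReference(arr.mean(axis=0))


def msc_apply(x: TableLike, ref: MscReference) -> TableLike:
    """Correct each row by inverting its least-squares affine fit to ref.

    For row x with fit x ~ a + b*ref, returns (x - a) / b.  Rows whose slope
    is numerically zero carry no scatter-consistent signal and are rejected.
    """
    arr = _rows(x)
    if arr.shape[1] != ref.n_bands:
        raise ValueError(
            f"table has {arr.shape[1]} bands, MSC reference has {ref.n_bands}"
        )
    r = ref.spectrum
    r_centered = r - r.mean()
    denom = float(r_centered @ r_centered)
    if denom <= 0:
        raise ValueError("MSC reference is constant; slope is unidentifiable")
    b = (arr - arr.mean(axis=1, keepdims=True)) @ r_centered / denom
    bad = np.nonzero(np.abs(b) < 1e-12)[0]
    if bad.size:
        raise ValueError(
            f"MSC slope ~ 0 for spectrum {_row_name(x, bad[0])}; cannot invert"
        )
    a = arr.mean(axis=1) - b * r.mean()
    out = (arr - a[:, None]) / b[:, None]
    return _rewrap(x, out)


def sg1(x: TableLike, window: int = 11, polyorder: int = 2) -> TableLike:
    """Savitzky-Golay first derivative per band index.

    The analysis grid is uniform in nm, so the index derivative is
    proportional to the nm derivative.  Exact for polynomial rows up to
    ``polyorder``; boundaries use one-sided fits (same-length output).
    """
    arr = _rows(x)
    if window % 2 == 0 or window < polyorder + 2:
        raise ValueError(
            f"window must be odd and >= polyorder + 2 (got window={window}, "
            f"polyorder={polyorder})"
        )
    if window > arr.shape[1]:
        raise ValueError(f"window {window} exceeds band count {arr.shape[1]}")
    out = savgol_filter(
        arr, window_length=window, polyorder=polyorder, deriv=1, delta=1.0,
        axis=1, mode="interp",
    )
    return _rewrap(x, out)


class make_preprocessor:
    """Stateful pretreatment with fit/apply split for leakage-free pipelines.

    ``method`` in {"raw", "snv", "sg1", "msc"}.  Only MSC carries state (its
    reference); fit on calibration rows once, then apply anywhere.
    """

    METHODS = ("raw", "snv", "sg1", "msc")

    def __init__(self, method: str = "raw", sg1_window: int = 11,
                 sg1_polyorder: int = 2):
        if method not in self.METHODS:
            raise ValueError(f"method must be one of {self.METHODS}, got {method!r}")
        self.method = method
        self.sg1_window = sg1_window
        self.sg1_polyorder = sg1_polyorder
        self.msc_reference: MscReference | None = None

    def fit(self, calibration: TableLike) -> "make_preprocessor":
        if self.method == "msc":
            self.msc_reference = msc_fit(calibration)
        return self

    def apply(self, x: TableLike) -> TableLike:
        if self.method == "raw":
            return x
        if self.method == "snv":
            return snv(x)
        if self.method == "sg1":
            return sg1(x, self.sg1_window, self.sg1_polyorder)
        if self.msc_reference is None:
            raise RuntimeError("MSC preprocessor used before fit()")
        return msc_apply(x, self.msc_reference)
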