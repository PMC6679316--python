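"""Object-wise spectra table: one row per kernel, one column per band."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .grid import WavelengthGrid

__all__ = ["SpectraTable"]


@dataclass
class SpectraTable:
    """Samples x bands reflectance matrix with wavelengths, ids and labels.

    ``labels`` are integer class codes (1 = untreated, 2/3/4 = increasing
    surface-residue concentration); ``None`` for unlabeled tables.
    """

    x: np.ndarray
    grid: WavelengthGrid
    ids: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2:
            raise ValueError("x must be 2-D (samples x bands)")
        if self.x.shape[1] != self.grid.n_bands:
            raise ValueError(
                f"x has {self.x.shape[1]} bands but grid has {self.grid.n_bands}"
            )
        self.ids = np.asarray(self.ids)
        if self.ids.shape != (self.x.shape[0],):
            raise ValueError("ids length must match number of rows")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.x.shape[0],):
                raise ValueError("labels length must match number of rows")

    @property
    def n_samples(self) -> int:
        return self.x.shape[0]

    @property
    def n_bands(self) -> int:
        return self.x.shape[1]

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.values

    def take_rows(self, rows: Sequence[int] | np.ndarray) -> "SpectraTable":
        rows = np.asarray(rows)
        labels = None if self.labels is None else self.labels[rows]
        return SpectraTable(self.x[rows], self.grid, self.ids[rows], labels)

    def take_bands(self, bands: Sequence[int] | np.ndarray) -> "SpectraTable":
        bands = np.asarray(bands)
        return SpectraTable(
            self.x[:, bands], self.grid.subset(bands), self.ids, self.labels
        )

    def with_x(self, x: np.ndarray) -> "SpectraTable":
        """Same metadata, new spectra matrix (e.g. after preprocessing)."""
        return SpectraTable(x, self.grid, self.ids, self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"id": self.ids}
        if self.labels is not None:
            cols["label"] = self.labels
        for j, wl in enumerate(self.wavelengths):
            cols[f"{wl:.1f}"] = self.x[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraTable":
        df = pd.read_csv(path)
        meta = [c for c in ("id", "label") if c in df.columns]
        band_cols = [c for c in df.columns if c not in meta]
        grid = WavelengthGrid(np.array([float(c) for c in band_cols]))
        labels = df["label"].to_numpy() if "label" in meta else None
        ids = df["id"].to_numpy() if "id" in meta else np.arange(len(df))
        return cls(df[band_cols].to_numpy(float), grid, ids, labels)
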