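"""Synthetic NIR scenes of seed kernels carrying graded surface residues.

The generator emulates the statistical structure the downstream chemometrics
assumes, so every stage is testable without camera data:

* a 254-band grid whose central 220 bands span 931.8-1653.8 nm linearly;
* four spectral classes sharing one smooth baseline, separated only by a
  Gaussian absorption dip near 1520 nm whose depth grows with residue
  concentration — so mean reflectance over 1400-1650 nm is ordered
  class 1 (untreated) > 2 > 3 > 4;
* per-sample (table) or per-grain (scene) multiplicative/additive scatter
  distortion — exactly what multiplicative scatter correction removes;
* additive white Gaussian sensor noise per pixel and band;
* elliptical, non-overlapping grain regions on a dark background, with raw
  DN frames synthesized by inverting the black/white correction:
  I = R_true * (W - B) + B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .grid import WavelengthGrid, make_wavelength_grid
from .hypercube import Hypercube, ReferenceFrames
from .table import SpectraTable

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "simulate_class_spectrum",
    "simulate_spectra_table",
    "simulate_scene",
]

logger = logging.getLogger(__name__)

# deterministic baseline: broad reflectance humps typical of kernel NIR spectra
_BASELINE_HUMPS = (  # (amplitude, center nm, width nm)
    (0.25, 1050.0, 180.0),
    (0.18, 1400.0, 260.0),
    (0.10, 1680.0, 220.0),
)
_BASELINE_FLOOR = 0.30


@dataclass(frozen=True)
class SceneConfig:
    """All knobs of the synthetic experiment, with the defaults used throughout.

    ``dip_depths`` are in reflectance units, one per class, zero for the
    untreated class and strictly increasing with concentration.  Scatter
    standard deviations act per sample (table) or per grain (scene); noise is
    per band and pixel.  DN levels define the dark/white reference frames.
    """

    n_classes: int = 4
    grains_per_class: int = 25
    height: int = 400
    width: int = 400
    n_bands: int = 254
    analysis_lo_nm: float = 931.8
    analysis_hi_nm: float = 1653.8
    n_lead: int = 20
    n_trail: int = 14
    dip_center_nm: float = 1520.0
    dip_width_nm: float = 60.0
    dip_depths: Tuple[float, ...] = (0.0, 0.04, 0.08, 0.12)
    scatter_slope_sd: float = 0.03
    scatter_offset_sd: float = 0.01
    noise_sd: float = 0.004
    background_reflectance: float = 0.02
    dark_level: float = 100.0
    white_level: float = 3500.0
    frame_noise_sd: float = 0.5
    axis_major_px: Tuple[float, float] = (9.0, 12.0)
    axis_minor_px: Tuple[float, float] = (6.0, 8.0)
    placement_margin_px: float = 6.0
    max_place_retries: int = 2000
    dn_dtype: str = "float32"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.dip_depths) != self.n_classes:
            raise ValueError("need one dip depth per class")
        if self.dip_depths[0] != 0.0:
            raise ValueError("class 1 (untreated) must have dip depth 0")
        if not np.all(np.diff(self.dip_depths) > 0):
            raise ValueError("dip depths must strictly increase with class")
        for name in ("scatter_slope_sd", "scatter_offset_sd", "noise_sd",
                     "frame_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.white_level <= self.dark_level:
            raise ValueError("white_level must exceed dark_level")
        if self.grains_per_class < 1:
            raise ValueError("grains_per_class must be >= 1")

    def make_grid(self) -> WavelengthGrid:
        return make_wavelength_grid(
            self.n_bands, self.analysis_lo_nm, self.analysis_hi_nm,
            self.n_lead, self.n_trail,
        )


@dataclass
class GroundTruth:
    """Per-grain truth channel: geometry, class label, noise-free spectrum.

    ``label_image`` maps each pixel to its grain id (0 = background); grain
    ids are 1..G in placement order.
    """

    centers: np.ndarray      # (G, 2) row, col
    axes: np.ndarray         # (G, 2) major, minor semi-axes px
    angles: np.ndarray       # (G,) radians
    labels: np.ndarray       # (G,) class 1..n_classes
    spectra: np.ndarray      # (G, n_bands) grain's distorted noise-free spectrum
    label_image: np.ndarray  # (H, W) int32 grain ids

    @property
    def n_grains(self) -> int:
        return int(self.labels.size)

    def mask(self, grain_id: int) -> np.ndarray:
        return self.label_image == grain_id

    def to_csv(self, path: str | Path) -> None:
        """Structured text sidecar: one row per grain with geometry + class."""
        df = pd.DataFrame({
            "id": np.arange(1, self.n_grains + 1),
            "class": self.labels,
            "center_row": self.centers[:, 0],
            "center_col": self.centers[:, 1],
            "semi_major_px": self.axes[:, 0],
            "semi_minor_px": self.axes[:, 1],
            "angle_rad": self.angles,
        })
        df.to_csv(path, index=False)


def _baseline(grid: WavelengthGrid) -> np.ndarray:
    wl = grid.values
    base = np.full(wl.shape, _BASELINE_FLOOR)
    for amp, center, width in _BASELINE_HUMPS:
        base += amp * np.exp(-(((wl - center) / width) ** 2))
    return base


def simulate_class_spectrum(
    class_label: int,
    grid: WavelengthGrid,
    config: SceneConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Noise-free reflectance spectrum of one class.

    Deterministic: a fixed sum of broad Gaussian humps minus the class's
    absorption dip (``rng`` is accepted for API symmetry and unused).  The
    untreated class (label 1) has zero dip depth and equals the baseline.
    """
    if not 1 <= class_label <= config.n_classes:
        raise ValueError(
            f"class_label must be in 1..{config.n_classes}, got {class_label}"
        )
    wl = grid.values
    depth = config.dip_depths[class_label - 1]
    dip = depth * np.exp(-(((wl - config.dip_center_nm) / config.dip_width_nm) ** 2))
    spectrum = _baseline(grid) - dip
    return np.clip(spectrum, 1e-6, 1.0)


def _scatter_distort(
    spectrum: np.ndarray, rng: np.random.Generator, config: SceneConfig
) -> np.ndarray:
    """One draw of the multiplicative/additive scatter model."""
    slope = rng.normal(0.0, config.scatter_slope_sd)
    offset = rng.normal(0.0, config.scatter_offset_sd)
    return spectrum * (1.0 + slope) + offset


def simulate_spectra_table(config: SceneConfig) -> SpectraTable:
    """Object-wise spectra table bypassing the imaging chain.

    Each row is one kernel: its class spectrum under a per-sample affine
    scatter distortion plus additive band noise.  Rows are grouped by class
    (labels 1..n_classes, ``grains_per_class`` rows each); fully reproducible
    from ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    grid = config.make_grid()
    rows, labels = [], []
    for cls in range(1, config.n_classes + 1):
        clean = simulate_class_spectrum(cls, grid, config)
        for _ in range(config.grains_per_class):
            row = _scatter_distort(clean, rng, config)
            row = row + rng.normal(0.0, config.noise_sd, size=grid.n_bands)
            rows.append(row)
            labels.append(cls)
    x = np.vstack(rows)
    n = x.shape[0]
    return SpectraTable(x, grid, ids=np.arange(1, n + 1), labels=np.array(labels))


def _place_grains(config: SceneConfig, rng: np.random.Generator):
    """Rejection-sample non-overlapping ellipse placements.

    Overlap is tested conservatively on bounding circles (major semi-axis +
    margin), so accepted placements are guaranteed disjoint.
    """
    n = config.n_classes * config.grains_per_class
    centers = np.zeros((n, 2))
    axes = np.zeros((n, 2))
    angles = np.zeros(n)
    radii = np.zeros(n)
    for g in range(n):
        for attempt in range(config.max_place_retries):
            a = rng.uniform(*config.axis_major_px)
            b = rng.uniform(*config.axis_minor_px)
            r = a + config.placement_margin_px / 2.0
            cy = rng.uniform(r, config.height - r)
            cx = rng.uniform(r, config.width - r)
            if g == 0 or np.all(
                np.hypot(centers[:g, 0] - cy, centers[:g, 1] - cx)
                > radii[:g] + r
            ):
                centers[g] = (cy, cx)
                axes[g] = (a, b)
                angles[g] = rng.uniform(0.0, np.pi)
                radii[g] = r
                break
        else:
            raise RuntimeError(
                f"could not place grain {g + 1}/{n} after "
                f"{config.max_place_retries} retries; enlarge the image or "
                "shrink the grains"
            )
    return centers, axes, angles


def simulate_scene(
    config: SceneConfig,
) -> Tuple[Hypercube, ReferenceFrames, GroundTruth]:
    """Full synthetic acquisition: raw DN cube, reference frames, ground truth.

    Builds a true-reflectance scene (dark background, per-grain distorted
    class spectra with per-pixel noise), then synthesizes the raw cube by
    inverting the black/white correction against single-line dark/white
    reference frames at the configured DN levels (plus frame noise).
    Correcting the returned cube with the returned frames therefore recovers
    the true reflectance exactly when ``frame_noise_sd`` is 0.
    """
    rng = np.random.default_rng(config.rng_seed)
    grid = config.make_grid()
    nb = grid.n_bands
    H, W = config.height, config.width
    dtype = np.dtype(config.dn_dtype)
    if dtype not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("dn_dtype must be float32 or float64")

    centers, axes, angles = _place_grains(config, rng)
    n_grains = centers.shape[0]
    # class labels in placement order: grain g -> class g // grains_per_class + 1
    labels = np.repeat(np.arange(1, config.n_classes + 1), config.grains_per_class)

    label_image = np.zeros((H, W), dtype=np.int32)
    spectra = np.zeros((n_grains, nb))
    r_true = np.full((H, W, nb), config.background_reflectance, dtype=dtype)
    for g in range(n_grains):
        clean = simulate_class_spectrum(int(labels[g]), grid, config)
        spec = np.clip(_scatter_distort(clean, rng, config), 1e-6, 1.2)
        spectra[g] = spec
        rr, cc = draw_ellipse(
            centers[g, 0], centers[g, 1], axes[g, 0], axes[g, 1],
            shape=(H, W), rotation=angles[g],
        )
        label_image[rr, cc] = g + 1
        noise = rng.normal(0.0, config.noise_sd, size=(rr.size, nb))
        r_true[rr, cc, :] = (spec[None, :] + noise).astype(dtype)

    truth = GroundTruth(centers, axes, angles, labels, spectra, label_image)

    # single-line reference frames, broadcast along the scan axis
    dark = np.full((1, W, nb), config.dark_level, dtype=dtype)
    white = np.full((1, W, nb), config.white_level, dtype=dtype)
    if config.frame_noise_sd > 0:
        dark += rng.normal(0.0, config.frame_noise_sd, dark.shape).astype(dtype)
        white += rng.normal(0.0, config.frame_noise_sd, white.shape).astype(dtype)

    raw = r_true * (white - dark) + dark  # invert R = (I - B) / (W - B)
    cube = Hypercube(raw, grid, kind="raw")
    refs = ReferenceFrames(dark=dark, white=white)
    logger.info("simulated scene: %d grains on %dx%d px, %d bands", n_grains, H, W, nb)
    return cube, refs, truth
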