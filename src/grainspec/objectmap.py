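"""Object-wise classification maps.

Each segmented kernel is classified once from its pixel-averaged spectrum
(object-wise, rather than per pixel) through a frozen trained pipeline, and
the kernels are painted with their predicted class index over a black
background, with a chroma bar mapping indices 1-4 to colors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from .classify import TrainedModel
from .hypercube import Hypercube, trim_bands
from .preprocess import make_preprocessor
from .segmentation import LabeledRegions, extract_object_spectra
from .synthetic import GroundTruth
from .table import SpectraTable

__all__ = ["TrainedPipeline", "ClassMap", "classify_objects",
           "render_class_map", "true_labels_for_regions"]

#: class index -> RGB, background black; mirrors a 4-level chroma bar
DEFAULT_PALETTE: Dict[int, Tuple[int, int, int]] = {
    1: (43, 131, 186),    # untreated
    2: (171, 221, 164),   # 1:1000
    3: (253, 174, 97),    # 1:500
    4: (215, 25, 28),     # 1:100
}


@dataclass
class TrainedPipeline:
    """Frozen prediction chain: trim -> pretreatment -> band subset -> model.

    Carries everything needed to classify new object spectra without refit:
    the analysis band window, the fitted preprocessor (with its MSC reference
    when applicable), the selected band indices relative to the trimmed grid,
    and the tuned classifier.
    """

    trim_lo_nm: float
    trim_hi_nm: float
    preprocessor: make_preprocessor
    band_indices: np.ndarray
    model: TrainedModel
    trimmed_wavelengths: np.ndarray

    def predict_table(self, table: SpectraTable) -> np.ndarray:
        trimmed = trim_bands(table, self.trim_lo_nm, self.trim_hi_nm)
        if trimmed.n_bands != self.trimmed_wavelengths.size or not np.allclose(
            trimmed.wavelengths, self.trimmed_wavelengths
        ):
            raise ValueError(
                "band axis mismatch: input trims to "
                f"{trimmed.n_bands} bands, pipeline was trained on "
                f"{self.trimmed_wavelengths.size}"
            )
        processed = self.preprocessor.apply(trimmed)
        return self.model.predict(processed.x[:, self.band_indices])


@dataclass
class ClassMap:
    """Predicted-class image: 0 background, kernel pixels = class 1-4."""

    label_image: np.ndarray
    grain_labels: np.ndarray
    palette: Dict[int, Tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE))

    @property
    def legend(self) -> Dict[int, Tuple[int, int, int]]:
        return self.palette

    def to_rgb(self) -> np.ndarray:
        rgb = np.zeros((*self.label_image.shape, 3), dtype=np.uint8)
        for cls, color in self.palette.items():
            rgb[self.label_image == cls] = color
        return rgb


def classify_objects(
    cube: Hypercube, regions: LabeledRegions, pipeline: TrainedPipeline
) -> np.ndarray:
    """One predicted class per kernel from its mean spectrum."""
    spectra = extract_object_spectra(cube, regions)
    return pipeline.predict_table(spectra)


def render_class_map(
    regions: LabeledRegions,
    labels: np.ndarray,
    palette: Optional[Dict[int, Tuple[int, int, int]]] = None,
    png_path: Optional[str | Path] = None,
    envi_path: Optional[str | Path] = None,
) -> ClassMap:
    """Paint each kernel with its predicted class.

    Optionally writes a PNG with a chroma bar (values 1-4) and a single-band
    integer ENVI raster of the class indices.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (regions.n_regions,):
        raise ValueError("need exactly one label per region")
    palette = dict(palette or DEFAULT_PALETTE)
    bad = np.setdiff1d(np.unique(labels), list(palette))
    if bad.size:
        raise ValueError(f"labels {bad.tolist()} outside palette classes "
                         f"{sorted(palette)}")
    class_image = np.zeros_like(regions.label_image, dtype=np.int32)
    lab = regions.label_image
    fg = lab > 0
    class_image[fg] = labels[lab[fg] - 1]
    cmap = ClassMap(class_image, labels, palette)

    if png_path is not None:
        _write_png(cmap, png_path)
    if envi_path is not None:
        from .envi import write_envi_array
        write_envi_array(class_image[:, :, None], envi_path,
                         interleave="bsq", force=True)
    return cmap


def _write_png(cmap: ClassMap, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    classes = sorted(cmap.palette)
    colors = ["black"] + [tuple(c / 255 for c in cmap.palette[k]) for k in classes]
    listed = ListedColormap(colors)
    norm = BoundaryNorm(np.arange(-0.5, len(classes) + 1), listed.N)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(cmap.label_image, cmap=listed, norm=norm,
                   interpolation="nearest")
    ax.set_axis_off()
    cbar = fig.colorbar(im, ax=ax, ticks=classes, shrink=0.8)
    cbar.set_label("class")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def true_labels_for_regions(
    regions: LabeledRegions, truth: GroundTruth
) -> np.ndarray:
    """Ground-truth class per segmented region, by majority pixel overlap.

    Regions with no overlap against any true grain get label 0.
    """
    out = np.zeros(regions.n_regions, dtype=int)
    lab, tlab = regions.label_image, truth.label_image
    if lab.shape != tlab.shape:
        raise ValueError("region and truth images differ in shape")
    for rid in range(1, regions.n_regions + 1):
        overlap = tlab[lab == rid]
        overlap = overlap[overlap > 0]
        if overlap.size:
            grains, counts = np.unique(overlap, return_counts=True)
            out[rid - 1] = truth.labels[grains[np.argmax(counts)] - 1]
    return out
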