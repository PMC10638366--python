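"""Core raster containers shared across the pipeline.

All rasters are 2-D numpy arrays in row-major order with the origin at the
top-left pixel; physical calibration is carried as a scalar pixel size in
µm/pixel.  Areas are always expressed in µm².
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "SEMImage",
    "PoreLabelMap",
    "ChamberMap",
    "MIN_IMAGE_SIDE",
]

#: Smallest raster side accepted anywhere in the pipeline (pixels).
MIN_IMAGE_SIDE = 64


@dataclass
class SEMImage:
    """A calibrated grayscale SEM raster.

    Parameters
    ----------
    pixels
        2-D array of intensities, ``uint8`` or ``uint16`` (floats are
        accepted for intermediate products).
    pixel_size
        Physical edge length of one pixel in µm.
    id
        Free-form specimen/image identifier.
    """

    pixels: np.ndarray
    pixel_size: float
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("SEMImage.pixels must be 2-D grayscale")
        if min(self.pixels.shape) < MIN_IMAGE_SIDE:
            raise ValueError(
                f"image sides must be >= {MIN_IMAGE_SIDE} px, got {self.pixels.shape}"
            )
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive (µm/pixel)")
        if self.pixels.dtype == np.uint8:
            pass
        elif self.pixels.dtype == np.uint16:
            pass
        elif np.issubdtype(self.pixels.dtype, np.floating):
            pass
        else:
            raise ValueError(f"unsupported image dtype {self.pixels.dtype}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def astype_float(self) -> np.ndarray:
        """Return intensities as float64 without rescaling."""
        return self.pixels.astype(np.float64)


@dataclass
class PoreLabelMap:
    """Integer labelling of individual pores aligned to an image.

    ``labels == 0`` is non-pore; pores are labelled ``1..n_pores`` with
    consecutive positive integers, each an 8-connected component.
    ``provenance`` records which stage produced the map.
    """

    labels: np.ndarray
    provenance: str = "ground_truth"

    _ALLOWED = ("classical", "learned", "ground_truth", "corrected")

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D raster")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer raster")
        if self.provenance not in self._ALLOWED:
            raise ValueError(f"provenance must be one of {self._ALLOWED}")

    @property
    def n_pores(self) -> int:
        return int(self.labels.max(initial=0))

    def check_consecutive(self) -> None:
        """Raise if labels are not exactly 0..max with no gaps."""
        present = np.unique(self.labels)
        expected = np.arange(present[-1] + 1) if present.size else present
        if present[0] != 0 and self.labels.max() > 0:
            # a map with no background at all is legal but odd; only gaps fail
            expected = np.arange(present[0], present[-1] + 1)
        if not np.array_equal(present[present > 0], np.arange(1, self.labels.max(initial=0) + 1)):
            raise ValueError("pore labels are not consecutive 1..n")


@dataclass
class ChamberMap:
    """Per-chamber labelling of a test with ontogenetic ordering.

    ``labels == 0`` is off-test background.  ``ontogeny_order`` maps each
    chamber label to its rank, rank 1 being the oldest chamber (the
    proloculus end).  ``apex`` is the (row, col) pixel coordinate of that
    oldest end, used to recover an ordering when explicit ranks are absent.
    """

    labels: np.ndarray
    ontogeny_order: Mapping[int, int] | None = None
    apex: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("chamber labels must be a 2-D raster")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("chamber labels must be integers")
        if self.ontogeny_order is not None:
            present = set(np.unique(self.labels).tolist()) - {0}
            ranks = sorted(self.ontogeny_order.values())
            if set(self.ontogeny_order) != present:
                raise ValueError("ontogeny_order must cover exactly the nonzero labels")
            if ranks != list(range(1, len(ranks) + 1)):
                raise ValueError("ontogeny ranks must be a permutation of 1..n_chambers")

    @property
    def chamber_labels(self) -> np.ndarray:
        lab = np.unique(self.labels)
        return lab[lab > 0]

    def silhouette(self) -> np.ndarray:
        """Binary on-test mask (union of all chambers)."""
        return self.labels > 0

    def replace(self, **kw) -> "ChamberMap":
        return dataclasses.replace(self, **kw)
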