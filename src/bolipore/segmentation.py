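"""Pore segmentation: test detection, classical operator chain, corrections.

The classical path is a deterministic reference chain: illumination
flattening by large-kernel background subtraction, hysteresis thresholding
of dark pixels inside the detected test, speckle removal, optional
watershed splitting of touching pores, then area/solidity filtering and
8-connected labelling.  The trainable pixel-classifier path lives in
:mod:`bolipore.learned` and re-uses the same post-processing so both routes
are directly comparable against ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import apply_hysteresis_threshold, gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .core import PoreLabelMap, SEMImage

__all__ = [
    "SegConfig",
    "NoSpecimenError",
    "detect_test_mask",
    "segment_pores_classical",
    "remove_artifacts",
    "postprocess_binary",
]


class NoSpecimenError(RuntimeError):
    """Raised when no specimen can be found in an image."""


@dataclass(frozen=True)
class SegConfig:
    """Tunable parameters of the pore segmentation chain.

    ``min_pore_area`` (µm², default 1.0) floors the component size; the
    smallest mean pore size seen in bolivinids is ~6 µm², but the floor is
    kept low and configurable so that the failure mode of very-small-pored
    species (whose pores go unrecognised) is reproducible.
    """

    min_pore_area: float = 1.0
    max_pore_area: float = 500.0
    threshold_method: str = "otsu_global"
    split_touching: bool = False
    solidity_min: float = 0.65
    flatten_sigma_um: float = 20.0
    mask_erosion_px: int = 2
    despeckle_px: int = 3
    hysteresis_weak: float = 0.0

    def validate(self) -> None:
        if not 0 < self.min_pore_area < self.max_pore_area:
            raise ValueError("require 0 < min_pore_area < max_pore_area")
        if self.threshold_method not in ("otsu_global", "otsu_local"):
            raise ValueError("threshold_method must be otsu_global or otsu_local")
        if not 0 <= self.solidity_min <= 1:
            raise ValueError("solidity_min must be in [0, 1]")


def detect_test_mask(image: SEMImage) -> np.ndarray:
    """Locate the specimen: largest bright connected component after global
    thresholding, with holes filled.

    A contrast-free dark frame raises :class:`NoSpecimenError`; a uniformly
    bright frame is treated as all-specimen.
    """
    arr = image.astype_float()
    lo, hi = arr.min(), arr.max()
    if hi - lo < 1e-9:
        full = 255.0 if image.pixels.dtype != np.uint16 else 65535.0
        if lo > full / 2.0:
            return np.ones_like(arr, dtype=bool)
        raise NoSpecimenError("no specimen found: image has no contrast")
    smoothed = gaussian(arr, sigma=2, preserve_range=True)
    thr = threshold_otsu(smoothed)
    bright = smoothed > thr
    if not bright.any():
        raise NoSpecimenError("no specimen found: nothing above threshold")
    lab, n = ndi.label(bright)
    if n == 0:
        raise NoSpecimenError("no specimen found")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    mask = lab == sizes.argmax()
    mask = ndi.binary_fill_holes(mask)
    return mask


def postprocess_binary(
    binary: np.ndarray, pixel_size: float, config: SegConfig, provenance: str
) -> PoreLabelMap:
    """Shared tail of both segmentation routes: despeckling, optional
    watershed split, area/solidity filtering, consecutive 8-connected
    labelling.

    Despeckling drops connected specks below ``despeckle_px`` pixels — a
    size-based cleanup chosen over a morphological opening because an
    opening's structuring element also destroys the smallest legitimate
    pores (3-4 px across at 1 µm/pixel).
    """
    config.validate()
    lab0 = cc_label(binary, connectivity=2)
    sizes = np.bincount(lab0.ravel())
    keep = sizes >= config.despeckle_px
    keep[0] = False
    opened = keep[lab0]
    if config.split_touching:
        labels = _watershed_split(opened, pixel_size, config)
    else:
        labels = cc_label(opened, connectivity=2)
    labels = _filter_components(labels, pixel_size, config)
    return PoreLabelMap(labels, provenance=provenance)


def _watershed_split(opened: np.ndarray, pixel_size: float, config: SegConfig) -> np.ndarray:
    from skimage.feature import peak_local_max

    if not opened.any():
        return np.zeros(opened.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(opened)
    min_sep = max(int(round(2.0 * np.sqrt(config.min_pore_area / np.pi) / pixel_size)), 1)
    coords = peak_local_max(dist, min_distance=min_sep, labels=cc_label(opened, connectivity=2))
    seeds = np.zeros(opened.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        seeds[r, c] = i
    if seeds.max() == 0:
        return cc_label(opened, connectivity=2)
    return watershed(-dist, seeds, mask=opened)


def _filter_components(labels: np.ndarray, pixel_size: float, config: SegConfig) -> np.ndarray:
    min_px = int(np.ceil(config.min_pore_area / pixel_size**2))
    max_px = int(np.floor(config.max_pore_area / pixel_size**2))
    out = np.zeros(labels.shape, dtype=np.int32)
    nxt = 1
    for rp in regionprops(labels):
        if rp.area < min_px or rp.area > max_px:
            continue
        if rp.solidity < config.solidity_min:
            continue
        out[labels == rp.label] = nxt
        nxt += 1
    return out


def _flatten(arr: np.ndarray, pixel_size: float, config: SegConfig) -> np.ndarray:
    sigma = max(config.flatten_sigma_um / pixel_size, 1.0)
    background = gaussian(arr, sigma=sigma, preserve_range=True)
    return arr - background


def segment_pores_classical(image: SEMImage, config: SegConfig | None = None) -> PoreLabelMap:
    """Deterministic classical pore segmentation.

    The flattened image is renormalised to [0, 1] inside the (eroded) test
    mask before thresholding, which makes the labelling invariant to
    rescaling all intensities by a positive constant.
    """
    config = config or SegConfig()
    config.validate()
    mask = detect_test_mask(image)
    if config.mask_erosion_px > 0:
        mask = ndi.binary_erosion(mask, iterations=config.mask_erosion_px)
    arr = image.astype_float()
    flat = _flatten(arr, image.pixel_size, config)
    vals = flat[mask]
    if vals.size == 0:
        return PoreLabelMap(np.zeros(arr.shape, np.int32), provenance="classical")
    lo, hi = vals.min(), vals.max()
    if hi - lo < 1e-12:
        return PoreLabelMap(np.zeros(arr.shape, np.int32), provenance="classical")
    norm = np.zeros_like(flat)
    norm[mask] = (flat[mask] - lo) / (hi - lo)
    if config.threshold_method == "otsu_global":
        vals = norm[mask]
        med = float(np.median(vals))
        sigma = 1.4826 * float(np.median(np.abs(vals - med)))
        p_low = float(np.percentile(vals, 0.2))
        delta = med - p_low
        if delta <= max(4.0 * sigma, 0.02):
            # no resolvable dark pore class (poreless or noise-only frame)
            return PoreLabelMap(np.zeros(arr.shape, np.int32), provenance="classical")
        strong = float(threshold_otsu(vals))
        if strong > p_low + 0.8 * delta:
            # Otsu collapsed into the shell mode (pores are a tiny class);
            # fall back to a quantile midpoint between pore and shell levels
            strong = p_low + 0.55 * delta
        # optional hysteresis: grow definite-pore cores up to a weaker level
        weak = strong + config.hysteresis_weak * (med - strong)
        if config.hysteresis_weak > 0:
            inv = 1.0 - norm
            grown = apply_hysteresis_threshold(inv, low=1.0 - weak, high=1.0 - strong)
            binary = mask & grown
        else:
            binary = mask & (norm < strong)
    else:  # otsu_local: block-wise local mean offset threshold
        from skimage.filters import threshold_local

        block = int(2 * round(25.0 / image.pixel_size) + 1)
        local_thr = threshold_local(norm, block_size=max(block, 3), offset=0.15)
        binary = mask & (norm < local_thr)
    return postprocess_binary(binary, image.pixel_size, config, provenance="classical")


def remove_artifacts(
    labelmap: PoreLabelMap, artifact_mask: np.ndarray
) -> PoreLabelMap:
    """Drop every pore component that touches the artifact mask.

    Emulates the manual correction step in which unwanted particles on the
    test surface are erased before measurement.  Whole components are
    removed (a pore contaminated by an artifact is not trusted), so the
    pore count never increases.
    """
    artifact_mask = np.asarray(artifact_mask, dtype=bool)
    if artifact_mask.shape != labelmap.labels.shape:
        raise ValueError("artifact mask shape does not match the label map")
    hit = np.unique(labelmap.labels[artifact_mask])
    hit = hit[hit > 0]
    labels = labelmap.labels.copy()
    if hit.size:
        labels[np.isin(labels, hit)] = 0
    # relabel consecutively, preserving component identity
    old = np.unique(labels)
    old = old[old > 0]
    lut = np.zeros(labelmap.labels.max(initial=0) + 1, dtype=np.int32)
    lut[old] = np.arange(1, old.size + 1)
    return PoreLabelMap(lut[labels], provenance="corrected")
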