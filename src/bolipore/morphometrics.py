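"""Per-pore and per-specimen pore parameters, and location summaries.

The three specimen-level parameters are

* pore density  PD = n_pores / ROI area            (pores/µm²)
* mean pore size  MPS = mean individual pore area  (µm²)
* porosity = 100 · Σ pore areas / ROI area         (% of ROI area)

which satisfy porosity = 100 · PD · MPS exactly for every specimen (the
identity does *not* survive averaging each parameter over a cohort, since a
mean of products is not the product of means).

A pore belongs to the ROI iff its centroid falls inside the ROI mask; an
included pore contributes its full area.  This keeps expected counts
unbiased at chamber boundaries and makes PD additive over chamber unions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .core import PoreLabelMap
from .roi import ROISelection

__all__ = [
    "SpecimenMorphometrics",
    "LocationSummary",
    "measure_pores",
    "specimen_params",
    "summarize_location",
    "PARAMETERS",
]

PARAMETERS = ("pore_density", "mean_pore_size", "porosity")


@dataclass
class SpecimenMorphometrics:
    specimen_id: str
    location: str
    species: str
    roi_area: float
    n_pores: int
    pore_density: float
    mean_pore_size: float
    porosity: float

    def as_dict(self) -> dict:
        return {
            "specimen_id": self.specimen_id,
            "location": self.location,
            "species": self.species,
            "roi_area_um2": self.roi_area,
            "n_pores": self.n_pores,
            "pore_density": self.pore_density,
            "mean_pore_size_um2": self.mean_pore_size,
            "porosity_pct": self.porosity,
        }


@dataclass
class LocationSummary:
    """Mean, sample SD (n−1) and SEM = SD/√n per parameter for one location."""

    location: str
    n: int
    stats: pd.DataFrame  # index: parameter; columns: mean, sd, sem


def measure_pores(
    labelmap: PoreLabelMap, roi: ROISelection, pixel_size: float
) -> pd.DataFrame:
    """Measure every pore whose centroid lies inside the ROI mask.

    Returns a DataFrame with columns ``pore_id``, ``area_um2``,
    ``centroid_row``, ``centroid_col``, ``eccentricity``; areas are full
    pixel counts × pixel_size², regardless of how much of the pore body
    crosses the ROI boundary.
    """
    if labelmap.labels.shape != roi.mask.shape:
        raise ValueError("label map and ROI mask are misaligned")
    rows = []
    for rp in regionprops(labelmap.labels):
        r = int(round(rp.centroid[0]))
        c = int(round(rp.centroid[1]))
        r = min(max(r, 0), roi.mask.shape[0] - 1)
        c = min(max(c, 0), roi.mask.shape[1] - 1)
        if not roi.mask[r, c]:
            continue
        rows.append(
            {
                "pore_id": int(rp.label),
                "area_um2": float(rp.area * pixel_size**2),
                "centroid_row": float(rp.centroid[0]),
                "centroid_col": float(rp.centroid[1]),
                "eccentricity": float(rp.eccentricity),
            }
        )
    return pd.DataFrame(
        rows, columns=["pore_id", "area_um2", "centroid_row", "centroid_col", "eccentricity"]
    )


def specimen_params(
    records: pd.DataFrame,
    roi: ROISelection,
    meta: "dict | None" = None,
) -> SpecimenMorphometrics:
    """Aggregate per-pore records into the specimen-level parameters.

    With zero pores, PD and porosity are 0 and MPS is reported as NaN (with
    a warning) rather than 0, so that downstream size regressions are not
    corrupted by fictitious zero-size pores.
    """
    meta = meta or {}
    if roi.area <= 0:
        raise ValueError("ROI area must be positive")
    n = len(records)
    pd_ = n / roi.area
    total = float(records["area_um2"].sum()) if n else 0.0
    if n:
        mps = total / n
    else:
        warnings.warn("specimen has no pores; mean pore size is undefined", stacklevel=2)
        mps = float("nan")
    porosity = 100.0 * total / roi.area
    return SpecimenMorphometrics(
        specimen_id=str(meta.get("specimen_id", "")),
        location=str(meta.get("location", "")),
        species=str(meta.get("species", "B. spissa")),
        roi_area=float(roi.area),
        n_pores=n,
        pore_density=float(pd_),
        mean_pore_size=mps,
        porosity=float(porosity),
    )


def summarize_location(specimens: "list[SpecimenMorphometrics]") -> LocationSummary:
    """Summarise one location's specimens: mean, sample SD, SEM.

    With a single specimen the SD and SEM are undefined and reported NaN.
    """
    if not specimens:
        raise ValueError("no specimens to summarize")
    locs = {s.location for s in specimens}
    if len(locs) > 1:
        raise ValueError(f"specimens span multiple locations: {sorted(locs)}")
    n = len(specimens)
    rows = {}
    for p in PARAMETERS:
        x = np.array([getattr(s, p) for s in specimens], dtype=float)
        mean = float(np.nanmean(x))
        if n >= 2:
            sd = float(np.nanstd(x, ddof=1))
            sem = sd / np.sqrt(n)
        else:
            sd = float("nan")
            sem = float("nan")
        rows[p] = {"mean": mean, "sd": sd, "sem": sem}
    stats = pd.DataFrame(rows).T[["mean", "sd", "sem"]]
    return LocationSummary(location=locs.pop(), n=n, stats=stats)
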