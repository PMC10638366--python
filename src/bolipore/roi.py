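"""Ontogenetic size normalisation: select the oldest chambers covering
50,000–70,000 µm².

Pore density rises with each newly built chamber as the surface/volume
ratio falls, so specimens at different growth stages are only comparable
over a fixed-area window of their oldest chambers.  The window binds on
area, not chamber count; whole chambers only — a prefix that overshoots the
upper bound is an error rather than a partial crop.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core import ChamberMap

__all__ = [
    "ROISelection",
    "SpecimenTooSmallError",
    "WindowUnattainableError",
    "DEFAULT_WINDOW",
    "order_chambers",
    "select_roi",
    "select_prefix_by_area",
]

#: Cumulative-area window of the oldest chambers, µm².
DEFAULT_WINDOW: tuple[float, float] = (50_000.0, 70_000.0)


class SpecimenTooSmallError(RuntimeError):
    """Total test area below the lower window bound."""


class WindowUnattainableError(RuntimeError):
    """No whole-chamber prefix lands inside the area window."""


@dataclass
class ROISelection:
    """The measurement region: a prefix of the ontogenetically oldest
    chambers, its binary mask and its area in µm²."""

    chamber_ranks_included: tuple[int, ...]
    mask: np.ndarray
    area: float


def order_chambers(chambers: ChamberMap) -> list[int]:
    """Return chamber labels ordered oldest → youngest.

    Explicit ontogeny ranks are passed through; otherwise chambers are
    ranked by increasing centroid distance from the apex coordinate.
    """
    labels = chambers.chamber_labels
    if labels.size == 0:
        raise ValueError("chamber map is empty")
    if chambers.ontogeny_order is not None:
        return sorted(labels.tolist(), key=lambda l: chambers.ontogeny_order[l])
    if chambers.apex is None:
        raise ValueError("chamber map has neither ontogeny ranks nor an apex")
    cents = ndi.center_of_mass(np.ones_like(chambers.labels), chambers.labels, labels)
    ay, ax = chambers.apex
    dists = [np.hypot(cy - ay, cx - ax) for cy, cx in cents]
    return [int(l) for _, l in sorted(zip(dists, labels.tolist()))]


def select_prefix_by_area(
    areas_um2: "list[float] | np.ndarray",
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> tuple[int, float]:
    """Pure-arithmetic core of the window rule.

    Given chamber areas ordered oldest → youngest, return ``(k, area)``
    where the first ``k`` chambers are the smallest prefix with cumulative
    area at or above the lower bound.  Raises if the total falls short or
    the prefix overshoots the upper bound.
    """
    lo, hi = window
    areas = np.asarray(areas_um2, dtype=float)
    cum = np.cumsum(areas)
    if cum.size == 0 or cum[-1] < lo:
        total = float(cum[-1]) if cum.size else 0.0
        raise SpecimenTooSmallError(
            f"specimen too small: total area {total:.0f} µm² < {lo:.0f} µm²"
        )
    k = int(np.searchsorted(cum, lo, side="left")) + 1
    area = float(cum[k - 1])
    if area > hi:
        raise WindowUnattainableError(
            f"window unattainable: oldest {k} chambers cover {area:.0f} µm² > {hi:.0f} µm²"
        )
    return k, area


def select_roi(
    chambers: ChamberMap,
    order: "list[int] | None" = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
    pixel_size: float = 1.0,
) -> ROISelection:
    """Select the size-normalised region of interest.

    Chamber areas are taken from pixel counts of the chamber map scaled by
    ``pixel_size``²; the selection is the smallest oldest-chamber prefix
    whose cumulative area reaches the window.
    """
    if order is None:
        order = order_chambers(chambers)
    if not order:
        raise ValueError("empty chamber order")
    counts = np.bincount(chambers.labels.ravel(), minlength=max(order) + 1)
    areas = [counts[l] * pixel_size**2 for l in order]
    k, area = select_prefix_by_area(areas, window)
    included = order[:k]
    mask = np.isin(chambers.labels, included)
    ranks = tuple(range(1, k + 1))
    return ROISelection(chamber_ranks_included=ranks, mask=mask, area=area)
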