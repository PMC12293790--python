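"""Iterative nuclear-stain threshold ("peeling") segmentation.

Nuclei in tissue sections imaged at 20x overlap heavily, and a single global
threshold on the DAPI channel fuses neighbouring nuclei into one region.
This module exploits the fact that DAPI intensity is highest at a nucleus's
center and falls off toward its boundary: the stain threshold is raised
step-by-step (by a user-defined *range*), and at each step any connected
region that is fully isolated and whose boundary-pixel count fits within the
user-defined *perimeter* is accepted as one nucleus, recorded, and erased
before the next step.  Overlapping nuclei that form one oversized region at
a low threshold separate into individually acceptable cores at a higher one.

Conventions (fixed so an independent re-implementation can reproduce the
output exactly):

- "above the threshold" keeps values >= T; values < T are deleted;
- regions are 8-connected components of the surviving pixels;
- the boundary of a region is the count of member pixels with at least one
  4-neighbour outside the region (image edges count as outside);
- components are processed in raster-scan order of their first pixel, and
  nuclei are returned in acceptance order;
- a nucleus's pixel set is recorded at its acceptance threshold (its bright
  core), optionally dilated back toward the original footprint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "SegmentationParams",
    "Nucleus",
    "boundary_length",
    "peel_iteration",
    "segment_nuclei",
]

_EIGHT = np.ones((3, 3), dtype=bool)
_FOUR = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the peeling segmentation.

    dapi_start_threshold
        First nuclear-stain threshold, 0-255 scale.
    range_increment
        Per-iteration threshold increase (the "range").
    dapi_upper_limit
        Iteration stops once the threshold exceeds this.
    perimeter_max
        Maximum boundary-pixel count for a region to be accepted as a single
        nucleus; fused nuclei exceed it and are deferred to later iterations.
    min_area_px
        Specks smaller than this are never accepted (noise floor).
    dilate_px
        If > 0, each accepted nucleus's pixel set is grown back by this many
        morphological dilation steps, restricted to pixels that were above
        the start threshold and unclaimed by other nuclei.  Off by default:
        marker statistics then use the bright core recorded at acceptance.
    """

    dapi_start_threshold: int = 40
    range_increment: int = 10
    dapi_upper_limit: int = 255
    perimeter_max: int = 120
    min_area_px: int = 20
    dilate_px: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dapi_start_threshold <= 255:
            raise ValueError("dapi_start_threshold must be in [0, 255]")
        if self.range_increment < 1:
            raise ValueError("range_increment must be >= 1")
        if not self.dapi_start_threshold < self.dapi_upper_limit <= 255:
            raise ValueError("need dapi_start_threshold < dapi_upper_limit <= 255")
        if self.perimeter_max < 1 or self.min_area_px < 1 or self.dilate_px < 0:
            raise ValueError("perimeter_max/min_area_px must be positive, dilate_px >= 0")

    def max_iterations(self) -> int:
        """Guaranteed upper bound on the number of peel iterations."""
        span = self.dapi_upper_limit - self.dapi_start_threshold
        return math.ceil(span / self.range_increment) + 1


@dataclass(eq=False)
class Nucleus:
    """One accepted nucleus: its pixels at acceptance, centroid and boundary.

    Pixel coordinates are (x, y) = (column, row) within the tile the
    segmentation ran on.
    """

    pixel_set: frozenset[tuple[int, int]]
    centroid: tuple[float, float]
    area_px: int
    boundary_px: int
    accept_threshold: int

    @classmethod
    def from_mask(cls, region: np.ndarray, threshold: int) -> "Nucleus":
        ys, xs = np.nonzero(region)
        return cls(
            pixel_set=frozenset(zip(xs.tolist(), ys.tolist())),
            centroid=(float(xs.mean()), float(ys.mean())),
            area_px=int(len(xs)),
            boundary_px=boundary_length_mask(region),
            accept_threshold=int(threshold),
        )


def boundary_length_mask(region: np.ndarray) -> int:
    """Boundary-pixel count of a boolean region mask (4-neighbourhood)."""
    if not region.any():
        raise ValueError("empty region")
    interior = ndimage.binary_erosion(region, structure=_FOUR, border_value=0)
    return int(region.sum() - interior.sum())


def boundary_length(pixel_set) -> int:
    """Boundary-pixel count of a set of (x, y) pixels.

    A member pixel is on the boundary iff at least one of its 4-neighbours
    is not in the set.
    """
    pixels = set(pixel_set)
    if not pixels:
        raise ValueError("empty pixel set")
    n = 0
    for x, y in pixels:
        if (
            (x - 1, y) not in pixels
            or (x + 1, y) not in pixels
            or (x, y - 1) not in pixels
            or (x, y + 1) not in pixels
        ):
            n += 1
    return n


def _ordered_labels(labels: np.ndarray, n: int) -> list[int]:
    """Component labels sorted by first pixel in raster-scan order."""
    flat = labels.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    idx = np.nonzero(flat)[0]
    # reversed so earlier indices overwrite later ones
    first[flat[idx[::-1]]] = idx[::-1]
    return sorted(range(1, n + 1), key=lambda lab: first[lab])


def peel_iteration(
    working: np.ndarray, threshold: int, params: SegmentationParams
) -> tuple[list[Nucleus], np.ndarray]:
    """One peel step at a fixed threshold.

    Deletes pixels below ``threshold``, labels the survivors, accepts every
    component whose area is at least ``min_area_px`` and whose boundary fits
    within ``perimeter_max``, and erases accepted pixels from the returned
    working image.  Unaccepted components survive into ``remaining`` for the
    next, higher, threshold.
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    remaining = np.where(working >= threshold, working, 0)
    surviving = remaining > 0
    labels, n = ndimage.label(surviving, structure=_EIGHT)
    accepted: list[Nucleus] = []
    for lab in _ordered_labels(labels, n):
        region = labels == lab
        area = int(region.sum())
        if area < params.min_area_px:
            continue
        if boundary_length_mask(region) > params.perimeter_max:
            continue
        accepted.append(Nucleus.from_mask(region, threshold))
        remaining[region] = 0
    return accepted, remaining


def segment_nuclei(tile, params: SegmentationParams | None = None) -> list[Nucleus]:
    """Segment all nuclei in a spot tile by iterative threshold peeling.

    ``tile`` may be a :class:`~spotcall.masking.SpotTile` (its masked nuclear
    channel is used) or a bare 2-D array of nuclear-stain intensities.
    Iterates thresholds ``start, start + range, ...`` until the threshold
    exceeds the upper limit or the working image is black; returns accepted
    nuclei in acceptance order, with pairwise-disjoint pixel sets.
    """
    if params is None:
        params = SegmentationParams()
    if hasattr(tile, "masked_channel"):
        working = tile.masked_channel(tile.nuclear_channel).astype(np.int32)
    else:
        working = np.asarray(tile).astype(np.int32)
        if working.ndim != 2:
            raise ValueError("expected a 2-D nuclear-intensity array")
    initial = working >= params.dapi_start_threshold

    nuclei: list[Nucleus] = []
    threshold = params.dapi_start_threshold
    while threshold <= params.dapi_upper_limit and working.any():
        accepted, working = peel_iteration(working, threshold, params)
        nuclei.extend(accepted)
        threshold += params.range_increment

    if params.dilate_px > 0 and nuclei:
        nuclei = _dilate_back(nuclei, initial, params.dilate_px)
    return nuclei


def _dilate_back(
    nuclei: list[Nucleus], initial: np.ndarray, steps: int
) -> list[Nucleus]:
    """Grow accepted cores back toward the start-threshold footprint.

    Earlier-accepted nuclei claim contested pixels first; growth never
    leaves the initial footprint or enters another nucleus.
    """
    claimed = np.zeros_like(initial, dtype=bool)
    masks = []
    for nuc in nuclei:
        m = np.zeros_like(initial, dtype=bool)
        xs = [p[0] for p in nuc.pixel_set]
        ys = [p[1] for p in nuc.pixel_set]
        m[ys, xs] = True
        claimed |= m
        masks.append(m)
    out = []
    for nuc, m in zip(nuclei, masks):
        allowed = initial & ~(claimed & ~m)
        grown = ndimage.binary_dilation(m, structure=_EIGHT, iterations=steps, mask=allowed)
        claimed |= grown
        new = Nucleus.from_mask(grown, nuc.accept_threshold)
        out.append(new)
    return out
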