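"""Marker-positivity quantification within one spot.

A pixel is marker-positive when every RGB channel falls inside a closed
user-defined [min, max] range — determined against biological controls.  A
cell is positive when enough of its nucleus pixels are positive.  The spot
intensity is the mean main-channel value over marker-positive pixels lying
inside segmented nuclei: restricting to nuclei excludes red-blood-cell
autofluorescence (red signal with no underlying nuclear stain) from the
measurement, the main false-positive source for a red nuclear marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .masking import SpotTile
from .segmentation import Nucleus, SegmentationParams, segment_nuclei

__all__ = [
    "MarkerParams",
    "SpotMeasurements",
    "pixel_marker_mask",
    "classify_cells",
    "spot_intensity",
    "quantify_spot",
]


@dataclass(frozen=True)
class MarkerParams:
    """RGB positivity thresholds and the per-cell positivity rule.

    rgb_min, rgb_max
        Closed per-channel intensity range a pixel must fall into to be
        marker-positive (0-255 scale each).
    main_channel
        The fluorophore's dominant channel (Texas Red: 0).
    cell_positive_pixel_fraction
        Fraction of a nucleus's pixels that must be positive for the cell to
        count as positive; inclusive at the boundary.
    min_positive_pixels
        Alternative absolute-count rule: when set, a cell is positive iff it
        has at least this many positive pixels (the fraction is ignored).
    intensity_scope
        "nuclei" (default) averages the main channel over positive pixels
        inside segmented nuclei; "spot" averages over all positive pixels in
        the spot disk, a looser reading that does not exclude RBC blobs.
    """

    rgb_min: tuple[int, int, int] = (100, 0, 0)
    rgb_max: tuple[int, int, int] = (255, 255, 255)
    main_channel: int = 0
    cell_positive_pixel_fraction: float = 0.10
    min_positive_pixels: int | None = None
    intensity_scope: str = "nuclei"

    def __post_init__(self) -> None:
        for lo, hi in zip(self.rgb_min, self.rgb_max):
            if not (0 <= lo <= hi <= 255):
                raise ValueError("need 0 <= rgb_min <= rgb_max <= 255 per channel")
        if not 0 < self.cell_positive_pixel_fraction <= 1:
            raise ValueError("cell_positive_pixel_fraction must be in (0, 1]")
        if self.intensity_scope not in ("nuclei", "spot"):
            raise ValueError("intensity_scope must be 'nuclei' or 'spot'")


@dataclass(frozen=True)
class SpotMeasurements:
    """Per-spot quantities: counts, percent positivity and marker intensity."""

    n_cells: int
    n_positive_cells: int
    pct_positive: float
    spot_intensity: float

    def __post_init__(self) -> None:
        if self.n_positive_cells > self.n_cells:
            raise ValueError("positive cells exceed total cells")


def pixel_marker_mask(tile: SpotTile, params: MarkerParams) -> np.ndarray:
    """Boolean mask of marker-positive pixels inside the spot disk."""
    px = tile.tile.astype(np.int32)
    lo = np.asarray(params.rgb_min, dtype=np.int32)
    hi = np.asarray(params.rgb_max, dtype=np.int32)
    within = np.all((px >= lo) & (px <= hi), axis=-1)
    return within & tile.mask


def classify_cells(
    nuclei: list[Nucleus], marker_mask: np.ndarray, params: MarkerParams
) -> list[bool]:
    """Per-cell positivity flags, in the order the nuclei were accepted."""
    flags = []
    for nuc in nuclei:
        pos = sum(1 for x, y in nuc.pixel_set if marker_mask[y, x])
        if params.min_positive_pixels is not None:
            flags.append(pos >= params.min_positive_pixels)
        else:
            flags.append(pos / nuc.area_px >= params.cell_positive_pixel_fraction)
    return flags


def spot_intensity(
    tile: SpotTile,
    nuclei: list[Nucleus],
    marker_mask: np.ndarray,
    params: MarkerParams,
) -> float:
    """Mean main-channel intensity over the measurement pixel set.

    With the default nuclei scope the set is {marker-positive pixels inside
    some nucleus}; 0.0 when the set is empty.
    """
    if params.intensity_scope == "spot":
        sel = marker_mask
    else:
        sel = np.zeros_like(marker_mask)
        for nuc in nuclei:
            for x, y in nuc.pixel_set:
                sel[y, x] = True
        sel &= marker_mask
    if not sel.any():
        return 0.0
    return float(tile.tile[:, :, params.main_channel][sel].mean())


def quantify_spot(
    tile: SpotTile,
    seg_params: SegmentationParams | None = None,
    marker_params: MarkerParams | None = None,
    *,
    nuclei: list[Nucleus] | None = None,
) -> SpotMeasurements:
    """Segment, classify and measure one spot.

    Pre-segmented ``nuclei`` may be supplied (e.g. for QC reuse); otherwise
    :func:`segment_nuclei` runs on the tile's masked nuclear channel.
    """
    marker_params = marker_params or MarkerParams()
    if nuclei is None:
        nuclei = segment_nuclei(tile, seg_params)
    mask = pixel_marker_mask(tile, marker_params)
    flags = classify_cells(nuclei, mask, marker_params)
    n = len(nuclei)
    npos = sum(flags)
    return SpotMeasurements(
        n_cells=n,
        n_positive_cells=npos,
        pct_positive=100.0 * npos / n if n else 0.0,
        spot_intensity=spot_intensity(tile, nuclei, mask, marker_params),
    )
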