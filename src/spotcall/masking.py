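"""Spot geometry: physical diameter -> pixel radius, and masked tile extraction.

Every downstream measurement runs on a :class:`SpotTile`: a square crop
centered on the spot with a circular mask; pixels outside the mask count as
black.  Tiles at image borders are clipped, and the clipped-away area also
counts as black, so a spot near the edge simply analyses fewer pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import SlideImage, SpotRecord

__all__ = ["SpotTile", "spot_radius_px", "extract_spot_tile"]


def spot_radius_px(diameter_um: float, microns_per_pixel: float) -> int:
    """Integer pixel radius of a spot of physical ``diameter_um``.

    Uses round-half-up on ``diameter / (2 * scale)``; raises if the scale is
    too coarse for the spot to span at least one pixel of radius.
    """
    if not (diameter_um > 0 and microns_per_pixel > 0):
        raise ValueError("diameter and pixel scale must be positive")
    r = math.floor(diameter_um / (2.0 * microns_per_pixel) + 0.5)
    if r < 1:
        raise ValueError(
            f"pixel scale {microns_per_pixel} um/px too coarse for a "
            f"{diameter_um} um spot (radius would be {r} px)"
        )
    return r


@dataclass(eq=False)
class SpotTile:
    """A masked square crop around one spot.

    ``tile`` keeps the raw pixel values; ``mask`` is True inside the spot
    disk.  ``masked()`` returns the working copy (outside-mask pixels set to
    zero) that segmentation and quantification consume.
    """

    tile: np.ndarray  # (h, w, 3) uint8
    mask: np.ndarray  # (h, w) bool
    origin_x: int
    origin_y: int
    spot: SpotRecord
    radius_px: int
    nuclear_channel: int = 2
    main_channel: int = 0

    def masked(self) -> np.ndarray:
        """RGB tile with outside-mask pixels zeroed."""
        out = self.tile.copy()
        out[~self.mask] = 0
        return out

    def masked_channel(self, channel: int) -> np.ndarray:
        """One channel of the tile with outside-mask pixels zeroed."""
        out = self.tile[:, :, channel].copy()
        out[~self.mask] = 0
        return out


def extract_spot_tile(image: SlideImage, spot: SpotRecord) -> SpotTile:
    """Cut the square tile around ``spot`` and build its disk mask.

    A pixel (px, py) is inside the spot iff
    ``(px - cx)**2 + (py - cy)**2 <= r**2`` on the integer lattice, with the
    center rounded to the nearest pixel.
    """
    if not image.contains(spot.center_x, spot.center_y):
        raise ValueError(
            f"spot {spot.barcode!r} center ({spot.center_x}, {spot.center_y}) "
            f"outside image of size {image.width}x{image.height}"
        )
    r = spot_radius_px(spot.diameter_um, image.microns_per_pixel)
    cx = int(round(spot.center_x))
    cy = int(round(spot.center_y))

    x0, x1 = max(0, cx - r), min(image.width - 1, cx + r)
    y0, y1 = max(0, cy - r), min(image.height - 1, cy + r)
    tile = image.pixels[y0 : y1 + 1, x0 : x1 + 1, :].copy()

    yy, xx = np.ogrid[y0 : y1 + 1, x0 : x1 + 1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    return SpotTile(
        tile=tile,
        mask=mask,
        origin_x=x0,
        origin_y=y0,
        spot=spot,
        radius_px=r,
        nuclear_channel=image.nuclear_channel,
        main_channel=image.main_channel,
    )
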