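"""Quality-control overlays: spot circles drawn on the slide raster."""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
from skimage.draw import circle_perimeter

from .io import SlideImage
from .masking import spot_radius_px

__all__ = ["save_spot_overlay"]

_CALL_COLORS = {
    "positive": (255, 64, 64),
    "negative": (64, 160, 255),
    "excluded": (160, 160, 160),
}


def save_spot_overlay(image: SlideImage, results, path: str | os.PathLike) -> None:
    """Write a PNG of the slide with each spot circled, coloured by call."""
    canvas = image.pixels.copy()
    for r in results:
        radius = spot_radius_px(55.0 if not hasattr(r, "diameter_um") else r.diameter_um,
                                image.microns_per_pixel)
        rr, cc = circle_perimeter(
            int(round(r.center_y)), int(round(r.center_x)), radius,
            shape=canvas.shape[:2],
        )
        canvas[rr, cc] = np.asarray(_CALL_COLORS.get(r.call, (255, 255, 255)), dtype=np.uint8)
    iio.imwrite(os.fspath(path), canvas)
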