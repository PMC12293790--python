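"""Watch the iterative threshold peeling separate two fused nuclei.

Two center-bright Gaussian nuclei overlap enough that a single DAPI
threshold sees one region.  Raising the threshold step by step shrinks the
region toward the two bright cores; once they separate and each core's
boundary fits the perimeter limit, they are accepted as individual cells.
"""

import numpy as np
from scipy import ndimage

from spotcall.segmentation import SegmentationParams, peel_iteration, segment_nuclei

size, d, sigma, peak = 49, 12.0, 4.3, 220
c = size // 2
yy, xx = np.mgrid[0:size, 0:size]
g1 = peak * np.exp(-(((xx - (c - d / 2)) ** 2 + (yy - c) ** 2)) / (2 * sigma**2))
g2 = peak * np.exp(-(((xx - (c + d / 2)) ** 2 + (yy - c) ** 2)) / (2 * sigma**2))
tile = np.clip(np.rint(np.maximum(g1, g2)), 0, 255).astype(np.uint8)

params = SegmentationParams(
    dapi_start_threshold=40, range_increment=10, perimeter_max=40, min_area_px=20
)

_, n_single = ndimage.label(tile >= params.dapi_start_threshold, structure=np.ones((3, 3)))
print(f"single threshold at {params.dapi_start_threshold}: {n_single} region(s)")

working = tile.astype(np.int32)
threshold = params.dapi_start_threshold
while threshold <= params.dapi_upper_limit and working.any():
    accepted, working = peel_iteration(working, threshold, params)
    _, n_regions = ndimage.label(working > 0, structure=np.ones((3, 3)))
    print(
        f"threshold {threshold:>3}: accepted {len(accepted)} nucleus/nuclei, "
        f"{n_regions} region(s) remain"
    )
    threshold += params.range_increment

nuclei = segment_nuclei(tile, params)
print(f"\nfinal count: {len(nuclei)} nuclei, accepted at thresholds "
      f"{[n.accept_threshold for n in nuclei]}")
print("a fused pair is deferred (boundary too long) until its bright cores "
      "separate —\nthe reason segmentation works where one global threshold "
      "cannot.")
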