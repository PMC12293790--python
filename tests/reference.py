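"""Independent brute-force references used to cross-check the implementation.

Everything here is deliberately naive — explicit loops, BFS flood fill —
and shares no code with the package.
"""

from __future__ import annotations

from collections import deque


def ref_segment(tile, start, increment, upper, perimeter_max, min_area):
    """Peeling segmentation by explicit per-threshold flood fill.

    ``tile`` is a 2-D list/array of intensities.  Returns a list of
    (frozenset of (x, y), accept_threshold) in acceptance order.
    """
    h = len(tile)
    w = len(tile[0]) if h else 0
    working = [[int(tile[y][x]) for x in range(w)] for y in range(h)]
    accepted = []
    threshold = start
    while threshold <= upper and any(v > 0 for row in working for v in row):
        # delete below-threshold pixels
        for y in range(h):
            for x in range(w):
                if working[y][x] < threshold:
                    working[y][x] = 0
        # label 8-connected components in raster-scan order of first pixel
        seen = [[False] * w for _ in range(h)]
        for y0 in range(h):
            for x0 in range(w):
                if working[y0][x0] == 0 or seen[y0][x0]:
                    continue
                comp = []
                queue = deque([(x0, y0)])
                seen[y0][x0] = True
                while queue:
                    x, y = queue.popleft()
                    comp.append((x, y))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            nx, ny = x + dx, y + dy
                            if (
                                0 <= nx < w
                                and 0 <= ny < h
                                and not seen[ny][nx]
                                and working[ny][nx] > 0
                            ):
                                seen[ny][nx] = True
                                queue.append((nx, ny))
                pixels = set(comp)
                boundary = sum(
                    1
                    for (x, y) in comp
                    if (x - 1, y) not in pixels
                    or (x + 1, y) not in pixels
                    or (x, y - 1) not in pixels
                    or (x, y + 1) not in pixels
                )
                if len(comp) >= min_area and boundary <= perimeter_max:
                    accepted.append((frozenset(pixels), threshold))
                    for x, y in comp:
                        working[y][x] = 0
        threshold += increment
    return accepted


def ref_quantify(rgb, mask, nuclei_pixel_sets, rgb_min, rgb_max, main_channel, fraction):
    """Per-pixel triple-loop marker quantification.

    Returns (n_cells, n_positive, pct_positive, spot_intensity) with the
    same semantics as the package: a pixel is positive iff every channel is
    within its closed range and the pixel is inside the spot mask; a cell is
    positive iff its positive fraction reaches ``fraction``; intensity is
    the mean main-channel value over positive pixels inside nuclei.
    """
    h = len(rgb)
    w = len(rgb[0]) if h else 0
    positive = [[False] * w for _ in range(h)]
    for y in range(h):
        for x in range(w):
            if not mask[y][x]:
                continue
            ok = True
            for c in range(3):
                v = int(rgb[y][x][c])
                if v < rgb_min[c] or v > rgb_max[c]:
                    ok = False
                    break
            positive[y][x] = ok
    n_cells = len(nuclei_pixel_sets)
    n_pos = 0
    values = []
    for pixels in nuclei_pixel_sets:
        hits = 0
        for x, y in pixels:
            if positive[y][x]:
                hits += 1
                values.append(int(rgb[y][x][main_channel]))
        if hits / len(pixels) >= fraction:
            n_pos += 1
    pct = 100.0 * n_pos / n_cells if n_cells else 0.0
    intensity = sum(values) / len(values) if values else 0.0
    return n_cells, n_pos, pct, intensity


def random_test_tile(rng, size=None):
    """A random small intensity tile: blobs + speckle + flat patches."""
    import numpy as np

    h = int(rng.integers(8, 33)) if size is None else size
    w = int(rng.integers(8, 33)) if size is None else size
    tile = np.zeros((h, w), dtype=float)
    for _ in range(int(rng.integers(1, 6))):
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        sigma = rng.uniform(1.0, 4.0)
        peak = rng.uniform(60, 255)
        yy, xx = np.mgrid[0:h, 0:w]
        tile = np.maximum(tile, peak * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2)))
    # speckle noise and an occasional flat rectangle
    tile += rng.normal(0, 15, size=(h, w))
    if rng.uniform() < 0.5:
        x0, y0 = int(rng.integers(0, w)), int(rng.integers(0, h))
        tile[y0 : y0 + int(rng.integers(2, 8)), x0 : x0 + int(rng.integers(2, 8))] = rng.uniform(0, 255)
    return np.clip(np.rint(tile), 0, 255).astype(np.uint8)
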