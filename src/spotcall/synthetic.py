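"""Synthetic slides, spot grids and ratings with known ground truth.

The renderer emulates the features of a DAPI + red-marker fluorescence scan
that the analysis depends on:

- circular 55 um capture spots, each containing on the order of tens of
  nuclei (per-spot counts drawn around the low-forties, matching reported
  per-spot cell statistics for dense brain-tumour tissue);
- nuclei as center-bright, edge-dim blue blobs (clipped 2-D Gaussians), the
  premise the iterative peeling segmentation relies on, with neighbouring
  nuclei allowed to overlap;
- punctate red marker foci confined to the nuclei designated positive;
- nucleus-free red autofluorescent blobs (red-blood-cell confounders) with
  zero blue signal, so nuclei-restricted intensity measurement is testable
  in isolation;
- mild Gaussian background noise.

All randomness flows from a single integer seed; the same spec renders the
same bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .agreement import RatingsMatrix
from .calling import CallParams
from .io import SPOT_DIAMETER_UM, SlideImage, SpotGrid, SpotRecord
from .masking import spot_radius_px
from .segmentation import SegmentationParams

__all__ = [
    "NucleusModel",
    "SpotSpec",
    "SceneSpec",
    "GroundTruth",
    "render_slide",
    "grid_scene",
    "make_ratings",
]


@dataclass(frozen=True)
class NucleusModel:
    """Appearance model of one nucleus.

    Nuclei are drawn as clipped isotropic Gaussians on the blue channel:
    peak intensity drawn uniformly from ``peak_range``, standard deviation
    ``radius_um / (microns_per_pixel * sigma_factor)`` so that intensity at
    the nominal radius falls below a typical start threshold — the minimal
    profile satisfying the segmentation's center-bright premise.
    """

    radius_um: float = 3.0
    peak_range: tuple[int, int] = (180, 240)
    sigma_factor: float = 1.85
    render_floor: int = 10  # values below this are not drawn

    def radius_px(self, microns_per_pixel: float) -> float:
        return self.radius_um / microns_per_pixel

    def sigma_px(self, microns_per_pixel: float) -> float:
        return self.radius_px(microns_per_pixel) / self.sigma_factor


@dataclass(frozen=True)
class SpotSpec:
    """One spot to render: where, how many nuclei, what fraction positive."""

    center_x: float
    center_y: float
    n_nuclei: int
    positive_fraction: float = 0.0
    barcode: str | None = None


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic slide; ``seed`` is mandatory."""

    width: int
    height: int
    spots: tuple[SpotSpec, ...]
    seed: int
    microns_per_pixel: float = 0.5
    spot_diameter_um: float = SPOT_DIAMETER_UM
    nucleus: NucleusModel = field(default_factory=NucleusModel)
    separation_factor: float = 1.4  # min center distance, in nucleus radii
    foci_per_positive: int = 4
    focus_radius_px: float = 2.0
    focus_offset_px: float = 1.0
    focus_intensity: int = 200
    rbc_per_spot: int = 1
    rbc_radius_px: float = 4.0
    rbc_intensity: int = 180
    noise_sigma: float = 2.0

    def suggested_segmentation_params(self) -> SegmentationParams:
        """Peeling parameters matched to this scene's nucleus scale.

        ``perimeter_max`` sits above the boundary count of one nucleus core
        but below that of two fused cores, so overlapping pairs are deferred
        until a higher threshold separates them.
        """
        r = self.nucleus.radius_px(self.microns_per_pixel)
        return SegmentationParams(
            dapi_start_threshold=40,
            range_increment=10,
            dapi_upper_limit=255,
            perimeter_max=max(8, int(round(6.7 * r))),
            min_area_px=max(6, int(round(0.55 * r * r))),
        )


@dataclass(eq=False)
class GroundTruth:
    """What the renderer actually placed, per spot and per nucleus."""

    spots: pd.DataFrame  # barcode, n_cells, n_positive, pct_positive, call
    nuclei: pd.DataFrame  # barcode, x, y, peak, positive


def _place_centers(
    rng: np.random.Generator,
    n: int,
    cx: float,
    cy: float,
    placement_radius: float,
    min_separation: float,
    max_attempts_per_point: int = 400,
) -> np.ndarray:
    """Rejection-sample n points in a disk with pairwise min separation."""
    pts: list[tuple[float, float]] = []
    attempts = 0
    limit = max_attempts_per_point * max(n, 1)
    while len(pts) < n:
        if attempts > limit:
            raise ValueError(
                f"could not place {n} nuclei in a spot of placement radius "
                f"{placement_radius:.1f}px at separation {min_separation:.1f}px: "
                "spec is overcrowded"
            )
        attempts += 1
        rr = placement_radius * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        x, y = cx + rr * np.cos(th), cy + rr * np.sin(th)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_separation**2 for px, py in pts):
            pts.append((x, y))
    return np.asarray(pts, dtype=float).reshape(n, 2)


def _draw_gaussian(channel: np.ndarray, x: float, y: float, peak: float, sigma: float, floor: int) -> None:
    """Max-blend a clipped Gaussian blob into one channel (in place)."""
    h, w = channel.shape
    ext = int(np.ceil(sigma * np.sqrt(2.0 * np.log(peak / floor)))) + 1
    x0, x1 = max(0, int(x) - ext), min(w - 1, int(x) + ext)
    y0, y1 = max(0, int(y) - ext), min(h - 1, int(y) + ext)
    if x0 > x1 or y0 > y1:
        return
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    vals = peak * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma**2))
    vals[vals < floor] = 0.0
    region = channel[y0 : y1 + 1, x0 : x1 + 1]
    np.maximum(region, vals, out=region)


def _draw_disk(channel: np.ndarray, x: float, y: float, radius: float, value: float) -> None:
    h, w = channel.shape
    ext = int(np.ceil(radius)) + 1
    x0, x1 = max(0, int(x) - ext), min(w - 1, int(x) + ext)
    y0, y1 = max(0, int(y) - ext), min(h - 1, int(y) + ext)
    if x0 > x1 or y0 > y1:
        return
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    inside = (xx - x) ** 2 + (yy - y) ** 2 <= radius**2
    region = channel[y0 : y1 + 1, x0 : x1 + 1]
    region[inside] = np.maximum(region[inside], value)


def render_slide(
    spec: SceneSpec, call_params: CallParams | None = None
) -> tuple[SlideImage, SpotGrid, GroundTruth]:
    """Render a slide from a scene spec; deterministic given ``spec.seed``.

    The returned ground-truth calls are what a perfect analysis under
    ``call_params`` (default rule) would report: excluded below the
    minimum cell count, else decided by the true positive fraction (marker
    intensity inside foci equals ``spec.focus_intensity``).
    """
    call_params = call_params or CallParams()
    rng = np.random.default_rng(spec.seed)
    red = np.zeros((spec.height, spec.width), dtype=float)
    green = np.zeros_like(red)
    blue = np.zeros_like(red)

    mpp = spec.microns_per_pixel
    r_spot = spot_radius_px(spec.spot_diameter_um, mpp)
    r_nuc = spec.nucleus.radius_px(mpp)
    sigma = spec.nucleus.sigma_px(mpp)
    sep = spec.separation_factor * r_nuc

    spot_rows, nuc_rows, records = [], [], []
    for k, s in enumerate(spec.spots):
        barcode = s.barcode or f"SPOT-{k + 1:04d}"
        records.append(
            SpotRecord(
                barcode=barcode,
                center_x=s.center_x,
                center_y=s.center_y,
                diameter_um=spec.spot_diameter_um,
            )
        )
        centers = _place_centers(rng, s.n_nuclei, s.center_x, s.center_y, r_spot - r_nuc - 1.0, sep)
        n_pos = int(round(s.positive_fraction * s.n_nuclei))
        pos_idx = set(rng.choice(s.n_nuclei, size=n_pos, replace=False).tolist()) if n_pos else set()

        for i, (x, y) in enumerate(centers):
            peak = float(rng.integers(spec.nucleus.peak_range[0], spec.nucleus.peak_range[1] + 1))
            _draw_gaussian(blue, x, y, peak, sigma, spec.nucleus.render_floor)
            positive = i in pos_idx
            if positive:
                for _ in range(spec.foci_per_positive):
                    ang = rng.uniform(0, 2 * np.pi)
                    d = rng.uniform(0, spec.focus_offset_px)
                    _draw_disk(
                        red,
                        x + d * np.cos(ang),
                        y + d * np.sin(ang),
                        spec.focus_radius_px,
                        spec.focus_intensity,
                    )
            nuc_rows.append(
                {"barcode": barcode, "x": x, "y": y, "peak": peak, "positive": positive}
            )

        # nucleus-free red blobs: far enough from every nucleus that the
        # blue Gaussian tails are zero underneath them
        clearance = 2.6 * sigma + spec.rbc_radius_px
        for _ in range(spec.rbc_per_spot):
            for _attempt in range(200):
                rr = (r_spot - spec.rbc_radius_px - 1.0) * np.sqrt(rng.uniform())
                th = rng.uniform(0, 2 * np.pi)
                bx, by = s.center_x + rr * np.cos(th), s.center_y + rr * np.sin(th)
                if all((bx - x) ** 2 + (by - y) ** 2 >= clearance**2 for x, y in centers):
                    _draw_disk(red, bx, by, spec.rbc_radius_px, spec.rbc_intensity)
                    break

        true_n = s.n_nuclei
        pct = 100.0 * n_pos / true_n if true_n else 0.0
        intensity = float(spec.focus_intensity) if n_pos else 0.0
        if true_n < call_params.min_cells:
            call = "excluded"
        else:
            gt = (lambda v, t: v > t) if call_params.comparator == "gt" else (lambda v, t: v >= t)
            by_i = gt(intensity, call_params.intensity_threshold)
            by_p = gt(pct, call_params.percent_threshold)
            positive = {
                "intensity_only": by_i,
                "percent_only": by_p,
                "both": by_i and by_p,
            }[call_params.mode]
            call = "positive" if positive else "negative"
        spot_rows.append(
            {
                "barcode": barcode,
                "n_cells": true_n,
                "n_positive": n_pos,
                "pct_positive": pct,
                "call": call,
            }
        )

    if spec.noise_sigma > 0:
        stack = np.stack([red, green, blue], axis=-1)
        stack = stack + rng.normal(0.0, spec.noise_sigma, size=stack.shape)
        pixels = np.clip(np.rint(stack), 0, 255).astype(np.uint8)
    else:
        pixels = np.clip(
            np.rint(np.stack([red, green, blue], axis=-1)), 0, 255
        ).astype(np.uint8)

    image = SlideImage(pixels=pixels, nuclear_channel=2, main_channel=0, microns_per_pixel=mpp)
    grid = SpotGrid(spots=records, source_dialect="plain_xy")
    truth = GroundTruth(
        spots=pd.DataFrame(spot_rows, columns=["barcode", "n_cells", "n_positive", "pct_positive", "call"]),
        nuclei=pd.DataFrame(nuc_rows, columns=["barcode", "x", "y", "peak", "positive"]),
    )
    return image, grid, truth


def grid_scene(
    n_cols: int,
    n_rows: int,
    seed: int,
    *,
    mean_cells: float = 42.1,
    sd_cells: float = 15.0,
    cell_range: tuple[int, int] = (11, 60),
    positive_fractions=(0.0, 0.4),
    positive_spot_fraction: float = 0.4,
    sparse_spots: int = 0,
    sparse_cells: int = 5,
    microns_per_pixel: float = 0.5,
    **overrides,
) -> SceneSpec:
    """Lay spots on a rectangular grid with realistic per-spot cell counts.

    Per-spot nucleus counts are drawn from a clipped normal calibrated to
    reported per-spot cell statistics (mean ~42); the upper clip is set by
    the generator's minimum-separation constraint rather than the observed
    maximum.  ``positive_spot_fraction`` of the (non-sparse) spots receive
    positive nuclei at ``positive_fractions[1]``; ``sparse_spots`` spots get
    ``sparse_cells`` nuclei each (below the default minimum-cell filter).
    """
    rng = np.random.default_rng(seed)
    r_spot = spot_radius_px(SPOT_DIAMETER_UM, microns_per_pixel)
    pitch = 2 * r_spot + 10
    margin = r_spot + 6
    n = n_cols * n_rows

    counts = np.clip(
        np.rint(rng.normal(mean_cells, sd_cells, size=n)), cell_range[0], cell_range[1]
    ).astype(int)
    n_sparse = min(sparse_spots, n)
    n_positive_spots = int(round(positive_spot_fraction * (n - n_sparse)))
    roles = ["sparse"] * n_sparse + ["positive"] * n_positive_spots
    roles += ["negative"] * (n - len(roles))
    rng.shuffle(roles)

    spots = []
    for k in range(n):
        i, j = divmod(k, n_cols)
        if roles[k] == "sparse":
            n_nuc, frac = sparse_cells, 0.0
        elif roles[k] == "positive":
            n_nuc, frac = int(counts[k]), positive_fractions[1]
        else:
            n_nuc, frac = int(counts[k]), positive_fractions[0]
        spots.append(
            SpotSpec(
                center_x=margin + j * pitch,
                center_y=margin + i * pitch,
                n_nuclei=n_nuc,
                positive_fraction=frac,
            )
        )
    width = 2 * margin + (n_cols - 1) * pitch
    height = 2 * margin + (n_rows - 1) * pitch
    return SceneSpec(
        width=width,
        height=height,
        spots=tuple(spots),
        seed=seed,
        microns_per_pixel=microns_per_pixel,
        **overrides,
    )


def make_ratings(
    n_subjects: int,
    positive_props,
    agreement_structure="perfect",
    seed: int = 0,
) -> RatingsMatrix:
    """Binary ratings with exact per-rater marginals and tunable agreement.

    Each rater labels exactly ``round(p_r * n_subjects)`` subjects positive.
    ``agreement_structure`` selects how those positive sets relate:

    - ``"perfect"``: nested sets (maximal overlap, hence maximal agreement);
    - ``"independent"``: each rater's positive set drawn independently at
      random, giving chance-level agreement;
    - a float: target mean pairwise percent agreement.  Starting from the
      nested configuration, positives are swapped onto fresh subjects (one
      rater at a time, preserving marginals) until the mean pairwise
      agreement falls to the target; achievable to within one swap's
      granularity, ``400 / (3 n_subjects)`` percentage points for 3 raters.
    """
    props = np.asarray(positive_props, dtype=float)
    if np.any((props < 0) | (props > 1)):
        raise ValueError("positive proportions must lie in [0, 1]")
    n_raters = props.size
    if n_raters < 2:
        raise ValueError("need at least two raters")
    rng = np.random.default_rng(seed)
    k = np.rint(props * n_subjects).astype(int)
    labels = np.full((n_subjects, n_raters), "negative", dtype=object)

    if isinstance(agreement_structure, str) and agreement_structure == "independent":
        for r in range(n_raters):
            idx = rng.choice(n_subjects, size=k[r], replace=False)
            labels[idx, r] = "positive"
        return RatingsMatrix(subjects=[f"s{i}" for i in range(n_subjects)], labels=labels)

    # nested (maximal-overlap) start
    for r in range(n_raters):
        labels[: k[r], r] = "positive"
    if isinstance(agreement_structure, str):
        if agreement_structure != "perfect":
            raise ValueError(f"unknown agreement structure {agreement_structure!r}")
        return RatingsMatrix(subjects=[f"s{i}" for i in range(n_subjects)], labels=labels)

    target = float(agreement_structure)
    if not 0 <= target <= 100:
        raise ValueError("target agreement must be a percent in [0, 100]")
    n_pairs = n_raters * (n_raters - 1) // 2
    step = 100.0 * 2 * (n_raters - 1) / (n_pairs * n_subjects)  # drop per swap

    def mean_agreement() -> float:
        tot = 0.0
        for i in range(n_raters):
            for j in range(i + 1, n_raters):
                tot += np.mean(labels[:, i] == labels[:, j])
        return 100.0 * tot / n_pairs

    current = mean_agreement()
    r = 0
    while current - target > step / 2:
        unanimous_pos = np.nonzero(np.all(labels == "positive", axis=1))[0]
        unanimous_neg = np.nonzero(np.all(labels == "negative", axis=1))[0]
        if unanimous_pos.size == 0 or unanimous_neg.size == 0:
            raise ValueError("cannot reach the requested agreement with these marginals")
        i = int(rng.choice(unanimous_pos))
        j = int(rng.choice(unanimous_neg))
        labels[i, r] = "negative"
        labels[j, r] = "positive"
        current -= step
        r = (r + 1) % n_raters
    return RatingsMatrix(subjects=[f"s{i}" for i in range(n_subjects)], labels=labels)
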