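"""Final spot annotation: minimum-cell filter plus the user-selected rule.

A spot with fewer cells than ``min_cells`` is "excluded" (too little
material to judge).  Otherwise the call is "positive" when the selected
criteria pass — marker intensity above its threshold, percent positive
cells above its threshold, or both — and "negative" otherwise.  The default
comparison is strict (intensity > 60 and percent > 10); an inclusive ">="
variant is available via ``comparator="ge"``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import SlideImage, SpotGrid
from .marker import MarkerParams, SpotMeasurements, quantify_spot
from .masking import extract_spot_tile
from .segmentation import SegmentationParams

__all__ = ["CallParams", "SpotResult", "call_spot", "run_pipeline"]

MODES = ("intensity_only", "percent_only", "both")


@dataclass(frozen=True)
class CallParams:
    """The call rule: which measurements decide positivity, and thresholds."""

    mode: str = "both"
    intensity_threshold: float = 60.0
    percent_threshold: float = 10.0
    min_cells: int = 10
    comparator: str = "gt"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.intensity_threshold < 0 or self.percent_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if self.min_cells < 1:
            raise ValueError("min_cells must be >= 1")
        if self.comparator not in ("gt", "ge"):
            raise ValueError("comparator must be 'gt' or 'ge'")


@dataclass(frozen=True)
class SpotResult:
    """One spot's measurements plus the final annotation."""

    barcode: str
    center_x: float
    center_y: float
    measurements: SpotMeasurements
    call: str  # positive | negative | excluded


def call_spot(m: SpotMeasurements, params: CallParams | None = None) -> str:
    """Apply the minimum-cell filter and the call rule to one measurement."""
    params = params or CallParams()
    if m.n_cells < params.min_cells:
        return "excluded"
    exceeds = (lambda v, t: v > t) if params.comparator == "gt" else (lambda v, t: v >= t)
    by_intensity = exceeds(m.spot_intensity, params.intensity_threshold)
    by_percent = exceeds(m.pct_positive, params.percent_threshold)
    if params.mode == "intensity_only":
        positive = by_intensity
    elif params.mode == "percent_only":
        positive = by_percent
    else:
        positive = by_intensity and by_percent
    return "positive" if positive else "negative"


def run_pipeline(
    image: SlideImage,
    grid: SpotGrid,
    seg_params: SegmentationParams | None = None,
    marker_params: MarkerParams | None = None,
    call_params: CallParams | None = None,
) -> list[SpotResult]:
    """Analyse every spot on the slide, in grid order.

    Deterministic: identical inputs produce identical results.  A spot whose
    center lies outside the image aborts the run with its barcode named.
    """
    seg_params = seg_params or SegmentationParams()
    marker_params = marker_params or MarkerParams()
    call_params = call_params or CallParams()
    results = []
    for spot in grid:
        tile = extract_spot_tile(image, spot)
        m = quantify_spot(tile, seg_params, marker_params)
        results.append(
            SpotResult(
                barcode=spot.barcode,
                center_x=spot.center_x,
                center_y=spot.center_y,
                measurements=m,
                call=call_spot(m, call_params),
            )
        )
    return results
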