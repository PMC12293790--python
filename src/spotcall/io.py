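"""Reading and writing slide images, spot tables and annotation CSVs.

Supported spot-table dialects:

``loupe_csv``
    As exported from Loupe Browser: ``Barcode, X Coordinate, Y Coordinate``
    (pixel coordinates in the full-resolution image).
``tissue_positions``
    The Visium ``tissue_positions.csv`` layout: ``barcode, in_tissue,
    array_row, array_col, pxl_row_in_fullres, pxl_col_in_fullres``.  Rows
    with ``in_tissue == 0`` are dropped at read time.
``plain_xy``
    A minimal user-defined table: ``id, x, y``.

Coordinates are 0-based pixel indices, x = column (increasing right),
y = row (increasing down).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SlideImage",
    "SpotRecord",
    "SpotGrid",
    "load_slide_image",
    "read_spot_table",
    "write_results_csv",
    "write_loupe_categories",
    "read_ratings_csv",
    "RESULT_COLUMNS",
    "SPOT_DIAMETER_UM",
]

#: Physical diameter of a Visium/CytAssist capture spot.
SPOT_DIAMETER_UM = 55.0

RESULT_COLUMNS = [
    "barcode",
    "center_x",
    "center_y",
    "n_cells",
    "n_positive_cells",
    "pct_positive",
    "spot_intensity",
    "call",
]


@dataclass(eq=False)
class SlideImage:
    """An 8-bit RGB fluorescence raster with channel-role metadata.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array.
    nuclear_channel
        Index of the nuclear-counterstain channel (DAPI is blue, index 2).
    main_channel
        Index of the marker fluorophore's dominant channel (Texas Red is
        red, index 0).
    microns_per_pixel
        Physical pixel size in micrometres.
    """

    pixels: np.ndarray
    nuclear_channel: int = 2
    main_channel: int = 0
    microns_per_pixel: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected an (H, W, 3) array, got {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {self.pixels.dtype}")
        for c in (self.nuclear_channel, self.main_channel):
            if c not in (0, 1, 2):
                raise ValueError(f"channel index {c} out of range")
        if self.nuclear_channel == self.main_channel:
            raise ValueError("nuclear and main channel must differ")
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def nuclear(self) -> np.ndarray:
        """The nuclear-stain channel as an (H, W) view."""
        return self.pixels[:, :, self.nuclear_channel]

    def main(self) -> np.ndarray:
        """The marker main channel as an (H, W) view."""
        return self.pixels[:, :, self.main_channel]

    def contains(self, x: float, y: float) -> bool:
        return 0 <= x < self.width and 0 <= y < self.height


@dataclass(frozen=True)
class SpotRecord:
    """One barcoded capture spot: center pixel coordinates + physical size."""

    barcode: str
    center_x: float
    center_y: float
    diameter_um: float = SPOT_DIAMETER_UM

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError("diameter_um must be positive")


@dataclass
class SpotGrid:
    """An ordered collection of spots with unique barcodes."""

    spots: list[SpotRecord]
    source_dialect: str = "plain_xy"

    def __post_init__(self) -> None:
        if not self.spots:
            raise ValueError("spot grid is empty")
        barcodes = [s.barcode for s in self.spots]
        if len(set(barcodes)) != len(barcodes):
            dupes = sorted({b for b in barcodes if barcodes.count(b) > 1})
            raise ValueError(f"duplicate barcodes in spot table: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.spots)

    def __iter__(self):
        return iter(self.spots)


def load_slide_image(
    path: str | os.PathLike,
    *,
    nuclear_channel: int = 2,
    main_channel: int = 0,
    microns_per_pixel: float = 1.0,
) -> SlideImage:
    """Load a TIFF or PNG slide scan as an 8-bit RGB :class:`SlideImage`.

    16-bit rasters are rescaled to 8-bit by exact linear division
    (65535 -> 255).  A fourth (alpha) channel, if present, is dropped.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 2 or (arr.ndim == 3 and arr.shape[2] == 1):
        raise ValueError("single-channel image: an RGB raster is required")
    if arr.ndim != 3 or arr.shape[2] > 4:
        raise ValueError(f"unsupported image shape {arr.shape}")
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype == np.uint16:
        arr = (arr // 257).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise ValueError(f"unsupported image dtype {arr.dtype}")
    return SlideImage(
        pixels=arr,
        nuclear_channel=nuclear_channel,
        main_channel=main_channel,
        microns_per_pixel=microns_per_pixel,
    )


_DIALECT_COLUMNS = {
    "loupe_csv": ["Barcode", "X Coordinate", "Y Coordinate"],
    "tissue_positions": [
        "barcode",
        "in_tissue",
        "array_row",
        "array_col",
        "pxl_row_in_fullres",
        "pxl_col_in_fullres",
    ],
    "plain_xy": ["id", "x", "y"],
}


def read_spot_table(
    path: str | os.PathLike,
    dialect: str = "plain_xy",
    *,
    diameter_um: float = SPOT_DIAMETER_UM,
) -> SpotGrid:
    """Read a spot-coordinate CSV in one of the supported dialects.

    ``tissue_positions`` rows with ``in_tissue == 0`` are dropped;
    ``pxl_col_in_fullres`` maps to ``center_x`` and ``pxl_row_in_fullres``
    to ``center_y``.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECT_COLUMNS)}")
    df = pd.read_csv(path)
    required = _DIALECT_COLUMNS[dialect]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"spot table {path} is missing columns {missing} for dialect {dialect!r}")

    if dialect == "loupe_csv":
        ids, xs, ys = df["Barcode"], df["X Coordinate"], df["Y Coordinate"]
    elif dialect == "tissue_positions":
        df = df[df["in_tissue"].astype(int) == 1]
        ids, xs, ys = df["barcode"], df["pxl_col_in_fullres"], df["pxl_row_in_fullres"]
    else:
        ids, xs, ys = df["id"], df["x"], df["y"]

    xs = pd.to_numeric(xs, errors="raise")
    ys = pd.to_numeric(ys, errors="raise")
    spots = [
        SpotRecord(barcode=str(b), center_x=float(x), center_y=float(y), diameter_um=diameter_um)
        for b, x, y in zip(ids, xs, ys)
    ]
    return SpotGrid(spots=spots, source_dialect=dialect)


def write_results_csv(results, path: str | os.PathLike) -> None:
    """Write the per-spot results table.

    Columns are fixed (``barcode, center_x, center_y, n_cells,
    n_positive_cells, pct_positive, spot_intensity, call``); percentages are
    rendered with 1 decimal and intensities with 2.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to write")
    rows = []
    for r in results:
        m = r.measurements
        rows.append(
            {
                "barcode": r.barcode,
                "center_x": r.center_x,
                "center_y": r.center_y,
                "n_cells": m.n_cells,
                "n_positive_cells": m.n_positive_cells,
                "pct_positive": f"{m.pct_positive:.1f}",
                "spot_intensity": f"{m.spot_intensity:.2f}",
                "call": r.call,
            }
        )
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, index=False)


def write_loupe_categories(
    results, path: str | os.PathLike, category_name: str = "marker_call"
) -> None:
    """Write a Loupe-Browser-importable two-column category CSV.

    Excluded spots (too few cells) are omitted so the file round-trips into
    the browser cleanly; the full audit trail stays in the results CSV.
    """
    rows = [
        {"Barcode": r.barcode, category_name: r.call}
        for r in results
        if r.call != "excluded"
    ]
    pd.DataFrame(rows, columns=["Barcode", category_name]).to_csv(path, index=False)


def read_ratings_csv(path: str | os.PathLike) -> pd.Series:
    """Read a two-column (id, label) annotation CSV as a Series keyed by id.

    Accepts the Loupe category dialect (``Barcode,<name>``) directly, so a
    program-written file and a human-exported one load the same way.
    """
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"ratings file {path} needs at least two columns (id, label)")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise ValueError(f"duplicate spot ids in ratings file {path}")
    return pd.Series(df.iloc[:, 1].values, index=ids, name=str(df.columns[1]))
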