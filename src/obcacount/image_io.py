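"""Channel I/O and pre-processing.

Reads single-plane grayscale TIFF/PNG channels, converts 8-bit data to the
16-bit working range, applies percentile-based brightness/contrast
stretching, merges channels into an RGB-style composite for inspection,
and reads/writes the CSV count tables and point-set sidecar files.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import ChannelImage, ColocResult, CompositeImage, PointSet
from .exceptions import FormatError, ParameterError, ShapeMismatchError

__all__ = [
    "read_channel",
    "write_channel",
    "to_16bit",
    "adjust_brightness_contrast",
    "merge_channels",
    "write_counts",
    "read_counts",
    "write_points",
    "read_points",
]

#: Default percentile pair for brightness/contrast stretching.
DEFAULT_PERCENTILES = (0.35, 99.65)


def read_channel(path, pixel_size_um: float = 0.325, role: str = "") -> ChannelImage:
    """Read a single-plane grayscale TIFF or PNG channel.

    Bit depth is inferred from the file dtype (uint8 -> 8, uint16 -> 16).
    Multi-plane or RGB files are rejected with a :class:`FormatError`
    naming the offending shape.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            arr = iio.imread(path)
    except FormatError:
        raise
    except Exception as exc:  # pragma: no cover - backend-specific
        raise IOError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(
            f"{path.name}: expected a single-plane grayscale image, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise FormatError(f"{path.name}: unsupported dtype {arr.dtype}; need uint8/uint16")
    return ChannelImage(
        pixels=arr,
        bit_depth=depth,
        pixel_size_um=pixel_size_um,
        role=role or path.stem,
    )


def write_channel(img: ChannelImage, path) -> None:
    """Write a channel as a grayscale TIFF or PNG, rounding float grids."""
    path = Path(path)
    arr = img.pixels
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    if not np.issubdtype(arr.dtype, np.integer):
        arr = np.clip(np.rint(arr), 0, img.max_value)
    arr = arr.astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)


def to_16bit(img: ChannelImage) -> ChannelImage:
    """Convert a channel to the 16-bit working range.

    8-bit input is linearly rescaled by 257 (0 -> 0, 255 -> 65535), the
    standard full-range conversion; 16-bit input is returned unchanged.
    The map is exact on integers, so the operation is idempotent.
    """
    if img.bit_depth == 16:
        return img
    px = img.pixels
    if np.issubdtype(px.dtype, np.integer):
        scaled = px.astype(np.uint16) * np.uint16(257)
    else:
        scaled = px.astype(np.float64) * 257.0
    return ChannelImage(scaled, bit_depth=16, pixel_size_um=img.pixel_size_um, role=img.role)


def adjust_brightness_contrast(
    img: ChannelImage,
    low_percentile: float = DEFAULT_PERCENTILES[0],
    high_percentile: float = DEFAULT_PERCENTILES[1],
) -> ChannelImage:
    """Linear contrast stretch mapping intensity percentiles to the full
    bit range.

    Intensities at or below the ``low_percentile`` value map to 0, those
    at or above the ``high_percentile`` value map to ``2**bit_depth - 1``,
    values in between are mapped linearly.  The map is monotone, so pixel
    ordering is preserved.  A degenerate (constant) stretch window maps
    everything to 0 rather than erroring, so batch runs never crash on
    blank fields.
    """
    if not (0 <= low_percentile < high_percentile <= 100):
        raise ParameterError(
            f"need 0 <= low < high <= 100, got ({low_percentile}, {high_percentile})"
        )
    px = img.astype_float()
    lo, hi = np.percentile(px, [low_percentile, high_percentile])
    if hi <= lo:
        out = np.zeros_like(px)
    else:
        out = np.clip((px - lo) / (hi - lo), 0.0, 1.0) * img.max_value
    if np.issubdtype(img.pixels.dtype, np.integer):
        out = np.rint(out).astype(img.pixels.dtype)
    return img.with_pixels(out)


def merge_channels(
    nuclear: ChannelImage,
    marker: ChannelImage,
    marker2: Optional[ChannelImage] = None,
) -> CompositeImage:
    """Merge channels into a composite: green = nuclear, red = marker,
    blue = optional second marker.  Source channels are not modified."""
    channels = {"green": nuclear, "red": marker}
    if marker2 is not None:
        channels["blue"] = marker2
    shapes = {ch.shape for ch in channels.values()}
    if len(shapes) != 1:
        raise ShapeMismatchError(f"channel dimensions differ: {sorted(shapes)}")
    return CompositeImage(channels)


_COUNT_COLUMNS = ["field_id", "marker", "n_cat1", "n_cat2", "n_cat3", "n_coloc"]


def write_counts(results: Sequence[ColocResult], path) -> None:
    """Write count results to CSV, one row per field x marker.

    Columns: field_id, marker, n_cat1, n_cat2, n_cat3 (empty for
    two-channel fields), n_coloc.  Rows are sorted by (field_id, marker)
    so output is deterministic regardless of input order.
    """
    rows = []
    for r in sorted(results, key=lambda r: (r.field_id, r.marker)):
        rows.append(
            {
                "field_id": r.field_id,
                "marker": r.marker,
                "n_cat1": r.n_per_category.get(1, 0),
                "n_cat2": r.n_per_category.get(2, 0),
                "n_cat3": r.n_per_category.get(3, pd.NA),
                "n_coloc": r.n_coloc,
            }
        )
    df = pd.DataFrame(rows, columns=_COUNT_COLUMNS)
    df["n_cat3"] = df["n_cat3"].astype("Int64")
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise IOError(f"cannot write counts to {path}: {exc}") from exc


def read_counts(path) -> List[ColocResult]:
    """Read a count table written by :func:`write_counts`."""
    df = pd.read_csv(path, dtype={"field_id": str, "marker": str})
    out: List[ColocResult] = []
    for _, row in df.iterrows():
        cats = {1: int(row["n_cat1"]), 2: int(row["n_cat2"])}
        if not pd.isna(row["n_cat3"]):
            cats[3] = int(row["n_cat3"])
        out.append(
            ColocResult(
                field_id=str(row["field_id"]),
                marker=str(row["marker"]),
                n_per_category=cats,
                n_coloc=int(row["n_coloc"]),
            )
        )
    return out


def write_points(ps: PointSet, path) -> None:
    """Write a point set as CSV with columns row, col, category."""
    df = pd.DataFrame(
        {
            "row": ps.points[:, 0],
            "col": ps.points[:, 1],
            "category": np.full(len(ps), ps.category, dtype=int),
        }
    )
    df.to_csv(path, index=False)


def read_points(path, source_shape) -> List[PointSet]:
    """Read point sets from CSV, one :class:`PointSet` per category."""
    df = pd.read_csv(path)
    out = []
    for cat, grp in df.groupby("category", sort=True):
        pts = grp[["row", "col"]].to_numpy(dtype=np.float64)
        out.append(PointSet(points=pts, category=int(cat), source_shape=tuple(source_shape)))
    return out
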