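"""Core in-memory containers shared by all pipeline stages.

A multiplex field is handled one grayscale channel at a time
(:class:`ChannelImage`); segmentations are integer label grids
(:class:`LabelMap`); both counting methods exchange category-tagged point
sets (:class:`PointSet`); a counting run yields one :class:`ColocResult`
per field and marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .exceptions import BoundsError, FormatError, ShapeMismatchError

#: Microscope pixel size the package assumes by default, in micrometres.
DEFAULT_PIXEL_SIZE_UM = 0.325


@dataclass
class ChannelImage:
    """One grayscale fluorescence channel.

    Parameters
    ----------
    pixels : ndarray
        2D non-negative intensity grid.  Integer dtypes are used for raw
        data; float grids appear after smoothing or illumination
        correction and stay within the declared bit range.
    bit_depth : {8, 16}
        Declared bit depth; all intensities must lie in
        ``[0, 2**bit_depth - 1]``.
    pixel_size_um : float
        Physical pixel size in micrometres (default 0.325).
    role : str
        Free-text channel label, e.g. ``"DAPI"`` or ``"CD4"``.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    role: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise FormatError(
                f"channel image must be a 2D grid of at least 1x1 pixels, "
                f"got shape {self.pixels.shape}"
            )
        if self.bit_depth not in (8, 16):
            raise FormatError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixel_size_um <= 0:
            raise FormatError("pixel_size_um must be positive")
        lo = float(self.pixels.min()) if self.pixels.size else 0.0
        hi = float(self.pixels.max()) if self.pixels.size else 0.0
        if lo < 0 or hi > self.max_value:
            raise FormatError(
                f"intensities [{lo}, {hi}] outside [0, {self.max_value}] "
                f"for bit depth {self.bit_depth}"
            )

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def max_value(self) -> int:
        """Largest representable intensity, ``2**bit_depth - 1``."""
        return (1 << self.bit_depth) - 1

    def astype_float(self) -> np.ndarray:
        return np.asarray(self.pixels, dtype=np.float64)

    def with_pixels(self, pixels: np.ndarray, bit_depth: Optional[int] = None) -> "ChannelImage":
        """New image sharing this channel's metadata."""
        return ChannelImage(
            pixels=pixels,
            bit_depth=self.bit_depth if bit_depth is None else bit_depth,
            pixel_size_um=self.pixel_size_um,
            role=self.role,
        )


@dataclass
class CompositeImage:
    """Color composite for visualization: green = nuclear, red = first
    marker, blue = optional second marker.  Both counting engines consume
    single channels; composites exist for inspection and fixtures only.
    """

    channels: Dict[str, ChannelImage]

    _SLOTS = ("green", "red", "blue")

    def __post_init__(self) -> None:
        slots = list(self.channels)
        if not (2 <= len(slots) <= 3):
            raise FormatError(f"composite needs 2 or 3 channels, got {len(slots)}")
        for s in slots:
            if s not in self._SLOTS:
                raise FormatError(f"unknown color slot {s!r}")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ShapeMismatchError(f"channel dimensions differ: {sorted(shapes)}")

    @property
    def shape(self) -> Tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class LabelMap:
    """Integer-labeled segmentation of one channel.

    ``labels`` holds 0 for background and consecutive 1..n for the n
    connected objects.
    """

    labels: np.ndarray
    n_objects: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError("label map must be 2D")
        present = np.unique(self.labels)
        present = present[present > 0]
        if len(present) != self.n_objects or (
            self.n_objects and present[-1] != self.n_objects
        ):
            raise FormatError(
                f"labels must be consecutive 1..{self.n_objects}, found {present[:10]}..."
            )

    @property
    def shape(self) -> Tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]


@dataclass
class PointSet:
    """Category-tagged (row, col) coordinates — the currency of both
    counting methods.

    Coordinates are 0-based real values with origin at the top-left; all
    points must lie inside ``source_shape`` and be pairwise distinct.
    """

    points: np.ndarray
    category: int
    source_shape: Tuple[int, int]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise FormatError(f"points must be (n, 2), got {pts.shape}")
        self.points = pts
        if self.category < 1:
            raise FormatError("category must be >= 1")
        h, w = self.source_shape
        if pts.size and (
            pts[:, 0].min() < 0
            or pts[:, 1].min() < 0
            or pts[:, 0].max() > h - 1
            or pts[:, 1].max() > w - 1
        ):
            raise BoundsError(
                f"points outside image bounds {(h, w)}: "
                f"rows [{pts[:, 0].min()}, {pts[:, 0].max()}], "
                f"cols [{pts[:, 1].min()}, {pts[:, 1].max()}]"
            )
        if pts.shape[0] > 1:
            uniq = np.unique(pts, axis=0)
            if uniq.shape[0] != pts.shape[0]:
                raise FormatError("point set contains identical points")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class ColocResult:
    """Counts for one field and marker.

    ``n_per_category`` maps point category (1 = nuclear, 2 = first marker,
    3 = optional second marker) to its detection count; ``n_coloc`` is the
    combined-category count (12 for two channels, 123 for three): the
    number of nuclear points with at least one colocalized partner in
    every marker category.
    """

    field_id: str
    marker: str
    n_per_category: Dict[int, int] = field(default_factory=dict)
    n_coloc: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.n_per_category.values()) or self.n_coloc < 0:
            raise FormatError("counts must be non-negative")
        # the counting unit is the lowest (nuclear) category, counted once per
        # point; one marker can partner several nuclei, so only the counting
        # category bounds n_coloc
        if self.n_per_category:
            counting = min(self.n_per_category)
            if self.n_coloc > self.n_per_category[counting]:
                raise FormatError(
                    f"n_coloc={self.n_coloc} exceeds the counting category "
                    f"count {self.n_per_category[counting]}"
                )
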