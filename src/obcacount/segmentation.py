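"""Object identification by global multi-class Otsu thresholding.

Each channel is segmented on its own: the intensity histogram is split
into three classes by exhaustive maximization of the between-class
variance, pixels above the upper threshold (by default — the middle class
is treated as background) form the foreground, connected components are
labeled, optionally size-filtered, and finally shrunk to their centroids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage as ndi

from .containers import ChannelImage, LabelMap, PointSet
from .exceptions import DegenerateHistogramError, ParameterError

__all__ = [
    "SegmentationConfig",
    "multi_otsu_thresholds",
    "identify_objects",
    "centroids",
]


@dataclass
class SegmentationConfig:
    """Parameters of :func:`identify_objects`.

    n_classes : number of Otsu classes (3 reproduces three-class
        thresholding; the middle class goes to background by default,
        the conservative choice for dim nonspecific staining).
    middle_class : ``"background"`` or ``"foreground"`` — where the middle
        Otsu class is assigned (only meaningful for n_classes = 3).
    connectivity : 4 or 8; pixel connectivity for component labeling.
    min_area / max_area : optional size filter in pixels; components
        outside the window are removed and labels recompacted.  Off by
        default.
    n_bins : histogram bins used for non-8-bit data.
    """

    n_classes: int = 3
    middle_class: str = "background"
    connectivity: int = 8
    min_area: int = 0
    max_area: Optional[int] = None
    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.middle_class not in ("background", "foreground"):
            raise ParameterError(f"middle_class must be background/foreground, got {self.middle_class!r}")
        if self.connectivity not in (4, 8):
            raise ParameterError("connectivity must be 4 or 8")
        if self.n_classes < 2:
            raise ParameterError("n_classes must be >= 2")


def _between_class_objective_terms(counts: np.ndarray, values: np.ndarray):
    w = counts.astype(np.float64)
    m = w * values.astype(np.float64)
    return np.concatenate([[0.0], np.cumsum(w)]), np.concatenate([[0.0], np.cumsum(m)])


def otsu_threshold_indices(counts: np.ndarray, n_classes: int = 3) -> Tuple[int, ...]:
    """Bin indices (i1 < i2 < ...) of the class boundaries that maximize
    the between-class variance; class k holds bins (i_{k-1}, i_k] with
    i_0 = -1 and i_{n} = last bin.

    Maximizing the between-class variance is equivalent to maximizing
    sum_k w_k mu_k^2 (empty classes contribute 0).  Ties are broken by the
    lexicographically smallest index tuple.
    """
    counts = np.asarray(counts, dtype=np.float64)
    L = counts.size
    if np.count_nonzero(counts) < n_classes:
        raise DegenerateHistogramError(
            f"histogram has {np.count_nonzero(counts)} populated bins, need >= {n_classes}"
        )
    values = np.arange(L, dtype=np.float64)
    W, M = _between_class_objective_terms(counts, values)

    def seg(lo, hi):
        # classes are bins lo+1..hi (inclusive); lo/hi are cumulative indices
        w = W[hi + 1] - W[lo + 1]
        m = M[hi + 1] - M[lo + 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(w > 0, m * m / np.where(w > 0, w, 1.0), 0.0)
        return t

    if n_classes == 2:
        i = np.arange(L - 1)
        obj = seg(np.full_like(i, -1), i) + seg(i, np.full_like(i, L - 1))
        best = int(np.argmax(obj))  # argmax returns the first (smallest) maximizer
        return (best,)
    if n_classes == 3:
        i = np.arange(L)[:, None]
        j = np.arange(L)[None, :]
        obj = (
            seg(np.full((L, L), -1), np.broadcast_to(i, (L, L)))
            + seg(np.broadcast_to(i, (L, L)), np.broadcast_to(j, (L, L)))
            + seg(np.broadcast_to(j, (L, L)), np.full((L, L), L - 1))
        )
        obj = np.where(j > i, obj, -np.inf)
        obj = np.where((i < L - 1) & (j < L - 1), obj, -np.inf)
        flat = int(np.argmax(obj))  # row-major: first max is lexicographically smallest
        return (flat // L, flat % L)
    # generic slow path for n_classes >= 4 (exhaustive over combinations)
    from itertools import combinations

    best_obj, best_tuple = -np.inf, None
    for tup in combinations(range(L - 1), n_classes - 1):
        bounds = (-1,) + tup + (L - 1,)
        o = sum(float(seg(np.array([bounds[k]]), np.array([bounds[k + 1]]))[0]) for k in range(n_classes))
        if o > best_obj:
            best_obj, best_tuple = o, tup
    return best_tuple  # type: ignore[return-value]


def multi_otsu_thresholds(
    histogram: np.ndarray,
    n_classes: int = 3,
    values: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Intensity thresholds (t1 < t2 < ...) maximizing between-class
    variance over all (n_classes - 1)-tuples of histogram split points.

    ``histogram`` holds bin counts; ``values`` the intensity of each bin
    (defaults to the bin index).  Class k contains intensities v with
    t_{k-1} < v <= t_k, i.e. each threshold is the highest value belonging
    to the class below it; foreground in three-class segmentation is
    everything strictly above the last threshold.
    """
    histogram = np.asarray(histogram)
    if values is None:
        values = np.arange(histogram.size, dtype=np.float64)
    else:
        values = np.asarray(values, dtype=np.float64)
        if values.size != histogram.size:
            raise ParameterError("values must match histogram length")
    idx = otsu_threshold_indices(histogram, n_classes)
    return values[list(idx)]


def identify_objects(
    img: ChannelImage, config: Optional[SegmentationConfig] = None
) -> LabelMap:
    """Segment one channel into labeled objects.

    Foreground is the upper Otsu class (plus the middle class when
    ``middle_class="foreground"``); components are labeled with the
    configured connectivity, size-filtered, and relabeled 1..n.  A
    degenerate image (fewer distinct intensities than classes) yields an
    empty LabelMap rather than an error, so blank fields pass through
    batch runs.
    """
    cfg = config or SegmentationConfig()
    px = img.pixels
    if np.issubdtype(px.dtype, np.integer) and img.bit_depth == 8:
        counts = np.bincount(px.ravel().astype(np.int64), minlength=256)[:256]
        bin_index = px.astype(np.int64)
    else:
        edges = np.linspace(0.0, float(img.max_value), cfg.n_bins + 1)
        counts, _ = np.histogram(px, bins=edges)
        bin_index = np.clip(
            np.searchsorted(edges, px, side="right") - 1, 0, cfg.n_bins - 1
        )
    try:
        idx = otsu_threshold_indices(counts, cfg.n_classes)
    except DegenerateHistogramError:
        return LabelMap(labels=np.zeros(img.shape, dtype=np.int32), n_objects=0)
    cut = idx[-1] if cfg.middle_class == "background" else idx[-2] if cfg.n_classes >= 3 else idx[-1]
    fg = bin_index > cut
    structure = np.ones((3, 3), bool) if cfg.connectivity == 8 else ndi.generate_binary_structure(2, 1)
    labels, n = ndi.label(fg, structure=structure)
    if n and (cfg.min_area > 0 or cfg.max_area is not None):
        sizes = np.bincount(labels.ravel(), minlength=n + 1)
        keep = sizes >= cfg.min_area
        if cfg.max_area is not None:
            keep &= sizes <= cfg.max_area
        keep[0] = False
        remap = np.zeros(n + 1, dtype=np.int32)
        remap[keep] = np.arange(1, int(keep.sum()) + 1, dtype=np.int32)
        labels = remap[labels]
        n = int(keep.sum())
    return LabelMap(labels=labels.astype(np.int32), n_objects=int(n))


def centroids(lm: LabelMap, category: int = 1) -> PointSet:
    """Shrink each labeled object to a point: the unweighted mean of its
    pixel coordinates (morphological center, not intensity-weighted)."""
    if lm.n_objects == 0:
        return PointSet(
            points=np.empty((0, 2)), category=category, source_shape=lm.shape
        )
    cms = ndi.center_of_mass(
        np.ones(lm.shape), labels=lm.labels, index=np.arange(1, lm.n_objects + 1)
    )
    return PointSet(
        points=np.asarray(cms, dtype=np.float64),
        category=category,
        source_shape=lm.shape,
    )
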