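"""Colocalization criteria and the two end-to-end counting pipelines.

Two decision rules are implemented:

* ``centroid_expand`` (automated pipeline): every object is shrunk to its
  centroid and re-expanded to a disk of ``expand_px`` pixels; a nuclear
  point and a marker point are colocalized iff their expanded disks share
  at least one in-bounds lattice pixel.  This follows the construction of
  the automated pipeline (expand both channels, relate overlaps), whose
  effective centroid-distance threshold is therefore ~2 x expand_px; a
  ``max_dist`` override applies a direct centroid-distance rule instead
  for users who want a literal distance cut.
* ``overlay`` (semi-automated method): points carry per-category overlay
  radii; two points are colocalized iff their Euclidean distance is at
  most the sum of their radii (exact, no rasterization).

The counting unit is always the nuclear (category 1) point, counted once
regardless of how many partners it has; for three channels a nucleus is
in the combined category 123 iff it has at least one partner in *each*
marker category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .containers import ChannelImage, ColocResult, LabelMap, PointSet
from .exceptions import ParameterError, ShapeMismatchError
from .maxima import MaximaConfig, edit_points, find_maxima
from .preprocess import apply_illumination, fit_illumination
from .segmentation import SegmentationConfig, centroids, identify_objects

__all__ = [
    "ColocConfig",
    "expand_points",
    "count_coloc_pairs",
    "count_coloc_triples",
    "run_automated_pipeline",
    "run_semiauto_pipeline",
]

logger = logging.getLogger(__name__)

#: Overlay radius used when a category has no explicit entry.
DEFAULT_OVERLAY_RADIUS = 50.0


@dataclass
class ColocConfig:
    """Colocalization parameters.

    mode : ``"centroid_expand"`` (automated) or ``"overlay"``
        (semi-automated).
    expand_px : disk radius for centroid expansion, pixels (default 5).
    overlay_radius : per-category overlay radii, pixels (default 50 for
        every category; 30 is the documented choice for hard, fragmented
        morphologies).
    max_dist : optional direct centroid-distance threshold overriding the
        disk-overlap rule in centroid_expand mode.
    """

    mode: str = "centroid_expand"
    expand_px: int = 5
    overlay_radius: Dict[int, float] = field(default_factory=dict)
    max_dist: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("centroid_expand", "overlay"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.expand_px < 1:
            raise ParameterError("expand_px must be >= 1")
        if any(r <= 0 for r in self.overlay_radius.values()):
            raise ParameterError("all overlay radii must be > 0")

    def radius_for(self, category: int) -> float:
        return self.overlay_radius.get(category, DEFAULT_OVERLAY_RADIUS)


def expand_points(ps: PointSet, radius: float, shape) -> LabelMap:
    """Expand each point to a filled Euclidean disk; overlapping disks of
    the same set are partitioned by the nearest-point rule (ties go to the
    lower point index), so every input point remains one labeled object.

    A pixel belongs to a disk iff its center is within ``radius`` of the
    point (closed disk).
    """
    h, w = shape
    best_d2 = np.full((h, w), np.inf)
    labels = np.zeros((h, w), dtype=np.int32)
    r2 = float(radius) ** 2
    for i, (pr, pc) in enumerate(ps.points, start=1):
        r0 = max(int(np.ceil(pr - radius)), 0)
        r1 = min(int(np.floor(pr + radius)), h - 1)
        c0 = max(int(np.ceil(pc - radius)), 0)
        c1 = min(int(np.floor(pc + radius)), w - 1)
        if r1 < r0 or c1 < c0:
            continue
        rr = np.arange(r0, r1 + 1)[:, None] - pr
        cc = np.arange(c0, c1 + 1)[None, :] - pc
        d2 = rr * rr + cc * cc
        win_d = best_d2[r0 : r1 + 1, c0 : c1 + 1]
        win_l = labels[r0 : r1 + 1, c0 : c1 + 1]
        take = (d2 <= r2) & (d2 < win_d)  # strict: earlier (lower) index wins ties
        win_d[take] = d2[take]
        win_l[take] = i
    # points whose entire disk was clipped off the image keep no pixels,
    # but every in-bounds point owns at least its own containing pixel
    n = len(ps)
    present = np.unique(labels)
    present = present[present > 0]
    if len(present) != n:
        # relabel consecutively (can only happen for degenerate radii)
        remap = np.zeros(n + 1, dtype=np.int32)
        remap[present] = np.arange(1, len(present) + 1, dtype=np.int32)
        labels = remap[labels]
        n = len(present)
    return LabelMap(labels=labels, n_objects=int(n))


def _disks_share_pixel(p, q, radius: float, shape) -> bool:
    """True iff some in-bounds lattice pixel lies within ``radius`` of both
    points (closed disks)."""
    h, w = shape
    r0 = max(int(np.ceil(max(p[0], q[0]) - radius)), 0)
    r1 = min(int(np.floor(min(p[0], q[0]) + radius)), h - 1)
    c0 = max(int(np.ceil(max(p[1], q[1]) - radius)), 0)
    c1 = min(int(np.floor(min(p[1], q[1]) + radius)), w - 1)
    if r1 < r0 or c1 < c0:
        return False
    rr = np.arange(r0, r1 + 1, dtype=np.float64)[:, None]
    cc = np.arange(c0, c1 + 1, dtype=np.float64)[None, :]
    r2 = float(radius) ** 2
    dp = (rr - p[0]) ** 2 + (cc - p[1]) ** 2
    dq = (rr - q[0]) ** 2 + (cc - q[1]) ** 2
    return bool(np.any((dp <= r2) & (dq <= r2)))


def _check_shapes(shape, *point_sets: PointSet) -> None:
    for ps in point_sets:
        if tuple(ps.source_shape) != tuple(shape):
            raise ShapeMismatchError(
                f"point set from shape {ps.source_shape}, expected {tuple(shape)}"
            )


def _pair_partners(a: PointSet, b: PointSet, cfg: ColocConfig, shape):
    """Boolean masks (over a, over b): has at least one colocalized
    partner in the other set."""
    na, nb = len(a), len(b)
    a_hit = np.zeros(na, dtype=bool)
    b_hit = np.zeros(nb, dtype=bool)
    if na == 0 or nb == 0:
        return a_hit, b_hit
    if cfg.mode == "overlay":
        thr = cfg.radius_for(a.category) + cfg.radius_for(b.category)
        tree = cKDTree(b.points)
        for i, p in enumerate(a.points):
            js = tree.query_ball_point(p, thr)
            if js:
                a_hit[i] = True
                b_hit[np.asarray(js)] = True
        return a_hit, b_hit
    if cfg.max_dist is not None:
        thr = float(cfg.max_dist)
        tree = cKDTree(b.points)
        for i, p in enumerate(a.points):
            js = tree.query_ball_point(p, thr)
            if js:
                a_hit[i] = True
                b_hit[np.asarray(js)] = True
        return a_hit, b_hit
    # centroid_expand: shared-lattice-pixel test; disks cannot share a pixel
    # if centroids are farther apart than 2*radius
    r = float(cfg.expand_px)
    tree = cKDTree(b.points)
    for i, p in enumerate(a.points):
        for j in tree.query_ball_point(p, 2.0 * r + 1e-9):
            if _disks_share_pixel(p, b.points[j], r, shape):
                a_hit[i] = True
                b_hit[j] = True
    return a_hit, b_hit


def count_coloc_pairs(
    a: PointSet,
    b: PointSet,
    cfg: Optional[ColocConfig] = None,
    shape=None,
    field_id: str = "",
    marker: str = "",
) -> ColocResult:
    """Two-channel colocalization count.

    ``a`` is the nuclear (counting) category: ``n_coloc`` is the number of
    a-points with at least one colocalized b-partner, each counted once.
    """
    cfg = cfg or ColocConfig()
    shape = tuple(shape) if shape is not None else tuple(a.source_shape)
    _check_shapes(shape, a, b)
    a_hit, _ = _pair_partners(a, b, cfg, shape)
    return ColocResult(
        field_id=field_id,
        marker=marker,
        n_per_category={a.category: len(a), b.category: len(b)},
        n_coloc=int(a_hit.sum()),
    )


def count_coloc_triples(
    a: PointSet,
    b: PointSet,
    c: PointSet,
    cfg: Optional[ColocConfig] = None,
    shape=None,
    field_id: str = "",
    marker: str = "",
) -> ColocResult:
    """Three-channel combined-category (123) count: a nuclear point counts
    iff it has a colocalized partner in *both* marker categories."""
    cfg = cfg or ColocConfig()
    shape = tuple(shape) if shape is not None else tuple(a.source_shape)
    _check_shapes(shape, a, b, c)
    ab, _ = _pair_partners(a, b, cfg, shape)
    ac, _ = _pair_partners(a, c, cfg, shape)
    return ColocResult(
        field_id=field_id,
        marker=marker,
        n_per_category={a.category: len(a), b.category: len(b), c.category: len(c)},
        n_coloc=int((ab & ac).sum()),
    )


def run_automated_pipeline(
    channels: Sequence[ChannelImage],
    expand_px: int = 5,
    illum: str = "divide",
    seg_config: Optional[SegmentationConfig] = None,
    field_id: str = "",
    marker: str = "",
) -> ColocResult:
    """Automated counting: illumination correction, three-class Otsu
    object identification, shrink-to-point, expand-and-relate.

    ``channels`` is [nuclear, marker] or [nuclear, marker, marker2], all
    of identical dimensions.  ``illum`` is ``divide``, ``subtract`` or
    ``off``.
    """
    if not 2 <= len(channels) <= 3:
        raise ParameterError(f"need 2 or 3 channels, got {len(channels)}")
    shapes = {ch.shape for ch in channels}
    if len(shapes) != 1:
        raise ShapeMismatchError(f"channel dimensions differ: {sorted(shapes)}")
    if illum not in ("divide", "subtract", "off"):
        raise ParameterError(f"illum must be divide/subtract/off, got {illum!r}")
    point_sets: List[PointSet] = []
    for i, ch in enumerate(channels):
        work = ch
        if illum != "off":
            work = apply_illumination(ch, fit_illumination(ch), mode=illum)
        lm = identify_objects(work, seg_config)
        ps = centroids(lm, category=i + 1)
        logger.info(
            "automated stage: channel %d (%s): %d objects", i + 1, ch.role or "?", lm.n_objects
        )
        point_sets.append(ps)
    cfg = ColocConfig(mode="centroid_expand", expand_px=expand_px)
    shape = channels[0].shape
    if len(point_sets) == 2:
        return count_coloc_pairs(point_sets[0], point_sets[1], cfg, shape, field_id, marker)
    return count_coloc_triples(*point_sets, cfg=cfg, shape=shape, field_id=field_id, marker=marker)


def run_semiauto_pipeline(
    channels: Sequence[ChannelImage],
    maxima_cfgs: Sequence[MaximaConfig],
    edits: Optional[Sequence[Optional[dict]]] = None,
    coloc_cfg: Optional[ColocConfig] = None,
    field_id: str = "",
    marker: str = "",
) -> ColocResult:
    """Semi-automated counting: pre-blur, prominence maxima detection and
    scripted point edits per channel, then overlay-disk colocalization.

    ``edits`` is an optional per-channel list of dicts with keys ``add``,
    ``remove`` and ``snap_radius`` (see :func:`obcacount.maxima.edit_points`),
    standing in for the observer's manual correction.
    """
    if not 2 <= len(channels) <= 3:
        raise ParameterError(f"need 2 or 3 channels, got {len(channels)}")
    if len(maxima_cfgs) != len(channels):
        raise ParameterError("need one MaximaConfig per channel")
    shapes = {ch.shape for ch in channels}
    if len(shapes) != 1:
        raise ShapeMismatchError(f"channel dimensions differ: {sorted(shapes)}")
    cfg = coloc_cfg or ColocConfig(mode="overlay")
    if cfg.mode != "overlay":
        cfg = ColocConfig(mode="overlay", overlay_radius=cfg.overlay_radius)
    point_sets: List[PointSet] = []
    for i, (ch, mcfg) in enumerate(zip(channels, maxima_cfgs)):
        ps = find_maxima(ch, mcfg, category=i + 1)
        if edits is not None and i < len(edits) and edits[i]:
            e = edits[i]
            ps = edit_points(
                ps,
                add=e.get("add"),
                remove=e.get("remove"),
                snap_radius=e.get("snap_radius", 5.0),
            )
        logger.info(
            "semi-automated stage: channel %d (%s): %d maxima", i + 1, ch.role or "?", len(ps)
        )
        point_sets.append(ps)
    shape = channels[0].shape
    if len(point_sets) == 2:
        return count_coloc_pairs(point_sets[0], point_sets[1], cfg, shape, field_id, marker)
    return count_coloc_triples(*point_sets, cfg=cfg, shape=shape, field_id=field_id, marker=marker)
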