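"""Prominence-based 2D maxima detection and point editing.

This is the computational core of the semi-automated counting method: an
optional Gaussian pre-blur, detection of local maxima whose *prominence*
(peak height minus the highest saddle connecting the peak to any strictly
higher region) exceeds a noise tolerance, and reproducible point-list
editing that stands in for manual correction.

Detection semantics
-------------------
* A local maximum is a connected plateau of equal-valued pixels with no
  strictly higher neighbor; it is reported as one point at the plateau's
  pixel centroid.
* The prominence of the highest peak (no strictly higher region exists)
  is its height above the image minimum.  Equal-valued peaks connected
  only through strictly lower ground are therefore each reported.
* A maximum is accepted iff prominence > noise_tolerance (strict).  With
  tolerance 0 every local maximum is accepted, so a completely flat image
  yields exactly one point (the whole image is one plateau); with any
  positive tolerance a flat image yields none.

The flood is a single descending sweep with union-find: pixels are added
in decreasing intensity order; when a pixel connects two components the
lower peak dies and its prominence is its height minus the merge level
(the highest saddle).  This is an exact computation, not an approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numba import njit
from scipy import ndimage as ndi

from .containers import ChannelImage, PointSet
from .exceptions import BoundsError, ParameterError

__all__ = [
    "MaximaConfig",
    "pre_blur",
    "find_maxima",
    "maxima_with_prominence",
    "edit_points",
]

logger = logging.getLogger(__name__)


@dataclass
class MaximaConfig:
    """Detection parameters.

    pre_blur_radius : Gaussian sigma in pixels applied before detection
        (0 = no blur).  The blur suppresses single-pixel noise peaks.
    noise_tolerance : required prominence, in intensity units of the
        (possibly blurred) image.
    exclude_border : drop maxima whose nearest pixel lies on the image
        border (off by default; edge cells count).
    """

    pre_blur_radius: float = 0.0
    noise_tolerance: float = 0.0
    exclude_border: bool = False

    def __post_init__(self) -> None:
        if self.pre_blur_radius < 0:
            raise ParameterError("pre_blur_radius must be >= 0")
        if self.noise_tolerance < 0:
            raise ParameterError("noise_tolerance must be >= 0")


def pre_blur(img: ChannelImage, radius: float) -> ChannelImage:
    """Gaussian smoothing with sigma = ``radius`` (0 returns the input).

    The result stays in real-valued intensity space — no re-quantization
    happens before maxima detection.  Reflective boundary handling keeps
    total intensity conserved.
    """
    if radius < 0:
        raise ParameterError(f"pre-blur radius must be >= 0, got {radius}")
    if radius == 0:
        return img
    out = ndi.gaussian_filter(img.astype_float(), sigma=radius, mode="reflect")
    return img.with_pixels(out)


@njit(cache=False)
def _prominence_flood(flat, order, H, W):  # pragma: no cover - compiled
    """Descending union-find flood over the flattened image.

    Returns per-candidate arrays (peak value, coord sums, plateau size,
    prominence, is-a-maximum flag, alive flag).  One candidate is created
    for every plateau that has no higher processed neighbor at creation
    time; candidates merged at their own level are folded together;
    candidates absorbed at their own level by a higher component are
    flagged as non-maxima.
    """
    n = H * W
    parent = np.full(n, -1, dtype=np.int64)  # -1 = unprocessed
    comp_peak = np.zeros(n, dtype=np.float64)
    comp_head = np.full(n, -1, dtype=np.int64)  # head candidate id at root
    cand_peak = np.zeros(n, dtype=np.float64)
    cand_sr = np.zeros(n, dtype=np.float64)
    cand_sc = np.zeros(n, dtype=np.float64)
    cand_npx = np.zeros(n, dtype=np.int64)
    cand_prom = np.full(n, -1.0, dtype=np.float64)  # -1 = alive
    cand_ismax = np.zeros(n, dtype=np.uint8)
    cand_alive = np.zeros(n, dtype=np.uint8)
    cand_next = np.full(n, -1, dtype=np.int64)
    ncand = 0

    def find(i, parent):
        r = i
        while parent[r] != r:
            r = parent[r]
        while parent[i] != r:
            nxt = parent[i]
            parent[i] = r
            i = nxt
        return r

    nbr_roots = np.empty(8, dtype=np.int64)
    for oi in range(n):
        p = order[oi]
        v = flat[p]
        pr = p // W
        pc = p % W
        # gather distinct roots of processed neighbors
        k = 0
        for dr in range(-1, 2):
            rr = pr + dr
            if rr < 0 or rr >= H:
                continue
            for dc in range(-1, 2):
                if dr == 0 and dc == 0:
                    continue
                cc = pc + dc
                if cc < 0 or cc >= W:
                    continue
                q = rr * W + cc
                if parent[q] == -1:
                    continue
                root = find(q, parent)
                dup = False
                for t in range(k):
                    if nbr_roots[t] == root:
                        dup = True
                        break
                if not dup:
                    nbr_roots[k] = root
                    k += 1
        if k == 0:
            # new component: this pixel seeds a candidate plateau
            parent[p] = p
            comp_peak[p] = v
            cid = ncand
            ncand += 1
            cand_peak[cid] = v
            cand_sr[cid] = pr
            cand_sc[cid] = pc
            cand_npx[cid] = 1
            cand_ismax[cid] = 1
            cand_alive[cid] = 1
            comp_head[p] = cid
            continue
        # pick survivor: highest peak, ties -> smallest root index
        best = nbr_roots[0]
        for t in range(1, k):
            r = nbr_roots[t]
            if comp_peak[r] > comp_peak[best] or (
                comp_peak[r] == comp_peak[best] and r < best
            ):
                best = r
        P = comp_peak[best]
        if P == v:
            # all connected components are plateaus at this very level:
            # fold their candidates into one (they are one plateau)
            keep = comp_head[best]
            for t in range(k):
                r = nbr_roots[t]
                if r == best:
                    continue
                cid = comp_head[r]
                # single alive candidate per same-level component
                cand_sr[keep] += cand_sr[cid]
                cand_sc[keep] += cand_sc[cid]
                cand_npx[keep] += cand_npx[cid]
                cand_alive[cid] = 0
                parent[r] = best
            cand_sr[keep] += pr
            cand_sc[keep] += pc
            cand_npx[keep] += 1
            parent[p] = best
        else:
            # p is a slope pixel joining (and possibly merging) components
            for t in range(k):
                r = nbr_roots[t]
                if r == best:
                    continue
                if comp_peak[r] < P:
                    # every alive candidate in r dies at saddle level v
                    cid = comp_head[r]
                    while cid != -1:
                        if cand_alive[cid] == 1:
                            cand_prom[cid] = cand_peak[cid] - v
                            if cand_peak[cid] == v:
                                # absorbed at its own level: not a maximum
                                cand_ismax[cid] = 0
                            cand_alive[cid] = 0
                        cid = cand_next[cid]
                else:
                    # equal peaks above v: both survive; concatenate lists
                    cid = comp_head[r]
                    if cid != -1:
                        tail = cid
                        while cand_next[tail] != -1:
                            tail = cand_next[tail]
                        cand_next[tail] = comp_head[best]
                        comp_head[best] = cid
                parent[r] = best
            parent[p] = best
    # survivors: prominence relative to the image minimum
    gmin = flat[order[n - 1]]
    for cid in range(ncand):
        if cand_alive[cid] == 1:
            cand_prom[cid] = cand_peak[cid] - gmin
            cand_alive[cid] = 0
    return (
        cand_peak[:ncand],
        cand_sr[:ncand],
        cand_sc[:ncand],
        cand_npx[:ncand],
        cand_prom[:ncand],
        cand_ismax[:ncand],
    )


def maxima_with_prominence(img: ChannelImage):
    """All local maxima of a channel with their prominences.

    Returns ``(points, peaks, prominences)`` where ``points`` is an
    (n, 2) array of plateau centroids sorted by descending peak intensity
    then row-major position.
    """
    px = img.astype_float()
    H, W = px.shape
    flat = px.ravel()
    # stable argsort on negated values: descending value, ties ascending index
    order = np.argsort(-flat, kind="stable").astype(np.int64)
    peak, sr, sc, npx, prom, ismax = _prominence_flood(flat, order, H, W)
    keep = ismax == 1
    peak, prom = peak[keep], prom[keep]
    rows = sr[keep] / npx[keep]
    cols = sc[keep] / npx[keep]
    idx = np.lexsort((cols, rows, -peak))
    return np.column_stack([rows[idx], cols[idx]]), peak[idx], prom[idx]


def find_maxima(
    img: ChannelImage, cfg: MaximaConfig, category: int = 1
) -> PointSet:
    """Detect prominence-thresholded maxima as a category-tagged PointSet.

    Applies the configured pre-blur, accepts each local maximum iff its
    prominence strictly exceeds ``noise_tolerance`` (tolerance 0 accepts
    every local maximum), and returns points sorted by descending
    intensity then row-major order.
    """
    work = pre_blur(img, cfg.pre_blur_radius)
    pts, peaks, proms = maxima_with_prominence(work)
    if cfg.noise_tolerance > 0:
        keep = proms > cfg.noise_tolerance
        pts = pts[keep]
    if cfg.exclude_border and len(pts):
        h, w = img.shape
        r = np.rint(pts[:, 0])
        c = np.rint(pts[:, 1])
        pts = pts[(r > 0) & (r < h - 1) & (c > 0) & (c < w - 1)]
    return PointSet(points=pts, category=category, source_shape=img.shape)


def edit_points(
    ps: PointSet,
    add: Optional[Sequence[Tuple[float, float]]] = None,
    remove: Optional[Sequence[Tuple[float, float]]] = None,
    snap_radius: float = 5.0,
) -> PointSet:
    """Apply a reproducible manual-correction edit list.

    Each ``remove`` target deletes the nearest existing point within
    ``snap_radius`` (a warning is logged and nothing happens if none is in
    range); ``add`` points are then appended, rejecting duplicates within
    0.5 px of an existing point.  Adds outside the image raise
    :class:`BoundsError`.
    """
    pts: List[np.ndarray] = [p for p in ps.points]
    h, w = ps.source_shape
    for target in remove or []:
        t = np.asarray(target, dtype=np.float64)
        if not pts:
            logger.warning("remove %s ignored: point set is empty", tuple(t))
            continue
        arr = np.asarray(pts)
        d = np.hypot(arr[:, 0] - t[0], arr[:, 1] - t[1])
        i = int(np.argmin(d))  # argmin takes the lowest index on ties
        if d[i] <= snap_radius:
            pts.pop(i)
        else:
            logger.warning(
                "remove %s ignored: nearest point %.2f px away exceeds snap radius %.2f",
                tuple(t), d[i], snap_radius,
            )
    for added in add or []:
        a = np.asarray(added, dtype=np.float64)
        if not (0 <= a[0] <= h - 1 and 0 <= a[1] <= w - 1):
            raise BoundsError(f"added point {tuple(a)} outside image bounds {(h, w)}")
        if pts:
            arr = np.asarray(pts)
            if np.hypot(arr[:, 0] - a[0], arr[:, 1] - a[1]).min() < 0.5:
                logger.warning("add %s rejected: duplicate within 0.5 px", tuple(a))
                continue
        pts.append(a)
    out = np.asarray(pts).reshape(-1, 2)
    return PointSet(points=out, category=ps.category, source_shape=ps.source_shape)
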