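"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity by direct enumeration or a closed form,
sharing no code with the package's implementation paths.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi


# ---------------------------------------------------------------------------
# multi-Otsu: exhaustive between-class variance over all threshold tuples


def otsu_bruteforce_2(counts: np.ndarray) -> int:
    counts = np.asarray(counts, dtype=np.float64)
    L = counts.size
    vals = np.arange(L, dtype=np.float64)
    W = np.concatenate([[0.0], np.cumsum(counts)])
    M = np.concatenate([[0.0], np.cumsum(counts * vals)])

    def term(lo, hi):  # class = bins lo..hi inclusive
        w = W[hi + 1] - W[lo]
        if w <= 0:
            return 0.0
        m = M[hi + 1] - M[lo]
        return m * m / w

    best_obj, best_i = -1.0, None
    for i in range(L - 1):
        obj = term(0, i) + term(i + 1, L - 1)
        if obj > best_obj:
            best_obj, best_i = obj, i
    return best_i


def otsu_bruteforce_3(counts: np.ndarray):
    """Exhaustive search over all (t1 < t2) bin-index pairs, first
    (lexicographically smallest) maximizer wins."""
    counts = np.asarray(counts, dtype=np.float64)
    L = counts.size
    vals = np.arange(L, dtype=np.float64)
    W = np.concatenate([[0.0], np.cumsum(counts)])
    M = np.concatenate([[0.0], np.cumsum(counts * vals)])

    def term(lo, hi):
        w = W[hi + 1] - W[lo]
        if w <= 0:
            return 0.0
        m = M[hi + 1] - M[lo]
        return m * m / w

    best_obj, best = -1.0, None
    for i in range(L - 1):
        for j in range(i + 1, L - 1):
            obj = term(0, i) + term(i + 1, j) + term(j + 1, L - 1)
            if obj > best_obj:
                best_obj, best = obj, (i, j)
    return best


# ---------------------------------------------------------------------------
# prominence maxima: threshold-descent flood fill from every local maximum


def maxima_oracle(img: np.ndarray, tolerance: float):
    """All accepted maxima of a 2D image under the prominence rule.

    For every equal-value plateau with no higher neighbor, descend the
    unique intensity levels; the prominence is the peak height minus the
    highest level at which the connected component (of pixels >= level)
    containing the plateau includes a strictly higher pixel, or height
    minus the image minimum if no such level exists.  Accept iff
    prominence > tolerance, or tolerance == 0.

    Returns (points, peaks) sorted by descending peak then row-major.
    """
    img = np.asarray(img, dtype=np.float64)
    struct = np.ones((3, 3), dtype=bool)
    values = np.unique(img)
    gmin = float(img.min())
    accepted = []
    for v in values:
        lab, n = ndi.label(img == v, structure=struct)
        for k in range(1, n + 1):
            mask = lab == k
            ring = ndi.binary_dilation(mask, structure=struct) & ~mask
            if ring.any() and img[ring].max() > v:
                continue  # the plateau has a strictly higher neighbor
            prom = v - gmin
            for t in values[values < v][::-1]:
                lab2, _ = ndi.label(img >= t, structure=struct)
                rid = lab2[mask][0]
                if img[lab2 == rid].max() > v:
                    prom = v - t
                    break
            if prom > tolerance or tolerance == 0:
                rr, cc = np.nonzero(mask)
                accepted.append((float(v), rr.mean(), cc.mean()))
    accepted.sort(key=lambda x: (-x[0], x[1], x[2]))
    pts = np.array([(r, c) for _, r, c in accepted], dtype=np.float64).reshape(-1, 2)
    peaks = np.array([p for p, _, _ in accepted], dtype=np.float64)
    return pts, peaks


# ---------------------------------------------------------------------------
# colocalization: O(n^2)/O(n^3) scans with the shared-lattice-pixel rule


def disks_share_pixel_slow(p, q, radius, shape) -> bool:
    h, w = shape
    r2 = radius * radius
    lo_r = max(int(np.floor(min(p[0], q[0]) - radius)), 0)
    hi_r = min(int(np.ceil(max(p[0], q[0]) + radius)), h - 1)
    lo_c = max(int(np.floor(min(p[1], q[1]) - radius)), 0)
    hi_c = min(int(np.ceil(max(p[1], q[1]) + radius)), w - 1)
    for rr in range(lo_r, hi_r + 1):
        for cc in range(lo_c, hi_c + 1):
            if (rr - p[0]) ** 2 + (cc - p[1]) ** 2 <= r2 and (
                rr - q[0]
            ) ** 2 + (cc - q[1]) ** 2 <= r2:
                return True
    return False


def coloc_pairs_oracle(a_pts, b_pts, radius, shape) -> int:
    """Number of a-points whose expanded disk shares a lattice pixel with
    some b-disk; all-pairs scan (disks farther apart than 2*radius cannot
    share a pixel, by the triangle inequality)."""
    count = 0
    lim = (2.0 * radius) ** 2
    for p in a_pts:
        for q in b_pts:
            d2 = (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2
            if d2 <= lim + 1e-9 and disks_share_pixel_slow(p, q, radius, shape):
                count += 1
                break
    return count


def coloc_triples_oracle(a_pts, b_pts, c_pts, radius, shape) -> int:
    count = 0
    lim = (2.0 * radius) ** 2
    for p in a_pts:
        hit_b = any(
            (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 <= lim + 1e-9
            and disks_share_pixel_slow(p, q, radius, shape)
            for q in b_pts
        )
        if not hit_b:
            continue
        hit_c = any(
            (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 <= lim + 1e-9
            and disks_share_pixel_slow(p, q, radius, shape)
            for q in c_pts
        )
        if hit_c:
            count += 1
    return count


# ---------------------------------------------------------------------------
# centroids: brute-force pixel scan per label


def centroids_oracle(labels: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, 2))
    for k in range(1, n + 1):
        px = np.argwhere(labels == k)
        out[k - 1] = px.mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# Gaussian blur: direct convolution with an explicitly built kernel


def gaussian_blur_oracle(img: np.ndarray, sigma: float) -> np.ndarray:
    """Direct 2D convolution with a truncated (4 sigma) Gaussian kernel
    under symmetric (reflect) boundary handling."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k1 = np.exp(-(x * x) / (2.0 * sigma * sigma))
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    padded = np.pad(np.asarray(img, dtype=np.float64), radius, mode="symmetric")
    h, w = img.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = (padded[i : i + 2 * radius + 1, j : j + 2 * radius + 1] * kernel).sum()
    return out


# ---------------------------------------------------------------------------
# paired t closed form (mean/SD formula + t CDF for 3 df via arctan)


def paired_t_closed_form(d: np.ndarray):
    """t statistic from the definition; exact p only for n = 4 (3 df),
    where the t CDF has the elementary closed form
    F(t) = 1/2 + (1/pi) * [ (t/sqrt(3)) / (1 + t^2/3) + arctan(t/sqrt(3)) ].
    """
    d = np.asarray(d, dtype=np.float64)
    n = d.size
    sd = np.sqrt(((d - d.mean()) ** 2).sum() / (n - 1))
    t = d.mean() / (sd / np.sqrt(n))
    if n != 4:
        return t, None
    x = t / np.sqrt(3.0)
    cdf = 0.5 + (x / (1.0 + x * x) + np.arctan(x)) / np.pi
    p = 2.0 * min(cdf, 1.0 - cdf)
    return t, p
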