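"""Independent brute-force oracles used by the tests.

These implementations deliberately avoid the package's own code paths so
that agreement is meaningful: the enclosing-circle oracle enumerates all
pair/triple circles, the warp oracle maps every output pixel through the
inverse matrix by hand, and centroids/extrema come from raw pixel sums.
"""

import math

import numpy as np


def brute_force_enclosing_circle(points):
    """O(n^3) minimum enclosing circle: all pair-diameter and triple
    circumcircle candidates, smallest one containing every point."""
    pts = np.unique(np.asarray(points, dtype=float).reshape(-1, 2), axis=0)
    n = len(pts)
    assert n >= 2, "oracle needs >=2 distinct points"
    eps = 1e-9

    def contains_all(c, r):
        return bool((np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
                     <= r + eps * (1 + r)).all())

    best = None
    for i in range(n):
        for j in range(i + 1, n):
            c = (pts[i] + pts[j]) / 2.0
            r = float(np.linalg.norm(pts[i] - c))
            if contains_all(c, r) and (best is None or r < best[1]):
                best = (c, r)
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                ax, ay = pts[i]
                bx, by = pts[j]
                cx, cy = pts[k]
                d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
                if abs(d) < 1e-12:
                    continue
                ux = ((ax ** 2 + ay ** 2) * (by - cy)
                      + (bx ** 2 + by ** 2) * (cy - ay)
                      + (cx ** 2 + cy ** 2) * (ay - by)) / d
                uy = ((ax ** 2 + ay ** 2) * (cx - bx)
                      + (bx ** 2 + by ** 2) * (ax - cx)
                      + (cx ** 2 + cy ** 2) * (bx - ax)) / d
                c = np.array([ux, uy])
                r = float(np.linalg.norm(pts[i] - c))
                if contains_all(c, r) and (best is None or r < best[1]):
                    best = (c, r)
    assert best is not None
    return best  # (center (2,), radius)


def mask_centroid(mask):
    """(x, y) centroid of foreground pixels by brute-force pixel sum."""
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    assert xs.size > 0
    return float(xs.mean()), float(ys.mean())


def extrema_circle(mask):
    """Circle estimate from exhaustive pixel-extrema scan of a disk mask."""
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    cx = (xs.min() + xs.max()) / 2.0
    cy = (ys.min() + ys.max()) / 2.0
    r = ((xs.max() - xs.min()) + (ys.max() - ys.min())) / 4.0
    return (cx, cy), float(r)


def brute_force_warp_nearest(raster, matrix):
    """Per-pixel inverse-mapped nearest-neighbor warp, written longhand."""
    raster = np.asarray(raster)
    h, w = raster.shape
    inv = np.linalg.inv(np.asarray(matrix, dtype=float))
    out = np.zeros_like(raster)
    for y in range(h):
        for x in range(w):
            sx = inv[0, 0] * x + inv[0, 1] * y + inv[0, 2]
            sy = inv[1, 0] * x + inv[1, 1] * y + inv[1, 2]
            ix, iy = int(round(sx)), int(round(sy))
            if 0 <= ix < w and 0 <= iy < h:
                out[y, x] = raster[iy, ix]
    return out


def innermost_scan(mask, side):
    """Exhaustive scan for the extreme-x pixel with the min-y/min-x tie rule."""
    best = None
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            key = (-x, y, x) if side == "max" else (x, y, x)
            if best is None or key < best:
                best = key
    assert best is not None
    return (abs(best[0]), best[1])


def rasterize_ellipse(shape, center, a, b, orientation_deg=0.0):
    """Filled ellipse by the center-of-pixel inclusion test."""
    h, w = shape
    ys = np.arange(h, dtype=float)[:, None]
    xs = np.arange(w, dtype=float)[None, :]
    th = math.radians(orientation_deg)
    dx = xs - center[0]
    dy = ys - center[1]
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0
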