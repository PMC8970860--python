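"""Limbus/sclera circle modeling, corneal-reflex localization, and eccentric
limbus-center recovery.

The limbus in the primary gaze is modeled by the minimum enclosing circle of
its mask; the sclera circle shares the center of its component's enclosing
circle but takes a radius of ``ratio`` (default 2.5) times the limbus radius.
In eccentric gazes the visible limbus is treated as an ellipse: its center is
recovered by stepping one limbus radius back from the outer short-axis
contour point, keeping the candidate nearer the modeled sclera (eyeball)
center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import EllipseModel, find_contours

from .errors import (DegenerateMaskError, GeometryInconsistencyError,
                     InvalidGeometryError, NoReflexError)

__all__ = [
    "Circle", "EllipseFit", "EyeModel", "min_enclosing_circle",
    "enclosing_circle_of_points", "detect_corneal_reflex", "model_sclera",
    "fit_ellipse", "recover_limbus_center",
]

Point2D = tuple[float, float]


@dataclass(frozen=True)
class Circle:
    center: Point2D
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise InvalidGeometryError(f"radius must be positive, got {self.radius}")
        object.__setattr__(self, "center", tuple(float(v) for v in self.center))

    def contains(self, point, tol: float = 1e-9) -> bool:
        dx = point[0] - self.center[0]
        dy = point[1] - self.center[1]
        return math.hypot(dx, dy) <= self.radius + tol

    def to_dict(self) -> dict:
        return {"center": list(self.center), "radius": self.radius}


@dataclass(frozen=True)
class EllipseFit:
    center: Point2D
    semi_major: float
    semi_minor: float
    orientation_deg: float  # major-axis direction, in (-90, 90]

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise InvalidGeometryError(
                f"need semi_major >= semi_minor > 0, got "
                f"({self.semi_major}, {self.semi_minor})")
        object.__setattr__(self, "center", tuple(float(v) for v in self.center))
        a = math.fmod(self.orientation_deg, 180.0)
        if a > 90.0:
            a -= 180.0
        elif a <= -90.0:
            a += 180.0
        object.__setattr__(self, "orientation_deg", a)

    @property
    def axis_ratio(self) -> float:
        return self.semi_minor / self.semi_major

    @property
    def minor_axis_dir(self) -> np.ndarray:
        th = math.radians(self.orientation_deg)
        return np.array([-math.sin(th), math.cos(th)])

    def to_dict(self) -> dict:
        return {"center": list(self.center), "semi_major": self.semi_major,
                "semi_minor": self.semi_minor,
                "orientation_deg": self.orientation_deg}


@dataclass(frozen=True)
class EyeModel:
    """Per-eye primary-gaze model: limbus and sclera circles plus the reflex."""

    limbus: Circle
    sclera: Circle
    reflex: Point2D | None = None

    def to_dict(self) -> dict:
        return {"limbus": self.limbus.to_dict(), "sclera": self.sclera.to_dict(),
                "reflex": None if self.reflex is None else list(self.reflex)}


# -- minimum enclosing circle (Welzl) --------------------------------------

def _circle_from_2(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, float]:
    c = (p + q) / 2.0
    return c, float(np.linalg.norm(p - c))


def _circle_from_3(p: np.ndarray, q: np.ndarray,
                   r: np.ndarray) -> tuple[np.ndarray, float] | None:
    ax, ay = p
    bx, by = q
    cx, cy = r
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None  # collinear
    ux = ((ax * ax + ay * ay) * (by - cy) + (bx * bx + by * by) * (cy - ay)
          + (cx * cx + cy * cy) * (ay - by)) / d
    uy = ((ax * ax + ay * ay) * (cx - bx) + (bx * bx + by * by) * (ax - cx)
          + (cx * cx + cy * cy) * (bx - ax)) / d
    c = np.array([ux, uy])
    return c, float(np.linalg.norm(p - c))


def _trivial_circle(support: list[np.ndarray]) -> tuple[np.ndarray, float]:
    if not support:
        return np.zeros(2), 0.0
    if len(support) == 1:
        return support[0].copy(), 0.0
    if len(support) == 2:
        return _circle_from_2(support[0], support[1])
    circ = _circle_from_3(*support)
    if circ is None:  # collinear support: widest pair
        best = max(((p, q) for p in support for q in support),
                   key=lambda pq: np.linalg.norm(pq[0] - pq[1]))
        return _circle_from_2(*best)
    return circ


def _welzl(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Iterative move-to-front Welzl on a small point set."""
    pts = [points[i] for i in range(len(points))]

    def mec(n: int, support: list[np.ndarray]) -> tuple[np.ndarray, float]:
        c, r = _trivial_circle(support)
        if len(support) == 3:
            return c, r
        for i in range(n):
            p = pts[i]
            if np.linalg.norm(p - c) > r + 1e-10 * (1.0 + r):
                c, r = mec(i, support + [p])
                pts.insert(0, pts.pop(i))  # move-to-front
        return c, r

    return mec(len(pts), [])


def enclosing_circle_of_points(points: np.ndarray) -> Circle:
    """Minimum enclosing circle of ``(N, 2)`` points given as (x, y)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise DegenerateMaskError("no points to enclose")
    pts = np.unique(pts, axis=0)
    if len(pts) == 1:
        # rasterized single pixel: enclose its unit cell footprint center
        return Circle(center=tuple(pts[0]), radius=0.5)
    if len(pts) > 32:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear input; Welzl handles it directly
    c, r = _welzl(pts)
    return Circle(center=(float(c[0]), float(c[1])), radius=max(float(r), 0.5))


def min_enclosing_circle(mask: np.ndarray) -> Circle:
    """Minimum enclosing circle of a mask's foreground pixel centers."""
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    if xs.size == 0:
        raise DegenerateMaskError("empty mask")
    return enclosing_circle_of_points(np.column_stack([xs, ys]).astype(float))


# -- corneal reflex --------------------------------------------------------

def detect_corneal_reflex(image: np.ndarray, limbus_mask: np.ndarray,
                          rel_threshold: float = 0.9,
                          abs_floor: float = 0.8) -> Point2D:
    """Locate the specular reflex inside the limbus.

    Pixels outside ``limbus_mask`` are ignored; in-mask pixels are
    thresholded at ``rel_threshold`` x the in-mask maximum, and the
    intensity-weighted centroid of the largest bright component is returned.
    If the in-mask maximum is below ``abs_floor`` (fraction of dynamic range)
    no reflex is deemed present.
    """
    mask = np.asarray(limbus_mask, dtype=bool)
    if not mask.any():
        raise DegenerateMaskError("empty limbus mask")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.shape != mask.shape:
        raise InvalidGeometryError(
            f"image shape {img.shape} != mask shape {mask.shape}")
    if img.max() > 1.0:
        img = img / 255.0

    peak = img[mask].max()
    if peak < abs_floor:
        raise NoReflexError(
            f"in-limbus peak intensity {peak:.3f} below floor {abs_floor}")
    bright = mask & (img >= rel_threshold * peak)
    labels, n = ndimage.label(bright, structure=np.ones((3, 3), int))
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    comp = labels == areas.argmax()
    ys, xs = np.nonzero(comp)
    w = img[ys, xs]
    return (float((xs * w).sum() / w.sum()), float((ys * w).sum() / w.sum()))


# -- sclera modeling -------------------------------------------------------

def model_sclera(sclera_component: np.ndarray, limbus_radius: float,
                 ratio: float = 2.5) -> Circle:
    """Sclera circle: enclosing-circle center, radius = ratio x limbus radius."""
    if not limbus_radius > 0:
        raise InvalidGeometryError(f"limbus radius must be positive, got {limbus_radius}")
    mec = min_enclosing_circle(sclera_component)
    return Circle(center=mec.center, radius=ratio * limbus_radius)


# -- ellipse fitting -------------------------------------------------------

def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    inner = ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool))
    ys, xs = np.nonzero(mask & ~inner)
    return np.column_stack([xs, ys]).astype(float)


def fit_ellipse(mask: np.ndarray) -> EllipseFit:
    """Direct least-squares ellipse fit to a mask component's boundary.

    The conic is fit to the subpixel 0.5-level contour; the mask must expose
    at least five non-collinear boundary pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    bpix = _boundary_pixels(mask)
    if len(bpix) < 5:
        raise DegenerateMaskError(
            f"ellipse fit needs >=5 boundary pixels, found {len(bpix)}")
    centered = bpix - bpix.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateMaskError("boundary pixels are collinear")

    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise DegenerateMaskError("no boundary contour found")
    contour = max(contours, key=len)  # (row, col) -> (x, y)
    pts = contour[:, ::-1]

    model = EllipseModel.from_estimate(pts)
    if not model:
        raise DegenerateMaskError("degenerate conic: ellipse fit failed")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not (np.isfinite([xc, yc, a, b, theta]).all() and a > 0 and b > 0):
        raise DegenerateMaskError("degenerate conic: non-finite ellipse")
    if b > a:
        a, b = b, a
        theta += math.pi / 2.0
    return EllipseFit(center=(float(xc), float(yc)), semi_major=float(a),
                      semi_minor=float(b),
                      orientation_deg=math.degrees(theta))


# -- eccentric limbus-center recovery --------------------------------------

def recover_limbus_center(fit: EllipseFit, limbus_radius: float,
                          sclera_model: Circle,
                          circularity_threshold: float = 0.95) -> Circle:
    """Limbus circle for an eccentric gaze from its elliptical appearance.

    Near-circular fits (axis ratio above ``circularity_threshold``) keep the
    ellipse center.  Otherwise the two candidate centers lie one limbus
    radius from the outer short-axis contour point, along the short axis; the
    candidate nearer the sclera (eyeball) center wins, since the limbus must
    sit on the eyeball.  Perfectly symmetric ties resolve toward the fit
    center's side of the eyeball (the apparent gaze direction).
    """
    if not limbus_radius > 0:
        raise InvalidGeometryError(f"limbus radius must be positive, got {limbus_radius}")
    if fit.axis_ratio > circularity_threshold:
        return Circle(center=fit.center, radius=limbus_radius)

    center = np.asarray(fit.center)
    sclera_c = np.asarray(sclera_model.center)
    v = fit.minor_axis_dir
    # outward = away from the eyeball center; on a tie, toward the gaze
    # direction (from the eyeball center to the fit center), else +v.
    outward = center - sclera_c
    if np.linalg.norm(outward) < 1e-9:
        outward = v
    if float(np.dot(v, outward)) < 0:
        v = -v
    p_out = center + fit.semi_minor * v
    candidates = [p_out - limbus_radius * v, p_out + limbus_radius * v]
    candidates.sort(key=lambda p: float(np.linalg.norm(p - sclera_c)))
    for cand in candidates:
        if sclera_model.contains(cand, tol=1e-6):
            return Circle(center=(float(cand[0]), float(cand[1])),
                          radius=limbus_radius)
    raise GeometryInconsistencyError(
        "both candidate limbus centers fall outside the modeled sclera")
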