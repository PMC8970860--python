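"""Reference-line similarity registration onto the primary gaze frame.

The reference line joins the nasal-most ("innermost") point of each eye's
sclera component — the point of the image-left component with maximal x and
the point of the image-right component with minimal x, ties broken by minimal
y then minimal x.  A gaze frame is registered by translating its line center
onto the primary line center and scaling/rotating (about the moving center)
so the line lengths and angles match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, DegenerateMaskError
from .segmentation import split_eyes
from .transforms import SimilarityTransform, apply_transform

__all__ = [
    "ReferenceLine", "innermost_points", "reference_line", "solve_similarity",
    "apply_transform", "register_gaze", "RegisteredGaze",
]

Point2D = tuple[float, float]


def _normalize_angle(deg: float) -> float:
    """Wrap an angle to (-180, 180]."""
    a = math.fmod(deg, 360.0)
    if a > 180.0:
        a -= 360.0
    elif a <= -180.0:
        a += 360.0
    return a


@dataclass(frozen=True)
class ReferenceLine:
    """Segment between the two innermost sclera points."""

    center: Point2D
    length: float
    angle_deg: float

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise DegenerateGeometryError(f"length must be positive, got {self.length}")
        object.__setattr__(self, "center", tuple(float(v) for v in self.center))
        object.__setattr__(self, "angle_deg", _normalize_angle(self.angle_deg))

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        th = math.radians(self.angle_deg)
        half = 0.5 * self.length * np.array([math.cos(th), math.sin(th)])
        c = np.asarray(self.center, dtype=float)
        return c - half, c + half


def _extreme_point(mask: np.ndarray, side: str) -> Point2D:
    """Extreme-x foreground pixel; ties by minimal y, then minimal x."""
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    if xs.size == 0:
        raise DegenerateMaskError("empty sclera component")
    x_star = xs.max() if side == "max" else xs.min()
    y_star = ys[xs == x_star].min()
    return (float(x_star), float(y_star))


def innermost_points(left_sclera: np.ndarray,
                     right_sclera: np.ndarray) -> tuple[Point2D, Point2D]:
    """Nasal-most point of each sclera component, toward the facial midline."""
    return (_extreme_point(left_sclera, "max"),
            _extreme_point(right_sclera, "min"))


def reference_line(p_left: Point2D, p_right: Point2D) -> ReferenceLine:
    """Line from the left-eye point to the right-eye point."""
    (x0, y0), (x1, y1) = p_left, p_right
    dx, dy = x1 - x0, y1 - y0
    length = math.hypot(dx, dy)
    if length == 0:
        raise DegenerateGeometryError("reference points coincide")
    return ReferenceLine(center=((x0 + x1) / 2.0, (y0 + y1) / 2.0),
                         length=length,
                         angle_deg=math.degrees(math.atan2(dy, dx)))


def solve_similarity(moving: ReferenceLine,
                     fixed: ReferenceLine) -> SimilarityTransform:
    """Similarity transform mapping the moving line onto the fixed line.

    Scales and rotates about the moving line's center, then translates the
    center onto the fixed center; maps the moving endpoints exactly onto the
    fixed endpoints.
    """
    return SimilarityTransform(
        scale=fixed.length / moving.length,
        rotation_deg=_normalize_angle(fixed.angle_deg - moving.angle_deg),
        translation=(fixed.center[0] - moving.center[0],
                     fixed.center[1] - moving.center[1]),
        pivot=moving.center,
    )


@dataclass
class RegisteredGaze:
    image: np.ndarray
    sclera_mask: np.ndarray
    masks: dict[str, np.ndarray]
    transform: SimilarityTransform
    line: ReferenceLine  # the scene's own (pre-registration) reference line


def measure_reference_line(sclera_mask: np.ndarray,
                           min_area: int = 40) -> ReferenceLine:
    """Reference line of a two-eye sclera mask."""
    left, right = split_eyes(sclera_mask, min_area=min_area)
    p_left, p_right = innermost_points(left, right)
    return reference_line(p_left, p_right)


def register_gaze(scene_image: np.ndarray, sclera_mask: np.ndarray,
                  primary_line: ReferenceLine,
                  extra_masks: dict[str, np.ndarray] | None = None,
                  min_area: int = 40) -> RegisteredGaze:
    """Register one gaze frame onto the primary frame.

    Measures the frame's own sclera reference line, solves the similarity
    onto ``primary_line`` and warps the image (bilinear) plus the sclera and
    any extra masks (nearest).
    """
    line = measure_reference_line(sclera_mask, min_area=min_area)
    T = solve_similarity(line, primary_line)
    if T.is_identity:
        reg_image = np.array(scene_image)
        reg_sclera = np.asarray(sclera_mask, dtype=bool).copy()
        reg_masks = {k: np.asarray(m, dtype=bool).copy()
                     for k, m in (extra_masks or {}).items()}
    else:
        reg_image = apply_transform(scene_image, T, "bilinear")
        reg_sclera = apply_transform(np.asarray(sclera_mask, dtype=bool), T, "nearest")
        reg_masks = {k: apply_transform(np.asarray(m, dtype=bool), T, "nearest")
                     for k, m in (extra_masks or {}).items()}
    return RegisteredGaze(image=reg_image, sclera_mask=reg_sclera,
                          masks=reg_masks, transform=T, line=line)
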