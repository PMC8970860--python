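"""2D similarity transforms (isotropic scale + rotation + translation).

Coordinate convention used throughout the package: pixel coordinates with the
origin at the top-left corner, x increasing rightward (columns), y increasing
downward (rows); subpixel positions are reals and points are ``(x, y)`` pairs.

A :class:`SimilarityTransform` maps a point ``p`` to::

    p' = s * R(theta) @ (p - pivot) + pivot + translation

i.e. scaling and rotation happen about ``pivot``, followed by a translation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, warp

from .errors import InvalidGeometryError, SpecificationError

__all__ = ["SimilarityTransform", "apply_transform"]


@dataclass(frozen=True)
class SimilarityTransform:
    """Angle-preserving 2D transform: isotropic scale, rotation, translation.

    Parameters
    ----------
    scale:
        Isotropic scale factor, must be positive.
    rotation_deg:
        Rotation angle in degrees (positive rotates +x toward +y, which on a
        y-down raster appears clockwise).
    translation:
        Translation applied after the scaled rotation about ``pivot``.
    pivot:
        Fixed point of the scale/rotation part.
    """

    scale: float = 1.0
    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    pivot: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise InvalidGeometryError(f"scale must be positive, got {self.scale}")
        object.__setattr__(self, "translation", tuple(float(v) for v in self.translation))
        object.__setattr__(self, "pivot", tuple(float(v) for v in self.pivot))

    # -- matrix forms ------------------------------------------------------

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on column vectors ``(x, y, 1)``."""
        th = math.radians(self.rotation_deg)
        a = self.scale * math.cos(th)
        b = self.scale * math.sin(th)
        A = np.array([[a, -b], [b, a]])
        c = np.asarray(self.pivot, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        offset = c + t - A @ c
        M = np.eye(3)
        M[:2, :2] = A
        M[:2, 2] = offset
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "SimilarityTransform":
        M = np.asarray(M, dtype=float)
        a, b = M[0, 0], M[1, 0]
        scale = math.hypot(a, b)
        if scale <= 0:
            raise InvalidGeometryError("matrix is not a similarity (zero scale)")
        rotation = math.degrees(math.atan2(b, a))
        return cls(scale=scale, rotation_deg=rotation,
                   translation=(M[0, 2], M[1, 2]), pivot=(0.0, 0.0))

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()

    @property
    def is_identity(self) -> bool:
        return bool(np.allclose(self.matrix, np.eye(3), atol=1e-12))

    # -- algebra -----------------------------------------------------------

    def apply(self, points) -> np.ndarray:
        """Map one ``(x, y)`` point or an ``(N, 2)`` array of points."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        M = self.matrix
        out = pts @ M[:2, :2].T + M[:2, 2]
        return out[0] if single else out

    def inverse(self) -> "SimilarityTransform":
        return SimilarityTransform.from_matrix(np.linalg.inv(self.matrix))

    def then(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Composite transform: apply ``self`` first, then ``other``."""
        return SimilarityTransform.from_matrix(other.matrix @ self.matrix)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "rotation_deg": self.rotation_deg,
            "translation": list(self.translation),
            "pivot": list(self.pivot),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(scale=d["scale"], rotation_deg=d["rotation_deg"],
                   translation=tuple(d["translation"]), pivot=tuple(d["pivot"]))


def apply_transform(raster: np.ndarray, T: SimilarityTransform,
                    interp: str = "bilinear") -> np.ndarray:
    """Warp a raster by a similarity transform.

    ``interp`` is ``"bilinear"`` for intensity images or ``"nearest"`` for
    binary masks (keeps masks binary).  The output has the same shape as the
    input; source pixels falling outside the input fill with 0.  Applying the
    identity with nearest interpolation returns a byte-identical raster.
    """
    raster = np.asarray(raster)
    if raster.size == 0:
        raise InvalidGeometryError("empty raster")
    if interp not in ("bilinear", "nearest"):
        raise SpecificationError(f"unknown interpolation {interp!r}")
    order = 1 if interp == "bilinear" else 0

    was_bool = raster.dtype == bool
    img = raster.astype(np.float64)
    inv = AffineTransform(matrix=np.linalg.inv(T.matrix))
    out = warp(img, inverse_map=inv, order=order, cval=0.0,
               preserve_range=True, mode="constant")
    if was_bool:
        return out > 0.5
    return out.astype(raster.dtype) if raster.dtype.kind in "ui" else out
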