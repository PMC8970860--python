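"""Forward renderer for synthetic nine-gaze eye scenes with full ground truth.

Scenes contain two schematic eyes on a dark background: each eyeball is a
mid-gray disk (the modeled sclera), the limbus is a darker disk displaced from
the eyeball center by the gaze offset, and the primary gaze additionally
carries one near-white specular reflex blob per eye.  The sclera disk radius
is 2.5x the limbus radius by construction.  Every scene comes with exact
binary masks and the generating parameters, so downstream stages can be
tested against known geometry.

Gaze labels form a fixed vocabulary (viewer/image directions, x rightward,
y downward): ``up_left, up, up_right, left, primary, right, down_left, down,
down_right``.  "left eye" / "right eye" mean the image-left and image-right
eye throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import InvalidGeometryError, SpecificationError
from .transforms import SimilarityTransform, apply_transform

__all__ = [
    "GAZE_LABELS", "GAZE_DIRECTIONS", "SCLERA_LIMBUS_RATIO",
    "EyeParams", "RenderOptions", "JitterSpec", "SceneGroundTruth",
    "SyntheticScene", "make_eye_scene", "make_nine_gaze_set",
    "simulate_palsy_preset", "default_subject", "save_scene_set",
    "load_scene_set",
]

GAZE_LABELS = ("up_left", "up", "up_right", "left", "primary", "right",
               "down_left", "down", "down_right")

_D = 1.0 / math.sqrt(2.0)
#: Unit direction of each gaze in image coordinates (x right, y down).
GAZE_DIRECTIONS = {
    "primary": (0.0, 0.0),
    "up": (0.0, -1.0), "down": (0.0, 1.0),
    "left": (-1.0, 0.0), "right": (1.0, 0.0),
    "up_left": (-_D, -_D), "up_right": (_D, -_D),
    "down_left": (-_D, _D), "down_right": (_D, _D),
}

#: Adult sclera-to-limbus radius ratio used by the eyeball model.
SCLERA_LIMBUS_RATIO = 2.5

EYES = ("left", "right")


@dataclass(frozen=True)
class EyeParams:
    """Geometry of one eye in one gaze, in primary-frame pixel coordinates."""

    limbus_radius_px: float
    sclera_center: tuple[float, float]
    gaze_offset: tuple[float, float] = (0.0, 0.0)
    reflex_point: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.limbus_radius_px > 0:
            raise InvalidGeometryError(
                f"limbus_radius_px must be positive, got {self.limbus_radius_px}")
        object.__setattr__(self, "sclera_center",
                           tuple(float(v) for v in self.sclera_center))
        object.__setattr__(self, "gaze_offset",
                           tuple(float(v) for v in self.gaze_offset))
        if self.reflex_point is not None:
            object.__setattr__(self, "reflex_point",
                               tuple(float(v) for v in self.reflex_point))
        # the limbus disk must stay inside the eyeball disk
        if math.hypot(*self.gaze_offset) > self.sclera_radius_px - self.limbus_radius_px + 1e-9:
            raise InvalidGeometryError(
                f"gaze offset {self.gaze_offset} pushes the limbus outside the "
                f"eyeball (|offset| must be <= {self.sclera_radius_px - self.limbus_radius_px:.2f})")

    @property
    def sclera_radius_px(self) -> float:
        return SCLERA_LIMBUS_RATIO * self.limbus_radius_px

    @property
    def limbus_center(self) -> tuple[float, float]:
        cx, cy = self.sclera_center
        dx, dy = self.gaze_offset
        return (cx + dx, cy + dy)

    def to_dict(self) -> dict:
        return {
            "limbus_radius_px": self.limbus_radius_px,
            "sclera_center": list(self.sclera_center),
            "gaze_offset": list(self.gaze_offset),
            "reflex_point": None if self.reflex_point is None else list(self.reflex_point),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EyeParams":
        return cls(limbus_radius_px=d["limbus_radius_px"],
                   sclera_center=tuple(d["sclera_center"]),
                   gaze_offset=tuple(d["gaze_offset"]),
                   reflex_point=None if d.get("reflex_point") is None
                   else tuple(d["reflex_point"]))


@dataclass(frozen=True)
class RenderOptions:
    """Intensity levels (fractions of dynamic range) and shape details.

    Each rendered eye region is the sclera disk plus two wedge-shaped canthus
    corners at the horizontal extremes of the eyeball.  The corners emulate
    the pointed inner/outer commissures of a real palpebral fissure: they
    give the innermost-point landmark a rotation-covariant, subpixel-stable
    anchor, which a perfectly circular disk cannot provide (its extreme-x
    point is invariant under rotation about the disk center).  Set
    ``canthus_protrude_px=0`` for plain disks.
    """

    background: float = 0.1
    sclera_level: float = 0.75
    limbus_level: float = 0.35
    reflex_level: float = 0.98
    reflex_radius_px: float = 2.0
    canthus_protrude_px: float = 6.0
    canthus_half_height_px: float = 14.0
    canthus_inset_px: float = 8.0


@dataclass(frozen=True)
class JitterSpec:
    """Ranges for random camera jitter applied to non-primary gaze frames."""

    scale: tuple[float, float] = (0.9, 1.1)
    rotation_deg: tuple[float, float] = (-10.0, 10.0)
    translation_px: tuple[float, float] = (-20.0, 20.0)

    def sample(self, rng: np.random.Generator,
               pivot: tuple[float, float]) -> SimilarityTransform:
        return SimilarityTransform(
            scale=float(rng.uniform(*self.scale)),
            rotation_deg=float(rng.uniform(*self.rotation_deg)),
            translation=(float(rng.uniform(*self.translation_px)),
                         float(rng.uniform(*self.translation_px))),
            pivot=pivot,
        )


@dataclass
class SceneGroundTruth:
    """Exact generating parameters for a nine-gaze scene set."""

    eyes: dict[str, dict[str, EyeParams]]  # gaze -> eye -> params (primary frame)
    jitter: dict[str, SimilarityTransform]  # gaze -> camera jitter
    image_shape: tuple[int, int]  # (height, width)

    def __post_init__(self) -> None:
        missing = [g for g in GAZE_LABELS if g not in self.eyes]
        if missing:
            raise SpecificationError(f"ground truth missing gazes: {missing}")
        if not self.jitter.get("primary", SimilarityTransform()).is_identity:
            raise InvalidGeometryError("primary gaze must have identity jitter")

    def distance_truth(self, gaze: str, eye: str) -> float:
        """True primary-frame distance from the limbus center to the reflex."""
        reflex = self.eyes["primary"][eye].reflex_point
        lc = self.eyes[gaze][eye].limbus_center
        return math.hypot(lc[0] - reflex[0], lc[1] - reflex[1])

    def to_dict(self) -> dict:
        return {
            "image_shape": list(self.image_shape),
            "eyes": {g: {e: p.to_dict() for e, p in d.items()}
                     for g, d in self.eyes.items()},
            "jitter": {g: t.to_dict() for g, t in self.jitter.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneGroundTruth":
        return cls(
            eyes={g: {e: EyeParams.from_dict(p) for e, p in dd.items()}
                  for g, dd in d["eyes"].items()},
            jitter={g: SimilarityTransform.from_dict(t)
                    for g, t in d["jitter"].items()},
            image_shape=tuple(d["image_shape"]),
        )


@dataclass
class SyntheticScene:
    """One rendered gaze frame plus its exact masks and generating params."""

    gaze: str
    image: np.ndarray  # float64 in [0, 1], shape (H, W)
    sclera_mask: np.ndarray  # bool, eyeball disks (limbus included)
    limbus_mask: np.ndarray  # bool, limbus disks
    truth: dict[str, EyeParams]  # eye -> params (pre-jitter, primary frame)
    jitter: SimilarityTransform = field(default_factory=SimilarityTransform)


def _disk_mask(shape: tuple[int, int], center: tuple[float, float],
               radius: float) -> np.ndarray:
    """Rasterize a disk by the center-of-pixel inclusion test."""
    h, w = shape
    cx, cy = center
    ys = np.arange(h, dtype=float)[:, None]
    xs = np.arange(w, dtype=float)[None, :]
    return (xs - cx) ** 2 + (ys - cy) ** 2 <= radius ** 2


def _triangle_mask(shape: tuple[int, int], verts: np.ndarray) -> np.ndarray:
    """Rasterize a triangle by half-plane center-of-pixel tests."""
    h, w = shape
    ys = np.arange(h, dtype=float)[:, None]
    xs = np.arange(w, dtype=float)[None, :]
    mask = np.ones(shape, dtype=bool)
    v = np.asarray(verts, dtype=float)
    # orient consistently so all edge cross-products share a sign
    e1, e2 = v[1] - v[0], v[2] - v[0]
    area2 = e1[0] * e2[1] - e1[1] * e2[0]
    if area2 < 0:
        v = v[::-1]
    for i in range(3):
        a, b = v[i], v[(i + 1) % 3]
        mask &= (b[0] - a[0]) * (ys - a[1]) - (b[1] - a[1]) * (xs - a[0]) >= 0
    return mask


def _eye_region_mask(shape: tuple[int, int], eye: EyeParams,
                     opts: RenderOptions) -> np.ndarray:
    """Eyeball disk plus two canthal wedge corners on the horizontal axis."""
    region = _disk_mask(shape, eye.sclera_center, eye.sclera_radius_px)
    if opts.canthus_protrude_px > 0:
        cx, cy = eye.sclera_center
        R = eye.sclera_radius_px
        hh = opts.canthus_half_height_px
        for sign in (-1.0, 1.0):
            tip = (cx + sign * (R + opts.canthus_protrude_px), cy)
            bx = cx + sign * (R - opts.canthus_inset_px)
            region |= _triangle_mask(shape, [tip, (bx, cy - hh), (bx, cy + hh)])
    return region


def _eye_extent(eye: EyeParams, opts: RenderOptions) -> float:
    return eye.sclera_radius_px + max(opts.canthus_protrude_px, 0.0)


def _check_scene_geometry(eyes, image_shape, opts: RenderOptions) -> None:
    h, w = image_shape
    for name, eye in zip(EYES, eyes):
        cx, cy = eye.sclera_center
        rx = _eye_extent(eye, opts)
        ry = eye.sclera_radius_px
        if cx - rx < 0 or cy - ry < 0 or cx + rx > w - 1 or cy + ry > h - 1:
            raise InvalidGeometryError(
                f"{name} eye region (center {eye.sclera_center}, extent "
                f"{rx:.1f}) exceeds image bounds {image_shape}")
    (l, r) = eyes
    gap = math.hypot(l.sclera_center[0] - r.sclera_center[0],
                     l.sclera_center[1] - r.sclera_center[1])
    if gap <= _eye_extent(l, opts) + _eye_extent(r, opts):
        raise InvalidGeometryError("eye regions overlap")


def make_eye_scene(eyes: tuple[EyeParams, EyeParams],
                   image_shape: tuple[int, int],
                   render_options: RenderOptions | None = None,
                   gaze: str = "primary",
                   seed: int | None = None) -> SyntheticScene:
    """Render one two-eye scene; reflexes are drawn where ``reflex_point`` is set.

    Rendering is fully deterministic; ``seed`` is accepted for interface
    symmetry but unused.
    """
    del seed
    opts = render_options or RenderOptions()
    if gaze not in GAZE_LABELS:
        raise SpecificationError(f"unknown gaze label {gaze!r}")
    _check_scene_geometry(eyes, image_shape, opts)

    img = np.full(image_shape, opts.background, dtype=np.float64)
    sclera_mask = np.zeros(image_shape, dtype=bool)
    limbus_mask = np.zeros(image_shape, dtype=bool)
    for eye in eyes:
        sd = _eye_region_mask(image_shape, eye, opts)
        ld = _disk_mask(image_shape, eye.limbus_center, eye.limbus_radius_px)
        img[sd] = opts.sclera_level
        img[ld] = opts.limbus_level
        sclera_mask |= sd
        limbus_mask |= ld
        if eye.reflex_point is not None:
            rd = _disk_mask(image_shape, eye.reflex_point, opts.reflex_radius_px)
            img[rd] = opts.reflex_level
    return SyntheticScene(gaze=gaze, image=img, sclera_mask=sclera_mask,
                          limbus_mask=limbus_mask,
                          truth={e: p for e, p in zip(EYES, eyes)})


def _normalize_jitter(jitter_spec, image_shape, seed) -> dict[str, SimilarityTransform]:
    pivot = ((image_shape[1] - 1) / 2.0, (image_shape[0] - 1) / 2.0)
    jitter = {g: SimilarityTransform() for g in GAZE_LABELS}
    if jitter_spec is None:
        return jitter
    if isinstance(jitter_spec, JitterSpec):
        rng = np.random.default_rng(seed)
        for g in GAZE_LABELS:
            if g != "primary":
                jitter[g] = jitter_spec.sample(rng, pivot)
        return jitter
    if isinstance(jitter_spec, dict):
        for g, t in jitter_spec.items():
            if g not in GAZE_LABELS:
                raise SpecificationError(f"unknown gaze label {g!r} in jitter spec")
            if g == "primary" and not t.is_identity:
                raise InvalidGeometryError("primary gaze jitter must be identity")
            jitter[g] = t
        return jitter
    raise SpecificationError(f"unsupported jitter spec {jitter_spec!r}")


def make_nine_gaze_set(subject: tuple[EyeParams, EyeParams],
                       deviation_spec: dict[str, dict[str, tuple[float, float]]],
                       jitter_spec=None,
                       seed: int | None = None,
                       image_shape: tuple[int, int] = (512, 512),
                       render_options: RenderOptions | None = None,
                       ) -> tuple[dict[str, SyntheticScene], SceneGroundTruth]:
    """Render the full nine-gaze set for one subject.

    ``subject`` gives the two baseline (primary-gaze) eyes; ``deviation_spec``
    maps every gaze label to per-eye limbus offsets from the eyeball center.
    ``jitter_spec`` is ``None`` (no jitter), a dict of per-gaze transforms, or
    a :class:`JitterSpec` sampled with ``seed``.  Non-primary frames are
    rendered in the primary frame and then warped by their jitter transform
    (bilinear for the image, nearest for masks).  Ground truth stays in the
    primary frame.
    """
    missing = [g for g in GAZE_LABELS if g not in deviation_spec]
    if missing:
        raise SpecificationError(f"deviation spec missing gazes: {missing}")
    for g, per_eye in deviation_spec.items():
        if g not in GAZE_LABELS:
            raise SpecificationError(f"unknown gaze label {g!r} in deviation spec")
        for e in EYES:
            if e not in per_eye:
                raise SpecificationError(f"deviation spec for {g!r} missing eye {e!r}")

    jitter = _normalize_jitter(jitter_spec, image_shape, seed)
    left0, right0 = subject
    scenes: dict[str, SyntheticScene] = {}
    truth_eyes: dict[str, dict[str, EyeParams]] = {}
    for g in GAZE_LABELS:
        eyes = []
        for base, e in zip((left0, right0), EYES):
            reflex = base.reflex_point if g == "primary" else None
            eyes.append(replace(base, gaze_offset=tuple(deviation_spec[g][e]),
                                reflex_point=reflex))
        scene = make_eye_scene(tuple(eyes), image_shape, render_options, gaze=g)
        T = jitter[g]
        if not T.is_identity:
            scene.image = apply_transform(scene.image, T, "bilinear")
            scene.sclera_mask = apply_transform(scene.sclera_mask, T, "nearest")
            scene.limbus_mask = apply_transform(scene.limbus_mask, T, "nearest")
            scene.jitter = T
        scenes[g] = scene
        truth_eyes[g] = {e: p for e, p in zip(EYES, eyes)}
    truth = SceneGroundTruth(eyes=truth_eyes, jitter=jitter,
                             image_shape=tuple(image_shape))
    return scenes, truth


# -- palsy presets ---------------------------------------------------------

_PRESET_DEFAULT_RATIO = {"CN4_bilateral": 0.9, "CN6_left": 0.3}


def simulate_palsy_preset(name: str, excursion_px: float = 32.0,
                          ratio: float | None = None,
                          ) -> dict[str, dict[str, tuple[float, float]]]:
    """Build a deviation spec emulating a cranial-nerve palsy.

    ``CN6_left`` scales the image-left eye's outward (leftward) excursions by
    ``ratio`` while inward excursions stay matched with the right eye.
    ``CN4_bilateral`` scales each eye's downward-inward excursion by ``ratio``
    relative to its downward-outward excursion ("inward" is toward the facial
    midline: +x for the image-left eye, -x for the image-right eye).
    """
    if name not in _PRESET_DEFAULT_RATIO:
        raise SpecificationError(
            f"unknown palsy preset {name!r}; expected one of "
            f"{sorted(_PRESET_DEFAULT_RATIO)}")
    if ratio is None:
        ratio = _PRESET_DEFAULT_RATIO[name]
    if not 0 < ratio <= 1:
        raise SpecificationError(f"ratio must be in (0, 1], got {ratio}")

    spec: dict[str, dict[str, tuple[float, float]]] = {}
    for g in GAZE_LABELS:
        dx, dy = GAZE_DIRECTIONS[g]
        base = (excursion_px * dx, excursion_px * dy)
        per_eye = {"left": base, "right": base}
        if name == "CN6_left" and dx < 0:
            # image-left eye abduction (leftward) impaired
            per_eye["left"] = (ratio * base[0], base[1])
        elif name == "CN4_bilateral":
            if g == "down_right":  # down + inward for the image-left eye
                per_eye["left"] = (ratio * base[0], ratio * base[1])
            if g == "down_left":  # down + inward for the image-right eye
                per_eye["right"] = (ratio * base[0], ratio * base[1])
        spec[g] = per_eye
    return spec


def default_subject(image_shape: tuple[int, int] = (512, 512),
                    limbus_radius_px: float | None = None,
                    ) -> tuple[EyeParams, EyeParams]:
    """Two eyes on a horizontal midline, reflexes at the primary limbus centers.

    The limbus radius defaults to 24 px at a 512-px image scale and shrinks
    proportionally for smaller frames.
    """
    h, w = image_shape
    if limbus_radius_px is None:
        limbus_radius_px = round(24.0 * min(h, w) / 512.0)
    cy = h // 2
    lx, rx = round(0.27 * w), round(0.73 * w)
    left = EyeParams(limbus_radius_px, (lx, cy), (0.0, 0.0), reflex_point=(lx, cy))
    right = EyeParams(limbus_radius_px, (rx, cy), (0.0, 0.0), reflex_point=(rx, cy))
    return left, right


# -- disk I/O --------------------------------------------------------------

def _write_png(path: Path, array: np.ndarray) -> None:
    if array.dtype == bool:
        data = (array.astype(np.uint8)) * 255
    else:
        data = np.clip(np.round(array * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(data).save(path)


def save_scene_set(scenes: dict[str, SyntheticScene], truth: SceneGroundTruth,
                   out_dir) -> None:
    """Write ``<gaze>.png`` + mask PNGs + a ``truth.json`` sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for g, scene in scenes.items():
        _write_png(out / f"{g}.png", scene.image)
        _write_png(out / f"{g}.sclera.png", scene.sclera_mask)
        _write_png(out / f"{g}.limbus.png", scene.limbus_mask)
    (out / "truth.json").write_text(json.dumps(truth.to_dict(), indent=2,
                                               sort_keys=True))


def load_scene_set(in_dir) -> tuple[dict[str, dict[str, np.ndarray]],
                                    SceneGroundTruth | None]:
    """Read a scene directory back as arrays; truth is optional."""
    src = Path(in_dir)
    out: dict[str, dict[str, np.ndarray]] = {}
    for g in GAZE_LABELS:
        img_path = src / f"{g}.png"
        if not img_path.exists():
            continue
        entry = {"image": np.asarray(Image.open(img_path).convert("L"),
                                     dtype=np.float64) / 255.0}
        for target in ("sclera", "limbus"):
            mpath = src / f"{g}.{target}.png"
            if mpath.exists():
                entry[f"{target}_mask"] = (
                    np.asarray(Image.open(mpath).convert("L")) > 0)
        out[g] = entry
    truth_path = src / "truth.json"
    truth = (SceneGroundTruth.from_dict(json.loads(truth_path.read_text()))
             if truth_path.exists() else None)
    return out, truth
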