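"""Full nine-gaze deviation measurement pipeline and reporting.

The pipeline (a) obtains sclera/limbus masks per gaze (provided or from a
pluggable segmenter), (b) measures the primary reference line and registers
the eight eccentric frames onto it, (c) models each eye's primary limbus and
sclera circles and locates the corneal reflex — the reflex is taken from the
primary gaze only and reused as the fixed anchor for every other gaze —
(d) recovers per-gaze limbus centers and their pixel distances to the anchor,
and (e) evaluates declarative movement-percentage comparisons.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .config import ComparisonRow, PipelineConfig
from .errors import (InputValidationError, SpecificationError,
                     StrabmetricError, UndefinedRatioError)
from .geometry import (Circle, EyeModel, detect_corneal_reflex, fit_ellipse,
                       min_enclosing_circle, model_sclera,
                       recover_limbus_center)
from .registration import (ReferenceLine, innermost_points, reference_line,
                           register_gaze)
from .segmentation import Segmenter, ThresholdSegmenter, split_eyes
from .synthetic import EYES, GAZE_LABELS
from .transforms import SimilarityTransform

__all__ = [
    "GazeInput", "DeviationMeasurement", "MovementReport",
    "measure_deviation", "movement_ratio", "compare_excursions",
    "run_pipeline", "render_overlay",
]

Point2D = tuple[float, float]


@dataclass
class GazeInput:
    """One gaze frame: raster image plus optional precomputed masks."""

    image: np.ndarray
    sclera_mask: np.ndarray | None = None
    limbus_mask: np.ndarray | None = None


@dataclass(frozen=True)
class DeviationMeasurement:
    gaze: str
    eye: str
    limbus_center: Point2D  # primary frame
    distance_px: float  # to the same eye's primary reflex

    def to_dict(self) -> dict:
        return {"gaze": self.gaze, "eye": self.eye,
                "limbus_center": [self.limbus_center[0], self.limbus_center[1]],
                "distance_px": self.distance_px,
                "distance_px_rounded": int(round(self.distance_px))}


@dataclass
class MovementReport:
    measurements: list[DeviationMeasurement]
    ratios: dict[str, float]
    eye_models: dict[str, EyeModel]  # eye -> primary-gaze model
    transforms: dict[str, SimilarityTransform] = field(default_factory=dict)

    def distance(self, gaze: str, eye: str) -> float:
        for m in self.measurements:
            if m.gaze == gaze and m.eye == eye:
                return m.distance_px
        raise SpecificationError(f"no measurement for gaze={gaze!r}, eye={eye!r}")

    def to_dict(self) -> dict:
        return {
            "measurements": [m.to_dict() for m in self.measurements],
            "ratios": self.ratios,
            "eye_models": {e: m.to_dict() for e, m in self.eye_models.items()},
            "transforms": {g: t.to_dict() for g, t in self.transforms.items()},
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path=None) -> str:
        """Distances per (gaze, eye) plus the ratio rows, Table-style."""
        lines = ["section,label,eye,gaze,distance_px,percentage"]
        for m in self.measurements:
            lines.append(f"distance,,{m.eye},{m.gaze},"
                         f"{int(round(m.distance_px))},")
        for label, pct in self.ratios.items():
            lines.append(f"ratio,{label},,,,{pct}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def measure_deviation(limbus_center: Point2D, reflex: Point2D) -> float:
    """Euclidean pixel distance between a limbus center and a reflex point."""
    dx = limbus_center[0] - reflex[0]
    dy = limbus_center[1] - reflex[1]
    d = math.hypot(dx, dy)
    if not math.isfinite(d):
        raise SpecificationError("non-finite point coordinates")
    return d


def movement_ratio(numerator_px: float, denominator_px: float,
                   ndigits: int | None = 1) -> float:
    """Movement percentage 100 x numerator/denominator, rounded for reporting.

    Pass ``ndigits=None`` for the unrounded value.
    """
    if denominator_px <= 0:
        raise UndefinedRatioError(
            f"denominator must be positive, got {denominator_px}")
    pct = 100.0 * numerator_px / denominator_px
    return pct if ndigits is None else round(pct, ndigits)


def compare_excursions(report: MovementReport,
                       rows: list[ComparisonRow] | tuple[ComparisonRow, ...],
                       ndigits: int | None = 1) -> dict[str, float]:
    """Evaluate movement-percentage rows against a report's distances."""
    out: dict[str, float] = {}
    for row in rows:
        for gaze, eye in (row.numerator, row.denominator):
            if gaze not in GAZE_LABELS:
                raise SpecificationError(f"unknown gaze {gaze!r} in comparison "
                                         f"{row.label!r}")
            if eye not in EYES:
                raise SpecificationError(f"unknown eye {eye!r} in comparison "
                                         f"{row.label!r}")
        num = report.distance(*row.numerator)
        den = report.distance(*row.denominator)
        out[row.label] = movement_ratio(num, den, ndigits=ndigits)
    return out


def _stage(gaze: str, eye: str | None = None):
    where = f"gaze {gaze!r}" + ("" if eye is None else f", eye {eye!r}")
    return where


def run_pipeline(nine_gaze_inputs: dict, config: PipelineConfig | None = None,
                 segmenter: Segmenter | None = None) -> MovementReport:
    """Measure ocular deviation over a full nine-gaze input set.

    ``nine_gaze_inputs`` maps every gaze label to an object with ``image``
    and optional ``sclera_mask`` / ``limbus_mask`` attributes (or an
    equivalent dict).  Missing masks are produced by ``segmenter`` (default:
    :class:`ThresholdSegmenter`).  Deterministic for fixed inputs and config.
    """
    cfg = config or PipelineConfig()
    seg = segmenter or ThresholdSegmenter(min_area=cfg.min_component_area)

    missing = [g for g in GAZE_LABELS if g not in nine_gaze_inputs]
    if missing:
        raise InputValidationError(f"missing gaze images: {missing}")

    def _get(entry, key):
        if isinstance(entry, dict):
            return entry.get(key)
        return getattr(entry, key, None)

    # 1. masks per gaze
    frames: dict[str, dict[str, np.ndarray]] = {}
    for g in GAZE_LABELS:
        entry = nine_gaze_inputs[g]
        image = _get(entry, "image")
        if image is None:
            raise InputValidationError(f"no image for {_stage(g)}")
        sclera = _get(entry, "sclera_mask")
        limbus = _get(entry, "limbus_mask")
        try:
            if sclera is None:
                sclera = seg.segment(image, "sclera")
            if limbus is None:
                limbus = seg.segment(image, "limbus")
        except StrabmetricError as exc:
            raise type(exc)(f"segmentation failed at {_stage(g)}: {exc}") from exc
        frames[g] = {"image": np.asarray(image),
                     "sclera": np.asarray(sclera, dtype=bool),
                     "limbus": np.asarray(limbus, dtype=bool)}

    # 2. primary reference line
    try:
        left_s, right_s = split_eyes(frames["primary"]["sclera"],
                                     min_area=cfg.min_component_area)
        p_left, p_right = innermost_points(left_s, right_s)
        primary_line: ReferenceLine = reference_line(p_left, p_right)
    except StrabmetricError as exc:
        raise type(exc)(f"reference line failed at {_stage('primary')}: {exc}") from exc

    # 3. register eccentric gazes onto the primary frame
    registered: dict[str, dict[str, np.ndarray]] = {
        "primary": frames["primary"]}
    transforms: dict[str, SimilarityTransform] = {
        "primary": SimilarityTransform()}
    for g in GAZE_LABELS:
        if g == "primary":
            continue
        try:
            reg = register_gaze(frames[g]["image"], frames[g]["sclera"],
                                primary_line,
                                extra_masks={"limbus": frames[g]["limbus"]},
                                min_area=cfg.min_component_area)
        except StrabmetricError as exc:
            raise type(exc)(f"registration failed at {_stage(g)}: {exc}") from exc
        registered[g] = {"image": reg.image, "sclera": reg.sclera_mask,
                         "limbus": reg.masks["limbus"]}
        transforms[g] = reg.transform

    # 4. primary-gaze eye models (limbus circle, sclera circle, reflex)
    eye_models: dict[str, EyeModel] = {}
    prim = registered["primary"]
    try:
        lim_l, lim_r = split_eyes(prim["limbus"], min_area=cfg.min_component_area)
        scl_l, scl_r = split_eyes(prim["sclera"], min_area=cfg.min_component_area)
    except StrabmetricError as exc:
        raise type(exc)(f"eye split failed at {_stage('primary')}: {exc}") from exc
    for eye, lim_mask, scl_mask in (("left", lim_l, scl_l),
                                    ("right", lim_r, scl_r)):
        try:
            limbus = min_enclosing_circle(lim_mask)
            sclera = model_sclera(scl_mask, limbus.radius,
                                  ratio=cfg.sclera_limbus_ratio)
            reflex = detect_corneal_reflex(prim["image"], lim_mask,
                                           rel_threshold=cfg.reflex_threshold_frac,
                                           abs_floor=cfg.reflex_abs_floor)
        except StrabmetricError as exc:
            raise type(exc)(f"primary modeling failed at "
                            f"{_stage('primary', eye)}: {exc}") from exc
        eye_models[eye] = EyeModel(limbus=limbus, sclera=sclera, reflex=reflex)

    # 5. eccentric limbus recovery and distances
    measurements: list[DeviationMeasurement] = []
    for g in GAZE_LABELS:
        if g == "primary":
            continue
        try:
            lim_l, lim_r = split_eyes(registered[g]["limbus"],
                                      min_area=cfg.min_component_area)
            scl_l, scl_r = split_eyes(registered[g]["sclera"],
                                      min_area=cfg.min_component_area)
        except StrabmetricError as exc:
            raise type(exc)(f"eye split failed at {_stage(g)}: {exc}") from exc
        for eye, lim_mask, scl_mask in (("left", lim_l, scl_l),
                                        ("right", lim_r, scl_r)):
            model = eye_models[eye]
            try:
                fit = fit_ellipse(lim_mask)
                sclera_g = model_sclera(scl_mask, model.limbus.radius,
                                        ratio=cfg.sclera_limbus_ratio)
                limbus_g = recover_limbus_center(
                    fit, model.limbus.radius, sclera_g,
                    circularity_threshold=cfg.circularity_threshold)
                dist = measure_deviation(limbus_g.center, model.reflex)
            except StrabmetricError as exc:
                raise type(exc)(f"measurement failed at {_stage(g, eye)}: "
                                f"{exc}") from exc
            measurements.append(DeviationMeasurement(
                gaze=g, eye=eye, limbus_center=limbus_g.center,
                distance_px=dist))

    if cfg.anatomical_laterality:
        # anatomical left = image-right (the subject faces the camera)
        flip = {"left": "right", "right": "left"}
        measurements = [DeviationMeasurement(m.gaze, flip[m.eye],
                                             m.limbus_center, m.distance_px)
                        for m in measurements]
        eye_models = {flip[e]: m for e, m in eye_models.items()}

    report = MovementReport(measurements=measurements, ratios={},
                            eye_models=eye_models, transforms=transforms)
    report.ratios = compare_excursions(report, cfg.comparisons)
    return report


# -- overlay rendering -----------------------------------------------------

def render_overlay(image: np.ndarray, eye_models: dict[str, EyeModel],
                   measurements: list[DeviationMeasurement],
                   out_path=None) -> tuple[np.ndarray, list[tuple]]:
    """Draw the measurement geometry over a (primary-frame) image.

    Purely presentational: draws limbus circles (red), sclera circles
    (yellow), reflex cross-hairs, center-to-reflex segments, and distance
    labels.  Returns the annotated RGB array and a log of drawing calls
    (op name + geometry) so tests can assert counts without pixel checks.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        if img.max() > 1.0:
            img = img / 255.0
        rgb = np.stack([img] * 3, axis=-1)
    else:
        rgb = img if img.max() <= 1.0 else img / 255.0
    pil = Image.fromarray(np.clip(np.round(rgb * 255), 0, 255).astype(np.uint8))
    draw = ImageDraw.Draw(pil)
    log: list[tuple] = []

    def circle(c: Circle, color):
        x, y = c.center
        r = c.radius
        draw.ellipse([x - r, y - r, x + r, y + r], outline=color, width=2)
        log.append(("circle", c.center, c.radius, color))

    def cross(p: Point2D, color, size=6):
        x, y = p
        draw.line([x - size, y, x + size, y], fill=color, width=1)
        draw.line([x, y - size, x, y + size], fill=color, width=1)
        log.append(("cross", tuple(p), color))

    for eye, model in eye_models.items():
        circle(model.limbus, (255, 0, 0))
        circle(model.sclera, (255, 255, 0))
        if model.reflex is not None:
            cross(model.reflex, (0, 255, 255))

    for m in measurements:
        model = eye_models.get(m.eye)
        if model is None or model.reflex is None:
            continue
        draw.line([m.limbus_center[0], m.limbus_center[1],
                   model.reflex[0], model.reflex[1]], fill=(0, 255, 0), width=1)
        log.append(("segment", m.limbus_center, tuple(model.reflex)))
        lx = (m.limbus_center[0] + model.reflex[0]) / 2.0 + 4
        ly = (m.limbus_center[1] + model.reflex[1]) / 2.0
        text = f"{int(round(m.distance_px))}"
        draw.text((lx, ly), text, fill=(0, 255, 0))
        log.append(("label", text))

    out = np.asarray(pil)
    if out_path is not None:
        pil.save(out_path)
    return out, log
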