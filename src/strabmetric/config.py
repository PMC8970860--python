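"""Pipeline configuration, loadable from YAML/JSON dicts."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .errors import SpecificationError

__all__ = ["ComparisonRow", "PipelineConfig", "DEFAULT_COMPARISONS"]


@dataclass(frozen=True)
class ComparisonRow:
    """One movement-percentage row: 100 x numerator / denominator distances.

    ``numerator`` and ``denominator`` are ``(gaze, eye)`` references into the
    measured distances, which supports both within-eye comparisons (same eye,
    two gazes) and between-eye comparisons (same direction, two eyes).
    """

    label: str
    numerator: tuple[str, str]
    denominator: tuple[str, str]

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonRow":
        try:
            return cls(label=str(d["label"]),
                       numerator=(d["numerator"][0], d["numerator"][1]),
                       denominator=(d["denominator"][0], d["denominator"][1]))
        except (KeyError, IndexError, TypeError) as exc:
            raise SpecificationError(f"malformed comparison row: {d!r}") from exc

    def to_dict(self) -> dict:
        return {"label": self.label, "numerator": list(self.numerator),
                "denominator": list(self.denominator)}


#: Default report rows: left/right excursion symmetry on the four cardinals.
DEFAULT_COMPARISONS = (
    ComparisonRow("left_vs_right_up", ("up", "left"), ("up", "right")),
    ComparisonRow("left_vs_right_down", ("down", "left"), ("down", "right")),
    ComparisonRow("outward_left_vs_right", ("left", "left"), ("right", "right")),
    ComparisonRow("inward_left_vs_right", ("right", "left"), ("left", "right")),
)


@dataclass(frozen=True)
class PipelineConfig:
    reflex_threshold_frac: float = 0.9
    reflex_abs_floor: float = 0.8
    circularity_threshold: float = 0.95
    sclera_limbus_ratio: float = 2.5
    min_component_area: int = 40
    anatomical_laterality: bool = False
    dice_variant: str = "standard"
    comparisons: tuple[ComparisonRow, ...] = DEFAULT_COMPARISONS

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        rows = d.pop("comparisons", None)
        known = {f for f in cls.__dataclass_fields__ if f != "comparisons"}
        unknown = set(d) - known
        if unknown:
            raise SpecificationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d) if rows is None else cls(
            **d, comparisons=tuple(ComparisonRow.from_dict(r) for r in rows))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["comparisons"] = [r.to_dict() for r in self.comparisons]
        return d
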