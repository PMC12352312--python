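"""Shared domain types and box geometry used by every pipeline stage.

Coordinate convention: 0-based, half-open pixel boxes
``[x_min, x_max) x [y_min, y_max)``, so that ``area = (x_max - x_min) *
(y_max - y_min)`` is exact and boxes map directly onto array slices.
Fractional coordinates are allowed (detectors emit sub-pixel boxes).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from PIL import Image


class ComponentClass(str, Enum):
    """The eleven components a specimen sheet may carry."""

    primary_specimen_label = "primary_specimen_label"
    data_outside_label = "data_outside_label"
    annotation_label = "annotation_label"
    stamp = "stamp"
    swing_tag = "swing_tag"
    number_outside_label = "number_outside_label"
    small_database_label = "small_database_label"
    medium_database_label = "medium_database_label"
    full_database_label = "full_database_label"
    colour_target = "colour_target"
    scale = "scale"


class FieldClass(str, Enum):
    """The twelve data fields of a primary specimen label."""

    family = "family"
    genus = "genus"
    species = "species"
    infraspecific_taxon = "infraspecific_taxon"
    authority = "authority"
    collector_number = "collector_number"
    collector = "collector"
    locality = "locality"
    geolocation = "geolocation"
    year = "year"
    month = "month"
    day = "day"


class LabelClass(str, Enum):
    """Writing type of a primary specimen label."""

    typewritten = "typewritten"
    printed = "printed"
    handwritten = "handwritten"
    combination = "combination"
    empty = "empty"


#: Fields whose text is cross-checked against taxonomic reference lists.
CROSS_CHECKED_FIELDS = (
    FieldClass.family,
    FieldClass.genus,
    FieldClass.species,
    FieldClass.authority,
)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel rectangle, half-open on both axes.

    Raises ``ValueError`` on construction if the box is degenerate
    (non-positive extent) or has negative coordinates.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )
        if self.x_min < 0 or self.y_min < 0:
            raise ValueError("box coordinates must be non-negative")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def translate(self, dx: float, dy: float) -> "BoundingBox":
        return BoundingBox(
            self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy
        )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0.0 when disjoint."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def crop(
    image: Image.Image,
    box: BoundingBox,
    pad_fraction: float = 0.0,
    sheet_id: str = "<unknown>",
) -> Image.Image:
    """Crop ``box`` out of ``image``, expanded by ``pad_fraction`` per side.

    The expansion is ``pad_fraction * width`` horizontally and
    ``pad_fraction * height`` vertically on each side, clipped to the image
    bounds. Raises ``ValueError`` (naming the sheet and box) when the box
    does not intersect the image at all.
    """
    w, h = image.size
    if box.x_min >= w or box.y_min >= h:
        raise ValueError(f"box {box.as_tuple()} lies outside sheet {sheet_id!r}")
    px = pad_fraction * box.width
    py = pad_fraction * box.height
    x0 = max(0, math.floor(box.x_min - px))
    y0 = max(0, math.floor(box.y_min - py))
    x1 = min(w, math.ceil(box.x_max + px))
    y1 = min(h, math.ceil(box.y_max + py))
    return image.crop((x0, y0, x1, y1))


@dataclass(frozen=True)
class DetectedComponent:
    component_class: ComponentClass
    box: BoundingBox
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass(frozen=True)
class FieldDetection:
    field_class: FieldClass
    box: BoundingBox
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass(frozen=True)
class TextCandidate:
    """One engine's reading of one field.

    ``formatted_text`` is the deterministic result of the field-formatting
    rules applied to ``raw_text`` (see :func:`sheetscribe.taxonmatch.normalize_field`).
    """

    field_class: FieldClass
    engine_id: str
    raw_text: str
    formatted_text: str


@dataclass(frozen=True)
class MatchResult:
    """Outcome of correcting one field against a reference list.

    ``score`` is 1.0 for an exact hit (``changed`` is False), in
    ``[threshold, 1)`` when a close reference name was substituted, and 0.0
    when nothing similar enough was found (``matched_name`` is None).
    """

    query: str
    matched_name: Optional[str]
    score: float
    changed: bool


@dataclass
class FieldRecord:
    """Per-field slot of a :class:`SpecimenRecord`."""

    chosen_text: str = ""
    engine_texts: dict[str, str] = field(default_factory=dict)
    llm_text: Optional[str] = None
    match_score: Optional[float] = None


@dataclass
class SpecimenRecord:
    """Full extraction result for one primary specimen label."""

    sheet_id: str
    label_class: LabelClass = LabelClass.printed
    fields: dict[FieldClass, FieldRecord] = field(default_factory=dict)
    chosen_engine: str = ""
    provenance: list[str] = field(default_factory=list)

    def note(self, message: str) -> None:
        self.provenance.append(message)

    def field_text(self, fc: FieldClass) -> Optional[str]:
        rec = self.fields.get(fc)
        if rec is None:
            return None
        return rec.chosen_text


def detections_to_jsonl(
    sheet_id: str,
    detections: Iterable[DetectedComponent | FieldDetection],
) -> str:
    """Serialize detections as JSON lines keyed by class-name strings."""
    lines = []
    for det in detections:
        cls = (
            det.component_class
            if isinstance(det, DetectedComponent)
            else det.field_class
        )
        lines.append(
            json.dumps(
                {
                    "sheet_id": sheet_id,
                    "class": cls.value,
                    "x_min": det.box.x_min,
                    "y_min": det.box.y_min,
                    "x_max": det.box.x_max,
                    "y_max": det.box.y_max,
                    "confidence": det.confidence,
                },
                sort_keys=False,
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
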