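"""Pluggable detectors and primary-label selection.

The pipeline is detector-agnostic: anything satisfying
:class:`DetectorInterface` can fill the sheet-component or label-field
slot. Production deployments plug in trained object-detection weights via
:class:`YoloDetector`; the test suite and synthetic runs use
:class:`OracleDetector`, which replays ground truth with optional box
jitter and drop-out so every downstream stage is exercised hermetically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np
from PIL import Image

from .core import (
    BoundingBox,
    ComponentClass,
    DetectedComponent,
    FieldClass,
    FieldDetection,
)


@runtime_checkable
class DetectorInterface(Protocol):
    """Contract: image -> list of (class name, box, confidence).

    ``vocabulary`` declares which class enum the detector emits
    (:class:`ComponentClass` or :class:`FieldClass`). ``sheet_id`` lets
    replay-style detectors look up their ground truth; real detectors
    ignore it.
    """

    vocabulary: type

    def detect(
        self, image: Image.Image, sheet_id: Optional[str] = None
    ) -> list[tuple[str, BoundingBox, float]]: ...


def _stable_rng(seed: int, sheet_id: Optional[str]) -> np.random.Generator:
    # str hash is salted per interpreter run; crc32 keeps replays reproducible
    salt = zlib.crc32((sheet_id or "").encode("utf-8"))
    return np.random.default_rng((seed + salt) % 2**31)


@dataclass
class OracleDetector:
    """Replays ground-truth boxes, optionally degraded.

    With ``jitter_px = 0`` and ``drop_rate = 0`` the output equals the
    ground truth exactly (confidence 1.0). Jitter shifts each box edge by a
    uniform offset in ``[-jitter_px, jitter_px]``; drops are Bernoulli per
    box. Degradation is deterministic in ``(seed, sheet_id)``.
    """

    ground_truth: dict[str, list[tuple[str, BoundingBox]]]
    vocabulary: type = ComponentClass
    jitter_px: float = 0.0
    drop_rate: float = 0.0
    seed: int = 0

    def detect(
        self, image: Image.Image, sheet_id: Optional[str] = None
    ) -> list[tuple[str, BoundingBox, float]]:
        truth = self.ground_truth.get(sheet_id or "", [])
        rng = _stable_rng(self.seed, sheet_id)
        out = []
        w, h = image.size
        for cls_name, box in truth:
            if self.drop_rate > 0 and rng.random() < self.drop_rate:
                continue
            if self.jitter_px > 0:
                d = rng.uniform(-self.jitter_px, self.jitter_px, size=4)
                x0 = min(max(0.0, box.x_min + d[0]), w - 1.0)
                y0 = min(max(0.0, box.y_min + d[1]), h - 1.0)
                box = BoundingBox(
                    x0,
                    y0,
                    max(x0 + 1.0, min(float(w), box.x_max + d[2])),
                    max(y0 + 1.0, min(float(h), box.y_max + d[3])),
                )
                conf = float(rng.uniform(0.5, 1.0))
            else:
                conf = 1.0
            out.append((cls_name, box, conf))
        return out


class YoloDetector:
    """Adapter for ultralytics YOLO weights (optional extra).

    Instantiating requires the ``ultralytics`` package and a weights file;
    neither ships with this package, keeping the build hermetic.
    """

    def __init__(self, weights_path: str, vocabulary: type = ComponentClass):
        try:
            from ultralytics import YOLO  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError(
                "the YOLO adapter requires the 'ultralytics' package"
            ) from exc
        self._model = YOLO(weights_path)  # pragma: no cover
        self.vocabulary = vocabulary  # pragma: no cover

    def detect(self, image, sheet_id=None):  # pragma: no cover - needs weights
        out = []
        for result in self._model(image, verbose=False):
            for b in result.boxes:
                cls_name = result.names[int(b.cls)]
                x0, y0, x1, y1 = (float(v) for v in b.xyxy[0])
                out.append((cls_name, BoundingBox(x0, y0, x1, y1), float(b.conf)))
        return out


def detect_components(
    image: Image.Image,
    detector: DetectorInterface,
    sheet_id: Optional[str] = None,
    min_confidence: float = 0.0,
) -> list[DetectedComponent]:
    """Run the sheet-component detector; classes outside the 11-component
    vocabulary raise, confidences below ``min_confidence`` are filtered."""
    raw = detector.detect(image, sheet_id)
    out = []
    for cls_name, box, conf in raw:
        if conf < min_confidence:
            continue
        out.append(DetectedComponent(ComponentClass(cls_name), box, conf))
    return out


def detect_fields(
    label_image: Image.Image,
    detector: DetectorInterface,
    sheet_id: Optional[str] = None,
    min_confidence: float = 0.0,
) -> list[FieldDetection]:
    """Run the label-field detector on a primary-label crop; detections are
    restricted to the 12 field classes. Duplicates pass through untouched —
    :func:`dedupe_fields` resolves them downstream."""
    raw = detector.detect(label_image, sheet_id)
    out = []
    for cls_name, box, conf in raw:
        if conf < min_confidence:
            continue
        out.append(FieldDetection(FieldClass(cls_name), box, conf))
    return out


def select_primary_labels(
    components: Sequence[DetectedComponent],
) -> list[DetectedComponent]:
    """All primary-specimen-label detections, best confidence first. Each is
    processed independently downstream (sheet_id suffixed ``#k``)."""
    labels = [
        c
        for c in components
        if c.component_class is ComponentClass.primary_specimen_label
    ]
    return sorted(labels, key=lambda c: -c.confidence)


def dedupe_fields(
    detections: Sequence[FieldDetection],
) -> tuple[dict[FieldClass, FieldDetection], list[str]]:
    """Keep at most one detection per field class: highest confidence wins;
    confidence ties go to the box earlier in reading order (smaller y_min,
    then smaller x_min). Returns (kept, provenance notes for discards)."""
    kept: dict[FieldClass, FieldDetection] = {}
    notes: list[str] = []

    def rank(d: FieldDetection) -> tuple:
        return (-d.confidence, d.box.y_min, d.box.x_min)

    for det in detections:
        cur = kept.get(det.field_class)
        if cur is None:
            kept[det.field_class] = det
        elif rank(det) < rank(cur):
            kept[det.field_class] = det
            notes.append(
                f"discarded duplicate {det.field_class.value} detection "
                f"(conf {cur.confidence:.3f})"
            )
        else:
            notes.append(
                f"discarded duplicate {det.field_class.value} detection "
                f"(conf {det.confidence:.3f})"
            )
    return kept, notes
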