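"""Text-recognition engines and per-field candidate collection.

The standard pipeline runs two engines over every detected field — an OCR
engine for typeset text and an HTR model for handwriting — and keeps both
readings; arbitration later decides which engine's outputs to trust.
Real Tesseract/TrOCR adapters are optional extras (system binary / model
download); :class:`FixtureEngine` replays ground-truth text through a
seeded noise model so the suite runs hermetically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Protocol, Sequence, runtime_checkable

import numpy as np
from PIL import Image

from .core import FieldClass, TextCandidate
from .synthdata import NoiseModel, corrupt_text
from .taxonmatch import normalize_field


@runtime_checkable
class RecognitionEngineInterface(Protocol):
    """Contract: image region -> raw text (possibly empty, never None)."""

    engine_id: str

    def recognize(
        self,
        image: Image.Image,
        sheet_id: Optional[str] = None,
        field_class: Optional[FieldClass] = None,
    ) -> str: ...


@dataclass
class FixtureEngine:
    """Replays ground-truth field text, optionally corrupted.

    ``ground_truth`` maps ``(sheet_id, field_class)`` to the text printed
    on the label. With a zero-rate noise model the text is returned
    verbatim; otherwise it is passed through the character-level noise
    model, deterministically per (seed, sheet_id, field).
    """

    engine_id: str
    ground_truth: dict[tuple[str, FieldClass], str]
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def recognize(
        self,
        image: Image.Image,
        sheet_id: Optional[str] = None,
        field_class: Optional[FieldClass] = None,
    ) -> str:
        text = self.ground_truth.get((sheet_id or "", field_class), "")
        key = f"{self.engine_id}|{sheet_id}|{field_class}"
        rng = np.random.default_rng(
            (self.seed + zlib.crc32(key.encode("utf-8"))) % 2**31
        )
        return corrupt_text(text, self.noise, rng).strip()


class TesseractEngine:
    """Adapter for the Tesseract OCR engine via pytesseract (optional)."""

    engine_id = "tesseract"

    def __init__(self) -> None:
        try:
            import pytesseract  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError("TesseractEngine requires 'pytesseract'") from exc
        self._tess = pytesseract  # pragma: no cover

    def recognize(self, image, sheet_id=None, field_class=None):  # pragma: no cover
        return self._tess.image_to_string(image).strip()


class TrOCREngine:
    """Adapter for the TrOCR handwritten-text transformer (optional)."""

    engine_id = "trocr"

    def __init__(self, model_name: str = "microsoft/trocr-large-handwritten"):
        try:
            from transformers import (  # type: ignore
                TrOCRProcessor,
                VisionEncoderDecoderModel,
            )
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError("TrOCREngine requires 'transformers'") from exc
        self._processor = TrOCRProcessor.from_pretrained(model_name)  # pragma: no cover
        self._model = VisionEncoderDecoderModel.from_pretrained(  # pragma: no cover
            model_name
        )

    def recognize(self, image, sheet_id=None, field_class=None):  # pragma: no cover
        pixel_values = self._processor(
            image.convert("RGB"), return_tensors="pt"
        ).pixel_values
        ids = self._model.generate(pixel_values)
        return self._processor.batch_decode(ids, skip_special_tokens=True)[0].strip()


def recognize_fields(
    field_crops: Mapping[FieldClass, Image.Image],
    engines: Sequence[RecognitionEngineInterface],
    sheet_id: Optional[str] = None,
) -> tuple[list[TextCandidate], list[str]]:
    """Run every engine over every field crop.

    Produces exactly ``len(field_crops) * len(engines)`` candidates, in
    field order then engine order. An engine failure on one crop yields an
    empty-text candidate plus a provenance note; the batch never aborts.
    ``formatted_text`` carries the per-field formatting rules applied to
    the raw engine output.
    """
    candidates: list[TextCandidate] = []
    notes: list[str] = []
    for field_class, image in field_crops.items():
        for engine in engines:
            try:
                raw = engine.recognize(image, sheet_id, field_class).strip()
            except Exception as exc:
                raw = ""
                notes.append(
                    f"engine {engine.engine_id} failed on "
                    f"{field_class.value}: {exc}"
                )
            candidates.append(
                TextCandidate(
                    field_class=field_class,
                    engine_id=engine.engine_id,
                    raw_text=raw,
                    formatted_text=normalize_field(raw, field_class),
                )
            )
    return candidates, notes
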