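"""Label writing-type classification.

The writing type (typewritten, printed, handwritten, combination, empty)
decides which recognition engine a label falls back to during arbitration.
A trained image classifier fills :class:`LabelClassifierInterface` in
production; :class:`OracleLabelClassifier` replays ground truth (with an
optional error rate) for hermetic runs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional, Protocol, runtime_checkable

import numpy as np
from PIL import Image

from .core import LabelClass


@runtime_checkable
class LabelClassifierInterface(Protocol):
    def classify(
        self, label_image: Image.Image, sheet_id: Optional[str] = None
    ) -> tuple[LabelClass, float]: ...


@dataclass
class OracleLabelClassifier:
    """Replays the true label class; with ``error_rate > 0`` it instead
    returns, deterministically per (seed, sheet_id), a class drawn uniformly
    from the other four."""

    ground_truth: dict[str, LabelClass]
    error_rate: float = 0.0
    seed: int = 0

    def classify(
        self, label_image: Image.Image, sheet_id: Optional[str] = None
    ) -> tuple[LabelClass, float]:
        truth = self.ground_truth[sheet_id or ""]
        if self.error_rate > 0:
            salt = zlib.crc32((sheet_id or "").encode("utf-8"))
            rng = np.random.default_rng((self.seed + salt) % 2**31)
            if rng.random() < self.error_rate:
                others = [c for c in LabelClass if c is not truth]
                return others[int(rng.integers(len(others)))], 1.0 - self.error_rate
        return truth, 1.0


def classify_label(
    label_image: Image.Image,
    classifier: LabelClassifierInterface,
    sheet_id: Optional[str] = None,
) -> tuple[LabelClass, float, list[str]]:
    """Classify a label crop, with a safe fallback.

    A classifier failure degrades to ``printed`` with confidence 0 (the
    OCR-preferring default) and a provenance note rather than aborting the
    sheet. Returns ``(label_class, confidence, notes)``.
    """
    try:
        label_class, confidence = classifier.classify(label_image, sheet_id)
        return label_class, confidence, []
    except Exception as exc:
        return (
            LabelClass.printed,
            0.0,
            [f"label classifier failed ({exc}); defaulting to 'printed'"],
        )
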