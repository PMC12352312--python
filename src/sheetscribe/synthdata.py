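"""Synthetic specimen sheets with exact ground truth.

Emulates the inputs the pipeline consumes in production — a photographed
herbarium sheet carrying a primary specimen label with up to twelve data
fields, plus distractor components (stamp, scale bar, colour target, swing
tag, database labels) — at drawing-board fidelity: flat background, one
text line per field, no plant material. Because the generator also emits
the exact component boxes, field boxes (in both sheet and label-crop
coordinates), field texts and writing class, oracle detectors and fixture
engines can replay any degradation level against a known truth.

The character noise model emulates OCR/HTR error modes (confusion-pair
substitutions such as l/t and i/e, doublings, dropped letters) so that
reference-list correction can be tested against known clean targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from .core import BoundingBox, ComponentClass, FieldClass, LabelClass
from .taxonmatch import ReferenceLists

# Confusion pairs seen in practice: l/t and i/e shape confusions, rn->m
# ligature collapse, el<->le transpositions, vowel swaps.
DEFAULT_CONFUSIONS: dict[str, str] = {
    "l": "t",
    "t": "l",
    "i": "e",
    "e": "i",
    "a": "o",
    "o": "a",
    "n": "u",
    "u": "n",
    "rn": "m",
    "el": "le",
    "le": "el",
}


@dataclass(frozen=True)
class NoiseModel:
    """Character-level corruption. Zero rates ⇒ identity transform.

    Substitutions are drawn from the confusion table only (characters and
    bigrams without an entry are never substituted); insertions double the
    current character; deletions drop it.
    """

    char_sub_rate: float = 0.0
    char_del_rate: float = 0.0
    char_ins_rate: float = 0.0
    confusion: dict[str, str] = dc_field(
        default_factory=lambda: dict(DEFAULT_CONFUSIONS)
    )

    def __post_init__(self) -> None:
        for r in (self.char_sub_rate, self.char_del_rate, self.char_ins_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"noise rate {r} outside [0, 1]")

    @property
    def is_identity(self) -> bool:
        return (
            self.char_sub_rate == 0
            and self.char_del_rate == 0
            and self.char_ins_rate == 0
        )


def corrupt_text(text: str, noise: NoiseModel, rng: np.random.Generator) -> str:
    """Apply the noise model to ``text`` under the supplied generator.

    Bigram confusions (e.g. el->le) fire first, then per-character
    deletion / substitution / doubling. Deterministic for a given rng state.
    """
    if noise.is_identity or not text:
        return text
    # bigram pass
    chars: list[str] = []
    i = 0
    while i < len(text):
        pair = text[i : i + 2]
        if (
            len(pair) == 2
            and pair in noise.confusion
            and rng.random() < noise.char_sub_rate
        ):
            chars.append(noise.confusion[pair])
            i += 2
        else:
            chars.append(text[i])
            i += 1
    # per-character pass
    out: list[str] = []
    for ch in chars:
        if len(ch) > 1:  # bigram replacement, already corrupted
            out.append(ch)
            continue
        if rng.random() < noise.char_del_rate:
            continue
        if ch in noise.confusion and rng.random() < noise.char_sub_rate:
            ch = noise.confusion[ch]
        out.append(ch)
        if rng.random() < noise.char_ins_rate:
            out.append(ch)
    return "".join(out)


_COLLECTORS = (
    "J. Smith",
    "A. Brown",
    "E. Fitzpatrick",
    "M. Nguyen",
    "R. Taylor",
    "K. Thompson",
    "L. Chen",
    "G. Papadopoulos",
)
_TOWNS = (
    "Creswick",
    "Maldon",
    "Orbost",
    "Halls Gap",
    "Mallacoota",
    "Wilsons Promontory",
    "Mount Buffalo",
    "Anglesea",
)
_DIRECTIONS = ("N", "S", "E", "W", "NE", "SW")

# Probability each optional field appears on a label (taxon core fields
# are always present; infraspecific rank is rare, mirroring real sheets).
FIELD_PRESENCE = {
    FieldClass.family: 0.9,
    FieldClass.genus: 1.0,
    FieldClass.species: 1.0,
    FieldClass.infraspecific_taxon: 0.15,
    FieldClass.authority: 0.8,
    FieldClass.collector_number: 0.85,
    FieldClass.collector: 0.95,
    FieldClass.locality: 0.9,
    FieldClass.geolocation: 0.6,
    FieldClass.year: 0.95,
    FieldClass.month: 0.9,
    FieldClass.day: 0.85,
}


def sample_taxon_content(
    refs: ReferenceLists,
    misspell: NoiseModel,
    rng: np.random.Generator,
    presence: Optional[dict[FieldClass, float]] = None,
) -> dict[FieldClass, dict[str, str]]:
    """Draw one label's content; returns field -> {"text", "truth"}.

    Taxon fields come from the reference lists, the rest from templated
    generators. ``text`` is what gets printed on the label — the
    cross-checked fields optionally corrupted by ``misspell`` — while
    ``truth`` stays clean, so correction can be measured against known
    targets. Raises on an empty reference list.
    """
    presence = FIELD_PRESENCE if presence is None else presence
    for name in ReferenceLists.VALID_NAMES:
        if not refs.get(name):
            raise ValueError(f"reference list {name!r} is empty")

    def pick(name: str) -> str:
        names = refs.get(name)
        return names[int(rng.integers(len(names)))]

    truth: dict[FieldClass, str] = {
        FieldClass.family: pick("family"),
        FieldClass.genus: pick("genus"),
        FieldClass.species: pick("species"),
        FieldClass.infraspecific_taxon: f"var. {pick('species')}",
        FieldClass.authority: pick("authority"),
        FieldClass.collector_number: str(int(rng.integers(1, 9999))),
        FieldClass.collector: _COLLECTORS[int(rng.integers(len(_COLLECTORS)))],
        FieldClass.locality: (
            f"{int(rng.integers(1, 40))} km "
            f"{_DIRECTIONS[int(rng.integers(len(_DIRECTIONS)))]} of "
            f"{_TOWNS[int(rng.integers(len(_TOWNS)))]}"
        ),
        FieldClass.geolocation: (
            f"{int(rng.integers(34, 39))}°{int(rng.integers(0, 60)):02d}'S "
            f"{int(rng.integers(141, 150))}°{int(rng.integers(0, 60)):02d}'E "
            f"{int(rng.integers(5, 1200))} m"
        ),
        FieldClass.year: str(int(rng.integers(1880, 2024))),
        FieldClass.month: str(int(rng.integers(1, 13))),
        FieldClass.day: str(int(rng.integers(1, 29))),
    }
    content: dict[FieldClass, dict[str, str]] = {}
    for fc in FieldClass:
        if rng.random() >= presence.get(fc, 1.0):
            continue
        clean = truth[fc]
        printed = clean
        if fc in (
            FieldClass.family,
            FieldClass.genus,
            FieldClass.species,
            FieldClass.authority,
        ):
            printed = corrupt_text(clean, misspell, rng)
        content[fc] = {"text": printed, "truth": clean}
    return content


@dataclass
class SheetSpec:
    """Everything needed to render one sheet deterministically."""

    sheet_id: str
    canvas_size: tuple[int, int]
    components: list[tuple[ComponentClass, BoundingBox]]
    label_box: BoundingBox
    label_content: dict[FieldClass, dict[str, str]]
    label_class: LabelClass
    seed: int = 0


def _find_font(script: bool, size: int) -> ImageFont.FreeTypeFont:
    # DejaVu ships with matplotlib: sans for print-like labels, serif
    # italic as the script-like stand-in for handwriting.
    from matplotlib import font_manager

    family, style = ("DejaVu Serif", "italic") if script else ("DejaVu Sans", "normal")
    path = font_manager.findfont(
        font_manager.FontProperties(family=family, style=style)
    )
    return ImageFont.truetype(path, size)


def build_sheet_spec(
    sheet_id: str,
    content: dict[FieldClass, dict[str, str]],
    label_class: LabelClass,
    rng: np.random.Generator,
    canvas_size: tuple[int, int] = (900, 1200),
) -> SheetSpec:
    """Lay out a sheet: distractor components in the upper region, the
    primary label in the lower region, so boxes never collide."""
    w, h = canvas_size
    label_box = BoundingBox(80, 700, 640, 1160)
    components: list[tuple[ComponentClass, BoundingBox]] = [
        (ComponentClass.primary_specimen_label, label_box)
    ]
    distractors = [
        (ComponentClass.scale, BoundingBox(60, 40, 460, 70)),
        (ComponentClass.colour_target, BoundingBox(640, 40, 840, 110)),
        (ComponentClass.stamp, BoundingBox(680, 180, 830, 280)),
        (ComponentClass.swing_tag, BoundingBox(100, 160, 260, 240)),
        (ComponentClass.small_database_label, BoundingBox(680, 1060, 860, 1120)),
        (ComponentClass.number_outside_label, BoundingBox(100, 320, 240, 360)),
        (ComponentClass.annotation_label, BoundingBox(330, 300, 600, 420)),
    ]
    for cls, box in distractors:
        if rng.random() < 0.6:
            components.append((cls, box))
    return SheetSpec(
        sheet_id=sheet_id,
        canvas_size=canvas_size,
        components=components,
        label_box=label_box,
        label_content=dict(content) if label_class is not LabelClass.empty else {},
        label_class=label_class,
    )


def render_sheet(spec: SheetSpec) -> tuple[Image.Image, dict]:
    """Raster the sheet and return (image, ground truth).

    The ground truth carries the exact component boxes, the field boxes in
    both sheet and label-crop coordinates, the printed and clean texts, and
    the writing class. Raises when a field's text overflows the label box,
    naming the field.
    """
    w, h = spec.canvas_size
    image = Image.new("RGB", (w, h), (245, 242, 232))
    draw = ImageDraw.Draw(image)
    script = spec.label_class in (LabelClass.handwritten, LabelClass.combination)
    font = _find_font(script, 22)
    caption_font = _find_font(False, 14)

    for cls, box in spec.components:
        if cls is ComponentClass.primary_specimen_label:
            continue
        draw.rectangle(box.as_tuple(), outline=(120, 110, 90), width=2)
        draw.text(
            (box.x_min + 4, box.y_min + 2),
            cls.value.replace("_", " "),
            fill=(120, 110, 90),
            font=caption_font,
        )

    lb = spec.label_box
    draw.rectangle(lb.as_tuple(), fill=(255, 255, 250), outline=(40, 40, 40), width=3)

    fields_truth: dict[str, dict] = {}
    y = lb.y_min + 18
    for fc in FieldClass:
        if fc not in spec.label_content:
            continue
        text = spec.label_content[fc]["text"]
        if not text:
            continue
        x = lb.x_min + 16
        tb = draw.textbbox((x, y), text, font=font)
        if tb[2] > lb.x_max - 8 or tb[3] > lb.y_max - 8:
            raise ValueError(
                f"sheet {spec.sheet_id!r}: field {fc.value!r} overflows the label box"
            )
        draw.text((x, y), text, fill=(25, 25, 30), font=font)
        box_sheet = BoundingBox(tb[0] - 2, tb[1] - 2, tb[2] + 2, tb[3] + 2)
        box_label = box_sheet.translate(-lb.x_min, -lb.y_min)
        fields_truth[fc.value] = {
            "text": text,
            "truth": spec.label_content[fc]["truth"],
            "box_sheet": list(box_sheet.as_tuple()),
            "box_label": list(box_label.as_tuple()),
        }
        y = tb[3] + 12

    truth = {
        "sheet_id": spec.sheet_id,
        "label_class": spec.label_class.value,
        "components": [
            {"class": cls.value, "box": list(box.as_tuple())}
            for cls, box in spec.components
        ],
        "fields": fields_truth,
    }
    return image, truth


#: Writing-class sampling weights; empty labels are rare but do occur.
CLASS_WEIGHTS = {
    LabelClass.typewritten: 0.3,
    LabelClass.printed: 0.3,
    LabelClass.handwritten: 0.25,
    LabelClass.combination: 0.12,
    LabelClass.empty: 0.03,
}


def generate_batch(
    n_sheets: int,
    seed: int,
    noise: NoiseModel = NoiseModel(),
    refs: Optional[ReferenceLists] = None,
    class_weights: Optional[dict[LabelClass, float]] = None,
) -> list[tuple[str, Image.Image, dict]]:
    """Generate ``n_sheets`` (sheet_id, image, ground truth) triples,
    fully deterministic in ``seed``."""
    refs = refs or ReferenceLists.bundled_fixture()
    weights = class_weights or CLASS_WEIGHTS
    classes = list(weights)
    p = np.array([weights[c] for c in classes], dtype=float)
    p /= p.sum()
    rng = np.random.default_rng(seed % 2**31)
    out = []
    for i in range(n_sheets):
        sheet_id = f"synth-{seed}-{i:04d}"
        label_class = classes[int(rng.choice(len(classes), p=p))]
        content = sample_taxon_content(refs, noise, rng)
        spec = build_sheet_spec(sheet_id, content, label_class, rng)
        image, truth = render_sheet(spec)
        out.append((sheet_id, image, truth))
    return out


def write_batch(
    batch: list[tuple[str, Image.Image, dict]],
    out_dir: str | Path,
) -> Path:
    """Write sheet PNGs plus a ``ground_truth.json``; returns the JSON path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truths = {}
    for sheet_id, image, truth in batch:
        image.save(out_dir / f"{sheet_id}.png")
        truths[sheet_id] = truth
    gt_path = out_dir / "ground_truth.json"
    gt_path.write_text(json.dumps(truths, indent=1), encoding="utf-8")
    return gt_path
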