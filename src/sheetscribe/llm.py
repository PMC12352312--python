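"""Multimodal-LLM correction of the extracted record.

After reference-list correction, the label image plus the per-field
accepted text, both engines' raw readings and the adjustment notes are
handed to a multimodal language model, zero-shot, which returns
corrections only for fields it considers wrong. The client is pluggable;
an offline stub ships for testing and hermetic runs. Match scores are
never recomputed after LLM correction — they describe the reference-match
stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence, runtime_checkable

from PIL import Image

from .core import FieldClass, SpecimenRecord


@runtime_checkable
class LLMClientInterface(Protocol):
    model_name: str

    def complete(self, prompt: str, image: Optional[Image.Image]) -> str: ...


@dataclass
class StubLLMClient:
    """Offline stand-in client returning canned responses per sheet_id
    (empty string — no corrections — by default)."""

    responses: dict[str, str] = field(default_factory=dict)
    model_name: str = "stub"
    sheet_id: Optional[str] = None

    def complete(self, prompt: str, image: Optional[Image.Image]) -> str:
        return self.responses.get(self.sheet_id or "", "")


class OpenAIClient:
    """Adapter for OpenAI-compatible chat APIs (optional extra; requires
    the ``openai`` package and an API key)."""

    def __init__(self, model_name: str = "gpt-4o", api_key_env: str = "OPENAI_API_KEY"):
        try:
            import openai  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError("OpenAIClient requires the 'openai' package") from exc
        import base64
        import io
        import os

        self.model_name = model_name  # pragma: no cover
        self._client = openai.OpenAI(api_key=os.environ[api_key_env])  # pragma: no cover
        self._b64 = base64  # pragma: no cover
        self._io = io  # pragma: no cover

    def complete(self, prompt, image):  # pragma: no cover - needs network
        content: list = [{"type": "text", "text": prompt}]
        if image is not None:
            buf = self._io.BytesIO()
            image.save(buf, format="PNG")
            data = self._b64.b64encode(buf.getvalue()).decode()
            content.append(
                {
                    "type": "image_url",
                    "image_url": {"url": f"data:image/png;base64,{data}"},
                }
            )
        resp = self._client.chat.completions.create(
            model=self.model_name, messages=[{"role": "user", "content": content}]
        )
        return resp.choices[0].message.content or ""


def build_prompt(record: SpecimenRecord, adjustments: Sequence[str]) -> str:
    """Zero-shot correction prompt.

    Lists all 12 fields with the currently accepted text, every engine's
    raw reading, and how the text was adjusted during reference-list
    cross-checking; asks the model to answer with one ``field: value``
    line per field whose accepted text is wrong, and nothing else.
    """
    lines = [
        "You are transcribing a herbarium primary specimen label from its image.",
        "The desired fields are:",
        "  " + ", ".join(fc.value for fc in FieldClass),
        "",
        "Currently accepted text for each field:",
    ]
    for fc in FieldClass:
        lines.append(f"  {fc.value}: {record.field_text(fc) or ''}")
    lines.append("")
    lines.append("Raw text recognition outputs:")
    for fc in FieldClass:
        fr = record.fields.get(fc)
        for engine_id, text in sorted((fr.engine_texts if fr else {}).items()):
            lines.append(f"  {fc.value} [{engine_id}]: {text}")
    lines.append("")
    lines.append("Adjustments made by reference-list cross-checking:")
    if adjustments:
        for adj in adjustments:
            lines.append(f"  {adj}")
    else:
        lines.append("  (none)")
    lines.append("")
    lines.append(
        "Compare the accepted text with the label image. Output the text for "
        "any fields where the accepted text is incorrect, one per line, "
        "formatted exactly as 'field: value'. Output nothing else. If every "
        "field is correct, output nothing."
    )
    return "\n".join(lines)


def parse_response(response: str) -> tuple[dict[FieldClass, str], list[str]]:
    """Total parser for the model's reply.

    Lines of the form ``field: value`` for known fields become
    corrections; everything else is ignored with a provenance note.
    Returns (corrections, notes).
    """
    corrections: dict[FieldClass, str] = {}
    notes: list[str] = []
    valid = {fc.value: fc for fc in FieldClass}
    for line in response.splitlines():
        line = line.strip()
        if not line:
            continue
        key, sep, value = line.partition(":")
        fc = valid.get(key.strip().lower())
        if sep and fc is not None:
            corrections[fc] = value.strip()
        else:
            notes.append(f"llm: ignored response line {line!r}")
    return corrections, notes


def serialize_correction(correction: dict[FieldClass, str]) -> str:
    """Inverse of :func:`parse_response` for valid corrections."""
    return "\n".join(f"{fc.value}: {text}" for fc, text in correction.items())


def apply_corrections(
    record: SpecimenRecord, correction: dict[FieldClass, str]
) -> SpecimenRecord:
    """Overwrite chosen text with the model's corrections, in place.

    ``llm_text`` keeps the model's value; match scores are left untouched
    (they describe the pre-LLM reference match); every overwrite lands in
    provenance. Fields the model did not mention are unchanged.
    """
    from .core import FieldRecord

    for fc, text in correction.items():
        fr = record.fields.get(fc)
        if fr is None:
            fr = FieldRecord()
            record.fields[fc] = fr
        record.note(f"llm corrected {fc.value}: {fr.chosen_text!r} -> {text!r}")
        fr.llm_text = text
        fr.chosen_text = text
    return record
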