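"""Output emission: results CSV, per-field text files and the HTML report.

The CSV is the machine-readable product: one row per primary label with
every engine's reading, the chosen text, the LLM value and the reference
match score for the four cross-checked fields (1.0 = exact hit, 0.8–1.0 =
corrected, 0.0 = no match). The HTML report is the human cross-checking
surface: each field crop sits beside every reading so a curator can verify
the extraction against the pixels.
"""

from __future__ import annotations

import csv
import html
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .core import (
    CROSS_CHECKED_FIELDS,
    FieldClass,
    FieldRecord,
    LabelClass,
    SpecimenRecord,
)

DEFAULT_ENGINE_IDS = ("tesseract", "trocr")


@dataclass
class OutputLayout:
    """Directory layout of one pipeline run."""

    root: Path

    def __post_init__(self) -> None:
        self.root = Path(self.root)

    @property
    def csv_path(self) -> Path:
        return self.root / "results.csv"

    @property
    def html_path(self) -> Path:
        return self.root / "report.html"

    def sheet_dir(self, sheet_id: str) -> Path:
        return self.root / "sheets" / sheet_id

    def crop_path(self, sheet_id: str, name: str) -> Path:
        return self.sheet_dir(sheet_id) / f"{sheet_id}_{name}.png"


def format_score(score: Optional[float]) -> str:
    if score is None:
        return ""
    if score in (0.0, 1.0):
        return f"{score:.1f}"
    return f"{score:.3f}"


def csv_columns(engine_ids: Sequence[str] = DEFAULT_ENGINE_IDS) -> list[str]:
    cols = ["sheet_id", "label_class", "chosen_engine"]
    for fc in FieldClass:
        cols.append(fc.value)
        for eng in engine_ids:
            cols.append(f"{fc.value}_{eng}")
        cols.append(f"{fc.value}_llm")
        if fc in CROSS_CHECKED_FIELDS:
            cols.append(f"{fc.value}_score")
    return cols


def write_csv(
    records: Sequence[SpecimenRecord],
    path: str | Path,
    engine_ids: Sequence[str] = DEFAULT_ENGINE_IDS,
) -> Path:
    """One RFC-4180 row per primary label, UTF-8 with header. An empty
    record list still writes the header row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = csv_columns(engine_ids)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols, quoting=csv.QUOTE_MINIMAL)
        writer.writeheader()
        for rec in records:
            row = {
                "sheet_id": rec.sheet_id,
                "label_class": rec.label_class.value,
                "chosen_engine": rec.chosen_engine,
            }
            for fc in FieldClass:
                fr = rec.fields.get(fc)
                row[fc.value] = fr.chosen_text if fr else ""
                for eng in engine_ids:
                    row[f"{fc.value}_{eng}"] = fr.engine_texts.get(eng, "") if fr else ""
                row[f"{fc.value}_llm"] = (fr.llm_text or "") if fr else ""
                if fc in CROSS_CHECKED_FIELDS:
                    row[f"{fc.value}_score"] = format_score(
                        fr.match_score if fr else None
                    )
            writer.writerow(row)
    return path


def read_csv(
    path: str | Path, engine_ids: Sequence[str] = DEFAULT_ENGINE_IDS
) -> list[SpecimenRecord]:
    """Reconstruct records from a results CSV (inverse of
    :func:`write_csv` for every text and score field)."""
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            rec = SpecimenRecord(
                sheet_id=row["sheet_id"],
                label_class=LabelClass(row["label_class"]),
                chosen_engine=row.get("chosen_engine", ""),
            )
            for fc in FieldClass:
                chosen = row.get(fc.value, "")
                engine_texts = {
                    eng: row.get(f"{fc.value}_{eng}", "") for eng in engine_ids
                }
                llm_text = row.get(f"{fc.value}_llm", "") or None
                score_text = row.get(f"{fc.value}_score", "")
                if not (chosen or any(engine_texts.values()) or llm_text or score_text):
                    continue
                rec.fields[fc] = FieldRecord(
                    chosen_text=chosen,
                    engine_texts=engine_texts,
                    llm_text=llm_text,
                    match_score=float(score_text) if score_text else None,
                )
            records.append(rec)
    return records


def write_field_texts(record: SpecimenRecord, layout: OutputLayout) -> None:
    """Plain-text dump of every reading for one label, beside its crops."""
    out = layout.sheet_dir(record.sheet_id) / f"{record.sheet_id}_text.txt"
    out.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"label_class: {record.label_class.value}"]
    for fc, fr in record.fields.items():
        lines.append(f"{fc.value}: {fr.chosen_text}")
        for eng, text in sorted(fr.engine_texts.items()):
            lines.append(f"{fc.value} [{eng}]: {text}")
    out.write_text("\n".join(lines) + "\n", encoding="utf-8")


_CSS = """
body { font-family: sans-serif; margin: 2em; }
table { border-collapse: collapse; margin-bottom: 2em; }
td, th { border: 1px solid #999; padding: 4px 8px; vertical-align: middle; }
tr.changed { background: #fff3cd; }
img.crop { max-height: 48px; }
img.label { max-width: 480px; border: 1px solid #333; }
.placeholder { color: #999; font-style: italic; }
.banner { color: #666; font-size: 1.2em; }
"""


def write_html(
    records: Sequence[SpecimenRecord],
    layout: OutputLayout,
    engine_ids: Sequence[str] = DEFAULT_ENGINE_IDS,
) -> Path:
    """Self-contained HTML report; image paths are relative to the report.

    A missing crop file renders as a placeholder cell, never a crash; rows
    whose text was changed during correction are visibly flagged.
    """
    esc = html.escape
    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>",
        "<title>Specimen label extraction report</title>",
        f"<style>{_CSS}</style></head><body>",
        "<h1>Specimen label extraction report</h1>",
    ]
    if not records:
        parts.append("<p class='banner'>No records were produced by this run.</p>")
    for rec in records:
        parts.append(f"<h2>{esc(rec.sheet_id)}</h2>")
        parts.append(
            f"<p>Writing type: <b>{esc(rec.label_class.value)}</b> &mdash; "
            f"chosen engine: <b>{esc(rec.chosen_engine or '—')}</b></p>"
        )
        label_crop = layout.crop_path(rec.sheet_id, "label")
        if label_crop.exists():
            rel = label_crop.relative_to(layout.root)
            parts.append(f"<img class='label' src='{rel.as_posix()}'>")
        else:
            parts.append("<p class='placeholder'>label crop missing</p>")
        header = (
            "<tr><th>field</th><th>crop</th>"
            + "".join(f"<th>{esc(e)}</th>" for e in engine_ids)
            + "<th>result</th><th>score</th></tr>"
        )
        rows = [header]
        for fc, fr in rec.fields.items():
            changed = any(
                fr.chosen_text != t for t in fr.engine_texts.values()
            ) or fr.llm_text is not None
            crop = layout.crop_path(rec.sheet_id, fc.value)
            if crop.exists():
                rel = crop.relative_to(layout.root)
                crop_cell = f"<img class='crop' src='{rel.as_posix()}'>"
            else:
                crop_cell = "<span class='placeholder'>missing</span>"
            cells = [f"<td>{esc(fc.value)}</td>", f"<td>{crop_cell}</td>"]
            for eng in engine_ids:
                cells.append(f"<td>{esc(fr.engine_texts.get(eng, ''))}</td>")
            flag = " &#x270e;" if changed else ""
            cells.append(f"<td><b>{esc(fr.chosen_text)}</b>{flag}</td>")
            cells.append(f"<td>{esc(format_score(fr.match_score))}</td>")
            cls = " class='changed'" if changed else ""
            rows.append(f"<tr{cls}>{''.join(cells)}</tr>")
        parts.append("<table>" + "".join(rows) + "</table>")
    parts.append("</body></html>")
    layout.root.mkdir(parents=True, exist_ok=True)
    layout.html_path.write_text("\n".join(parts), encoding="utf-8")
    return layout.html_path
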