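"""Pipeline orchestration: components → primary label → fields →
classify → recognize → correct → LLM → report.

Adapters (detectors, classifier, engines, LLM client) are resolved from a
:class:`PipelineConfig`, loadable from YAML. Oracle/fixture adapters can
be assembled directly from a synthetic batch's ground truth, which is how
the hermetic test path and the ``synth``/``run`` round trip work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

from PIL import Image

from .classification import (
    LabelClassifierInterface,
    OracleLabelClassifier,
    classify_label,
)
from .core import (
    BoundingBox,
    ComponentClass,
    FieldClass,
    FieldRecord,
    LabelClass,
    SpecimenRecord,
    crop,
)
from .detection import (
    DetectorInterface,
    OracleDetector,
    dedupe_fields,
    detect_components,
    detect_fields,
    select_primary_labels,
)
from .evaluate import GroundTruthRecord
from .llm import LLMClientInterface, StubLLMClient, apply_corrections, build_prompt, parse_response
from .recognition import FixtureEngine, RecognitionEngineInterface, recognize_fields
from .report import OutputLayout, write_csv, write_field_texts, write_html
from .synthdata import NoiseModel
from .taxonmatch import (
    MatchConfig,
    ReferenceLists,
    arbitrate,
    assign_scores,
    match_candidates,
)

logger = logging.getLogger("sheetscribe")


@dataclass
class PipelineConfig:
    component_detector: DetectorInterface = None  # type: ignore[assignment]
    field_detector: DetectorInterface = None  # type: ignore[assignment]
    classifier: LabelClassifierInterface = None  # type: ignore[assignment]
    engines: list[RecognitionEngineInterface] = dc_field(default_factory=list)
    ocr_engine: str = "tesseract"
    htr_engine: str = "trocr"
    refs: ReferenceLists = dc_field(default_factory=ReferenceLists)
    matching: MatchConfig = dc_field(default_factory=MatchConfig)
    llm_enabled: bool = False
    llm_client: Optional[LLMClientInterface] = None
    pad_fraction: float = 0.0
    min_confidence: float = 0.0
    seed: int = 0


def config_from_ground_truth(
    ground_truth: dict,
    refs: Optional[ReferenceLists] = None,
    engine_noise: NoiseModel = NoiseModel(),
    matching: MatchConfig = MatchConfig(),
    llm_enabled: bool = False,
    llm_client: Optional[LLMClientInterface] = None,
    seed: int = 0,
    jitter_px: float = 0.0,
    drop_rate: float = 0.0,
    classifier_error_rate: float = 0.0,
) -> PipelineConfig:
    """Assemble an all-oracle configuration from a synthetic batch's
    ground truth (the ``ground_truth.json`` schema of the synthdata
    module)."""
    comp_gt: dict[str, list] = {}
    field_gt: dict[str, list] = {}
    class_gt: dict[str, LabelClass] = {}
    text_gt: dict[tuple[str, FieldClass], str] = {}
    for sheet_id, truth in ground_truth.items():
        comp_gt[sheet_id] = [
            (c["class"], BoundingBox(*c["box"])) for c in truth["components"]
        ]
        class_gt[sheet_id] = LabelClass(truth["label_class"])
        field_gt[sheet_id] = [
            (name, BoundingBox(*f["box_label"]))
            for name, f in truth["fields"].items()
        ]
        for name, f in truth["fields"].items():
            text_gt[(sheet_id, FieldClass(name))] = f["text"]
    return PipelineConfig(
        component_detector=OracleDetector(
            comp_gt, ComponentClass, jitter_px, drop_rate, seed
        ),
        field_detector=OracleDetector(field_gt, FieldClass, jitter_px, drop_rate, seed),
        classifier=OracleLabelClassifier(class_gt, classifier_error_rate, seed),
        engines=[
            FixtureEngine("tesseract", text_gt, engine_noise, seed),
            FixtureEngine("trocr", text_gt, engine_noise, seed + 1),
        ],
        refs=refs or ReferenceLists.bundled_fixture(),
        matching=matching,
        llm_enabled=llm_enabled,
        llm_client=llm_client,
        seed=seed,
    )


def truth_records(
    ground_truth: dict, use_clean_text: bool = False
) -> list[GroundTruthRecord]:
    """Ground-truth records for evaluation. By default the text as printed
    on the label is the truth (the transcription target); with
    ``use_clean_text`` the uncorrupted reference names are used instead,
    which is the right target when measuring the value of correction."""
    key = "truth" if use_clean_text else "text"
    return [
        GroundTruthRecord(
            sheet_id=sheet_id,
            label_class=LabelClass(t["label_class"]),
            fields={FieldClass(n): f[key] for n, f in t["fields"].items()},
        )
        for sheet_id, t in ground_truth.items()
    ]


def process_sheet(
    sheet_id: str,
    image: Image.Image,
    cfg: PipelineConfig,
    layout: Optional[OutputLayout] = None,
) -> list[SpecimenRecord]:
    """Run the full stage order on one sheet; one record per primary
    label detected (sheet_id suffixed ``#k`` when there are several), or a
    single empty-fields record when none is found."""
    components = detect_components(
        image, cfg.component_detector, sheet_id, cfg.min_confidence
    )
    primaries = select_primary_labels(components)
    if not primaries:
        rec = SpecimenRecord(sheet_id=sheet_id, label_class=LabelClass.empty)
        rec.note(
            "no components detected" if not components
            else "no primary specimen label detected"
        )
        logger.info("%s: %s", sheet_id, rec.provenance[-1])
        return [rec]

    records = []
    for k, det in enumerate(primaries):
        record_id = sheet_id if len(primaries) == 1 else f"{sheet_id}#{k}"
        rec = SpecimenRecord(sheet_id=record_id)
        label_img = crop(image, det.box, cfg.pad_fraction, sheet_id)

        label_class, _conf, cls_notes = classify_label(
            label_img, cfg.classifier, sheet_id
        )
        rec.label_class = label_class
        rec.provenance.extend(cls_notes)

        field_dets = detect_fields(
            label_img, cfg.field_detector, sheet_id, cfg.min_confidence
        )
        kept, dd_notes = dedupe_fields(field_dets)
        rec.provenance.extend(dd_notes)
        if not kept:
            rec.note("no fields detected on primary label")

        crops = {
            fc: crop(label_img, d.box, cfg.pad_fraction, sheet_id)
            for fc, d in kept.items()
        }
        candidates, rec_notes = recognize_fields(crops, cfg.engines, sheet_id)
        rec.provenance.extend(rec_notes)

        matches = match_candidates(candidates, cfg.refs, cfg.matching)
        winner, chosen, arb_notes = arbitrate(
            candidates,
            matches,
            label_class,
            cfg.ocr_engine,
            cfg.htr_engine,
            cfg.matching.threshold,
        )
        rec.chosen_engine = winner
        rec.provenance.extend(arb_notes)
        for note in arb_notes:
            if note.startswith("corrected "):
                logger.info("%s: %s", record_id, note)

        for fc in kept:
            engine_texts = {
                c.engine_id: c.raw_text for c in candidates if c.field_class is fc
            }
            rec.fields[fc] = FieldRecord(
                chosen_text=chosen.get(fc, ""), engine_texts=engine_texts
            )
        if cfg.matching.enabled:
            assign_scores(rec, matches.get(winner, {}))

        if cfg.llm_enabled and cfg.llm_client is not None:
            adjustments = [n for n in arb_notes if n.startswith("corrected ")]
            prompt = build_prompt(rec, adjustments)
            if hasattr(cfg.llm_client, "sheet_id"):
                cfg.llm_client.sheet_id = record_id  # stub routing
            try:
                response = cfg.llm_client.complete(prompt, label_img)
            except Exception as exc:
                rec.note(f"llm call failed: {exc}")
                response = ""
            corrections, llm_notes = parse_response(response)
            rec.provenance.extend(llm_notes)
            apply_corrections(rec, corrections)

        if layout is not None:
            out = layout.sheet_dir(record_id)
            out.mkdir(parents=True, exist_ok=True)
            label_img.save(layout.crop_path(record_id, "label"))
            for fc, im in crops.items():
                im.save(layout.crop_path(record_id, fc.value))
        records.append(rec)
    return records


def run(
    inputs: Sequence[tuple[str, Image.Image] | str | Path],
    cfg: PipelineConfig,
    out_dir: str | Path,
) -> tuple[list[SpecimenRecord], OutputLayout]:
    """Process a batch of sheets and write the full output directory
    (crops, per-label text files, results.csv, report.html).

    Inputs are (sheet_id, image) pairs or image paths (the stem becomes
    the sheet_id). A sheet that fails at any stage is skipped with a
    logged error; the batch never aborts.
    """
    layout = OutputLayout(Path(out_dir))
    records: list[SpecimenRecord] = []
    for item in inputs:
        if isinstance(item, (str, Path)):
            path = Path(item)
            sheet_id = path.stem
            try:
                image = Image.open(path)
                image.load()
            except Exception as exc:
                logger.error("skipping unreadable image %s: %s", path, exc)
                continue
        else:
            sheet_id, image = item
        try:
            recs = process_sheet(sheet_id, image, cfg, layout)
        except Exception as exc:
            logger.error("skipping sheet %s: %s", sheet_id, exc)
            continue
        for rec in recs:
            write_field_texts(rec, layout)
        records.extend(recs)
    engine_ids = [e.engine_id for e in cfg.engines] or ["tesseract", "trocr"]
    write_csv(records, layout.csv_path, engine_ids)
    write_html(records, layout, engine_ids)
    return records, layout


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file.

    Adapters are registered by ``kind``: ``oracle``/``fixture`` adapters
    point at a ground-truth JSON written by the synthdata module; ``yolo``,
    ``tesseract``, ``trocr`` and ``openai`` resolve the optional real
    adapters. Reference lists default to the bundled fixture lists.
    """
    import json

    import yaml

    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    base = Path(path).parent

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    gt_path = raw.get("ground_truth")
    gt = (
        json.loads(resolve(gt_path).read_text(encoding="utf-8")) if gt_path else None
    )
    seed = int(raw.get("seed", 0))

    refs_cfg = raw.get("reference_lists", "bundled")
    if refs_cfg == "bundled":
        refs = ReferenceLists.bundled_fixture()
    else:
        refs = ReferenceLists.from_files(
            {name: resolve(p) for name, p in refs_cfg.items()}
        )

    m = raw.get("matching", {})
    matching = MatchConfig(
        threshold=float(m.get("threshold", 0.8)),
        enabled=bool(m.get("enabled", True)),
    )
    llm = raw.get("llm", {})
    llm_enabled = bool(llm.get("enabled", False))
    llm_client: Optional[LLMClientInterface] = None
    if llm_enabled:
        if llm.get("kind", "stub") == "openai":  # pragma: no cover - network
            from .llm import OpenAIClient

            llm_client = OpenAIClient(
                llm.get("model", "gpt-4o"), llm.get("api_key_env", "OPENAI_API_KEY")
            )
        else:
            llm_client = StubLLMClient()

    if gt is None:
        raise ValueError(
            "config must name a ground_truth JSON for oracle adapters "
            "(real-detector configs must be assembled programmatically)"
        )
    cfg = config_from_ground_truth(
        gt,
        refs=refs,
        engine_noise=NoiseModel(
            char_sub_rate=float(raw.get("engine_noise", {}).get("sub_rate", 0.0)),
            char_del_rate=float(raw.get("engine_noise", {}).get("del_rate", 0.0)),
            char_ins_rate=float(raw.get("engine_noise", {}).get("ins_rate", 0.0)),
        ),
        matching=matching,
        llm_enabled=llm_enabled,
        llm_client=llm_client,
        seed=seed,
        jitter_px=float(raw.get("jitter_px", 0.0)),
        drop_rate=float(raw.get("drop_rate", 0.0)),
        classifier_error_rate=float(raw.get("classifier_error_rate", 0.0)),
    )
    cfg.pad_fraction = float(raw.get("pad_fraction", 0.0))
    cfg.min_confidence = float(raw.get("min_confidence", 0.0))
    return cfg
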