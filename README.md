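# sheetscribe

A modular pipeline for digitizing herbarium specimen sheets: it detects the
components of a photographed sheet, crops the primary specimen label, detects
the twelve data fields written on it, classifies the label's writing type,
reads each field with two text-recognition engines, corrects taxon names
against reference lists, optionally refines the record with a multimodal LLM,
and emits a results CSV plus an HTML report for manual cross-checking. An
evaluation harness and a synthetic-sheet generator make every stage testable
offline, with no model weights or network access.

It is aimed at herbarium curators and biodiversity-informatics developers who
need label transcription at scale, and at anyone building or benchmarking
label-extraction components (the detector, classifier, engine and LLM slots
are all pluggable adapters).

## The method

**Components and fields.** A sheet-component detector proposes bounding boxes
for 11 component classes (primary specimen label, annotation labels, stamps,
swing tags, database labels, colour target, scale, …). Each primary specimen
label is cropped and passed to a label-field detector for the 12 fields:
family, genus, species (specific epithet), infraspecific taxon, authority,
collector number, collector, locality, geolocation, year, month, day.

**Recognition and correction.** Every field crop is read by an OCR engine and
an HTR engine. Family/genus are title-cased, epithets lower-cased, and edge
punctuation stripped. The four taxon fields (family, genus, species,
authority) are then cross-checked against reference name lists using the
Gestalt (Ratcliff/Obershelp) similarity

    sim(a, b) = 2·M / (|a| + |b|)

where M counts characters matched by recursively removing the longest common
substring. A field is replaced by the closest reference name when
sim ≥ 0.8 (user-adjustable; matching can be disabled). The match score is 1.0
for an exact hit, the similarity in [0.8, 1.0) for a correction, and 0.0 when
nothing matches. The mean match score per engine arbitrates which engine's
text is used for the remaining fields; with no clear winner, handwritten and
mixed labels fall back to the HTR engine, others to OCR. A multimodal LLM
(pluggable client, zero-shot prompt, offline stub provided) may then overwrite
individual fields; match scores always describe the pre-LLM reference match.

**Evaluation.** Predictions are scored against ground truth by label
classification accuracy, field-presence accuracy, and per-field Gestalt
similarity after removing non-ASCII characters and punctuation
(case-insensitive); fields present on exactly one side score zero, fields on
neither side are excluded. Detection quality is reported per class as
precision/recall/f1 at IoU 0.5, plus mAP50.

## Worked example

```bash
python examples/correct_taxon_names.py
```

prints

```
      Ahnfletia [genus  ] ->       Ahnfeltia  score=0.889  changed=True
      Odontitis [genus  ] ->       Odontites  score=0.889  changed=True
 sisymbrifolium [species] -> sisymbriifolium  score=0.966  changed=True
       serulata [species] ->       sertulata  score=0.941  changed=True
        Banksia [genus  ] ->         Banksia  score=1.000  changed=False
         Xyzabc [genus  ] ->      (no match)  score=0.000  changed=False
```

Each misspelled name is corrected to the closest reference name at or above
the 80% similarity threshold; `Banksia` is an exact hit (score 1.0, no
change); `Xyzabc` has no close match, so the text passes through with score 0.
Note `serulata`: `sertulata` and `serrulata` tie at 16/17, and list order
decides — fuzzy matching can pick a defensible but wrong neighbour, which is
why scores below 1.0 are flagged for review.

The full pipeline, end to end on synthetic sheets:

```bash
python examples/run_pipeline_on_synthetic_sheets.py   # CSV + HTML report
python examples/measure_correction_value.py           # matching on vs off
python examples/score_detection_quality.py            # f1 / mAP50
```

Or from the shell, the whole pipeline with a single command:

```bash
sheetscribe synth -n 10 --seed 1 --noise 0.1 -o demo   # sheets + ground truth
sheetscribe run demo -c demo/config.yaml -o demo_out   # full pipeline
sheetscribe evaluate demo_out/results.csv demo/ground_truth.json
```

`results.csv` has one row per primary label with columns `<field>`,
`<field>_tesseract`, `<field>_trocr`, `<field>_llm` and `<field>_score` for
the four taxon fields; `report.html` shows each field crop beside all
readings with changed rows highlighted.

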