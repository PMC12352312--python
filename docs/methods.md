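# Methods

This note documents the models, conventions and design choices behind
sheetscribe, in the order the pipeline runs.

## Geometry and detection

Boxes are 0-based, half-open pixel rectangles `[x_min, x_max) × [y_min,
y_max)` with fractional coordinates allowed, so `area = width × height` is
exact and boxes map directly to array slices. Crops may be expanded by a
`pad_fraction` per side (default 0, clipped to the image); real detectors
tend to under-crop, so the knob exists even though the default pipeline does
not use it.

Detectors are adapters: anything mapping an image to `(class, box,
confidence)` triples fills the slot. The shipped `OracleDetector` replays
ground truth with optional uniform box jitter and Bernoulli drop-out,
deterministically per `(seed, sheet_id)` (sheet ids are hashed with CRC-32,
not Python's salted `hash`, so replays are stable across interpreter runs).
Every primary-specimen-label detection is processed independently, best
confidence first (`sheet_id#k` suffixes when there are several — nothing is
discarded). Duplicate field detections are resolved to the highest
confidence, ties to reading order (smaller `y_min`, then `x_min`).

## Writing-type classification and engine arbitration

The label classifier returns one of five classes: typewritten, printed,
handwritten, combination ("mixed"), empty. Classes map totally onto an
engine-preference role: handwritten and combination prefer the HTR engine,
the other three the OCR engine. Empty labels carry nothing to recognize, so
OCR-preference is a harmless convention. A classifier failure degrades to
`printed` with confidence 0 and a provenance note rather than aborting the
sheet.

Arbitration between the two engines uses the arithmetic mean of each
engine's match scores over the cross-checked fields actually detected — a
scale-free aggregate across labels with different field counts. An engine
wins outright only when its mean is strictly greater *and* at least one mean
reaches the matching threshold; equal means, both means below threshold, or
no cross-checked fields at all fall back to the label-class preference. The
winning engine supplies the text for every field; cross-checked fields take
its corrected text.

## Formatting and reference matching

Per-field formatting: family and genus are stripped of edge punctuation and
whitespace then title-cased; specific and infraspecific epithets stripped
then lower-cased; all other fields only have edge whitespace stripped (no
abbreviation expansion is applied to authorities).

The similarity is the Gestalt (Ratcliff/Obershelp) statistic: `2·M/(|a|+|b|)`
with `M` the characters matched by recursively removing the longest common
substring and matching the flanks independently. Ties among equally long
common substrings resolve to the smallest index in the first string, then the
second — the same convention as the brute-force oracle the tests compare
against, and in practice the same values as `difflib.SequenceMatcher`. Two
caveats are inherent to the statistic and deliberately preserved: it is
order-sensitive in rare tie cases (so the evaluation does not assert exact
symmetry), and two empty strings are defined to be identical (1.0), which is
consistent with the evaluation convention that only fields present somewhere
are scored.

Matching is case-insensitive: queries are compared casefolded against
casefolded reference names, but the substituted name keeps the list's
original case. An exact (case-insensitive) membership hit scores 1.0 and is
never "changed". Otherwise the best-scoring reference name is substituted iff
its similarity is ≥ the threshold (inclusive, default 0.8, user-adjustable;
matching can be disabled entirely, which passes text through with no scores).
Ties between reference names break by list order — first occurrence wins —
which reproduces the known failure mode where a misspelling like `serulata`
is corrected to the earlier-listed `sertulata` rather than the intended
`serrulata`. Empty queries never match. Raising the threshold can only
reduce the number of changed fields (monotone by construction).

The bundled reference lists are small fixtures (tens of names each, one name
per line, `#` comments); production use points the config at full exports
(e.g. World Flora Online / national species lists), which are multi-gigabyte
external resources and out of scope. Matching never assesses taxonomic
status — names are matched as strings.

## LLM correction

The prompt lists all 12 field names, the currently accepted text per field,
every engine's raw reading, and the adjustments made during reference
matching, and asks for corrections only, one `field: value` line per wrong
field — zero-shot, no examples. The parser is total: well-formed lines for
known fields become corrections, everything else is ignored with a
provenance note. Corrections overwrite the chosen text and are logged;
match scores are *not* recomputed (they describe the reference-match stage,
and the CSV couples them to it). The client is an interface; the shipped
stub returns canned responses per sheet and the pipeline with the
empty-responding stub is byte-identical to running with the LLM disabled.
One request is sent per primary label.

## Outputs

The results CSV has one row per primary label: `sheet_id`, `label_class`,
`chosen_engine`, then per field the chosen text, one column per engine's raw
reading, the LLM value, and — for family, genus, species and authority
only — the match score (3 decimals; exact 1 and 0 as `1.0`/`0.0`). RFC-4180
quoting, UTF-8, header always written; reading the CSV back reconstructs
every text and score. The HTML report is hand-emitted HTML5 (escaped, no
template engine) showing each field crop beside all readings; changed rows
are highlighted, missing crops render placeholders.

## Evaluation

Texts are normalized for scoring by deleting all non-ASCII characters and
ASCII punctuation (the ASCII set is the operative definition of
"punctuation"), lower-casing, and collapsing whitespace. A (sheet, field)
pair enters the similarity pool only if text is present on at least one
side; one-sided presence scores 0. Field-presence accuracy uses the same
denominator — pairs present on at least one side — a declared choice, since
counting both-absent pairs would inflate the metric with the many fields
rare labels omit. Aggregates (label-classification accuracy, field-presence
accuracy, similarity median and mean) are reported as percentages to one
decimal.

Detection metrics: per-class precision/recall/f1 at an IoU threshold with
greedy one-to-one matching by descending confidence. f1 at IoU 0.5 is the
primary surface; VOC-style average precision (precision-envelope
integration) and mAP50 are secondary utilities.

## Synthetic data

The generator emulates the *structure* of a digitized herbarium sheet, not
its appearance: a flat canvas with a bordered primary label in the lower
region (one text line per populated field) and a random subset of distractor
components laid out disjointly above. Taxon fields are drawn from the
bundled reference lists, the rest from templated generators (collectors,
Australian-style localities, DMS geolocations, dates 1880–2023). Field
presence follows fixed probabilities (taxon core always present,
infraspecific rank rare at 15%); writing classes are sampled at 30/30/25/12/3
percent for typewritten/printed/handwritten/combination/empty. Print-like
labels render in DejaVu Sans, script-like in DejaVu Serif italic (fonts
located through matplotlib, which always ships them) — visually distinct
without bundling font binaries.

The character noise model emulates OCR/HTR error modes: confusion-pair
substitutions (l/t, i/e, vowel swaps, rn→m, el↔le transpositions —
sufficient to generate the classic `Ahnfletia`-for-`Ahnfeltia` error),
doublings and deletions, each at a configurable rate; zero rates are the
identity. Misspellings are applied to the *printed* label text while the
clean reference name is kept as truth, so correction value can be measured
exactly. Everything — content, layout, pixels, noise — is deterministic
under a fixed seed.

What passing on synthetic sheets does **not** show: robustness to real image
noise, skew, fonts, handwriting variability, multilingual labels, or
detector/classifier error distributions of trained models. The synthetic
path validates the pipeline's logic (geometry, arbitration, correction,
scoring, reporting) and the exact contracts of its adapters; real-world
accuracy is a property of the plugged-in models.

## Problem sizes and defaults

The standard verification runs use 20 clean sheets for the end-to-end
identity check, 50 noisy labels at a 10% character-confusion rate for the
correction-value comparison, and the exhaustive similarity sweep over all
string pairs of length ≤ 6 on a three-letter alphabet (~1.2 M pairs) plus
randomized longer pairs — sizes at which every property is exercised while
the whole suite stays fast. Canvas size is 900×1200 px; all seeds are
explicit function arguments.

## Known limitations

- Reference lists are held in memory and scanned linearly per query; fine
  for national-list scale (10⁵–10⁶ names) per-field lookups but not indexed.
- The authority field gets no abbreviation normalization, so `A.S.George`
  vs `A. S. George` counts as a (close) correction rather than an exact hit.
- Rotated boxes and polygon masks are unsupported; boxes are axis-aligned.
- Text on non-primary-label components (annotation labels, swing tags,
  data written on the sheet) is detected but not recognized.
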