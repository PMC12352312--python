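"""Field formatting, Gestalt similarity and reference-list correction.

This is the arithmetic heart of the pipeline. Recognized text for the
family, genus, specific-epithet and authority fields is normalized and
cross-checked against reference name lists; the closest name under the
Gestalt (Ratcliff/Obershelp) similarity is substituted when it scores at
or above the user threshold (default 0.8). The per-field match scores also
arbitrate between the OCR and HTR engines for the remaining fields.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from statistics import fmean
from typing import Iterable, Mapping, Optional, Sequence

from .core import (
    CROSS_CHECKED_FIELDS,
    FieldClass,
    LabelClass,
    MatchResult,
    SpecimenRecord,
    TextCandidate,
)

_EDGE_STRIP = string.punctuation + string.whitespace

#: Label classes whose arbitration fallback prefers the HTR engine.
HTR_PREFERRED_CLASSES = frozenset({LabelClass.handwritten, LabelClass.combination})


def engine_preference(label_class: LabelClass) -> str:
    """Fallback engine role for a label writing type: ``"htr"`` or ``"ocr"``.

    Handwritten and combination ("mixed") labels prefer the HTR engine;
    typewritten, printed and empty labels prefer the OCR engine. The mapping
    is total over :class:`LabelClass`.
    """
    return "htr" if label_class in HTR_PREFERRED_CLASSES else "ocr"


def normalize_field(text: str, field: FieldClass) -> str:
    """Apply the per-field formatting rules.

    Family and genus: strip punctuation/whitespace from both ends, then
    title case. Specific epithet and infraspecific taxon: strip, then lower
    case. Every other field: edge whitespace stripped only.
    """
    if field in (FieldClass.family, FieldClass.genus):
        return text.strip(_EDGE_STRIP).title()
    if field in (FieldClass.species, FieldClass.infraspecific_taxon):
        return text.strip(_EDGE_STRIP).lower()
    return text.strip()


def _longest_match(a: str, b: str) -> tuple[int, int, int]:
    """Longest common substring of ``a`` and ``b``.

    Returns ``(i, j, k)``: ``a[i:i+k] == b[j:j+k]`` with ``k`` maximal;
    ties resolved to the smallest ``i``, then the smallest ``j``. Dynamic
    programming over one row of suffix-match lengths, O(len(a)*len(b)).
    """
    best_i = best_j = best_k = 0
    prev = [0] * (len(b) + 1)
    for i in range(len(a) - 1, -1, -1):
        cur = [0] * (len(b) + 1)
        ca = a[i]
        for j in range(len(b) - 1, -1, -1):
            if ca == b[j]:
                k = prev[j + 1] + 1
                cur[j] = k
                # >= : scanning i downward, so later (smaller) i wins ties;
                # scanning j downward makes smaller j win within a row.
                if k >= best_k:
                    best_i, best_j, best_k = i, j, k
        prev = cur
    return best_i, best_j, best_k


def _matched_chars(a: str, b: str) -> int:
    """Total characters matched by recursive longest-common-substring
    decomposition (the M of the Ratcliff/Obershelp statistic)."""
    stack = [(a, b)]
    total = 0
    while stack:
        x, y = stack.pop()
        if not x or not y:
            continue
        i, j, k = _longest_match(x, y)
        if k == 0:
            continue
        total += k
        stack.append((x[:i], y[:j]))
        stack.append((x[i + k :], y[j + k :]))
    return total


def gestalt_similarity(a: str, b: str) -> float:
    """Gestalt (Ratcliff/Obershelp) similarity: ``2 * M / (|a| + |b|)``.

    M counts the characters matched by recursively removing the longest
    common substring and matching the flanks on each side independently.
    Two empty strings are defined to be identical (similarity 1.0).
    """
    if not a and not b:
        return 1.0
    return 2.0 * _matched_chars(a, b) / (len(a) + len(b))


@dataclass
class ReferenceLists:
    """Ordered, duplicate-free reference name lists for the four
    cross-checked fields. List order is the tie-breaker in matching, so it
    is preserved exactly as read from the source files."""

    lists: dict[str, list[str]] = dc_field(default_factory=dict)

    VALID_NAMES = ("family", "genus", "species", "authority")

    def __post_init__(self) -> None:
        for name, names in self.lists.items():
            if name not in self.VALID_NAMES:
                raise ValueError(f"unknown reference list {name!r}")
            seen: set[str] = set()
            deduped = []
            for n in names:
                if n not in seen:
                    seen.add(n)
                    deduped.append(n)
            self.lists[name] = deduped

    def get(self, list_name: str) -> list[str]:
        if list_name not in self.VALID_NAMES:
            raise ValueError(f"unknown reference list {list_name!r}")
        return self.lists.get(list_name, [])

    @classmethod
    def from_files(cls, paths: Mapping[str, str | Path]) -> "ReferenceLists":
        """Read one-name-per-line UTF-8 files; ``#`` lines are comments."""
        lists = {}
        for name, path in paths.items():
            names = []
            for line in Path(path).read_text(encoding="utf-8").splitlines():
                line = line.strip()
                if line and not line.startswith("#"):
                    names.append(line)
            lists[name] = names
        return cls(lists)

    @classmethod
    def bundled_fixture(cls) -> "ReferenceLists":
        """Small fixture lists shipped with the package (test/demo scale;
        real use supplies full World Flora Online / national-list exports)."""
        from importlib import resources

        paths = {}
        for name in cls.VALID_NAMES:
            paths[name] = resources.files("sheetscribe.data") / f"{name}.txt"
        return cls.from_files(paths)


FIELD_TO_LIST = {
    FieldClass.family: "family",
    FieldClass.genus: "genus",
    FieldClass.species: "species",
    FieldClass.authority: "authority",
}


@dataclass(frozen=True)
class MatchConfig:
    threshold: float = 0.8
    enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError(f"threshold {self.threshold} outside (0, 1]")


def closest_match(
    query: str,
    list_name: str,
    refs: ReferenceLists,
    cfg: MatchConfig = MatchConfig(),
) -> MatchResult:
    """Correct ``query`` against one reference list.

    Exact hits (case-insensitive) score 1.0 and are left unchanged. Otherwise
    the reference name with the highest Gestalt similarity is substituted iff
    that similarity meets ``cfg.threshold``; ties are broken by list order
    (first name wins). Below threshold — or with matching disabled, or an
    empty query — the original text is kept with score 0.
    """
    names = refs.get(list_name)
    if not cfg.enabled or not query:
        return MatchResult(query=query, matched_name=None, score=0.0, changed=False)
    q = query.casefold()
    for name in names:
        if name.casefold() == q:
            return MatchResult(query=query, matched_name=name, score=1.0, changed=False)
    best_name: Optional[str] = None
    best_score = 0.0
    for name in names:
        s = gestalt_similarity(q, name.casefold())
        if s > best_score:  # strict: earlier list entries win ties
            best_score = s
            best_name = name
    if best_name is not None and best_score >= cfg.threshold:
        return MatchResult(
            query=query, matched_name=best_name, score=best_score, changed=True
        )
    return MatchResult(query=query, matched_name=None, score=0.0, changed=False)


def match_candidates(
    candidates: Sequence[TextCandidate],
    refs: ReferenceLists,
    cfg: MatchConfig = MatchConfig(),
) -> dict[str, dict[FieldClass, MatchResult]]:
    """Run :func:`closest_match` for every cross-checked candidate,
    grouped as engine_id -> field -> MatchResult."""
    out: dict[str, dict[FieldClass, MatchResult]] = {}
    for cand in candidates:
        if cand.field_class not in FIELD_TO_LIST:
            continue
        out.setdefault(cand.engine_id, {})[cand.field_class] = closest_match(
            cand.formatted_text, FIELD_TO_LIST[cand.field_class], refs, cfg
        )
    return out


def arbitration_score(matches: Mapping[FieldClass, MatchResult]) -> Optional[float]:
    """Arithmetic mean of an engine's match scores over the cross-checked
    fields it produced; None when there are none."""
    scores = [m.score for fc, m in matches.items() if fc in CROSS_CHECKED_FIELDS]
    if not scores:
        return None
    return fmean(scores)


def arbitrate(
    candidates: Sequence[TextCandidate],
    matches: Mapping[str, Mapping[FieldClass, MatchResult]],
    label_class: LabelClass,
    ocr_engine: str,
    htr_engine: str,
    threshold: float = 0.8,
) -> tuple[str, dict[FieldClass, str], list[str]]:
    """Pick the winning engine and the per-field chosen text.

    An engine wins outright when its mean match score over the detected
    cross-checked fields is strictly greater than the other's and at least
    one mean reaches ``threshold``. Otherwise (equal means, both means below
    threshold, or no cross-checked fields detected) handwritten/combination
    labels take the HTR engine and all other labels the OCR engine.

    Cross-checked fields always carry the winning engine's corrected text;
    every other field carries the winning engine's formatted text. Returns
    ``(engine_id, chosen texts, provenance notes)``.
    """
    notes: list[str] = []
    means = {
        eng: arbitration_score(matches.get(eng, {})) for eng in (ocr_engine, htr_engine)
    }
    m_ocr, m_htr = means[ocr_engine], means[htr_engine]
    winner: Optional[str] = None
    if m_ocr is not None and m_htr is not None:
        if m_ocr != m_htr and max(m_ocr, m_htr) >= threshold:
            winner = ocr_engine if m_ocr > m_htr else htr_engine
            notes.append(
                f"arbitration: {winner} wins on mean match score "
                f"({ocr_engine}={m_ocr:.3f}, {htr_engine}={m_htr:.3f})"
            )
    if winner is None:
        winner = htr_engine if engine_preference(label_class) == "htr" else ocr_engine
        notes.append(
            f"arbitration: no superior engine; label class "
            f"{label_class.value!r} falls back to {winner}"
        )
    chosen: dict[FieldClass, str] = {}
    for cand in candidates:
        if cand.engine_id != winner:
            continue
        text = cand.formatted_text
        match = matches.get(winner, {}).get(cand.field_class)
        if match is not None and match.changed and match.matched_name is not None:
            notes.append(
                f"corrected {cand.field_class.value}: {match.query!r} -> "
                f"{match.matched_name!r} ({match.score:.3f})"
            )
            text = match.matched_name
        chosen[cand.field_class] = text
    return winner, chosen, notes


def assign_scores(
    record: SpecimenRecord,
    matches: Mapping[FieldClass, MatchResult],
) -> SpecimenRecord:
    """Record match scores on the four cross-checked fields, in place.

    Only family, genus, species and authority ever carry a score (1.0 for
    an exact reference hit, the similarity in [threshold, 1) after a
    correction, 0.0 when nothing matched); no other field is scored.
    """
    for fc in CROSS_CHECKED_FIELDS:
        if fc in record.fields and fc in matches:
            record.fields[fc].match_score = matches[fc].score
    return record
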