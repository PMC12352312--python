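"""Correct misspelled taxon names against reference lists.

Builds the bundled fixture reference lists and runs the Gestalt
(Ratcliff/Obershelp) closest-match correction on classic label
misspellings. A score of 1.0 is an exact hit, 0.8-1.0 a correction, 0 no
match at the 80% threshold.
"""

from sheetscribe import ReferenceLists, closest_match

refs = ReferenceLists.bundled_fixture()

queries = [
    ("Ahnfletia", "genus"),        # misspelling of Ahnfeltia
    ("Odontitis", "genus"),        # misspelling of Odontites
    ("sisymbrifolium", "species"), # misspelling of sisymbriifolium
    ("serulata", "species"),       # ambiguous: sertulata vs serrulata tie
    ("Banksia", "genus"),          # exact hit
    ("Xyzabc", "genus"),           # nothing close
]

for query, list_name in queries:
    r = closest_match(query, list_name, refs)
    print(
        f"{query:>15} [{list_name:7}] -> "
        f"{r.matched_name or '(no match)':>15}  score={r.score:.3f}  "
        f"changed={r.changed}"
    )

print(
    "\nEach line shows the corrected name assigned to the field; "
    "scores below the 0.8 threshold leave the text unchanged with score 0."
)
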