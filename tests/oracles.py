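"""Independent brute-force oracle for the Gestalt similarity.

Deliberately naive: the longest common substring is found by enumerating
every start pair (smallest-i, then smallest-j tie-break, matching the
implementation's declared convention), and the decomposition recurses on
plain string slices. Shares no code with the package implementation.
"""


def brute_longest_common_substring(a: str, b: str) -> tuple[int, int, int]:
    best = (0, 0, 0)
    for i in range(len(a)):
        for j in range(len(b)):
            k = 0
            while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                k += 1
            if k > best[2]:
                best = (i, j, k)
    return best


def brute_matched_chars(a: str, b: str) -> int:
    i, j, k = brute_longest_common_substring(a, b)
    if k == 0:
        return 0
    return (
        k
        + brute_matched_chars(a[:i], b[:j])
        + brute_matched_chars(a[i + k :], b[j + k :])
    )


def brute_gestalt(a: str, b: str) -> float:
    if not a and not b:
        return 1.0
    return 2.0 * brute_matched_chars(a, b) / (len(a) + len(b))
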