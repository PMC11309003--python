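"""Low-level alignment primitives shared by the linkage modules.

Edit distance is unit-cost Levenshtein throughout: a substitution, an
inserted base, or a deleted base each count as one edit.  Ambiguity codes
(anything outside ACGT, e.g. N) never match anything, including another
ambiguity code, so windows containing N can only align by spending edits.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str, ambiguous_code: int) -> np.ndarray:
    """Encode a sequence as uint8, mapping non-ACGT to a sentinel byte.

    Query and target must use *different* sentinels so that N-vs-N never
    counts as a match.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    acgt = (arr == 65) | (arr == 67) | (arr == 71) | (arr == 84)
    arr[~acgt] = ambiguous_code
    return arr


def levenshtein(a: str, b: str) -> int:
    """Global unit-cost edit distance between two sequences."""
    qa = _encode(a, 1)
    qb = _encode(b, 2)
    n = qb.size
    prev = np.arange(n + 1, dtype=np.int64)
    idx = np.arange(n + 1)
    for i, ca in enumerate(qa, start=1):
        cand = np.minimum(prev[:-1] + (qb != ca), prev[1:] + 1)
        cur = np.empty(n + 1, dtype=np.int64)
        cur[0] = i
        cur[1:] = cand
        prev = np.minimum.accumulate(cur - idx) + idx
    return int(prev[-1])


def semiglobal_end_scores(query: str, target: str) -> np.ndarray:
    """Semi-global edit distances of `query` against windows of `target`.

    The whole query must be consumed; the alignment start and end inside the
    target are free.  Returns an int array `row` of length len(target)+1
    where row[j] is the minimum edit count over alignments ending exactly at
    target position j.  Vectorised over the target: the horizontal (gap in
    query) dependency is resolved with a min-plus prefix scan,
    D[i][j] = min_k<=j (T[k] + (j-k)) = j + cummin(T[k]-k).
    """
    q = _encode(query, 1)
    t = _encode(target, 2)
    n = t.size
    idx = np.arange(n + 1)
    prev = np.zeros(n + 1, dtype=np.int64)  # D[0][j] = 0: free start
    for ca in q:
        cand = np.minimum(prev[:-1] + (t != ca), prev[1:] + 1)
        cur = np.empty(n + 1, dtype=np.int64)
        cur[0] = prev[0] + 1
        cur[1:] = cand
        prev = np.minimum.accumulate(cur - idx) + idx
    return prev


def best_semiglobal_distance(query: str, target: str) -> int:
    """Minimum semi-global edit distance of query anywhere in target (+ strand)."""
    return int(semiglobal_end_scores(query, target).min())


def leftmost_start(query: str, target: str, end: int, dist: int) -> int:
    """Recover the leftmost alignment start for a semi-global hit.

    Given that some alignment of the full query ends at target position
    `end` with `dist` edits, the start lies in [end-m-dist, end-m+dist].
    The candidate window is tiny, so each candidate start is checked with a
    global edit distance.
    """
    m = len(query)
    lo = max(0, end - m - dist)
    hi = min(end, end - m + dist)
    for s in range(lo, hi + 1):
        if levenshtein(query, target[s:end]) == dist:
            return s
    raise AssertionError("no start consistent with reported distance")
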