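"""Semi-global pairwise DNA alignment.

Reads are compared with reference barcodes by optimal dynamic-programming
alignment in which gaps at either end of either sequence are free, matching
the behaviour of ``usearch_global``-style amplicon searches: a short merged
read may sit anywhere inside a longer reference (or overhang it) without
paying terminal-gap penalties, while internal indels and mismatches are
penalised.

Definitions used throughout the package:

* **score** — DP optimum under (match, mismatch, internal-gap) scoring with
  zero-cost terminal gaps.
* **identity** — matching columns divided by alignment columns, where columns
  are counted along the optimal path only (terminal-gap columns excluded,
  internal-gap columns included and counted as non-matches).
* **query coverage** — aligned (non-terminal-gap) query positions divided by
  query length.

Among co-optimal alignments a single canonical path is reported: the end cell
maximises (score, query index, target index) over the last DP row and column,
and traceback prefers diagonal over query-gap ("up") over target-gap ("left")
steps. ``N`` never matches any base, including another ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_MATCH = 2
DEFAULT_MISMATCH = -4
DEFAULT_GAP = -4


def encode(sequence: str) -> np.ndarray:
    """Encode an A/C/G/T/N string as an int8 array (N = 4)."""
    try:
        return np.fromiter(
            (_CODE[c] for c in sequence), dtype=np.int8, count=len(sequence)
        )
    except KeyError as exc:
        raise ValueError(f"sequence contains invalid character {exc}") from None


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentHit:
    """One accepted query↔reference alignment.

    Spans are 0-based half-open on the aligned orientation of the query (for
    minus-strand hits, coordinates refer to the reverse-complemented query).
    """

    reference_id: str
    identity: float
    query_coverage: float
    score: int
    query_span: tuple[int, int]
    reference_span: tuple[int, int]
    strand: str = "+"


@njit(cache=True)
def _semiglobal_kernel(q, t, match, mismatch, gap):  # pragma: no cover - numba
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            if qi == t[j - 1] and qi < 4:
                s = match
            else:
                s = mismatch
            best = H[i - 1, j - 1] + s
            v = H[i - 1, j] + gap
            if v > best:
                best = v
            v = H[i, j - 1] + gap
            if v > best:
                best = v
            H[i, j] = best
    # End cell: max score over last row and last column; ties prefer the
    # larger query index, then the larger target index.
    bs = np.int32(-2147483648)
    bi = -1
    bj = -1
    for j in range(m + 1):
        sc = H[n, j]
        if sc > bs or (sc == bs and (n > bi or (n == bi and j > bj))):
            bs = sc
            bi = n
            bj = j
    for i in range(n + 1):
        sc = H[i, m]
        if sc > bs or (sc == bs and (i > bi or (i == bi and m > bj))):
            bs = sc
            bi = i
            bj = m
    i = bi
    j = bj
    matches = 0
    cols = 0
    while i > 0 and j > 0:
        qi = q[i - 1]
        is_match = qi == t[j - 1] and qi < 4
        s = match if is_match else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            if is_match:
                matches += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
        cols += 1
    return bs, matches, cols, i, bi, j, bj


def semiglobal_align(
    query: str,
    target: str,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap: int = DEFAULT_GAP,
    reference_id: str = "",
    _query_enc: np.ndarray | None = None,
    _target_enc: np.ndarray | None = None,
) -> AlignmentHit:
    """Optimal free-end-gap alignment of ``query`` against ``target``."""
    q = encode(query) if _query_enc is None else _query_enc
    t = encode(target) if _target_enc is None else _target_enc
    if q.size == 0 or t.size == 0:
        raise ValueError("cannot align an empty sequence")
    score, matches, cols, qs, qe, ts, te = _semiglobal_kernel(
        q, t, match, mismatch, gap
    )
    identity = matches / cols if cols else 0.0
    coverage = (qe - qs) / q.size
    return AlignmentHit(
        reference_id=reference_id,
        identity=identity,
        query_coverage=coverage,
        score=int(score),
        query_span=(int(qs), int(qe)),
        reference_span=(int(ts), int(te)),
    )
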