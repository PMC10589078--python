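"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's numpy/numba code paths: plain-Python
dynamic programming, naive substring scanning and pairwise folding, written
from the definitions.
"""

from __future__ import annotations

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def semiglobal_oracle(query, target, match=2, mismatch=-4, gap=-4):
    """Textbook free-end-gap DP returning (score, identity, coverage).

    Follows the same canonical convention as the implementation: the end
    cell maximises (score, query index, target index) over the final row and
    column, and traceback prefers diagonal over up over left. N matches
    nothing.
    """
    q = [_CODE[c] for c in query]
    t = [_CODE[c] for c in target]
    n, m = len(q), len(t)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (q[i - 1] == t[j - 1] and q[i - 1] < 4) else mismatch
            H[i][j] = max(
                H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap
            )
    candidates = [(H[n][j], n, j) for j in range(m + 1)]
    candidates += [(H[i][m], i, m) for i in range(n + 1)]
    score, bi, bj = max(candidates)
    i, j = bi, bj
    matches = 0
    columns = 0
    while i > 0 and j > 0:
        is_match = q[i - 1] == t[j - 1] and q[i - 1] < 4
        s = match if is_match else mismatch
        if H[i][j] == H[i - 1][j - 1] + s:
            matches += is_match
            i -= 1
            j -= 1
        elif H[i][j] == H[i - 1][j] + gap:
            i -= 1
        else:
            j -= 1
        columns += 1
    identity = matches / columns if columns else 0.0
    coverage = (bi - i) / n
    return score, identity, coverage


def substring_offsets_oracle(needle: str, haystack: str) -> list[int]:
    """All offsets where needle matches haystack exactly; N matches nothing."""
    hits = []
    for off in range(len(haystack) - len(needle) + 1):
        ok = True
        for a, b in zip(needle, haystack[off:]):
            if a != b or a == "N":
                ok = False
                break
        if ok:
            hits.append(off)
    return hits


def lca_fold_oracle(lineages, lca_fn):
    """Pairwise left fold of a two-argument LCA over a lineage list."""
    acc = lineages[0]
    for lin in lineages[1:]:
        acc = lca_fn([acc, lin])
    return acc
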