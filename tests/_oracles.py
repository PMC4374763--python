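"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the dumbest correct method —
exhaustive dynamic programming, substring enumeration, all-pairs scans — so
agreement with the package implementation is evidence, not tautology.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices
from Bio.Seq import reverse_complement

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def needle_score(a: str, b: str, gap_open: float = 10.0,
                 gap_extend: float = 0.5) -> float:
    """Optimal global affine-gap alignment score with free end gaps.

    Internal gap of length L costs ``gap_open + gap_extend * L``; terminal
    gaps cost nothing (EMBOSS endweight=false semantics).  Plain O(nm)
    three-state dynamic program.
    """
    first = gap_open + gap_extend
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # free leading end gap
    for j in range(1, m + 1):
        Y[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = float(_BLOSUM62[a[i - 1], b[j - 1]])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - first)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - first)
    best = NEG
    for j in range(m + 1):  # free trailing gap in b
        best = max(best, M[n][j], X[n][j], Y[n][j])
    for i in range(n + 1):  # free trailing gap in a
        best = max(best, M[i][m], X[i][m], Y[i][m])
    return best


def best_repeat_bruteforce(a: str, b: str, min_length: int = 15,
                           max_mismatch_frac: float = 0.10):
    """Best equal-length substring pair by exhaustive extension.

    Returns ``(length, mismatches)`` of the longest qualifying pair (ties:
    fewest mismatches) or None.  Cubic; only for small windows.
    """
    best = None
    for i in range(len(a)):
        for j in range(len(b)):
            mism = 0
            max_len = min(len(a) - i, len(b) - j)
            for length in range(1, max_len + 1):
                if a[i + length - 1] != b[j + length - 1]:
                    mism += 1
                if length >= min_length and mism <= max_mismatch_frac * length:
                    key = (length, -mism)
                    if best is None or key > (best[0], -best[1]):
                        best = (length, mism)
    return best


def pcr_bruteforce(template: str, fwd: str, rev: str,
                   max_product: int) -> list[int]:
    """All products from exhaustive primer-site pairing on both strands."""
    products = []
    for left, right in ((fwd, reverse_complement(rev)),
                        (rev, reverse_complement(fwd))):
        for i in range(len(template)):
            if template[i : i + len(left)] != left:
                continue
            for j in range(i + len(left), len(template)):
                if template[j : j + len(right)] != right:
                    continue
                length = j + len(right) - i
                if length <= max_product:
                    products.append(length)
    return sorted(products)
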