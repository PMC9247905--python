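"""Independent oracles used to cross-check the implementation.

These deliberately share no code with the package: a Gotoh-style dynamic
program for local alignment scores written from the recurrences, a full
recursive enumerator over alignments for very short strings, and an
exhaustive scan for the coupling-threshold optimiser.
"""

from __future__ import annotations

import math


def gotoh_local_score(a: str, b: str, match: float = 1.0,
                      mismatch: float = 0.0, gap_open: float = -1.0,
                      gap_extend: float = -0.5) -> float:
    """Affine-gap Smith-Waterman score (gap of length L costs
    open + (L-1)*extend), computed with the textbook three-matrix DP."""
    n, m = len(a), len(b)
    NEG = -math.inf
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "X") else mismatch
            M[i][j] = s + max(0.0, M[i - 1][j - 1], Ix[i - 1][j - 1],
                              Iy[i - 1][j - 1])
            Ix[i][j] = max(M[i - 1][j] + gap_open, Ix[i - 1][j] + gap_extend)
            Iy[i][j] = max(M[i][j - 1] + gap_open, Iy[i][j - 1] + gap_extend)
            best = max(best, M[i][j])
    return best


def enumerate_local_score(a: str, b: str, match: float = 1.0,
                          mismatch: float = 0.0, gap_open: float = -1.0,
                          gap_extend: float = -0.5) -> float:
    """Exhaustive enumeration of every local alignment (tiny strings only):
    all substring pairs, all monotone match/gap paths between them."""
    best = 0.0

    def rec(i, j, end_i, end_j, score, last):
        nonlocal best
        if i == end_i and j == end_j:
            best = max(best, score)
            return
        if i < end_i and j < end_j:
            s = match if (a[i] == b[j] and a[i] != "X") else mismatch
            rec(i + 1, j + 1, end_i, end_j, score + s, "m")
        if i < end_i:
            cost = gap_extend if last == "x" else gap_open
            rec(i + 1, j, end_i, end_j, score + cost, "x")
        if j < end_j:
            cost = gap_extend if last == "y" else gap_open
            rec(i, j + 1, end_i, end_j, score + cost, "y")

    for i1 in range(len(a) + 1):
        for i2 in range(i1, len(a) + 1):
            for j1 in range(len(b) + 1):
                for j2 in range(j1, len(b) + 1):
                    if (i2 - i1) + (j2 - j1) == 0:
                        continue
                    rec(i1, j1, i2, j2, 0.0, None)
    return best


def scan_threshold(probabilities, truths) -> float:
    """Exhaustive scan over observed probabilities maximising TP/FP,
    infinite ratio for FP=0, lowest threshold on ties."""
    best_t, best_ratio = None, -math.inf
    for t in sorted(set(probabilities)):
        tp = sum(1 for p, tr in zip(probabilities, truths) if p >= t and tr)
        fp = sum(1 for p, tr in zip(probabilities, truths) if p >= t and not tr)
        if tp == 0:
            continue
        ratio = math.inf if fp == 0 else tp / fp
        if ratio > best_ratio:
            best_ratio, best_t = ratio, t
    return best_t
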