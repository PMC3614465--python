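"""Independent reference implementations used only by the tests.

Everything here is deliberately written in the most naive way that is
still correct — scalar Python loops, explicit threshold sweeps,
brute-force path enumeration — so that agreement with the package is
evidence, not tautology.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

NEG = float("-inf")


def affine_local_score(read: str, window: str, match=5, mismatch=-4,
                       gap_open=-10, gap_extend=0) -> int:
    """Plain scalar three-matrix affine-gap local DP; best score over
    alignments that end with an aligned pair (0 when none is positive)."""
    m, n = len(read), len(window)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    GR = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in read
    GF = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in reference
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if read[i - 1] == window[j - 1] and read[i - 1] in "ACGT" else mismatch
            prev = max(0, M[i - 1][j - 1], GR[i - 1][j - 1], GF[i - 1][j - 1])
            M[i][j] = prev + s
            GR[i][j] = max(M[i][j - 1] + gap_open, GR[i][j - 1] + gap_extend)
            GF[i][j] = max(M[i - 1][j] + gap_open, GF[i - 1][j] + gap_extend)
            best = max(best, M[i][j])
    return best


def enumerate_cooptimal(read: str, window: str, match=5, mismatch=-4,
                        gap_open=-10, gap_extend=0) -> set:
    """All co-optimal local alignments (as column tuples) by recursive
    traceback over a scalar DP — no cap, no vectorisation."""
    m, n = len(read), len(window)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    GR = [[NEG] * (n + 1) for _ in range(m + 1)]
    GF = [[NEG] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if read[i - 1] == window[j - 1] and read[i - 1] in "ACGT" else mismatch
            M[i][j] = max(0, M[i - 1][j - 1], GR[i - 1][j - 1], GF[i - 1][j - 1]) + s
            GR[i][j] = max(M[i][j - 1] + gap_open, GR[i][j - 1] + gap_extend)
            GF[i][j] = max(M[i - 1][j] + gap_open, GF[i - 1][j] + gap_extend)
    best = max((M[i][j] for i in range(m + 1) for j in range(n + 1)), default=0)
    if best <= 0:
        return set()

    out = set()

    def col(state, i, j):
        if state == "M":
            op = "=" if read[i - 1] == window[j - 1] and read[i - 1] in "ACGT" else "X"
            return (op, i - 1, j - 1)
        if state == "GR":
            return ("D", -1, j - 1)
        return ("I", i - 1, -1)

    def walk(state, i, j, suffix):
        suffix = (col(state, i, j),) + suffix
        if state == "M":
            s = match if read[i - 1] == window[j - 1] and read[i - 1] in "ACGT" else mismatch
            rest = M[i][j] - s
            if rest == 0:
                out.add(suffix)
            if M[i - 1][j - 1] == rest:
                walk("M", i - 1, j - 1, suffix)
            if GR[i - 1][j - 1] == rest:
                walk("GR", i - 1, j - 1, suffix)
            if GF[i - 1][j - 1] == rest:
                walk("GF", i - 1, j - 1, suffix)
        elif state == "GR":
            if M[i][j - 1] + gap_open == GR[i][j]:
                walk("M", i, j - 1, suffix)
            if GR[i][j - 1] + gap_extend == GR[i][j]:
                walk("GR", i, j - 1, suffix)
        else:
            if M[i - 1][j] + gap_open == GF[i][j]:
                walk("M", i - 1, j, suffix)
            if GF[i - 1][j] + gap_extend == GF[i][j]:
                walk("GF", i - 1, j, suffix)

    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if M[i][j] == best:
                walk("M", i, j, ())
    return out


def brute_force_cooptimal(read: str, window: str, match=5, mismatch=-4,
                          gap_open=-10, gap_extend=0) -> set:
    """True exhaustive search over every alignment path (tractable only
    for tiny instances).  An alignment starts and ends with an aligned
    column; a gap run in one sequence may not directly abut a gap run
    in the other."""
    m, n = len(read), len(window)
    results = []

    def score_of(cols):
        total = 0
        prev = None
        for op, _, _ in cols:
            if op == "=":
                total += match
            elif op == "X":
                total += mismatch
            else:
                total += gap_open if op != prev else gap_extend
            prev = op
        return total

    def extend(cols, i, j):
        # cols aligned so far; (i, j) next free indices
        if cols and cols[-1][0] in ("=", "X"):
            results.append(tuple(cols))
        last = cols[-1][0] if cols else None
        if i < m and j < n:
            op = "=" if read[i] == window[j] and read[i] in "ACGT" else "X"
            cols.append((op, i, j))
            extend(cols, i + 1, j + 1)
            cols.pop()
        if j < n and last != "I":  # gap in read consumes a window base
            cols.append(("D", -1, j))
            extend(cols, i, j + 1)
            cols.pop()
        if i < m and last != "D":  # gap in reference consumes a read base
            cols.append(("I", i, -1))
            extend(cols, i + 1, j)
            cols.pop()

    for i0 in range(m):
        for j0 in range(n):
            op = "=" if read[i0] == window[j0] and read[i0] in "ACGT" else "X"
            extend([(op, i0, j0)], i0 + 1, j0 + 1)

    if not results:
        return set()
    best = max(score_of(c) for c in results)
    if best <= 0:
        return set()
    return {c for c in results if score_of(c) == best}


def auc_pairwise(scores, labels) -> float:
    """AUC as the probability that a random positive outscores a random
    negative (ties count one half)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == -1]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def bep_sweep(scores, labels) -> float:
    """Break-even point by an explicit sweep with counting loops."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == -1]
    thresholds = sorted(set(scores)) + [float("inf")]
    best = None
    for t in thresholds:
        tpr = sum(1 for s in pos if s >= t) / len(pos)
        tnr = sum(1 for s in neg if s < t) / len(neg)
        gap = abs(tpr - tnr)
        if best is None or gap < best[0]:
            best = (gap, tpr)
    return best[1]


def pileup_bruteforce(reads, start, end):
    """O(reads x positions) depth count: reads as (start, end) pairs."""
    depth = [0] * (end - start)
    for r_start, r_end in reads:
        for pos in range(start, end):
            if r_start <= pos < r_end:
                depth[pos - start] += 1
    return depth


def pca_eigh_oracle(entries: np.ndarray, p: int):
    """Column-centred PCA via the explicit strain covariance matrix and
    a symmetric eigen-decomposition (different route than SVD)."""
    X = entries.astype(float)
    Xc = X - X.mean(axis=0, keepdims=True)
    cov = Xc @ Xc.T  # strain-by-strain scatter
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0, None)
    coords = vecs[:, :p] * np.sqrt(vals[:p])
    frac = vals / vals.sum()
    return coords, frac
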