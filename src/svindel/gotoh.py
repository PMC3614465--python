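"""Affine-gap local alignment (Gotoh) with co-optimal traceback enumeration.

This is the second mapping pass of the split-read pipeline: the unmapped
mate of a mapped-unmapped read pair is realigned against a reference
window.  An indel announces itself as a long gap run in the best local
alignment — a gap run in the read is evidence for a deletion, a gap run
in the reference is evidence for an insertion.

The dynamic program is the classic three-state formulation (one matrix
for alignments ending in an aligned pair, one per gap direction) run in
O(mn) time.  Because the default gap-extension score is zero, rows are
vectorised with a running-maximum trick, which keeps realignment of
thousands of reads against 5 kb windows cheap.

Alignments here always begin and end with an aligned column: a local
alignment that started or ended inside a gap could always be trimmed
without losing score, and an indel signature must be bracketed by
aligned read fragments anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "ScoringScheme",
    "LocalAlignment",
    "IndelSignature",
    "align_local",
    "passes_penalty_filter",
    "extract_signatures",
]

# column operations: aligned match, aligned mismatch, gap in the read
# (reference base against nothing -> deletion evidence), gap in the
# reference (read base against nothing -> insertion evidence)
OP_MATCH = "="
OP_MISMATCH = "X"
OP_GAP_READ = "D"
OP_GAP_REF = "I"

_NEG = -(10**9)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores and the penalty budget for near-optimal filtering.

    Defaults are the nucleotide scores of the NUC4.2 matrix reduced to
    match/mismatch (+5 / -4), affine gaps that cost 10 to open and
    nothing to extend, and an accumulated-penalty budget of 30 which
    admits up to 7 mismatches (7*4 = 28) or 3 gap openings (3*10 = 30).
    """

    match: int = 5
    mismatch: int = -4
    gap_open: int = -10
    gap_extend: int = 0
    max_penalty: int = 30

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0:
            raise ValueError("mismatch score must be negative")
        if self.gap_open >= 0:
            raise ValueError("gap-open score must be negative")
        if self.gap_extend > 0:
            raise ValueError("gap-extend score must be <= 0")
        if self.max_penalty < 0:
            raise ValueError("max-penalty must be non-negative")


@dataclass(frozen=True)
class LocalAlignment:
    """One local alignment of a read inside a reference window.

    ``columns`` is a tuple of ``(op, read_index, ref_index)`` triples in
    left-to-right order; the index not consumed by a gap column is -1.
    Intervals are 0-based half-open on the read and on the window.
    """

    columns: tuple[tuple[str, int, int], ...]
    score: int
    read_interval: tuple[int, int]
    ref_interval: tuple[int, int]
    n_mismatch: int
    n_gap_open: int

    @staticmethod
    def from_columns(
        columns: tuple[tuple[str, int, int], ...], scheme: ScoringScheme
    ) -> "LocalAlignment":
        n_match = sum(1 for op, _, _ in columns if op == OP_MATCH)
        n_mismatch = sum(1 for op, _, _ in columns if op == OP_MISMATCH)
        n_gap_open = 0
        n_gap_cols = 0
        prev = None
        for op, _, _ in columns:
            if op in (OP_GAP_READ, OP_GAP_REF):
                n_gap_cols += 1
                if op != prev:
                    n_gap_open += 1
            prev = op
        score = (
            scheme.match * n_match
            + scheme.mismatch * n_mismatch
            + scheme.gap_open * n_gap_open
            + scheme.gap_extend * (n_gap_cols - n_gap_open)
        )
        read_idx = [i for _, i, _ in columns if i >= 0]
        ref_idx = [j for _, _, j in columns if j >= 0]
        return LocalAlignment(
            columns=columns,
            score=score,
            read_interval=(read_idx[0], read_idx[-1] + 1),
            ref_interval=(ref_idx[0], ref_idx[-1] + 1),
            n_mismatch=n_mismatch,
            n_gap_open=n_gap_open,
        )


@dataclass(frozen=True)
class IndelSignature:
    """A single read's indel evidence: one qualifying gap run.

    ``ref_position`` is the 0-based offset inside the alignment window
    of the first deleted base (deletions) or of the reference base
    before which the new sequence is inserted (insertions).
    """

    kind: str  # "deletion" | "insertion"
    ref_position: int
    length: int
    left_fragment_len: int
    right_fragment_len: int
    inserted_sequence: str = ""
    source_read_id: str = ""
    alignment_score: int = 0


def _encode(seq: str) -> np.ndarray:
    """Map bases to integer codes; anything not A/C/G/T (incl. N) scores
    as a mismatch against everything, itself included."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


def _dp_matrices(
    rcodes: np.ndarray, wcodes: np.ndarray, scheme: ScoringScheme
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill the three Gotoh matrices.

    M[i, j]  — best alignment ending with read[i-1] aligned to window[j-1]
    Gr[i, j] — best alignment ending with a gap-in-read column that
               consumes window[j-1]
    Gf[i, j] — best alignment ending with a gap-in-reference column that
               consumes read[i-1]
    """
    m, n = len(rcodes), len(wcodes)
    go, ge = scheme.gap_open, scheme.gap_extend
    M = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    Gr = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    Gf = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    jidx = np.arange(1, n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        ri = rcodes[i - 1]
        s = np.where((wcodes == ri) & (ri >= 0), scheme.match, scheme.mismatch)
        prev_best = np.maximum(
            np.maximum(M[i - 1, :-1], Gr[i - 1, :-1]),
            np.maximum(Gf[i - 1, :-1], 0),
        )
        M[i, 1:] = prev_best + s
        Gf[i, 1:] = np.maximum(M[i - 1, 1:] + go, Gf[i - 1, 1:] + ge)
        # Gr has an intra-row dependency; with the substitution
        # B[j] = Gr[i, j] - ge*j it becomes a running maximum.
        c = M[i, :-1] + go - ge * jidx
        Gr[i, 1:] = np.maximum.accumulate(c) + ge * jidx
    return M, Gr, Gf


def _enumerate_tracebacks(
    M: np.ndarray,
    Gr: np.ndarray,
    Gf: np.ndarray,
    rcodes: np.ndarray,
    wcodes: np.ndarray,
    scheme: ScoringScheme,
    best: int,
    cap: Optional[int],
) -> Optional[list[tuple[tuple[str, int, int], ...]]]:
    """Depth-first enumeration of every traceback achieving ``best``.

    Returns None when more than ``cap`` co-optimal alignments exist
    (the caller treats the read as ambiguous).  Predecessors are
    explored in a fixed order (aligned, gap-in-read, gap-in-reference)
    so the enumeration order is deterministic.
    """
    go, ge = scheme.gap_open, scheme.gap_extend
    ends = np.argwhere(M == best)
    results: list[tuple[tuple[str, int, int], ...]] = []
    for end_i, end_j in ends:
        # backtracking DFS; the shared path list is pushed/popped
        path: list[tuple[str, int, int]] = []

        def preds(state: str, i: int, j: int) -> Iterator[tuple[str, int, int]]:
            if state == "M":
                s = (
                    scheme.match
                    if rcodes[i - 1] == wcodes[j - 1] and rcodes[i - 1] >= 0
                    else scheme.mismatch
                )
                rest = M[i, j] - s
                if rest == 0:
                    yield ("start", i - 1, j - 1)
                if M[i - 1, j - 1] == rest and rest > _NEG // 2:
                    yield ("M", i - 1, j - 1)
                if Gr[i - 1, j - 1] == rest and rest > _NEG // 2:
                    yield ("Gr", i - 1, j - 1)
                if Gf[i - 1, j - 1] == rest and rest > _NEG // 2:
                    yield ("Gf", i - 1, j - 1)
            elif state == "Gr":
                v = Gr[i, j]
                if M[i, j - 1] + go == v:
                    yield ("M", i, j - 1)
                if Gr[i, j - 1] + ge == v and Gr[i, j - 1] > _NEG // 2:
                    yield ("Gr", i, j - 1)
            else:  # Gf
                v = Gf[i, j]
                if M[i - 1, j] + go == v:
                    yield ("M", i - 1, j)
                if Gf[i - 1, j] + ge == v and Gf[i - 1, j] > _NEG // 2:
                    yield ("Gf", i - 1, j)

        def column(state: str, i: int, j: int) -> tuple[str, int, int]:
            if state == "M":
                op = (
                    OP_MATCH
                    if rcodes[i - 1] == wcodes[j - 1] and rcodes[i - 1] >= 0
                    else OP_MISMATCH
                )
                return (op, i - 1, j - 1)
            if state == "Gr":
                return (OP_GAP_READ, -1, j - 1)
            return (OP_GAP_REF, i - 1, -1)

        stack: list[tuple[Iterator[tuple[str, int, int]], bool]] = []
        state, i, j = "M", int(end_i), int(end_j)
        path.append(column(state, i, j))
        stack.append((preds(state, i, j), True))
        while stack:
            it, _pushed = stack[-1]
            nxt = next(it, None)
            if nxt is None:
                stack.pop()
                path.pop()
                continue
            nstate, ni, nj = nxt
            if nstate == "start":
                results.append(tuple(reversed(path)))
                if cap is not None and len(results) > cap:
                    return None
                continue
            path.append(column(nstate, ni, nj))
            stack.append((preds(nstate, ni, nj), True))
    return results


def align_local(
    read: str,
    window: str,
    scheme: ScoringScheme = ScoringScheme(),
    max_alignments: Optional[int] = 10,
) -> list[LocalAlignment]:
    """All co-optimal local alignments of ``read`` inside ``window``.

    Every traceback achieving the maximum local score is returned,
    deduplicated and sorted deterministically.  A read with more than
    ``max_alignments`` co-optimal placements is treated as hopelessly
    ambiguous and yields an empty list; pass ``max_alignments=None``
    to enumerate exhaustively.  Returns an empty list when no positive-
    scoring alignment exists.
    """
    if not read or not window:
        raise ValueError("read and window must be non-empty")
    rcodes = _encode(read)
    wcodes = _encode(window)
    M, Gr, Gf = _dp_matrices(rcodes, wcodes, scheme)
    best = int(M.max())
    if best <= 0:
        return []
    column_sets = _enumerate_tracebacks(
        M, Gr, Gf, rcodes, wcodes, scheme, best, max_alignments
    )
    if column_sets is None:
        return []
    unique = sorted(set(column_sets))
    return [LocalAlignment.from_columns(cols, scheme) for cols in unique]


def passes_penalty_filter(
    aln: LocalAlignment, scheme: ScoringScheme = ScoringScheme()
) -> bool:
    """Accumulated-penalty filter on a near-best alignment.

    An alignment is kept while its accumulated error cost — mismatches
    at ``|mismatch|`` points each plus gap openings at ``|gap_open|``
    points each — stays within ``max_penalty``.  With the default
    scheme this admits up to 7 mismatches or up to 3 gap openings.
    """
    penalty = (-scheme.mismatch) * aln.n_mismatch + (-scheme.gap_open) * aln.n_gap_open
    return penalty <= scheme.max_penalty


def extract_signatures(
    aln: LocalAlignment,
    min_gap_run: int = 2,
    min_fragment: int = 8,
    read_id: str = "",
    read: str = "",
) -> list[IndelSignature]:
    """Indel signatures from the gap runs of one alignment.

    A run of at least ``min_gap_run`` consecutive gap columns in the
    read is a deletion signature (length = reference bases spanned); a
    run in the reference is an insertion signature (length = read bases
    in the run, with the inserted sequence taken from ``read``).  Runs
    whose flanking read fragments are shorter than ``min_fragment``
    bases are discarded: short flanks align promiscuously and carry no
    placement information.
    """
    cols = aln.columns
    # run-length encode the column ops
    runs: list[tuple[str, int, int]] = []  # (op-class, start-col, end-col)
    k = 0
    while k < len(cols):
        op = cols[k][0]
        cls = op if op in (OP_GAP_READ, OP_GAP_REF) else "A"
        k2 = k
        while k2 < len(cols):
            op2 = cols[k2][0]
            cls2 = op2 if op2 in (OP_GAP_READ, OP_GAP_REF) else "A"
            if cls2 != cls:
                break
            k2 += 1
        runs.append((cls, k, k2))
        k = k2
    read_consumed = np.cumsum([1 if c[1] >= 0 else 0 for c in cols])
    total_read = int(read_consumed[-1]) if len(cols) else 0
    out: list[IndelSignature] = []
    for cls, a, b in runs:
        if cls == "A":
            continue
        run_len = b - a
        if run_len < min_gap_run:
            continue
        left = int(read_consumed[a - 1]) if a > 0 else 0
        right = total_read - int(read_consumed[b - 1])
        if left < min_fragment or right < min_fragment:
            continue
        if cls == OP_GAP_READ:
            ref_pos = cols[a][2]
            out.append(
                IndelSignature(
                    kind="deletion",
                    ref_position=ref_pos,
                    length=run_len,
                    left_fragment_len=left,
                    right_fragment_len=right,
                    source_read_id=read_id,
                    alignment_score=aln.score,
                )
            )
        else:
            # insertion point: the window base aligned immediately after
            # the run (runs at the alignment boundary never qualify
            # because a flank would be empty)
            next_ref = cols[b][2] if b < len(cols) else -1
            if next_ref < 0:
                continue
            ins_seq = ""
            if read:
                ins_seq = "".join(
                    read[c[1]] for c in cols[a:b] if c[1] >= 0
                )
            out.append(
                IndelSignature(
                    kind="insertion",
                    ref_position=next_ref,
                    length=run_len,
                    left_fragment_len=left,
                    right_fragment_len=right,
                    inserted_sequence=ins_seq,
                    source_read_id=read_id,
                    alignment_score=aln.score,
                )
            )
    return out
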