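"""Cohort-level analysis of classified indel calls.

Positively classified indels from many strains are merged (identical
or slightly shifted calls of the same length become one cohort indel),
encoded into a strains x indels matrix with +1 for a carried deletion,
-1 for a carried insertion and 0 for absence, and summarised by PCA:
the eigenvectors of the strain covariance of such a genotype matrix
recover population structure.  Two per-indel rules are also applied:
the whole-gene-loss call from unique-coverage profiles, and the
reading-frame effect of coding indels.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StrainCall",
    "CohortIndel",
    "IndelMatrix",
    "PCAResult",
    "merge_across_strains",
    "build_matrix",
    "pca",
    "classify_gene_loss",
    "annotate_frame_effect",
]

DEFAULT_MERGE_SHIFT = 10


@dataclass(frozen=True)
class StrainCall:
    """One positively classified indel in one strain."""

    strain: str
    chrom: str
    start: int
    length: int
    kind: str  # "deletion" | "insertion"


@dataclass
class CohortIndel:
    chrom: str
    start: int  # representative start: median of member starts
    length: int
    kind: str
    carriers: frozenset

    @property
    def frequency(self) -> int:
        return len(self.carriers)


@dataclass
class IndelMatrix:
    strains: list[str]
    indels: list[CohortIndel]
    entries: np.ndarray  # (M strains, N indels) in {1, -1, 0}

    def decode_carriers(self, j: int) -> frozenset:
        col = self.entries[:, j]
        return frozenset(s for s, v in zip(self.strains, col) if v != 0)


@dataclass
class PCAResult:
    coordinates: np.ndarray  # (M, p)
    explained_variance: np.ndarray  # fractions over all components


def merge_across_strains(
    calls: Iterable[StrainCall], merge_shift: int = DEFAULT_MERGE_SHIFT
) -> list[CohortIndel]:
    """Combine identical or few-bp-shifted same-length calls.

    Within each (chrom, kind, length) group, calls whose starts differ
    by at most ``merge_shift`` are chained by single linkage; each
    chain becomes one cohort indel whose representative start is the
    median member start.
    """
    groups: dict[tuple[str, str, int], list[StrainCall]] = {}
    for call in calls:
        groups.setdefault((call.chrom, call.kind, call.length), []).append(call)
    merged: list[CohortIndel] = []
    for (chrom, kind, length), members in groups.items():
        members.sort(key=lambda c: (c.start, c.strain))
        cluster: list[StrainCall] = []
        for call in members:
            if cluster and call.start - cluster[-1].start > merge_shift:
                merged.append(_finish_cluster(chrom, kind, length, cluster))
                cluster = []
            cluster.append(call)
        if cluster:
            merged.append(_finish_cluster(chrom, kind, length, cluster))
    merged.sort(key=lambda m: (m.chrom, m.start, m.kind, m.length))
    return merged


def _finish_cluster(
    chrom: str, kind: str, length: int, cluster: list[StrainCall]
) -> CohortIndel:
    rep = int(statistics.median(c.start for c in cluster))
    return CohortIndel(
        chrom=chrom,
        start=rep,
        length=length,
        kind=kind,
        carriers=frozenset(c.strain for c in cluster),
    )


def build_matrix(
    cohort: Sequence[CohortIndel], strains: Sequence[str]
) -> IndelMatrix:
    """Strains x non-private indels, entries +1 / -1 / 0.

    Private indels (carried by a single strain) are dropped; a carried
    deletion is encoded +1, a carried insertion -1, absence 0.
    """
    kept = [ind for ind in cohort if ind.frequency >= 2]
    strains = list(strains)
    idx = {s: i for i, s in enumerate(strains)}
    entries = np.zeros((len(strains), len(kept)), dtype=np.int8)
    for j, ind in enumerate(kept):
        value = 1 if ind.kind == "deletion" else -1
        for s in ind.carriers:
            if s in idx:
                entries[idx[s], j] = value
    return IndelMatrix(strains=strains, indels=kept, entries=entries)


def pca(matrix: IndelMatrix, p: int = 2) -> PCAResult:
    """Principal components of the strain covariance.

    Columns (indels) are mean-centred — no variance scaling — and the
    strain-by-strain covariance is eigen-decomposed via SVD.  The
    coordinates of strain i on component c are returned for the first
    p components; explained-variance fractions cover all components
    and sum to one.
    """
    M, N = matrix.entries.shape
    if M < 2 or N < 1:
        raise ValueError("need at least 2 strains and 1 indel for PCA")
    if p > min(M, N):
        logger.warning("p=%d clipped to min(M, N)=%d", p, min(M, N))
        p = min(M, N)
    X = matrix.entries.astype(float)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    coords = U * S
    total = float((S**2).sum())
    if total == 0:
        frac = np.zeros_like(S)
    else:
        frac = S**2 / total
    return PCAResult(coordinates=coords[:, :p], explained_variance=frac)


def classify_gene_loss(
    deletion_interval: tuple[int, int],
    gene_interval: tuple[int, int],
    within_umr_depth: np.ndarray,
    left_flank_umr_depth: np.ndarray,
    right_flank_umr_depth: np.ndarray,
    min_zero_within: float = 0.9,
    min_covered_flank: float = 0.9,
) -> tuple[bool, str]:
    """Whole-gene-loss call for a deletion spanning a gene.

    True iff the deletion covers the entire gene, at least 90% of the
    positions inside the deletion have zero unique-read depth, and at
    least 90% of the positions of each deletion-length-sized flank are
    covered by unique reads.  Flank arrays may be shorter when clipped
    at chromosome ends; the thresholds apply proportionally.
    """
    d_start, d_end = deletion_interval
    g_start, g_end = gene_interval
    if not (d_start <= g_start and g_end <= d_end):
        return False, "deletion does not span the entire gene"
    within = np.asarray(within_umr_depth)
    if within.size == 0:
        return False, "empty deletion interval"
    if float(np.mean(within == 0)) < min_zero_within:
        return False, "unique coverage present inside the deletion"
    for name, flank in (("left", left_flank_umr_depth), ("right", right_flank_umr_depth)):
        flank = np.asarray(flank)
        if flank.size == 0 or float(np.mean(flank > 0)) < min_covered_flank:
            return False, f"insufficient unique coverage in the {name} flank"
    return True, "gene loss"


def annotate_frame_effect(
    indel_start: int,
    indel_end: int,
    length: int,
    cds_intervals: Sequence[tuple[int, int]],
) -> str:
    """'in-frame' / 'frameshift' / 'non-coding' for a single indel.

    An indel overlapping a coding interval keeps the reading frame iff
    its length is divisible by 3.  Each indel is judged alone, without
    considering possibly compensating nearby variants.
    """
    lo, hi = indel_start, max(indel_end, indel_start + 1)
    overlaps = any(lo < c_end and c_start < hi for c_start, c_end in cds_intervals)
    if not overlaps:
        return "non-coding"
    return "in-frame" if length % 3 == 0 else "frameshift"
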