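"""Alignment features for candidate classification.

Each indel candidate is summarised by a fixed-order real vector built
from the first-pass alignments around it and from its own supporting
split reads.  Deletions get 17 features in four groups, insertions the
13 features of groups 2-4 (coverage *inside* an insertion point is not
defined), and the baseline representation ``f1`` is the bare split-read
support count.

Feature groups
--------------
1. (deletions only) uniquely mapped (UMR) and non-uniquely mapped
   (N-UMR) reads overlapping the deleted interval — a true deletion
   should show no unique coverage inside.
2. UMR/N-UMR counts in 60 bp flanks on either side, approximately one
   read length, representing local coverage.
3. Concordance of single-position variants (SPVs: SNPs plus short
   indels expanded position-wise) between the first mapping pass and
   the split-read alignments — do the flanking first-pass reads and the
   split reads come from the same haplotype?
4. General attributes: length, support, distinct anchor positions,
   mean accumulated alignment penalty.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .alignio import AlignedRead, AlignmentSet, ReferenceGenome
from .candidates import IndelCandidate

logger = logging.getLogger(__name__)

__all__ = [
    "PileupProfile",
    "LabeledFeatureVector",
    "DELETION_FEATURES",
    "INSERTION_FEATURES",
    "pileup",
    "call_first_pass_spvs",
    "split_read_spvs",
    "extract_features",
    "f1_vector",
    "write_features_tsv",
    "read_features_tsv",
]

DEFAULT_FLANK = 60

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

DELETION_FEATURES = [
    # group 1 — within-deletion coverage (deletions only)
    "n_umr_within",
    "n_numr_within",
    "frac_zero_umr_within",
    "ratio_umr_within_to_flank",
    # group 2 — flank coverage
    "n_umr_up",
    "n_umr_down",
    "n_numr_up",
    "n_numr_down",
    # group 3 — SPV concordance between mapping passes
    "n_spv_concordant",
    "n_spv_first_only",
    "n_spv_split_only",
    "n_spv_discordant",
    "frac_concordant",
    # group 4 — general attributes
    "indel_length",
    "n_support",
    "n_distinct_anchor_positions",
    "mean_penalty",
]
INSERTION_FEATURES = DELETION_FEATURES[4:]
assert len(DELETION_FEATURES) == 17 and len(INSERTION_FEATURES) == 13


@dataclass
class PileupProfile:
    """Per-position UMR and N-UMR read depth over an interval."""

    chrom: str
    start: int
    end: int
    umr_depth: np.ndarray
    numr_depth: np.ndarray


@dataclass
class LabeledFeatureVector:
    candidate_id: str
    kind: str  # "deletion" | "insertion"
    feature_names: list[str]
    values: np.ndarray
    label: int = 0  # +1 / -1 / 0 (unlabeled)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.feature_names):
            raise ValueError("feature names and values differ in length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.candidate_id}: non-finite feature values")


def pileup(
    alignments: AlignmentSet, chrom: str, start: int, end: int
) -> PileupProfile:
    """Depth profile over [start, end), split by read uniqueness.

    Every placement of an overlapping read adds one to the depth of the
    positions it spans; the read's UMR/N-UMR call decides which array
    it contributes to.
    """
    if start < 0:
        logger.warning("pileup interval clipped at chromosome start")
        start = 0
    n = max(0, end - start)
    umr = np.zeros(n, dtype=np.int64)
    numr = np.zeros(n, dtype=np.int64)
    for read in alignments.overlapping(chrom, start, end):
        lo = max(read.start, start) - start
        hi = min(read.end, end) - start
        if alignments.is_umr(read):
            umr[lo:hi] += 1
        else:
            numr[lo:hi] += 1
    return PileupProfile(chrom=chrom, start=start, end=end, umr_depth=umr, numr_depth=numr)


def _walk_cigar(read: AlignedRead):
    """Yield (op, ref_pos, read_pos, length) per cigar run."""
    ref = read.start
    qry = 0
    for m in _CIGAR_RE.finditer(read.cigar):
        length, op = int(m.group(1)), m.group(2)
        yield op, ref, qry, length
        if op in "M=XDN":
            ref += length
        if op in "M=XIS":
            qry += length
    if ref != read.end:
        raise ValueError(
            f"{read.read_id}: cigar consumes {ref - read.start} reference bases, "
            f"expected {read.end - read.start}"
        )


def call_first_pass_spvs(
    alignments: AlignmentSet,
    genome: ReferenceGenome,
    chrom: str,
    start: int,
    end: int,
    min_reads: int = 2,
) -> set[tuple[int, str]]:
    """Majority-vote single-position variants from first-pass reads.

    A position inside [start, end) yields an SPV when at least
    ``min_reads`` reads overlap it and a strict majority of them carry
    the same non-reference allele.  Short first-pass indels are
    expanded to consecutive positions: every deleted base becomes
    ``(pos, "-")`` and an insertion marks ``(pos, "+")`` at the base
    following the insertion point.
    """
    start = max(0, start)
    end = min(len(genome.sequences[chrom]), end)
    n = end - start
    if n <= 0:
        return set()
    coverage = np.zeros(n, dtype=np.int64)
    allele_counts: dict[int, dict[str, int]] = {}
    ref_seq = genome.slice(chrom, start, end)

    def bump(pos: int, allele: str) -> None:
        if start <= pos < end:
            allele_counts.setdefault(pos, {})
            allele_counts[pos][allele] = allele_counts[pos].get(allele, 0) + 1

    for read in alignments.overlapping(chrom, start, end):
        lo = max(read.start, start) - start
        hi = min(read.end, end) - start
        coverage[lo:hi] += 1
        for op, ref, qry, length in _walk_cigar(read):
            if op in "M=X":
                for k in range(length):
                    pos = ref + k
                    if start <= pos < end:
                        base = read.sequence[qry + k]
                        if base != ref_seq[pos - start]:
                            bump(pos, base)
            elif op == "D":
                for k in range(length):
                    bump(ref + k, "-")
            elif op == "I":
                bump(ref, "+")
    spvs: set[tuple[int, str]] = set()
    for pos, counts in allele_counts.items():
        cov = coverage[pos - start]
        if cov < min_reads:
            continue
        allele, count = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        if 2 * count > cov:
            spvs.add((pos, allele))
    return spvs


def split_read_spvs(
    candidate: IndelCandidate, start: int, end: int
) -> set[tuple[int, str]]:
    """SPVs seen by the candidate's supporting split alignments inside
    [start, end): mismatch columns plus length-1 gap columns (gap runs
    long enough to be signatures are the indel itself, not SPVs)."""
    spvs: set[tuple[int, str]] = set()
    for rec in candidate.supporting:
        for pos, allele in rec.spvs:
            if start <= pos < end:
                spvs.add((pos, allele))
    return spvs


def _spv_concordance(
    first: set[tuple[int, str]], split: set[tuple[int, str]]
) -> tuple[int, int, int, int, float]:
    concordant = first & split
    first_pos = {p for p, _ in first}
    split_pos = {p for p, _ in split}
    conc_pos = {p for p, _ in concordant}
    discordant_pos = (first_pos & split_pos) - conc_pos
    n_first_only = sum(1 for p, _ in first if p not in split_pos)
    n_split_only = sum(1 for p, _ in split if p not in first_pos)
    union = len(first | split)
    frac = len(concordant) / union if union else 0.0
    return len(concordant), n_first_only, n_split_only, len(discordant_pos), frac


def extract_features(
    candidate: IndelCandidate,
    alignments: AlignmentSet,
    genome: ReferenceGenome,
    flank: int = DEFAULT_FLANK,
    candidate_id: Optional[str] = None,
) -> LabeledFeatureVector:
    """The f17 (deletion) or f13 (insertion) vector for one candidate."""
    if not candidate.supporting:
        raise ValueError(
            f"candidate {candidate.chrom}:{candidate.start} has no supporting "
            "alignments attached; it must come from this pipeline"
        )
    chrom = candidate.chrom
    chrom_len = len(genome.sequences[chrom])
    up = pileup(alignments, chrom, max(0, candidate.start - flank), candidate.start)
    down_anchor = candidate.end if candidate.kind == "deletion" else candidate.start
    down = pileup(alignments, chrom, down_anchor, min(chrom_len, down_anchor + flank))

    def n_reads(lo: int, hi: int, want_umr: bool) -> int:
        return sum(
            1
            for r in alignments.overlapping(chrom, lo, hi)
            if alignments.is_umr(r) == want_umr
        )

    n_umr_up = n_reads(up.start, up.end, True)
    n_numr_up = n_reads(up.start, up.end, False)
    n_umr_down = n_reads(down.start, down.end, True)
    n_numr_down = n_reads(down.start, down.end, False)

    vic_lo = candidate.start - flank
    vic_hi = (candidate.end if candidate.kind == "deletion" else candidate.start) + flank
    first = call_first_pass_spvs(alignments, genome, chrom, vic_lo, vic_hi)
    split = split_read_spvs(candidate, max(0, vic_lo), min(chrom_len, vic_hi))
    conc, first_only, split_only, discordant, frac = _spv_concordance(first, split)

    anchor_positions = {rec.anchor_start for rec in candidate.supporting}
    mean_penalty = float(
        np.mean([rec.penalty for rec in candidate.supporting])
    )
    common = [
        float(n_umr_up),
        float(n_umr_down),
        float(n_numr_up),
        float(n_numr_down),
        float(conc),
        float(first_only),
        float(split_only),
        float(discordant),
        frac,
        float(candidate.length),
        float(candidate.support),
        float(len(anchor_positions)),
        mean_penalty,
    ]
    cid = candidate_id or (
        f"{chrom}:{candidate.start + 1}:"
        f"{'DEL' if candidate.kind == 'deletion' else 'INS'}:{candidate.length}"
    )
    if candidate.kind == "deletion":
        within = pileup(alignments, chrom, candidate.start, candidate.end)
        n_umr_within = n_reads(candidate.start, candidate.end, True)
        n_numr_within = n_reads(candidate.start, candidate.end, False)
        npos = len(within.umr_depth)
        frac_zero = float(np.mean(within.umr_depth == 0)) if npos else 1.0
        ratio = n_umr_within / (1.0 + 0.5 * (n_umr_up + n_umr_down))
        values = [
            float(n_umr_within),
            float(n_numr_within),
            frac_zero,
            ratio,
        ] + common
        names = DELETION_FEATURES
    else:
        values = common
        names = INSERTION_FEATURES
    return LabeledFeatureVector(
        candidate_id=cid, kind=candidate.kind, feature_names=list(names), values=values
    )


def f1_vector(
    candidate: IndelCandidate, candidate_id: Optional[str] = None
) -> LabeledFeatureVector:
    """The support-count-only baseline representation."""
    cid = candidate_id or (
        f"{candidate.chrom}:{candidate.start + 1}:"
        f"{'DEL' if candidate.kind == 'deletion' else 'INS'}:{candidate.length}"
    )
    return LabeledFeatureVector(
        candidate_id=cid,
        kind=candidate.kind,
        feature_names=["n_support"],
        values=[float(candidate.support)],
    )


def write_features_tsv(
    vectors: list[LabeledFeatureVector], path: str, header_lines: Iterable[str] = ()
) -> None:
    """Feature table: candidate id, type, named features, label.

    This single format serves both as the training corpus (label +-1)
    and as prediction input (label NA).
    """
    if not vectors:
        raise ValueError("no feature vectors to write")
    names = vectors[0].feature_names
    for v in vectors:
        if v.feature_names != names:
            raise ValueError("mixed feature sets in one table")
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(["candidate_id", "type"] + names + ["label"]) + "\n")
        for v in vectors:
            label = str(v.label) if v.label in (1, -1) else "NA"
            fh.write(
                "\t".join(
                    [v.candidate_id, v.kind]
                    + [repr(float(x)) for x in v.values]
                    + [label]
                )
                + "\n"
            )


def read_features_tsv(path: str) -> list[LabeledFeatureVector]:
    df = pd.read_csv(path, sep="\t", comment="#")
    names = [c for c in df.columns if c not in ("candidate_id", "type", "label")]
    out = []
    for _, row in df.iterrows():
        label = 0 if pd.isna(row["label"]) else int(row["label"])
        out.append(
            LabeledFeatureVector(
                candidate_id=str(row["candidate_id"]),
                kind=str(row["type"]),
                feature_names=names,
                values=row[names].to_numpy(dtype=float),
                label=label,
            )
        )
    return out
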