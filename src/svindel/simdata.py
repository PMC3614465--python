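"""Fully synthetic, truth-labeled inputs for the split-read pipeline.

The generator emulates the study conditions the caller is built for:
a random reference chromosome (optionally containing a duplicated
segment to create repetitive context), a donor genome that diverges
from it by implanted deletions and short insertions, FR paired-end
reads with Gaussian insert sizes and optional per-base errors, and a
first-pass mapper that places each read at its truth-projected
position and declares it mapped only within a mismatch/gap tolerance.
Reads that straddle an indel junction exceed that tolerance, so their
mapped partners become the mapped-unmapped pairs (MURs) the realigner
consumes.  Reads from the duplicated segment are reported with both
placements, producing non-uniquely mapped reads and — through multi-
placed anchors — the shifted false candidates the classifier must
learn to reject.

What this emulation deliberately leaves out: base-quality models, PCR
duplicates, chimeric fragments, and a genome-wide mapping search.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pysam

from .alignio import ReferenceGenome, revcomp
from .candidates import IndelCandidate
from .classifier import TrainingSet
from .cohort import CohortIndel, IndelMatrix, build_matrix
from .features import LabeledFeatureVector

__all__ = [
    "SimConfig",
    "Variant",
    "TruthTable",
    "SimResult",
    "generate_reference",
    "implant_variants",
    "simulate_reads",
    "emulate_first_pass",
    "simulate",
    "write_fasta",
    "write_sam",
    "write_truth_tsv",
    "make_labeled_features",
    "make_shifted_training_set",
    "permute_labels",
    "make_planted_direction_set",
    "make_two_population_matrix",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulation.

    Defaults describe the reference scenario: a 100 kb chromosome, 20x
    coverage with 2 x 50 bp error-free FR pairs at 300 +- 30 bp insert
    size, 20 implanted deletions of 30-1,000 bp and 10 insertions of
    2-5 bp, and a first-pass mapper tolerating up to 4 differences per
    read of which at most 3 may be gaps.  ``dup_length`` > 0 adds a
    duplicated segment (with ``dup_deletions`` of the deletions placed
    inside its source copy) to create non-unique mappings and false
    candidates.
    """

    genome_length: int = 100_000
    coverage: float = 20.0
    read_length: int = 50
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.0
    n_deletions: int = 20
    deletion_length: tuple[int, int] = (30, 1000)
    n_insertions: int = 10
    insertion_length: tuple[int, int] = (2, 5)
    dup_length: int = 0
    dup_deletions: int = 1
    # per-base divergence between the two duplicated-segment copies;
    # segmental duplications are rarely identical, and the divergence is
    # what lets first-pass reads map uniquely to their own copy while
    # split reads still cross-align, creating classifiable decoys
    dup_divergence: float = 0.02
    max_diffs: int = 4
    max_gaps: int = 3
    chrom: str = "chr1"
    min_spacing: int = 100

    def __post_init__(self) -> None:
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.insert_mean <= self.read_length:
            raise ValueError("insert_mean must exceed read_length")
        if min(self.n_deletions, self.n_insertions) < 0:
            raise ValueError("variant counts must be >= 0")


@dataclass(frozen=True)
class Variant:
    """An implanted indel in reference coordinates.

    Deletions remove ``reference[start:start+length]`` from the donor
    (the removed bases are kept for round-trips); insertions place
    ``inserted_sequence`` immediately before ``reference[start]``.
    """

    kind: str  # "deletion" | "insertion"
    start: int
    length: int
    inserted_sequence: str = ""
    deleted_sequence: str = ""


@dataclass
class ReadTruth:
    read_id: str
    mate: int  # 1 | 2
    donor_start: int
    donor_end: int
    strand: str
    raw_seq: str  # as sequenced
    spans_indel: bool = False
    expect_mapped: bool = True


@dataclass
class TruthTable:
    variants: list[Variant]
    donor_length: int
    # colinear donor blocks: (donor_start, ref_start, length); insertion
    # blocks carry ref_start = -1
    blocks: list[tuple[int, int, int]]
    dup_intervals: list[tuple[int, int]] = field(default_factory=list)
    reads: list[ReadTruth] = field(default_factory=list)

    def reconstruct_reference(self, donor: str) -> str:
        """Apply the variants to the donor to rebuild the reference."""
        parts: list[str] = []
        vmap = {}
        for v in self.variants:
            vmap[v.start] = v
        ref_pos = 0
        donor_pos = 0
        for dstart, rstart, length in self.blocks:
            if rstart < 0:
                donor_pos += length  # inserted bases: skipped
                continue
            if rstart > ref_pos:
                v = vmap.get(ref_pos)
                parts.append(v.deleted_sequence if v else "")
            parts.append(donor[dstart : dstart + length])
            ref_pos = rstart + length
            donor_pos = dstart + length
        # trailing deletion (cannot occur with end spacing, kept for safety)
        v = vmap.get(ref_pos)
        if v is not None and v.kind == "deletion":
            parts.append(v.deleted_sequence)
        return "".join(parts)


@dataclass
class SimResult:
    config: SimConfig
    seed: int
    reference: ReferenceGenome
    donor: str
    truth: TruthTable
    header: pysam.AlignmentHeader
    records: list[pysam.AlignedSegment]


def generate_reference(
    length: int,
    seed: int,
    chrom: str = "chr1",
    dup_length: int = 0,
    dup_divergence: float = 0.0,
) -> tuple[ReferenceGenome, list[tuple[int, int]]]:
    """Uniform random A/C/G/T chromosome, deterministic per seed.

    With ``dup_length`` > 0 a segment of that length is copied to a
    second, disjoint locus; both intervals are returned so the mapper
    emulator can report two placements for reads inside them.  The
    copy accumulates substitutions at rate ``dup_divergence`` per base,
    emulating a diverged segmental duplication.
    """
    if length < 1000:
        raise ValueError("length must be >= 1000")
    rng = np.random.default_rng(seed)
    arr = rng.choice(_BASES, size=length)
    dup: list[tuple[int, int]] = []
    if dup_length > 0:
        if 3 * dup_length > length:
            raise ValueError("duplicated segment too long for the genome")
        src = int(rng.integers(0, length // 3 - dup_length))
        tgt = int(rng.integers(2 * length // 3, length - dup_length))
        copy = arr[src : src + dup_length].copy()
        if dup_divergence > 0:
            hits = np.nonzero(rng.random(dup_length) < dup_divergence)[0]
            for k in hits:
                copy[k] = rng.choice(_BASES[_BASES != copy[k]])
        arr[tgt : tgt + dup_length] = copy
        dup = [(src, src + dup_length), (tgt, tgt + dup_length)]
    seq = arr.tobytes().decode("ascii")
    return ReferenceGenome(sequences={chrom: seq}), dup


def _draw_positions(
    rng: np.random.Generator,
    lo: int,
    hi: int,
    lengths: list[int],
    taken: list[tuple[int, int]],
    spacing: int,
    max_tries: int = 10_000,
) -> list[int]:
    positions = []
    for length in lengths:
        for _ in range(max_tries):
            pos = int(rng.integers(lo, hi - length))
            span = (pos - spacing, pos + length + spacing)
            if all(span[1] <= s or span[0] >= e for s, e in taken):
                taken.append((pos, pos + length))
                positions.append(pos)
                break
        else:
            raise ValueError("cannot place variants without overlap; too crowded")
    return positions


def implant_variants(
    genome: ReferenceGenome,
    config: SimConfig,
    seed: int,
    dup_intervals: Sequence[tuple[int, int]] = (),
) -> tuple[str, TruthTable]:
    """Build the donor genome and its truth table.

    Variants are placed uniformly, pairwise separated by at least
    ``min_spacing`` and kept away from chromosome ends; with an active
    duplicated segment, ``dup_deletions`` of the deletions are forced
    into its source copy (capped to a quarter of its length so the
    flanks stay inside the copy) and no variant lands in the target
    copy.
    """
    rng = np.random.default_rng(seed)
    ref = genome.sequences[config.chrom]
    L = len(ref)
    lo, hi = config.min_spacing, L - config.min_spacing
    taken: list[tuple[int, int]] = []
    # the target copy must stay identical to the pre-variant source copy
    if dup_intervals:
        tgt = dup_intervals[1]
        taken.append((tgt[0] - config.min_spacing, tgt[1] + config.min_spacing))

    variants: list[Variant] = []
    dmin, dmax = config.deletion_length
    n_dup_del = min(config.dup_deletions, config.n_deletions) if dup_intervals else 0
    if n_dup_del:
        src = dup_intervals[0]
        cap = max(dmin, (src[1] - src[0]) // (4 * n_dup_del))
        lens = [int(rng.integers(dmin, min(dmax, cap) + 1)) for _ in range(n_dup_del)]
        margin = config.min_spacing
        for pos, ln in zip(
            _draw_positions(rng, src[0] + margin, src[1] - margin, lens, taken,
                            config.min_spacing),
            lens,
        ):
            variants.append(
                Variant("deletion", pos, ln, deleted_sequence=ref[pos : pos + ln])
            )
    lens = [
        int(rng.integers(dmin, dmax + 1)) for _ in range(config.n_deletions - n_dup_del)
    ]
    for pos, ln in zip(
        _draw_positions(rng, lo, hi, lens, taken, config.min_spacing), lens
    ):
        variants.append(
            Variant("deletion", pos, ln, deleted_sequence=ref[pos : pos + ln])
        )
    imin, imax = config.insertion_length
    lens = [int(rng.integers(imin, imax + 1)) for _ in range(config.n_insertions)]
    for pos, ln in zip(
        _draw_positions(rng, lo, hi, lens, taken, config.min_spacing), lens
    ):
        seq = "".join(chr(b) for b in rng.choice(_BASES, size=ln))
        variants.append(Variant("insertion", pos, ln, inserted_sequence=seq))
    variants.sort(key=lambda v: v.start)

    parts: list[str] = []
    blocks: list[tuple[int, int, int]] = []
    ref_pos = 0
    donor_pos = 0
    for v in variants:
        seg = ref[ref_pos : v.start]
        if seg:
            blocks.append((donor_pos, ref_pos, len(seg)))
            parts.append(seg)
            donor_pos += len(seg)
        if v.kind == "deletion":
            ref_pos = v.start + v.length
        else:
            blocks.append((donor_pos, -1, v.length))
            parts.append(v.inserted_sequence)
            donor_pos += v.length
            ref_pos = v.start
    seg = ref[ref_pos:]
    if seg:
        blocks.append((donor_pos, ref_pos, len(seg)))
        parts.append(seg)
        donor_pos += len(seg)
    donor = "".join(parts)
    truth = TruthTable(
        variants=variants,
        donor_length=len(donor),
        blocks=blocks,
        dup_intervals=list(dup_intervals),
    )
    return donor, truth


def simulate_reads(
    donor: str, config: SimConfig, seed: int
) -> list[tuple[ReadTruth, ReadTruth]]:
    """FR paired-end reads from the donor.

    Fragments are uniform on the donor with Gaussian insert (outer
    fragment) length truncated at twice the read length; mate 1 is the
    forward-strand fragment start, mate 2 the reverse-complemented
    fragment end; substitution errors hit each sequenced base with
    probability ``error_rate``.
    """
    rng = np.random.default_rng(seed)
    L = len(donor)
    rl = config.read_length
    n_pairs = int(round(config.coverage * L / (2 * rl)))
    pairs: list[tuple[ReadTruth, ReadTruth]] = []

    def seq_with_errors(seq: str) -> str:
        if config.error_rate <= 0:
            return seq
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        hits = np.nonzero(rng.random(len(arr)) < config.error_rate)[0]
        for k in hits:
            choices = _BASES[_BASES != arr[k]]
            arr[k] = rng.choice(choices)
        return arr.tobytes().decode("ascii")

    for idx in range(n_pairs):
        while True:
            frag = int(round(rng.normal(config.insert_mean, config.insert_sd)))
            if frag >= 2 * rl:
                break
        frag = min(frag, L)
        start = int(rng.integers(0, L - frag + 1))
        end = start + frag
        rid = f"pair{idx:07d}"
        r1 = ReadTruth(
            read_id=rid,
            mate=1,
            donor_start=start,
            donor_end=start + rl,
            strand="+",
            raw_seq=seq_with_errors(donor[start : start + rl]),
        )
        r2 = ReadTruth(
            read_id=rid,
            mate=2,
            donor_start=end - rl,
            donor_end=end,
            strand="-",
            raw_seq=seq_with_errors(revcomp(donor[end - rl : end])),
        )
        pairs.append((r1, r2))
    return pairs


def _project(
    truth: TruthTable, ds: int, de: int
) -> tuple[int, list[tuple[str, int]], int, int]:
    """Project a donor interval onto the reference.

    Returns (ref_start, cigar ops, interior gap columns, edge-clipped
    bases).  Interior insertion blocks become I ops, jumps between
    colinear blocks become D ops, inserted bases at a read edge are
    soft-clipped.
    """
    ops: list[tuple[str, int]] = []
    ref_start = -1
    prev_ref_end = -1
    for dstart, rstart, length in truth.blocks:
        dend = dstart + length
        if dend <= ds or dstart >= de:
            continue
        o_lo, o_hi = max(ds, dstart), min(de, dend)
        olen = o_hi - o_lo
        if rstart < 0:
            ops.append(("I", olen))
            continue
        r_lo = rstart + (o_lo - dstart)
        if prev_ref_end >= 0 and r_lo > prev_ref_end:
            ops.append(("D", r_lo - prev_ref_end))
        ops.append(("M", olen))
        if ref_start < 0:
            ref_start = r_lo
        prev_ref_end = r_lo + olen
    # soft-clip edge insertions
    clip = 0
    while ops and ops[0][0] in ("I", "D"):
        op, ln = ops.pop(0)
        if op == "I":
            ops.insert(0, ("S", ln))
            clip += ln
            break
        # leading D: no read bases consumed, just shift the start
    while ops and ops[-1][0] in ("I", "D"):
        op, ln = ops.pop()
        if op == "I":
            ops.append(("S", ln))
            clip += ln
            break
    gap_cols = sum(ln for op, ln in ops if op in ("I", "D"))
    return ref_start, ops, gap_cols, clip


_CIGAR_NUM = {"M": 0, "I": 1, "D": 2, "S": 4}


def emulate_first_pass(
    pairs: list[tuple[ReadTruth, ReadTruth]],
    truth: TruthTable,
    genome: ReferenceGenome,
    config: SimConfig,
) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment]]:
    """Truth-position mapper with a difference tolerance.

    Each read is aligned only at its truth-projected reference
    position; it is declared mapped iff that alignment shows at most
    ``max_diffs`` differences (mismatches + gap columns + soft-clipped
    bases) of which at most ``max_gaps`` are gap columns.  Reads whose
    projected interval lies inside a duplicated-segment copy and whose
    alignment is also tolerable at the partner copy are emitted with a
    secondary placement (and mapping quality 0).
    """
    chrom = config.chrom
    ref = genome.sequences[chrom]
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": chrom, "LN": len(ref)}],
        }
    )
    dup = truth.dup_intervals
    delta = dup[1][0] - dup[0][0] if dup else 0

    def evaluate(read: ReadTruth):
        ref_start, ops, gap_cols, clip = _project(
            truth, read.donor_start, read.donor_end
        )
        if ref_start < 0 or not any(op == "M" for op, _ in ops):
            return None
        fwd = read.raw_seq if read.strand == "+" else revcomp(read.raw_seq)
        mism = _count_mismatches(fwd, ops, ref, ref_start)
        if mism is None:
            return None
        diffs = mism + gap_cols + clip
        if diffs > config.max_diffs or gap_cols > config.max_gaps:
            return None
        ref_end = ref_start + sum(ln for op, ln in ops if op in ("M", "D"))
        placements = [(ref_start, ops)]
        for (a_lo, a_hi), shift in (
            ((dup[0][0], dup[0][1]), delta),
            ((dup[1][0], dup[1][1]), -delta),
        ) if dup else ():
            if a_lo <= ref_start and ref_end <= a_hi:
                alt = ref_start + shift
                mism2 = _count_mismatches(fwd, ops, ref, alt)
                if (
                    mism2 is not None
                    and mism2 + gap_cols + clip <= config.max_diffs
                ):
                    placements.append((alt, ops))
        return fwd, placements, gap_cols + clip

    records: list[pysam.AlignedSegment] = []
    for r1, r2 in pairs:
        evals = {1: evaluate(r1), 2: evaluate(r2)}
        reads = {1: r1, 2: r2}
        for mate in (1, 2):
            read = reads[mate]
            other = evals[3 - mate]
            mine = evals[mate]
            read.expect_mapped = mine is not None
            read.spans_indel = mine is None
            if mine is not None:
                fwd, placements, _ = mine
                multi = len(placements) > 1
                for k, (pos, ops) in enumerate(placements):
                    rec = pysam.AlignedSegment(header)
                    rec.query_name = read.read_id
                    rec.query_sequence = fwd
                    rec.flag = 0
                    rec.is_paired = True
                    rec.is_read1 = mate == 1
                    rec.is_read2 = mate == 2
                    rec.is_reverse = read.strand == "-"
                    rec.is_secondary = k > 0
                    rec.reference_id = 0
                    rec.reference_start = pos
                    rec.mapping_quality = 0 if multi else 60
                    rec.cigartuples = [(_CIGAR_NUM[op], ln) for op, ln in ops]
                    if other is not None:
                        opos = other[1][0][0]
                        rec.next_reference_id = 0
                        rec.next_reference_start = opos
                        rec.mate_is_reverse = reads[3 - mate].strand == "-"
                    else:
                        rec.mate_is_unmapped = True
                        rec.next_reference_id = 0
                        rec.next_reference_start = pos
                    records.append(rec)
            else:
                rec = pysam.AlignedSegment(header)
                rec.query_name = read.read_id
                rec.query_sequence = read.raw_seq  # raw, as sequenced
                rec.is_paired = True
                rec.is_read1 = mate == 1
                rec.is_read2 = mate == 2
                rec.is_unmapped = True
                if other is not None:
                    opos = other[1][0][0]
                    rec.reference_id = 0
                    rec.reference_start = opos
                    rec.next_reference_id = 0
                    rec.next_reference_start = opos
                    rec.mate_is_reverse = reads[3 - mate].strand == "-"
                else:
                    rec.reference_id = -1
                    rec.reference_start = -1
                    rec.next_reference_id = -1
                    rec.next_reference_start = -1
                    rec.mate_is_unmapped = True
                records.append(rec)
    return header, records


def _count_mismatches(
    fwd: str, ops: list[tuple[str, int]], ref: str, ref_start: int
) -> Optional[int]:
    """Mismatches of the forward-strand read over the M runs of a
    projected alignment placed at ``ref_start``; None if out of range."""
    mism = 0
    qpos = 0
    rpos = ref_start
    if ref_start < 0:
        return None
    for op, ln in ops:
        if op == "M":
            if rpos + ln > len(ref):
                return None
            for k in range(ln):
                if fwd[qpos + k] != ref[rpos + k]:
                    mism += 1
            qpos += ln
            rpos += ln
        elif op == "I" or op == "S":
            qpos += ln
        elif op == "D":
            rpos += ln
    return mism


def simulate(config: SimConfig, seed: int) -> SimResult:
    """Run the whole generator with a single seed."""
    rng = np.random.default_rng(seed)
    s_ref, s_var, s_reads = (int(x) for x in rng.integers(0, 2**31 - 1, size=3))
    genome, dup = generate_reference(
        config.genome_length,
        s_ref,
        chrom=config.chrom,
        dup_length=config.dup_length,
        dup_divergence=config.dup_divergence,
    )
    donor, truth = implant_variants(genome, config, s_var, dup_intervals=dup)
    pairs = simulate_reads(donor, config, s_reads)
    header, records = emulate_first_pass(pairs, truth, genome, config)
    truth.reads = [r for pair in pairs for r in pair]
    return SimResult(
        config=config,
        seed=seed,
        reference=genome,
        donor=donor,
        truth=truth,
        header=header,
        records=records,
    )


def write_fasta(genome: ReferenceGenome, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def write_sam(
    header: pysam.AlignmentHeader, records: list[pysam.AlignedSegment], path: str
) -> None:
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for rec in records:
            fh.write(rec)


def write_truth_tsv(truth: TruthTable, path: str, chrom: str = "chr1") -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tkind\tlength\tinserted_seq\n")
        for v in truth.variants:
            fh.write(
                f"{chrom}\t{v.start + 1}\t{v.kind}\t{v.length}\t"
                f"{v.inserted_sequence or '.'}\n"
            )


def match_truth(
    candidate: IndelCandidate, variants: Sequence[Variant], max_shift: int = 10
) -> bool:
    return any(
        v.kind == candidate.kind
        and v.length == candidate.length
        and abs(v.start - candidate.start) <= max_shift
        for v in variants
    )


def make_labeled_features(
    truth: TruthTable,
    candidates: Sequence[IndelCandidate],
    vectors: Sequence[LabeledFeatureVector],
    max_shift: int = 10,
) -> list[LabeledFeatureVector]:
    """Label feature vectors against the implanted truth (+1 when the
    candidate matches an implanted variant in kind, length and start
    within ``max_shift`` bp; -1 otherwise).  Stands in for wet-lab
    validation of candidates."""
    if len(candidates) != len(vectors):
        raise ValueError("candidates and vectors must be parallel")
    out = []
    for cand, vec in zip(candidates, vectors):
        label = 1 if match_truth(cand, truth.variants, max_shift) else -1
        out.append(replace_label(vec, label))
    return out


def replace_label(vec: LabeledFeatureVector, label: int) -> LabeledFeatureVector:
    return LabeledFeatureVector(
        candidate_id=vec.candidate_id,
        kind=vec.kind,
        feature_names=list(vec.feature_names),
        values=vec.values.copy(),
        label=label,
    )


# ---------------------------------------------------------------------------
# synthetic inputs for the classifier and cohort stages


def make_shifted_training_set(
    n: int = 200,
    n_features: int = 2,
    shift: float = 2.0,
    seed: int = 0,
    kind: str = "deletion",
) -> TrainingSet:
    """Balanced Gaussian set where feature 0 of the positive class is
    shifted by ``shift`` standard deviations; the rest is noise.

    The default keeps one nuisance dimension next to the informative
    one: a univariate 2-SD shift has a Bayes-optimal AUC of
    Phi(2/sqrt(2)) = 0.921, and every extra noise dimension eats into
    the margin a finite-sample learner can recover from it, so the
    benchmark stays close to that ceiling while still requiring the
    learner to ignore an uninformative feature."""
    rng = np.random.default_rng(seed)
    n_pos = n // 2
    X = rng.normal(size=(n, n_features))
    y = np.full(n, -1, dtype=int)
    y[:n_pos] = 1
    X[:n_pos, 0] += shift
    perm = rng.permutation(n)
    names = [f"f{k}" for k in range(n_features)]
    return TrainingSet(X=X[perm], y=y[perm], feature_names=names, kind=kind)


def permute_labels(train: TrainingSet, seed: int = 0) -> TrainingSet:
    rng = np.random.default_rng(seed)
    return TrainingSet(
        X=train.X.copy(),
        y=rng.permutation(train.y),
        feature_names=list(train.feature_names),
        kind=train.kind,
    )


def make_planted_direction_set(
    n: int = 500,
    n_features: int = 8,
    noise_sd: float = 0.5,
    seed: int = 0,
    kind: str = "deletion",
) -> tuple[TrainingSet, np.ndarray]:
    """Labels from a known linear rule with margin noise; returns the
    set and the true (unit) weight direction, whose first component is
    positive by construction."""
    rng = np.random.default_rng(seed)
    w = rng.normal(size=n_features)
    w[0] = abs(w[0]) + 1.0
    w /= np.linalg.norm(w)
    X = rng.normal(size=(n, n_features))
    margin = X @ w + rng.normal(scale=noise_sd, size=n)
    y = np.where(margin >= 0, 1, -1)
    if len(set(y)) < 2:  # pragma: no cover - essentially impossible
        y[0] = -y[0]
    names = [f"f{k}" for k in range(n_features)]
    return TrainingSet(X=X, y=y, feature_names=names, kind=kind), w


def make_two_population_matrix(
    n_strains: int = 50,
    n_indels: int = 500,
    seed: int = 0,
    carrier_rate: float = 0.8,
    leak_rate: float = 0.05,
) -> tuple[IndelMatrix, np.ndarray]:
    """Strains split into two populations with population-specific
    indel sets: an indel belonging to population P is carried by each
    P strain with ``carrier_rate`` and by each other strain with
    ``leak_rate``.  Private columns are regenerated so every column is
    shared by at least two strains.  Returns the matrix and the 0/1
    population label per strain."""
    rng = np.random.default_rng(seed)
    labels = np.zeros(n_strains, dtype=int)
    labels[n_strains // 2 :] = 1
    strains = [f"strain{k:03d}" for k in range(n_strains)]
    cohort: list[CohortIndel] = []
    for j in range(n_indels):
        pop = j % 2
        kind = "deletion" if rng.random() < 0.8 else "insertion"
        while True:
            carry = np.where(
                labels == pop,
                rng.random(n_strains) < carrier_rate,
                rng.random(n_strains) < leak_rate,
            )
            if carry.sum() >= 2:
                break
        cohort.append(
            CohortIndel(
                chrom="chr1",
                start=1000 * (j + 1),
                length=50,
                kind=kind,
                carriers=frozenset(s for s, c in zip(strains, carry) if c),
            )
        )
    return build_matrix(cohort, strains), labels
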