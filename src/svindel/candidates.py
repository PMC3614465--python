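"""Indel candidate generation: realignment windows, split-read
alignment of unmapped mates, and aggregation of per-read signatures
into supported candidates.

The strategy is deliberately non-conservative: anchors may carry
mismatches and multiple placements, and the mate is accepted wherever
it aligns inside the window (no insert-size concordance filter).  The
cost — spurious candidates from repeats and ambiguous tracebacks — is
paid back later by the SVM classification stage.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .alignio import (
    AlignedRead,
    MappedUnmappedPair,
    ReferenceGenome,
    RegionMask,
    revcomp,
)
from .gotoh import (
    IndelSignature,
    ScoringScheme,
    align_local,
    extract_signatures,
    passes_penalty_filter,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnchorWindow",
    "IndelCandidate",
    "SupportRecord",
    "place_window",
    "detect_candidates",
    "filter_candidates",
    "write_candidates_tsv",
    "write_candidates_vcf",
]

DEFAULT_WINDOW_SIZE = 5000


@dataclass(frozen=True)
class AnchorWindow:
    """A realignment window placed relative to one anchor placement.

    A forward-strand anchor expects its FR-library mate downstream, so
    the window spans the ``window_size`` bases after the anchor and the
    mate is reverse-complemented into reference orientation; a reverse-
    strand anchor mirrors this upstream with the mate's raw sequence.
    """

    chrom: str
    start: int
    end: int
    oriented_read: str


@dataclass
class SupportRecord:
    """One read's contribution to a candidate."""

    read_id: str
    alignment_score: int
    penalty: int
    anchor_start: int
    # single-position variants seen by this split alignment, in global
    # reference coordinates: mismatches as (pos, base), single-gap
    # columns as (pos, "-") / (pos, "+")
    spvs: frozenset = frozenset()


@dataclass
class IndelCandidate:
    """A located indel supported by >= 2 independent split reads."""

    chrom: str
    start: int  # first deleted base, or insertion point (0-based)
    end: int  # deletions: start + length; insertions: start
    kind: str  # "deletion" | "insertion"
    length: int
    inserted_sequence: str = ""
    support: int = 0
    supporting: list[SupportRecord] = field(default_factory=list)

    @property
    def read_ids(self) -> list[str]:
        return [s.read_id for s in self.supporting]

    @property
    def alignment_scores(self) -> list[int]:
        return [s.alignment_score for s in self.supporting]


def place_window(
    mur: MappedUnmappedPair,
    placement: AlignedRead,
    genome: ReferenceGenome,
    window_size: int = DEFAULT_WINDOW_SIZE,
    mask: Optional[RegionMask] = None,
) -> Optional[AnchorWindow]:
    """Realignment window for one anchor placement, or None.

    None is returned when the placement sits inside the mask or the
    clipped window is empty.  Windows are clipped at chromosome ends
    rather than dropped, so candidates near termini stay reachable.
    """
    if mask is not None and mask.contains_interval(
        placement.chrom, placement.start, placement.end
    ):
        return None
    chrom_len = len(genome.sequences[placement.chrom])
    if placement.strand == "+":
        start, end = placement.end, placement.end + window_size
        oriented = revcomp(mur.mate_sequence)
    else:
        start, end = placement.start - window_size, placement.start
        oriented = mur.mate_sequence
    start, end = max(0, start), min(chrom_len, end)
    if start >= end:
        return None
    return AnchorWindow(
        chrom=placement.chrom, start=start, end=end, oriented_read=oriented
    )


def _alignment_spvs(aln, window_start: int) -> frozenset:
    """Mismatch and single-gap columns of a split alignment, as SPVs in
    global reference coordinates."""
    spvs = set()
    cols = aln.columns
    k = 0
    while k < len(cols):
        op, ri, rj = cols[k]
        if op == "X":
            spvs.add((window_start + rj, None, ri))  # base filled by caller
            k += 1
        elif op in ("D", "I"):
            k2 = k
            while k2 < len(cols) and cols[k2][0] == op:
                k2 += 1
            if k2 - k == 1:  # length-1 gap -> SPV, longer runs are signatures
                if op == "D":
                    spvs.add((window_start + cols[k][2], "-", -1))
                else:
                    nxt = next((c[2] for c in cols[k2:] if c[2] >= 0), -1)
                    if nxt >= 0:
                        spvs.add((window_start + nxt, "+", -1))
            k = k2
        else:
            k += 1
    return frozenset(spvs)


def detect_candidates(
    murs: Iterable[MappedUnmappedPair],
    genome: ReferenceGenome,
    scheme: ScoringScheme = ScoringScheme(),
    window_size: int = DEFAULT_WINDOW_SIZE,
    min_support: int = 2,
    min_gap_run: int = 2,
    min_fragment: int = 8,
    max_alignments: int = 10,
    mask: Optional[RegionMask] = None,
) -> list[IndelCandidate]:
    """Run the split-read realignment over all MURs and aggregate.

    Per anchor placement: place the window, align the oriented mate,
    keep near-best alignments within the penalty budget, extract gap-
    run signatures, and lift them to reference coordinates.  Signatures
    are grouped by exact location — (chrom, kind, start, length), plus
    the inserted sequence for insertions — and groups supported by at
    least ``min_support`` distinct read ids become candidates.
    """
    murs = list(murs)
    if not murs:
        logger.warning("empty MUR stream: no candidates")
        return []
    groups: dict[tuple, dict[str, SupportRecord]] = defaultdict(dict)
    for mur in murs:
        read_id = mur.anchor.read_id
        for placement in mur.anchor_placements:
            window = place_window(mur, placement, genome, window_size, mask)
            if window is None:
                continue
            window_seq = genome.slice(window.chrom, window.start, window.end)
            alignments = align_local(
                window.oriented_read, window_seq, scheme, max_alignments
            )
            for aln in alignments:
                if not passes_penalty_filter(aln, scheme):
                    continue
                sigs = extract_signatures(
                    aln,
                    min_gap_run=min_gap_run,
                    min_fragment=min_fragment,
                    read_id=read_id,
                    read=window.oriented_read,
                )
                if not sigs:
                    continue
                spvs = set()
                for pos, allele, ri in _alignment_spvs(aln, window.start):
                    if allele is None:
                        spvs.add((pos, window.oriented_read[ri]))
                    else:
                        spvs.add((pos, allele))
                penalty = (
                    -scheme.mismatch * aln.n_mismatch
                    - scheme.gap_open * aln.n_gap_open
                )
                for sig in sigs:
                    gstart = window.start + sig.ref_position
                    key = (
                        window.chrom,
                        sig.kind,
                        gstart,
                        sig.length,
                        sig.inserted_sequence if sig.kind == "insertion" else "",
                    )
                    # one contribution per read id per location: support
                    # must come from independent reads
                    if read_id not in groups[key]:
                        groups[key][read_id] = SupportRecord(
                            read_id=read_id,
                            alignment_score=aln.score,
                            penalty=penalty,
                            anchor_start=placement.start,
                            spvs=frozenset(spvs),
                        )
    candidates: list[IndelCandidate] = []
    for (chrom, kind, start, length, ins_seq), by_read in groups.items():
        if len(by_read) < min_support:
            continue
        supporting = [by_read[rid] for rid in sorted(by_read)]
        candidates.append(
            IndelCandidate(
                chrom=chrom,
                start=start,
                end=start + length if kind == "deletion" else start,
                kind=kind,
                length=length,
                inserted_sequence=ins_seq,
                support=len(supporting),
                supporting=supporting,
            )
        )
    candidates.sort(key=lambda c: (c.chrom, c.start, c.kind, c.length))
    return candidates


def filter_candidates(
    candidates: list[IndelCandidate], min_len: int = 2, max_len: int = DEFAULT_WINDOW_SIZE
) -> list[IndelCandidate]:
    """Length filter, inclusive on both bounds."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [c for c in candidates if min_len <= c.length <= max_len]


_TSV_HEADER = [
    "chrom",
    "start",
    "end",
    "type",
    "length",
    "support",
    "inserted_seq",
    "mean_score",
]


def write_candidates_tsv(
    candidates: list[IndelCandidate], path: str, header_lines: Iterable[str] = ()
) -> None:
    """Candidate table, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for c in candidates:
            mean_score = sum(c.alignment_scores) / len(c.alignment_scores)
            fh.write(
                "\t".join(
                    [
                        c.chrom,
                        str(c.start + 1),
                        str(c.end if c.kind == "deletion" else c.start + 1),
                        "DEL" if c.kind == "deletion" else "INS",
                        str(c.length),
                        str(c.support),
                        c.inserted_sequence or ".",
                        f"{mean_score:.1f}",
                    ]
                )
                + "\n"
            )


def write_candidates_vcf(
    candidates: list[IndelCandidate], genome: ReferenceGenome, path: str
) -> None:
    """Minimal VCF 4.2 with symbolic-free REF/ALT padded by the base
    before the event; SVLEN is negative for deletions."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in genome.lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Split reads">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in candidates:
            pad_pos = c.start - 1
            if pad_pos < 0:
                continue
            pad = genome.slice(c.chrom, pad_pos, pad_pos + 1)
            if c.kind == "deletion":
                ref = pad + genome.slice(c.chrom, c.start, c.end)
                alt = pad
                info = f"SVTYPE=DEL;END={c.end};SVLEN={-c.length};SUPPORT={c.support}"
            else:
                ref = pad
                alt = pad + c.inserted_sequence
                info = (
                    f"SVTYPE=INS;END={c.start};SVLEN={c.length};SUPPORT={c.support}"
                )
            fh.write(
                f"{c.chrom}\t{pad_pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n"
            )
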