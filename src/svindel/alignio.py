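"""Reference and alignment input: FASTA loading, mapped-unmapped read
pairs, read-uniqueness classification, and region masks.

The first mapping pass (an external short-read mapper, or the emulator
in :mod:`svindel.simdata`) produces a SAM/BAM stream that must retain
unmapped mates.  From it we pull every read pair with exactly one
mapped end — the mapped end anchors the realignment of its partner.
"""

from __future__ import annotations

import bisect
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union

import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceGenome",
    "AlignedRead",
    "MappedUnmappedPair",
    "RegionMask",
    "AlignmentSet",
    "load_reference",
    "load_mask",
    "extract_murs",
    "classify_uniqueness",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceGenome:
    """In-memory reference: chromosome name -> upper-cased sequence."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def slice(self, chrom: str, start: int, end: int) -> str:
        """0-based half-open slice, clipped to chromosome bounds."""
        seq = self.sequences[chrom]
        return seq[max(0, start) : min(len(seq), end)]


@dataclass(frozen=True)
class AlignedRead:
    """One placement of a first-pass read on the reference.

    Coordinates are 0-based half-open; ``sequence`` is the forward-
    strand (reference-oriented) sequence as stored in SAM.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str  # "+" | "-"
    cigar: str
    mapq: int
    sequence: str
    mate: int = 1  # 1 | 2: which end of the pair this read is
    is_secondary: bool = False
    mate_mapped: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.read_id}: start must be < end for a mapped read")


@dataclass
class MappedUnmappedPair:
    """A read pair with exactly one mapped end (a MUR).

    ``anchor`` is the primary placement of the mapped end;
    ``anchor_placements`` lists every reported placement (a non-unique
    anchor keeps all of them, and each spawns its own realignment
    window).  ``mate_sequence`` is the unmapped partner's raw
    (as-sequenced) bases.
    """

    anchor: AlignedRead
    mate_sequence: str
    anchor_placements: list[AlignedRead] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.mate_sequence:
            raise ValueError("mate sequence must be non-empty")
        if not self.anchor_placements:
            self.anchor_placements = [self.anchor]


class RegionMask:
    """Sorted, non-overlapping genomic intervals (0-based half-open)."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for chrom, start, end in intervals:
            if start < end:
                by_chrom[chrom].append((start, end))
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[tuple[int, int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self._by_chrom[chrom] = merged

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        return [
            (c, s, e) for c in sorted(self._by_chrom) for s, e in self._by_chrom[c]
        ]

    def contains_interval(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) lies entirely inside one mask interval."""
        ivs = self._by_chrom.get(chrom)
        if not ivs:
            return False
        k = bisect.bisect_right(ivs, (start, float("inf"))) - 1
        return k >= 0 and ivs[k][0] <= start and end <= ivs[k][1]


def load_reference(path: str) -> ReferenceGenome:
    """Load a FASTA reference fully into memory (case-folded to upper)."""
    sequences: dict[str, str] = {}
    try:
        for record in SeqIO.parse(path, "fasta"):
            if record.id in sequences:
                raise ValueError(f"duplicate chromosome name: {record.id}")
            sequences[record.id] = str(record.seq).upper()
    except (ValueError, KeyError) as exc:
        raise ValueError(f"malformed FASTA {path}: {exc}") from exc
    if not sequences:
        raise ValueError(f"no sequences found in {path}")
    return ReferenceGenome(sequences=sequences)


def load_mask(path: str) -> RegionMask:
    """Read a BED file (0-based half-open) into a RegionMask."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            intervals.append((parts[0], int(parts[1]), int(parts[2])))
    return RegionMask(intervals)


def _to_aligned_read(rec: pysam.AlignedSegment) -> AlignedRead:
    return AlignedRead(
        read_id=rec.query_name,
        chrom=rec.reference_name,
        start=rec.reference_start,
        end=rec.reference_end,
        strand="-" if rec.is_reverse else "+",
        cigar=rec.cigarstring or "",
        mapq=rec.mapping_quality,
        sequence=rec.query_sequence or "",
        mate=2 if rec.is_read2 else 1,
        is_secondary=rec.is_secondary,
        mate_mapped=not rec.mate_is_unmapped,
    )


def _iter_records(
    alignments: Union[str, Iterable[pysam.AlignedSegment]],
) -> Iterator[pysam.AlignedSegment]:
    if isinstance(alignments, str):
        with pysam.AlignmentFile(alignments, check_sq=False) as fh:
            yield from fh.fetch(until_eof=True)
    else:
        yield from alignments


def extract_murs(
    alignments: Union[str, Iterable[pysam.AlignedSegment]],
    mask: Optional[RegionMask] = None,
) -> list[MappedUnmappedPair]:
    """Pull every mapped-unmapped read pair from a first-pass stream.

    A pair qualifies when exactly one end has at least one mapped
    placement and the other end is present as an unmapped record with a
    sequence.  Pairs whose every anchor placement lies inside ``mask``
    (e.g. centromeres) are dropped.  Multi-placed anchors are retained
    with all placements.
    """
    # qname -> {1: [...records...], 2: [...]}
    by_pair: dict[str, dict[int, list[pysam.AlignedSegment]]] = defaultdict(
        lambda: {1: [], 2: []}
    )
    n_records = 0
    for rec in _iter_records(alignments):
        if rec.is_supplementary:
            continue
        n_records += 1
        endno = 2 if rec.is_read2 else 1
        by_pair[rec.query_name][endno].append(rec)

    murs: list[MappedUnmappedPair] = []
    per_chrom: dict[str, int] = defaultdict(int)
    saw_unmapped = False
    for qname, ends in by_pair.items():
        sides = {}
        for endno in (1, 2):
            recs = ends[endno]
            mapped = [r for r in recs if not r.is_unmapped]
            unmapped = [r for r in recs if r.is_unmapped]
            if unmapped:
                saw_unmapped = True
            sides[endno] = (mapped, unmapped)
        for anchor_end, mate_end in ((1, 2), (2, 1)):
            anchor_mapped, _ = sides[anchor_end]
            mate_mapped, mate_unmapped = sides[mate_end]
            if not anchor_mapped or mate_mapped or not mate_unmapped:
                continue
            mate_seq = mate_unmapped[0].query_sequence or ""
            if not mate_seq:
                continue
            placements = [_to_aligned_read(r) for r in anchor_mapped]
            placements.sort(key=lambda r: (r.is_secondary, r.chrom, r.start))
            if mask is not None and all(
                mask.contains_interval(p.chrom, p.start, p.end) for p in placements
            ):
                continue
            murs.append(
                MappedUnmappedPair(
                    anchor=placements[0],
                    mate_sequence=mate_seq,
                    anchor_placements=placements,
                )
            )
            per_chrom[placements[0].chrom] += 1
    if not murs and not saw_unmapped:
        logger.warning(
            "no unmapped-mate records in %d alignment records; MUR count 0 "
            "(was the mapper run with unmapped-mate retention?)",
            n_records,
        )
    for chrom in sorted(per_chrom):
        logger.info("chromosome %s: %d mapped-unmapped pairs", chrom, per_chrom[chrom])
    return murs


def classify_uniqueness(
    placements: list[AlignedRead], min_mapq: int = 1
) -> str:
    """UMR/N-UMR call for all placements of one read.

    A read is uniquely mapped (``"UMR"``) iff the mapper reported a
    single placement with mapping quality >= ``min_mapq``; otherwise it
    is non-uniquely mapped (``"N-UMR"``).
    """
    if not placements:
        raise ValueError("classify_uniqueness called with zero placements")
    if len(placements) == 1 and placements[0].mapq >= min_mapq:
        return "UMR"
    return "N-UMR"


class AlignmentSet:
    """First-pass mapped reads indexed for interval queries.

    Groups the placements of each physical read — keyed by (read id,
    mate number), since both mates of a pair share the SAM query name —
    computes its UMR/N-UMR call, and answers "which placements overlap
    [start, end) on chrom" by binary search over start coordinates.
    """

    def __init__(self, reads: Iterable[AlignedRead], min_mapq: int = 1):
        self.by_read: dict[tuple[str, int], list[AlignedRead]] = defaultdict(list)
        for read in reads:
            self.by_read[(read.read_id, read.mate)].append(read)
        self.uniqueness: dict[tuple[str, int], str] = {
            key: classify_uniqueness(placements, min_mapq)
            for key, placements in self.by_read.items()
        }
        self._by_chrom: dict[str, list[AlignedRead]] = defaultdict(list)
        for placements in self.by_read.values():
            for read in placements:
                self._by_chrom[read.chrom].append(read)
        self._starts: dict[str, list[int]] = {}
        self._max_len: dict[str, int] = {}
        for chrom, reads_ in self._by_chrom.items():
            reads_.sort(key=lambda r: r.start)
            self._starts[chrom] = [r.start for r in reads_]
            self._max_len[chrom] = max((r.end - r.start) for r in reads_)

    @classmethod
    def from_sam(
        cls, alignments: Union[str, Iterable[pysam.AlignedSegment]], min_mapq: int = 1
    ) -> "AlignmentSet":
        reads = [
            _to_aligned_read(rec)
            for rec in _iter_records(alignments)
            if not rec.is_unmapped and not rec.is_supplementary
        ]
        return cls(reads, min_mapq=min_mapq)

    def is_umr(self, read: AlignedRead) -> bool:
        return self.uniqueness[(read.read_id, read.mate)] == "UMR"

    def overlapping(self, chrom: str, start: int, end: int) -> list[AlignedRead]:
        reads = self._by_chrom.get(chrom)
        if not reads:
            return []
        starts = self._starts[chrom]
        lo = bisect.bisect_left(starts, start - self._max_len[chrom])
        hi = bisect.bisect_left(starts, end)
        return [r for r in reads[lo:hi] if r.end > start and r.start < end]
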