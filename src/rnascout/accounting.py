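"""Alignment accounting.

Turns one batch of alignment records into classified spot counts, per-tile
coverage increments and observed introns, and enforces the first-batch
quality filter that blacklists runs with very low unique alignability.

Spot semantics: the unit of counting is a *spot* — one read for single-end
data, one read pair for paired-end data.  Every spot is classified exactly
once as uniquely aligned, multi-mapped or unmapped; only uniquely aligned
spots are counted into tile coverage (one increment, at the tile of the
leftmost aligned base of the spot's representative alignment).
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .introns import Intron, IntronSet
from .tiles import TileIndex

logger = logging.getLogger(__name__)

# MAPQ at or above which an alignment without an NH tag counts as unique.
MAPQ_UNIQUE_THRESHOLD = 30

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = frozenset("MDN=X")


class AlignmentError(ValueError):
    """Malformed alignment record (bad CIGAR or position)."""


class AlignmentRecord:
    """Minimal carrier for the SAM fields the accounting needs.

    ``pos`` is the 1-based leftmost reference position; ``ref_name`` is None
    for unmapped records; ``nh`` is the number-of-hits tag when the aligner
    emitted one, with MAPQ as the fallback uniqueness signal.
    """

    __slots__ = (
        "qname", "ref_name", "pos", "cigar", "nh", "mapq",
        "is_paired", "is_first", "is_secondary", "is_supplementary",
        "is_reverse", "mate_mapped",
    )

    def __init__(
        self,
        qname: str,
        ref_name: Optional[str] = None,
        pos: int = 0,
        cigar: Optional[str] = None,
        nh: Optional[int] = None,
        mapq: int = 0,
        is_paired: bool = False,
        is_first: bool = True,
        is_secondary: bool = False,
        is_supplementary: bool = False,
        is_reverse: bool = False,
        mate_mapped: bool = True,
    ):
        self.qname = qname
        self.ref_name = ref_name
        self.pos = pos
        self.cigar = cigar
        self.nh = nh
        self.mapq = mapq
        self.is_paired = is_paired
        self.is_first = is_first
        self.is_secondary = is_secondary
        self.is_supplementary = is_supplementary
        self.is_reverse = is_reverse
        self.mate_mapped = mate_mapped

    @property
    def is_mapped(self) -> bool:
        return self.ref_name is not None

    def __repr__(self) -> str:  # pragma: no cover
        where = f"{self.ref_name}:{self.pos}" if self.is_mapped else "unmapped"
        return f"AlignmentRecord({self.qname!r}, {where}, {self.cigar})"

    @classmethod
    def from_pysam(cls, aln) -> "AlignmentRecord":
        """Convert a :class:`pysam.AlignedSegment`."""
        nh = aln.get_tag("NH") if aln.has_tag("NH") else None
        return cls(
            qname=aln.query_name,
            ref_name=None if aln.is_unmapped else aln.reference_name,
            pos=0 if aln.is_unmapped else aln.reference_start + 1,
            cigar=aln.cigarstring,
            nh=nh,
            mapq=aln.mapping_quality,
            is_paired=aln.is_paired,
            is_first=not (aln.is_paired and aln.is_read2),
            is_secondary=aln.is_secondary,
            is_supplementary=aln.is_supplementary,
            is_reverse=aln.is_reverse,
            mate_mapped=not (aln.is_paired and aln.mate_is_unmapped),
        )


def parse_cigar(cigar: str) -> List[Tuple[str, int]]:
    """Parse a CIGAR string into ``(op, length)`` pairs, validating syntax."""
    if not cigar or cigar == "*":
        raise AlignmentError(f"empty CIGAR {cigar!r}")
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise AlignmentError(f"malformed CIGAR {cigar!r}")
    if any(n < 1 for _, n in ops):
        raise AlignmentError(f"zero-length operation in CIGAR {cigar!r}")
    return ops


def reference_span(cigar: str) -> int:
    """Number of reference bases consumed by a CIGAR."""
    return sum(n for op, n in parse_cigar(cigar) if op in _REF_CONSUMING)


def extract_introns_from_cigar(position: int, cigar: str, sequence: str) -> List[Intron]:
    """Introns induced by the N operations of a spliced alignment.

    For each N of length ``n`` preceded by ``o`` reference-consuming bases
    since the 1-based leftmost position ``p``, the intron is
    ``(sequence, p + o, p + o + n - 1)`` — first and last intronic base,
    1-based inclusive.  N consumes reference, so later gaps are shifted by
    earlier ones.
    """
    introns: List[Intron] = []
    offset = 0
    for op, n in parse_cigar(cigar):
        if op == "N":
            introns.append((sequence, position + offset, position + offset + n - 1))
        if op in _REF_CONSUMING:
            offset += n
    return introns


@dataclass
class BatchResult:
    """Classified outcome of one downloaded batch.

    Invariants: unique + multi + unmapped = downloaded;
    tile increments sum to the unique count; spliced <= unique.
    """

    run_id: str
    spots_downloaded: int
    spots_unique: int = 0
    spots_multi: int = 0
    spots_unmapped: int = 0
    spots_spliced: int = 0
    tile_increments: Dict[int, int] = field(default_factory=dict)
    introns_observed: IntronSet = field(default_factory=IntronSet)

    def validate(self) -> None:
        if self.spots_unique + self.spots_multi + self.spots_unmapped != self.spots_downloaded:
            raise AssertionError("spot classification is not a partition")
        if sum(self.tile_increments.values()) != self.spots_unique:
            raise AssertionError("tile increments do not sum to the unique count")
        if self.spots_spliced > self.spots_unique:
            raise AssertionError("spliced count exceeds unique count")


class FilterDecision(enum.Enum):
    KEEP = "keep"
    BLACKLIST = "blacklist"


def is_unique_alignment(record: AlignmentRecord) -> bool:
    """Uniqueness: NH == 1 when the tag is present, else MAPQ >= 30."""
    if not record.is_mapped:
        return False
    if record.nh is not None:
        return record.nh == 1
    return record.mapq >= MAPQ_UNIQUE_THRESHOLD


def _valid_mapped(record: AlignmentRecord, tiles: TileIndex) -> bool:
    """Mapped record with a well-formed CIGAR and an in-bounds position.

    Records failing this are skipped with a warning and the spot falls back
    to the remaining records (or unmapped)."""
    if not record.is_mapped:
        return False
    if not tiles.has_sequence(record.ref_name):
        logger.warning("record %s maps to unknown sequence %s; treated as unmapped",
                       record.qname, record.ref_name)
        return False
    try:
        span = reference_span(record.cigar)
    except AlignmentError as exc:
        logger.warning("record %s skipped: %s", record.qname, exc)
        return False
    if record.pos < 1 or record.pos - 1 + span > tiles.sequence_length(record.ref_name):
        logger.warning("record %s at %s:%d spans beyond sequence end; treated as unmapped",
                       record.qname, record.ref_name, record.pos)
        return False
    return True


def classify_batch(
    run_id: str,
    records: Iterable[AlignmentRecord],
    spots_downloaded: int,
    tiles: TileIndex,
) -> BatchResult:
    """Classify one batch of alignment records into a :class:`BatchResult`.

    Records are grouped into spots by query name (secondary and supplementary
    records are ignored).  A spot is unique iff at least one of its primary
    records aligns uniquely; its representative is the leftmost-mapping unique
    record, whose leftmost aligned base determines the single tile increment.
    A unique spot is spliced iff any of its valid records contains an N
    operation; introns are recorded from the N operations of its unique
    records.  Downloaded spots with no record at all count as unmapped.
    """
    spots: Dict[str, List[AlignmentRecord]] = {}
    for record in records:
        if record.is_secondary or record.is_supplementary:
            continue
        spots.setdefault(record.qname, []).append(record)
    if len(spots) > spots_downloaded:
        raise ValueError(
            f"batch claims {spots_downloaded} spots but contains {len(spots)} query names"
        )

    result = BatchResult(run_id=run_id, spots_downloaded=spots_downloaded)
    increments = result.tile_increments
    for qname, recs in spots.items():
        mapped = [r for r in recs if _valid_mapped(r, tiles)]
        if not mapped:
            result.spots_unmapped += 1
            continue
        unique = [r for r in mapped if is_unique_alignment(r)]
        if not unique:
            result.spots_multi += 1
            continue
        result.spots_unique += 1
        # representative: leftmost-mapping unique record (genome order)
        rep = min(unique, key=lambda r: (r.ref_name, r.pos))
        tile = tiles.tile_of(rep.ref_name, rep.pos - 1)
        increments[tile] = increments.get(tile, 0) + 1
        if any("N" in r.cigar for r in mapped):
            result.spots_spliced += 1
        for r in unique:
            if "N" in r.cigar:
                for intron in extract_introns_from_cigar(r.pos, r.cigar, r.ref_name):
                    result.introns_observed.add(*intron)
    result.spots_unmapped += spots_downloaded - len(spots)
    result.validate()
    return result


def quality_filter(first_batch: BatchResult, threshold: float = 0.05) -> FilterDecision:
    """First-batch alignability filter.

    A run is blacklisted iff the uniquely aligned fraction of its first batch
    is strictly below ``threshold`` (a run at exactly the threshold is kept);
    an empty download also blacklists.  The decision is permanent.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if first_batch.spots_downloaded == 0:
        return FilterDecision.BLACKLIST
    fraction = first_batch.spots_unique / first_batch.spots_downloaded
    return FilterDecision.BLACKLIST if fraction < threshold else FilterDecision.KEEP


def introns_from_alignment_file(path, min_support: int = 1) -> IntronSet:
    """Introns induced by the uniquely aligned spliced records of a SAM/BAM file."""
    import pysam

    out = IntronSet()
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        for aln in handle:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            cigar = aln.cigarstring
            if not cigar or "N" not in cigar:
                continue
            record = AlignmentRecord.from_pysam(aln)
            if not is_unique_alignment(record):
                continue
            for intron in extract_introns_from_cigar(record.pos, cigar, record.ref_name):
                out.add(*intron)
    return out.filtered(min_support) if min_support > 1 else out
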