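"""Second-pass split parsing: splice exclusion and ligation-junction calling.

Proximity-ligation reads carry two kinds of splits: endogenous splice
junctions (canonical GT/AG introns) and ligation junctions produced by
religation of spatially close RNA strands. The two-pass strategy supplies
splice junctions observed in a ligation-free control experiment (plus the
annotation) to the second-pass aligner, so that here every second-pass
split either matches the known splice set — and is discarded — or is a
ligation junction.

Co-linear non-splice splits ("neo-junctions") come from the SAM output's
N operations; non-co-linear splits come from the aligner's chimeric output.
Both are reduced to pairs of *ligation points*: the last aligned base
before and the first aligned base after the skipped region.
"""

from __future__ import annotations

import bisect
import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import (
    Dict, Iterable, List, NamedTuple, Optional, Sequence, Set, Tuple, Union,
)

from intervaltree import IntervalTree

from .io_formats import (
    ChimericJunctionRecord,
    IntronRecord,
    SplitAlignmentRecord,
)

logger = logging.getLogger(__name__)

_CIGAR_TOKEN = re.compile(r"(\d+)([A-Z=])")
_VALID_OPS = set("MIDNSHP=X")
_REF_CONSUMING = set("MDN=X")


class SplitInterval(NamedTuple):
    """The skipped reference interval of one N split, 1-based inclusive."""

    intron_start: int
    intron_end: int


class LigationPoint(NamedTuple):
    """One side of a ligation junction (1-based genomic base)."""

    chrom: str
    pos: int
    side: str  # 'donor' | 'acceptor'


@dataclass
class LigationJunction:
    """A non-splice split (neo or chimeric) with its supporting reads."""

    id: str
    kind: str  # 'neo' | 'chimeric'
    point_a: LigationPoint
    point_b: LigationPoint
    read_ids: Set[str] = field(default_factory=set)

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    @property
    def span(self) -> Optional[int]:
        """|pos_b - pos_a|; defined only for same-chromosome junctions."""
        if self.point_a.chrom != self.point_b.chrom:
            return None
        return abs(self.point_b.pos - self.point_a.pos)


# ---------------------------------------------------------------------------
# CIGAR walking
# ---------------------------------------------------------------------------

def parse_cigar(cigar: str) -> List[Tuple[int, str]]:
    """Parse a CIGAR string into (length, op) pairs, validating strictly."""
    if not cigar or cigar == "*":
        raise ValueError("empty CIGAR")
    ops: List[Tuple[int, str]] = []
    idx = 0
    for m in _CIGAR_TOKEN.finditer(cigar):
        if m.start() != idx:
            raise ValueError(f"invalid CIGAR {cigar!r}")
        length, op = int(m.group(1)), m.group(2)
        if op not in _VALID_OPS:
            raise ValueError(f"invalid CIGAR op {op!r} in {cigar!r}")
        if length <= 0:
            raise ValueError(f"non-positive op length in CIGAR {cigar!r}")
        ops.append((length, op))
        idx = m.end()
    if idx != len(cigar):
        raise ValueError(f"invalid CIGAR {cigar!r}")
    return ops


def extract_splits_from_cigar(pos: int, cigar: str) -> List[SplitInterval]:
    """Return the skipped intervals (N operations) of an alignment.

    ``pos`` is the 1-based leftmost mapped coordinate. M/=/X/D/N consume
    reference; I/S/H/P do not. Deletions (D) consume reference but are
    never reported as splits.
    """
    ref = pos
    splits: List[SplitInterval] = []
    for length, op in parse_cigar(cigar):
        if op == "N":
            splits.append(SplitInterval(ref, ref + length - 1))
            ref += length
        elif op in _REF_CONSUMING:
            ref += length
    return splits


def reference_span(pos: int, cigar: str) -> Tuple[int, int]:
    """1-based inclusive reference interval covered by the alignment."""
    ref = pos
    for length, op in parse_cigar(cigar):
        if op in _REF_CONSUMING:
            ref += length
    return pos, ref - 1


# ---------------------------------------------------------------------------
# known-splice exclusion set
# ---------------------------------------------------------------------------

class KnownJunctionSet:
    """Membership over (chrom, intron_start, intron_end) with tolerance.

    With tolerance t, a query (c, a, b) matches a stored (c, a', b') iff
    |a - a'| <= t and |b - b'| <= t. Tolerance 0 (the default) is exact
    coordinate matching.
    """

    def __init__(
        self,
        introns: Iterable[Tuple[str, int, int]] = (),
        tolerance: int = 0,
    ) -> None:
        if tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        self.tolerance = tolerance
        self._exact: Set[Tuple[str, int, int]] = set()
        self._by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        self._sorted = True
        for chrom, a, b in introns:
            self.add(chrom, a, b)

    def add(self, chrom: str, intron_start: int, intron_end: int) -> None:
        key = (chrom, intron_start, intron_end)
        if key in self._exact:
            return
        self._exact.add(key)
        self._by_chrom.setdefault(chrom, []).append((intron_start, intron_end))
        self._sorted = False

    def __len__(self) -> int:
        return len(self._exact)

    def __contains__(self, key: Tuple[str, int, int]) -> bool:
        return self.matches(*key)

    def matches(self, chrom: str, intron_start: int, intron_end: int) -> bool:
        if self.tolerance == 0:
            return (chrom, intron_start, intron_end) in self._exact
        pairs = self._by_chrom.get(chrom)
        if not pairs:
            return False
        if not self._sorted:
            for lst in self._by_chrom.values():
                lst.sort()
            self._sorted = True
            pairs = self._by_chrom[chrom]
        t = self.tolerance
        lo = bisect.bisect_left(pairs, (intron_start - t, -1))
        for a, b in pairs[lo:]:
            if a > intron_start + t:
                break
            if abs(b - intron_end) <= t:
                return True
        return False


def _flatten_introns(
    source: Union[Iterable[IntronRecord], Iterable[Iterable[IntronRecord]], None],
) -> List[IntronRecord]:
    if source is None:
        return []
    out: List[IntronRecord] = []
    for item in source:
        if isinstance(item, IntronRecord):
            out.append(item)
        else:
            out.extend(item)
    return out


def build_known_set(
    control_sj=None,
    annotation_sj=None,
    tolerance: int = 0,
) -> KnownJunctionSet:
    """Union of control-derived and annotation-derived splice junctions.

    ``control_sj`` may be a single list of :class:`IntronRecord` or a list
    of such lists (one per control replicate). Supplying only
    ``annotation_sj`` reproduces annotation-only exclusion, which misses
    sample-specific unannotated introns.
    """
    known = KnownJunctionSet(tolerance=tolerance)
    for rec in _flatten_introns(control_sj):
        known.add(*rec.key)
    for rec in _flatten_introns(annotation_sj):
        known.add(*rec.key)
    return known


def classify_split(s: SplitInterval, chrom: str, known: KnownJunctionSet) -> str:
    """'splice' if the skipped interval matches the known set, else 'neo'."""
    return "splice" if known.matches(chrom, s.intron_start, s.intron_end) else "neo"


# ---------------------------------------------------------------------------
# region mask
# ---------------------------------------------------------------------------

class RegionMask:
    """Genomic regions (e.g. rRNA loci) whose reads are discarded."""

    def __init__(self, regions: Iterable[Tuple[str, int, int]] = ()) -> None:
        self._trees: Dict[str, IntervalTree] = {}
        for chrom, start, end in regions:
            if end > start:
                self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def overlaps(self, chrom: str, start0: int, end0: int) -> bool:
        """True iff [start0, end0) (0-based half-open) hits a masked region."""
        tree = self._trees.get(chrom)
        if tree is None or end0 <= start0:
            return False
        return bool(tree.overlap(start0, end0))

    def contains_pos(self, chrom: str, pos: int) -> bool:
        """True iff the 1-based position lies inside a masked region."""
        return self.overlaps(chrom, pos - 1, pos)


# ---------------------------------------------------------------------------
# ligation-junction extraction
# ---------------------------------------------------------------------------

def _neo_id(chrom: str, donor: int, acceptor: int) -> str:
    return f"neo:{chrom}:{donor}-{acceptor}"


def neo_junctions_from_alignments(
    alignments: Iterable[SplitAlignmentRecord],
    known: KnownJunctionSet,
    unique_only: bool = True,
    mask: Optional[RegionMask] = None,
    counters: Optional[Dict[str, int]] = None,
) -> List[LigationJunction]:
    """Call co-linear ligation junctions (neo-junctions) from SAM splits.

    Every N split not matching the known splice set becomes a ligation
    junction keyed by its exact skipped interval; read ids are aggregated
    across alignments. Ligation points are the last aligned base before
    (donor) and the first aligned base after (acceptor) the skipped region.
    """
    stats = counters if counters is not None else {}
    stats.setdefault("alignments", 0)
    stats.setdefault("splits", 0)
    stats.setdefault("splice_excluded", 0)
    stats.setdefault("masked_reads", 0)
    stats.setdefault("non_unique_skipped", 0)

    agg: Dict[Tuple[str, int, int], Set[str]] = {}
    for aln in alignments:
        if not aln.is_primary:
            continue
        stats["alignments"] += 1
        if unique_only and not aln.is_unique:
            stats["non_unique_skipped"] += 1
            continue
        if mask is not None:
            lo, hi = reference_span(aln.pos, aln.cigar)
            if mask.overlaps(aln.chrom, lo - 1, hi):
                stats["masked_reads"] += 1
                continue
        for split in extract_splits_from_cigar(aln.pos, aln.cigar):
            stats["splits"] += 1
            if classify_split(split, aln.chrom, known) == "splice":
                stats["splice_excluded"] += 1
                continue
            key = (aln.chrom, split.intron_start, split.intron_end)
            agg.setdefault(key, set()).add(aln.read_id)

    junctions = [
        LigationJunction(
            id=_neo_id(chrom, a - 1, b + 1),
            kind="neo",
            point_a=LigationPoint(chrom, a - 1, "donor"),
            point_b=LigationPoint(chrom, b + 1, "acceptor"),
            read_ids=reads,
        )
        for (chrom, a, b), reads in sorted(agg.items())
    ]
    stats["neo_junctions"] = len(junctions)
    return junctions


def _chimeric_points(
    rec: ChimericJunctionRecord,
) -> Tuple[LigationPoint, LigationPoint]:
    """Recover ligation points from strand-directed breakpoints.

    The donor breakpoint is the first skipped base past the donor segment
    along the donor strand; stepping one base back toward the segment gives
    the last aligned base. Symmetrically for the acceptor.
    """
    d = rec.pos_donor - 1 if rec.strand_donor == "+" else rec.pos_donor + 1
    a = rec.pos_acceptor + 1 if rec.strand_acceptor == "+" else rec.pos_acceptor - 1
    return (
        LigationPoint(rec.chrom_donor, d, "donor"),
        LigationPoint(rec.chrom_acceptor, a, "acceptor"),
    )


def chimeric_to_ligation(
    records: Sequence[ChimericJunctionRecord],
    mask: Optional[RegionMask] = None,
    include_mate_encompassing: bool = False,
    counters: Optional[Dict[str, int]] = None,
) -> List[LigationJunction]:
    """Convert chimeric-output rows to ligation junctions.

    One junction per distinct (donor, acceptor) point pair; read ids
    aggregated. Rows with junction_type -1 (junction falling between read
    mates, hence no sequenced ligation point) are excluded by default.
    Same-chromosome backward-orientation rows are retained: they encode
    intragenic contacts, as in circular RNAs.
    """
    stats = counters if counters is not None else {}
    stats.setdefault("chimeric_records", 0)
    stats.setdefault("mate_encompassing_skipped", 0)
    stats.setdefault("masked_chimeric", 0)

    agg: Dict[Tuple[LigationPoint, LigationPoint], Set[str]] = {}
    for rec in records:
        stats["chimeric_records"] += 1
        if rec.junction_type == -1 and not include_mate_encompassing:
            stats["mate_encompassing_skipped"] += 1
            continue
        pd, pa = _chimeric_points(rec)
        if mask is not None and (
            mask.contains_pos(pd.chrom, pd.pos) or mask.contains_pos(pa.chrom, pa.pos)
        ):
            stats["masked_chimeric"] += 1
            continue
        # canonical unordered key so donor/acceptor swaps collapse
        if (pd.chrom, pd.pos) <= (pa.chrom, pa.pos):
            key = (pd, pa)
        else:
            key = (pa, pd)
        agg.setdefault(key, set()).add(rec.read_id)

    junctions = [
        LigationJunction(
            id=f"chim:{pa.chrom}:{pa.pos}|{pb.chrom}:{pb.pos}",
            kind="chimeric",
            point_a=pa,
            point_b=pb,
            read_ids=reads,
        )
        for (pa, pb), reads in sorted(agg.items())
    ]
    stats["chimeric_junctions"] = len(junctions)
    return junctions


# ---------------------------------------------------------------------------
# mapping summary
# ---------------------------------------------------------------------------

def mapping_summary(
    alignments: Iterable[SplitAlignmentRecord],
    junctions: Sequence[LigationJunction],
    n_total_reads: Optional[int] = None,
) -> Dict[str, float]:
    """Read-level mapping statistics.

    Reports the number of mapped and uniquely mapped reads, and the
    fraction of uniquely mapped reads carrying at least one ligation
    junction. The mapped fraction needs the total read count (mapped +
    unmapped), which the mapped-only stream cannot provide; pass
    ``n_total_reads`` (see :func:`proxilig.io_formats.count_sam_reads`).
    """
    mapped: Set[str] = set()
    unique: Set[str] = set()
    for aln in alignments:
        if not aln.is_primary:
            continue
        mapped.add(aln.read_id)
        if aln.is_unique:
            unique.add(aln.read_id)

    ligation_reads: Set[str] = set()
    for j in junctions:
        ligation_reads |= j.read_ids
    unique_with_ligation = unique & ligation_reads

    if not mapped:
        warnings.warn("no mapped alignments; all fractions reported as 0",
                      stacklevel=2)
    if n_total_reads is None:
        frac_mapped = 0.0
        if mapped:
            warnings.warn(
                "total read count unknown; mapped fraction reported as 0",
                stacklevel=2,
            )
    else:
        frac_mapped = len(mapped) / n_total_reads if n_total_reads else 0.0

    return {
        "n_total": float(n_total_reads) if n_total_reads is not None else 0.0,
        "n_mapped": float(len(mapped)),
        "n_unique": float(len(unique)),
        "n_unique_with_ligation": float(len(unique_with_ligation)),
        "frac_mapped": frac_mapped,
        "frac_unique_of_mapped": len(unique) / len(mapped) if mapped else 0.0,
        "frac_ligation_of_unique": (
            len(unique_with_ligation) / len(unique) if unique else 0.0
        ),
    }


# ---------------------------------------------------------------------------
# junction table round trip (internal format)
# ---------------------------------------------------------------------------

_JUNCTION_HEADER = (
    "id\tkind\tchrom_a\tpos_a\tside_a\tchrom_b\tpos_b\tside_b\tn_reads\tread_ids\n"
)


def write_junction_table(junctions: Sequence[LigationJunction], path) -> None:
    with open(path, "w") as fh:
        fh.write(_JUNCTION_HEADER)
        for j in junctions:
            fh.write(
                f"{j.id}\t{j.kind}\t"
                f"{j.point_a.chrom}\t{j.point_a.pos}\t{j.point_a.side}\t"
                f"{j.point_b.chrom}\t{j.point_b.pos}\t{j.point_b.side}\t"
                f"{j.n_reads}\t{','.join(sorted(j.read_ids))}\n"
            )


def read_junction_table(path) -> List[LigationJunction]:
    junctions: List[LigationJunction] = []
    with open(path) as fh:
        header = fh.readline()
        if header != _JUNCTION_HEADER:
            raise ValueError(f"{path}: not a ligation-junction table")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            junctions.append(
                LigationJunction(
                    id=f[0],
                    kind=f[1],
                    point_a=LigationPoint(f[2], int(f[3]), f[4]),
                    point_b=LigationPoint(f[5], int(f[6]), f[7]),
                    read_ids=set(f[9].split(",")) if f[9] else set(),
                )
            )
    return junctions
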