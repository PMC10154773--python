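"""Browser-ready outputs: span-filtered junction tracks and binned matrices.

Co-linear (same-chromosome) contacts are exported as BED12 arc tracks,
restricted by default to spans of at most 50,000 nt; contact maps are
binned at 100-bp resolution into plain-text COO triplets that convert to
a cooler container with a one-liner downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .clustering import PointCluster
from .contacts import Contact

#: default maximum outer span (nt) of a co-linear contact shown on a track
DEFAULT_MAX_SPAN = 50_000
#: default contact-matrix bin size (bp)
DEFAULT_BIN_SIZE = 100


@dataclass(frozen=True)
class TrackConfig:
    """Track/matrix parameters; region restricts intra-chromosomal maps."""

    max_span: int = DEFAULT_MAX_SPAN
    bin_size: int = DEFAULT_BIN_SIZE
    region: Optional[Tuple[str, int, int]] = None  # (chrom, start0, end0)

    def __post_init__(self) -> None:
        if self.max_span < 1:
            raise ValueError("max_span must be >= 1")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")


def contact_span(
    contact: Contact, clusters: Mapping[str, PointCluster]
) -> Optional[int]:
    """Outer span of a same-chromosome contact; None for trans."""
    a = clusters[contact.cluster_a]
    b = clusters[contact.cluster_b]
    if a.chrom != b.chrom:
        return None
    return max(a.end, b.end) - min(a.start, b.start)


def filter_colinear(
    contacts: Sequence[Contact],
    clusters: Mapping[str, PointCluster],
    cfg: TrackConfig = TrackConfig(),
) -> List[Contact]:
    """Same-chromosome contacts with outer span <= max_span (inclusive)."""
    kept: List[Contact] = []
    for c in contacts:
        span = contact_span(c, clusters)
        if span is not None and span <= cfg.max_span:
            kept.append(c)
    return kept


def bin_matrix(
    contacts: Sequence[Contact],
    clusters: Mapping[str, PointCluster],
    cfg: TrackConfig = TrackConfig(),
) -> List[Tuple[int, int, int]]:
    """Bin same-chromosome contacts into upper-triangle COO triplets.

    Each contact adds its read support r to the bin pair
    (floor(midpoint_a / bin), floor(midpoint_b / bin)), canonicalized so
    i <= j; triplets are summed and returned sorted. When a region is
    configured, only contacts with both midpoints inside it (on its
    chromosome) are binned.
    """
    acc: Dict[Tuple[int, int], int] = {}
    for c in contacts:
        a = clusters[c.cluster_a]
        b = clusters[c.cluster_b]
        if a.chrom != b.chrom:
            continue
        ma, mb = a.midpoint, b.midpoint
        if cfg.region is not None:
            chrom, lo, hi = cfg.region
            if a.chrom != chrom or not (lo <= ma < hi and lo <= mb < hi):
                continue
        i = int(ma // cfg.bin_size)
        j = int(mb // cfg.bin_size)
        if i > j:
            i, j = j, i
        acc[(i, j)] = acc.get((i, j), 0) + c.r
    return [(i, j, v) for (i, j), v in sorted(acc.items())]
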