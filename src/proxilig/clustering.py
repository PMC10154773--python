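"""Single-linkage clustering of ligation points.

Technical (gap-placement) and biological (stochastic religation) variation
smears the two coordinates of a ligation junction over a few nucleotides,
so ligation points form clusters rather than exact recurrent positions.
Points are clustered per chromosome by single linkage with a distance
cutoff delta: two consecutive sorted points join the same cluster iff they
are at most delta nt apart. Each cluster is exported with floor(delta/2)
flanks on both sides, so an isolated point yields a cluster of length
delta (for even delta) — e.g. length 10 at the default delta = 10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .junctions import LigationJunction


class InvariantError(RuntimeError):
    """An internal pipeline invariant was violated."""


@dataclass(frozen=True)
class ClusterConfig:
    """Clustering parameters: cutoff delta (nt) and derived flank."""

    delta: int = 10

    def __post_init__(self) -> None:
        if self.delta < 1:
            raise ValueError("delta must be >= 1")

    @property
    def flank(self) -> int:
        return self.delta // 2


@dataclass
class PointCluster:
    """A delta-linked group of ligation points.

    ``start``/``end`` are the 0-based half-open exported interval
    [min - flank, max + flank), clipped at 0 near the chromosome start.
    """

    id: str
    chrom: str
    start: int
    end: int
    member_positions: Tuple[int, ...]

    @property
    def n_members(self) -> int:
        return len(self.member_positions)

    @property
    def s(self) -> int:
        """Cluster length."""
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


PointRef = Tuple[int, str, str]  # (pos, junction_id, side 'a'|'b')


def collect_points(
    junctions: Sequence[LigationJunction],
) -> Dict[str, List[PointRef]]:
    """Per-chromosome sorted ligation-point multisets with back-references.

    Every junction contributes exactly two points (its two sides);
    multiplicity is preserved.
    """
    by_chrom: Dict[str, List[PointRef]] = {}
    for j in junctions:
        by_chrom.setdefault(j.point_a.chrom, []).append((j.point_a.pos, j.id, "a"))
        by_chrom.setdefault(j.point_b.chrom, []).append((j.point_b.pos, j.id, "b"))
    for refs in by_chrom.values():
        refs.sort()
    return by_chrom


def _sweep_groups(positions: Sequence[int], delta: int) -> List[List[int]]:
    """Group sorted positions: consecutive gap <= delta joins a group."""
    groups: List[List[int]] = []
    current: List[int] = []
    prev: Optional[int] = None
    for pos in positions:
        if prev is not None and pos - prev > delta:
            groups.append(current)
            current = []
        current.append(pos)
        prev = pos
    if current:
        groups.append(current)
    return groups


def cluster_points(
    positions: Sequence[int],
    cfg: ClusterConfig,
    chrom: str = "",
    id_offset: int = 0,
) -> List[PointCluster]:
    """Single-linkage clustering of one chromosome's sorted positions.

    Returns clusters ordered by start, non-overlapping in members. The
    exported interval is [min - flank, max + flank) half-open, with the
    left flank clipped at coordinate 0.
    """
    if list(positions) != sorted(positions):
        raise ValueError("positions must be sorted ascending")
    clusters: List[PointCluster] = []
    for k, group in enumerate(_sweep_groups(positions, cfg.delta)):
        start = max(0, group[0] - cfg.flank)
        end = group[-1] + cfg.flank
        clusters.append(
            PointCluster(
                id=f"C{id_offset + k + 1:06d}",
                chrom=chrom,
                start=start,
                end=end,
                member_positions=tuple(group),
            )
        )
    return clusters


def cluster_junction_points(
    junctions: Sequence[LigationJunction],
    cfg: ClusterConfig,
) -> Tuple[List[PointCluster], Dict[Tuple[str, str], str]]:
    """Cluster all junction points and assign each point to its cluster.

    Returns (clusters ordered by (chrom, start), map (junction_id, side)
    -> cluster id). The map is total over junction sides.
    """
    by_chrom = collect_points(junctions)
    clusters: List[PointCluster] = []
    assignment: Dict[Tuple[str, str], str] = {}
    offset = 0
    for chrom in sorted(by_chrom):
        refs = by_chrom[chrom]
        chrom_clusters = cluster_points(
            [p for p, _, _ in refs], cfg, chrom=chrom, id_offset=offset
        )
        offset += len(chrom_clusters)
        clusters.extend(chrom_clusters)
        # walk refs and clusters in lockstep: both sorted by position
        i = 0
        for cl in chrom_clusters:
            for _ in cl.member_positions:
                pos, jid, side = refs[i]
                assignment[(jid, side)] = cl.id
                i += 1
        if i != len(refs):
            raise InvariantError(
                f"{chrom}: {len(refs) - i} ligation points left unassigned"
            )
    return clusters, assignment


def assign_points(
    junctions: Sequence[LigationJunction],
    clusters: Sequence[PointCluster],
) -> Dict[Tuple[str, str], str]:
    """Map every (junction id, side) to the cluster containing that point."""
    member_index: Dict[Tuple[str, int], str] = {}
    for cl in clusters:
        for pos in cl.member_positions:
            member_index[(cl.chrom, pos)] = cl.id
    assignment: Dict[Tuple[str, str], str] = {}
    for j in junctions:
        for side, point in (("a", j.point_a), ("b", j.point_b)):
            cid = member_index.get((point.chrom, point.pos))
            if cid is None:
                raise InvariantError(
                    f"ligation point {point.chrom}:{point.pos} of junction "
                    f"{j.id} not covered by any cluster"
                )
            assignment[(j.id, side)] = cid
    return assignment


def interpoint_distance_quantiles(
    points_by_chrom: Mapping[str, Sequence],
    quantiles: Sequence[float] = (0.25, 0.5, 0.75, 0.9),
) -> pd.Series:
    """Quantiles of consecutive-point distances, pooled over chromosomes.

    Distances are taken between consecutive sorted points within each
    chromosome only; chromosomes with fewer than two points contribute
    nothing.
    """
    distances: List[np.ndarray] = []
    for refs in points_by_chrom.values():
        positions = np.sort(
            np.asarray([r[0] if isinstance(r, tuple) else r for r in refs])
        )
        if positions.size >= 2:
            distances.append(np.diff(positions))
    if not distances:
        warnings.warn("fewer than 2 points on every chromosome; no distances",
                      stacklevel=2)
        return pd.Series(dtype=float, name="distance")
    pooled = np.concatenate(distances)
    return pd.Series(
        np.quantile(pooled, list(quantiles)),
        index=list(quantiles),
        name="distance",
    )


# ---------------------------------------------------------------------------
# cluster BED round trip
# ---------------------------------------------------------------------------

def write_cluster_bed(clusters: Sequence[PointCluster], path) -> None:
    """BED: chrom, start, end, id, score = member count, plus member list."""
    with open(path, "w") as fh:
        for cl in clusters:
            members = ",".join(str(p) for p in cl.member_positions)
            fh.write(
                f"{cl.chrom}\t{cl.start}\t{cl.end}\t{cl.id}\t"
                f"{cl.n_members}\t.\t{members}\n"
            )


def read_cluster_bed(path) -> List[PointCluster]:
    clusters: List[PointCluster] = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            clusters.append(
                PointCluster(
                    id=f[3],
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    member_positions=tuple(int(p) for p in f[6].split(",")),
                )
            )
    return clusters
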