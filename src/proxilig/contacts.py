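"""Contact assembly, categorization and summary statistics.

A contact is an unordered pair of ligation-point clusters linked by at
least one ligation junction. Contacts fall into three categories:
intragenic (both ends overlap a common annotated gene), cis (same
chromosome, not intragenic) and trans (different chromosomes). Read
support r counts distinct read ids over all linking junctions, guarding
against double counting when one read supports several junctions between
the same cluster pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .clustering import PointCluster
from .io_formats import GeneModel
from .junctions import LigationJunction

CATEGORIES = ("intragenic", "cis", "trans")


@dataclass
class Contact:
    """A canonical cluster pair with category, support and distance."""

    cluster_a: str
    cluster_b: str
    r: int
    kinds: frozenset
    junction_ids: Tuple[str, ...]
    category: Optional[str] = None
    d: Optional[float] = None


class GeneIndex:
    """Interval index of gene models for overlap queries."""

    def __init__(self, genes: Sequence[GeneModel] = ()) -> None:
        self._trees: Dict[str, IntervalTree] = {}
        for g in genes:
            # 1-based inclusive -> 0-based half-open
            self._trees.setdefault(g.chrom, IntervalTree()).addi(
                g.start - 1, g.end, g.gene_id
            )

    def overlapping(self, chrom: str, start0: int, end0: int) -> Set[str]:
        tree = self._trees.get(chrom)
        if tree is None or end0 <= start0:
            return set()
        return {iv.data for iv in tree.overlap(start0, end0)}


def assemble_contacts(
    junctions: Sequence[LigationJunction],
    assignment: Mapping[Tuple[str, str], str],
    clusters: Mapping[str, PointCluster],
) -> Tuple[List[Contact], int]:
    """Group junctions by unordered cluster pair.

    Junctions whose two points fall into the same cluster (self-contacts)
    are dropped and counted; returns (contacts, n_self_contacts). Cluster
    order within a contact is canonical: sorted by (chrom, start).
    """
    groups: Dict[Tuple[str, str], List[LigationJunction]] = {}
    n_self = 0
    for j in junctions:
        ca = assignment[(j.id, "a")]
        cb = assignment[(j.id, "b")]
        if ca == cb:
            n_self += 1
            continue
        a, b = clusters[ca], clusters[cb]
        if (a.chrom, a.start, a.end) > (b.chrom, b.start, b.end):
            ca, cb = cb, ca
        groups.setdefault((ca, cb), []).append(j)

    contacts: List[Contact] = []
    for (ca, cb), linked in groups.items():
        reads: Set[str] = set()
        kinds: Set[str] = set()
        for j in linked:
            reads |= j.read_ids
            kinds.add(j.kind)
        contacts.append(
            Contact(
                cluster_a=ca,
                cluster_b=cb,
                r=len(reads),
                kinds=frozenset(kinds),
                junction_ids=tuple(sorted(j.id for j in linked)),
            )
        )
    contacts.sort(
        key=lambda c: (
            clusters[c.cluster_a].chrom, clusters[c.cluster_a].start,
            clusters[c.cluster_b].chrom, clusters[c.cluster_b].start,
        )
    )
    return contacts, n_self


def categorize(
    contact: Contact,
    clusters: Mapping[str, PointCluster],
    genes: GeneIndex,
) -> str:
    """intragenic / cis / trans per the cluster pair's gene overlap."""
    a = clusters[contact.cluster_a]
    b = clusters[contact.cluster_b]
    if a.chrom != b.chrom:
        return "trans"
    genes_a = genes.overlapping(a.chrom, a.start, a.end)
    genes_b = genes.overlapping(b.chrom, b.start, b.end)
    if genes_a & genes_b:
        return "intragenic"
    return "cis"


def contact_distance(
    contact: Contact, clusters: Mapping[str, PointCluster]
) -> float:
    """Distance d between cluster midpoints, floored at 1 nt.

    Defined only for same-chromosome contacts; the floor keeps log2 d
    defined for overlapping clusters.
    """
    a = clusters[contact.cluster_a]
    b = clusters[contact.cluster_b]
    if a.chrom != b.chrom:
        raise ValueError("distance undefined for trans contacts")
    return max(1.0, abs(a.midpoint - b.midpoint))


def annotate_contacts(
    contacts: Sequence[Contact],
    clusters: Mapping[str, PointCluster],
    genes: GeneIndex,
) -> None:
    """Fill category and d in place."""
    for c in contacts:
        c.category = categorize(c, clusters, genes)
        if c.category != "trans":
            c.d = contact_distance(c, clusters)


def _mean_sd(values: List[float]) -> Tuple[float, float]:
    if not values:
        return (np.nan, np.nan)
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else np.nan
    return mean, sd


def summarize(
    contacts: Sequence[Contact],
    clusters: Mapping[str, PointCluster],
) -> pd.DataFrame:
    """Per-category contact statistics.

    Rows: intragenic, cis, trans. Columns: n; mean/sd of cluster length s
    (each contact contributes both of its clusters); mean/sd of log2 d
    (absent for trans); mean/sd of log2 r. Standard deviations use the
    n-1 denominator and are NaN for fewer than two values.
    """
    s_vals: Dict[str, List[float]] = {c: [] for c in CATEGORIES}
    d_vals: Dict[str, List[float]] = {c: [] for c in CATEGORIES}
    r_vals: Dict[str, List[float]] = {c: [] for c in CATEGORIES}
    n: Dict[str, int] = {c: 0 for c in CATEGORIES}

    for c in contacts:
        if c.category not in CATEGORIES:
            raise ValueError(f"contact without category: {c}")
        n[c.category] += 1
        s_vals[c.category].append(clusters[c.cluster_a].s)
        s_vals[c.category].append(clusters[c.cluster_b].s)
        r_vals[c.category].append(np.log2(c.r))
        if c.category != "trans" and c.d is not None:
            d_vals[c.category].append(np.log2(c.d))

    rows = []
    for cat in CATEGORIES:
        s_mean, s_sd = _mean_sd(s_vals[cat])
        r_mean, r_sd = _mean_sd(r_vals[cat])
        if cat == "trans":
            d_mean, d_sd = (np.nan, np.nan)
        else:
            d_mean, d_sd = _mean_sd(d_vals[cat])
        rows.append(
            {
                "category": cat,
                "n": n[cat],
                "s_mean": s_mean,
                "s_sd": s_sd,
                "log2_d_mean": d_mean,
                "log2_d_sd": d_sd,
                "log2_r_mean": r_mean,
                "log2_r_sd": r_sd,
            }
        )
    return pd.DataFrame(rows).set_index("category")


# ---------------------------------------------------------------------------
# contact table round trip (internal format)
# ---------------------------------------------------------------------------

_CONTACT_HEADER = (
    "cluster_a\tcluster_b\tcategory\tr\td\tkinds\tjunction_ids\n"
)


def write_contact_table(contacts: Sequence[Contact], path) -> None:
    with open(path, "w") as fh:
        fh.write(_CONTACT_HEADER)
        for c in contacts:
            d = "" if c.d is None else repr(c.d)
            fh.write(
                f"{c.cluster_a}\t{c.cluster_b}\t{c.category or ''}\t{c.r}\t{d}\t"
                f"{','.join(sorted(c.kinds))}\t{','.join(c.junction_ids)}\n"
            )


def read_contact_table(path) -> List[Contact]:
    contacts: List[Contact] = []
    with open(path) as fh:
        header = fh.readline()
        if header != _CONTACT_HEADER:
            raise ValueError(f"{path}: not a contact table")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            contacts.append(
                Contact(
                    cluster_a=f[0],
                    cluster_b=f[1],
                    category=f[2] or None,
                    r=int(f[3]),
                    d=float(f[4]) if f[4] else None,
                    kinds=frozenset(f[5].split(",")) if f[5] else frozenset(),
                    junction_ids=tuple(f[6].split(",")) if f[6] else (),
                )
            )
    return contacts
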