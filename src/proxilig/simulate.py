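"""Deterministic generator of aligner-style outputs with planted truth.

Emits the same dialects the readers consume — second-pass SAM text,
9-column splice-junction tables (control and annotation-only), a
14-column chimeric-junction table and a gene GTF — together with truth
tables of the planted introns, ligation junctions and contacts. Reads are
written as already-aligned records: the generator emulates what a spliced
aligner would report for planted splice splits, co-linear ligation splits
and chimeras, so the parsing/clustering/contact logic is testable without
an aligner or any download.

Planted ligation points are kept pairwise far apart (well beyond twice
the largest clustering cutoff), so with per-read coordinate jitter of at
most floor(delta/2) every planted junction maps to exactly one recovered
contact and recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .clustering import PointCluster
from .contacts import Contact
from .io_formats import (
    ChimericJunctionRecord,
    GeneModel,
    IntronRecord,
    write_chimeric_table,
    write_sj_table,
)

#: minimum separation (nt) between any two planted ligation points; must
#: exceed 2*delta + 2*jitter for both supported cutoffs (10 and 20)
MIN_POINT_SEPARATION = 150

_GENE_MARGIN = 300


class FixtureError(ValueError):
    """Invalid fixture configuration or planted coordinates out of range."""


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for the synthetic fixture.

    Defaults model a small two-chromosome genome with six genes, two
    introns per gene (three of the twelve left out of the annotation),
    24 planted contacts (12 co-linear neo junctions + 12 chimeras, three
    reads each), 2-nt coordinate jitter per read, and a sprinkling of
    splice-only, multi-mapped and unmapped reads.
    """

    seed: int
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    n_genes: int = 6
    introns_per_gene: int = 2
    n_unannotated_introns: int = 3
    n_neo: int = 12
    n_chimeric: int = 12
    n_splice_reads: int = 40
    reads_per_junction: int = 3
    n_multimapped: int = 2
    n_unmapped: int = 2
    jitter: int = 2
    read_length: int = 75

    def __post_init__(self) -> None:
        if self.jitter < 0:
            raise FixtureError("jitter must be >= 0")
        for name in (
            "n_genes", "introns_per_gene", "n_unannotated_introns", "n_neo",
            "n_chimeric", "n_splice_reads", "reads_per_junction",
            "n_multimapped", "n_unmapped",
        ):
            if getattr(self, name) < 0:
                raise FixtureError(f"{name} must be >= 0")
        if self.read_length < 40:
            raise FixtureError("read_length must be >= 40")


@dataclass(frozen=True)
class TrueContact:
    """A planted junction / contact: cluster centers, category, support."""

    kind: str  # 'neo' | 'chimeric'
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    category: str
    r: int


@dataclass
class FixtureTruth:
    """Planted ground truth for end-to-end verification."""

    introns: List[IntronRecord]
    unannotated_introns: List[Tuple[str, int, int]]
    junctions: List[TrueContact]

    @property
    def contacts(self) -> List[TrueContact]:
        # each planted junction is isolated, so junction == contact here
        return self.junctions


class _Registry:
    """Per-chromosome placed-point registry enforcing minimum separation."""

    def __init__(self, rng: np.random.Generator) -> None:
        self._rng = rng
        self._points: Dict[str, List[int]] = {}

    def _clear_of(self, chrom: str, pos: int) -> bool:
        return all(
            abs(pos - q) >= MIN_POINT_SEPARATION
            for q in self._points.get(chrom, ())
        )

    def place(self, chrom: str, lo: int, hi: int) -> int:
        if hi - lo < MIN_POINT_SEPARATION:
            raise FixtureError(
                f"placement window [{lo},{hi}) on {chrom} too narrow"
            )
        for _ in range(1000):
            pos = int(self._rng.integers(lo, hi))
            if self._clear_of(chrom, pos):
                self._points.setdefault(chrom, []).append(pos)
                return pos
        raise FixtureError(f"could not place a point in [{lo},{hi}) on {chrom}")

    def place_at(self, chrom: str, pos: int) -> int:
        if not self._clear_of(chrom, pos):
            raise FixtureError(
                f"forced point {chrom}:{pos} violates minimum separation"
            )
        self._points.setdefault(chrom, []).append(pos)
        return pos


def _layout_genes(cfg: FixtureConfig) -> List[GeneModel]:
    chroms = sorted(cfg.chrom_sizes)
    if not chroms:
        raise FixtureError("chrom_sizes must not be empty")
    gene_length = max(20_000, 6_000 * cfg.introns_per_gene + 16_000)
    spacing = gene_length + 40_000
    per_chrom: Dict[str, int] = {c: 0 for c in chroms}
    genes: List[GeneModel] = []
    for i in range(cfg.n_genes):
        chrom = chroms[i % len(chroms)]
        k = per_chrom[chrom]
        per_chrom[chrom] += 1
        start = 50_000 + k * spacing
        end = start + gene_length - 1
        if end + 10_000 > cfg.chrom_sizes[chrom]:
            raise FixtureError(
                f"gene G{i + 1} [{start},{end}] exceeds {chrom} size "
                f"{cfg.chrom_sizes[chrom]}"
            )
        genes.append(GeneModel(f"G{i + 1}", chrom, start, end, "+"))
    return genes


def _plant_introns(
    cfg: FixtureConfig, genes: Sequence[GeneModel], rng: np.random.Generator
) -> Tuple[List[Dict], List[int]]:
    introns: List[Dict] = []
    for g in genes:
        for j in range(cfg.introns_per_gene):
            s = g.start + 2_000 + j * 6_000
            e = s + 999
            if e > g.end - 2_000:
                raise FixtureError(f"intron [{s},{e}] exceeds gene {g.gene_id}")
            introns.append({"gene": g, "start": s, "end": e, "annotated": 1})
    n_unann = min(cfg.n_unannotated_introns, len(introns))
    unann_idx = sorted(
        int(i) for i in rng.choice(len(introns), size=n_unann, replace=False)
    ) if n_unann else []
    for i in unann_idx:
        introns[i]["annotated"] = 0
    return introns, unann_idx


def generate_fixture(
    cfg: FixtureConfig, outdir
) -> Tuple[Dict[str, Path], FixtureTruth]:
    """Write all fixture files into ``outdir``; return (paths, truth).

    Deterministic for a fixed config: running twice produces byte-identical
    files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    registry = _Registry(rng)

    genes = _layout_genes(cfg)
    introns, unann_idx = _plant_introns(cfg, genes, rng)
    chroms = sorted(cfg.chrom_sizes)
    genes_by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    def jit() -> int:
        if cfg.jitter == 0:
            return 0
        return int(rng.integers(-cfg.jitter, cfg.jitter + 1))

    sam_records: List[Tuple] = []  # (qname, flag, rname, pos, mapq, cigar)
    chimeric_rows: List[ChimericJunctionRecord] = []
    true_junctions: List[TrueContact] = []

    # ---- planted neo junctions (co-linear) -------------------------------
    n_intra = (cfg.n_neo + 1) // 2
    n_cis = cfg.n_neo - n_intra
    ann_genes = [
        g for g in genes
        if any(iv["gene"] is g and iv["annotated"] for iv in introns)
    ]
    n_combined = min(2, n_intra) if ann_genes else 0

    intron_coords = {(iv["gene"].chrom, iv["start"], iv["end"]) for iv in introns}

    for j in range(n_intra):
        if j < n_combined:
            g = ann_genes[j % len(ann_genes)]
            intron = next(
                iv for iv in introns if iv["gene"] is g and iv["annotated"]
            )
            p_a = registry.place_at(g.chrom, intron["end"] + 35)
            attached = (intron["start"], intron["end"])
        else:
            g = genes[int(rng.integers(len(genes)))]
            p_a = registry.place(g.chrom, g.start + _GENE_MARGIN, g.start + 8_000)
            attached = None
        p_b = registry.place(g.chrom, p_a + 2_000, g.end - _GENE_MARGIN)
        if (g.chrom, p_a + 1, p_b - 1) in intron_coords:
            raise FixtureError("planted neo split collides with a true intron")
        true_junctions.append(
            TrueContact("neo", g.chrom, p_a, g.chrom, p_b, "intragenic",
                        cfg.reads_per_junction)
        )
        for k in range(cfg.reads_per_junction):
            pa, pb = p_a + jit(), p_b + jit()
            rid = f"neo{j:03d}_{k}"
            if attached is not None:
                a_len = 25
                mid = pa - attached[1]
                gap = pb - pa - 1
                cigar = (
                    f"{a_len}M{attached[1] - attached[0] + 1}N"
                    f"{mid}M{gap}N25M"
                )
                sam_records.append(
                    (rid, 0, g.chrom, attached[0] - a_len, 255, cigar)
                )
            else:
                l1 = cfg.read_length // 2
                l2 = cfg.read_length - l1
                gap = pb - pa - 1
                cigar = f"{l1}M{gap}N{l2}M"
                sam_records.append((rid, 0, g.chrom, pa - l1 + 1, 255, cigar))

    cis_chroms = [c for c in chroms if len(genes_by_chrom.get(c, [])) >= 2]
    if n_cis and not cis_chroms:
        raise FixtureError("cis junctions need >= 2 genes on one chromosome")
    for j in range(n_cis):
        chrom = cis_chroms[j % len(cis_chroms)]
        cands = genes_by_chrom[chrom]
        gi, gj = sorted(cands, key=lambda g: g.start)[:2] if len(cands) == 2 else (
            cands[int(rng.integers(len(cands) - 1))], cands[-1]
        )
        if gi.start > gj.start:
            gi, gj = gj, gi
        p_a = registry.place(chrom, gi.start + _GENE_MARGIN, gi.end - _GENE_MARGIN)
        p_b = registry.place(chrom, gj.start + _GENE_MARGIN, gj.end - _GENE_MARGIN)
        true_junctions.append(
            TrueContact("neo", chrom, p_a, chrom, p_b, "cis",
                        cfg.reads_per_junction)
        )
        l1 = cfg.read_length // 2
        l2 = cfg.read_length - l1
        for k in range(cfg.reads_per_junction):
            pa, pb = p_a + jit(), p_b + jit()
            gap = pb - pa - 1
            sam_records.append(
                (f"cis{j:03d}_{k}", 0, chrom, pa - l1 + 1, 255,
                 f"{l1}M{gap}N{l2}M")
            )

    # ---- planted chimeric junctions --------------------------------------
    n_trans = cfg.n_chimeric // 2
    n_back = cfg.n_chimeric - n_trans
    if n_trans and len(chroms) < 2:
        raise FixtureError("trans chimeras need >= 2 chromosomes")

    def chimeric_rows_for(
        j: int, tag: str, cd: str, pd0: int, sd: str, ca: str, pa0: int, sa: str
    ) -> None:
        for k in range(cfg.reads_per_junction):
            pd_j, pa_j = pd0 + jit(), pa0 + jit()
            brk_d = pd_j + 1 if sd == "+" else pd_j - 1
            brk_a = pa_j - 1 if sa == "+" else pa_j + 1
            chimeric_rows.append(
                ChimericJunctionRecord(
                    chrom_donor=cd, pos_donor=brk_d, strand_donor=sd,
                    chrom_acceptor=ca, pos_acceptor=brk_a, strand_acceptor=sa,
                    junction_type=0, repeat_left=0, repeat_right=0,
                    read_id=f"{tag}{j:03d}_{k}",
                    seg1_start=pd_j - 34, cigar1="35M",
                    seg2_start=pa_j, cigar2="40M",
                )
            )

    for j in range(n_trans):
        g1 = genes_by_chrom[chroms[0]][j % len(genes_by_chrom[chroms[0]])]
        g2 = genes_by_chrom[chroms[1]][j % len(genes_by_chrom[chroms[1]])]
        p_d = registry.place(g1.chrom, g1.start + _GENE_MARGIN, g1.end - _GENE_MARGIN)
        p_a = registry.place(g2.chrom, g2.start + _GENE_MARGIN, g2.end - _GENE_MARGIN)
        strand_a = "-" if j % 2 else "+"
        true_junctions.append(
            TrueContact("chimeric", g1.chrom, p_d, g2.chrom, p_a, "trans",
                        cfg.reads_per_junction)
        )
        chimeric_rows_for(j, "tr", g1.chrom, p_d, "+", g2.chrom, p_a, strand_a)

    for j in range(n_back):
        g = genes[j % len(genes)]
        p_acc = registry.place(g.chrom, g.start + _GENE_MARGIN, g.start + 8_000)
        p_don = registry.place(g.chrom, p_acc + 2_000, g.end - _GENE_MARGIN)
        # backward orientation: donor downstream of acceptor (circRNA-like)
        true_junctions.append(
            TrueContact("chimeric", g.chrom, p_acc, g.chrom, p_don,
                        "intragenic", cfg.reads_per_junction)
        )
        chimeric_rows_for(n_trans + j, "bk", g.chrom, p_don, "+",
                          g.chrom, p_acc, "+")

    # ---- splice-only reads ------------------------------------------------
    sj_counts = [0] * len(introns)
    for m in range(cfg.n_splice_reads):
        i = m % len(introns) if introns else 0
        if not introns:
            break
        iv = introns[i]
        sj_counts[i] += 1
        length = iv["end"] - iv["start"] + 1
        sam_records.append(
            (f"sp{m:03d}", 0, iv["gene"].chrom, iv["start"] - 30, 255,
             f"30M{length}N30M")
        )

    # ---- multi-mapped decoys and unmapped reads ---------------------------
    if cfg.n_multimapped:
        chrom0 = chroms[0]
        d_a = registry.place(chrom0, 5_000, 20_000)
        d_b = registry.place(chrom0, 25_000, 40_000)
        for k in range(cfg.n_multimapped):
            gap = d_b - d_a - 1
            sam_records.append(
                (f"mm{k}", 0, chrom0, d_a - 29, 3, f"30M{gap}N30M")
            )
    for k in range(cfg.n_unmapped):
        sam_records.append((f"un{k}", 4, "*", 0, 0, "*"))

    # ---- range checks ------------------------------------------------------
    for qname, flag, rname, pos, _, _ in sam_records:
        if rname != "*" and not (1 <= pos <= cfg.chrom_sizes[rname]):
            raise FixtureError(f"read {qname} at {rname}:{pos} out of range")
    for t in true_junctions:
        for chrom, pos in ((t.chrom_a, t.pos_a), (t.chrom_b, t.pos_b)):
            if not (1 <= pos <= cfg.chrom_sizes[chrom]):
                raise FixtureError(f"planted point {chrom}:{pos} out of range")

    # ---- write files -------------------------------------------------------
    paths = {
        "sam": outdir / "ligation.sam",
        "control_sj": outdir / "control.sj.tsv",
        "annotation_sj": outdir / "annotation.sj.tsv",
        "genes_gtf": outdir / "genes.gtf",
        "chimeric": outdir / "chimeric.tsv",
        "truth_introns": outdir / "truth_introns.tsv",
        "truth_contacts": outdir / "truth_contacts.tsv",
    }

    with open(paths["sam"], "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom in chroms:
            fh.write(f"@SQ\tSN:{chrom}\tLN:{cfg.chrom_sizes[chrom]}\n")
        for qname, flag, rname, pos, mapq, cigar in sam_records:
            fh.write(
                f"{qname}\t{flag}\t{rname}\t{pos}\t{mapq}\t{cigar}\t"
                "*\t0\t0\t*\t*\n"
            )

    intron_records = [
        IntronRecord(
            chrom=iv["gene"].chrom,
            intron_start=iv["start"],
            intron_end=iv["end"],
            strand_code=1,
            motif_code=1,
            annotated=iv["annotated"],
            unique_reads=sj_counts[i],
        )
        for i, iv in enumerate(introns)
    ]
    write_sj_table(intron_records, paths["control_sj"])
    write_sj_table(
        [r for r in intron_records if r.annotated], paths["annotation_sj"]
    )
    write_chimeric_table(chimeric_rows, paths["chimeric"])

    with open(paths["genes_gtf"], "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tsynthetic\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tsynthetic\ttranscript\t{g.start}\t{g.end}\t.\t"
                f'{g.strand}\t.\t{attrs} transcript_id "{g.gene_id}.1";\n'
            )

    with open(paths["truth_introns"], "w") as fh:
        fh.write("chrom\tintron_start\tintron_end\tannotated\n")
        for iv in introns:
            fh.write(
                f"{iv['gene'].chrom}\t{iv['start']}\t{iv['end']}\t"
                f"{iv['annotated']}\n"
            )

    with open(paths["truth_contacts"], "w") as fh:
        fh.write("kind\tchrom_a\tpos_a\tchrom_b\tpos_b\tcategory\tr\n")
        for t in true_junctions:
            fh.write(
                f"{t.kind}\t{t.chrom_a}\t{t.pos_a}\t{t.chrom_b}\t{t.pos_b}\t"
                f"{t.category}\t{t.r}\n"
            )

    truth = FixtureTruth(
        introns=intron_records,
        unannotated_introns=[
            (introns[i]["gene"].chrom, introns[i]["start"], introns[i]["end"])
            for i in unann_idx
        ],
        junctions=true_junctions,
    )
    return paths, truth


def read_truth_contacts(path) -> List[TrueContact]:
    out: List[TrueContact] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                TrueContact(f[0], f[1], int(f[2]), f[3], int(f[4]), f[5],
                            int(f[6]))
            )
    return out


# ---------------------------------------------------------------------------
# truth evaluation
# ---------------------------------------------------------------------------

def _cluster_contains(
    cluster: PointCluster, chrom: str, pos: int, window: int
) -> bool:
    return (
        cluster.chrom == chrom
        and cluster.start - window <= pos <= cluster.end + window
    )


def evaluate_against_truth(
    contacts: Sequence[Contact],
    clusters: Mapping[str, PointCluster],
    truth: Sequence[TrueContact],
    match_window: int = 0,
    require_category: bool = True,
    require_r: bool = True,
) -> Tuple[float, float]:
    """Score recovered contacts against planted truth.

    A recovered contact matches a true contact iff its two cluster
    intervals contain the corresponding planted centers (within
    ``match_window``), in either orientation, and — when required — the
    category and read support agree. Matching is one-to-one. Returns
    (precision, recall); each is 1.0 when its denominator is empty.
    """
    matched_true: set = set()
    n_matched = 0
    for c in contacts:
        a = clusters[c.cluster_a]
        b = clusters[c.cluster_b]
        for ti, t in enumerate(truth):
            if ti in matched_true:
                continue
            geometric = (
                _cluster_contains(a, t.chrom_a, t.pos_a, match_window)
                and _cluster_contains(b, t.chrom_b, t.pos_b, match_window)
            ) or (
                _cluster_contains(a, t.chrom_b, t.pos_b, match_window)
                and _cluster_contains(b, t.chrom_a, t.pos_a, match_window)
            )
            if not geometric:
                continue
            if require_category and c.category != t.category:
                continue
            if require_r and c.r != t.r:
                continue
            matched_true.add(ti)
            n_matched += 1
            break
    precision = n_matched / len(contacts) if contacts else 1.0
    recall = len(matched_true) / len(truth) if truth else 1.0
    return precision, recall
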