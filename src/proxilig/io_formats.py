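"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions are strict and asymmetric by design:

* internal junction/intron coordinates are **1-based inclusive** (the
  convention of splice-junction tables and chimeric-junction tables
  emitted by spliced aligners);
* everything in the BED family (cluster BED, BEDPE, BED12 tracks, masks)
  is **0-based half-open**.

Conversions happen exactly once, at the format boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import pysam

PathLike = Union[str, Path]

#: mapping quality at/above which an alignment is considered uniquely mapped.
#: 255 is the conventional unique-mapper value of spliced short-read aligners.
DEFAULT_UNIQUE_MAPQ = 255

_CIGAR_OPS = set("MIDNSHP=X")


class FormatError(ValueError):
    """Malformed input file; message names the file and line when known."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitAlignmentRecord:
    """One aligned read segment from the second-pass SAM output.

    ``pos`` is the 1-based leftmost mapped reference coordinate;
    ``is_unique`` is derived from mapping quality.
    """

    read_id: str
    chrom: str
    strand: str  # '+' or '-'
    pos: int
    cigar: str
    is_unique: bool
    is_primary: bool


@dataclass(frozen=True)
class IntronRecord:
    """One row of a 9-column splice-junction table.

    ``intron_start``/``intron_end`` are the 1-based first and last intronic
    bases. ``strand_code`` is 0 (undefined), 1 (+) or 2 (-); ``motif_code``
    0..6 encodes the splice-site dinucleotides; ``annotated`` is 0/1.
    """

    chrom: str
    intron_start: int
    intron_end: int
    strand_code: int
    motif_code: int
    annotated: int
    unique_reads: int
    multi_reads: int = 0
    max_overhang: int = 0

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise ValueError(
                f"intron_start {self.intron_start} > intron_end {self.intron_end}"
            )

    @property
    def key(self) -> Tuple[str, int, int]:
        return (self.chrom, self.intron_start, self.intron_end)


@dataclass(frozen=True)
class ChimericJunctionRecord:
    """One read-level row of a chimeric-junction table (14 classic columns).

    ``junction_type`` -1 marks a junction lying between read mates (no
    sequenced ligation point); 0/1/2 are sequenced junctions by splice-motif
    class. Breakpoint positions are 1-based and strand-directed: the donor
    breakpoint is the first skipped base after the donor segment along the
    donor strand, the acceptor breakpoint the last skipped base before the
    acceptor segment along the acceptor strand.
    """

    chrom_donor: str
    pos_donor: int
    strand_donor: str
    chrom_acceptor: str
    pos_acceptor: int
    strand_acceptor: str
    junction_type: int
    repeat_left: int
    repeat_right: int
    read_id: str
    seg1_start: int
    cigar1: str
    seg2_start: int
    cigar2: str


@dataclass(frozen=True)
class GeneModel:
    """A gene locus; coordinates 1-based inclusive internally."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.start > self.end:
            raise ValueError(f"gene start {self.start} > end {self.end}")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def _count_header_lines(path: PathLike) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                n += 1
            else:
                break
    return n


def read_sam_splits(
    path: PathLike,
    unique_mapq: int = DEFAULT_UNIQUE_MAPQ,
) -> Iterator[SplitAlignmentRecord]:
    """Stream alignment records from a SAM text file.

    Unmapped records are skipped. Parse failures are reported with the
    offending line number.
    """
    path = str(path)
    lineno = _count_header_lines(path)
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        it = iter(sam)
        while True:
            lineno += 1
            try:
                aln = next(it)
            except StopIteration:
                return
            except Exception as exc:  # pysam raises plain ValueError
                raise FormatError(
                    f"{path}: malformed SAM record at line {lineno}: {exc}"
                ) from None
            if aln.is_unmapped:
                continue
            cigar = aln.cigarstring
            if not cigar:
                raise FormatError(
                    f"{path}: mapped record without CIGAR at line {lineno}"
                )
            yield SplitAlignmentRecord(
                read_id=aln.query_name,
                chrom=aln.reference_name,
                strand="-" if aln.is_reverse else "+",
                pos=aln.reference_start + 1,
                cigar=cigar,
                is_unique=aln.mapping_quality >= unique_mapq,
                is_primary=not (aln.is_secondary or aln.is_supplementary),
            )


def count_sam_reads(path: PathLike) -> Tuple[int, int, int]:
    """Return (total, mapped, unique-mapped) primary-record counts.

    Counts every primary record including unmapped ones, which
    :func:`read_sam_splits` deliberately skips.
    """
    total = mapped = unique = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_secondary or aln.is_supplementary:
                continue
            total += 1
            if not aln.is_unmapped:
                mapped += 1
                if aln.mapping_quality >= DEFAULT_UNIQUE_MAPQ:
                    unique += 1
    return total, mapped, unique


# ---------------------------------------------------------------------------
# splice-junction tables (9 columns)
# ---------------------------------------------------------------------------

def read_sj_table(path: PathLike) -> List[IntronRecord]:
    """Read a 9-column tab-separated splice-junction table."""
    records: List[IntronRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 columns, got {len(fields)}"
                )
            try:
                records.append(
                    IntronRecord(
                        chrom=fields[0],
                        intron_start=int(fields[1]),
                        intron_end=int(fields[2]),
                        strand_code=int(fields[3]),
                        motif_code=int(fields[4]),
                        annotated=int(fields[5]),
                        unique_reads=int(fields[6]),
                        multi_reads=int(fields[7]),
                        max_overhang=int(fields[8]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return records


def write_sj_table(records: Iterable[IntronRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.chrom, r.intron_start, r.intron_end, r.strand_code,
                        r.motif_code, r.annotated, r.unique_reads,
                        r.multi_reads, r.max_overhang,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# chimeric-junction tables
# ---------------------------------------------------------------------------

def read_chimeric_table(path: PathLike) -> List[ChimericJunctionRecord]:
    """Read a chimeric-junction table.

    Accepts both the classic headerless 14-column dialect and the newer
    dialect with a header line starting ``chr_donorA`` and trailing
    ``#``-comment lines; extra columns beyond the first 14 are ignored.
    """
    records: List[ChimericJunctionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "chr_donorA":
                continue
            if len(fields) < 14:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=14 columns, got {len(fields)}"
                )
            try:
                records.append(
                    ChimericJunctionRecord(
                        chrom_donor=fields[0],
                        pos_donor=int(fields[1]),
                        strand_donor=fields[2],
                        chrom_acceptor=fields[3],
                        pos_acceptor=int(fields[4]),
                        strand_acceptor=fields[5],
                        junction_type=int(fields[6]),
                        repeat_left=int(fields[7]),
                        repeat_right=int(fields[8]),
                        read_id=fields[9],
                        seg1_start=int(fields[10]),
                        cigar1=fields[11],
                        seg2_start=int(fields[12]),
                        cigar2=fields[13],
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return records


def write_chimeric_table(
    records: Iterable[ChimericJunctionRecord], path: PathLike
) -> None:
    """Write the classic headerless 14-column dialect."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.chrom_donor, r.pos_donor, r.strand_donor,
                        r.chrom_acceptor, r.pos_acceptor, r.strand_acceptor,
                        r.junction_type, r.repeat_left, r.repeat_right,
                        r.read_id, r.seg1_start, r.cigar1, r.seg2_start,
                        r.cigar2,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def read_gene_models(path: PathLike, format: str = "gtf") -> List[GeneModel]:
    """Read gene loci from GTF (``gene`` feature rows) or BED6.

    BED input (0-based half-open) is converted to the internal 1-based
    inclusive convention.
    """
    if format == "gtf":
        return _read_gtf_genes(path)
    if format == "bed":
        return _read_bed6_genes(path)
    raise ValueError(f"unknown annotation format {format!r}; expected 'gtf' or 'bed'")


def _gtf_attribute(attributes: str, key: str) -> Optional[str]:
    # GTF attributes: key "value"; pairs separated by semicolons
    for part in attributes.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            value = part[len(key):].strip()
            return value.strip('"')
    return None


def _read_gtf_genes(path: PathLike) -> List[GeneModel]:
    genes: List[GeneModel] = []
    saw_rows = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 GTF columns, got {len(fields)}"
                )
            saw_rows = True
            if fields[2] != "gene":
                continue
            gene_id = _gtf_attribute(fields[8], "gene_id")
            if gene_id is None:
                raise FormatError(f"{path}: line {lineno}: gene row without gene_id")
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=fields[0],
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=fields[6],
                )
            )
    if saw_rows and not genes:
        warnings.warn(
            f"{path}: no 'gene' feature rows found; gene-level categorization "
            "will be empty",
            stacklevel=2,
        )
    return genes


def _read_bed6_genes(path: PathLike) -> List[GeneModel]:
    genes: List[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=6 BED columns, got {len(fields)}"
                )
            genes.append(
                GeneModel(
                    gene_id=fields[3],
                    chrom=fields[0],
                    start=int(fields[1]) + 1,  # 0-based -> 1-based
                    end=int(fields[2]),
                    strand=fields[5],
                )
            )
    return genes


def read_bed_regions(path: PathLike) -> List[Tuple[str, int, int]]:
    """Read BED intervals as (chrom, start, end), 0-based half-open."""
    regions: List[Tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 BED columns, got {len(fields)}"
                )
            regions.append((fields[0], int(fields[1]), int(fields[2])))
    return regions


# ---------------------------------------------------------------------------
# browser-facing writers (0-based half-open)
# ---------------------------------------------------------------------------

def write_bedpe(contacts: Sequence, clusters: dict, path: PathLike) -> None:
    """Write contacts as 8-column BEDPE (name '.', score = read support)."""
    with open(path, "w") as fh:
        for c in contacts:
            a = clusters[c.cluster_a]
            b = clusters[c.cluster_b]
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t"
                f"{b.chrom}\t{b.start}\t{b.end}\t.\t{c.r}\n"
            )


def write_bed12_track(contacts: Sequence, clusters: dict, path: PathLike) -> None:
    """Write same-chromosome contacts as a BED12 junction-arc track.

    Each contact becomes one record spanning both clusters, with the two
    cluster intervals as blocks and score = min(1000, read support).
    Overlapping clusters collapse to a single block to keep the record valid.
    """
    with open(path, "w") as fh:
        for idx, c in enumerate(contacts, start=1):
            a = clusters[c.cluster_a]
            b = clusters[c.cluster_b]
            if a.chrom != b.chrom:
                continue
            start = min(a.start, b.start)
            end = max(a.end, b.end)
            score = min(1000, c.r)
            name = f"contact_{idx}"
            if b.start < a.end:  # blocks would overlap
                blocks = [(start, end - start)]
            else:
                blocks = [(a.start, a.end - a.start), (b.start, b.end - b.start)]
            sizes = ",".join(str(s) for _, s in blocks)
            starts = ",".join(str(p - start) for p, _ in blocks)
            fh.write(
                f"{a.chrom}\t{start}\t{end}\t{name}\t{score}\t.\t"
                f"{start}\t{end}\t0\t{len(blocks)}\t{sizes}\t{starts}\n"
            )


def write_coo_matrix(
    triplets: Iterable[Tuple[int, int, int]], path: PathLike
) -> None:
    """Write (bin_i, bin_j, value) triplets as tab-separated text."""
    with open(path, "w") as fh:
        for i, j, v in triplets:
            fh.write(f"{i}\t{j}\t{v}\n")
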