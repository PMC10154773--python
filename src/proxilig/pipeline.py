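"""Stage orchestration: YAML configuration, manifests, and stage runners.

Stages (``extract``, ``cluster``, ``contacts``, ``tracks``, ``summarize``)
are idempotent, re-runnable functions over files in the output directory;
``all`` chains them. Each stage writes a manifest recording its inputs,
parameters and output checksums, so two runs with identical configuration
and inputs are byte-identical — there is no unseeded randomness anywhere
in the main pipeline.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from . import clustering, contacts as contacts_mod, io_formats, junctions, tracks
from .clustering import ClusterConfig, InvariantError
from .tracks import TrackConfig

logger = logging.getLogger("proxilig")

STAGES = ("extract", "cluster", "contacts", "tracks", "summarize")


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


_INPUT_KEYS = {
    "control_sj", "annotation_sj", "genes", "genes_format", "sam",
    "chimeric", "mask",
}
_PARAM_KEYS = {
    "delta", "tolerance", "unique_only", "unique_mapq",
    "include_mate_encompassing", "max_span", "bin_size", "region",
}
_TOP_KEYS = {"inputs", "params", "output_dir", "seed"}


@dataclass
class PipelineConfig:
    control_sj: List[str] = field(default_factory=list)
    annotation_sj: Optional[str] = None
    genes: Optional[str] = None
    genes_format: str = "gtf"
    sam: List[str] = field(default_factory=list)
    chimeric: List[str] = field(default_factory=list)
    mask: Optional[str] = None
    delta: int = 10
    tolerance: int = 0
    unique_only: bool = True
    unique_mapq: int = io_formats.DEFAULT_UNIQUE_MAPQ
    include_mate_encompassing: bool = False
    max_span: int = tracks.DEFAULT_MAX_SPAN
    bin_size: int = tracks.DEFAULT_BIN_SIZE
    region: Optional[Tuple[str, int, int]] = None
    output_dir: str = "proxilig_out"
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.delta < 1:
            raise ConfigError("delta must be >= 1")
        if self.tolerance < 0:
            raise ConfigError("tolerance must be >= 0")
        if self.max_span < 1:
            raise ConfigError("max_span must be >= 1")
        if self.bin_size < 1:
            raise ConfigError("bin_size must be >= 1")

    def require_inputs(self, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            paths = value if isinstance(value, list) else ([value] if value else [])
            if not paths:
                raise ConfigError(f"missing required input: {name}")
            for p in paths:
                if not Path(p).exists():
                    raise ConfigError(f"input file not found: {p}")


def _parse_region(value) -> Tuple[str, int, int]:
    if isinstance(value, (list, tuple)) and len(value) == 3:
        return (str(value[0]), int(value[1]), int(value[2]))
    if isinstance(value, str) and ":" in value and "-" in value:
        chrom, span = value.split(":", 1)
        lo, hi = span.split("-", 1)
        return (chrom, int(lo), int(hi))
    raise ConfigError(f"cannot parse region {value!r}; expected 'chrom:start-end'")


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load a YAML configuration file, applying keyword overrides.

    Unknown keys at any level are a hard error listing the offenders.
    """
    cfg = PipelineConfig()
    if path is not None:
        if not Path(path).exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        unknown = sorted(set(raw) - _TOP_KEYS)
        if unknown:
            raise ConfigError(f"{path}: unknown config keys: {', '.join(unknown)}")
        inputs = raw.get("inputs") or {}
        params = raw.get("params") or {}
        unknown = sorted(set(inputs) - _INPUT_KEYS)
        if unknown:
            raise ConfigError(f"{path}: unknown input keys: {', '.join(unknown)}")
        unknown = sorted(set(params) - _PARAM_KEYS)
        if unknown:
            raise ConfigError(f"{path}: unknown param keys: {', '.join(unknown)}")
        for key, value in inputs.items():
            if key in ("control_sj", "sam", "chimeric") and isinstance(value, str):
                value = [value]
            setattr(cfg, key, value)
        for key, value in params.items():
            if key == "region" and value is not None:
                value = _parse_region(value)
            setattr(cfg, key, value)
        if "output_dir" in raw:
            cfg.output_dir = str(raw["output_dir"])
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
    for key, value in overrides.items():
        if value is None:
            continue
        if not hasattr(cfg, key):
            raise ConfigError(f"unknown config override: {key}")
        if key == "region":
            value = _parse_region(value)
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(
    outdir: Path, stage: str, inputs: List[str], params: Dict,
    outputs: List[Path], counts: Dict[str, int],
) -> None:
    manifest = {
        "stage": stage,
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
        "params": params,
        "outputs": {str(p): _sha256(p) for p in outputs},
        "counts": counts,
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _outdir(cfg: PipelineConfig) -> Path:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _load_mask(cfg: PipelineConfig) -> Optional[junctions.RegionMask]:
    if cfg.mask is None:
        return None
    return junctions.RegionMask(io_formats.read_bed_regions(cfg.mask))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_extract(cfg: PipelineConfig) -> Path:
    """Parse second-pass outputs into the ligation-junction table."""
    cfg.require_inputs("sam")
    if cfg.chimeric:
        cfg.require_inputs("chimeric")
    if cfg.control_sj:
        cfg.require_inputs("control_sj")
    if cfg.annotation_sj:
        cfg.require_inputs("annotation_sj")
    out = _outdir(cfg)
    mask = _load_mask(cfg)

    control = [io_formats.read_sj_table(p) for p in cfg.control_sj]
    annotation = (
        io_formats.read_sj_table(cfg.annotation_sj) if cfg.annotation_sj else []
    )
    known = junctions.build_known_set(control, annotation, tolerance=cfg.tolerance)

    counters: Dict[str, int] = {}

    def stream():
        for p in cfg.sam:
            yield from io_formats.read_sam_splits(p, unique_mapq=cfg.unique_mapq)

    neo = junctions.neo_junctions_from_alignments(
        stream(), known, unique_only=cfg.unique_only, mask=mask,
        counters=counters,
    )
    chim_records = []
    for p in cfg.chimeric:
        chim_records.extend(io_formats.read_chimeric_table(p))
    chim = junctions.chimeric_to_ligation(
        chim_records, mask=mask,
        include_mate_encompassing=cfg.include_mate_encompassing,
        counters=counters,
    )
    all_junctions = neo + chim
    # post-condition: no emitted junction matches the known splice set
    for j in all_junctions:
        if j.kind == "neo" and known.matches(
            j.point_a.chrom, j.point_a.pos + 1, j.point_b.pos - 1
        ):
            raise InvariantError(f"splice junction leaked into output: {j.id}")

    table = out / "junctions.tsv"
    junctions.write_junction_table(all_junctions, table)
    counters["known_splice_junctions"] = len(known)
    counters["ligation_junctions"] = len(all_junctions)
    logger.info(
        "extract: alignments=%d splits=%d splice_excluded=%d neo=%d "
        "chimeric=%d",
        counters.get("alignments", 0), counters.get("splits", 0),
        counters.get("splice_excluded", 0), counters.get("neo_junctions", 0),
        counters.get("chimeric_junctions", 0),
    )
    _write_manifest(
        out, "extract",
        cfg.sam + cfg.chimeric + cfg.control_sj
        + ([cfg.annotation_sj] if cfg.annotation_sj else []),
        {"tolerance": cfg.tolerance, "unique_only": cfg.unique_only,
         "unique_mapq": cfg.unique_mapq,
         "include_mate_encompassing": cfg.include_mate_encompassing},
        [table], counters,
    )
    return table


def stage_cluster(cfg: PipelineConfig) -> Path:
    """Cluster ligation points at cutoff delta; write the cluster BED."""
    out = _outdir(cfg)
    table = out / "junctions.tsv"
    if not table.exists():
        raise ConfigError(f"input file not found: {table} (run extract first)")
    all_junctions = junctions.read_junction_table(table)
    clusters, _ = clustering.cluster_junction_points(
        all_junctions, ClusterConfig(delta=cfg.delta)
    )
    bed = out / "clusters.bed"
    clustering.write_cluster_bed(clusters, bed)
    n_points = sum(c.n_members for c in clusters)
    logger.info(
        "cluster: delta=%d points=%d clusters=%d", cfg.delta, n_points,
        len(clusters),
    )
    _write_manifest(
        out, "cluster", [str(table)], {"delta": cfg.delta}, [bed],
        {"points": n_points, "clusters": len(clusters)},
    )
    return bed


def stage_contacts(cfg: PipelineConfig) -> Path:
    """Assemble, categorize and export contacts."""
    cfg.require_inputs("genes")
    out = _outdir(cfg)
    jt, cb = out / "junctions.tsv", out / "clusters.bed"
    for p in (jt, cb):
        if not p.exists():
            raise ConfigError(f"input file not found: {p} (run earlier stages)")
    all_junctions = junctions.read_junction_table(jt)
    clusters = {c.id: c for c in clustering.read_cluster_bed(cb)}
    assignment = clustering.assign_points(all_junctions, clusters.values())
    contact_list, n_self = contacts_mod.assemble_contacts(
        all_junctions, assignment, clusters
    )
    genes = contacts_mod.GeneIndex(
        io_formats.read_gene_models(cfg.genes, format=cfg.genes_format)
    )
    contacts_mod.annotate_contacts(contact_list, clusters, genes)

    table = out / "contacts.tsv"
    contacts_mod.write_contact_table(contact_list, table)
    bedpe = out / "contacts.bedpe"
    io_formats.write_bedpe(contact_list, clusters, bedpe)

    by_cat = {c: 0 for c in contacts_mod.CATEGORIES}
    for c in contact_list:
        by_cat[c.category] += 1
    logger.info(
        "contacts: total=%d intragenic=%d cis=%d trans=%d self_contacts=%d",
        len(contact_list), by_cat["intragenic"], by_cat["cis"],
        by_cat["trans"], n_self,
    )
    _write_manifest(
        out, "contacts", [str(jt), str(cb), cfg.genes],
        {"genes_format": cfg.genes_format},
        [table, bedpe],
        {"contacts": len(contact_list), "self_contacts": n_self, **by_cat},
    )
    return table


def stage_tracks(cfg: PipelineConfig) -> Path:
    """Write the span-filtered BED12 track and the binned COO matrix."""
    out = _outdir(cfg)
    ct, cb = out / "contacts.tsv", out / "clusters.bed"
    for p in (ct, cb):
        if not p.exists():
            raise ConfigError(f"input file not found: {p} (run earlier stages)")
    contact_list = contacts_mod.read_contact_table(ct)
    clusters = {c.id: c for c in clustering.read_cluster_bed(cb)}
    tcfg = TrackConfig(
        max_span=cfg.max_span, bin_size=cfg.bin_size, region=cfg.region
    )
    colinear = tracks.filter_colinear(contact_list, clusters, tcfg)
    bed12 = out / "track.bed12"
    io_formats.write_bed12_track(colinear, clusters, bed12)
    triplets = tracks.bin_matrix(contact_list, clusters, tcfg)
    coo = out / "matrix.coo.tsv"
    io_formats.write_coo_matrix(triplets, coo)
    logger.info(
        "tracks: colinear_kept=%d max_span=%d bins=%d bin_size=%d",
        len(colinear), cfg.max_span, len(triplets), cfg.bin_size,
    )
    _write_manifest(
        out, "tracks", [str(ct), str(cb)],
        {"max_span": cfg.max_span, "bin_size": cfg.bin_size,
         "region": list(cfg.region) if cfg.region else None},
        [bed12, coo],
        {"colinear": len(colinear), "triplets": len(triplets)},
    )
    return bed12


def stage_summarize(cfg: PipelineConfig) -> Path:
    """Contact statistics, inter-point distance quantiles, mapping summary."""
    out = _outdir(cfg)
    ct, cb, jt = out / "contacts.tsv", out / "clusters.bed", out / "junctions.tsv"
    for p in (ct, cb, jt):
        if not p.exists():
            raise ConfigError(f"input file not found: {p} (run earlier stages)")
    contact_list = contacts_mod.read_contact_table(ct)
    clusters = {c.id: c for c in clustering.read_cluster_bed(cb)}
    all_junctions = junctions.read_junction_table(jt)

    stats = contacts_mod.summarize(contact_list, clusters)
    stats_path = out / "contact_stats.tsv"
    stats.to_csv(stats_path, sep="\t", float_format="%.6g")

    points = clustering.collect_points(all_junctions)
    quant = clustering.interpoint_distance_quantiles(points)
    quant_path = out / "distance_quantiles.tsv"
    quant.to_csv(quant_path, sep="\t", header=["distance"], index_label="quantile")

    summary_path = out / "mapping_summary.tsv"
    outputs = [stats_path, quant_path]
    if cfg.sam:
        cfg.require_inputs("sam")
        total = mapped = unique = 0
        for p in cfg.sam:
            t, m, u = io_formats.count_sam_reads(p)
            total, mapped, unique = total + t, mapped + m, unique + u

        def stream():
            for p in cfg.sam:
                yield from io_formats.read_sam_splits(
                    p, unique_mapq=cfg.unique_mapq
                )

        summary = junctions.mapping_summary(
            stream(), all_junctions, n_total_reads=total
        )
        with open(summary_path, "w") as fh:
            for key, value in summary.items():
                fh.write(f"{key}\t{value:.6g}\n")
        outputs.append(summary_path)

    logger.info("summarize: contacts=%d clusters=%d", len(contact_list),
                len(clusters))
    _write_manifest(
        out, "summarize", [str(ct), str(cb), str(jt)] + cfg.sam, {},
        outputs, {"contacts": len(contact_list)},
    )
    return stats_path


def run(stage: str, cfg: PipelineConfig) -> None:
    """Run one named stage, or ``all`` to chain the full pipeline."""
    cfg.validate()
    if stage == "all":
        for s in STAGES:
            run(s, cfg)
        return
    if stage == "extract":
        stage_extract(cfg)
    elif stage == "cluster":
        stage_cluster(cfg)
    elif stage == "contacts":
        stage_contacts(cfg)
    elif stage == "tracks":
        stage_tracks(cfg)
    elif stage == "summarize":
        stage_summarize(cfg)
    else:
        raise ConfigError(f"unknown stage: {stage}")
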