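"""End-to-end orchestration and the output-folder contract.

Stage order: demultiplex + quality-bin, cluster the truncated high bin
into OTUs, map all high+mid reads onto the seeds for abundance, extend
each seed to the best full-length member read, classify the extended
seeds (from a precomputed tabular hit file or an external aligner
hook), and aggregate counts at every rank.

The output folder is a stable contract::

    OTU_table.tsv      OTU x sample integer counts
    OTU_taxonomy.tsv   per-OTU 7-rank lineage ('?' = unassigned)
    seeds.fasta        extended OTU seed sequences
    table.biom         BIOM 1.0 JSON with taxonomy metadata
    logs/              run log + demultiplexing report
    config/            copies of mapping and filter-option files
    higher_taxa/       one taxa x sample TSV per rank
"""

from __future__ import annotations

import json
import shutil
import subprocess
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import seqio
from .biomio import write_biom
from .cluster import (
    cluster_otus, dereplicate, load_external_clusters, map_reads_to_otus,
)
from .demux import DemuxResult, FilterSpec, demultiplex_run
from .seeds import extend_seeds
from .seqio import read_mapping, read_option_file, read_sequences
from .taxonomy import (
    RANKS, LcaSpec, TaxonomyPath, aggregate_taxa, classify_all,
    read_blast_table, read_reference_taxonomy, write_taxonomy_tsv,
)


@dataclass
class RunConfig:
    input_paths: list
    mapping_path: object
    output_dir: object
    option_path: Optional[object] = None
    platform: str = "454"  # 454 | miseq (second input file = reverse mates)
    cluster_identity: float = 0.97
    external_seeds: Optional[object] = None       # FASTA from external clusterer
    external_membership: Optional[object] = None  # read_id<TAB>otu_id
    blast_table: Optional[object] = None          # precomputed outfmt-6 hits
    reference_taxonomy: Optional[object] = None
    aligner_cmd: Optional[str] = None   # template: {query} {out}
    tree_cmd: Optional[str] = None      # template: {seeds} {out}; stores returned tree
    lca_spec: LcaSpec = field(default_factory=LcaSpec)
    filter_spec: Optional[FilterSpec] = None
    overwrite: bool = False


@dataclass
class StageRecord:
    name: str
    seconds: float
    counts: dict


@dataclass
class RunLog:
    stages: list[StageRecord] = field(default_factory=list)
    failed_stage: Optional[str] = None

    def add(self, name: str, seconds: float, **counts) -> None:
        if any(s.name == name for s in self.stages):
            raise ValueError(f"stage {name!r} already logged")
        self.stages.append(StageRecord(name, seconds, counts))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _prepare_outdir(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    if out.exists() and any(out.iterdir()) and not config.overwrite:
        raise FileExistsError(f"output dir {out} is not empty (use overwrite)")
    for sub in ("logs", "config", "higher_taxa"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    return out


def write_reports(run_log: RunLog, demux_result: Optional[DemuxResult],
                  outdir) -> None:
    """Human-readable run report + machine-readable per-stage TSV."""
    outdir = Path(outdir)
    lines = ["amplitax run report", "==================="]
    rows = []
    for stage in run_log.stages:
        counts = ", ".join(f"{k}={v}" for k, v in stage.counts.items())
        lines.append(f"{stage.name:<14} {stage.seconds:8.2f}s  {counts}")
        rows.append({"stage": stage.name, "seconds": round(stage.seconds, 3),
                     **stage.counts})
    if run_log.failed_stage:
        lines.append(f"FAILED at stage: {run_log.failed_stage}")
    (outdir / "run_report.txt").write_text("\n".join(lines) + "\n")
    pd.DataFrame(rows).to_csv(outdir / "stage_counts.tsv", sep="\t", index=False)
    if demux_result is not None:
        pd.DataFrame(demux_result.report.to_rows()).to_csv(
            outdir / "demux_report.tsv", sep="\t", index=False)
        summary = {
            "total_input": demux_result.report.total_input,
            "unassigned": demux_result.report.unassigned,
            "reject_reasons": demux_result.report.reject_reasons,
        }
        (outdir / "demux_summary.json").write_text(json.dumps(summary, indent=1))


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages and populate the output folder; returns its path.

    A stage failure raises StageError naming the stage; partial outputs
    and the log are retained for debugging.
    """
    out = _prepare_outdir(config)
    log = RunLog()
    demux_result: Optional[DemuxResult] = None
    current = "setup"
    try:
        # config copies
        shutil.copy(config.mapping_path, out / "config" / "mapping.tsv")
        if config.option_path:
            shutil.copy(config.option_path, out / "config" / "filter_options.txt")

        current = "demultiplex"
        t0 = time.perf_counter()
        mapping = read_mapping(config.mapping_path)
        spec = config.filter_spec
        if spec is None:
            spec = (FilterSpec.from_options(read_option_file(config.option_path))
                    if config.option_path else FilterSpec())
        paths = [Path(p) for p in config.input_paths]
        mate = paths[1] if len(paths) > 1 else None
        reads = read_sequences(paths[0], mate_path=mate)
        demux_result = demultiplex_run(reads, mapping, spec)
        log.add(current, time.perf_counter() - t0,
                input=demux_result.report.total_input,
                high=len(demux_result.high), mid=len(demux_result.mid),
                unassigned=demux_result.report.unassigned)

        current = "cluster"
        t0 = time.perf_counter()
        if config.external_seeds:
            clusters = load_external_clusters(config.external_seeds,
                                              config.external_membership)
        else:
            derep = dereplicate(demux_result.high_truncated)
            clusters = cluster_otus(derep, config.cluster_identity)
        log.add(current, time.perf_counter() - t0, otus=len(clusters))

        current = "map_reads"
        t0 = time.perf_counter()
        all_reads = demux_result.high + demux_result.mid
        matrix, unmapped = map_reads_to_otus(all_reads, clusters,
                                             config.cluster_identity)
        log.add(current, time.perf_counter() - t0,
                mapped=matrix.total(), unmapped=len(unmapped))

        current = "seed_extension"
        t0 = time.perf_counter()
        full_high = {r.read_id: r for r in demux_result.high}
        clusters, kept = extend_seeds(clusters, full_high,
                                      config.cluster_identity, spec)
        log.add(current, time.perf_counter() - t0,
                extended=len(clusters) - len(kept), kept_representative=len(kept))
        seqio.write_fasta(
            [seqio.SequenceRead(read_id=c.otu_id, bases=c.seed.bases)
             for c in sorted(clusters, key=lambda c: c.otu_id)],
            out / "seeds.fasta")

        current = "classify"
        t0 = time.perf_counter()
        otu_ids = [c.otu_id for c in clusters]
        if config.blast_table and config.reference_taxonomy:
            hit_table = read_blast_table(config.blast_table)
            ref_tax = read_reference_taxonomy(config.reference_taxonomy)
            assignments = classify_all(otu_ids, hit_table, ref_tax,
                                       config.lca_spec)
        elif config.aligner_cmd and config.reference_taxonomy:
            hits_path = out / "logs" / "aligner_hits.tsv"
            cmd = config.aligner_cmd.format(query=out / "seeds.fasta",
                                            out=hits_path)
            proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
            if proc.returncode != 0:
                raise RuntimeError(f"aligner failed: {proc.stderr.strip()}")
            hit_table = read_blast_table(hits_path)
            ref_tax = read_reference_taxonomy(config.reference_taxonomy)
            assignments = classify_all(otu_ids, hit_table, ref_tax,
                                       config.lca_spec)
        else:
            assignments = {oid: TaxonomyPath.unassigned() for oid in otu_ids}
        log.add(current, time.perf_counter() - t0,
                assigned=sum(1 for p in assignments.values() if p.depth > 0))

        current = "write_outputs"
        t0 = time.perf_counter()
        matrix.write_tsv(out / "OTU_table.tsv")
        write_taxonomy_tsv(assignments, out / "OTU_taxonomy.tsv")
        write_biom(matrix, assignments, out / "table.biom")
        for rank in RANKS:
            table = aggregate_taxa(matrix, assignments, rank)
            table.to_csv(out / "higher_taxa" / f"{rank}.tsv", sep="\t")
        log.add(current, time.perf_counter() - t0)

        if config.tree_cmd:
            current = "tree"
            t0 = time.perf_counter()
            tree_path = out / "tree.nwk"
            cmd = config.tree_cmd.format(seeds=out / "seeds.fasta", out=tree_path)
            proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
            if proc.returncode != 0:
                raise RuntimeError(f"tree command failed: {proc.stderr.strip()}")
            log.add(current, time.perf_counter() - t0)
    except Exception as exc:
        log.failed_stage = current
        write_reports(log, demux_result, out / "logs")
        raise StageError(current, exc) from exc
    write_reports(log, demux_result, out / "logs")
    return out
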