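"""End-to-end probe design: load → scan → specificity → encode → assemble → write.

The pipeline is fully deterministic: identical configurations produce
byte-identical outputs. Per-target candidate counts at every stage are
logged to the run report, and they are monotone non-increasing from the
scan through the specificity filters.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd

from . import assembly as asm
from . import defaults, sequence_io, specificity
from .codebook import Codebook, assign_codewords, generate_mhd4_codebook
from .scanner import OligoCandidate, scan_target
from .sequence_io import GenomeAssembly, TargetSpec
from .specificity import build_index, find_hits, find_hits_blast
from .thermo import ThermoParameters

logger = logging.getLogger("probecraft")


@dataclass
class RunConfig:
    """Everything one design run needs."""

    probe_type: Literal["chromatin", "merfish", "smfish"]
    genome: str | Path | None = None
    spliced: str | Path | None = None
    unspliced: str | Path | None = None
    gene_map: str | Path | None = None
    targets: str | Path | None = None
    params: str | Path | None = None
    readouts: str | Path | None = None
    primers: str | Path | None = None
    out_dir: str | Path = "probecraft_out"
    antisense_only: bool = False
    avoid_exons: bool = False
    probes_per_target: int | Literal["all"] = "all"
    output_mode: Literal["template", "primary"] = "template"
    backend: Literal["builtin", "blast"] = "builtin"
    seed: int = 0
    seed_k: int = specificity.DEFAULT_SEED_K
    min_matched: int = specificity.DEFAULT_MIN_MATCHED

    def __post_init__(self) -> None:
        if self.probe_type not in ("chromatin", "merfish", "smfish"):
            raise ValueError(f"unknown probe type {self.probe_type!r}")
        if (self.antisense_only or self.avoid_exons) and self.probe_type != "chromatin":
            raise ValueError("antisense_only/avoid_exons apply only to chromatin tracing")
        if self.output_mode not in ("template", "primary"):
            raise ValueError(f"unknown output mode {self.output_mode!r}")
        if self.backend not in ("builtin", "blast"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class RunReport:
    """Per-target candidate counts at each pipeline stage."""

    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    stages: list[str] = field(default_factory=list)
    total_probes: int = 0
    output_paths: dict[str, Path] = field(default_factory=dict)

    def record(self, stage: str, label: str, count: int) -> None:
        if stage not in self.stages:
            self.stages.append(stage)
        self.stage_counts.setdefault(label, {})[stage] = count
        logger.info("stage %-12s target %-20s %d oligos", stage, label, count)

    def frame(self) -> pd.DataFrame:
        rows = [{"target": label, **counts}
                for label, counts in self.stage_counts.items()]
        return pd.DataFrame(rows, columns=["target", *self.stages])

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(self.frame().to_string(index=False))
            fh.write(f"\ntotal probes written: {self.total_probes}\n")


def _hits_for(oligos: list[OligoCandidate], index, db: dict[str, str],
              config: RunConfig):
    """hits_by_oligo map via the configured backend."""
    if config.backend == "builtin":
        return {o.sequence: find_hits(o.sequence, index, config.min_matched)
                for o in oligos}
    queries = {f"q{i}": o.sequence for i, o in enumerate(oligos)}
    by_name = find_hits_blast(queries, db, config.min_matched)
    return {queries[name]: hits for name, hits in by_name.items()}


def run_design(config: RunConfig) -> RunReport:
    """Execute one design run and write all outputs.

    Stages, per probe type:

    * chromatin — extract genomic regions, scan, genome-uniqueness filter,
      optional antisense (unspliced transcriptome) and exon-avoidance
      (spliced transcriptome) filters, subsample, single-readout assembly.
    * merfish/smfish — resolve transcripts, scan, isoform-specificity
      filter against the spliced transcriptome, (merfish) codeword
      assignment, subsample, assembly.

    A target ending with zero probes is a warning, not an error.
    """
    report = RunReport()
    params = (ThermoParameters.from_table(config.params)
              if config.params else ThermoParameters())

    if config.targets is None:
        raise ValueError("a targets file is required")
    spec = _load_targets(config)

    if config.probe_type == "chromatin":
        records, codebook = _run_chromatin(config, spec, params, report)
    else:
        records, codebook = _run_rna(config, spec, params, report)

    if not records:
        raise RuntimeError("no probes survived the design; nothing to write")
    out_dir = Path(config.out_dir)
    report.total_probes = len(records)
    report.output_paths = asm.write_outputs(
        records, out_dir, mode=config.output_mode, codebook=codebook)
    report.write(out_dir / "run_report.txt")
    return report


def _load_targets(config: RunConfig) -> TargetSpec:
    path = Path(config.targets)
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        seqs = sequence_io.read_fasta(path)
        if config.probe_type != "chromatin":
            raise ValueError("FASTA targets are supported for chromatin tracing "
                             "only; RNA modes need transcript-ID tables")
        # carry raw sequences through the chromatin path without coordinates
        return TargetSpec(mode="chromatin",
                          entries=[("__fasta__", 1, len(s), name)
                                   for name, s in seqs.items()])
    return sequence_io.read_target_table(path, config.probe_type)


def _load_primers(config: RunConfig) -> dict[str, asm.PrimerPair]:
    if config.primers:
        return defaults.load_primers_table(config.primers)
    return defaults.load_default_primers()


def _run_chromatin(config: RunConfig, spec: TargetSpec,
                   params: ThermoParameters, report: RunReport):
    if config.genome is None:
        raise ValueError("chromatin tracing requires a genome FASTA")
    assembly = GenomeAssembly.from_fasta(config.genome)
    if spec.entries and spec.entries[0][0] == "__fasta__":
        targets = list(zip(spec.labels,
                           sequence_io.read_fasta(config.targets).values()))
    else:
        targets = sequence_io.extract_regions(assembly, spec)

    genome_index = build_index(assembly.contigs, k=config.seed_k, name="genome")
    unspliced_index = spliced_index = None
    if config.antisense_only:
        if config.unspliced is None:
            raise ValueError("antisense_only requires the unspliced transcriptome")
        unspliced_index = build_index(sequence_io.read_fasta(config.unspliced),
                                      k=config.seed_k, name="unspliced")
    if config.avoid_exons:
        if config.spliced is None:
            raise ValueError("avoid_exons requires the spliced transcriptome")
        spliced_index = build_index(sequence_io.read_fasta(config.spliced),
                                    k=config.seed_k, name="spliced")

    pool: list[OligoCandidate] = []
    scanned: dict[str, list[OligoCandidate]] = {}
    for label, seq in targets:
        scanned[label] = scan_target((label, seq), params, pool)
        report.record("scan", label, len(scanned[label]))

    readout_map = asm.assign_target_readouts(
        [label for label, _ in targets], _readout_library(config, "chromatin"))
    primers = (None if config.output_mode == "primary"
               else _load_primers(config)["chromatin"])

    records: list[asm.ProbeRecord] = []
    for label, _ in targets:
        oligos = scanned[label]
        hits = _hits_for(oligos, genome_index, assembly.contigs, config)
        oligos = specificity.genome_uniqueness_filter(
            oligos, genome_index, config.min_matched, hits_by_oligo=hits)
        report.record("unique", label, len(oligos))
        if unspliced_index is not None:
            db = unspliced_index.sequences
            hits = _hits_for(oligos, unspliced_index, db, config)
            oligos = specificity.antisense_filter(
                oligos, unspliced_index, config.min_matched, hits_by_oligo=hits)
            report.record("antisense", label, len(oligos))
        if spliced_index is not None:
            db = spliced_index.sequences
            hits = _hits_for(oligos, spliced_index, db, config)
            oligos = specificity.exon_avoidance_filter(
                oligos, spliced_index, config.min_matched, hits_by_oligo=hits)
            report.record("exon_free", label, len(oligos))
        chosen = asm.select_probes(oligos, config.probes_per_target)
        report.record("selected", label, len(chosen))
        if not chosen:
            logger.warning("target %s retained zero probes", label)
            continue
        records.extend(asm.assemble_single_readout(
            chosen, readout_map[label], primers, "chromatin"))
    return records, None


def _readout_library(config: RunConfig, use: str) -> asm.ReadoutLibrary:
    if config.readouts:
        return asm.ReadoutLibrary.from_table(config.readouts, use)  # type: ignore[arg-type]
    return defaults.load_default_readouts(use)


def _run_rna(config: RunConfig, spec: TargetSpec,
             params: ThermoParameters, report: RunReport):
    if config.spliced is None or config.gene_map is None:
        raise ValueError("RNA modes require the spliced transcriptome and gene map")
    gene_map = sequence_io.read_gene_map(config.gene_map)
    transcriptome = sequence_io.load_transcriptome(config.spliced, gene_map,
                                                   "spliced")
    resolved = sequence_io.load_transcript_targets(spec, transcriptome)

    genes = sorted({gene for _, _, gene, _ in resolved})
    codebook: Codebook | None = None
    if config.probe_type == "merfish":
        base = generate_mhd4_codebook()
        if len(genes) > base.capacity:
            raise ValueError(
                f"{len(genes)} genes exceed the MHD4 capacity of {base.capacity} "
                "input sequences")
        expr: dict[str, float] = {}
        for _, _, gene, e in resolved:
            expr[gene] = expr.get(gene, 0.0) + float(e)
        rna_lib = _readout_library(config, "rna")
        base.readout_ids = {b: rna_lib.entries[b][0] for b in range(16)}
        codebook = assign_codewords(genes, expr, base)

    spliced_index = build_index(
        {t.transcript_id: t.sequence for t in transcriptome},
        k=config.seed_k,
        gene_map={t.transcript_id: t.gene_id for t in transcriptome},
        name="spliced")

    pool: list[OligoCandidate] = []
    kept_by_label: dict[str, list[OligoCandidate]] = {}
    gene_of_label: dict[str, str] = {}
    for label, seq, gene, _ in resolved:
        gene_of_label[label] = gene
        oligos = scan_target((label, seq), params, pool)
        report.record("scan", label, len(oligos))
        hits = _hits_for(oligos, spliced_index, spliced_index.sequences, config)
        oligos = specificity.isoform_specificity_filter(
            oligos, spliced_index, gene, config.min_matched, hits_by_oligo=hits)
        report.record("isoform", label, len(oligos))
        chosen = asm.select_probes(oligos, config.probes_per_target)
        report.record("selected", label, len(chosen))
        if not chosen:
            logger.warning("target %s retained zero probes", label)
        kept_by_label[label] = chosen

    primers_map = (None if config.output_mode == "primary"
                   else _load_primers(config))
    records: list[asm.ProbeRecord] = []
    if config.probe_type == "merfish":
        oligos_by_gene: dict[str, list[OligoCandidate]] = {}
        for label, oligos in kept_by_label.items():
            oligos_by_gene.setdefault(gene_of_label[label], []).extend(oligos)
        oligos_by_gene = {g: o for g, o in oligos_by_gene.items() if o}
        primers = primers_map["merfish"] if primers_map else None
        records = asm.assemble_merfish(oligos_by_gene, codebook,
                                       _readout_library(config, "rna"), primers)
    else:
        readout_map = asm.assign_target_readouts(
            list(kept_by_label), _readout_library(config, "rna"))
        primers = primers_map["smfish"] if primers_map else None
        for label, oligos in kept_by_label.items():
            if oligos:
                records.extend(asm.assemble_single_readout(
                    oligos, readout_map[label], primers, "smfish"))
    return records, codebook
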