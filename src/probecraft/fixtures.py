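"""Deterministic synthetic genomes and transcriptomes for testing.

Generates base-wise independently sampled contigs at a target GC, plants
gene models (whose genomic spans become the unspliced transcriptome and
whose exon concatenations, strand-corrected, become the spliced
transcriptome), and then copies chosen segments elsewhere to plant exact
duplications that stress the uniqueness filter. A truth table records
every planted feature so tests can assert against it independently of
the generator's internal path.

Planted coordinates here are 0-based half-open (internal convention);
the emitted BED file follows the same convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sequence_io import (GenomeAssembly, TranscriptModel, reverse_complement,
                          write_fasta)


@dataclass(frozen=True)
class PlantedGene:
    """A gene model to plant: genomic span, strand, and exon intervals
    (0-based half-open, within the span)."""

    gene_id: str
    transcript_id: str
    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} needs at least one exon")
        for a, b in self.exons:
            if not (self.start <= a < b <= self.end):
                raise ValueError(
                    f"exon ({a},{b}) of {self.transcript_id} outside gene span")


@dataclass(frozen=True)
class PlantedDuplication:
    """Copy ``contig[start:end]`` onto ``dest_contig`` at ``dest_start``."""

    contig: str
    start: int
    end: int
    dest_contig: str
    dest_start: int


@dataclass
class FixtureSpec:
    seed: int = 0
    n_contigs: int = 1
    contig_length: int = 10000
    gc_target: float = 50.0  # percent
    planted_genes: tuple[PlantedGene, ...] = ()
    planted_duplications: tuple[PlantedDuplication, ...] = ()


@dataclass
class Fixture:
    assembly: GenomeAssembly
    spliced: list[TranscriptModel]
    unspliced: list[TranscriptModel]
    gene_map: dict[str, str]
    truth: pd.DataFrame  # one row per planted feature

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit genome FASTA, transcriptome FASTAs, gene map TSV, and a
        BED of planted features (0-based half-open)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out_dir / "genome.fasta",
            "spliced": out_dir / "spliced.fasta",
            "unspliced": out_dir / "unspliced.fasta",
            "gene_map": out_dir / "gene_map.tsv",
            "bed": out_dir / "planted.bed",
        }
        write_fasta(self.assembly.contigs, paths["genome"])
        write_fasta({t.transcript_id: t.sequence for t in self.spliced},
                    paths["spliced"])
        write_fasta({t.transcript_id: t.sequence for t in self.unspliced},
                    paths["unspliced"])
        pd.DataFrame({"transcript_id": list(self.gene_map),
                      "gene_id": list(self.gene_map.values())}
                     ).to_csv(paths["gene_map"], sep="\t", index=False)
        bed = self.truth[self.truth["feature"].isin(["gene", "exon", "duplication"])]
        bed[["contig", "start", "end", "name", "score", "strand"]].to_csv(
            paths["bed"], sep="\t", header=False, index=False)
        return paths


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build a synthetic genome + transcriptomes + truth table.

    Contig bases are drawn independently with P(G) = P(C) = gc/200.
    Duplications are applied after gene placement (so a duplicated gene
    segment genuinely recurs in the genome). Planted features may not
    overlap one another on the same contig.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_target / 100.0
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    bases = np.array(list("ACGT"))
    contigs = {
        f"ctg{i + 1}": "".join(
            bases[rng.choice(4, size=spec.contig_length, p=probs)])
        for i in range(spec.n_contigs)
    }

    # refuse overlapping planted footprints (genes and duplication targets)
    footprints: dict[str, list[tuple[int, int, str]]] = {c: [] for c in contigs}
    for g in spec.planted_genes:
        for s, e, name in footprints[g.contig]:
            if _intervals_overlap((g.start, g.end), (s, e)):
                raise ValueError(f"planted gene {g.gene_id} overlaps {name}")
        footprints[g.contig].append((g.start, g.end, g.gene_id))
    for d in spec.planted_duplications:
        dest = (d.dest_start, d.dest_start + (d.end - d.start))
        for s, e, name in footprints[d.dest_contig]:
            if _intervals_overlap(dest, (s, e)):
                raise ValueError(f"duplication destination overlaps {name}")
        footprints[d.dest_contig].append((*dest, f"dup@{d.dest_start}"))

    rows = []
    for g in spec.planted_genes:
        rows.append({"feature": "gene", "contig": g.contig, "start": g.start,
                     "end": g.end, "name": g.gene_id, "score": 0,
                     "strand": g.strand, "transcript_id": g.transcript_id,
                     "sequence": ""})
        for a, b in g.exons:
            rows.append({"feature": "exon", "contig": g.contig, "start": a,
                         "end": b, "name": g.transcript_id, "score": 0,
                         "strand": g.strand, "transcript_id": g.transcript_id,
                         "sequence": ""})

    # apply duplications after gene placement
    for d in spec.planted_duplications:
        segment = contigs[d.contig][d.start:d.end]
        dest = contigs[d.dest_contig]
        if d.dest_start + len(segment) > len(dest):
            raise ValueError("duplication destination out of contig bounds")
        contigs[d.dest_contig] = (dest[:d.dest_start] + segment +
                                  dest[d.dest_start + len(segment):])
        rows.append({"feature": "duplication", "contig": d.dest_contig,
                     "start": d.dest_start, "end": d.dest_start + len(segment),
                     "name": f"{d.contig}:{d.start}-{d.end}", "score": 0,
                     "strand": "+", "transcript_id": "", "sequence": segment})

    assembly = GenomeAssembly(contigs)
    spliced, unspliced = [], []
    gene_map: dict[str, str] = {}
    for g in spec.planted_genes:
        gene_map[g.transcript_id] = g.gene_id
        span = contigs[g.contig][g.start:g.end]
        exonic = "".join(contigs[g.contig][a:b] for a, b in sorted(g.exons))
        if g.strand == "-":
            span = reverse_complement(span)
            exonic = reverse_complement(exonic)
        unspliced.append(TranscriptModel(g.transcript_id, g.gene_id, span,
                                         "unspliced"))
        spliced.append(TranscriptModel(g.transcript_id, g.gene_id, exonic,
                                       "spliced"))

    truth = pd.DataFrame(rows, columns=["feature", "contig", "start", "end",
                                        "name", "score", "strand",
                                        "transcript_id", "sequence"])
    return Fixture(assembly, spliced, unspliced, gene_map, truth)
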