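"""Reading genomes, transcriptomes and target specifications.

Conventions
-----------
* FASTA sequences are uppercased on load; the record name is the header up
  to the first whitespace and insertion order is preserved.
* Target coordinates are accepted 1-based inclusive (UCSC spreadsheet
  style); all internal arithmetic is 0-based half-open.
* Transcript version suffixes (``ENST0001.5`` → ``ENST0001``) are stripped
  on both sides before matching.
* The only ambiguity code tolerated is ``N``; other IUPAC codes are
  rejected at load time because the thermodynamic tables downstream are
  defined only for A/C/G/T.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

NUCLEOTIDES = frozenset("ACGTN")

_VERSION_RE = re.compile(r"\.\d+$")


class FastaError(ValueError):
    """Raised for malformed or empty FASTA input."""


def strip_version(transcript_id: str) -> str:
    """Drop a trailing ``.N`` version suffix from a transcript identifier."""
    return _VERSION_RE.sub("", transcript_id)


def _validate_alphabet(name: str, seq: str) -> None:
    bad = set(seq) - NUCLEOTIDES
    if bad:
        raise FastaError(
            f"sequence {name!r} contains non-nucleotide characters: "
            f"{sorted(bad)} (only A/C/G/T/N are accepted)"
        )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an insertion-ordered ``{name: sequence}`` map.

    Sequences are uppercased; headers are truncated at the first whitespace.
    Raises :class:`FastaError` on empty files, empty records, duplicate
    names, or non-ACGTN characters.
    """
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaError(f"record {rec.id!r} in {path} has an empty sequence")
        if rec.id in records:
            raise FastaError(f"duplicate record name {rec.id!r} in {path}")
        _validate_alphabet(rec.id, seq)
        records[rec.id] = seq
    if not records:
        raise FastaError(f"{path} contains no FASTA records")
    return records


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]],
                path: str | Path, width: int = 80) -> None:
    """Write ``{name: sequence}`` (or name/sequence pairs) as FASTA."""
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement; ``N`` maps to ``N``."""
    _validate_alphabet("<input>", seq.upper())
    return str(Seq(seq.upper()).reverse_complement())


@dataclass
class GenomeAssembly:
    """A set of named contigs, normalized to uppercase A/C/G/T/N.

    ``masked`` optionally records, per contig, a boolean mask of positions
    that were soft-masked (lowercase) in the source FASTA, for use with the
    ``skip_masked`` scanning option.
    """

    contigs: dict[str, str]
    masked: dict[str, list[bool]] | None = None

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            _validate_alphabet(name, seq)

    @classmethod
    def from_fasta(cls, path: str | Path, track_masked: bool = False) -> "GenomeAssembly":
        if not track_masked:
            return cls(read_fasta(path))
        contigs: dict[str, str] = {}
        masked: dict[str, list[bool]] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            raw = str(rec.seq)
            if not raw:
                raise FastaError(f"record {rec.id!r} has an empty sequence")
            contigs[rec.id] = raw.upper()
            masked[rec.id] = [c.islower() for c in raw]
            _validate_alphabet(rec.id, contigs[rec.id])
        if not contigs:
            raise FastaError(f"{path} contains no FASTA records")
        return cls(contigs, masked)

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: version-stripped id, owning gene, sequence, and
    whether the sequence is the spliced (exonic) or unspliced (genomic
    span) form."""

    transcript_id: str
    gene_id: str
    sequence: str
    kind: Literal["spliced", "unspliced"] = "spliced"

    def __post_init__(self) -> None:
        if _VERSION_RE.search(self.transcript_id):
            raise ValueError(
                f"transcript id {self.transcript_id!r} carries a version suffix; "
                "strip it before constructing a TranscriptModel"
            )
        _validate_alphabet(self.transcript_id, self.sequence)


@dataclass
class TargetSpec:
    """Targets for one design run.

    ``entries`` rows are, per mode:

    * ``chromatin`` — ``(contig, start, end, label)`` with 1-based inclusive
      coordinates;
    * ``merfish`` — ``(transcript_id, expression, label)``; expression is
      required (FPKM-like, non-negative);
    * ``smfish`` — ``(transcript_id, expression-or-None, label)``.
    """

    mode: Literal["chromatin", "merfish", "smfish"]
    entries: list[tuple]

    def __post_init__(self) -> None:
        if self.mode not in ("chromatin", "merfish", "smfish"):
            raise ValueError(f"unknown target mode {self.mode!r}")
        if self.mode == "merfish":
            for row in self.entries:
                if row[1] is None:
                    raise ValueError(
                        f"merfish target {row[0]!r} lacks an expression value; "
                        "bulk expression (e.g. FPKM) is required for codeword "
                        "rearrangement"
                    )

    @property
    def labels(self) -> list[str]:
        return [row[-1] for row in self.entries]


def extract_regions(assembly: GenomeAssembly, spec: TargetSpec) -> list[tuple[str, str]]:
    """Extract plus-strand genomic segments for chromatin-tracing targets.

    Input coordinates are 1-based inclusive; the returned sequence length
    is ``end − start + 1``.
    """
    if spec.mode != "chromatin":
        raise ValueError("extract_regions applies only to chromatin-mode targets")
    out: list[tuple[str, str]] = []
    for contig, start, end, label in spec.entries:
        if contig not in assembly:
            raise KeyError(f"target {label!r}: unknown contig {contig!r}")
        clen = assembly.length(contig)
        if not (1 <= start <= end <= clen):
            raise ValueError(
                f"target {label!r}: coordinates {contig}:{start}-{end} out of "
                f"bounds for contig of length {clen} (expect 1 <= start <= end <= length)"
            )
        out.append((label, assembly.contigs[contig][start - 1:end]))
    return out


def load_transcript_targets(
    spec: TargetSpec, transcriptome: Sequence[TranscriptModel]
) -> list[tuple[str, str, str, float | None]]:
    """Resolve transcript targets to ``(label, sequence, gene_id, expression)``.

    IDs are version-stripped on both sides; unresolvable IDs raise a
    ``KeyError`` listing every missing ID at once.
    """
    if spec.mode not in ("merfish", "smfish"):
        raise ValueError("load_transcript_targets applies to merfish/smfish targets")
    by_id = {strip_version(t.transcript_id): t for t in transcriptome if t.kind == "spliced"}
    missing = [strip_version(row[0]) for row in spec.entries
               if strip_version(row[0]) not in by_id]
    if missing:
        raise KeyError(
            f"{len(missing)} target transcript ID(s) not found in the spliced "
            f"transcriptome: {', '.join(sorted(set(missing)))}"
        )
    out = []
    for row in spec.entries:
        tid, expression, label = row[0], row[1], row[-1]
        t = by_id[strip_version(tid)]
        out.append((label, t.sequence, t.gene_id, expression))
    return out


def load_transcriptome(
    fasta_path: str | Path,
    gene_map: Mapping[str, str],
    kind: Literal["spliced", "unspliced"] = "spliced",
) -> list[TranscriptModel]:
    """Load a transcriptome FASTA into :class:`TranscriptModel` records.

    FASTA headers and gene-map keys are version-stripped. Transcripts
    absent from the gene map raise ``KeyError``.
    """
    seqs = read_fasta(fasta_path)
    gmap = {strip_version(k): v for k, v in gene_map.items()}
    models = []
    for name, seq in seqs.items():
        tid = strip_version(name)
        if tid not in gmap:
            raise KeyError(f"transcript {tid!r} has no gene-map entry")
        models.append(TranscriptModel(tid, gmap[tid], seq, kind))
    return models


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Read a transcript→gene map from a two-column TSV/CSV (or a GTF).

    Tabular files need columns ``transcript_id`` and ``gene_id`` (or two
    unnamed columns in that order). ``.gtf`` files are parsed for
    transcript features.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        spans = read_gtf_transcripts(path)
        return dict(zip(spans["transcript_id"], spans["gene_id"]))
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    cols = [c.lower() for c in df.columns]
    if "transcript_id" in cols and "gene_id" in cols:
        df.columns = cols
        pairs = df[["transcript_id", "gene_id"]].itertuples(index=False)
    else:
        # headerless two-column file
        df = pd.read_csv(path, sep=sep, header=None)
        pairs = df.iloc[:, :2].itertuples(index=False)
    out: dict[str, str] = {}
    for tid, gid in pairs:
        tid = strip_version(str(tid))
        if tid in out and out[tid] != str(gid):
            raise ValueError(f"transcript {tid!r} maps to multiple genes")
        out[tid] = str(gid)
    return out


_GTF_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_transcripts(path: str | Path) -> pd.DataFrame:
    """Extract transcript spans from a GTF into a BED-like frame.

    Returns columns ``contig, start, end, strand, transcript_id, gene_id``
    with ``start``/``end`` 0-based half-open (BED convention). Transcript
    spans are taken from ``transcript`` features when present, otherwise
    from the union of each transcript's ``exon`` features.
    """
    rows: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in ("transcript", "exon"):
                continue
            attrs = dict(_GTF_ATTR_RE.findall(f[8]))
            tid = strip_version(attrs.get("transcript_id", ""))
            gid = strip_version(attrs.get("gene_id", ""))
            if not tid:
                continue
            start, end = int(f[3]) - 1, int(f[4])  # GTF is 1-based inclusive
            cur = rows.get(tid)
            if cur is None:
                rows[tid] = [f[0], start, end, f[6], tid, gid, f[2] == "transcript"]
            else:
                if cur[6] and f[2] == "exon":
                    continue  # a transcript feature already fixed the span
                cur[1] = min(cur[1], start)
                cur[2] = max(cur[2], end)
                cur[6] = cur[6] or f[2] == "transcript"
    return pd.DataFrame(
        [r[:6] for r in rows.values()],
        columns=["contig", "start", "end", "strand", "transcript_id", "gene_id"],
    )


def unspliced_from_gtf(assembly: GenomeAssembly, gtf_path: str | Path) -> list[TranscriptModel]:
    """Build the unspliced transcriptome (genomic transcript spans,
    strand-corrected) from a GTF and the genome assembly."""
    spans = read_gtf_transcripts(gtf_path)
    models = []
    for row in spans.itertuples(index=False):
        seq = assembly.contigs[row.contig][row.start:row.end]
        if row.strand == "-":
            seq = reverse_complement(seq)
        models.append(TranscriptModel(row.transcript_id, row.gene_id, seq, "unspliced"))
    return models


def read_target_table(path: str | Path, mode: str) -> TargetSpec:
    """Read a target table (CSV/TSV/XLSX) into a :class:`TargetSpec`.

    Chromatin tables need columns ``contig, start, end`` (optional
    ``label``); RNA tables need ``transcript_id`` (optional ``expression``,
    ``label``). Labels default to ``contig:start-end`` or the transcript id.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep)
    df.columns = [str(c).strip().lower() for c in df.columns]
    entries: list[tuple] = []
    if mode == "chromatin":
        required = {"contig", "start", "end"}
        if not required <= set(df.columns):
            raise ValueError(f"chromatin target table needs columns {sorted(required)}")
        for i, row in df.iterrows():
            label = str(row["label"]) if "label" in df.columns else \
                f"{row['contig']}:{int(row['start'])}-{int(row['end'])}"
            entries.append((str(row["contig"]), int(row["start"]), int(row["end"]), label))
    else:
        if "transcript_id" not in df.columns:
            raise ValueError("RNA target table needs a transcript_id column")
        for _, row in df.iterrows():
            expr = None
            if "expression" in df.columns and not pd.isna(row["expression"]):
                expr = float(row["expression"])
            if expr is not None and not (expr >= 0):
                raise ValueError(f"expression for {row['transcript_id']} must be >= 0")
            label = str(row["label"]) if "label" in df.columns else strip_version(str(row["transcript_id"]))
            entries.append((str(row["transcript_id"]), expr, label))
    return TargetSpec(mode=mode, entries=entries)
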