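"""Probe assembly: readouts, primers, template/primary sequences, outputs.

A *template oligo* is the synthesis-ready sequence

    forward_primer + upstream readout(s) + targeting region
                   + downstream readout(s) + reverse_complement(reverse_primer)

ordered as an oligo pool and amplified; the functional *primary probe* is
the reverse complement of the template without its priming regions.
Chromatin-tracing and sequential smFISH probes carry one readout species
per target (one copy upstream, one downstream); MERFISH probes carry
three of their gene's four readouts (one upstream, two downstream),
cycling through the leave-one-out triplets of the codeword.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

from .codebook import Codebook, probe_readout_triplet
from .scanner import OligoCandidate
from .sequence_io import reverse_complement, write_fasta

ProbeType = Literal["chromatin", "merfish", "smfish"]


@dataclass
class ReadoutLibrary:
    """Ordered readout (secondary) sequences for one intended use."""

    entries: list[tuple[str, str]]  # (readout_id, sequence)
    intended_use: Literal["chromatin", "rna"]

    def __post_init__(self) -> None:
        seqs = [s for _, s in self.entries]
        if len(set(seqs)) != len(seqs):
            raise ValueError("readout sequences must be unique")
        minimum = 50 if self.intended_use == "chromatin" else 16
        if len(self.entries) < minimum:
            raise ValueError(
                f"a {self.intended_use} readout library needs at least "
                f"{minimum} entries (got {len(self.entries)})"
            )

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_table(cls, path: str | Path,
                   intended_use: Literal["chromatin", "rna"]) -> "ReadoutLibrary":
        df = _read_two_col(path, ("id", "sequence"))
        return cls([(str(r), str(s).upper()) for r, s in
                    zip(df["id"], df["sequence"])], intended_use)


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse amplification primers for one probe type.

    Both primers are stored 5′→3′; the reverse primer appears in the
    template as its reverse complement.
    """

    forward: str
    reverse: str
    probe_type: ProbeType


@dataclass(frozen=True)
class ProbeRecord:
    """One assembled probe with full provenance."""

    target_label: str
    oligo: OligoCandidate
    readouts: tuple[tuple[str, str], ...]  # (readout_id, 'upstream'|'downstream')
    primers: PrimerPair | None
    template_sequence: str
    primary_sequence: str
    probe_type: ProbeType
    gene_id: str | None = None
    codeword: str | None = None


def _read_two_col(path: str | Path, cols: tuple[str, str]) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if not set(cols) <= set(df.columns):
        raise ValueError(f"{path} needs columns {cols}")
    return df


def select_probes(oligos: Sequence[OligoCandidate],
                  n: int | Literal["all"] = "all") -> list[OligoCandidate]:
    """Pick ``n`` probes evenly spaced along the target by offset.

    ``n='all'`` returns everything in offset order. For ``n < m`` the
    chosen indices are ``round(i·(m−1)/(n−1))``; ``n=1`` takes the middle
    oligo. Requesting more probes than exist returns all with a warning.
    """
    ordered = sorted(oligos, key=lambda o: o.offset)
    if n == "all":
        return ordered
    if not isinstance(n, int) or n <= 0:
        raise ValueError("n must be a positive integer or 'all'")
    m = len(ordered)
    if n >= m:
        if n > m:
            warnings.warn(f"requested {n} probes but only {m} are available; "
                          "returning all")
        return ordered
    if n == 1:
        return [ordered[int((m - 1) / 2 + 0.5)]]
    idx = [round(i * (m - 1) / (n - 1)) for i in range(n)]
    return [ordered[i] for i in idx]


def _build_sequences(oligo_seq: str, upstream: Sequence[str],
                     downstream: Sequence[str], primers: PrimerPair | None,
                     spacer: str = "") -> tuple[str, str]:
    """(template_sequence, primary_sequence) for one probe."""
    core = spacer.join([*upstream, oligo_seq, *downstream]) if spacer else \
        "".join([*upstream, oligo_seq, *downstream])
    primary = reverse_complement(core)
    if primers is None:
        return core, primary
    template = primers.forward + core + reverse_complement(primers.reverse)
    return template, primary


def assemble_single_readout(oligos: Sequence[OligoCandidate],
                            readout: tuple[str, str],
                            primers: PrimerPair | None = None,
                            probe_type: ProbeType = "chromatin",
                            spacer: str = "") -> list[ProbeRecord]:
    """Assemble probes that all share one readout species: one copy
    upstream of the targeting region and one downstream."""
    labels = {o.target_label for o in oligos}
    if len(labels) > 1:
        raise ValueError("assemble_single_readout expects oligos from one target")
    rid, rseq = readout[0], readout[1].upper()
    records = []
    for o in sorted(oligos, key=lambda x: x.offset):
        template, primary = _build_sequences(o.sequence, [rseq], [rseq],
                                             primers, spacer)
        records.append(ProbeRecord(
            target_label=o.target_label, oligo=o,
            readouts=((rid, "upstream"), (rid, "downstream")),
            primers=primers, template_sequence=template,
            primary_sequence=primary, probe_type=probe_type,
        ))
    return records


def assign_target_readouts(labels: Sequence[str],
                           library: ReadoutLibrary) -> dict[str, tuple[str, str]]:
    """Readout for target index r is library entry r, in input order; no
    readout is reused across targets within one run."""
    if len(labels) > len(library):
        raise ValueError(
            f"{len(labels)} targets exceed the {len(library)} available readout "
            "sequences; provide additional secondary sequences in the readout table"
        )
    return {label: library.entries[i] for i, label in enumerate(labels)}


def assemble_merfish(oligos_by_gene: Mapping[str, Sequence[OligoCandidate]],
                     codebook: Codebook,
                     readouts: ReadoutLibrary,
                     primers: PrimerPair | None = None,
                     spacer: str = "") -> list[ProbeRecord]:
    """Assemble MERFISH probes: probe ``i`` of a gene carries the
    leave-one-out readout triplet of its codeword — first element
    upstream, the other two downstream."""
    if len(readouts) < 16:
        raise ValueError("MERFISH needs a readout library covering all 16 bits")
    bit_to_readout = {b: readouts.entries[b] for b in range(16)}
    records = []
    for gene in oligos_by_gene:
        if gene not in codebook.assignment:
            raise ValueError(f"gene {gene!r} has no codeword assignment")
    for gene, oligos in oligos_by_gene.items():
        word = codebook.codeword_of(gene)
        for i, o in enumerate(sorted(oligos, key=lambda x: x.offset)):
            bits = probe_readout_triplet(word, i)
            ids_seqs = [bit_to_readout[b] for b in bits]
            template, primary = _build_sequences(
                o.sequence, [ids_seqs[0][1]],
                [ids_seqs[1][1], ids_seqs[2][1]], primers, spacer)
            records.append(ProbeRecord(
                target_label=o.target_label, oligo=o,
                readouts=((ids_seqs[0][0], "upstream"),
                          (ids_seqs[1][0], "downstream"),
                          (ids_seqs[2][0], "downstream")),
                primers=primers, template_sequence=template,
                primary_sequence=primary, probe_type="merfish",
                gene_id=gene, codeword=str(word),
            ))
    return records


def records_frame(records: Sequence[ProbeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "target_label": r.target_label,
            "probe_type": r.probe_type,
            "offset": r.oligo.offset,
            "targeting_sequence": r.oligo.sequence,
            "tm": r.oligo.tm,
            "gc": r.oligo.gc,
            "readout_ids": ";".join(f"{rid}:{place}" for rid, place in r.readouts),
            "gene_id": r.gene_id or "",
            "codeword": r.codeword or "",
            "forward_primer": r.primers.forward if r.primers else "",
            "reverse_primer": r.primers.reverse if r.primers else "",
            "template_sequence": r.template_sequence,
            "primary_sequence": r.primary_sequence,
        })
    return pd.DataFrame(rows)


def write_outputs(records: Sequence[ProbeRecord], out_dir: str | Path,
                  mode: Literal["template", "primary"] = "template",
                  codebook: Codebook | None = None,
                  stem: str = "probes") -> dict[str, Path]:
    """Write the probe FASTA, the provenance table (CSV and XLSX), and —
    when a codebook is supplied — the MERFISH codebook spreadsheet.

    ``mode`` selects which sequence fills the FASTA body: the synthesis
    template (with primers) or the primary probe (no priming regions).
    """
    if not records:
        raise ValueError("no probe records to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = []
    for i, r in enumerate(records):
        rids = ",".join(rid for rid, _ in r.readouts)
        header = f"{r.target_label}|{r.oligo.offset}|{r.probe_type}|{rids}"
        seq = r.template_sequence if mode == "template" else r.primary_sequence
        fasta.append((header, seq))
    paths: dict[str, Path] = {
        "fasta": out_dir / f"{stem}.fasta",
        "csv": out_dir / f"{stem}.csv",
        "xlsx": out_dir / f"{stem}.xlsx",
    }
    write_fasta(fasta, paths["fasta"])
    df = records_frame(records)
    df.to_csv(paths["csv"], index=False)
    df.to_excel(paths["xlsx"], index=False)
    if codebook is not None and codebook.assignment:
        from .codebook import write_codebook
        cb_paths = write_codebook(codebook, out_dir)
        paths["codebook_csv"], paths["codebook_xlsx"] = cb_paths
    return paths
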