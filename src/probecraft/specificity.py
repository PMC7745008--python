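"""Strand-aware specificity screening against genome/transcriptome databases.

The built-in engine is an ungapped seed-and-extend aligner over a k-mer
index (default k = 12). Its hit model, applied identically to the forward
oligo (plus/plus orientation) and its reverse complement (plus/minus,
reported against the database plus strand):

* consider full-length ungapped placements of the oriented oligo on a
  database sequence (clipped at sequence ends);
* within a placement, a *hit segment* is a contiguous block of alignment
  columns that starts and ends on a match, contains at most
  ``max_mismatches`` (default 2) mismatching columns, and contains at
  least one run of ``k`` consecutive matches (the seed requirement, which
  is what makes k-mer seeding complete rather than heuristic);
* ``matched`` is the number of matching columns in the best such segment;
  segments with ``matched >= min_matched`` (default 18) are hits;
* hits whose database intervals overlap are merged, keeping the best
  (highest ``matched``; ties broken toward smaller start, then plus/plus).

An optional external backend drives NCBI ``blastn -task blastn-short``
and maps its tabular output onto the same ``AlignmentHit`` records, so
the downstream uniqueness / antisense / exon / isoform filters are
backend-agnostic.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from .scanner import OligoCandidate
from .sequence_io import reverse_complement, write_fasta

DEFAULT_SEED_K = 12
DEFAULT_MIN_MATCHED = 18
DEFAULT_MAX_MISMATCHES = 2


@dataclass(frozen=True)
class AlignmentHit:
    """One merged alignment locus on the database plus strand."""

    sequence_id: str
    orientation: Literal["plus/plus", "plus/minus"]
    start: int        # 0-based on the database sequence
    matched: int      # exactly matching columns in the best segment
    end: int = 0      # 0-based exclusive end of the segment


@dataclass
class SpecificityIndex:
    """k-mer index over a sequence database with strand-aware querying."""

    database_name: str
    k: int
    sequences: dict[str, str]
    seed_map: dict[str, list[tuple[str, int]]] = field(repr=False, default_factory=dict)
    gene_map: dict[str, str] | None = None

    def gene_of(self, sequence_id: str) -> str | None:
        if self.gene_map is None:
            return None
        return self.gene_map.get(sequence_id)


def build_index(db: Mapping[str, str], k: int = DEFAULT_SEED_K,
                gene_map: Mapping[str, str] | None = None,
                name: str = "db") -> SpecificityIndex:
    """Index every k-mer occurrence of every database sequence.

    Sequences shorter than k contribute no seeds (a warning is issued);
    k-mers containing N are not indexed.
    """
    if k < 8:
        raise ValueError("seed length k must be at least 8")
    seed_map: dict[str, list[tuple[str, int]]] = defaultdict(list)
    sequences = {sid: seq.upper() for sid, seq in db.items()}
    for sid, seq in sequences.items():
        if len(seq) < k:
            warnings.warn(f"database sequence {sid!r} is shorter than k={k}; "
                          "it contributes no seeds")
            continue
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if "N" not in kmer:
                seed_map[kmer].append((sid, i))
    return SpecificityIndex(
        database_name=name, k=k, sequences=sequences,
        seed_map=dict(seed_map),
        gene_map=dict(gene_map) if gene_map is not None else None,
    )


def _best_segment(match: list[bool], k: int, min_matched: int,
                  max_mismatches: int = DEFAULT_MAX_MISMATCHES) -> tuple[int, int, int] | None:
    """Best hit segment of a placement's match mask.

    Returns ``(matched, start, end)`` (columns, 0-based half-open within
    the mask) or None. Segments start/end on matches, carry ≤ 2 internal
    mismatches, and must contain a ≥ k exact run.
    """
    # maximal runs of consecutive matches: (start, length)
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(match)
    while i < n:
        if match[i]:
            j = i
            while j < n and match[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    best: tuple[int, int, int] | None = None
    for a in range(len(runs)):
        gap_cost = 0
        matched = 0
        longest = 0
        for b in range(a, len(runs)):
            if b > a:
                gap = runs[b][0] - (runs[b - 1][0] + runs[b - 1][1])
                gap_cost += gap
                if gap_cost > max_mismatches:
                    break
            matched += runs[b][1]
            longest = max(longest, runs[b][1])
            if longest >= k and matched >= min_matched:
                cand = (matched, runs[a][0], runs[b][0] + runs[b][1])
                if best is None or (cand[0], -cand[1]) > (best[0], -best[1]):
                    best = cand
    return best


def _placement_hits(oriented: str, index: SpecificityIndex,
                    min_matched: int,
                    max_mismatches: int = DEFAULT_MAX_MISMATCHES) -> list[AlignmentHit]:
    """Seeded ungapped hits of one oriented query; orientation unset."""
    k = index.k
    if len(oriented) < k:
        return []
    # candidate (sequence_id, placement offset) pairs from seed matches
    candidates: set[tuple[str, int]] = set()
    for q in range(len(oriented) - k + 1):
        for sid, p in index.seed_map.get(oriented[q:q + k], ()):
            candidates.add((sid, p - q))
    hits = []
    for sid, d in candidates:
        seq = index.sequences[sid]
        lo = max(0, -d)                      # query positions inside the db
        hi = min(len(oriented), len(seq) - d)
        if hi - lo < min_matched:
            continue
        mask = [oriented[j] == seq[d + j] and oriented[j] != "N"
                for j in range(lo, hi)]
        seg = _best_segment(mask, k, min_matched, max_mismatches)
        if seg is not None:
            matched, s, e = seg
            hits.append(AlignmentHit(sid, "plus/plus",
                                     start=d + lo + s, matched=matched,
                                     end=d + lo + e))
    return hits


def merge_hits(hits: Iterable[AlignmentHit]) -> list[AlignmentHit]:
    """Merge hits with overlapping database intervals per sequence,
    keeping the best (matched desc, start asc, plus/plus preferred)."""
    by_seq: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        by_seq[h.sequence_id].append(h)
    out: list[AlignmentHit] = []
    for sid in sorted(by_seq):
        group = sorted(by_seq[sid], key=lambda h: (h.start, h.end))
        clusters: list[list[AlignmentHit]] = []
        cur_end = None
        for h in group:
            if cur_end is not None and h.start < cur_end:
                clusters[-1].append(h)
                cur_end = max(cur_end, h.end)
            else:
                clusters.append([h])
                cur_end = h.end
        for cluster in clusters:
            out.append(min(cluster, key=lambda h: (-h.matched, h.start,
                                                   h.orientation != "plus/plus")))
    return sorted(out, key=lambda h: (h.sequence_id, h.start))


def find_hits(oligo: str, index: SpecificityIndex,
              min_matched: int = DEFAULT_MIN_MATCHED,
              max_mismatches: int = DEFAULT_MAX_MISMATCHES) -> list[AlignmentHit]:
    """All merged alignment loci of ``oligo`` in the indexed database.

    The forward oligo is searched in plus/plus orientation and its
    reverse complement in plus/minus; both are reported against the
    database plus strand.
    """
    oligo = oligo.upper()
    if len(oligo) < index.k:
        raise ValueError(f"oligo shorter than seed length k={index.k}")
    fwd = _placement_hits(oligo, index, min_matched, max_mismatches)
    rev = [AlignmentHit(h.sequence_id, "plus/minus", h.start, h.matched, h.end)
           for h in _placement_hits(reverse_complement(oligo), index,
                                    min_matched, max_mismatches)]
    return merge_hits(fwd + rev)


# ---------------------------------------------------------------------------
# optional external BLAST+ backend

def blast_available() -> bool:
    return shutil.which("blastn") is not None


def find_hits_blast(oligos: Mapping[str, str], db: Mapping[str, str],
                    min_matched: int = DEFAULT_MIN_MATCHED) -> dict[str, list[AlignmentHit]]:
    """Query many oligos against a database with ``blastn -task blastn-short``
    (e-value 10, dust off) and parse the tabular output into merged
    :class:`AlignmentHit` lists keyed by oligo name.

    ``matched`` is alignment length minus mismatches and gaps; alignments
    below ``min_matched`` matched columns are dropped, then loci are
    merged exactly as in the built-in engine.
    """
    if not blast_available():
        raise RuntimeError("blastn executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        qpath = Path(tmp) / "query.fa"
        spath = Path(tmp) / "subject.fa"
        write_fasta(oligos, qpath)
        write_fasta(db, spath)
        proc = subprocess.run(
            ["blastn", "-task", "blastn-short", "-evalue", "10", "-dust", "no",
             "-query", str(qpath), "-subject", str(spath),
             "-outfmt", "6 qseqid sseqid pident length mismatch gapopen "
                        "qstart qend sstart send sstrand"],
            capture_output=True, text=True, check=True,
        )
    raw: dict[str, list[AlignmentHit]] = {name: [] for name in oligos}
    for line in proc.stdout.splitlines():
        f = line.split("\t")
        qid, sid = f[0], f[1]
        length, mism, gapo = int(f[3]), int(f[4]), int(f[5])
        sstart, send = int(f[8]), int(f[9])
        matched = length - mism - gapo
        if matched < min_matched:
            continue
        if sstart <= send:
            orientation, start, end = "plus/plus", sstart - 1, send
        else:
            orientation, start, end = "plus/minus", send - 1, sstart
        raw[qid].append(AlignmentHit(sid, orientation, start, matched, end))
    return {name: merge_hits(hits) for name, hits in raw.items()}


# ---------------------------------------------------------------------------
# filters

def genome_uniqueness_filter(
    oligos: Sequence[OligoCandidate], genome_index: SpecificityIndex,
    min_matched: int = DEFAULT_MIN_MATCHED,
    hits_by_oligo: Mapping[str, list[AlignmentHit]] | None = None,
) -> list[OligoCandidate]:
    """Retain oligos with exactly one genome alignment (both orientations
    combined) — the self-locus. An oligo with zero hits indicates a
    database/target mismatch and raises."""
    out = []
    for o in oligos:
        hits = (hits_by_oligo[o.sequence] if hits_by_oligo is not None
                else find_hits(o.sequence, genome_index, min_matched))
        if len(hits) == 0:
            raise ValueError(
                f"oligo at {o.target_label}:{o.offset} has no genome hits; "
                "its self-locus is missing, so the genome index does not "
                "match the target source"
            )
        if len(hits) == 1:
            out.append(o)
    return out


def antisense_filter(
    oligos: Sequence[OligoCandidate], unspliced_index: SpecificityIndex,
    min_matched: int = DEFAULT_MIN_MATCHED,
    hits_by_oligo: Mapping[str, list[AlignmentHit]] | None = None,
) -> list[OligoCandidate]:
    """Keep only oligos whose final probe cannot bind unspliced RNA.

    Per oligo, against the unspliced transcriptome: no hits → retained
    unchanged; hits only plus/plus → replaced by its reverse complement
    (the probe then targets the antisense strand); hits only plus/minus →
    retained unchanged; hits in both orientations → rejected.
    """
    out = []
    for o in oligos:
        hits = (hits_by_oligo[o.sequence] if hits_by_oligo is not None
                else find_hits(o.sequence, unspliced_index, min_matched))
        orientations = {h.orientation for h in hits}
        if orientations == {"plus/plus"}:
            out.append(OligoCandidate(o.target_label, o.offset,
                                      reverse_complement(o.sequence), o.tm, o.gc))
        elif orientations <= {"plus/minus"}:  # empty or plus/minus only
            out.append(o)
        # both orientations: rejected
    return out


def exon_avoidance_filter(
    oligos: Sequence[OligoCandidate], spliced_index: SpecificityIndex,
    min_matched: int = DEFAULT_MIN_MATCHED,
    hits_by_oligo: Mapping[str, list[AlignmentHit]] | None = None,
) -> list[OligoCandidate]:
    """Reject oligos with any hit (either orientation) to a spliced
    transcript, so chromatin probes cannot collide with RNA probes."""
    out = []
    for o in oligos:
        hits = (hits_by_oligo[o.sequence] if hits_by_oligo is not None
                else find_hits(o.sequence, spliced_index, min_matched))
        if not hits:
            out.append(o)
    return out


def isoform_specificity_filter(
    oligos: Sequence[OligoCandidate], spliced_index: SpecificityIndex,
    target_gene: str,
    min_matched: int = DEFAULT_MIN_MATCHED,
    hits_by_oligo: Mapping[str, list[AlignmentHit]] | None = None,
) -> list[OligoCandidate]:
    """Retain RNA-FISH oligos that bind only isoforms of ``target_gene``.

    Only plus/plus hits matter: the probe, being the oligo's reverse
    complement, binds an RNA exactly where the oligo matches a transcript
    in plus/plus. Zero plus/plus hits is an error — an oligo must at
    least hit its own source transcript.
    """
    if spliced_index.gene_map is None:
        raise ValueError("isoform filtering needs a transcript→gene map on the index")
    out = []
    for o in oligos:
        hits = (hits_by_oligo[o.sequence] if hits_by_oligo is not None
                else find_hits(o.sequence, spliced_index, min_matched))
        pp = [h for h in hits if h.orientation == "plus/plus"]
        if not pp:
            raise ValueError(
                f"oligo at {o.target_label}:{o.offset} has no plus/plus hit in "
                "the spliced transcriptome; it must at least match its own transcript"
            )
        genes = {specificity_gene(spliced_index, h) for h in pp}
        if genes == {target_gene}:
            out.append(o)
    return out


def specificity_gene(index: SpecificityIndex, hit: AlignmentHit) -> str:
    gene = index.gene_of(hit.sequence_id)
    if gene is None:
        raise KeyError(f"no gene mapping for transcript {hit.sequence_id!r}")
    return gene
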