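"""MHD4 codebook generation and expression-aware codeword assignment.

The MERFISH barcode space used here is the set of weight-4 codewords of
the extended Hamming [16,11,4] code: 140 binary words of length 16 with
exactly four on-bits and minimum pairwise Hamming distance 4. Each gene
is assigned one codeword; its probes carry three of the four readout
sequences corresponding to the codeword's on-bits.

Because readout (secondary) sequences are shared across genes, two genes
whose codewords share an on-bit compete for the same readout signal. The
assignment step therefore minimizes a bit-sharing load: the sum over bit
positions of the squared total expression of the genes using that bit.
Genes are taken in descending expression order and greedily given the
unused codeword with the smallest incremental load — highly expressed
genes end up on disjoint or lightly loaded bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

CODE_LENGTH = 16
CODE_WEIGHT = 4
CODE_MIN_DISTANCE = 4


@dataclass(frozen=True)
class Codeword:
    """A 16-bit, weight-4 binary word."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bits) != CODE_LENGTH or any(b not in (0, 1) for b in self.bits):
            raise ValueError(f"codeword must be a binary vector of length {CODE_LENGTH}")
        if sum(self.bits) != CODE_WEIGHT:
            raise ValueError(f"codeword weight must be exactly {CODE_WEIGHT}")

    @property
    def on_bits(self) -> tuple[int, ...]:
        return tuple(i for i, b in enumerate(self.bits) if b)

    def __str__(self) -> str:
        return "".join(map(str, self.bits))


@dataclass
class Codebook:
    """Codewords, gene→codeword assignment, and bit→readout identities."""

    codewords: list[Codeword]
    assignment: dict[str, int] = field(default_factory=dict)
    readout_ids: dict[int, str] = field(default_factory=dict)

    def codeword_of(self, gene_id: str) -> Codeword:
        return self.codewords[self.assignment[gene_id]]

    @property
    def capacity(self) -> int:
        return len(self.codewords)


def hamming_distance(a: Codeword, b: Codeword) -> int:
    return sum(x != y for x, y in zip(a.bits, b.bits))


def _extended_hamming_codewords() -> list[tuple[int, ...]]:
    """All 2^11 codewords of the extended Hamming [16,11,4] code.

    Data bits occupy the non-power-of-two positions of the [15,11] Hamming
    code (1-based positions 3,5,6,7,9,...,15); parity bits at positions
    1,2,4,8 are set so each parity group has even parity; an overall
    parity bit extends the word to length 16 and distance 4.
    """
    data_positions = [p for p in range(1, 16) if p & (p - 1) != 0]
    parity_positions = [1, 2, 4, 8]
    words = []
    for message in range(1 << 11):
        bits = [0] * 17  # 1-based positions 1..15 + overall at index 16
        for idx, pos in enumerate(data_positions):
            bits[pos] = (message >> idx) & 1
        for p in parity_positions:
            bits[p] = sum(bits[q] for q in range(1, 16) if q & p and q != p) % 2
        bits[16] = sum(bits[1:16]) % 2
        words.append(tuple(bits[1:17]))
    return words


def generate_mhd4_codebook(readout_ids: Mapping[int, str] | None = None) -> Codebook:
    """The default MHD4 codebook: every weight-4 word of the extended
    Hamming [16,11,4] code (140 codewords, min pairwise distance 4).

    Codewords are ordered lexicographically by on-bit positions so the
    codebook is deterministic.
    """
    shell = [w for w in _extended_hamming_codewords() if sum(w) == CODE_WEIGHT]
    shell.sort(key=lambda w: tuple(i for i, b in enumerate(w) if b))
    cb = Codebook(codewords=[Codeword(w) for w in shell])
    if readout_ids is not None:
        cb.readout_ids = dict(readout_ids)
    return cb


def verify_codebook(cb: Codebook) -> list[str]:
    """Exhaustive diagnostics; an empty list means the codebook is valid."""
    problems = []
    for i, w in enumerate(cb.codewords):
        if len(w.bits) != CODE_LENGTH:
            problems.append(f"codeword {i} ({w}) has length {len(w.bits)}")
        if sum(w.bits) != CODE_WEIGHT:
            problems.append(f"codeword {i} ({w}) has weight {sum(w.bits)}")
    for i, j in combinations(range(len(cb.codewords)), 2):
        d = hamming_distance(cb.codewords[i], cb.codewords[j])
        if d < CODE_MIN_DISTANCE:
            problems.append(f"codewords {i} and {j} are at distance {d}")
    for gene, idx in cb.assignment.items():
        if not 0 <= idx < len(cb.codewords):
            problems.append(f"gene {gene!r} assigned out-of-range codeword {idx}")
    if len(set(cb.assignment.values())) != len(cb.assignment):
        problems.append("assignment is not injective")
    return problems


def bit_sharing_cost(assignment: Mapping[str, int], expr: Mapping[str, float],
                     cb: Codebook) -> float:
    """Σ over bit positions of (Σ expression of genes using that bit)²."""
    loads = [0.0] * CODE_LENGTH
    for gene, idx in assignment.items():
        if gene not in expr:
            raise KeyError(f"gene {gene!r} has no expression value")
        e = float(expr[gene])
        if not (e >= 0.0) or e != e:
            raise ValueError(f"expression for {gene!r} must be finite and >= 0")
        for b in cb.codewords[idx].on_bits:
            loads[b] += e
    return sum(l * l for l in loads)


def assign_codewords(genes: Sequence[str], expr: Mapping[str, float],
                     cb: Codebook) -> Codebook:
    """Greedy expression-aware codeword assignment.

    Genes are sorted by expression descending (ties by gene id); each in
    turn takes the unused codeword minimizing the incremental bit-sharing
    cost (ties by codeword index). The result never costs more than the
    identity (input-order) assignment.
    """
    if len(genes) > cb.capacity:
        raise ValueError(
            f"{len(genes)} genes exceed the codebook capacity of {cb.capacity}"
        )
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids in assignment request")
    missing = [g for g in genes if g not in expr]
    if missing:
        raise KeyError(f"missing expression values for: {', '.join(sorted(missing))}")
    order = sorted(genes, key=lambda g: (-float(expr[g]), g))
    loads = [0.0] * CODE_LENGTH
    used: set[int] = set()
    assignment: dict[str, int] = {}
    for gene in order:
        e = float(expr[gene])
        best_idx, best_inc = None, None
        for idx, w in enumerate(cb.codewords):
            if idx in used:
                continue
            inc = sum(2.0 * loads[b] * e + e * e for b in w.on_bits)
            if best_inc is None or inc < best_inc:
                best_idx, best_inc = idx, inc
        assert best_idx is not None
        used.add(best_idx)
        assignment[gene] = best_idx
        for b in cb.codewords[best_idx].on_bits:
            loads[b] += e
    return Codebook(codewords=cb.codewords, assignment=assignment,
                    readout_ids=dict(cb.readout_ids))


def probe_readout_triplet(codeword: Codeword, probe_index: int) -> tuple[int, int, int]:
    """The three on-bit positions carried by probe ``probe_index``.

    Cycles deterministically through the four leave-one-out subsets of
    the codeword's on-bits: probe ``i`` drops on-bit ``i mod 4``, so each
    readout appears on exactly three of every four consecutive probes.
    Returned positions are in ascending bit order.
    """
    if probe_index < 0:
        raise ValueError("probe_index must be non-negative")
    on = sorted(codeword.on_bits)
    drop = on[probe_index % CODE_WEIGHT]
    kept = tuple(b for b in on if b != drop)
    return kept  # type: ignore[return-value]


def codebook_frame(cb: Codebook) -> pd.DataFrame:
    """Tabular view of an assigned codebook: gene, 16-char bit string,
    and the readout ids of the on-bits."""
    rows = []
    for gene, idx in sorted(cb.assignment.items()):
        w = cb.codewords[idx]
        readouts = [cb.readout_ids.get(b, f"bit{b:02d}") for b in w.on_bits]
        rows.append({"gene_id": gene, "codeword": str(w),
                     "on_bits": ",".join(str(b) for b in w.on_bits),
                     "readouts": ",".join(readouts)})
    return pd.DataFrame(rows, columns=["gene_id", "codeword", "on_bits", "readouts"])


def write_codebook(cb: Codebook, out_dir: str | Path, stem: str = "codebook") -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = codebook_frame(cb)
    paths = [out_dir / f"{stem}.csv", out_dir / f"{stem}.xlsx"]
    df.to_csv(paths[0], index=False)
    df.to_excel(paths[1], index=False)
    return paths
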