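"""Default readout and primer libraries.

The sequences shipped under ``probecraft/data`` are *synthetic
placeholders*, not experimentally validated readout or primer sequences:
they were generated once with the deterministic procedure below
(seed 20201216) and are meant to be replaced by each lab's validated
sets via the editable CSV/XLSX tables. The generator enforces the
orthogonality conventions readout sets follow in practice: 20-nt
sequences, GC between 40 and 60 %, no homopolymer run over 4 nt, and no
12-mer shared between any two sequences in the combined pool (checking
both strands).

Shipped sets: 50 chromatin-tracing readouts, 16 RNA readouts (one per
MERFISH bit), and 3 primer pairs (one per probe type).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly import PrimerPair, ReadoutLibrary
from .sequence_io import reverse_complement

DEFAULT_SEED = 20201216
READOUT_LENGTH = 20
ORTHOGONALITY_K = 12
GC_RANGE = (40.0, 60.0)
MAX_RUN = 4


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def generate_orthogonal_set(n: int, rng: np.random.Generator,
                            used_kmers: set[str],
                            length: int = READOUT_LENGTH) -> list[str]:
    """Draw ``n`` random sequences satisfying the GC / homopolymer rules
    whose 12-mers (either strand) are disjoint from ``used_kmers`` and
    from each other; accepted sequences extend ``used_kmers`` in place."""
    bases = np.array(list("ACGT"))
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200000:
            raise RuntimeError("could not build an orthogonal sequence set")
        seq = "".join(bases[rng.integers(0, 4, size=length)])
        gc = 100.0 * sum(c in "GC" for c in seq) / length
        if not (GC_RANGE[0] <= gc <= GC_RANGE[1]):
            continue
        run, best = 1, 1
        for a, b in zip(seq, seq[1:]):
            run = run + 1 if a == b else 1
            best = max(best, run)
        if best > MAX_RUN:
            continue
        kmers = _kmers(seq, ORTHOGONALITY_K) | _kmers(reverse_complement(seq),
                                                      ORTHOGONALITY_K)
        if kmers & used_kmers:
            continue
        used_kmers |= kmers
        out.append(seq)
    return out


def generate_default_libraries(seed: int = DEFAULT_SEED) -> dict[str, pd.DataFrame]:
    """Regenerate the shipped placeholder tables deterministically."""
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    dna = generate_orthogonal_set(50, rng, used)
    rna = generate_orthogonal_set(16, rng, used)
    primers = generate_orthogonal_set(6, rng, used)
    return {
        "dna_readouts": pd.DataFrame(
            {"id": [f"DR{i + 1:03d}" for i in range(50)], "sequence": dna}),
        "rna_readouts": pd.DataFrame(
            {"id": [f"RR{i + 1:03d}" for i in range(16)], "sequence": rna}),
        "primers": pd.DataFrame({
            "probe_type": ["chromatin", "merfish", "smfish"],
            "forward": primers[0::2],
            "reverse": primers[1::2],
        }),
    }


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("probecraft") / "data" / name)


def load_default_readouts(intended_use: str) -> ReadoutLibrary:
    """The shipped placeholder readout library (``chromatin`` or ``rna``)."""
    name = "dna_readouts.csv" if intended_use == "chromatin" else "rna_readouts.csv"
    return ReadoutLibrary.from_table(_data_path(name), intended_use)  # type: ignore[arg-type]


def load_default_primers() -> dict[str, PrimerPair]:
    """The shipped placeholder primer pairs, keyed by probe type."""
    df = pd.read_csv(_data_path("primers.csv"))
    return {row.probe_type: PrimerPair(row.forward, row.reverse, row.probe_type)
            for row in df.itertuples(index=False)}


def load_primers_table(path: str | Path) -> dict[str, PrimerPair]:
    """Read a user primer table (CSV/TSV/XLSX) with columns
    probe_type, forward, reverse."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if not {"probe_type", "forward", "reverse"} <= set(df.columns):
        raise ValueError("primer table needs probe_type, forward, reverse columns")
    return {str(r.probe_type): PrimerPair(str(r.forward).upper(),
                                          str(r.reverse).upper(), str(r.probe_type))
            for r in df.itertuples(index=False)}


def write_default_tables(out_dir: str | Path,
                         seed: int = DEFAULT_SEED) -> list[Path]:
    """Write the placeholder tables (used once to produce the shipped
    ``probecraft/data`` CSVs; exposed so users can regenerate or reseed)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in generate_default_libraries(seed).items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    return paths
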