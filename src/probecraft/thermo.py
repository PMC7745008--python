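"""Physical-property computations and filters for candidate oligos.

Melting temperatures use the nearest-neighbor model with the SantaLucia
1998 unified parameter set at the 1 M Na+ reference state (no salt
correction) and a total strand concentration of 1e-6 mol/L:

    Tm = ΔH / (ΔS + R·ln(CT/x)) − 273.15

with ΔH, ΔS summed over dinucleotide stacks plus terminal-initiation
terms; x = 4 for non-self-complementary duplexes and 1 (plus the
symmetry entropy term) for self-complementary ones.

Secondary structure is modelled as perfect hairpin stems: substring pairs
that are exact reverse complements, stem length ≥ 4 nt, separated by a
loop of ≥ 3 nt. Cross-hybridization between a candidate and the accepted
probe pool is scored by local alignment (match +5, mismatch −4, gap open
−8, gap extend −6) of the candidate against each accepted oligo and its
reverse complement; the exactly matching aligned columns are concatenated
and their duplex Tm is compared to the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align

from .sequence_io import reverse_complement

#: Sentinel returned when no hairpin stem / no pool sequence exists.
NO_STRUCTURE = float("-inf")

# SantaLucia (1998) unified nearest-neighbor parameters.
# ΔH in kcal/mol, ΔS in cal/(mol·K). Keyed by the top-strand dinucleotide;
# each stack is equivalent to its reverse complement (e.g. AC ≡ GT).
NN_TABLES: dict[str, dict[str, tuple[float, float]]] = {
    "santalucia98": {
        "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
        "AT": (-7.2, -20.4),
        "TA": (-7.2, -21.3),
        "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
        "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
        "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
        "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
        "CG": (-10.6, -27.2),
        "GC": (-9.8, -24.4),
        "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
        # terminal initiation, per end
        "init_GC": (0.1, -2.8),
        "init_AT": (2.3, 4.1),
        # symmetry correction for self-complementary duplexes
        "sym": (0.0, -1.4),
    },
}

MIN_STEM = 4   # nt, shortest hairpin stem considered
MIN_LOOP = 3   # nt, shortest loop between stem halves

# local-alignment scoring for probe-probe cross-hybridization
ALIGN_MATCH = 5
ALIGN_MISMATCH = -4
ALIGN_GAP_OPEN = -8
ALIGN_GAP_EXTEND = -6


@dataclass
class ThermoParameters:
    """Tunable thresholds for oligo generation and the physical filters.

    Defaults follow the standard 30-nt multiplexed-FISH design: Tm ≥ 66 °C,
    GC within [30, 90] %, homopolymer runs of more than 5 nt rejected,
    hairpin stem Tm ≤ 76 °C, cross-hybridized region Tm ≤ 72 °C, evaluated
    at 1 M salt and 1e-6 M probe concentration.
    """

    window_length: int = 30          # nt
    tm_min: float = 66.0             # °C; a window at exactly tm_min passes
    gc_min: float = 30.0             # percent, inclusive
    gc_max: float = 90.0             # percent, inclusive
    max_run: int = 5                 # nt; runs longer than this are rejected
    stem_tm_max: float = 76.0        # °C
    crosshyb_tm_max: float = 72.0    # °C
    na_conc: float = 1.0             # mol/L (NN reference state; no correction applied)
    probe_conc: float = 1e-6         # mol/L total strand concentration
    nn_table: str = "santalucia98"
    gas_constant: float = 1.987      # cal/(mol·K), fixed

    def __post_init__(self) -> None:
        if self.na_conc <= 0 or self.probe_conc <= 0:
            raise ValueError("concentrations must be positive")
        if self.gc_min > self.gc_max:
            raise ValueError("gc_min must not exceed gc_max")
        if self.window_length < 10:
            raise ValueError("window_length must be at least 10 nt")
        if self.nn_table not in NN_TABLES:
            raise ValueError(f"unknown nearest-neighbor table {self.nn_table!r}")

    @classmethod
    def from_table(cls, path: str | Path) -> "ThermoParameters":
        """Load parameters from a name/value table (CSV/TSV/XLSX), one row
        per parameter; unnamed parameters keep their defaults."""
        path = Path(path)
        if path.suffix.lower() in (".xlsx", ".xls"):
            df = pd.read_excel(path)
        else:
            sep = "," if path.suffix.lower() == ".csv" else "\t"
            df = pd.read_csv(path, sep=sep)
        df.columns = [str(c).strip().lower() for c in df.columns]
        if not {"name", "value"} <= set(df.columns):
            raise ValueError("parameter table needs 'name' and 'value' columns")
        kwargs = {}
        numeric_ints = {"window_length", "max_run"}
        for _, row in df.iterrows():
            name = str(row["name"]).strip()
            if name == "gas_constant":
                continue  # fixed physical constant
            if name not in cls.__dataclass_fields__:
                raise ValueError(f"unknown parameter {name!r}")
            val = row["value"]
            if name == "nn_table":
                kwargs[name] = str(val)
            elif name in numeric_ints:
                kwargs[name] = int(val)
            else:
                kwargs[name] = float(val)
        return cls(**kwargs)


@dataclass(frozen=True)
class FilterVerdict:
    """Outcome of the physical-filter cascade for one window."""

    passed: bool
    failed_rule: str | None  # gc | repeat | tm | hairpin | crosshyb | alphabet
    measured: dict

    def __post_init__(self) -> None:
        if self.passed != (self.failed_rule is None):
            raise ValueError("passed must be equivalent to failed_rule is None")


def gc_content(seq: str) -> float:
    """GC content in percent. Rejects empty or N-containing input."""
    if not seq:
        raise ValueError("gc_content of empty sequence is undefined")
    seq = seq.upper()
    if set(seq) - set("ACGT"):
        raise ValueError("gc_content requires an A/C/G/T sequence")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def longest_homopolymer(seq: str) -> int:
    """Length of the longest run of a single identical base."""
    if not seq:
        raise ValueError("empty sequence")
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _is_self_complementary(seq: str) -> bool:
    return seq == reverse_complement(seq)


def duplex_tm(seq: str, params: ThermoParameters | None = None) -> float:
    """Melting temperature (°C) of ``seq`` against its perfect complement.

    Nearest-neighbor summation with terminal initiation terms; CT/4 in the
    log term for non-self-complementary duplexes, CT (and the symmetry
    entropy term) for self-complementary ones. No salt correction: the
    parameter set's 1 M Na+ reference state is assumed.
    """
    params = params or ThermoParameters()
    seq = seq.upper()
    if len(seq) < 2:
        raise ValueError("duplex_tm requires at least 2 nt")
    if set(seq) - set("ACGT"):
        raise ValueError("duplex_tm requires an A/C/G/T sequence")
    table = NN_TABLES[params.nn_table]
    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        h, s = table[seq[i:i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = table["init_GC" if terminal in "GC" else "init_AT"]
        dh += h
        ds += s
    if _is_self_complementary(seq):
        h, s = table["sym"]
        dh += h
        ds += s
        x = 1.0
    else:
        x = 4.0
    ct = params.probe_conc
    return dh * 1000.0 / (ds + params.gas_constant * math.log(ct / x)) - 273.15


def enumerate_stems(seq: str, min_stem: int = MIN_STEM,
                    min_loop: int = MIN_LOOP) -> list[tuple[int, int, int]]:
    """All perfect hairpin stems ``(i, j, length)``: seq[j:j+length] is the
    reverse complement of seq[i:i+length], with a loop of ≥ min_loop nt
    between the stem halves."""
    seq = seq.upper()
    n = len(seq)
    stems = []
    for length in range(min_stem, (n - min_loop) // 2 + 1):
        for i in range(n - 2 * length - min_loop + 1):
            target = reverse_complement(seq[i:i + length])
            for j in range(i + length + min_loop, n - length + 1):
                if seq[j:j + length] == target:
                    stems.append((i, j, length))
    return stems


def hairpin_stem_tm(seq: str, params: ThermoParameters | None = None) -> float:
    """Maximum duplex Tm over all perfect hairpin stems in ``seq``.

    Returns the ``NO_STRUCTURE`` sentinel when the sequence contains no
    stem of ≥ 4 nt with a ≥ 3-nt loop (such windows pass the filter).
    """
    params = params or ThermoParameters()
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    best = NO_STRUCTURE
    # longest stems dominate Tm, but enumerate all lengths for correctness
    for length in range(MIN_STEM, (n - MIN_LOOP) // 2 + 1):
        for i in range(n - 2 * length - MIN_LOOP + 1):
            target = reverse_complement(seq[i:i + length])
            j = seq.find(target, i + length + MIN_LOOP)
            while j != -1:
                if "N" not in seq[i:i + length]:
                    best = max(best, duplex_tm(seq[i:i + length], params))
                j = seq.find(target, j + 1)
    return best


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    aligner.match_score = ALIGN_MATCH
    aligner.mismatch_score = ALIGN_MISMATCH
    aligner.open_gap_score = ALIGN_GAP_OPEN
    aligner.extend_gap_score = ALIGN_GAP_EXTEND
    return aligner


_ALIGNER = _local_aligner()


def matched_region(a: str, b: str) -> str:
    """Concatenated exactly-matching columns of the best local alignment
    of ``a`` against ``b`` (empty string when the aligner finds nothing)."""
    if not a or not b:
        return ""
    alignments = _ALIGNER.align(a, b)
    if len(alignments) == 0 or alignments.score <= 0:
        return ""
    aln = alignments[0]
    cols_a, cols_b = aln[0], aln[1]
    return "".join(x for x, y in zip(cols_a, cols_b) if x == y and x != "-")


def cross_hybridization_tm(candidate: str,
                           accepted: Iterable[str],
                           params: ThermoParameters | None = None) -> float:
    """Worst-case Tm of the cross-hybridized region between ``candidate``
    and any accepted oligo (checked against each oligo and its reverse
    complement). ``NO_STRUCTURE`` sentinel for an empty pool."""
    params = params or ThermoParameters()
    if not candidate:
        raise ValueError("empty candidate")
    best = NO_STRUCTURE
    for other in accepted:
        for ref in (other, reverse_complement(other)):
            region = matched_region(candidate, ref)
            if len(region) >= 2 and "N" not in region:
                best = max(best, duplex_tm(region, params))
    return best


def passes_physical_filters(seq: str,
                            params: ThermoParameters | None = None,
                            accepted: Sequence[str] = ()) -> FilterVerdict:
    """Apply the physical-filter cascade to one window.

    Order (cheap to expensive, short-circuiting): alphabet, GC bounds
    (inclusive), homopolymer run, minimum Tm, hairpin stem Tm, cross-
    hybridization Tm against the accepted pool.
    """
    params = params or ThermoParameters()
    seq = seq.upper()
    measured: dict = {}
    if set(seq) - set("ACGT"):
        return FilterVerdict(False, "alphabet", measured)
    gc = gc_content(seq)
    measured["gc"] = gc
    if not (params.gc_min <= gc <= params.gc_max):
        return FilterVerdict(False, "gc", measured)
    run = longest_homopolymer(seq)
    measured["repeat"] = run
    if run > params.max_run:
        return FilterVerdict(False, "repeat", measured)
    tm = duplex_tm(seq, params)
    measured["tm"] = tm
    if tm < params.tm_min:
        return FilterVerdict(False, "tm", measured)
    stem_tm = hairpin_stem_tm(seq, params)
    measured["hairpin"] = stem_tm
    if stem_tm > params.stem_tm_max:
        return FilterVerdict(False, "hairpin", measured)
    xh_tm = cross_hybridization_tm(seq, accepted, params)
    measured["crosshyb"] = xh_tm
    if xh_tm > params.crosshyb_tm_max:
        return FilterVerdict(False, "crosshyb", measured)
    return FilterVerdict(True, None, measured)
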