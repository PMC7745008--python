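"""Sliding-window oligo generation.

Each target is scanned from its 5′ end with a window of
``params.window_length`` nt. An accepted window advances the scan by one
full window length (adjacent, non-overlapping tiling); a rejected window
advances it by 1 nt. Accepted oligos join the shared cross-hybridization
pool immediately, so later windows — in this target and in later targets
— are screened against them. The procedure is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .thermo import FilterVerdict, ThermoParameters, passes_physical_filters


@dataclass(frozen=True)
class OligoCandidate:
    """An accepted window: same strand as its input target.

    ``sequence`` always equals the target subsequence at
    ``[offset, offset + window_length)``; accepted oligos from one target
    never overlap.
    """

    target_label: str
    offset: int          # 0-based position in the target
    sequence: str
    tm: float            # °C
    gc: float            # percent


FilterFn = Callable[[str, ThermoParameters, Sequence[str]], FilterVerdict]


def scan_target(
    target: tuple[str, str],
    params: ThermoParameters | None = None,
    accepted_pool: list[OligoCandidate] | None = None,
    filter_fn: FilterFn = passes_physical_filters,
) -> list[OligoCandidate]:
    """Scan one ``(label, sequence)`` target and return accepted oligos
    in 5′→3′ order.

    ``accepted_pool`` is the shared library-wide pool: windows are
    cross-hybridization-screened against it plus the oligos already
    accepted in this scan, and newly accepted oligos are appended to it
    in place. ``filter_fn`` defaults to the physical-filter cascade; an
    injected predicate must honour the same
    ``(seq, params, accepted_sequences) -> FilterVerdict`` contract.
    """
    params = params or ThermoParameters()
    if accepted_pool is None:
        accepted_pool = []
    label, seq = target
    seq = seq.upper()
    w = params.window_length
    out: list[OligoCandidate] = []
    pos = 0
    while pos + w <= len(seq):
        window = seq[pos:pos + w]
        verdict = filter_fn(window, params, [o.sequence for o in accepted_pool])
        if verdict.passed:
            cand = OligoCandidate(
                target_label=label,
                offset=pos,
                sequence=window,
                tm=verdict.measured.get("tm", float("nan")),
                gc=verdict.measured.get("gc", float("nan")),
            )
            out.append(cand)
            accepted_pool.append(cand)
            pos += w
        else:
            pos += 1
    return out


def scan_targets(
    targets: Sequence[tuple[str, str]],
    params: ThermoParameters | None = None,
    filter_fn: FilterFn = passes_physical_filters,
) -> dict[str, list[OligoCandidate]]:
    """Scan several targets in input order with one shared pool."""
    params = params or ThermoParameters()
    pool: list[OligoCandidate] = []
    return {label: scan_target((label, seq), params, pool, filter_fn)
            for label, seq in targets}
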