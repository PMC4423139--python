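"""Recovery metrics for benchmarking decomposition on simulated data."""

from __future__ import annotations

from typing import Sequence


def boundary_recovery(
    true_units: Sequence[tuple[int, int]], found_units: Sequence[tuple[int, int]]
) -> float:
    """Fraction of true unit-boundary positions present among the found ones.

    Boundary positions are the union of unit start and end coordinates
    (adjacent units share one position).  Only meaningful when true and found
    coordinates live in the same frame, i.e. substitution-only noise.
    """
    true_pos = {p for u in true_units for p in u}
    if not true_pos:
        return 1.0
    found_pos = {p for u in found_units for p in u}
    return len(true_pos & found_pos) / len(true_pos)
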