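"""Motif-anchored tandem-repeat decomposition of cysteine-rich proteins.

Avian EDCRP and related proteins are organised as a short N-terminal segment,
a central region of 6-56 tandem repeats of 7-9 (exceptionally 10) residues
built on the conserved hexapeptide core ``CCDPCQ``, and a C-terminal segment.
Repeat units are typed by the residues C-terminal of the core: the main types
are KP, K(T/S)V, (T/S) and QS(V).  This module finds the cores, segments the
sequence into units, classifies each unit's tail, and summarises how unit
types alternate along the protein.

Scanning is greedy, left to right, and fully deterministic: the two cysteines
at the start of the core (the CC anchor) must match exactly, up to
``max_mismatch`` substitutions are tolerated in the rest of the core, ``X``
never matches, and accepted cores never overlap.  The decomposition is
loss-free: N-terminus, units, inter-unit linkers and C-terminus concatenate
back to the input sequence exactly.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import pandas as pd

from .seqio import ProteinRecord

CORE = "CCDPCQ"
MAX_MISMATCH = 1
EXACT_PREFIX_LEN = 2
MAX_TAIL = 4

LABEL_CORE_ONLY = "CORE_ONLY"
LABEL_OTHER = "OTHER"


@dataclass(frozen=True)
class CoreMatch:
    """One accepted occurrence of the repeat core."""

    start: int
    mismatches: int


@dataclass(frozen=True)
class RepeatUnit:
    """One repeat unit: the core plus its C-terminal tail, [start, end)."""

    start: int
    end: int
    core_start: int
    tail: str
    type_label: str

    def __post_init__(self) -> None:
        if self.core_start != self.start:
            raise ValueError("unit must begin with its core")
        if not (6 <= self.end - self.start <= 6 + MAX_TAIL):
            raise ValueError(
                f"unit length {self.end - self.start} outside [6, {6 + MAX_TAIL}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class TypeInventory:
    """Ordered tail-pattern -> label rules; first match wins, else OTHER.

    Patterns are tail strings in which ``[TS]`` marks a T-or-S wildcard
    position and a trailing ``V?`` marks an optional valine, mirroring the
    field's K(T/S)V / QS(V) notation.  The empty tail maps to CORE_ONLY.
    """

    def __init__(self, rules: Sequence[tuple[str, str]]):
        self.rules = [(p, lbl, re.compile(p + r"\Z")) for p, lbl in rules]

    def classify(self, tail: str) -> str:
        if len(tail) > MAX_TAIL:
            raise ValueError(f"tail {tail!r} longer than {MAX_TAIL} residues")
        if tail == "":
            return LABEL_CORE_ONLY
        for _, label, rx in self.rules:
            if rx.match(tail):
                return label
        return LABEL_OTHER

    def matches_any(self, tail: str) -> bool:
        """True if the non-empty tail matches some inventory rule."""
        return tail != "" and self.classify(tail) != LABEL_OTHER


#: The four main repeat types observed across birds, keyed by tail.
DEFAULT_INVENTORY = TypeInventory(
    [
        ("KP", "KP"),
        ("K[TS]V", "K(T/S)V"),
        ("[TS]", "(T/S)"),
        ("QSV?", "QS(V)"),
    ]
)


@dataclass(frozen=True)
class AlternationSummary:
    """Longest run of units whose labels strictly alternate between two types."""

    pair_labels: Optional[tuple[str, str]]
    n_pairs: int
    run_start_unit: int
    run_length: int


@dataclass
class RepeatArchitecture:
    """Full decomposition of one protein into N-terminus, units and C-terminus."""

    seq: str
    nterm: str
    units: list[RepeatUnit]
    linkers: list[tuple[tuple[int, int], str]]
    cterm: str
    n_cores: int
    record_id: str = ""
    type_counts: Counter = field(default_factory=Counter)
    alternation: AlternationSummary = field(
        default_factory=lambda: AlternationSummary(None, 0, 0, 0)
    )

    @property
    def n_repeats(self) -> int:
        return len(self.units)

    @property
    def labels(self) -> list[str]:
        return [u.type_label for u in self.units]

    def reconstruct(self) -> str:
        """Concatenate nterm, units and linkers in coordinate order, then cterm."""
        pieces = [(u.start, self.seq[u.start : u.end]) for u in self.units]
        pieces += [(iv[0], s) for iv, s in self.linkers]
        body = "".join(s for _, s in sorted(pieces))
        return self.nterm + body + self.cterm

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "length": len(self.seq),
            "nterm": {"interval": [0, len(self.nterm)], "seq": self.nterm},
            "cterm": {
                "interval": [len(self.seq) - len(self.cterm), len(self.seq)],
                "seq": self.cterm,
            },
            "n_cores": self.n_cores,
            "n_repeats": self.n_repeats,
            "units": [
                {
                    "start": u.start,
                    "end": u.end,
                    "seq": self.seq[u.start : u.end],
                    "tail": u.tail,
                    "type_label": u.type_label,
                }
                for u in self.units
            ],
            "linkers": [
                {"start": iv[0], "end": iv[1], "seq": s} for iv, s in self.linkers
            ],
            "type_counts": dict(self.type_counts),
            "alternation": {
                "pair_labels": list(self.alternation.pair_labels)
                if self.alternation.pair_labels
                else None,
                "n_pairs": self.alternation.n_pairs,
                "run_start_unit": self.alternation.run_start_unit,
                "run_length": self.alternation.run_length,
            },
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def units_table(self) -> pd.DataFrame:
        """One row per repeat unit (flat TSV-ready view)."""
        return pd.DataFrame(
            [
                {
                    "record_id": self.record_id,
                    "unit_index": i,
                    "start": u.start,
                    "end": u.end,
                    "length": u.length,
                    "seq": self.seq[u.start : u.end],
                    "tail": u.tail,
                    "type_label": u.type_label,
                }
                for i, u in enumerate(self.units)
            ],
            columns=[
                "record_id",
                "unit_index",
                "start",
                "end",
                "length",
                "seq",
                "tail",
                "type_label",
            ],
        )


def _window_mismatches(window: str, core: str, exact_prefix_len: int) -> Optional[int]:
    """Mismatch count of window vs core, or None if the exact prefix fails.

    ``X`` counts as a mismatch at any position.
    """
    if window[:exact_prefix_len] != core[:exact_prefix_len]:
        return None
    mm = 0
    for a, b in zip(window[exact_prefix_len:], core[exact_prefix_len:]):
        if a != b or a == "X":
            mm += 1
    return mm


def find_cores(
    seq: str,
    core: str = CORE,
    max_mismatch: int = MAX_MISMATCH,
    exact_prefix_len: int = EXACT_PREFIX_LEN,
) -> list[CoreMatch]:
    """Greedy left-to-right scan for non-overlapping core occurrences.

    A window matches when its first ``exact_prefix_len`` residues equal the
    core prefix exactly (the CC anchor) and the total number of mismatches in
    the remainder is at most ``max_mismatch``; the scan resumes at the end of
    each accepted match.
    """
    if not core:
        raise ValueError("core motif must be non-empty")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if exact_prefix_len > len(core):
        raise ValueError("exact_prefix_len exceeds core length")
    L = len(core)
    matches: list[CoreMatch] = []
    i = 0
    while i + L <= len(seq):
        mm = _window_mismatches(seq[i : i + L], core, exact_prefix_len)
        if mm is not None and mm <= max_mismatch:
            matches.append(CoreMatch(start=i, mismatches=mm))
            i += L
        else:
            i += 1
    return matches


def _check_cores(seq: str, cores: Sequence[CoreMatch], core_len: int) -> None:
    prev_end = -1
    for c in cores:
        if c.start < 0 or c.start + core_len > len(seq):
            raise ValueError(f"core at {c.start} outside sequence of length {len(seq)}")
        if c.start < prev_end:
            raise ValueError(f"overlapping cores at {c.start} (previous ends {prev_end})")
        prev_end = c.start + core_len


def segment_units(
    seq: str,
    cores: Sequence[CoreMatch],
    max_tail: int = MAX_TAIL,
    inventory: TypeInventory = DEFAULT_INVENTORY,
    core_len: int = len(CORE),
    record_id: str = "",
) -> RepeatArchitecture:
    """Segment a sequence into N-terminus, typed repeat units (+linkers), C-terminus.

    Consecutive cores closer than ``core_len + max_tail`` delimit units that
    span the whole gap; wider gaps truncate the unit at ``core + max_tail``
    and record the surplus as a linker.  The final unit's tail is the longest
    stretch of at most ``max_tail`` residues after its core that matches an
    inventory pattern; unmatched residues go to the C-terminus.
    """
    cores = sorted(cores, key=lambda c: c.start)
    _check_cores(seq, cores, core_len)
    if not cores:
        arch = RepeatArchitecture(
            seq=seq, nterm=seq, units=[], linkers=[], cterm="", n_cores=0,
            record_id=record_id,
        )
        return arch

    nterm = seq[: cores[0].start]
    units: list[RepeatUnit] = []
    linkers: list[tuple[tuple[int, int], str]] = []
    for i, c in enumerate(cores):
        s = c.start
        if i + 1 < len(cores):
            nxt = cores[i + 1].start
            gap = nxt - s
            if gap <= core_len + max_tail:
                end = nxt
            else:
                end = s + core_len + max_tail
                linkers.append(((end, nxt), seq[end:nxt]))
        else:
            rest = seq[s + core_len :]
            tail_len = 0
            for ln in range(min(max_tail, len(rest)), 0, -1):
                if inventory.matches_any(rest[:ln]):
                    tail_len = ln
                    break
            end = s + core_len + tail_len
        tail = seq[s + core_len : end]
        units.append(
            RepeatUnit(
                start=s, end=end, core_start=s, tail=tail,
                type_label=inventory.classify(tail),
            )
        )
    cterm = seq[units[-1].end :]
    arch = RepeatArchitecture(
        seq=seq, nterm=nterm, units=units, linkers=linkers, cterm=cterm,
        n_cores=len(cores), record_id=record_id,
    )
    arch.type_counts = Counter(arch.labels)
    arch.alternation = alternation_stats(arch.labels)
    return arch


def classify_tail(tail: str, inventory: TypeInventory = DEFAULT_INVENTORY) -> str:
    """Map a repeat-unit tail to its type label (first matching rule wins)."""
    return inventory.classify(tail)


def alternation_stats(labels: Sequence[str]) -> AlternationSummary:
    """Longest contiguous run whose labels strictly alternate between two types.

    Ties are broken by the earliest run start.  Fewer than two units, or no
    alternating stretch at all, yield ``n_pairs == 0`` with no pair labels.
    """
    n = len(labels)
    if n == 0:
        return AlternationSummary(None, 0, 0, 0)
    best_start, best_len = 0, 1
    run_start = 0
    for j in range(1, n):
        if labels[j] == labels[j - 1]:
            run_start = j
        elif j - run_start >= 2 and labels[j] != labels[j - 2]:
            # three distinct labels in a row: run restarts at the last pair
            run_start = j - 1
        if j - run_start + 1 > best_len:
            best_start, best_len = run_start, j - run_start + 1
    if best_len < 2:
        return AlternationSummary(None, 0, 0, min(1, n))
    pair = (labels[best_start], labels[best_start + 1])
    return AlternationSummary(
        pair_labels=pair,
        n_pairs=best_len // 2,
        run_start_unit=best_start,
        run_length=best_len,
    )


def decompose(
    rec: Union[ProteinRecord, str],
    core: str = CORE,
    max_mismatch: int = MAX_MISMATCH,
    exact_prefix_len: int = EXACT_PREFIX_LEN,
    max_tail: int = MAX_TAIL,
    inventory: TypeInventory = DEFAULT_INVENTORY,
) -> RepeatArchitecture:
    """Full decomposition: find cores, segment units, type tails, summarise."""
    if isinstance(rec, str):
        rec = ProteinRecord(id="seq", seq=rec)
    cores = find_cores(
        rec.seq, core=core, max_mismatch=max_mismatch,
        exact_prefix_len=exact_prefix_len,
    )
    return segment_units(
        rec.seq, cores, max_tail=max_tail, inventory=inventory,
        core_len=len(core), record_id=rec.id,
    )
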