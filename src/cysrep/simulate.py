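"""Synthetic EDCRP-like proteins, promoters and mutation noise with ground truth.

The generator emulates the documented architecture of avian EDCRP: an 8-20
residue N-terminal segment, 6-56 tandem repeats of 7-10 residues built on the
CCDPCQ core (optionally strictly alternating between two types), and a 52-75
residue C-terminal segment, with overall cysteine content landing in the
29-38% range for plans built from the four main repeat types.  Every call is
reproducible from its seed and returns the exact pre-noise architecture as
ground truth, so repeat decomposition, composition profiling and promoter
classification can all be benchmarked without any external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .composition import residue_profile
from .promoters import (
    CANONICAL_TATA,
    CLASS_CANONICAL,
    CLASS_NONE,
    CLASS_TATA_LIKE,
    DEFAULT_WINDOW,
    TATA_LIKE,
)
from .repeats import (
    CORE,
    DEFAULT_INVENTORY,
    RepeatArchitecture,
    RepeatUnit,
    TypeInventory,
    alternation_stats,
    decompose,
)
from .seqio import AA20, DnaRecord, ProteinRecord

#: residues drawn for terminal segments besides cysteine
TERMINAL_BACKGROUND = "KQPSVDGL"

#: the four main repeat-unit strings, keyed by their tail-type label
MAIN_UNITS = (
    ("KP", "CCDPCQKP"),
    ("K(T/S)V", "CCDPCQKTV"),
    ("(T/S)", "CCDPCQT"),
    ("QS(V)", "CCDPCQQSV"),
)

NTERM_RANGE = (8, 20)
CTERM_RANGE = (52, 75)
N_UNITS_RANGE = (6, 56)
UNIT_LEN_RANGE = (7, 10)
CYS_BAND = (29.0, 38.0)


@dataclass(frozen=True)
class RepeatPlan:
    """A blueprint for the central repeat region.

    ``unit_specs`` lists (type_label, unit_string) building blocks; the
    arrangement is the literal listed order, a strict two-type alternation,
    or a seeded random mix of the listed blocks.
    """

    unit_specs: tuple
    arrangement: str = "as_listed"  # as_listed | alternating | random
    n_units: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit_specs", tuple(tuple(u) for u in self.unit_specs))
        if not self.unit_specs:
            raise ValueError("plan needs at least one unit spec")
        for label, unit in self.unit_specs:
            if not unit.startswith(CORE):
                raise ValueError(f"unit {unit!r} does not start with the {CORE} core")
            if not (UNIT_LEN_RANGE[0] <= len(unit) <= UNIT_LEN_RANGE[1]):
                raise ValueError(
                    f"unit {unit!r} length outside {list(UNIT_LEN_RANGE)}"
                )
        if self.arrangement not in ("as_listed", "alternating", "random"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        n = self.resolved_n_units()
        if not (N_UNITS_RANGE[0] <= n <= N_UNITS_RANGE[1]):
            raise ValueError(f"n_units {n} outside {list(N_UNITS_RANGE)}")
        if self.arrangement == "alternating":
            if len(self.unit_specs) != 2:
                raise ValueError("alternating arrangement needs exactly 2 unit specs")
            if n % 2:
                raise ValueError("alternating arrangement needs an even n_units")

    def resolved_n_units(self) -> int:
        if self.n_units is not None:
            return self.n_units
        return len(self.unit_specs)

    @classmethod
    def alternating(
        cls, unit_a: tuple[str, str], unit_b: tuple[str, str], n_pairs: int
    ) -> "RepeatPlan":
        return cls((unit_a, unit_b), "alternating", n_units=2 * n_pairs)

    @classmethod
    def random_mix(cls, unit_specs: Sequence[tuple], n_units: int) -> "RepeatPlan":
        return cls(tuple(unit_specs), "random", n_units=n_units)

    def realize(self, rng: np.random.Generator) -> list[tuple[str, str]]:
        """The ordered (label, unit_string) list this plan emits."""
        n = self.resolved_n_units()
        if self.arrangement == "as_listed":
            if self.n_units is not None and self.n_units != len(self.unit_specs):
                raise ValueError("as_listed n_units must equal len(unit_specs)")
            return list(self.unit_specs)
        if self.arrangement == "alternating":
            a, b = self.unit_specs
            return [a if i % 2 == 0 else b for i in range(n)]
        idx = rng.integers(0, len(self.unit_specs), size=n)
        return [self.unit_specs[i] for i in idx]


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside each synthetic protein."""

    plan: RepeatPlan
    nterm_len: int
    cterm_len: int
    sub_rate: float
    indel_rate: float
    seed: int
    pre_noise_seq: str
    true_architecture: RepeatArchitecture


def _sample_terminal(rng: np.random.Generator, length: int, cys_fraction: float) -> str:
    """Terminal segment with an exact rounded cysteine count, random placement.

    Fixing the composition (rather than drawing each residue independently)
    keeps the simulated cysteine percentage deterministic for a given plan.
    """
    n_cys = int(round(cys_fraction * length))
    others = rng.choice(list(TERMINAL_BACKGROUND), size=length - n_cys)
    residues = ["C"] * n_cys + list(others)
    rng.shuffle(residues)
    return "".join(residues)


def _truth_architecture(
    nterm: str, units: Sequence[tuple[str, str]], cterm: str
) -> RepeatArchitecture:
    seq_units: list[RepeatUnit] = []
    pos = len(nterm)
    for label, unit in units:
        seq_units.append(
            RepeatUnit(
                start=pos, end=pos + len(unit), core_start=pos,
                tail=unit[len(CORE):], type_label=label,
            )
        )
        pos += len(unit)
    seq = nterm + "".join(u for _, u in units) + cterm
    arch = RepeatArchitecture(
        seq=seq, nterm=nterm, units=seq_units, linkers=[], cterm=cterm,
        n_cores=len(seq_units),
    )
    from collections import Counter

    arch.type_counts = Counter(arch.labels)
    arch.alternation = alternation_stats(arch.labels)
    return arch


def _same_architecture(a: RepeatArchitecture, b: RepeatArchitecture) -> bool:
    return (
        a.nterm == b.nterm
        and a.cterm == b.cterm
        and [(u.start, u.end, u.type_label) for u in a.units]
        == [(u.start, u.end, u.type_label) for u in b.units]
    )


def generate_edcrp_like(
    seed: int,
    plan: RepeatPlan,
    nterm_len: int = 12,
    cterm_len: int = 60,
    terminal_cys_fraction: float = 0.25,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    record_id: Optional[str] = None,
    species: str = "synthetic",
    inventory: TypeInventory = DEFAULT_INVENTORY,
    max_tries: int = 200,
) -> tuple[ProteinRecord, SyntheticTruth]:
    """Emit one EDCRP-like protein with its exact pre-noise ground truth.

    Terminal segments are resampled (composition fixed, placement random)
    until the zero-noise sequence decomposes exactly into the planned
    architecture, i.e. the random termini introduce no spurious cores and do
    not extend the last unit's tail.  Noise is applied after the truth is
    recorded.
    """
    if not (NTERM_RANGE[0] <= nterm_len <= NTERM_RANGE[1]):
        raise ValueError(f"nterm_len {nterm_len} outside {list(NTERM_RANGE)}")
    if not (CTERM_RANGE[0] <= cterm_len <= CTERM_RANGE[1]):
        raise ValueError(f"cterm_len {cterm_len} outside {list(CTERM_RANGE)}")
    if not (0.0 <= sub_rate <= 0.2 and 0.0 <= indel_rate <= 0.2):
        raise ValueError("sub_rate and indel_rate must lie in [0, 0.2]")
    if not (0.0 <= terminal_cys_fraction <= 1.0):
        raise ValueError("terminal_cys_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    units = plan.realize(rng)
    for _ in range(max_tries):
        nterm = _sample_terminal(rng, nterm_len, terminal_cys_fraction)
        cterm = _sample_terminal(rng, cterm_len, terminal_cys_fraction)
        truth_arch = _truth_architecture(nterm, units, cterm)
        if _same_architecture(decompose(truth_arch.seq, inventory=inventory), truth_arch):
            break
    else:
        raise RuntimeError(
            f"seed {seed}: no unambiguous termini found in {max_tries} tries"
        )
    cys = residue_profile(truth_arch.seq).cys_percent
    if not (CYS_BAND[0] <= cys <= CYS_BAND[1]):
        warnings.warn(
            f"plan yields cysteine content {cys:.1f}%, outside the "
            f"[{CYS_BAND[0]:g}, {CYS_BAND[1]:g}]% band typical of EDCRP"
        )
    noisy = mutate(truth_arch.seq, sub_rate, indel_rate, rng=rng)
    rec_id = record_id if record_id is not None else f"synthetic_edcrp_{seed}"
    rec = ProteinRecord(id=rec_id, seq=noisy, species=species)
    truth = SyntheticTruth(
        plan=plan, nterm_len=nterm_len, cterm_len=cterm_len,
        sub_rate=sub_rate, indel_rate=indel_rate, seed=seed,
        pre_noise_seq=truth_arch.seq, true_architecture=truth_arch,
    )
    return rec, truth


def mutate(
    seq: str,
    sub_rate: float,
    indel_rate: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Apply independent per-position substitutions and single-residue indels.

    Substitutions replace a residue with a uniformly chosen *different* one of
    the 20 standard amino acids; insertions and deletions each occur at
    ``indel_rate / 2`` per position.
    """
    if not (0.0 <= sub_rate <= 1.0 and 0.0 <= indel_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    aa = sorted(AA20)
    out: list[str] = []
    for ch in seq:
        if indel_rate and rng.random() < indel_rate / 2:
            out.append(aa[rng.integers(0, len(aa))])  # insertion before position
        if indel_rate and rng.random() < indel_rate / 2:
            continue  # deletion
        if sub_rate and rng.random() < sub_rate:
            choices = [a for a in aa if a != ch]
            ch = choices[rng.integers(0, len(choices))]
        out.append(ch)
    return "".join(out)


# ---------------------------------------------------------------------------
# promoters

_ALL_MOTIFS = tuple(CANONICAL_TATA) + (TATA_LIKE,)
_PLANT = {CLASS_CANONICAL: "TATAAA", CLASS_TATA_LIKE: TATA_LIKE}


def _window_instances(region: str) -> list[tuple[int, str]]:
    hits = []
    for m in _ALL_MOTIFS:
        i = region.find(m)
        while i != -1:
            hits.append((i, m))
            i = region.find(m, i + 1)
    return hits


def generate_promoter(
    seed: int,
    element: str,
    position: int = -30,
    length: int = 200,
    window: tuple[int, int] = DEFAULT_WINDOW,
    max_tries: int = 1000,
) -> DnaRecord:
    """Emit a promoter with a planted element (or none) and TSS at length-50.

    The uniform-random background is rejection-filtered so the scan window
    contains no motif instance other than those starting at the planted
    position; planting TATAAA may read as TATAAAA when followed by A, which
    leaves the class and position unchanged.
    """
    if element not in (CLASS_CANONICAL, CLASS_TATA_LIKE, CLASS_NONE):
        raise ValueError(f"unknown element class {element!r}")
    tss = length - 50
    motif = _PLANT.get(element)
    if motif is not None:
        if not (window[0] <= position and position + len(motif) <= window[1]):
            raise ValueError(
                f"position {position} (+{len(motif)} bp motif) outside window {window}"
            )
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    a, b = tss + window[0], tss + window[1]
    for _ in range(max_tries):
        seq = "".join(rng.choice(bases, size=length))
        if motif is not None:
            p = tss + position
            seq = seq[:p] + motif + seq[p + len(motif):]
        instances = _window_instances(seq[a:b])
        if motif is None:
            ok = not instances
        else:
            ok = bool(instances) and all(
                off == position - window[0] for off, _ in instances
            )
        if ok:
            return DnaRecord(id=f"synthetic_promoter_{element}_{seed}", seq=seq,
                             tss_index=tss, species="synthetic")
    raise RuntimeError(
        f"seed {seed}: no motif-clean background found in {max_tries} tries"
    )
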