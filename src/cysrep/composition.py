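"""Amino-acid composition and CC-dipeptide periodicity.

Cornification proteins cross-link either through disulfide bonds (cysteine)
or through transglutamination (lysine/glutamine), so the readouts here are
the residue fractions of C, K, Q, P, S and the spacing of consecutive-
cysteine (CC) dipeptide sites, which recur every 8-11 residues along
EDCRP-like proteins.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass
from typing import Union

from .seqio import ProteinRecord

CC_BAND = (8, 11)
CROSSLINK_RESIDUES = ("C", "K", "Q", "P", "S")


@dataclass(frozen=True)
class CompositionProfile:
    counts: dict
    fractions: dict
    length: int
    cys_percent: float
    cys_percent_rounded: int


@dataclass(frozen=True)
class CCPeriodicity:
    """Start positions of maximal CC+ runs and their successive spacings."""

    sites: list
    spacings: list
    in_band_fraction: float


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def residue_profile(
    seq: Union[str, ProteinRecord], include_x: bool = True
) -> CompositionProfile:
    """Residue counts and fractions; cysteine percent on the 0-100 scale.

    ``X`` (unknown residue) is counted under its own key and included in the
    length by default; ``include_x=False`` drops X positions from both counts
    and length, for partial sequences where unknowns should not dilute the
    cysteine percentage.
    """
    if isinstance(seq, ProteinRecord):
        seq = seq.seq
    if not seq:
        raise ValueError("empty sequence")
    if not include_x:
        seq = seq.replace("X", "")
        if not seq:
            raise ValueError("sequence contains only X residues")
    counts = Counter(seq)
    length = len(seq)
    fractions = {aa: c / length for aa, c in counts.items()}
    cys_percent = 100.0 * counts.get("C", 0) / length
    return CompositionProfile(
        counts=dict(counts),
        fractions=fractions,
        length=length,
        cys_percent=cys_percent,
        cys_percent_rounded=_round_half_away(cys_percent),
    )


def crosslink_profile(
    seq: Union[str, ProteinRecord], include_x: bool = True
) -> dict:
    """Fractions of the cross-linking-relevant residues C, K, Q, P, S."""
    prof = residue_profile(seq, include_x=include_x)
    return {aa: prof.fractions.get(aa, 0.0) for aa in CROSSLINK_RESIDUES}


def cc_periodicity(
    seq: Union[str, ProteinRecord], band: tuple[int, int] = CC_BAND
) -> CCPeriodicity:
    """Locate CC-dipeptide sites and their start-to-start spacings.

    A site is the start index of each maximal run of two or more consecutive
    cysteines (a run ``CCC...`` is a single site at its start).  The in-band
    fraction is the share of spacings inside the closed band, 0.0 when there
    are fewer than two sites.
    """
    if isinstance(seq, ProteinRecord):
        seq = seq.seq
    if not seq:
        raise ValueError("empty sequence")
    sites = [m.start() for m in re.finditer(r"C{2,}", seq)]
    spacings = [b - a for a, b in zip(sites, sites[1:])]
    if spacings:
        lo, hi = band
        in_band = sum(1 for d in spacings if lo <= d <= hi) / len(spacings)
    else:
        in_band = 0.0
    return CCPeriodicity(sites=sites, spacings=spacings, in_band_fraction=in_band)


def composition_row(rec: ProteinRecord, include_x: bool = True) -> dict:
    """One flat summary row per record (TSV-ready)."""
    prof = residue_profile(rec, include_x=include_x)
    per = cc_periodicity(rec)
    spac = sorted(per.spacings)
    median = (
        (spac[len(spac) // 2] + spac[(len(spac) - 1) // 2]) / 2 if spac else float("nan")
    )
    row = {
        "record_id": rec.id,
        "species": rec.species,
        "length": prof.length,
        "cys_percent": round(prof.cys_percent, 1),
        "cys_percent_rounded": prof.cys_percent_rounded,
        "cc_sites": len(per.sites),
        "cc_median_spacing": median,
        "cc_in_band_fraction": round(per.in_band_fraction, 4),
    }
    for aa in CROSSLINK_RESIDUES:
        row[f"pct_{aa}"] = round(100.0 * prof.fractions.get(aa, 0.0), 1)
    return row
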