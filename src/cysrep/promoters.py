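"""Core-promoter element classification: canonical TATA vs TATA-like AATAAAA.

Most avian EDCRP promoters carry the TATA-like heptamer AATAAAA in place of
the canonical TATA box found in other EDC genes (and in the loon and lizard
EDCRP promoters).  Classification is exact-match presence/absence of discrete
elements within an upstream window relative to the TSS, on the given strand
only; no position-weight matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .seqio import DnaRecord

CANONICAL_TATA = ("TATAAA", "TATAAAA")
TATA_LIKE = "AATAAAA"
DEFAULT_WINDOW = (-100, -15)

CLASS_CANONICAL = "canonical_tata"
CLASS_TATA_LIKE = "tata_like"
CLASS_NONE = "none"


@dataclass(frozen=True)
class PromoterAnnotation:
    element_class: str
    motif: Optional[str]
    position: Optional[int]  # motif start relative to TSS; negative = upstream
    window: tuple[int, int]
    approximate: bool = False  # True when scanned without a known TSS


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def _classify_window(
    region: str,
    window: tuple[int, int],
    canonical_motifs: Sequence[str],
    tata_like_motif: str,
    approximate: bool,
) -> PromoterAnnotation:
    # canonical first; among canonical hits prefer the longest motif, then the
    # most-upstream start
    canonical_hits = [
        (off, m) for m in canonical_motifs for off in _find_all(region, m)
    ]
    if canonical_hits:
        off, motif = min(canonical_hits, key=lambda t: (-len(t[1]), t[0]))
        return PromoterAnnotation(
            CLASS_CANONICAL, motif, window[0] + off, window, approximate
        )
    like_hits = _find_all(region, tata_like_motif)
    if like_hits:
        return PromoterAnnotation(
            CLASS_TATA_LIKE, tata_like_motif, window[0] + like_hits[0], window,
            approximate,
        )
    return PromoterAnnotation(CLASS_NONE, None, None, window, approximate)


def scan_promoter(
    rec: DnaRecord,
    window: tuple[int, int] = DEFAULT_WINDOW,
    canonical_motifs: Sequence[str] = CANONICAL_TATA,
    tata_like_motif: str = TATA_LIKE,
    fallback_tail: Optional[int] = None,
) -> PromoterAnnotation:
    """Classify the promoter element in a window upstream of the TSS.

    The window is ``[tss + window[0], tss + window[1])`` on the given strand;
    motif positions are reported relative to the TSS (negative = upstream).
    Canonical motifs take precedence over the TATA-like element.  A missing
    TSS raises ``ValueError`` unless ``fallback_tail`` is given, in which case
    the final ``fallback_tail`` bp are scanned and positions are reported
    relative to the 3' end, flagged approximate.
    """
    if window[0] >= window[1]:
        raise ValueError(f"empty window {window}")
    if rec.tss_index is None:
        if fallback_tail is None:
            raise ValueError(f"record {rec.id!r}: no TSS index and no fallback window")
        tail = rec.seq[-fallback_tail:]
        win = (-len(tail), 0)
        return _classify_window(
            tail, win, canonical_motifs, tata_like_motif, approximate=True
        )
    a = rec.tss_index + window[0]
    b = rec.tss_index + window[1]
    if a < 0 or b > len(rec.seq):
        raise ValueError(
            f"record {rec.id!r}: scan window [{a}, {b}) outside sequence "
            f"[0, {len(rec.seq)})"
        )
    return _classify_window(
        rec.seq[a:b], window, canonical_motifs, tata_like_motif, approximate=False
    )


def promoter_row(rec: DnaRecord, ann: PromoterAnnotation) -> dict:
    """Flat annotation row (TSV-ready)."""
    return {
        "record_id": rec.id,
        "species": rec.species,
        "element_class": ann.element_class,
        "motif": ann.motif or "",
        "position": ann.position if ann.position is not None else "",
        "window_start": ann.window[0],
        "window_end": ann.window[1],
        "approximate": ann.approximate,
    }
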