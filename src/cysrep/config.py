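"""Run configuration: defaults, YAML loading, flag overrides."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import yaml

from . import repeats, genestruct, promoters


@dataclass(frozen=True)
class RunConfig:
    """All tunables of the pipeline, with documented defaults."""

    core: str = repeats.CORE
    max_mismatch: int = repeats.MAX_MISMATCH
    exact_prefix_len: int = repeats.EXACT_PREFIX_LEN
    max_tail: int = repeats.MAX_TAIL
    inventory_rules: tuple = (
        ("KP", "KP"),
        ("K[TS]V", "K(T/S)V"),
        ("[TS]", "(T/S)"),
        ("QSV?", "QS(V)"),
    )
    cc_band: tuple = (8, 11)
    promoter_window: tuple = promoters.DEFAULT_WINDOW
    canonical_motifs: tuple = promoters.CANONICAL_TATA
    tata_like_motif: str = promoters.TATA_LIKE
    kmer_k: int = genestruct.DEFAULT_K
    k_neighbors: int = genestruct.DEFAULT_K_NEIGHBORS
    ms_min: float = genestruct.MS_MIN
    sj_min: float = genestruct.SJ_MIN
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.core:
            raise ValueError("core motif must be non-empty")
        if self.max_mismatch < 0 or self.max_tail < 0:
            raise ValueError("max_mismatch and max_tail must be >= 0")
        if self.exact_prefix_len > len(self.core):
            raise ValueError("exact_prefix_len exceeds core length")
        if self.cc_band[0] > self.cc_band[1]:
            raise ValueError("cc_band must be (low, high)")
        if self.promoter_window[0] >= self.promoter_window[1]:
            raise ValueError("promoter window must be (upstream, downstream)")

    def inventory(self) -> repeats.TypeInventory:
        return repeats.TypeInventory(list(self.inventory_rules))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["inventory_rules"] = [list(r) for r in self.inventory_rules]
        return d

    def with_overrides(self, **kw) -> "RunConfig":
        kw = {k: v for k, v in kw.items() if v is not None}
        return replace(self, **kw)


def load_config(path: Optional[Union[str, Path]] = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides."""
    base: dict = {}
    if path is not None:
        with open(path) as fh:
            base = yaml.safe_load(fh) or {}
        for key in ("inventory_rules", "cc_band", "promoter_window", "canonical_motifs"):
            if key in base:
                val = base[key]
                base[key] = tuple(
                    tuple(v) if isinstance(v, (list, tuple)) else v for v in val
                )
    cfg = RunConfig(**base)
    return cfg.with_overrides(**overrides)
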