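#!/usr/bin/env python
"""Segment the packaged protein panel into repeat architectures.

Decomposes the four printed main repeat-unit strings (the desk-scale worked
example) and the synthetic species stand-ins, then writes the architectures
as JSON and a flat per-unit TSV under results/.
"""

import json
from pathlib import Path

import pandas as pd

from cysrep.fixtures import (
    MAIN_UNIT_CONCAT,
    chicken_like_edcrp,
    falcon_like_edcrp,
    lizard_like_edcrp,
    ostrich_like_edcrp,
)
from cysrep.repeats import decompose
from cysrep.seqio import ProteinRecord

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    panel = [
        ProteinRecord(id="main_unit_concat", seq=MAIN_UNIT_CONCAT),
        chicken_like_edcrp(),
        falcon_like_edcrp(),
        ostrich_like_edcrp(),
        lizard_like_edcrp(),
    ]
    archs, tables = [], []
    for rec in panel:
        arch = decompose(rec)
        archs.append(arch.to_dict())
        tables.append(arch.units_table())
        lengths = [u.length for u in arch.units]
        print(
            f"{rec.id}: {arch.n_repeats} units "
            f"(lengths {min(lengths)}-{max(lengths)}), "
            f"types {dict(arch.type_counts)}, "
            f"alternation {arch.alternation.n_pairs} pairs, "
            f"nterm {len(arch.nterm)} aa, cterm {len(arch.cterm)} aa"
        )
    (RESULTS / "architectures.json").write_text(
        json.dumps(archs, indent=2, sort_keys=True) + "\n"
    )
    pd.concat(tables, ignore_index=True).to_csv(
        RESULTS / "repeat_units.tsv", sep="\t", index=False
    )
    print(f"\nwrote {RESULTS/'architectures.json'} and {RESULTS/'repeat_units.tsv'}")


if __name__ == "__main__":
    main()
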