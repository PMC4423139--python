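#!/usr/bin/env python
"""Homology-vs-convergence verdicts for the packaged gene-model fixtures.

Scores avian EDCRP against mammalian KRTAP (different exon structure,
different locus) and against lizard EDCRP (same structure, same EDWM/LOR
neighborhood); writes results/verdicts.json.
"""

import json
from pathlib import Path

from cysrep.fixtures import (
    avian_edcrp_gene,
    chicken_like_edcrp,
    falcon_like_edcrp,
    human_krtap_gene,
    krtap_like_proteins,
    lizard_edcrp_gene,
    lizard_like_edcrp,
)
from cysrep.genestruct import compare_genes

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    avian_proteins = [chicken_like_edcrp(), falcon_like_edcrp()]
    comparisons = {
        "avian_EDCRP_vs_human_KRTAP": compare_genes(
            avian_edcrp_gene(), avian_proteins,
            human_krtap_gene(), krtap_like_proteins(),
        ),
        "avian_EDCRP_vs_lizard_EDCRP": compare_genes(
            avian_edcrp_gene(), avian_proteins,
            lizard_edcrp_gene(), [lizard_like_edcrp()],
        ),
    }
    payload = {}
    for name, v in comparisons.items():
        payload[name] = {
            "motif_similarity": round(v.motif_similarity, 4),
            "structure_concordant": v.structure_concordant,
            "synteny_jaccard": round(v.synteny_jaccard, 4),
            "verdict": v.verdict,
            "rationale": v.rationale,
        }
        print(f"{name}: {v.verdict}\n  {v.rationale}")
    (RESULTS / "verdicts.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    print(f"\nwrote {RESULTS/'verdicts.json'}")


if __name__ == "__main__":
    main()
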