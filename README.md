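# cysrep

Analysis toolkit for cysteine-rich cornification proteins: the avian
**epidermal differentiation cysteine-rich protein (EDCRP)** found in feathers
and the mammalian **keratin-associated proteins (KRTAPs)** of hair. Both
protein families are built from tandem repeats dominated by cysteine (which
cross-links via disulfide bonds) plus lysine and glutamine (transglutamination
substrates), yet they arose independently — a textbook case of molecular
convergent evolution. `cysrep` makes that characterization executable:

- **Repeat architecture** (`cysrep.repeats`): motif-anchored segmentation of a
  protein into an N-terminal segment, tandem repeat units built on the
  conserved hexapeptide core `CCDPCQ`, and a C-terminal segment. Units are
  typed by their post-core tail — the main types are `CCDPCQKP`,
  `CCDPCQK(T/S)V`, `CCDPCQ(T/S)` and `CCDPCQQS(V)` — and the longest strictly
  alternating two-type run is summarised. Matching is greedy, left to right,
  with an exact CC anchor and at most one mismatch in the rest of the core;
  the decomposition is loss-free (segments concatenate back to the input).
- **Composition & CC periodicity** (`cysrep.composition`): residue fractions
  of the cross-linking residues C/K/Q/P/S, cysteine percent, and the spacing
  of consecutive-cysteine (CC) dipeptide sites, which recur every 8–11
  residues along EDCRP-like proteins.
- **Promoter elements** (`cysrep.promoters`): exact-match classification of a
  window upstream of the TSS (default −100..−15) as canonical TATA
  (`TATAAA`/`TATAAAA`), TATA-like (`AATAAAA`) or none.
- **Gene structure & synteny** (`cysrep.genestruct`): a pure decision function
  combining shared cysteine-rich k-mer similarity, exon-structure concordance
  (two exons with a non-coding first exon, EDCRP-style, vs single-exon,
  KRTAP-style) and a Jaccard index over flanking-gene names into a
  `supports_homology` / `supports_convergence` / `indeterminate` verdict.
- **Synthetic data** (`cysrep.simulate`): seeded generators for EDCRP-like
  proteins (with exact ground-truth architectures), promoters with planted
  elements, and substitution/indel noise — every stage is benchmarkable
  without downloads. Packaged stand-ins live in `cysrep.fixtures` (all
  synthetic; no third-party sequence panels are redistributed).

## Worked example

```python
from cysrep import decompose, residue_profile, cc_periodicity

seq = "CCDPCQKP" + "CCDPCQKTV" + "CCDPCQT" + "CCDPCQQSV"  # the 4 main unit types
arch = decompose(seq)
print(arch.n_repeats, arch.labels, [u.length for u in arch.units])
```

prints

```
4 ['KP', 'K(T/S)V', '(T/S)', 'QS(V)'] [8, 9, 7, 9]
```

i.e. the four main unit types are recovered as four distinct units of 7–9
residues each, the documented length range for EDCRP repeats. On the packaged
chicken-scale stand-in the composition profile reports 140 cysteines in 385
residues (36% rounded), and on the falcon-style stand-in the alternation
summary reports a maximal KP/QS(V) run of 14 pairs:

```python
from cysrep.fixtures import chicken_like_edcrp, falcon_like_edcrp
p = residue_profile(chicken_like_edcrp())
print(p.counts["C"], p.length, p.cys_percent_rounded)   # 140 385 36
print(decompose(falcon_like_edcrp()).alternation.n_pairs)  # 14
```

## Analysis scripts

The `analysis/` directory holds numbered narrative drivers that exercise the
library end to end and write tables under `results/`:

1. `01_segment_repeat_units.py` — repeat architectures of the packaged panel
2. `02_composition_periodicity.py` — composition and CC-spacing table
3. `03_promoter_elements.py` — promoter panel + 300-promoter confusion matrix
4. `04_gene_structure_verdicts.py` — homology/convergence verdicts
5. `05_noise_recovery_benchmark.py` — boundary recovery vs substitution rate

A `cysrep` CLI (`scan`, `promoter`, `compare`, `simulate`, `benchmark`) wraps
the same functions for shell use; see `cysrep --help`.

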