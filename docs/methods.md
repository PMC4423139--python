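# Methods

## The model

EDCRP-like proteins are treated as a three-part architecture: an N-terminal
segment (8–20 residues in complete avian sequences), a central region of 6–56
tandem repeat units, and a C-terminal segment (52–75 residues). Each repeat
unit is the conserved core hexapeptide `CCDPCQ` followed by a short tail of
0–4 residues; tails define the unit type. The biological readouts the package
computes — cysteine content near 29–38%, CC-dipeptide sites spaced 8–11
residues apart, lysine/glutamine abundance — are the properties that make
these proteins competent cross-linking substrates during cornification
(disulfide bonding via C, transglutamination via K/Q).

## Repeat decomposition

**Core matching.** A window matches the core when its first
`exact_prefix_len` (default 2) residues equal the core prefix exactly and the
remaining positions differ in at most `max_mismatch` (default 1) places; `X`
(unknown residue) counts as a mismatch anywhere. The CC anchor is exact by
design: the consecutive cysteines are the invariant feature of the repeat,
and requiring them prevents spurious matches inside cysteine-rich terminal
segments. The scan is greedy left-to-right and accepted matches never overlap
(the scan resumes at the match end). Because every candidate unit can be as
short as the 6-residue core, greedy leftmost acceptance maximises the number
of non-overlapping units; the test suite checks this against an exhaustive
dynamic program on short sequences.

**Segmentation.** Between consecutive cores separated by gap *g*: if
*g* ≤ 6 + `max_tail` (default tail cap 4), the unit spans the whole gap; if
*g* is larger, the unit is truncated at core + `max_tail` and the surplus is
recorded explicitly as a linker rather than silently absorbed. The final
unit's tail is the longest stretch of ≤ `max_tail` residues after its core
that matches an inventory pattern; unmatched residues become the C-terminus.
These rules make the decomposition loss-free — N-terminus, units, linkers and
C-terminus concatenate back to the input exactly — which is asserted as a
property test on every input.

**Typing.** The tail inventory is an ordered rule list with first-match-wins
semantics: `KP`, `K[TS]V`, `[TS]`, `QSV?` (labels `KP`, `K(T/S)V`, `(T/S)`,
`QS(V)`), with empty tails labelled `CORE_ONLY` and anything else `OTHER`.
Treating T/S as one type and the trailing V as optional follows the field's
own notation and affects the per-species type count (2–4 types); the
inventory is a configuration value for users who want finer classes. Both the
raw core count (`n_cores`) and the typed unit count (`n_repeats`) are
reported; with greedy non-overlapping matching they coincide, but both names
are kept because the two notions are conceptually distinct.

**Alternation.** The summary finds the longest contiguous run of units whose
labels strictly alternate between exactly two types (ties broken by earliest
start) and reports `floor(run_length / 2)` pairs, so a perfect A,B,…
alternation of 28 units reads as "alternates 14 times". Verified against an
exhaustive substring oracle.

## Composition and CC periodicity

Cysteine percent is reported on the 0–100 scale with one decimal and a
round-half-away-from-zero integer, so published integer percentages are
directly comparable. `X` positions are included in the length by default; a
flag excludes them for partial sequences (published percentages for partial
sequences may have been computed either way; including `X` is the
conservative default and the flag documents the alternative). A run of three
or more cysteines counts as a single CC site anchored at its start — run-start
anchoring makes spacings well-defined where the underlying convention is
ambiguous. With fewer than two sites the in-band fraction is defined as 0.

## Promoter classification

Classification is exact-match presence/absence of discrete elements, not a
position-weight matrix, because the underlying argument is about the presence
of a TATA-like element replacing a canonical TATA box, not about binding
scores. The default window −100..−15 relative to the TSS brackets the typical
core-promoter TATA position (≈ −30) generously, since no exact window is
canonical; it is a configuration value. Canonical motifs (`TATAAA`,
`TATAAAA`) take precedence over the TATA-like `AATAAAA`, preferring the
longest motif and then the most-upstream start; a planted `TATAAA` followed
by an A is therefore reported as the heptamer at the same position, leaving
class and position unchanged. Only the given strand is scanned. Without a
TSS, an optional fallback scans the final N bp and flags results approximate.

## Gene-structure comparison

The homology-vs-convergence verdict operationalises a qualitative argument;
the thresholds are package defaults, not published values. Sequence-level
similarity is the Jaccard index of the two families' k-mer vocabularies
(k = 5) restricted to k-mers with ≥ 2 cysteines — the shared signal between
EDCRP-like and KRTAP-like repeats is carried by CC-bearing motifs, and the
restriction keeps low-complexity background from dominating. Synteny is the
Jaccard index over up to `k_neighbors` (default 3) flanking gene names from
each end of the recorded neighbor list, compared case-insensitively; two
genes with no recorded neighbors compare as identical. With
`ms_min = 0.05` and `sj_min = 0.34` (one shared neighbor out of three):
similar sequences + concordant exon structure + shared neighborhood →
`supports_homology`; similar sequences + discordant structure + disjoint
neighborhood → `supports_convergence`; anything else — including the
genuinely open case of similar sequences with concordant structure but
ambiguous synteny — is `indeterminate`. The verdict is a pure, symmetric
function of its scores.

## Synthetic data

The generator emits the documented regime by construction: unit strings must
start with the core and be 7–10 residues, unit counts lie in [6, 56], termini
in [8, 20] and [52, 75] residues. Terminal segments place an exact rounded
count of cysteines (default fraction 0.25, remainder drawn uniformly from
K,Q,P,S,V,D,G,L) at random positions: fixing the composition rather than
sampling it keeps the simulated cysteine percentage deterministic for a given
plan, and plans built from the four main unit types land in the 29–38% band
(the generator warns when a custom plan leaves it). Termini are
rejection-resampled (bounded retries) until the zero-noise sequence
decomposes exactly into the planned architecture — i.e. the random termini
neither contain spurious cores nor extend the last unit's tail — which is
what makes the exact round-trip guarantee (decompose ∘ generate = truth at
zero noise) hold for every seed rather than merely with high probability.
Noise is applied after the truth is recorded: independent per-position
substitutions to a uniformly chosen different residue, and single-residue
insertions/deletions at half the indel rate each.

Promoter backgrounds are uniform over A,C,G,T and rejection-filtered so the
scan window contains no motif instance other than the planted one; the TSS
sits 50 bp before the 3' end of a 200 bp sequence.

**What the generator does not emulate:** conserved terminal sequence motifs
(termini are random-composition by default; a fixed-template option exists),
lineage structure across species, nucleotide-level repeat expansion
mechanisms such as unequal crossing-over, and alignment artifacts. Passing
recovery tests therefore demonstrates correctness of the segmentation logic
under the documented composition regime, not performance on real,
evolutionarily divergent sequence panels.

## Benchmarks and problem sizes

Boundary recovery is measured on boundary *positions* (the union of unit
start and end coordinates; adjacent units share one) rather than on whole
(start, end) unit tuples: a single substitution that destroys a core's CC
anchor then costs one boundary position instead of also charging the
truncated previous unit twice. The packaged benchmark uses 20-unit proteins,
100 seeded replicates per substitution rate; at 2% substitution the mean
recovery is ≈ 0.96, degrading smoothly to ≈ 0.76 at 10%. Recovery is only
computed for substitution-only noise, where true and recovered coordinates
share a frame. Property tests use 1,000 reconstruction inputs, 50 sequences
≤ 60 residues for the greedy-vs-DP check, 200 label lists for the alternation
oracle, and 300 planted promoters (100 per class) — sizes chosen so the whole
suite runs in well under a minute on one CPU while keeping each check
statistically meaningful.

## Known limitations

- The segmentation conventions at unit boundaries (last-unit tail rule,
  linker truncation) are the package's own; other reasonable conventions
  shift boundary placement by a residue or two in irregular regions.
- Gene-name synteny uses exact string matching; cross-species comparisons
  require pre-harmonised gene names.
- The verdict thresholds encode a qualitative argument and should be
  re-examined before applying the decision rule to other gene families.
- Indel noise shifts coordinates, so recovery under indels can only be
  assessed via alignment-free summaries (unit counts, type inventories), not
  the boundary metric.
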