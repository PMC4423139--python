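"""Gene-structure and synteny comparison: homology vs convergent evolution.

Avian and lizard EDCRP genes share a two-exon structure (non-coding exon 1,
coding exon 2) and sit at the same position in the epidermal differentiation
complex, between EDWM and the loricrin genes.  Mammalian KRTAP genes are
single-exon and cluster next to type-1 keratin genes instead.  This module
turns that qualitative argument into a pure decision function over three
scores: shared cysteine-rich k-mer similarity between the protein families,
exon-structure concordance, and a Jaccard index over flanking-gene names.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

from .seqio import ProteinRecord

DEFAULT_K = 5
MIN_CYS_IN_KMER = 2
DEFAULT_K_NEIGHBORS = 3

MS_MIN = 0.05
SJ_MIN = 0.34

VERDICT_HOMOLOGY = "supports_homology"
VERDICT_CONVERGENCE = "supports_convergence"
VERDICT_INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class GeneModel:
    """A curated gene record: exon intervals, coding exons, neighborhood.

    ``neighbors`` is the ordered list of flanking gene names by genomic
    position, with the gene itself excluded (implied mid-list).
    """

    gene_id: str
    species: str
    exons: tuple
    coding_exon_indices: tuple
    locus_label: str
    neighbors: tuple
    strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        object.__setattr__(
            self, "coding_exon_indices", tuple(self.coding_exon_indices)
        )
        object.__setattr__(self, "neighbors", tuple(self.neighbors))
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon interval [{s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e
        for i in self.coding_exon_indices:
            if not (0 <= i < len(self.exons)):
                raise ValueError(f"{self.gene_id}: coding exon index {i} out of range")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class StructureSignature:
    n_exons: int
    n_coding_exons: int
    has_noncoding_first_exon: bool


@dataclass(frozen=True)
class ConvergenceVerdict:
    motif_similarity: float
    structure_concordant: bool
    synteny_jaccard: float
    verdict: str
    rationale: str


def structure_signature(g: GeneModel) -> StructureSignature:
    """Exon-count signature of a gene model."""
    return StructureSignature(
        n_exons=len(g.exons),
        n_coding_exons=len(g.coding_exon_indices),
        has_noncoding_first_exon=0 not in g.coding_exon_indices,
    )


def _neighbor_set(g: GeneModel, k: int) -> set:
    names = list(g.neighbors)
    if len(names) > 2 * k:
        names = names[:k] + names[-k:]
    return {n.lower() for n in names}


def synteny_jaccard(
    g1: GeneModel, g2: GeneModel, k_neighbors: int = DEFAULT_K_NEIGHBORS
) -> float:
    """Jaccard index of up to ``k_neighbors`` flanking gene names per side.

    Names are compared case-insensitively and exactly (no ortholog mapping).
    Two genes with no recorded neighbors compare as identical (1.0).
    """
    a = _neighbor_set(g1, k_neighbors)
    b = _neighbor_set(g2, k_neighbors)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def _cys_kmers(records: Sequence[ProteinRecord], k: int) -> set:
    kmers: set = set()
    n_used = 0
    for rec in records:
        if len(rec.seq) < k:
            warnings.warn(f"record {rec.id!r}: shorter than k={k}, skipped")
            continue
        n_used += 1
        for i in range(len(rec.seq) - k + 1):
            km = rec.seq[i : i + k]
            if km.count("C") >= MIN_CYS_IN_KMER:
                kmers.add(km)
    if n_used == 0:
        raise ValueError(f"all sequences shorter than k={k}")
    return kmers


def motif_similarity(
    set1: Sequence[ProteinRecord], set2: Sequence[ProteinRecord], k: int = DEFAULT_K
) -> float:
    """Jaccard of cysteine-rich k-mer vocabularies of two protein families.

    Only k-mers containing at least two cysteines enter the sets — the shared
    signal between EDCRP-like and KRTAP-like repeats is carried by CC-bearing
    motifs, while low-complexity background is ignored.  If neither family
    contributes any such k-mer the similarity is 0.0 (no shared signal).
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    if not set1 or not set2:
        raise ValueError("both protein sets must be non-empty")
    a = _cys_kmers(set1, k)
    b = _cys_kmers(set2, k)
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def convergence_verdict(
    ms: float,
    s1: StructureSignature,
    s2: StructureSignature,
    sj: float,
    ms_min: float = MS_MIN,
    sj_min: float = SJ_MIN,
) -> ConvergenceVerdict:
    """Decide homology vs convergence from the three scores (pure function).

    Sequence similarity above ``ms_min`` is a precondition for either call;
    concordant exon structure plus shared synteny supports homology, while
    discordant structure plus absent synteny supports convergent evolution.
    Mixed evidence is indeterminate.
    """
    if not (0.0 <= ms <= 1.0 and 0.0 <= sj <= 1.0):
        raise ValueError("scores must lie in [0, 1]")
    concordant = s1 == s2
    fired = [
        f"motif_similarity={ms:.3f} ({'>=' if ms >= ms_min else '<'} {ms_min})",
        f"structure_{'concordant' if concordant else 'discordant'} "
        f"({s1.n_exons} vs {s2.n_exons} exons)",
        f"synteny_jaccard={sj:.3f} ({'>=' if sj >= sj_min else '<'} {sj_min})",
    ]
    if ms >= ms_min and concordant and sj >= sj_min:
        verdict = VERDICT_HOMOLOGY
    elif ms >= ms_min and not concordant and sj < sj_min:
        verdict = VERDICT_CONVERGENCE
    else:
        verdict = VERDICT_INDETERMINATE
    return ConvergenceVerdict(
        motif_similarity=ms,
        structure_concordant=concordant,
        synteny_jaccard=sj,
        verdict=verdict,
        rationale="; ".join(fired),
    )


def compare_genes(
    g1: GeneModel,
    proteins1: Sequence[ProteinRecord],
    g2: GeneModel,
    proteins2: Sequence[ProteinRecord],
    k: int = DEFAULT_K,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    ms_min: float = MS_MIN,
    sj_min: float = SJ_MIN,
) -> ConvergenceVerdict:
    """End-to-end comparison of two gene families (scores + verdict)."""
    ms = motif_similarity(proteins1, proteins2, k=k)
    sj = synteny_jaccard(g1, g2, k_neighbors=k_neighbors)
    return convergence_verdict(
        ms, structure_signature(g1), structure_signature(g2), sj,
        ms_min=ms_min, sj_min=sj_min,
    )


# ---------------------------------------------------------------------------
# gene-model I/O


def gene_model_to_dict(g: GeneModel) -> dict:
    return {
        "gene_id": g.gene_id,
        "species": g.species,
        "exons": [list(e) for e in g.exons],
        "coding_exon_indices": list(g.coding_exon_indices),
        "locus_label": g.locus_label,
        "neighbors": list(g.neighbors),
        "strand": g.strand,
    }


def gene_model_from_dict(d: dict) -> GeneModel:
    required = (
        "gene_id", "species", "exons", "coding_exon_indices",
        "locus_label", "neighbors",
    )
    for key in required:
        if key not in d:
            raise ValueError(f"gene model record missing field {key!r}")
    return GeneModel(
        gene_id=d["gene_id"],
        species=d["species"],
        exons=tuple(tuple(e) for e in d["exons"]),
        coding_exon_indices=tuple(d["coding_exon_indices"]),
        locus_label=d["locus_label"],
        neighbors=tuple(d["neighbors"]),
        strand=d.get("strand", "+"),
    )


def read_gene_models_json(path: Union[str, Path]) -> list[GeneModel]:
    """Read gene models from a JSON file holding one object or a list."""
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        data = [data]
    return [gene_model_from_dict(d) for d in data]


def write_gene_models_json(models: Sequence[GeneModel], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump([gene_model_to_dict(g) for g in models], fh, indent=2)
        fh.write("\n")


def read_gene_models_gff3(path: Union[str, Path]) -> list[GeneModel]:
    """Minimal GFF3 convenience reader (gene/exon/CDS features).

    Exons and coding status come from exon and CDS features under each gene;
    neighbors are the other genes on the same landmark ordered by start, and
    the landmark name is used as the locus label.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = sorted(db.features_of_type("gene"), key=lambda f: (f.seqid, f.start))
    by_seqid: dict[str, list] = {}
    for g in genes:
        by_seqid.setdefault(g.seqid, []).append(g)
    models = []
    for g in genes:
        exons = sorted(
            ((f.start - 1, f.end) for f in db.children(g, featuretype="exon")),
        )
        cds = sorted(
            ((f.start - 1, f.end) for f in db.children(g, featuretype="CDS")),
        )
        coding = tuple(
            i for i, (s, e) in enumerate(exons)
            if any(cs < e and s < ce for cs, ce in cds)
        )
        neighbors = tuple(
            other.id for other in by_seqid[g.seqid] if other.id != g.id
        )
        models.append(
            GeneModel(
                gene_id=g.id,
                species=g.attributes.get("species", [""])[0],
                exons=tuple(exons),
                coding_exon_indices=coding,
                locus_label=g.seqid,
                neighbors=neighbors,
                strand=g.strand if g.strand in "+-" else "+",
            )
        )
    return models
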