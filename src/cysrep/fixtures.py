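"""Packaged synthetic fixtures: stand-in proteins, gene models, promoters.

Real EDCRP/KRTAP sequence panels are not redistributed with the package, so
every fixture here is synthetic: hand-designed or generator-emitted sequences
that reproduce the documented *quantitative regime* of the real molecules
(segment lengths, repeat counts, cysteine content, alternation patterns,
gene structure and neighborhoods) without being the real sequences.
"""

from __future__ import annotations

from .genestruct import GeneModel
from .repeats import CORE
from .seqio import ProteinRecord
from .simulate import MAIN_UNITS, RepeatPlan, generate_edcrp_like

#: the four main repeat-unit strings as (label, unit) pairs
MAIN_REPEAT_UNITS = MAIN_UNITS

#: their concatenation — the desk-scale worked example for segmentation
MAIN_UNIT_CONCAT = "".join(u for _, u in MAIN_UNITS)


def chicken_like_edcrp() -> ProteinRecord:
    """Synthetic stand-in matching chicken EDCRP's documented composition.

    Hand-designed, not the real sequence: 385 residues of which 140 are
    cysteine (36% rounded), organised as a 15-residue N-terminal segment,
    38 repeat units (29 KP-type of 8 residues, 9 (T/S)-type of 7) and a
    75-residue C-terminal segment with periodic CC sites.
    """
    nterm = "MSCYQKCQPKSCFQC"  # 15 residues, 4 C, no CC dipeptide
    kp, ts = "CCDPCQKP", "CCDPCQT"
    units = (3 * kp + ts) * 9 + 2 * kp  # 29 KP + 9 (T/S) = 38 units, 295 aa, 114 C
    cterm = "CCYGKQS" * 10 + "CCYGK"  # 75 residues, 22 C, CC every 7
    seq = nterm + units + cterm
    assert len(seq) == 385 and seq.count("C") == 140
    return ProteinRecord(id="synthetic_chicken_edcrp", seq=seq,
                         species="synthetic (chicken-like)")


def falcon_like_edcrp() -> ProteinRecord:
    """Synthetic stand-in for the saker falcon pattern: KP and QSV units
    alternating 14 times (28 units), Neognathae-band cysteine content."""
    plan = RepeatPlan.alternating(MAIN_UNITS[0], MAIN_UNITS[3], n_pairs=14)
    rec, _ = generate_edcrp_like(
        seed=20150507, plan=plan, nterm_len=12, cterm_len=60,
        record_id="synthetic_falcon_edcrp", species="synthetic (falcon-like)",
    )
    return rec


def ostrich_like_edcrp() -> ProteinRecord:
    """Synthetic stand-in in the Palaeognathae cysteine band (29-31%):
    20 K(T/S)V-type units with lower-cysteine terminal segments."""
    plan = RepeatPlan.random_mix([MAIN_UNITS[1]], n_units=20)
    rec, _ = generate_edcrp_like(
        seed=20150508, plan=plan, nterm_len=20, cterm_len=75,
        terminal_cys_fraction=0.22,
        record_id="synthetic_ostrich_edcrp", species="synthetic (ostrich-like)",
    )
    return rec


def lizard_like_edcrp() -> ProteinRecord:
    """Synthetic stand-in for lizard EDCRP: same repeat vocabulary as the
    avian stand-ins (the two proteins are candidates for orthology)."""
    plan = RepeatPlan.random_mix(list(MAIN_UNITS), n_units=16)
    rec, _ = generate_edcrp_like(
        seed=20150509, plan=plan, nterm_len=14, cterm_len=55,
        record_id="synthetic_lizard_edcrp", species="synthetic (lizard-like)",
    )
    return rec


def krtap_like_proteins() -> list[ProteinRecord]:
    """Synthetic stand-ins for cysteine-rich human KRTAPs.

    Built from KRTAP-style CCQ(P/T)S repeats around a two-unit EDCRP-type
    stretch (KP unit + QSV unit), mimicking the similar-but-distinct repeat
    vocabularies of the two families: their cysteine-rich k-mer sets overlap
    over the shared stretch but differ elsewhere.
    """
    krtap_unit = "CCQPSCCQTS"
    shared = CORE + "KP" + CORE + "QSV"  # the aligned stretch both families share
    seq1 = "MSYN" + (krtap_unit * 3 + shared) * 2 + krtap_unit * 4 + "CCQSSCCQPS"
    seq2 = "MTCN" + (shared + krtap_unit * 4) * 2 + krtap_unit * 3 + "CCQTTCCQPT"
    return [
        ProteinRecord(id="synthetic_KRTAP_A", seq=seq1, species="synthetic (human-like)"),
        ProteinRecord(id="synthetic_KRTAP_B", seq=seq2, species="synthetic (human-like)"),
    ]


# ---------------------------------------------------------------------------
# gene models mirroring the documented loci


def avian_edcrp_gene() -> GeneModel:
    """Two exons, coding confined to exon 2, in the EDC between EDWM and LOR."""
    return GeneModel(
        gene_id="EDCRP_chicken", species="Gallus gallus",
        exons=((0, 150), (900, 2200)), coding_exon_indices=(1,),
        locus_label="EDC", neighbors=("PGLYRP3", "EDWM", "LOR"), strand="+",
    )


def lizard_edcrp_gene() -> GeneModel:
    """Same structure and neighborhood as the avian gene (orthology candidate)."""
    return GeneModel(
        gene_id="EDCRP_lizard", species="Anolis carolinensis",
        exons=((0, 140), (850, 2100)), coding_exon_indices=(1,),
        locus_label="EDC", neighbors=("PGLYRP3", "EDWM", "LOR"), strand="+",
    )


def human_krtap_gene() -> GeneModel:
    """Single coding exon in a KRTAP cluster next to type-1 keratin genes."""
    return GeneModel(
        gene_id="KRTAP_human", species="Homo sapiens",
        exons=((0, 600),), coding_exon_indices=(0,),
        locus_label="type1_keratin_cluster",
        neighbors=("KRT31", "KRT33A", "KRTAP1-3"), strand="-",
    )
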