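"""FASTA input/output and sequence record types.

Protein records hold the 20 standard amino acids plus ``X`` for residues that
are unknown because of gaps in the underlying genome assemblies; ``X`` never
matches a motif position anywhere downstream.  Aligned records additionally
allow the gap character ``-`` and must degap to a valid protein record.  DNA
records may carry a transcription start site (TSS) index used by the promoter
scanner.  All coordinates in this package are 0-based, half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_ALPHABET = AA20 | {"X"}
DNA_ALPHABET = frozenset("ACGTN")
GAP = "-"


@dataclass(frozen=True)
class ProteinRecord:
    """An ungapped, uppercase protein sequence with identifier and species."""

    id: str
    seq: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal protein character(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignedProteinRecord:
    """One row of a gapped protein alignment; degapping yields a ProteinRecord."""

    id: str
    aligned_seq: str
    species: str = ""

    def __post_init__(self) -> None:
        bad = set(self.aligned_seq) - PROTEIN_ALPHABET - {GAP}
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal aligned-protein character(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.aligned_seq)


@dataclass(frozen=True)
class DnaRecord:
    """A DNA sequence, optionally with a 0-based TSS position within it."""

    id: str
    seq: str
    tss_index: Union[int, None] = None
    species: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal DNA character(s) {sorted(bad)!r}"
            )
        if self.tss_index is not None and not (0 <= self.tss_index < len(self.seq)):
            raise ValueError(
                f"record {self.id!r}: tss_index {self.tss_index} outside "
                f"[0, {len(self.seq)})"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _split_description(rec: SeqRecord) -> tuple[str, str]:
    # FASTA description = "id species words..."; species is free text, may be empty
    desc = rec.description or ""
    if desc.startswith(rec.id):
        species = desc[len(rec.id):].strip()
    else:
        species = ""
    return rec.id, species


def _normalize(raw: str, rec_id: str) -> str:
    seq = raw.upper().replace("\r", "")
    if "*" in seq:
        warnings.warn(f"record {rec_id!r}: stripping '*' stop symbol(s)")
        seq = seq.replace("*", "")
    return seq


def read_fasta(
    path: Union[str, Path], alphabet: str
) -> list[Union[ProteinRecord, AlignedProteinRecord, DnaRecord]]:
    """Read a (multi-)FASTA file into typed records.

    ``alphabet`` is ``"protein"`` or ``"dna"``.  Lowercase input is normalized
    to uppercase, ``*`` stop symbols are stripped with a warning, and protein
    records containing ``-`` are returned as :class:`AlignedProteinRecord`.
    An empty file or illegal characters raise ``ValueError`` naming the record
    and the offending character.
    """
    if alphabet not in ("protein", "dna"):
        raise ValueError(f"alphabet must be 'protein' or 'dna', got {alphabet!r}")
    records: list = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rec_id, species = _split_description(rec)
        seq = _normalize(str(rec.seq), rec_id)
        if alphabet == "dna":
            records.append(DnaRecord(id=rec_id, seq=seq, species=species))
        elif GAP in seq:
            records.append(AlignedProteinRecord(id=rec_id, aligned_seq=seq, species=species))
        else:
            records.append(ProteinRecord(id=rec_id, seq=seq, species=species))
    if not records:
        raise ValueError(f"{path}: empty or non-FASTA file")
    return records


def write_fasta(
    records: Iterable[Union[ProteinRecord, AlignedProteinRecord, DnaRecord]],
    path: Union[str, Path],
) -> None:
    """Write records to FASTA; inverse of :func:`read_fasta` on record lists."""
    seqrecs = []
    for r in records:
        seq = r.aligned_seq if isinstance(r, AlignedProteinRecord) else r.seq
        desc = r.species if r.species else ""
        seqrecs.append(SeqRecord(Seq(seq), id=r.id, description=desc))
    SeqIO.write(seqrecs, str(path), "fasta")


def degap(rec: AlignedProteinRecord) -> ProteinRecord:
    """Remove alignment gaps, preserving id and species.

    Raises ``ValueError`` if the record is all gaps.
    """
    seq = rec.aligned_seq.replace(GAP, "")
    if not seq:
        raise ValueError(f"record {rec.id!r}: degapping left an empty sequence")
    return ProteinRecord(id=rec.id, seq=seq, species=rec.species)


def read_tss_table(path: Union[str, Path]) -> dict[str, int]:
    """Read a two-column TSV (record id, 0-based TSS index) sidecar."""
    table: dict[str, int] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected 'id<TAB>tss_index'")
            table[parts[0]] = int(parts[1])
    return table
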