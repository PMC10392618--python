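"""FASTA input/output for protein records (Biopython-backed)."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import ProteinRecord


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into validated records.

    Sequences are uppercased and whitespace-stripped; entry order is
    preserved. An empty file or a sequence letter outside the canonical
    20-residue alphabet raises ``ValueError`` (naming the position).
    """
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(
                id=rec.id,
                description=rec.description[len(rec.id):].strip()
                if rec.description.startswith(rec.id) else rec.description,
                sequence=str(rec.seq),
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA entries found")
    return records


def write_fasta(
    records: list[ProteinRecord], path: str | Path, width: int = 60
) -> None:
    """Write records as standard FASTA with sequence lines wrapped at *width*."""
    if not records:
        raise ValueError("refusing to write an empty record list")
    if width < 1:
        raise ValueError(f"line width must be positive, got {width}")
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(seq_records)
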