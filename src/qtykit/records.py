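"""Core sequence record type and validation helpers."""

from __future__ import annotations

from dataclasses import dataclass, field

from .tables import CANONICAL_AA


class SequenceAlphabetError(ValueError):
    """A sequence contains a letter outside the 20-residue canonical alphabet."""


def validate_sequence(seq: str, context: str = "sequence") -> str:
    """Uppercase *seq* and reject anything outside the canonical alphabet.

    Ambiguity codes (B/J/O/U/X/Z) and gaps are rejected rather than skipped:
    substitution statistics depend on exact residue counts.
    """
    seq = seq.strip().upper()
    if not seq:
        raise SequenceAlphabetError(f"{context}: empty sequence")
    for i, aa in enumerate(seq, start=1):
        if aa not in CANONICAL_AA:
            raise SequenceAlphabetError(
                f"{context}: illegal residue {aa!r} at position {i}"
            )
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence.

    Attributes
    ----------
    id : str
        Short identifier (FASTA header token).
    accession : str
        Optional database accession (e.g. a UniProt accession).
    description : str
        Free-text description.
    sequence : str
        Canonical 20-letter amino-acid sequence, uppercase.
    """

    id: str
    accession: str = ""
    description: str = ""
    sequence: str = field(default="")

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", validate_sequence(self.sequence, context=self.id or "record")
        )

    def __len__(self) -> int:
        return len(self.sequence)
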