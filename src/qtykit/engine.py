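"""The QTY substitution engine.

Within every transmembrane segment the four hydrophobic residues are
replaced by hydrophilic residues of near-identical side-chain shape:
L -> Q, I -> T, V -> T, F -> Y. Loop residues are untouched. The
replacement swaps lipid-facing aliphatic/aromatic side chains for ones
that hydrogen-bond with water (Q: 4 bonds; T, Y: 3 each), which is what
renders the variant water-soluble while preserving helical geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .records import ProteinRecord
from .tables import HBOND_WATER_CAPACITY, QTY_MAP
from .topology import TMSegment, TMTopology


def round2(x: float) -> float:
    """Round half-up to 2 decimals (the convention of printed percentages)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SubstitutionEvent:
    """One QTY replacement at a transmembrane position (1-based)."""

    position: int
    native_aa: str
    variant_aa: str
    segment_label: str = ""

    def __post_init__(self) -> None:
        if QTY_MAP.get(self.native_aa) != self.variant_aa:
            raise ValueError(
                f"not a QTY substitution: {self.native_aa}->{self.variant_aa} "
                f"at {self.position}"
            )


@dataclass(frozen=True)
class QTYVariant:
    """A native record, its QTY variant sequence and the substitution log."""

    native: ProteinRecord
    variant_sequence: str
    topology: TMTopology
    events: tuple[SubstitutionEvent, ...]
    overall_variation_pct: float
    tm_variation_pct: float

    @property
    def variant_id(self) -> str:
        return f"{self.native.id}_QTY"

    def variant_record(self) -> ProteinRecord:
        desc = (self.native.description + " QTY variant").strip()
        return ProteinRecord(
            id=self.variant_id,
            accession=self.native.accession,
            description=desc,
            sequence=self.variant_sequence,
        )


def apply_qty(
    record: ProteinRecord,
    topology: TMTopology,
    whole_sequence: bool = False,
) -> QTYVariant:
    """Apply the QTY code to *record* within the segments of *topology*.

    Parameters
    ----------
    record, topology
        Sequence and validated TM segment table (1-based inclusive ranges;
        out-of-range segments raise).
    whole_sequence
        Off by default. When True the code is applied at every position,
        ignoring the topology — an experimentation mode; the standard
        design substitutes only membrane-embedded residues.

    The operation is idempotent: Q, T and Y are outside the substitution
    domain, so re-applying the code changes nothing.
    """
    mask = topology.membership(len(record))
    seq = record.sequence
    out = list(seq)
    events: list[SubstitutionEvent] = []
    for i, aa in enumerate(seq):
        if not (whole_sequence or mask[i]):
            continue
        new = QTY_MAP.get(aa)
        if new is None:
            continue
        out[i] = new
        seg = topology.segment_at(i + 1)
        events.append(
            SubstitutionEvent(
                position=i + 1,
                native_aa=aa,
                variant_aa=new,
                segment_label=seg.label if seg is not None else "",
            )
        )
    n_tm = topology.n_tm_residues()
    overall = 100.0 * len(events) / len(seq)
    tm = 100.0 * len(events) / n_tm if n_tm else 0.0
    return QTYVariant(
        native=record,
        variant_sequence="".join(out),
        topology=topology,
        events=tuple(events),
        overall_variation_pct=round2(overall),
        tm_variation_pct=round2(tm),
    )


def variation_rates(variant: QTYVariant) -> tuple[float, float]:
    """(overall %, TM %) variation rates, rounded half-up to 2 decimals.

    overall = 100 * n_events / sequence length;
    TM      = 100 * n_events / total TM residues.
    """
    n_events = len(variant.events)
    length = len(variant.native)
    n_tm = variant.topology.n_tm_residues()
    if n_tm == 0:
        if n_events:
            raise ValueError(
                f"{n_events} substitution events recorded but topology has "
                "zero TM residues — impossible state"
            )
        return (0.0, 0.0)
    return (round2(100.0 * n_events / length), round2(100.0 * n_events / n_tm))


def hbond_capacity_gain(variant: QTYVariant) -> tuple[list[int], int]:
    """Water hydrogen-bond capacity gained by the substitutions.

    Each event contributes the capacity of its introduced side chain
    (Q: 4, T: 3, Y: 3); the replaced L/I/V/F side chains contribute none.
    Returns (per-event list in event order, total).
    """
    per_event = [HBOND_WATER_CAPACITY[e.variant_aa] for e in variant.events]
    return per_event, sum(per_event)
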