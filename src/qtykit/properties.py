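"""Sequence-level physico-chemical properties: molecular weight,
isoelectric point and hydropathy — the quantities reported alongside
native/QTY sequence pairs.

MW is the Expasy-style average-isotopic chain mass. pI follows the
Bjellqvist model: Henderson-Hasselbalch charges over the termini and the
ionizable side chains (D, E, C, Y, H, K, R), with the zero crossing found
by bisection. Q and T carry no ionizable group, so a QTY variant's pI can
move only through introduced tyrosines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import QTYVariant, round2, variation_rates
from .hydropathy import gravy, hydropathy_profile
from .records import ProteinRecord, validate_sequence
from .tables import PKA_SETS, RESIDUE_MASS_AVG, WATER_MASS_AVG


def molecular_weight(seq: str) -> float:
    """Average-isotopic molecular weight in Daltons, to 2 decimals.

    Sum of average residue masses plus one water for the chain termini.
    """
    seq = validate_sequence(seq)
    return round2(sum(RESIDUE_MASS_AVG[aa] for aa in seq) + WATER_MASS_AVG)


def net_charge(seq: str, pH: float, pka_set: str = "Bjellqvist") -> float:
    """Modelled net charge at *pH*.

    Positive groups (N-terminus, K, R, H) contribute 1/(1+10^(pH-pKa));
    negative groups (C-terminus, D, E, C, Y) contribute -1/(1+10^(pKa-pH)).
    Terminal residues may override the generic terminal pKa (Bjellqvist
    set only). Cysteines are treated as free; no disulfide correction.
    """
    seq = validate_sequence(seq)
    pka = PKA_SETS[pka_set]
    counts: dict[str, int] = {}
    for aa in seq:
        counts[aa] = counts.get(aa, 0) + 1

    charge = 0.0
    nterm_pka = pka["nterm_by_residue"].get(seq[0], pka["positive"]["Nterm"])
    charge += 1.0 / (1.0 + 10.0 ** (pH - nterm_pka))
    cterm_pka = pka["cterm_by_residue"].get(seq[-1], pka["negative"]["Cterm"])
    charge -= 1.0 / (1.0 + 10.0 ** (cterm_pka - pH))

    for aa, pk in pka["positive"].items():
        if aa != "Nterm" and counts.get(aa):
            charge += counts[aa] / (1.0 + 10.0 ** (pH - pk))
    for aa, pk in pka["negative"].items():
        if aa != "Cterm" and counts.get(aa):
            charge -= counts[aa] / (1.0 + 10.0 ** (pk - pH))
    return charge


def isoelectric_point(
    seq: str,
    pka_set: str = "Bjellqvist",
    tol_charge: float = 0.0,
    tol_ph: float = 1e-4,
) -> float:
    """pH at which the modelled net charge crosses zero, by bisection.

    The charge model is monotone decreasing in pH, so bisection on [0, 14]
    converges; iteration stops when the bracket is narrower than *tol_ph*
    (or, if *tol_charge* is set, as soon as |charge| falls below it —
    note a loose charge tolerance costs pH accuracy where the charge
    curve is flat, so it is off by default).
    """
    lo, hi = 0.0, 14.0
    mid = 7.0
    while hi - lo > tol_ph:
        mid = 0.5 * (lo + hi)
        q = net_charge(seq, mid, pka_set=pka_set)
        if tol_charge and abs(q) < tol_charge:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mid


@dataclass(frozen=True)
class SequenceProperties:
    """Bundle of the per-sequence metrics."""

    length: int
    mw: float
    pi: float
    gravy: float
    profile: np.ndarray

    def __post_init__(self) -> None:
        assert self.mw > 0 and 0.0 < self.pi < 14.0
        assert len(self.profile) >= 0


def sequence_properties(
    seq: str, window: int = 19, pka_set: str = "Bjellqvist"
) -> SequenceProperties:
    seq = validate_sequence(seq)
    profile = (
        hydropathy_profile(seq, window=window)
        if len(seq) >= window
        else np.empty(0)
    )
    return SequenceProperties(
        length=len(seq),
        mw=molecular_weight(seq),
        pi=isoelectric_point(seq, pka_set=pka_set),
        gravy=gravy(seq),
        profile=profile,
    )


def properties_table(variants: list[QTYVariant]) -> pd.DataFrame:
    """Native-vs-variant comparison table, one row per protein.

    Columns: id, length, MW_native, MW_QTY, pI_native, pI_QTY,
    overall_pct, TM_pct.
    """
    rows = []
    for v in variants:
        overall, tm = variation_rates(v)
        rows.append(
            {
                "id": v.native.id,
                "length": len(v.native),
                "MW_native": molecular_weight(v.native.sequence),
                "MW_QTY": molecular_weight(v.variant_sequence),
                "pI_native": round2(isoelectric_point(v.native.sequence)),
                "pI_QTY": round2(isoelectric_point(v.variant_sequence)),
                "overall_pct": overall,
                "TM_pct": tm,
            }
        )
    return pd.DataFrame(rows)
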