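"""Synthetic sequences, topologies and structures for testing.

The generator emulates a 12-transmembrane-helix transporter at the level
of residue composition and helix geometry only: alternating
hydrophobic-biased TM blocks and polar loops, with alpha-carbon traces on
ideal helix geometry. It makes no attempt at a realistic transporter fold
(no inverted-repeat architecture); what it supports is statistical and
geometric testing without any downloads. All randomness flows through an
explicit seed; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import ProteinRecord
from .structure import Atom, Residue, StructureModel
from .topology import TMSegment, TMTopology

#: TM composition with 48% total mass on L/I/V/F, the band in which real
#: transporter TM variation rates fall (~44-50%).
DEFAULT_TM_COMPOSITION: dict[str, float] = {
    "L": 0.16, "I": 0.12, "V": 0.12, "F": 0.08,
    "A": 0.10, "G": 0.07, "S": 0.06, "T": 0.06, "M": 0.05, "W": 0.03,
    "Y": 0.05, "C": 0.02, "P": 0.03, "N": 0.03, "Q": 0.02,
}

#: Polar-biased loop composition (no L/I/V/F).
DEFAULT_LOOP_COMPOSITION: dict[str, float] = {
    "G": 0.08, "S": 0.10, "T": 0.08, "N": 0.10, "Q": 0.08, "D": 0.10,
    "E": 0.10, "K": 0.10, "R": 0.10, "H": 0.04, "P": 0.06, "A": 0.06,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic transporter."""

    n_helices: int = 12
    helix_len: int = 21
    loop_len: int = 10
    tm_composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TM_COMPOSITION)
    )
    loop_composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOOP_COMPOSITION)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_helices < 1 or self.helix_len < 1 or self.loop_len < 0:
            raise ValueError("helix/loop dimensions must be positive")
        for name, comp in (
            ("tm_composition", self.tm_composition),
            ("loop_composition", self.loop_composition),
        ):
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} frequencies sum to {total}, not 1")


def _draw(rng: np.random.Generator, comp: dict[str, float], n: int) -> str:
    letters = sorted(comp)  # sorted for seed-stable ordering
    probs = np.array([comp[c] for c in letters])
    return "".join(rng.choice(list(letters), size=n, p=probs / probs.sum()))


def synthetic_transporter(spec: FixtureSpec) -> tuple[ProteinRecord, TMTopology]:
    """Generate loop-(TM-loop)*n sequence plus its exact topology.

    Length is ``n_helices*helix_len + (n_helices+1)*loop_len``;
    deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    parts = [_draw(rng, spec.loop_composition, spec.loop_len)]
    segments = []
    pos = spec.loop_len
    for k in range(spec.n_helices):
        parts.append(_draw(rng, spec.tm_composition, spec.helix_len))
        segments.append(TMSegment(pos + 1, pos + spec.helix_len, f"TM{k + 1}"))
        pos += spec.helix_len
        parts.append(_draw(rng, spec.loop_composition, spec.loop_len))
        pos += spec.loop_len
    record = ProteinRecord(
        id=f"synthetic_{spec.seed}",
        description=f"synthetic {spec.n_helices}-TM transporter (seed {spec.seed})",
        sequence="".join(parts),
    )
    return record, TMTopology(tuple(segments), source="annotation")


def ideal_helix_coords(sequence: str) -> StructureModel:
    """Alpha-carbon trace of *sequence* on a canonical alpha helix:
    1.5 A rise and 100 degrees rotation per residue, 2.3 A radius."""
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    i = np.arange(n)
    angle = np.deg2rad(100.0) * i
    coords = np.column_stack(
        [2.3 * np.cos(angle), 2.3 * np.sin(angle), 1.5 * i]
    )
    residues = tuple(
        Residue(resnum=k + 1, aa=aa, ca=coords[k])
        for k, aa in enumerate(sequence)
    )
    return StructureModel(id="ideal_helix", chain_id="A", residues=residues)


def perturb_structure(
    model: StructureModel, noise_sd: float, seed: int
) -> StructureModel:
    """Add independent Gaussian displacement (per-axis sd = *noise_sd*)
    to every alpha-carbon; deterministic given *seed*."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=(len(model), 3))
    residues = tuple(
        Residue(r.resnum, r.aa, r.ca + noise[k], r.atoms)
        for k, r in enumerate(model.residues)
    )
    return StructureModel(id=model.id, chain_id=model.chain_id, residues=residues)


def write_fixture_set(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a FASTA + TM-table + PDB fixture bundle under *out_dir*."""
    from .io import write_fasta
    from .structure import write_structure
    from .topology import write_tm_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record, topo = synthetic_transporter(FixtureSpec(seed=seed))
    paths = {
        "fasta": out / "transporter.fasta",
        "tm_table": out / "transporter.tm.tsv",
        "pdb": out / "transporter_ca.pdb",
    }
    write_fasta([record], paths["fasta"])
    write_tm_table({record.id: topo}, paths["tm_table"])
    write_structure(ideal_helix_coords(record.sequence), paths["pdb"])
    return paths
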