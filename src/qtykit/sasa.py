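"""Shrake-Rupley solvent-accessible surface area and the hydrophobic
surface fraction used to quantify surface hydrophobic patches.

Each atom's SASA is estimated by quadrature: a deterministic golden-ratio
spiral point set is placed on the atom's solvent-expanded sphere
(radius + probe) and points occluded by any neighbouring expanded sphere
are removed. The point set is fixed by construction, so results are
bit-stable. Membrane-embedded proteins expose large L/I/V/F patches to
the lipid; the fraction of SASA contributed by that residue set is the
numeric proxy for the hydrophobic patch, and drops after QTY
substitution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import StructureModel
from .tables import (
    CA_COARSE_RADIUS,
    QTY_HYDROPHOBIC_SET,
    VDW_DEFAULT,
    VDW_RADII,
)


def golden_spiral_points(n: int) -> np.ndarray:
    """*n* near-uniform points on the unit sphere via the golden-ratio
    (Fibonacci) spiral; deterministic, no randomness."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i * (1.0 - 1.0 / np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass(frozen=True)
class SASAResult:
    per_atom_sasa: np.ndarray      # (n_atoms,) A^2
    per_residue_sasa: np.ndarray   # (n_residues,) A^2
    total_sasa: float              # A^2
    hydrophobic_sasa: float        # A^2 over the hydrophobic residue set
    hydrophobic_fraction: float    # in [0, 1]
    coarse: bool                   # True when computed on CA beads only


def _atom_arrays(model: StructureModel) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """(coords, radii, residue index per atom, coarse flag)."""
    coords, radii, res_idx = [], [], []
    coarse = model.is_ca_only
    unknown: set[str] = set()
    for ri, res in enumerate(model.residues):
        if coarse:
            coords.append(res.ca)
            radii.append(CA_COARSE_RADIUS)
            res_idx.append(ri)
        else:
            atoms = res.atoms or ()
            for atom in atoms:
                el = atom.element.upper()
                if el not in VDW_RADII:
                    unknown.add(el)
                coords.append(atom.coord)
                radii.append(VDW_RADII.get(el, VDW_DEFAULT))
                res_idx.append(ri)
    if unknown:
        warnings.warn(
            f"unknown elements {sorted(unknown)}; using default radius "
            f"{VDW_DEFAULT} A", stacklevel=3,
        )
    return (
        np.array(coords, dtype=float),
        np.array(radii, dtype=float),
        np.array(res_idx, dtype=int),
        coarse,
    )


def shrake_rupley(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    hydrophobic_set: frozenset[str] | set[str] = QTY_HYDROPHOBIC_SET,
) -> SASAResult:
    """Per-atom, per-residue and total SASA of *model*.

    Full-atom models use the element radius table (C 1.70, N 1.55, O 1.52,
    S 1.80 A; unknown elements 1.70 with a warning). CA-only models fall
    back to one 3.0 A sphere per residue and the result is flagged
    ``coarse``. Neighbour search uses a KD-tree.
    """
    if not model.residues:
        raise ValueError("empty structure")
    coords, radii, res_idx, coarse = _atom_arrays(model)
    n_atoms = len(coords)
    expanded = radii + probe_radius
    sphere = golden_spiral_points(n_points)

    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    per_atom = np.zeros(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + expanded[i] * sphere
        neighbours = [
            j for j in tree.query_ball_point(coords[i], expanded[i] + expanded.max())
            if j != i
            and np.dot(coords[j] - coords[i], coords[j] - coords[i])
            < (expanded[i] + expanded[j]) ** 2
        ]
        if neighbours:
            nb_coords = coords[neighbours]          # (m, 3)
            nb_r2 = expanded[neighbours] ** 2       # (m,)
            d2 = ((pts[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=2)
            accessible = (d2 >= nb_r2[None, :]).all(axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * expanded[i] ** 2

    n_res = len(model.residues)
    per_residue = np.zeros(n_res)
    np.add.at(per_residue, res_idx, per_atom)
    total = float(per_atom.sum())
    if total <= 0:
        raise ValueError("zero total SASA")
    hydro = float(
        sum(
            per_residue[ri]
            for ri, res in enumerate(model.residues)
            if res.aa in hydrophobic_set
        )
    )
    return SASAResult(
        per_atom_sasa=per_atom,
        per_residue_sasa=per_residue,
        total_sasa=total,
        hydrophobic_sasa=hydro,
        hydrophobic_fraction=hydro / total,
        coarse=coarse,
    )


def hydrophobic_surface_fraction(
    model: StructureModel,
    sasa: SASAResult | None = None,
    hydrophobic_set: frozenset[str] | set[str] = QTY_HYDROPHOBIC_SET,
    **kwargs,
) -> float:
    """Fraction of total SASA contributed by residues in *hydrophobic_set*.

    The default set is exactly {L, I, V, F} — the residues the QTY code
    replaces — so the metric measures directly what QTY changes.
    """
    if sasa is None:
        sasa = shrake_rupley(model, hydrophobic_set=hydrophobic_set, **kwargs)
    if sasa.total_sasa <= 0:
        raise ValueError("zero total SASA")
    hydro = float(
        sum(
            sasa.per_residue_sasa[ri]
            for ri, res in enumerate(model.residues)
            if res.aa in hydrophobic_set
        )
    )
    return hydro / sasa.total_sasa
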