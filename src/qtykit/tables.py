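"""Physico-chemical constant tables shared across the package.

All tables are keyed by the 20 canonical one-letter amino-acid codes.
Sources are classical reference data: Kyte & Doolittle (1982) hydropathy,
Expasy-style average residue masses, and the Bjellqvist pKa set used by
the Expasy pI service (as also implemented in Biopython).
"""

from __future__ import annotations

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Kyte-Doolittle hydropathy index (dimensionless).
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Average (isotope-abundance weighted) residue masses in Daltons,
#: i.e. amino-acid mass minus one water; add WATER_MASS_AVG per chain.
RESIDUE_MASS_AVG: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MASS_AVG: float = 18.0153

#: The QTY substitution code: hydrophobic residue -> hydrophilic stand-in
#: with a near-identical side-chain shape.
QTY_MAP: dict[str, str] = {"L": "Q", "I": "T", "V": "T", "F": "Y"}

#: Water hydrogen bonds each introduced side chain can form:
#: Q amide = 2 donors + 2 acceptors; T/Y hydroxyl = 1 donor + 2 acceptors.
#: The replaced aliphatic/aromatic side chains (L,I,V,F) form none.
HBOND_WATER_CAPACITY: dict[str, int] = {"Q": 4, "T": 3, "Y": 3}

# --- pKa sets for the isoelectric-point model -------------------------------

#: Bjellqvist et al. (1993/1994) values, identical to Biopython's
#: Bio.SeqUtils.IsoelectricPoint tables (the Expasy lineage).
PKA_BJELLQVIST = {
    "positive": {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98},
    "negative": {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
    # residue-specific terminal overrides
    "nterm_by_residue": {
        "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44,
        "E": 7.7,
    },
    "cterm_by_residue": {"D": 4.55, "E": 4.75},
}

#: Classical EMBOSS values, for sensitivity checks.
PKA_EMBOSS = {
    "positive": {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5},
    "negative": {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
    "nterm_by_residue": {},
    "cterm_by_residue": {},
}

PKA_SETS = {"Bjellqvist": PKA_BJELLQVIST, "EMBOSS": PKA_EMBOSS}

#: Van der Waals radii (A) for SASA; unknown elements fall back to carbon.
VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80,
}
VDW_DEFAULT: float = 1.70

#: Sphere radius (A) used for one-bead-per-residue (CA-only) coarse SASA.
CA_COARSE_RADIUS: float = 3.0

#: The hydrophobic residue set targeted by the QTY code.
QTY_HYDROPHOBIC_SET = frozenset("LIVF")

#: A broader classical hydrophobic class, selectable by flag.
BROAD_HYDROPHOBIC_SET = frozenset("LIVFAMW")
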