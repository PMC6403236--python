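"""Physical constants, atomic masses and van der Waals radii.

Internal units follow the Gromacs convention throughout the package:
lengths in nm, energies in kJ/mol, masses in amu, charges in elementary
charges (e), times in ps.
"""

from __future__ import annotations

#: Coulomb prefactor f = 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
COULOMB_CONSTANT = 138.935458

#: Boltzmann constant in kJ mol^-1 K^-1.
BOLTZMANN_KJ_MOL_K = 0.0083144621

#: Standard atomic masses (amu), keyed by upper-case element symbol.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "NA": 22.990,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,
    "MN": 54.938,
    "FE": 55.845,
    "ZN": 65.38,
    "SE": 78.971,
}

#: Bondi van der Waals radii (nm), keyed by upper-case element symbol.
#: Used by the Shrake-Rupley solvent-accessible-surface computation.
VDW_RADII_NM: dict[str, float] = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "P": 0.180,
    "S": 0.180,
    "F": 0.147,
    "CL": 0.175,
    "BR": 0.185,
    "I": 0.198,
    "NA": 0.227,
    "K": 0.275,
    "MG": 0.173,
    "ZN": 0.139,
    "SE": 0.190,
}

#: Residue names recognised as amino acids (backbone N, CA, C).
PROTEIN_RESNAMES = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
        "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
        "TYR", "VAL", "HID", "HIE", "HIP", "HSD", "HSE", "HSP", "CYX",
        "ASH", "GLH", "LYN",
    }
)

#: Residue names recognised as nucleotides (backbone P, O5', C5', C4', C3', O3').
NUCLEIC_RESNAMES = frozenset(
    {
        "A", "U", "G", "C", "T", "DA", "DT", "DG", "DC",
        "RA", "RU", "RG", "RC", "ADE", "URA", "GUA", "CYT", "THY",
    }
)

#: Atom names that constitute the backbone, per residue class.
PROTEIN_BACKBONE_NAMES = frozenset({"N", "CA", "C"})
NUCLEIC_BACKBONE_NAMES = frozenset({"P", "O5'", "C5'", "C4'", "C3'", "O3'"})
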