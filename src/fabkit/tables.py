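"""Packaged chemical tables: van der Waals radii, hydrogen-bond donor/acceptor
typing, and charged-group definitions for salt bridges.

The tables are deliberately small and conventional.  Radii are Bondi-style
element radii; donors/acceptors cover the 20 standard amino acids at the
heavy-atom level.  All cutoffs that consume these tables are configurable at
the call sites; the tables themselves carry a version tag so reports can
record which convention produced them.
"""

from __future__ import annotations

import warnings

TABLES_VERSION = "fabkit-tables-1"

#: Element -> van der Waals radius in Angstrom (Bondi 1964 values, common picks
#: for elements Bondi does not list).
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "FE": 2.00,
    "ZN": 1.39,
    "MG": 1.73,
    "CA": 2.31,
    "NA": 2.27,
    "K": 2.75,
}

#: Fallback radius for elements missing from the table (a warning is emitted).
DEFAULT_VDW_RADIUS = 1.8


def vdw_radius(element: str, default: float = DEFAULT_VDW_RADIUS) -> float:
    """Look up the van der Waals radius for ``element`` (case-insensitive)."""
    key = element.strip().upper()
    if key in VDW_RADII:
        return VDW_RADII[key]
    warnings.warn(
        f"unknown element {element!r}: using default vdW radius {default} A",
        stacklevel=2,
    )
    return default


# --- hydrogen-bond typing ---------------------------------------------------
# Backbone: amide N donates (except proline), carbonyl O accepts.  Side chains
# follow standard polar-atom assignments.  His N atoms are treated as both
# donor and acceptor (protonation unknown at this level of modelling).

_BACKBONE_DONOR = ("N",)
_BACKBONE_ACCEPTOR = ("O", "OXT")

_SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TRP": ("NE1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
}

_SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASN": ("OD1",),
    "ASP": ("OD1", "OD2"),
    "GLN": ("OE1",),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "MET": ("SD",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
}

STANDARD_AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)


def hbond_donor_atoms(res_name: str) -> tuple[str, ...]:
    """Heavy donor atom names for a residue (empty for unknown residues)."""
    name = res_name.upper()
    if name not in STANDARD_AMINO_ACIDS:
        return ()
    backbone = () if name == "PRO" else _BACKBONE_DONOR
    return backbone + _SIDECHAIN_DONORS.get(name, ())


def hbond_acceptor_atoms(res_name: str) -> tuple[str, ...]:
    """Heavy acceptor atom names for a residue (empty for unknown residues)."""
    name = res_name.upper()
    if name not in STANDARD_AMINO_ACIDS:
        return ()
    return _BACKBONE_ACCEPTOR + _SIDECHAIN_ACCEPTORS.get(name, ())


# --- salt bridges -----------------------------------------------------------

#: residue -> negatively charged (carboxylate) oxygen atoms
NEGATIVE_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

#: residue -> positively charged (basic) nitrogen atoms
POSITIVE_ATOMS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}
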