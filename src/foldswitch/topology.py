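"""Standard amino-acid heavy-atom topology and atom class tables.

Used by the contact-geometry classifier: bonded antecedents define the
angle tests at polar atoms, and an atom is apolar when it is carbon or
sulfur with no nitrogen/oxygen bonded neighbour in the residue topology.
"""

from __future__ import annotations

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

_BACKBONE_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")]

_SIDECHAIN_BONDS = {
    "ALA": [],
    "ARG": [("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "CZ"),
            ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CB", "SG")],
    "GLN": [("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")],
    "GLU": [("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"), ("ND1", "CE1"),
            ("CD2", "NE2"), ("CE1", "NE2")],
    "ILE": [("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")],
    "MET": [("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "PRO": [("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "SER": [("CB", "OG")],
    "THR": [("CB", "OG1"), ("CB", "CG2")],
    "TRP": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "NE1"),
            ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"), ("CE3", "CZ3"),
            ("CZ3", "CH2"), ("CH2", "CZ2"), ("CZ2", "CE2")],
    "TYR": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "OH")],
    "VAL": [("CB", "CG1"), ("CB", "CG2")],
}


def _bond_map() -> dict[str, dict[str, set[str]]]:
    out: dict[str, dict[str, set[str]]] = {}
    for res, sc in _SIDECHAIN_BONDS.items():
        bonds = list(_BACKBONE_BONDS) + sc
        if res != "GLY":
            bonds.append(("CA", "CB"))
        adj: dict[str, set[str]] = {}
        for a, b in bonds:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        out[res] = adj
    return out


#: residue name -> atom name -> bonded heavy-atom neighbours
BONDED = _bond_map()


def bonded_neighbours(res_name: str, atom_name: str) -> set[str]:
    return BONDED.get(res_name, {}).get(atom_name, set())


def element_of(atom_name: str) -> str:
    """Leading element letter of a standard PDB heavy-atom name."""
    return atom_name[0]


def is_apolar(res_name: str, atom_name: str) -> bool:
    """Carbon/sulfur atoms with no N/O bonded neighbour are hydrophobic."""
    if element_of(atom_name) not in ("C", "S"):
        return False
    return not any(element_of(n) in ("N", "O")
                   for n in bonded_neighbours(res_name, atom_name))


def carbon_antecedent(res_name: str, atom_name: str) -> str | None:
    """The bonded carbon from which the angle at a polar atom is measured."""
    carbons = sorted(n for n in bonded_neighbours(res_name, atom_name)
                     if element_of(n) == "C")
    return carbons[0] if carbons else None


# atom-level charge sets for the Coulombic test (histidine counted positive)
POSITIVE_ATOMS = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
                  ("HIS", "ND1"), ("HIS", "NE2")}
NEGATIVE_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


def is_positive(res_name: str, atom_name: str) -> bool:
    return (res_name, atom_name) in POSITIVE_ATOMS


def is_negative(res_name: str, atom_name: str) -> bool:
    return (res_name, atom_name) in NEGATIVE_ATOMS or atom_name == "OXT"


# side-chain atoms able to donate or accept a hydrogen bond (helix caps)
SIDECHAIN_POLAR = {
    ("SER", "OG"), ("THR", "OG1"), ("ASN", "OD1"), ("ASN", "ND2"),
    ("GLN", "OE1"), ("GLN", "NE2"), ("TYR", "OH"), ("TRP", "NE1"),
    ("HIS", "ND1"), ("HIS", "NE2"), ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
}


def is_sidechain_polar(res_name: str, atom_name: str) -> bool:
    return (res_name, atom_name) in SIDECHAIN_POLAR


# one-letter residue classes for MSA column-pair statistics
HYDROPHOBIC_RESIDUES = set("AVLIMFWCY")
CHARGED_RESIDUES = set("DEKRH")
CAP_CAPABLE_RESIDUES = set("STNQDEHKRYW")
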