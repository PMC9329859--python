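"""Per-atom chemistry tables for standard amino acids.

All classifications here are pure functions of ``(residue name, atom name)``
on heavy atoms; hydrogens are never considered.  The donor/acceptor table
follows common heavy-atom hydrogen-bonding chemistry: backbone N donates,
backbone O accepts, hydroxyls (Ser/Thr/Tyr) do both, amides donate from N
and accept on O, His ring nitrogens do both, and the charged groups of
Arg/Lys (donors) and Asp/Glu (acceptors) complete the table.  Cys SG is
excluded by default (O/N-focused criteria).
"""

from __future__ import annotations

from dataclasses import dataclass

#: van der Waals radii by element, Angstrom (Bondi-style values).
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "other": 1.70,
}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

WATER_NAMES = {"HOH", "WAT"}

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

#: Side-chain heavy-atom hydrogen-bond donors per residue type.
SIDECHAIN_DONORS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
}

#: Side-chain heavy-atom hydrogen-bond acceptors per residue type.
SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}

#: Side-chain cationic nitrogens (Arg guanidinium + Lys ammonium only).
CATIONIC_ATOMS: set[tuple[str, str]] = {
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("LYS", "NZ"),
}

#: Side-chain anionic oxygens (Asp/Glu carboxylates only).
ANIONIC_ATOMS: set[tuple[str, str]] = {
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
}

#: Aromatic ring member atoms.  Trp is treated as a single 9-atom ring system.
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


@dataclass(frozen=True)
class ChemistryFlags:
    """Hydrogen-bonding / charge / ring classification of one heavy atom."""

    hbond_donor_heavy: bool = False
    hbond_acceptor_heavy: bool = False
    cationic: bool = False
    anionic: bool = False
    ring_member: bool = False


def chemistry_flags(aa3: str, atom_name: str) -> ChemistryFlags:
    """Classify a heavy atom of a standard amino acid.

    Unknown residue types yield all-false flags (the caller is expected to
    warn).  The classification depends only on ``(aa3, atom_name)``.
    """
    aa3 = aa3.upper()
    name = atom_name.upper()
    if aa3 not in STANDARD_AA:
        return ChemistryFlags()
    donor = name == "N" and aa3 != "PRO"
    acceptor = name in ("O", "OXT")
    donor = donor or name in SIDECHAIN_DONORS.get(aa3, ())
    acceptor = acceptor or name in SIDECHAIN_ACCEPTORS.get(aa3, ())
    return ChemistryFlags(
        hbond_donor_heavy=donor,
        hbond_acceptor_heavy=acceptor,
        cationic=(aa3, name) in CATIONIC_ATOMS,
        anionic=(aa3, name) in ANIONIC_ATOMS,
        ring_member=name in RING_ATOMS.get(aa3, ()),
    )


def element_of(atom_name: str, element_hint: str = "") -> str:
    """Coarse element class {C,N,O,S,other} from a PDB atom name or hint."""
    e = element_hint.strip().upper()
    if not e:
        stripped = atom_name.strip().lstrip("0123456789")
        e = stripped[:1].upper()
    if e in ("C", "N", "O", "S"):
        return e
    return "other"
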