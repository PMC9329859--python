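"""Two-body antibody-antigen structure model parsed from PDB files.

The complex is modelled as two rigid bodies: the antibody (one heavy and one
light chain, Chothia-numbered) and the antigen (every other protein chain the
caller names).  Only heavy atoms of standard amino acids are kept; ions and
small molecules are dropped, crystallographic waters optionally retained as
their oxygen atoms.  Alternate locations are resolved to the highest
occupancy (first wins on ties) and only model 1 is read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .chemistry import (
    BACKBONE_NAMES,
    STANDARD_AA,
    VDW_RADII,
    WATER_NAMES,
    ChemistryFlags,
    chemistry_flags,
    element_of,
)

log = logging.getLogger(__name__)

ROLE_HEAVY = "heavy"
ROLE_LIGHT = "light"
ROLE_ANTIGEN = "antigen"
ROLE_WATER = "water"


class ConfigurationError(ValueError):
    """Chain roles requested by the caller do not match the file."""


class InputError(ValueError):
    """The structure content is unusable (e.g. empty antigen)."""


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of one residue: chain, (number, insertion code), type, role.

    Ordering is lexicographic on (chain, number, insertion code), which is
    how Chothia-numbered residues compare.
    """

    chain_id: str
    number: int
    icode: str
    aa3: str = field(compare=False)
    role: str = field(compare=False)

    def __str__(self) -> str:  # e.g. "H:100A:TYR"
        return f"{self.chain_id}:{self.number}{self.icode.strip()}:{self.aa3}"


@dataclass(eq=False)
class AtomRecord:
    """One heavy atom.  Hashed by identity; unique per parsed structure."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    residue: ResidueKey
    occupancy: float = 1.0
    vdw_radius: float = VDW_RADII["C"]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise InputError(f"non-finite coordinates for atom {self.serial}")
        if self.vdw_radius <= 0:
            raise InputError(f"non-positive vdW radius for atom {self.serial}")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES

    @property
    def is_polar(self) -> bool:
        return self.element in ("N", "O")

    @property
    def is_carbon(self) -> bool:
        return self.element == "C"

    def __repr__(self) -> str:
        return f"<Atom {self.serial} {self.residue}/{self.name}>"


#: Default Chothia CDR intervals (inclusive, by Chothia residue number).
CHOTHIA_CDRS: dict[str, tuple[int, int]] = {
    "H1": (26, 32),
    "H2": (52, 56),
    "H3": (95, 102),
    "L1": (24, 34),
    "L2": (50, 56),
    "L3": (89, 97),
}


@dataclass(frozen=True)
class RegionScheme:
    """CDR interval definitions over Chothia numbers.

    ``cdr_ranges`` maps labels H1..L3 to inclusive number intervals; a
    residue whose base number falls inside an interval belongs to that CDR
    regardless of insertion code.  Everything else on an antibody chain is
    framework.
    """

    cdr_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(CHOTHIA_CDRS)
    )

    def labels_for_chain(self, role: str) -> list[str]:
        prefix = "H" if role == ROLE_HEAVY else "L"
        return [lab for lab in self.cdr_ranges if lab.startswith(prefix)]


DEFAULT_SCHEME = RegionScheme()

CDR_LABELS = ("H1", "H2", "H3", "L1", "L2", "L3")


class LabellingError(ValueError):
    """An antibody residue cannot be mapped to a region."""


def assign_region(residue: ResidueKey, scheme: RegionScheme = DEFAULT_SCHEME) -> str:
    """Region label for a residue: one of H1..L3, FwH, FwL or ``antigen``.

    Insertion-coded residues inherit the interval of their base number
    (Chothia H 100A sits inside H3 when 100 does).
    """
    if residue.role in (ROLE_ANTIGEN, ROLE_WATER):
        return "antigen"
    if residue.number is None:
        raise LabellingError(f"antibody residue without number: {residue}")
    for label in scheme.labels_for_chain(residue.role):
        lo, hi = scheme.cdr_ranges[label]
        if lo <= residue.number <= hi:
            return label
    return "FwH" if residue.role == ROLE_HEAVY else "FwL"


def classify_chemistry(atom: AtomRecord) -> ChemistryFlags:
    """Hydrogen-bond/charge/ring flags for a parsed atom.

    A pure function of ``(aa3, atom name)``; unknown residue types produce
    no flags and a logged warning.
    """
    if atom.residue.aa3 not in STANDARD_AA and atom.residue.aa3 not in WATER_NAMES:
        log.warning("unknown residue type %s: no chemistry flags", atom.residue.aa3)
    return chemistry_flags(atom.residue.aa3, atom.name)


@dataclass
class ComplexStructure:
    """An antibody-antigen complex as parsed atom lists with chain roles."""

    atoms: list[AtomRecord]
    heavy_chain: str
    light_chain: str
    ag_chains: frozenset[str]
    waters: list[AtomRecord] = field(default_factory=list)
    resolution: float | None = None
    name: str = ""

    @property
    def ab_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.residue.role in (ROLE_HEAVY, ROLE_LIGHT)]

    @property
    def ag_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.residue.role == ROLE_ANTIGEN]

    def residues(self, role: str | None = None) -> list[ResidueKey]:
        seen: dict[ResidueKey, None] = {}
        for a in self.atoms:
            if role is None or a.residue.role == role:
                seen.setdefault(a.residue)
        return list(seen)

    def atoms_of(self, residues: set[ResidueKey]) -> list[AtomRecord]:
        return [a for a in self.atoms if a.residue in residues]


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Pick one location per atom name: highest occupancy, first wins ties."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = chosen.get(atom.name)
        if prev is None or atom.occ > prev.occ + 1e-9:
            chosen[atom.name] = atom
    return list(chosen.values())


def read_complex(
    pdb_path,
    ab_chain_ids: tuple[str, str],
    ag_chain_ids,
    keep_waters: bool = False,
    vdw_radii: dict[str, float] | None = None,
) -> ComplexStructure:
    """Parse a PDB file into a two-body complex model.

    Parameters
    ----------
    pdb_path:
        PDB-format file with ATOM/HETATM records.
    ab_chain_ids:
        ``(heavy, light)`` chain identifiers.
    ag_chain_ids:
        Iterable of antigen chain identifiers.
    keep_waters:
        Retain crystallographic water oxygens (any chain, resname HOH/WAT).
    vdw_radii:
        Optional override of the per-element radius table.

    Hydrogens, ions and small molecules are discarded; only model 1 is used.
    """
    radii = dict(VDW_RADII)
    if vdw_radii:
        radii.update(vdw_radii)
    heavy_id, light_id = ab_chain_ids
    ag_ids = frozenset(ag_chain_ids)

    st = gemmi.read_pdb(str(pdb_path))
    if len(st) == 0:
        raise InputError(f"no models in {pdb_path}")
    model = st[0]
    present = {chain.name for chain in model}
    missing = ({heavy_id, light_id} | ag_ids) - present
    if missing:
        raise ConfigurationError(
            f"chains {sorted(missing)} not present in {pdb_path} (has {sorted(present)})"
        )

    atoms: list[AtomRecord] = []
    waters: list[AtomRecord] = []
    serial = 0
    for chain in model:
        if chain.name == heavy_id:
            role = ROLE_HEAVY
        elif chain.name == light_id:
            role = ROLE_LIGHT
        elif chain.name in ag_ids:
            role = ROLE_ANTIGEN
        else:
            role = None  # waters still collected below
        for res in chain:
            resname = res.name.upper()
            is_water = resname in WATER_NAMES
            if not is_water and role is None:
                continue
            if not is_water and resname not in STANDARD_AA:
                continue  # ions, ligands, sugars: stripped
            key = ResidueKey(
                chain_id=chain.name,
                number=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                aa3=resname,
                role=ROLE_WATER if is_water else role,
            )
            for atom in _resolve_altlocs(res):
                elem = element_of(atom.name, atom.element.name)
                if atom.element.is_hydrogen:
                    continue
                if is_water and atom.name.strip().upper() not in ("O", "OW"):
                    continue
                serial += 1
                rec = AtomRecord(
                    serial=serial,
                    name=atom.name.strip().upper(),
                    element=elem,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    residue=key,
                    occupancy=atom.occ,
                    vdw_radius=radii.get(elem, radii["other"]),
                )
                if is_water:
                    if keep_waters:
                        waters.append(rec)
                else:
                    atoms.append(rec)

    if not any(a.residue.role == ROLE_ANTIGEN for a in atoms):
        raise InputError(f"no antigen residues found in {pdb_path}")

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    return ComplexStructure(
        atoms=atoms,
        heavy_chain=heavy_id,
        light_chain=light_id,
        ag_chains=ag_ids,
        waters=waters,
        resolution=resolution,
        name=str(pdb_path),
    )


def coords_array(atoms: list[AtomRecord]) -> np.ndarray:
    return np.array([a.coords for a in atoms], dtype=float).reshape(len(atoms), 3)


def radii_array(atoms: list[AtomRecord]) -> np.ndarray:
    return np.array([a.vdw_radius for a in atoms], dtype=float)


def write_pdb(path, atom_rows) -> None:
    """Write fixed-format ATOM/HETATM records.

    ``atom_rows`` yields tuples ``(record, serial, name, resname, chain,
    resnum, icode, x, y, z, occ, element)``.  Used by the synthetic fixture
    generator; output is byte-deterministic.
    """
    with open(path, "w") as fh:
        for rec, serial, name, resname, chain, resnum, icode, x, y, z, occ, elem in atom_rows:
            aname = name if len(name) == 4 else f" {name:<3s}"
            fh.write(
                f"{rec:<6s}{serial:>5d} {aname:<4s}{'':1s}{resname:<3s} "
                f"{chain:1s}{resnum:>4d}{icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          "
                f"{elem:>2s}\n"
            )
        fh.write("END\n")
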