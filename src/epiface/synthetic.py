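"""Synthetic antibody-antigen complexes with planted, machine-readable truth.

The workhorse geometry is a two-slab complex on a 4 Angstrom grid: the
antigen contributes an island of residues whose facing carbons (CB, z=0)
are sealed from the solvent by an antibody slab directly above (CB at
z=gap), by four lateral prong carbons per antibody residue reaching
half-way to the neighbouring cells, and by their own backbone below.  A
one-cell rim of single-atom support residues around the island closes the
lateral channels while itself remaining solvent-exposed, so the planted
epitope is exactly the island.  Interaction plants (carbon pairs, shielded
pairs, hydrogen bonds, salt bridges, water bridges, ring stacks, ring-ion
pairs) and their super-threshold decoys are placed on isolated sites beside
the slab, far enough apart not to interact.

Geometry is idealized: residue shapes are designed for the geometric
detectors, not for chemical realism.  All output is deterministic per seed;
coordinate jitter is the only stochastic element and is kept small enough
not to cross any detection threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structures import CHOTHIA_CDRS, write_pdb

GRID = 4.0
#: Half-cell prong reach of antibody facing residues.
PRONG = 2.0


class GenerationError(ValueError):
    """Requested planted geometry cannot be placed."""


@dataclass
class _Atom:
    chain: str
    resnum: int
    icode: str
    resname: str
    name: str
    element: str
    xyz: np.ndarray
    hetatm: bool = False
    rigid: bool = False     # excluded from jitter (threshold-critical atoms)

    @property
    def atom_id(self) -> dict:
        return {
            "chain": self.chain,
            "number": self.resnum,
            "icode": self.icode,
            "aa3": self.resname,
            "atom": self.name,
        }

    @property
    def res_id(self) -> dict:
        return {
            "chain": self.chain,
            "number": self.resnum,
            "icode": self.icode,
            "aa3": self.resname,
        }


def _chothia_numbers(label: str):
    """Endless (number, icode) supply inside one Chothia CDR interval."""
    lo, hi = CHOTHIA_CDRS[label]
    for n in range(lo, hi + 1):
        yield n, ""
    for anchor in range(hi - 2, lo - 1, -1):
        for letter in "ABCDEFGHIJKLMNOPQRSTUVWXYZ":
            yield anchor, letter
    raise GenerationError(f"CDR interval {label} exhausted")


def _framework_numbers(chain_kind: str):
    """Endless framework (number, icode) supply avoiding all CDR intervals."""
    prefix = chain_kind
    blocked = [
        rng for lab, rng in CHOTHIA_CDRS.items() if lab.startswith(prefix)
    ]
    n = 1
    while n < 400:
        if not any(lo <= n <= hi for lo, hi in blocked):
            yield n, ""
        n += 1
    raise GenerationError("framework numbering exhausted")


class ComplexBuilder:
    """Accumulates atoms and manifest entries; writes PDB + JSON."""

    def __init__(self, seed: int, jitter: float = 0.02):
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        self.jitter = jitter
        self.atoms: list[_Atom] = []
        self.manifest: dict = {
            "seed": self.seed,
            "planted": [],
            "expected_epitope": [],
            "expected_paratope": [],
            "expected_cluster_atoms": [],
            "notes": {},
        }
        self._water_count = 0
        self._plant_x = 0.0  # advanced as sites are consumed

    # -- low-level ---------------------------------------------------------

    def add_atom(self, chain, resnum, icode, resname, name, element, xyz,
                 hetatm=False, rigid=False) -> _Atom:
        atom = _Atom(chain, resnum, icode, resname, name, element,
                     np.asarray(xyz, dtype=float), hetatm, rigid)
        self.atoms.append(atom)
        return atom

    def add_residue(self, chain, resnum, icode, resname, atom_specs,
                    rigid=False) -> list[_Atom]:
        return [
            self.add_atom(chain, resnum, icode, resname, nm, el, xyz, rigid=rigid)
            for nm, el, xyz in atom_specs
        ]

    def add_water(self, xyz) -> _Atom:
        self._water_count += 1
        return self.add_atom("W", self._water_count, "", "HOH", "O", "O",
                             xyz, hetatm=True, rigid=True)

    def next_site(self) -> np.ndarray:
        """Origin of the next isolated plant site (20 A spacing on +x)."""
        site = np.array([self._plant_x, 0.0, 0.0])
        self._plant_x += 20.0
        return site

    # -- output ------------------------------------------------------------

    def _jittered(self, atom: _Atom) -> np.ndarray:
        if self.jitter <= 0 or atom.rigid:
            return atom.xyz
        return atom.xyz + self.rng.uniform(-self.jitter, self.jitter, 3)

    def write(self, out_dir, stem: str = "complex") -> tuple[Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pdb_path = out_dir / f"{stem}.pdb"
        man_path = out_dir / f"{stem}.manifest.json"
        order = sorted(
            range(len(self.atoms)),
            key=lambda i: (
                self.atoms[i].chain,
                self.atoms[i].resnum,
                self.atoms[i].icode,
                i,
            ),
        )
        rows = []
        for serial, i in enumerate(order, start=1):
            a = self.atoms[i]
            x, y, z = self._jittered(a)
            rows.append((
                "HETATM" if a.hetatm else "ATOM",
                serial, a.name, a.resname, a.chain, a.resnum, a.icode,
                x, y, z, 1.0, a.element,
            ))
        write_pdb(pdb_path, rows)
        with open(man_path, "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
        return pdb_path, man_path


# ---------------------------------------------------------------------------
# slab complexes


def _ag_full_residue(b: ComplexBuilder, num, x, y, rigid=False):
    """Antigen island residue: facing CB plus a backbone stack below it."""
    return b.add_residue("A", num, "", "ALA", [
        ("CB", "C", (x, y, 0.0)),
        ("CA", "C", (x, y, -1.5)),
        ("N", "N", (x - 0.7, y, -2.6)),
        ("C", "C", (x + 0.7, y, -2.6)),
        ("O", "O", (x + 0.7, y, -3.8)),
    ], rigid=rigid)


def _ab_facing_residue(b: ComplexBuilder, chain, num, icode, x, y, gap,
                       rigid=False):
    """Antibody facing residue: CB over the cell, 4 prongs, up-blocker,
    backbone above.  Modelled as an (incomplete) Trp so every prong has a
    valid carbon name; the indole ring is deliberately incomplete so no
    spurious aromatic ring is fitted."""
    return b.add_residue(chain, num, icode, "TRP", [
        ("CB", "C", (x, y, gap)),
        ("CG", "C", (x + PRONG, y, gap - 0.4)),
        ("CD1", "C", (x - PRONG, y, gap - 0.6)),
        ("CD2", "C", (x, y + PRONG, gap - 0.4)),
        ("CE2", "C", (x, y - PRONG, gap - 0.6)),
        ("CE3", "C", (x, y, gap + 1.3)),
        ("CA", "C", (x, y, gap + 3.0)),
        ("N", "N", (x - 0.7, y, gap + 4.1)),
        ("C", "C", (x + 0.7, y, gap + 4.1)),
        ("O", "O", (x + 0.7, y, gap + 5.3)),
    ], rigid=rigid)


def _far_light_blob(b: ComplexBuilder):
    """Minimal detached light chain so both antibody chains exist."""
    for i in range(3):
        b.add_residue("L", i + 1, "", "GLY", [
            ("N", "N", (5.0 * i - 0.7, 60.0, 1.1)),
            ("CA", "C", (5.0 * i, 60.0, 0.0)),
            ("C", "C", (5.0 * i + 0.7, 60.0, 1.1)),
            ("O", "O", (5.0 * i + 0.7, 60.0, 2.3)),
        ])


def _brute_force_cluster(b: ComplexBuilder, ag_carbons, ab_carbons,
                         cc_dist=5.0):
    """Ground-truth biggest cluster by exhaustive union-find over the
    planted slab carbons (no polar atom shields by construction; the
    backbone stacks sit behind the facing carbons on both sides)."""
    atoms = ag_carbons + ab_carbons
    parent = list(range(len(atoms)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    na = len(ag_carbons)
    for i, a in enumerate(ag_carbons):
        for j, c in enumerate(ab_carbons):
            if np.linalg.norm(a.xyz - c.xyz) <= cc_dist:
                ri, rj = find(i), find(na + j)
                if ri != rj:
                    parent[ri] = rj
    groups: dict[int, list[int]] = {}
    for i in range(len(atoms)):
        # singletons are not cluster members (no edge)
        groups.setdefault(find(i), []).append(i)
    linked = [g for g in groups.values() if len(g) > 1]
    if not linked:
        return []
    biggest = max(linked, key=len)
    return [atoms[i].atom_id for i in biggest]


def make_slab_complex(
    n_res_per_side: int = 5,
    gap: float = 4.0,
    seed: int = 0,
    islands: list[tuple[int, tuple[float, float]]] | None = None,
    cdr_mode: str = "H3",
    jitter: float = 0.02,
) -> ComplexBuilder:
    """Two-slab complex whose epitope is exactly the antigen island(s).

    Parameters
    ----------
    n_res_per_side:
        Island edge length (ignored when ``islands`` given); >= 2.
    gap:
        Vertical distance between facing carbon planes; must stay below
        ``2 * probe + 2 * r_C`` so the probe cannot enter the interface.
    islands:
        Optional list of ``(n, (ox, oy))`` islands sharing one antibody.
    cdr_mode:
        "H3" numbers every facing antibody residue inside CDR H3;
        "mixed" spreads them over H1/H2/H3; "fw" uses framework numbers
        only (the epitope then has no CDR component at all).
    """
    if n_res_per_side < 2:
        raise GenerationError("need at least a 2x2 island")
    # below ~2*(probe + r_C) the water probe cannot enter the interface;
    # wider gaps produce a legitimately non-contacting pair (empty truth)
    sealed = gap < 2 * 1.4 + 2 * 1.7
    b = ComplexBuilder(seed, jitter)
    if islands is None:
        islands = [(n_res_per_side, (0.0, 0.0))]

    if cdr_mode == "H3":
        supply = _chothia_numbers("H3")
    elif cdr_mode == "fw":
        supply = _framework_numbers("H")
    elif cdr_mode == "mixed":
        def _mixed():
            gens = [_chothia_numbers(lab) for lab in ("H1", "H2", "H3")]
            i = 0
            while True:
                yield next(gens[i % 3])
                i += 1
        supply = _mixed()
    else:
        raise GenerationError(f"unknown cdr_mode {cdr_mode!r}")

    ag_num = 0
    ag_cbs, ab_carbons = [], []
    max_x = 0.0
    for n, (ox, oy) in islands:
        cells = [(ox + GRID * i, oy + GRID * j) for i in range(n) for j in range(n)]
        rim = sorted(
            {
                (x + GRID * dx, y + GRID * dy)
                for x, y in cells
                for dx in (-1, 0, 1)
                for dy in (-1, 0, 1)
            }
            - set(cells)
        )
        for x, y in cells:
            ag_num += 1
            atoms = _ag_full_residue(b, ag_num, x, y)
            ag_cbs.append(atoms[0])
            if sealed:
                b.manifest["expected_epitope"].append(atoms[0].res_id)
        for x, y in rim:
            ag_num += 1
            b.add_residue("A", ag_num, "", "GLY",
                          [("CA", "C", (x, y, 0.0))])
        for x, y in cells + rim:
            num, icode = next(supply)
            atoms = _ab_facing_residue(b, "H", num, icode, x, y, gap)
            ab_carbons.extend(atoms[:5])
            if sealed and (x, y) in cells:
                # rim-covering residues are usually buried too, but their
                # burial depends on the single-atom rim: not asserted
                b.manifest["expected_paratope"].append(atoms[0].res_id)
            max_x = max(max_x, x)

    _far_light_blob(b)
    b._plant_x = max_x + 17.0
    b.manifest["expected_cluster_atoms"] = _brute_force_cluster(
        b, ag_cbs, ab_carbons
    )
    b.manifest["notes"].update(
        kind="slab", gap=gap, islands=[[n, list(o)] for n, o in islands],
        cdr_mode=cdr_mode,
    )
    return b


def make_seam_complex(kind: str = "interchain", seed: int = 0,
                      jitter: float = 0.02) -> ComplexBuilder:
    """3x3 island whose center cell is buried only by joint coverage.

    No antibody residue sits above the center cell; the four neighbouring
    facing residues seal it with their prongs.  Splitting those
    neighbours between the two chains ("interchain") or between two CDRs
    of the heavy chain ("intercdr") plants a residue that is buried in
    the full complex but by no chain / no single CDR alone.
    """
    if kind not in ("interchain", "intercdr"):
        raise GenerationError(f"unknown seam kind {kind!r}")
    b = ComplexBuilder(seed, jitter)
    gap = 4.0
    n = 3
    xc = yc = GRID  # center cell
    cells = [(GRID * i, GRID * j) for i in range(n) for j in range(n)]
    rim = sorted(
        {
            (x + GRID * dx, y + GRID * dy)
            for x, y in cells
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
        }
        - set(cells)
    )
    seam_res = None
    for num, (x, y) in enumerate(cells, start=1):
        atoms = _ag_full_residue(b, num, x, y, rigid=True)
        b.manifest["expected_epitope"].append(atoms[0].res_id)
        if (x, y) == (xc, yc):
            seam_res = atoms[0].res_id
    for num, (x, y) in enumerate(rim, start=len(cells) + 1):
        b.add_residue("A", num, "", "GLY", [("CA", "C", (x, y, 0.0))])

    if kind == "interchain":
        supplies = {"H": _chothia_numbers("H3"), "L": _chothia_numbers("L3")}

        def place(x, y):
            left = x < xc or (x == xc and y < yc)
            return ("H" if left else "L"), supplies["H" if left else "L"]
    else:
        supplies = {"H1": _chothia_numbers("H1"), "H3": _chothia_numbers("H3")}

        def place(x, y):
            left = x < xc or (x == xc and y < yc)
            return "H", supplies["H1" if left else "H3"]

    for x, y in cells + rim:
        if (x, y) == (xc, yc):
            continue  # the seam: no direct coverage
        chain, supply = place(x, y)
        num, icode = next(supply)
        _ab_facing_residue(b, chain, num, icode, x, y, gap, rigid=True)
    if kind == "intercdr":
        _far_light_blob(b)
    b._plant_x = GRID * (n + 1) + 17.0
    b.manifest["notes"].update(kind=f"seam_{kind}", seam_residue=seam_res)
    return b


# ---------------------------------------------------------------------------
# interaction plants

PLANT_TYPES = (
    "cc_pair", "shielded_cc_pair", "hbond", "salt_bridge",
    "water_bridge", "pi_pi", "pi_cation", "pi_anion",
)


def _ring(center, z, phase=0.0):
    """Regular hexagon of Phe ring-carbon coordinates, radius 1.39 A."""
    cx, cy = center
    pts = []
    for k, name in enumerate(("CG", "CD1", "CE1", "CZ", "CE2", "CD2")):
        a = phase + k * math.pi / 3.0
        pts.append((name, "C", (cx + 1.39 * math.cos(a),
                                cy + 1.39 * math.sin(a), z)))
    return pts


def _ring_perp(center, z0):
    """Hexagon in the xz-plane (normal along y): a stacking decoy."""
    cx, cy = center
    pts = []
    for k, name in enumerate(("CG", "CD1", "CE1", "CZ", "CE2", "CD2")):
        a = k * math.pi / 3.0
        pts.append((name, "C", (cx + 1.39 * math.cos(a), cy,
                                z0 + 1.39 * math.sin(a))))
    return pts


def _next_ag_num(b: ComplexBuilder) -> int:
    nums = [a.resnum for a in b.atoms if a.chain == "A"]
    return (max(nums) if nums else 0) + 1


def _next_h_fw(b: ComplexBuilder):
    used = {(a.resnum, a.icode) for a in b.atoms if a.chain == "H"}
    for num, icode in _framework_numbers("H"):
        if (num, icode) not in used:
            return num, icode
    raise GenerationError("no framework numbers left")


def plant_interaction(b: ComplexBuilder, kind: str, decoy: bool = False,
                      decoy_kind: str = "far") -> dict:
    """Add one planted interaction (or a decoy) on a fresh isolated site.

    Returns the manifest entry.  Decoys use super-threshold distances or
    failing angles; their expected detection flag is False.
    """
    if kind not in PLANT_TYPES:
        raise GenerationError(f"unknown plant type {kind!r}")
    site = b.next_site()
    sx, sy = float(site[0]), float(site[1])
    for a in b.atoms:
        if not a.hetatm and np.linalg.norm(a.xyz[:2] - site[:2]) < 8.0:
            raise GenerationError("plant site clashes with existing atoms")
    ag_num = _next_ag_num(b)
    h_num, h_icode = _next_h_fw(b)
    entry: dict = {"type": kind, "decoy": bool(decoy), "atoms": {}}

    def ag_res(resname, specs):
        return b.add_residue("A", ag_num, "", resname, specs, rigid=True)

    def ab_res(resname, specs):
        return b.add_residue("H", h_num, h_icode, resname, specs, rigid=True)

    if kind in ("cc_pair", "shielded_cc_pair"):
        d = 5.5 if (decoy and decoy_kind == "far") else 4.0
        if kind == "shielded_cc_pair":
            ag = ag_res("SER", [
                ("CB", "C", (sx, sy, 0.0)),
                ("OG", "O", (sx, sy, d / 2.0)),
                ("CA", "C", (sx, sy, -1.5)),
            ])
            entry["atoms"]["shield"] = ag[1].atom_id
        else:
            ag = ag_res("ALA", [
                ("CB", "C", (sx, sy, 0.0)),
                ("CA", "C", (sx, sy, -1.5)),
            ])
        ab = ab_res("ALA", [
            ("CB", "C", (sx, sy, d)),
            ("CA", "C", (sx, sy, d + 1.5)),
        ])
        entry["atoms"]["epitope_c"] = ag[0].atom_id
        entry["atoms"]["paratope_c"] = ab[0].atom_id
        entry["expect"] = (
            "shielded" if kind == "shielded_cc_pair" and not decoy
            else not decoy
        )

    elif kind == "hbond":
        d = 4.5 if decoy else 2.9
        ag = ag_res("SER", [
            ("OG", "O", (sx, sy, 0.0)),
            ("CB", "C", (sx, sy, -1.2)),
            ("CA", "C", (sx, sy, -2.7)),
        ])
        ab = ab_res("SER", [
            ("OG", "O", (sx, sy, d)),
            ("CB", "C", (sx, sy, d + 1.2)),
            ("CA", "C", (sx, sy, d + 2.7)),
        ])
        entry["atoms"]["ag"] = ag[0].atom_id
        entry["atoms"]["ab"] = ab[0].atom_id
        entry["expect"] = not decoy

    elif kind == "salt_bridge":
        d = 4.6 if decoy else 3.0
        ag = ag_res("GLU", [
            ("OE1", "O", (sx, sy, 0.0)),
            ("CD", "C", (sx, sy, -1.3)),
            ("CG", "C", (sx, sy, -2.8)),
            ("CB", "C", (sx, sy, -4.3)),
            ("CA", "C", (sx, sy, -5.8)),
        ])
        ab = ab_res("LYS", [
            ("NZ", "N", (sx, sy, d)),
            ("CE", "C", (sx, sy, d + 1.5)),
            ("CD", "C", (sx, sy, d + 3.0)),
            ("CA", "C", (sx, sy, d + 4.5)),
        ])
        entry["atoms"]["ag"] = ag[0].atom_id
        entry["atoms"]["ab"] = ab[0].atom_id
        entry["expect"] = not decoy

    elif kind == "water_bridge":
        d_ab = 7.4 if decoy else 5.8   # water stays at 2.8 from the Ag side
        ag = ag_res("SER", [
            ("OG", "O", (sx, sy, 0.0)),
            ("CB", "C", (sx, sy, -1.2)),
            ("CA", "C", (sx, sy, -2.7)),
        ])
        water = b.add_water((sx, sy, 2.8))
        ab = ab_res("SER", [
            ("OG", "O", (sx, sy, d_ab)),
            ("CB", "C", (sx, sy, d_ab + 1.2)),
            ("CA", "C", (sx, sy, d_ab + 2.7)),
        ])
        entry["atoms"]["ag"] = ag[0].atom_id
        entry["atoms"]["ab"] = ab[0].atom_id
        entry["atoms"]["water"] = water.atom_id
        entry["expect"] = not decoy

    elif kind == "pi_pi":
        ag = ag_res("PHE", _ring((sx, sy), 0.0) + [
            ("CB", "C", (sx + 2.6, sy, -1.2)),
            ("CA", "C", (sx + 2.6, sy, -2.7)),
        ])
        if decoy and decoy_kind == "perpendicular":
            top = _ring_perp((sx, sy), 4.0)
            z_cb = 4.0
        else:
            z = 6.0 if decoy else 3.8
            top = _ring((sx, sy), z, phase=math.pi / 6.0)
            z_cb = z
        ab = ab_res("PHE", top + [
            ("CB", "C", (sx + 2.6, sy, z_cb + 1.2)),
            ("CA", "C", (sx + 2.6, sy, z_cb + 2.7)),
        ])
        entry["atoms"]["ag_ring"] = ag[0].res_id
        entry["atoms"]["ab_ring"] = ab[0].res_id
        entry["expect"] = not decoy

    elif kind in ("pi_cation", "pi_anion"):
        ag = ag_res("PHE", _ring((sx, sy), 0.0) + [
            ("CB", "C", (sx + 2.6, sy, -1.2)),
            ("CA", "C", (sx + 2.6, sy, -2.7)),
        ])
        if decoy:  # in the ring plane: distance passes, the angle fails
            ion_xyz = (sx + 4.5, sy, 0.0)
            dx, dz = 1.5, 0.0
        else:
            ion_xyz = (sx, sy, 4.0)
            dx, dz = 0.0, 1.5
        if kind == "pi_cation":
            ab = ab_res("LYS", [
                ("NZ", "N", ion_xyz),
                ("CE", "C", (ion_xyz[0] + dx, sy, ion_xyz[2] + dz)),
                ("CA", "C", (ion_xyz[0] + 2 * dx, sy, ion_xyz[2] + 2 * dz)),
            ])
        else:
            ab = ab_res("ASP", [
                ("OD1", "O", ion_xyz),
                ("CG", "C", (ion_xyz[0] + dx, sy, ion_xyz[2] + dz)),
                ("CB", "C", (ion_xyz[0] + 2 * dx, sy, ion_xyz[2] + 2 * dz)),
                ("CA", "C", (ion_xyz[0] + 3 * dx, sy, ion_xyz[2] + 3 * dz)),
            ])
        entry["atoms"]["ring"] = ag[0].res_id
        entry["atoms"]["ion"] = ab[0].atom_id
        entry["expect"] = not decoy

    b.manifest["planted"].append(entry)
    return entry


def make_planted_panel(seed: int = 0, jitter: float = 0.0) -> ComplexBuilder:
    """One fixture holding every plant type plus its decoy.

    Pure detector exercise: no slab, so no burial ground truth — the
    manifest's ``planted`` list is the only expectation.
    """
    b = ComplexBuilder(seed, jitter)
    b._plant_x = 0.0
    for kind in PLANT_TYPES:
        plant_interaction(b, kind, decoy=False)
    for kind in PLANT_TYPES:
        plant_interaction(b, kind, decoy=True)
    plant_interaction(b, "pi_pi", decoy=True, decoy_kind="perpendicular")
    _far_light_blob(b)
    # a token antigen stays mandatory even for a pure panel
    b.manifest["notes"]["kind"] = "planted_panel"
    return b


def make_zigzag_contact(n_links: int = 8, separation: float = 3.8,
                        seed: int = 0) -> ComplexBuilder:
    """Alternating carbon chain with all cross distances at ``separation``.

    Consecutive cross-interface carbons sit exactly ``separation`` apart
    and next-nearest pairs beyond 5 Angstrom, so the contact graph — and
    hence cluster membership — is identical for any cc_dist in [4, 5].
    """
    b = ComplexBuilder(seed, jitter=0.0)
    dz = math.sqrt(separation**2 - 1.25**2)
    ag_atoms, ab_atoms = [], []
    for k in range(n_links):
        a = b.add_residue("A", k + 1, "", "ALA",
                          [("CB", "C", (2.5 * k, 0.0, 0.0))], rigid=True)
        ag_atoms.append(a[0])
    num_gen = _framework_numbers("H")
    for k in range(n_links - 1):
        num, icode = next(num_gen)
        a = b.add_residue("H", num, icode, "ALA",
                          [("CB", "C", (2.5 * k + 1.25, 0.0, dz))], rigid=True)
        ab_atoms.append(a[0])
    _far_light_blob(b)
    b.manifest["notes"].update(kind="zigzag", separation=separation)
    b.manifest["expected_cluster_atoms"] = [
        a.atom_id for a in ag_atoms + ab_atoms
    ]
    return b


# ---------------------------------------------------------------------------
# pocket antigen


def _fibonacci_sphere(n):
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_pocket_antigen(depth: float = 8.0, mouth: float = 8.0,
                        seed: int = 0, shell_radius: float = 10.0,
                        spacing: float = 3.2) -> ComplexBuilder:
    """Spherical antigen shell with an axial pocket of known depth.

    ``mouth`` (diameter) must exceed ``2*(1.4 + r_C)`` so the water probe
    reaches the bottom, and stay below 18 so the CDR-sized probe cannot;
    the bottom residues are then exposed at probe 1.4 only.  With
    ``depth=0`` the shell is convex and everything is superficial.
    """
    if mouth >= 18.0:
        raise GenerationError("mouth must exclude the 9 A probe")
    if depth > 0 and mouth <= 2 * (1.4 + 1.7):
        raise GenerationError("mouth too narrow for the water probe")
    b = ComplexBuilder(seed, jitter=0.0)
    r_mouth = mouth / 2.0
    n_shell = int(4 * math.pi * shell_radius**2 / (spacing**2 * 0.85))
    pts = _fibonacci_sphere(n_shell) * shell_radius

    num = 0
    deep_expect, superficial_expect = [], []
    if depth > 0:
        keep = ~(
            (pts[:, 2] > 0)
            & (np.hypot(pts[:, 0], pts[:, 1]) < r_mouth + spacing * 0.5)
        )
    else:
        keep = np.ones(len(pts), bool)
    for p in pts[keep]:
        num += 1
        atoms = b.add_residue("A", num, "", "GLY",
                              [("CA", "C", tuple(p))], rigid=True)
        if depth == 0 or p[2] < -0.5 * shell_radius:
            superficial_expect.append(atoms[0].res_id)

    if depth > 0:
        z_top = math.sqrt(max(shell_radius**2 - r_mouth**2, 0.0))
        z_bot = z_top - depth
        # tube wall
        n_ring = max(8, int(2 * math.pi * r_mouth / 2.4))
        z = z_top
        while z > z_bot + 1.0:
            for k in range(n_ring):
                a = 2 * math.pi * k / n_ring
                num += 1
                b.add_residue("A", num, "", "GLY", [
                    ("CA", "C", (r_mouth * math.cos(a) + spacing * 0.0,
                                 r_mouth * math.sin(a), z)),
                ], rigid=True)
            z -= 2.4
        # bottom plate
        rr = 0.0
        while rr < r_mouth - 0.5:
            n_r = max(1, int(2 * math.pi * rr / 2.4))
            for k in range(n_r):
                a = 2 * math.pi * k / n_r
                num += 1
                atoms = b.add_residue("A", num, "", "GLY", [
                    ("CA", "C", (rr * math.cos(a), rr * math.sin(a), z_bot)),
                ], rigid=True)
                if rr < 1.0:
                    deep_expect.append(atoms[0].res_id)
            if rr < 1.0 and n_r == 1:
                pass
            rr += 2.4

    _far_light_blob(b)
    # a nominal heavy chain far away keeps the two-body reader happy
    b.add_residue("H", 1, "", "GLY", [
        ("N", "N", (-0.7, -60.0, 1.1)),
        ("CA", "C", (0.0, -60.0, 0.0)),
        ("C", "C", (0.7, -60.0, 1.1)),
        ("O", "O", (0.7, -60.0, 2.3)),
    ])
    b.manifest["notes"].update(kind="pocket", depth=depth, mouth=mouth,
                               shell_radius=shell_radius)
    b.manifest["expected_deep"] = deep_expect
    b.manifest["expected_superficial"] = superficial_expect
    return b
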