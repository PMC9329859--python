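"""Numerical solvent-accessibility engine and buried-interface set algebra.

Exposure is defined by rolling a spherical probe over the heavy atoms: an
atom is *exposed* when at least one point of its solvent-expanded sphere
(radius ``r_vdw + probe``) is not covered by any neighbouring expanded
sphere.  Atoms exposed in a monomer but not in the complex are *interfacial*;
interfacial residues of the antigen form the epitope and those of the
antibody the paratope.  Because the complex contains a superset of the
monomer's atoms and the same deterministic sample directions are reused, the
exposed set of an atom in the complex is exactly a subset of its monomer
exposed set, so buried areas are non-negative by construction.

Sphere sampling uses a fixed-orientation golden-spiral point set, making
every result bit-reproducible for a given ``n_points``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from .structures import (
    AtomRecord,
    ComplexStructure,
    RegionScheme,
    ResidueKey,
    DEFAULT_SCHEME,
    CDR_LABELS,
    assign_region,
    coords_array,
    radii_array,
)

log = logging.getLogger(__name__)

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

#: Probe radii for the exposedness classification: water-sized, CDR-loop
#: sized, and a quasi convex-hull probe.
EXPOSEDNESS_PROBES = (1.4, 9.0, 100.0)


@lru_cache(maxsize=8)
def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere directions (golden spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pts.setflags(write=False)
    return pts


@dataclass
class SasaResult:
    """Per-atom solvent accessibility at one probe radius."""

    atoms: list[AtomRecord]
    probe_radius: float
    n_sphere_points: int
    per_atom_area: np.ndarray          # Angstrom^2, aligned with ``atoms``
    exposed_fraction: np.ndarray       # fraction of sample points accessible

    @property
    def total_area(self) -> float:
        return float(self.per_atom_area.sum())

    @property
    def exposed_mask(self) -> np.ndarray:
        return self.exposed_fraction > 0.0

    @property
    def exposed_atoms(self) -> set[AtomRecord]:
        return {a for a, m in zip(self.atoms, self.exposed_mask) if m}

    def exposed_residues(self) -> set[ResidueKey]:
        return {a.residue for a, m in zip(self.atoms, self.exposed_mask) if m}

    def area_of(self, atom: AtomRecord) -> float:
        return float(self.per_atom_area[self.atoms.index(atom)])


def compute_sasa(
    atoms: list[AtomRecord],
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Solvent-accessible exposure of every atom in ``atoms``.

    An atom's expanded sphere is sampled at ``n_points`` fixed directions; a
    sample point is accessible when it lies outside every neighbour's
    expanded sphere.  Per-atom area is the accessible fraction of
    ``4*pi*(r+probe)^2``.
    """
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 92:
        raise ValueError("n_points must be at least 92")
    n = len(atoms)
    if n == 0:
        return SasaResult(atoms, probe_radius, n_points, np.zeros(0), np.zeros(0))

    xyz = coords_array(atoms)
    radii = radii_array(atoms) + probe_radius
    unit = sphere_points(n_points)

    tree = cKDTree(xyz)
    cutoff = 2.0 * radii.max()
    neighbor_lists = tree.query_ball_point(xyz, r=cutoff)

    frac = np.empty(n)
    warned = False
    for i in range(n):
        nbrs = [j for j in neighbor_lists[i] if j != i]
        if not warned and any(
            np.allclose(xyz[j], xyz[i], atol=1e-6) for j in nbrs
        ):
            log.warning("coincident atom centers detected; both retained")
            warned = True
        pts = xyz[i] + radii[i] * unit
        if not nbrs:
            frac[i] = 1.0
            continue
        nb_xyz = xyz[nbrs]
        nb_r2 = radii[nbrs] ** 2
        # relevant neighbours only: expanded spheres that can reach the shell
        d = np.linalg.norm(nb_xyz - xyz[i], axis=1)
        keep = d < radii[i] + np.sqrt(nb_r2)
        if not keep.any():
            frac[i] = 1.0
            continue
        nb_xyz = nb_xyz[keep]
        nb_r2 = nb_r2[keep]
        diff = pts[:, None, :] - nb_xyz[None, :, :]
        covered = (np.einsum("ijk,ijk->ij", diff, diff) < nb_r2[None, :]).any(axis=1)
        frac[i] = 1.0 - covered.mean()

    area = frac * 4.0 * np.pi * radii**2
    return SasaResult(atoms, probe_radius, n_points, area, frac)


def interface_area(
    ab_atoms: list[AtomRecord],
    ag_atoms: list[AtomRecord],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    calibration: float = 1.0,
) -> float:
    """Buried interface area A(Ab) + A(Ag) - A(complex), in Angstrom^2.

    ``calibration`` rescales the accessible-surface value (0.95 approximates
    a solvent-excluded-surface accounting; default 1.0).
    """
    a_ab = compute_sasa(ab_atoms, probe, n_points).total_area
    a_ag = compute_sasa(ag_atoms, probe, n_points).total_area
    a_cplx = compute_sasa(ab_atoms + ag_atoms, probe, n_points).total_area
    return calibration * (a_ab + a_ag - a_cplx)


@dataclass
class InterfaceSets:
    """Exposed/interfacial atom sets and the derived epitope/paratope."""

    probe: float
    n_points: int
    ab_sasa: SasaResult
    ag_sasa: SasaResult
    complex_sasa: SasaResult
    interfacial_ab: set[AtomRecord]
    interfacial_ag: set[AtomRecord]
    paratope: set[ResidueKey]
    epitope: set[ResidueKey]
    buried_area: dict[AtomRecord, float]   # monomer minus complex, per atom
    A_interface: float
    calibration: float = 1.0

    @property
    def ag_surface_residues(self) -> set[ResidueKey]:
        return self.ag_sasa.exposed_residues()

    @property
    def ab_surface_residues(self) -> set[ResidueKey]:
        return self.ab_sasa.exposed_residues()


def _interfacial(
    monomer: SasaResult, complex_area: dict[AtomRecord, float]
) -> tuple[set[AtomRecord], dict[AtomRecord, float]]:
    """Atoms exposed in the monomer that lost all exposure in the complex."""
    buried: dict[AtomRecord, float] = {}
    interfacial: set[AtomRecord] = set()
    for atom, area, exposed in zip(
        monomer.atoms, monomer.per_atom_area, monomer.exposed_mask
    ):
        delta = float(area) - complex_area[atom]
        buried[atom] = max(delta, 0.0)
        if exposed and complex_area[atom] <= 0.0:
            interfacial.add(atom)
    return interfacial, buried


def epitope_paratope(
    cs: ComplexStructure,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    calibration: float = 1.0,
) -> InterfaceSets:
    """Identify interfacial atoms and lift them to epitope/paratope residues.

    Both monomers are taken rigidly from the complex; an atom is interfacial
    when exposed in its monomer and fully buried in the complex, and a
    residue is interfacial when it owns at least one interfacial atom.
    """
    ab = cs.ab_atoms
    ag = cs.ag_atoms
    if not ab or not ag:
        raise ValueError("both antibody and antigen must be non-empty")
    ab_sasa = compute_sasa(ab, probe, n_points)
    ag_sasa = compute_sasa(ag, probe, n_points)
    cplx = compute_sasa(ab + ag, probe, n_points)
    cplx_area = {a: float(x) for a, x in zip(cplx.atoms, cplx.per_atom_area)}

    ifc_ab, buried_ab = _interfacial(ab_sasa, cplx_area)
    ifc_ag, buried_ag = _interfacial(ag_sasa, cplx_area)
    buried = {**buried_ab, **buried_ag}
    a_interface = calibration * (
        ab_sasa.total_area + ag_sasa.total_area - cplx.total_area
    )
    return InterfaceSets(
        probe=probe,
        n_points=n_points,
        ab_sasa=ab_sasa,
        ag_sasa=ag_sasa,
        complex_sasa=cplx,
        interfacial_ab=ifc_ab,
        interfacial_ag=ifc_ag,
        paratope={a.residue for a in ifc_ab},
        epitope={a.residue for a in ifc_ag},
        buried_area=buried,
        A_interface=a_interface,
        calibration=calibration,
    )


@dataclass
class SubEpitopeDecomposition:
    """Epitope subdivision by which antibody parts bury each residue.

    ``epitope_cdr[i]`` is the epitope of the antigen against CDR *i* alone;
    shared/inter-CDR/inter-chain/framework subsets follow from set algebra
    over reduced-system burial runs.
    """

    epitope: set[ResidueKey]
    epitope_cdr: dict[str, set[ResidueKey]]
    epitope_shared_pairs: dict[tuple[str, str], set[ResidueKey]]
    epitope_shared: set[ResidueKey]
    epitope_chain: dict[str, set[ResidueKey]]
    epitope_interchain: set[ResidueKey]
    epitope_cdr_all: set[ResidueKey]
    epitope_cdr_individuals: set[ResidueKey]
    epitope_intercdr: set[ResidueKey]
    epitope_fw: set[ResidueKey]
    epitope_extracdr: set[ResidueKey]
    epitope_intercdr_fw: set[ResidueKey]


def _epitope_against(
    ag_atoms: list[AtomRecord],
    ag_monomer: SasaResult,
    partner_atoms: list[AtomRecord],
    probe: float,
    n_points: int,
) -> set[ResidueKey]:
    """Antigen residues buried by ``partner_atoms`` in a reduced system."""
    if not partner_atoms:
        return set()
    cplx = compute_sasa(ag_atoms + partner_atoms, probe, n_points)
    exposed_in_cplx = {
        a for a, m in zip(cplx.atoms, cplx.exposed_mask) if m
    }
    out: set[ResidueKey] = set()
    for atom, exposed in zip(ag_monomer.atoms, ag_monomer.exposed_mask):
        if exposed and atom not in exposed_in_cplx:
            out.add(atom.residue)
    return out


def decompose_epitope(
    cs: ComplexStructure,
    sets: InterfaceSets,
    scheme: RegionScheme = DEFAULT_SCHEME,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> SubEpitopeDecomposition:
    """Run reduced-system burial for each CDR / chain / framework subset.

    Each reduced system keeps the antigen plus one antibody part (a single
    CDR, all CDRs, one chain, or the framework) and recomputes which antigen
    residues lose all exposure, exactly as for the full complex.
    """
    ag = cs.ag_atoms
    ag_monomer = sets.ag_sasa
    regions = {a: assign_region(a.residue, scheme) for a in cs.ab_atoms}

    cdr_atoms: dict[str, list[AtomRecord]] = {lab: [] for lab in CDR_LABELS}
    chain_atoms: dict[str, list[AtomRecord]] = {"H": [], "L": []}
    fw_atoms: list[AtomRecord] = []
    for atom, label in regions.items():
        chain_atoms["H" if atom.residue.role == "heavy" else "L"].append(atom)
        if label in cdr_atoms:
            cdr_atoms[label].append(atom)
        else:
            fw_atoms.append(atom)

    epi_cdr: dict[str, set[ResidueKey]] = {}
    for lab in CDR_LABELS:
        if not cdr_atoms[lab]:
            log.warning("CDR %s has no atoms; its epitope set is empty", lab)
            epi_cdr[lab] = set()
        else:
            epi_cdr[lab] = _epitope_against(ag, ag_monomer, cdr_atoms[lab], probe, n_points)

    shared_pairs: dict[tuple[str, str], set[ResidueKey]] = {}
    for i, a in enumerate(CDR_LABELS):
        for b in CDR_LABELS[i + 1:]:
            inter = epi_cdr[a] & epi_cdr[b]
            if inter:
                shared_pairs[(a, b)] = inter
    shared = set().union(*shared_pairs.values()) if shared_pairs else set()

    epi_chain = {
        k: _epitope_against(ag, ag_monomer, chain_atoms[k], probe, n_points)
        for k in ("H", "L")
    }
    epitope = sets.epitope
    interchain = epitope - (epi_chain["H"] | epi_chain["L"])

    all_cdr = [a for lab in CDR_LABELS for a in cdr_atoms[lab]]
    epi_cdr_all = _epitope_against(ag, ag_monomer, all_cdr, probe, n_points)
    epi_cdr_ind = set().union(*epi_cdr.values()) if epi_cdr else set()
    intercdr = epi_cdr_all - epi_cdr_ind

    epi_fw = _epitope_against(ag, ag_monomer, fw_atoms, probe, n_points)
    extracdr = epitope - epi_cdr_ind
    intercdr_fw = extracdr - (epi_fw | intercdr | interchain)

    return SubEpitopeDecomposition(
        epitope=epitope,
        epitope_cdr=epi_cdr,
        epitope_shared_pairs=shared_pairs,
        epitope_shared=shared,
        epitope_chain=epi_chain,
        epitope_interchain=interchain,
        epitope_cdr_all=epi_cdr_all,
        epitope_cdr_individuals=epi_cdr_ind,
        epitope_intercdr=intercdr,
        epitope_fw=epi_fw,
        epitope_extracdr=extracdr,
        epitope_intercdr_fw=intercdr_fw,
    )


@dataclass
class ExposednessProfile:
    """Epitope split by the largest probe that can still reach each residue."""

    exposed_at: dict[float, set[ResidueKey]]
    deep: set[ResidueKey]
    medium: set[ResidueKey]
    superficial: set[ResidueKey]
    fractions: dict[str, float] = field(default_factory=dict)
    defined: bool = True


def exposedness_profile(
    ag_atoms: list[AtomRecord],
    epitope: set[ResidueKey],
    probes: tuple[float, float, float] = EXPOSEDNESS_PROBES,
    n_points: int = 4000,
) -> ExposednessProfile:
    """Classify epitope residues as deep / medium / superficial.

    ``deep`` residues are reachable only by the water probe, ``medium`` by
    the CDR-sized probe, ``superficial`` by the quasi-planar probe.  The
    exposed sets are nested by construction (each larger-probe set is
    intersected with the previous one: exact-geometry nesting is guaranteed,
    and the intersection removes any sampling noise that would violate it).
    A denser point set than for burial is used because the accessible cone
    of a large probe is narrow.
    """
    p1, p2, p3 = sorted(probes)
    exposed: dict[float, set[ResidueKey]] = {}
    prev: set[ResidueKey] | None = None
    for p in (p1, p2, p3):
        res = compute_sasa(ag_atoms, p, n_points).exposed_residues()
        if prev is not None:
            res &= prev
        exposed[p] = res
        prev = res

    deep = epitope & (exposed[p1] - exposed[p2])
    medium = epitope & (exposed[p2] - exposed[p3])
    superficial = epitope & exposed[p3]
    if epitope:
        n = len(epitope)
        fractions = {
            "deep": len(deep) / n,
            "medium": len(medium) / n,
            "superficial": len(superficial) / n,
        }
        defined = True
    else:
        log.warning("empty epitope: exposedness fractions undefined")
        fractions = {}
        defined = False
    return ExposednessProfile(
        exposed_at=exposed,
        deep=deep,
        medium=medium,
        superficial=superficial,
        fractions=fractions,
        defined=defined,
    )
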