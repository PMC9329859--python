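"""Epitope surface topology: patches, linear stretches, secondary structure.

The epitope surface is split into connected components over an atom graph:
nodes are interfacial epitope atoms within a pruning distance (4 Angstrom)
of any paratope interfacial atom, and two atoms are connected when their
solvent-expanded spheres overlap (center distance <= r_i + r_j + 2*probe),
i.e. when they share contiguous accessible surface.  Component areas are
buried-area sums and components below 5% of the total epitope area are
discarded as spurious fragments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio.PDB.DSSP import make_dssp_dict
from scipy.spatial import cKDTree

from .sasa import InterfaceSets
from .structures import AtomRecord, ResidueKey, coords_array

log = logging.getLogger(__name__)


@dataclass
class PatchSet:
    """Connected components of the epitope contact surface."""

    components: list[tuple[set[AtomRecord], float]]   # (atoms, area), area desc
    kept_components: list[tuple[set[AtomRecord], float]]
    total_area: float
    largest_fraction: float
    empty: bool = False

    @property
    def n_patches(self) -> int:
        return len(self.kept_components)

    def kept_residues(self) -> list[set[ResidueKey]]:
        return [{a.residue for a in atoms} for atoms, _ in self.kept_components]


def epitope_patches(
    sets: InterfaceSets,
    prune_dist: float = 4.0,
    min_fraction: float = 0.05,
) -> PatchSet:
    """Split the epitope contact surface into area-weighted patches."""
    epi_atoms = sorted(sets.interfacial_ag, key=lambda a: a.serial)
    para_atoms = sorted(sets.interfacial_ab, key=lambda a: a.serial)
    if not epi_atoms or not para_atoms:
        log.warning("no interfacial atoms: empty patch set")
        return PatchSet([], [], 0.0, 0.0, empty=True)

    exyz = coords_array(epi_atoms)
    pxyz = coords_array(para_atoms)
    near = cKDTree(pxyz).query_ball_point(exyz, r=prune_dist)
    nodes = [a for a, hits in zip(epi_atoms, near) if hits]
    if not nodes:
        log.warning("all epitope atoms pruned: empty patch set")
        return PatchSet([], [], 0.0, 0.0, empty=True)

    nxyz = coords_array(nodes)
    radii = np.array([a.vdw_radius for a in nodes])
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(nodes)
    pairs = cKDTree(nxyz).query_pairs(r=float(2 * radii.max() + 2 * sets.probe))
    for i, j in pairs:
        if np.linalg.norm(nxyz[i] - nxyz[j]) <= radii[i] + radii[j] + 2 * sets.probe:
            g.add_edge(nodes[i], nodes[j])

    comps = []
    for comp in nx.connected_components(g):
        area = sum(sets.buried_area.get(a, 0.0) for a in comp)
        comps.append((set(comp), area))
    comps.sort(key=lambda t: (-t[1], min(a.serial for a in t[0])))
    total = sum(area for _, area in comps)
    kept = [(atoms, area) for atoms, area in comps if total > 0 and area >= min_fraction * total]
    largest = comps[0][1] / total if total > 0 else 0.0
    return PatchSet(comps, kept, total, largest)


@dataclass
class StretchDecomposition:
    """Sequence-continuous epitope segments, one chain never bridged."""

    stretches: list[list[ResidueKey]]
    gap_tolerance: int

    @property
    def lengths(self) -> list[int]:
        return [len(s) for s in self.stretches]

    @property
    def longest(self) -> int:
        return max(self.lengths, default=0)


def linear_stretches(
    epitope: set[ResidueKey],
    ag_sequence_order: list[ResidueKey],
    gap_tolerance: int = 1,
) -> StretchDecomposition:
    """Maximal epitope runs allowing up to ``gap_tolerance`` sequence gaps.

    Sequence positions follow the residue ordering per chain; numbering
    gaps (missing residues in the model) count as gaps of their numeric
    size.  Stretch lengths count epitope residues only.
    """
    by_chain: dict[str, list[ResidueKey]] = {}
    for res in ag_sequence_order:
        by_chain.setdefault(res.chain_id, []).append(res)

    stretches: list[list[ResidueKey]] = []
    for chain_res in by_chain.values():
        ordered = sorted(chain_res)
        positions: dict[ResidueKey, int] = {}
        pos = 0
        prev = None
        for res in ordered:
            if prev is not None:
                step = res.number - prev.number
                pos += max(1, step)
            positions[res] = pos
            prev = res
        epi = [r for r in ordered if r in epitope]
        current: list[ResidueKey] = []
        last_pos = None
        for res in epi:
            p = positions[res]
            if last_pos is not None and p - last_pos - 1 > gap_tolerance:
                stretches.append(current)
                current = []
            current.append(res)
            last_pos = p
        if current:
            stretches.append(current)
    return StretchDecomposition(stretches, gap_tolerance)


#: DSSP code grouping into helix / strand / coil classes.
SS_GROUPS = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


@dataclass
class SsComposition:
    epitope_fractions: dict[str, float]
    antigen_fractions: dict[str, float]
    classes: dict[ResidueKey, str] = field(default_factory=dict)


def ss_composition(
    epitope: set[ResidueKey],
    dssp_file,
    ag_residues: list[ResidueKey],
) -> SsComposition:
    """Helix/strand/coil composition of the epitope vs the whole antigen.

    ``dssp_file`` is a standard DSSP output file covering the antigen
    chains; residues missing from it count as coil (with a warning).
    """
    dssp_dict, _ = make_dssp_dict(str(dssp_file))
    lookup: dict[tuple[str, int, str], str] = {}
    for (chain, res_id), values in dssp_dict.items():
        _, num, icode = res_id
        lookup[(chain, num, icode.strip())] = values[1]

    classes: dict[ResidueKey, str] = {}
    for res in ag_residues:
        code = lookup.get((res.chain_id, res.number, res.icode))
        if code is None:
            log.warning("residue %s missing from DSSP file: counted as coil", res)
            classes[res] = "C"
        else:
            classes[res] = SS_GROUPS.get(code, "C")

    def fractions(residues) -> dict[str, float]:
        residues = [r for r in residues if r in classes]
        n = len(residues)
        if n == 0:
            return {"H": 0.0, "E": 0.0, "C": 0.0}
        return {
            cls: sum(1 for r in residues if classes[r] == cls) / n
            for cls in ("H", "E", "C")
        }

    return SsComposition(
        epitope_fractions=fractions(epitope),
        antigen_fractions=fractions(ag_residues),
        classes=classes,
    )
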