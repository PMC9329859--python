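"""Hydrophobic cluster detection at the antibody-antigen interface.

Cross-interface carbon pairs closer than ``cc_dist`` are candidate
hydrophobic contacts.  A candidate is rejected when a nearby O/N atom lies
geometrically *between* the two carbons, which is decided by a two-step
cosine test: with Cp the paratope carbon, Ce the epitope carbon and P the
polar atom,

    d1 = unit(Cp->Ce) . unit(Cp->P)

d1 < ``first_dot`` (0.85) clears P (it is off-axis); otherwise P is either
between the carbons or behind Ce, and

    d2 = unit(Cp->Ce) . unit(Ce->P)

d2 < ``second_dot`` (-0.2) confirms P is between them (shielding); a larger
value means P sits behind the epitope carbon and the pair stays clear.
Cleared pairs become edges of an undirected graph whose connected components
are the hydrophobic clusters.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structures import (
    AtomRecord,
    RegionScheme,
    ResidueKey,
    DEFAULT_SCHEME,
    assign_region,
    coords_array,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HydrophobicParams:
    """Geometric thresholds of the carbon-cluster protocol.

    ``cc_dist`` is robust in the 4-5 Angstrom range; the dot thresholds are
    cosines.  ``polar_search_dist`` bounds the search for shielding O/N
    atoms around either carbon of a candidate pair.
    """

    cc_dist: float = 5.0
    first_dot: float = 0.85
    second_dot: float = -0.2
    polar_search_dist: float = 5.0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.second_dot <= 1.0 and -1.0 <= self.first_dot <= 1.0):
            raise ValueError("dot thresholds must be cosines in [-1, 1]")
        if self.cc_dist <= 0 or self.polar_search_dist <= 0:
            raise ValueError("distances must be positive")


@dataclass
class CarbonContact:
    """One candidate carbon-carbon contact across the interface."""

    c_paratope: AtomRecord
    c_epitope: AtomRecord
    distance: float
    shielded_by: AtomRecord | None = None
    cleared: bool = False


def candidate_pairs(
    epitope_carbons: list[AtomRecord],
    paratope_carbons: list[AtomRecord],
    params: HydrophobicParams = HydrophobicParams(),
) -> list[CarbonContact]:
    """All cross-interface carbon pairs within ``cc_dist``."""
    if not epitope_carbons or not paratope_carbons:
        return []
    exyz = coords_array(epitope_carbons)
    pxyz = coords_array(paratope_carbons)
    pairs = cKDTree(pxyz).query_ball_tree(cKDTree(exyz), r=params.cc_dist)
    contacts = []
    for ip, eidx in enumerate(pairs):
        for ie in sorted(eidx):
            d = float(np.linalg.norm(pxyz[ip] - exyz[ie]))
            contacts.append(
                CarbonContact(paratope_carbons[ip], epitope_carbons[ie], d)
            )
    return contacts


def shielding_test(
    pair: CarbonContact,
    polar_atoms: list[AtomRecord],
    params: HydrophobicParams = HydrophobicParams(),
) -> CarbonContact:
    """Decide whether any nearby polar atom shields the contact.

    Mutates and returns ``pair`` with ``cleared`` / ``shielded_by`` set.
    Polar candidates are O/N atoms within ``polar_search_dist`` of either
    carbon, tried nearest-to-midpoint first so the recorded shielder is
    deterministic.
    """
    cp = pair.c_paratope.coords
    ce = pair.c_epitope.coords
    axis = ce - cp
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        log.warning(
            "coincident carbons %s / %s: pair rejected",
            pair.c_paratope, pair.c_epitope,
        )
        pair.cleared = False
        return pair
    axis = axis / norm
    mid = 0.5 * (cp + ce)

    candidates = []
    for p in polar_atoms:
        if p is pair.c_paratope or p is pair.c_epitope:
            continue
        dp = min(
            np.linalg.norm(p.coords - cp), np.linalg.norm(p.coords - ce)
        )
        if dp <= params.polar_search_dist:
            candidates.append((float(np.linalg.norm(p.coords - mid)), p))
    candidates.sort(key=lambda t: t[0])

    for _, p in candidates:
        v1 = p.coords - cp
        n1 = np.linalg.norm(v1)
        if n1 < 1e-9:
            continue
        d1 = float(axis @ (v1 / n1))
        if d1 < params.first_dot:
            continue  # off-axis: cannot shield
        v2 = p.coords - ce
        n2 = np.linalg.norm(v2)
        if n2 < 1e-9:
            continue
        d2 = float(axis @ (v2 / n2))
        if d2 < params.second_dot:
            pair.shielded_by = p
            pair.cleared = False
            return pair
        # otherwise P is behind the epitope carbon: does not shield
    pair.cleared = True
    return pair


def evaluate_contacts(
    epitope_carbons: list[AtomRecord],
    paratope_carbons: list[AtomRecord],
    polar_atoms: list[AtomRecord],
    params: HydrophobicParams = HydrophobicParams(),
) -> list[CarbonContact]:
    """Candidate enumeration followed by the shielding test on each pair."""
    contacts = candidate_pairs(epitope_carbons, paratope_carbons, params)
    if not contacts or not polar_atoms:
        for c in contacts:
            c.cleared = True
        return contacts
    pxyz = coords_array(polar_atoms)
    tree = cKDTree(pxyz)
    for c in contacts:
        idx = set(tree.query_ball_point(c.c_paratope.coords, params.polar_search_dist))
        idx |= set(tree.query_ball_point(c.c_epitope.coords, params.polar_search_dist))
        shielding_test(c, [polar_atoms[i] for i in sorted(idx)], params)
    return contacts


@dataclass
class HydrophobicClusterSet:
    """Connected components of the cleared carbon-contact graph."""

    clusters: list[set[AtomRecord]]            # size-descending
    contacts: list[CarbonContact] = field(default_factory=list)

    @property
    def biggest(self) -> set[AtomRecord]:
        return self.clusters[0] if self.clusters else set()

    @property
    def shielding_attributions(self) -> dict[AtomRecord, int]:
        """Rejections per polar atom, for the polar-role classification."""
        counts: Counter[AtomRecord] = Counter()
        for c in self.contacts:
            if c.shielded_by is not None:
                counts[c.shielded_by] += 1
        return dict(counts)

    def cluster_of(self, atom: AtomRecord) -> int | None:
        for i, cl in enumerate(self.clusters):
            if atom in cl:
                return i
        return None


def build_clusters(contacts: list[CarbonContact]) -> HydrophobicClusterSet:
    """Graph the cleared contacts and extract connected components.

    Components are ordered by size descending, ties broken by the lowest
    atom serial they contain.
    """
    g: nx.Graph = nx.Graph()
    for c in contacts:
        if c.cleared:
            g.add_edge(c.c_paratope, c.c_epitope)
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda s: (-len(s), min(a.serial for a in s)))
    return HydrophobicClusterSet(clusters=comps, contacts=list(contacts))


def find_hydrophobic_clusters(
    epitope_carbons: list[AtomRecord],
    paratope_carbons: list[AtomRecord],
    polar_atoms: list[AtomRecord],
    params: HydrophobicParams = HydrophobicParams(),
) -> HydrophobicClusterSet:
    """Full protocol: candidates, shielding, graph, components."""
    contacts = evaluate_contacts(
        epitope_carbons, paratope_carbons, polar_atoms, params
    )
    return build_clusters(contacts)


@dataclass
class ClusterStats:
    """Descriptors of the biggest hydrophobic cluster."""

    n_clusters: int
    n_atoms: int
    n_residues: int
    cdrs: set[str]
    n_cdrs: int
    cdr_pairs: set[tuple[str, str]]
    aa_by_atoms: dict[str, int]        # carbon count contributed per aa type
    aa_by_residues: dict[str, int]     # residue count per aa type
    second_to_first_ratio: float
    ss_classes: dict[str, int] = field(default_factory=dict)
    residues: set[ResidueKey] = field(default_factory=set)


def cluster_stats(
    clusters: HydrophobicClusterSet,
    scheme: RegionScheme = DEFAULT_SCHEME,
    ss_classes: dict[ResidueKey, str] | None = None,
) -> ClusterStats:
    """Composition and CDR participation of the biggest cluster.

    Amino-acid composition is reported twice: by contributed carbon atoms
    and by distinct residues.  ``ss_classes`` maps epitope residues to
    secondary-structure classes when available.
    """
    biggest = clusters.biggest
    residues = {a.residue for a in biggest}
    aa_atoms: Counter[str] = Counter(a.residue.aa3 for a in biggest)
    aa_res: Counter[str] = Counter(r.aa3 for r in residues)
    cdrs = set()
    for r in residues:
        label = assign_region(r, scheme)
        if label in ("H1", "H2", "H3", "L1", "L2", "L3"):
            cdrs.add(label)
    pairs = {
        (a, b)
        for i, a in enumerate(sorted(cdrs))
        for b in sorted(cdrs)[i + 1:]
    }
    ratio = (
        len(clusters.clusters[1]) / len(clusters.clusters[0])
        if len(clusters.clusters) > 1
        else 0.0
    )
    ss: Counter[str] = Counter()
    if ss_classes:
        for r in residues:
            if r.role == "antigen":
                ss[ss_classes.get(r, "C")] += 1
    return ClusterStats(
        n_clusters=len(clusters.clusters),
        n_atoms=len(biggest),
        n_residues=len(residues),
        cdrs=cdrs,
        n_cdrs=len(cdrs),
        cdr_pairs=pairs,
        aa_by_atoms=dict(aa_atoms),
        aa_by_residues=dict(aa_res),
        second_to_first_ratio=ratio,
        ss_classes=dict(ss),
        residues=residues,
    )
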