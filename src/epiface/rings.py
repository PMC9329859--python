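"""Aromatic-ring geometry and pi-stacking / pi-ion detection.

Ring planes are least-squares fits: the normal is the smallest principal
axis of the centered ring coordinates, so it is defined up to sign and all
criteria use absolute dot products.  Trp is treated as one bicyclic ring
system with a single centroid and normal.  A parallel stacking requires
near-collinear normals (|cos| > 0.85) and centroids within 5 Angstrom; an
ion faces a ring when it is within 5 Angstrom of the centroid and the
centroid-to-ion direction is within |cos| > 0.70 of the normal.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .chemistry import RING_ATOMS
from .hydrophobic import HydrophobicClusterSet
from .polar import InteractionRecord, InteractionTable
from .structures import AtomRecord, ResidueKey, classify_chemistry

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RingParams:
    pi_pi_dist: float = 5.0
    pi_pi_dot: float = 0.85
    pi_ion_dist: float = 5.0
    pi_ion_dot: float = 0.70

    def __post_init__(self) -> None:
        if not (0 <= self.pi_pi_dot <= 1 and 0 <= self.pi_ion_dot <= 1):
            raise ValueError("dot thresholds must be in [0, 1]")


@dataclass
class AromaticRing:
    """Plane fit of one aromatic ring system (Phe/Tyr/Trp/His)."""

    residue: ResidueKey
    member_atoms: list[AtomRecord]
    centroid: np.ndarray
    normal: np.ndarray                  # unit vector, sign-free


def ring_geometry(residue_atoms: list[AtomRecord]) -> AromaticRing | None:
    """Fit centroid and plane normal of a residue's aromatic ring.

    Returns None (with a warning) when ring atoms are missing.  The normal
    is the singular vector of the centered coordinates with the smallest
    singular value.
    """
    if not residue_atoms:
        return None
    residue = residue_atoms[0].residue
    wanted = RING_ATOMS.get(residue.aa3)
    if wanted is None:
        return None
    by_name = {a.name: a for a in residue_atoms if a.residue == residue}
    members = [by_name[n] for n in wanted if n in by_name]
    if len(members) < len(wanted):
        log.warning("ring atoms missing for %s: ring skipped", residue)
        return None
    xyz = np.array([a.coords for a in members])
    centroid = xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(xyz - centroid)
    normal = vt[-1]
    normal = normal / np.linalg.norm(normal)
    return AromaticRing(residue, members, centroid, normal)


def rings_of(atoms: list[AtomRecord]) -> list[AromaticRing]:
    """All complete aromatic rings found among ``atoms``, grouped by residue."""
    groups: dict[ResidueKey, list[AtomRecord]] = defaultdict(list)
    for a in atoms:
        if a.residue.aa3 in RING_ATOMS:
            groups[a.residue].append(a)
    out = []
    for res in sorted(groups):
        ring = ring_geometry(groups[res])
        if ring is not None:
            out.append(ring)
    return out


def detect_pi_pi(
    rings_ab: list[AromaticRing],
    rings_ag: list[AromaticRing],
    params: RingParams = RingParams(),
) -> list[InteractionRecord]:
    """Parallel-stacked cross-interface ring pairs."""
    records = []
    for ra in rings_ab:
        for rg in rings_ag:
            d = float(np.linalg.norm(ra.centroid - rg.centroid))
            if d >= params.pi_pi_dist:
                continue
            dot = abs(float(ra.normal @ rg.normal))
            if dot > params.pi_pi_dot:
                records.append(
                    InteractionRecord(
                        "pi_pi",
                        ab_atom=None,
                        ag_atom=None,
                        distance=d,
                        ab_residue=ra.residue,
                        ag_residue=rg.residue,
                        geometry={"normal_dot": dot},
                    )
                )
    return records


def detect_pi_ion(
    rings: list[AromaticRing],
    charged_atoms: list[AtomRecord],
    params: RingParams = RingParams(),
) -> list[InteractionRecord]:
    """Ions facing a ring surface, typed pi_cation / pi_anion by ion sign.

    Only cross-interface ring/ion pairs are considered (a ring on one
    molecule with a charged atom of the other).
    """
    records = []
    for ring in rings:
        ring_is_ag = ring.residue.role == "antigen"
        for ion in charged_atoms:
            ion_is_ag = ion.residue.role == "antigen"
            if ring_is_ag == ion_is_ag:
                continue
            flags = classify_chemistry(ion)
            if not (flags.cationic or flags.anionic):
                continue
            v = ion.coords - ring.centroid
            d = float(np.linalg.norm(v))
            if d >= params.pi_ion_dist or d < 1e-9:
                continue
            dot = abs(float((v / d) @ ring.normal))
            if dot <= params.pi_ion_dot:
                continue
            kind = "pi_cation" if flags.cationic else "pi_anion"
            records.append(
                InteractionRecord(
                    kind,
                    ab_atom=None if ion_is_ag else ion,
                    ag_atom=ion if ion_is_ag else None,
                    distance=d,
                    ab_residue=ring.residue if not ring_is_ag else ion.residue,
                    ag_residue=ring.residue if ring_is_ag else ion.residue,
                    geometry={"axis_dot": dot},
                )
            )
    return records


INTERACTION_ROLES = (
    "hydrophobic_cluster",
    "hbond",
    "salt_bridge",
    "water_mediated",
    "pi_pi",
    "pi_cation",
    "pi_anion",
)


@dataclass
class ResidueRoleProfile:
    """Interaction-role sets per interface residue of selected types."""

    roles: dict[ResidueKey, set[str]]
    frequencies: dict[str, dict[str, float]] = field(default_factory=dict)

    def residues_with(self, role: str) -> set[ResidueKey]:
        return {r for r, s in self.roles.items() if role in s}


def residue_role_profiles(
    interface_residues: set[ResidueKey],
    interactions: InteractionTable,
    clusters: HydrophobicClusterSet,
    target_aa: tuple[str, ...] = ("TYR", "TRP", "PHE", "SER"),
) -> ResidueRoleProfile:
    """Label target-type interface residues by the interactions they join.

    A residue joins a role when any of its atoms participates; frequencies
    are reported separately for the paratope (antibody side) and epitope.
    """
    targets = {r for r in interface_residues if r.aa3 in target_aa}
    roles: dict[ResidueKey, set[str]] = {r: set() for r in targets}

    cluster_residues = {a.residue for cl in clusters.clusters for a in cl}
    for r in targets:
        if r in cluster_residues:
            roles[r].add("hydrophobic_cluster")
    for rec in interactions.records:
        for res in (rec.ab_residue, rec.ag_residue):
            if res in roles:
                roles[res].add(rec.kind)

    freq: dict[str, dict[str, float]] = {}
    for side, pred in (
        ("paratope", lambda r: r.role in ("heavy", "light")),
        ("epitope", lambda r: r.role == "antigen"),
    ):
        side_res = [r for r in targets if pred(r)]
        n = len(side_res)
        if n == 0:
            continue
        counts = {role: 0 for role in INTERACTION_ROLES + ("none",)}
        for r in side_res:
            if not roles[r]:
                counts["none"] += 1
            for role in roles[r]:
                counts[role] += 1
        freq[side] = {k: v / n for k, v in counts.items()}
    return ResidueRoleProfile(roles=roles, frequencies=freq)
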