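"""Geometric detection of polar interactions across the interface.

A heavy-atom distance criterion (3.9 Angstrom) with donor/acceptor typing
stands in for a full hydrogen-bond geometry: hydrogens are absent from the
model, so angular terms cannot be evaluated.  Salt bridges are the subset of
those contacts formed between a side-chain cationic nitrogen (Arg/Lys) and a
side-chain anionic oxygen (Asp/Glu); they are reported once, as salt
bridges, never double-counted as plain hydrogen bonds.  A crystallographic
water that is simultaneously within the bond distance of polar atoms on
both sides mediates a water bridge.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import AtomRecord, ResidueKey, classify_chemistry, coords_array


@dataclass(frozen=True)
class PolarParams:
    hbond_dist: float = 3.9

    def __post_init__(self) -> None:
        if self.hbond_dist <= 0:
            raise ValueError("hbond distance must be positive")


@dataclass
class InteractionRecord:
    """One typed interaction with its participants and geometry."""

    kind: str                     # hbond | salt_bridge | water_mediated | pi_pi | pi_cation | pi_anion
    ab_atom: AtomRecord | None
    ag_atom: AtomRecord | None
    distance: float
    water: AtomRecord | None = None
    ab_residue: ResidueKey | None = None
    ag_residue: ResidueKey | None = None
    geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ab_residue is None and self.ab_atom is not None:
            self.ab_residue = self.ab_atom.residue
        if self.ag_residue is None and self.ag_atom is not None:
            self.ag_residue = self.ag_atom.residue


@dataclass
class InteractionTable:
    """All typed interaction records of one complex."""

    records: list[InteractionRecord] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[InteractionRecord]:
        return [r for r in self.records if r.kind == kind]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = defaultdict(int)
        for r in self.records:
            out[r.kind] += 1
        return dict(out)

    def atoms_in_polar_bonds(self) -> set[AtomRecord]:
        out: set[AtomRecord] = set()
        for r in self.records:
            if r.kind in ("hbond", "salt_bridge", "water_mediated"):
                if r.ab_atom is not None:
                    out.add(r.ab_atom)
                if r.ag_atom is not None:
                    out.add(r.ag_atom)
        return out

    def extend(self, records: list[InteractionRecord]) -> None:
        self.records.extend(records)

    def to_dataframe(self) -> pd.DataFrame:
        """Flat table: one row per typed interaction record."""
        rows = []
        for r in self.records:
            rows.append({
                "type": r.kind,
                "ab_chain": r.ab_residue.chain_id if r.ab_residue else "",
                "ab_resnum": r.ab_residue.number if r.ab_residue else "",
                "ab_icode": r.ab_residue.icode if r.ab_residue else "",
                "ab_aa3": r.ab_residue.aa3 if r.ab_residue else "",
                "ab_atom": r.ab_atom.name if r.ab_atom else "",
                "ag_chain": r.ag_residue.chain_id if r.ag_residue else "",
                "ag_resnum": r.ag_residue.number if r.ag_residue else "",
                "ag_icode": r.ag_residue.icode if r.ag_residue else "",
                "ag_aa3": r.ag_residue.aa3 if r.ag_residue else "",
                "ag_atom": r.ag_atom.name if r.ag_atom else "",
                "water": r.water.residue.number if r.water else "",
                "distance": round(r.distance, 3),
            })
        return pd.DataFrame(rows)


def detect_hbonds(
    ab_polar: list[AtomRecord],
    ag_polar: list[AtomRecord],
    params: PolarParams = PolarParams(),
) -> list[InteractionRecord]:
    """Donor/acceptor-compatible cross-interface pairs within the cutoff.

    Each unordered pair is reported once; compatibility means one side can
    donate while the other can accept (either direction).
    """
    if not ab_polar or not ag_polar:
        return []
    ab_xyz = coords_array(ab_polar)
    ag_xyz = coords_array(ag_polar)
    flags_ab = [classify_chemistry(a) for a in ab_polar]
    flags_ag = [classify_chemistry(a) for a in ag_polar]
    pairs = cKDTree(ab_xyz).query_ball_tree(cKDTree(ag_xyz), r=params.hbond_dist)
    records = []
    for ia, ag_idx in enumerate(pairs):
        fa = flags_ab[ia]
        for ig in sorted(ag_idx):
            fg = flags_ag[ig]
            ok = (fa.hbond_donor_heavy and fg.hbond_acceptor_heavy) or (
                fa.hbond_acceptor_heavy and fg.hbond_donor_heavy
            )
            if not ok:
                continue
            d = float(np.linalg.norm(ab_xyz[ia] - ag_xyz[ig]))
            records.append(
                InteractionRecord("hbond", ab_polar[ia], ag_polar[ig], d)
            )
    return records


def detect_salt_bridges(records: list[InteractionRecord]) -> list[InteractionRecord]:
    """Reclassify cation-N / anion-O contacts as salt bridges, in place.

    The typing rule is exhaustive: only Arg/Lys side-chain nitrogens against
    Asp/Glu side-chain oxygens qualify (His does not).
    """
    for r in records:
        if r.kind != "hbond" or r.ab_atom is None or r.ag_atom is None:
            continue
        fa = classify_chemistry(r.ab_atom)
        fg = classify_chemistry(r.ag_atom)
        if (fa.cationic and fg.anionic) or (fa.anionic and fg.cationic):
            r.kind = "salt_bridge"
    return records


@dataclass
class WaterBridgeSummary:
    records: list[InteractionRecord]
    n_waters: int                      # distinct bridging waters
    no_water_structure: bool = False


def detect_water_mediated(
    waters: list[AtomRecord],
    ab_polar: list[AtomRecord],
    ag_polar: list[AtomRecord],
    params: PolarParams = PolarParams(),
) -> WaterBridgeSummary:
    """Waters hydrogen-bonded to polar atoms of both molecules at once.

    One record per (water, antibody atom, antigen atom) triple; the number
    of distinct bridging waters is reported alongside.  Detection is
    symmetric in the two molecules.
    """
    if not waters:
        return WaterBridgeSummary([], 0, no_water_structure=True)
    if not ab_polar or not ag_polar:
        return WaterBridgeSummary([], 0)
    w_xyz = coords_array(waters)
    tree_ab = cKDTree(coords_array(ab_polar))
    tree_ag = cKDTree(coords_array(ag_polar))
    near_ab = tree_ab.query_ball_point(w_xyz, r=params.hbond_dist)
    near_ag = tree_ag.query_ball_point(w_xyz, r=params.hbond_dist)
    records = []
    bridging = set()
    for iw, water in enumerate(waters):
        if not near_ab[iw] or not near_ag[iw]:
            continue
        bridging.add(water)
        for ia in sorted(near_ab[iw]):
            for ig in sorted(near_ag[iw]):
                d = float(
                    np.linalg.norm(w_xyz[iw] - coords_array([ab_polar[ia]])[0])
                    + np.linalg.norm(w_xyz[iw] - coords_array([ag_polar[ig]])[0])
                )
                records.append(
                    InteractionRecord(
                        "water_mediated",
                        ab_polar[ia],
                        ag_polar[ig],
                        d,
                        water=water,
                    )
                )
    return WaterBridgeSummary(records, len(bridging))


@dataclass
class PolarRole:
    """Functional role of one interfacial polar atom."""

    atom: AtomRecord
    location: str                      # backbone | side_chain
    role: str                          # polar_bond | shielding | both | none


ROLE_ORDER = ("polar_bond", "shielding", "both", "none")


def polar_roles(
    interfacial_polar: list[AtomRecord],
    interactions: InteractionTable,
    shielding_attributions: dict[AtomRecord, int],
) -> tuple[list[PolarRole], dict[tuple[str, str], dict[str, float]]]:
    """Classify each polar atom and tabulate role fractions per stratum.

    Strata are (molecule in {Ab, Ag}) x (backbone / side_chain); within each
    stratum the four role fractions sum to one.
    """
    bonded = interactions.atoms_in_polar_bonds()
    roles: list[PolarRole] = []
    strata: dict[tuple[str, str], list[str]] = defaultdict(list)
    for atom in interfacial_polar:
        in_bond = atom in bonded
        shields = shielding_attributions.get(atom, 0) > 0
        if in_bond and shields:
            role = "both"
        elif in_bond:
            role = "polar_bond"
        elif shields:
            role = "shielding"
        else:
            role = "none"
        loc = "backbone" if atom.is_backbone else "side_chain"
        mol = "Ag" if atom.residue.role == "antigen" else "Ab"
        roles.append(PolarRole(atom, loc, role))
        strata[(mol, loc)].append(role)

    distribution: dict[tuple[str, str], dict[str, float]] = {}
    for key, vals in strata.items():
        n = len(vals)
        distribution[key] = {r: vals.count(r) / n for r in ROLE_ORDER}
    return roles, distribution
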