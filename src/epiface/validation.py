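"""Planted-truth verification: run every detector against a fixture manifest.

Given a parsed synthetic complex and its manifest, each planted entry is
checked against the corresponding detector: planted interactions must be
found (with the planted shielder attributed, for shielded carbon pairs) and
decoys must produce nothing.  Used by the test suite and the acceptance
script to measure recovery and false-positive rates.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hydrophobic import HydrophobicParams, evaluate_contacts
from .polar import PolarParams, detect_hbonds, detect_salt_bridges, detect_water_mediated
from .rings import RingParams, detect_pi_ion, detect_pi_pi, rings_of
from .structures import ComplexStructure, classify_chemistry


@dataclass
class PlantOutcome:
    kind: str
    decoy: bool
    ok: bool
    detail: str = ""


def _atom_lookup(cs: ComplexStructure):
    return {
        (a.residue.chain_id, a.residue.number, a.residue.icode, a.name): a
        for a in cs.atoms + cs.waters
    }


def _akey(ref: dict):
    return (ref["chain"], ref["number"], ref["icode"], ref["atom"])


def _rkey(ref: dict):
    return (ref["chain"], ref["number"], ref["icode"])


def verify_planted(
    cs: ComplexStructure,
    manifest: dict,
    hydrophobic_params: HydrophobicParams = HydrophobicParams(),
    polar_params: PolarParams = PolarParams(),
    ring_params: RingParams = RingParams(),
) -> list[PlantOutcome]:
    """Check every manifest ``planted`` entry against the detectors."""
    atoms = _atom_lookup(cs)
    ab_polar = [a for a in cs.ab_atoms if a.is_polar]
    ag_polar = [a for a in cs.ag_atoms if a.is_polar]
    hbonds = detect_salt_bridges(detect_hbonds(ab_polar, ag_polar, polar_params))
    waters = detect_water_mediated(cs.waters, ab_polar, ag_polar, polar_params)
    contacts = evaluate_contacts(
        [a for a in cs.ag_atoms if a.is_carbon],
        [a for a in cs.ab_atoms if a.is_carbon],
        [a for a in cs.atoms if a.is_polar],
        hydrophobic_params,
    )
    rings_ab = rings_of(cs.ab_atoms)
    rings_ag = rings_of(cs.ag_atoms)
    pi_pi = detect_pi_pi(rings_ab, rings_ag, ring_params)
    charged = [
        a for a in cs.atoms
        if classify_chemistry(a).cationic or classify_chemistry(a).anionic
    ]
    pi_ion = detect_pi_ion(rings_ab + rings_ag, charged, ring_params)

    outcomes: list[PlantOutcome] = []
    for entry in manifest.get("planted", []):
        kind = entry["type"]
        expect = entry.get("expect")
        refs = entry["atoms"]
        if kind in ("cc_pair", "shielded_cc_pair"):
            ep = atoms[_akey(refs["epitope_c"])]
            pp = atoms[_akey(refs["paratope_c"])]
            match = [
                c for c in contacts
                if c.c_epitope is ep and c.c_paratope is pp
            ]
            if expect == "shielded":
                shield = atoms[_akey(refs["shield"])]
                ok = (
                    len(match) == 1
                    and not match[0].cleared
                    and match[0].shielded_by is shield
                )
            elif expect:
                ok = len(match) == 1 and match[0].cleared
            else:
                ok = not match
        elif kind in ("hbond", "salt_bridge"):
            ab = atoms[_akey(refs["ab"])]
            ag = atoms[_akey(refs["ag"])]
            match = [
                r for r in hbonds
                if r.kind == kind and r.ab_atom is ab and r.ag_atom is ag
            ]
            ok = bool(match) == bool(expect)
        elif kind == "water_bridge":
            ab = atoms[_akey(refs["ab"])]
            ag = atoms[_akey(refs["ag"])]
            match = [
                r for r in waters.records
                if r.ab_atom is ab and r.ag_atom is ag
            ]
            ok = bool(match) == bool(expect)
        elif kind == "pi_pi":
            key = _rkey(refs["ag_ring"])
            match = [
                r for r in pi_pi
                if (r.ag_residue.chain_id, r.ag_residue.number,
                    r.ag_residue.icode) == key
            ]
            ok = bool(match) == bool(expect)
        elif kind in ("pi_cation", "pi_anion"):
            key = _rkey(refs["ring"])
            match = [
                r for r in pi_ion
                if r.kind == kind
                and (r.ag_residue.chain_id, r.ag_residue.number,
                     r.ag_residue.icode) == key
            ]
            ok = bool(match) == bool(expect)
        else:
            outcomes.append(PlantOutcome(kind, entry["decoy"], False, "unknown type"))
            continue
        outcomes.append(PlantOutcome(kind, entry["decoy"], ok))
    return outcomes


def recovery_rates(outcomes: list[PlantOutcome]) -> tuple[float, float]:
    """(fraction of planted interactions recovered, fraction of decoys
    correctly rejected)."""
    planted = [o for o in outcomes if not o.decoy]
    decoys = [o for o in outcomes if o.decoy]
    rec = sum(o.ok for o in planted) / len(planted) if planted else 1.0
    rej = sum(o.ok for o in decoys) / len(decoys) if decoys else 1.0
    return rec, rej
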