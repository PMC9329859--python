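"""Shared fixtures: parsed synthetic complexes with their manifests."""

from __future__ import annotations

import json

import pytest

from epiface.sasa import epitope_paratope
from epiface.structures import read_complex
from epiface.synthetic import make_planted_panel, make_slab_complex, plant_interaction


def residue_keyset(entries):
    """Manifest residue ids -> hashable (chain, number, icode) triples."""
    return {(d["chain"], d["number"], d["icode"]) for d in entries}


def residue_keys(residues):
    return {(r.chain_id, r.number, r.icode) for r in residues}


def atom_keys(atoms):
    return {
        (a.residue.chain_id, a.residue.number, a.residue.icode, a.name)
        for a in atoms
    }


def atom_keyset(entries):
    return {(d["chain"], d["number"], d["icode"], d["atom"]) for d in entries}


def atom_index(cs):
    """Lookup of parsed atoms by manifest atom id."""
    return {
        (a.residue.chain_id, a.residue.number, a.residue.icode, a.name): a
        for a in cs.atoms + cs.waters
    }


def load_fixture(builder, tmp_path, stem="fix", keep_waters=True):
    pdb, man = builder.write(tmp_path, stem=stem)
    cs = read_complex(pdb, ("H", "L"), {"A"}, keep_waters=keep_waters)
    with open(man) as fh:
        manifest = json.load(fh)
    return cs, manifest


@pytest.fixture(scope="session")
def slab(tmp_path_factory):
    """5x5 slab complex, parsed, with manifest and interface sets."""
    builder = make_slab_complex(5, gap=4.0, seed=11)
    cs, manifest = load_fixture(
        builder, tmp_path_factory.mktemp("slab"), "slab"
    )
    sets = epitope_paratope(cs)
    return cs, manifest, sets


@pytest.fixture(scope="session")
def planted_panel(tmp_path_factory):
    """All plant types plus decoys, parsed, with manifest."""
    builder = make_planted_panel(seed=7)
    return load_fixture(
        builder, tmp_path_factory.mktemp("panel"), "panel"
    )


@pytest.fixture(scope="session")
def slab_with_plants(tmp_path_factory):
    """Slab plus a hydrogen-bond and a salt-bridge plant (for the pipeline)."""
    builder = make_slab_complex(4, gap=4.0, seed=13)
    for kind in ("hbond", "salt_bridge", "water_bridge"):
        plant_interaction(builder, kind)
    return load_fixture(
        builder, tmp_path_factory.mktemp("slabp"), "slabp"
    )
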