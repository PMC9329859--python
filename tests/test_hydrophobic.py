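"""Carbon-cluster protocol: candidates, shielding geometry, components."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiface.hydrophobic import (
    CarbonContact,
    HydrophobicParams,
    build_clusters,
    candidate_pairs,
    cluster_stats,
    evaluate_contacts,
    find_hydrophobic_clusters,
    shielding_test,
)
from epiface.structures import AtomRecord, ResidueKey
from epiface.synthetic import make_zigzag_contact

from conftest import atom_keys, atom_keyset, load_fixture


def atom(serial, xyz, name="CB", element="C", resnum=None, chain="A",
         role="antigen", aa3="ALA"):
    key = ResidueKey(chain, resnum if resnum is not None else serial, "", aa3, role)
    return AtomRecord(serial, name, element, np.array(xyz, float), key)


def polar(serial, xyz):
    return atom(serial, xyz, name="OG", element="O", aa3="SER")


def pair(cp_xyz, ce_xyz):
    cp = atom(1, cp_xyz, chain="H", role="heavy")
    ce = atom(2, ce_xyz)
    return CarbonContact(cp, ce, float(np.linalg.norm(
        np.array(cp_xyz, float) - np.array(ce_xyz, float))))


class TestCandidatePairs:
    def test_pair_within_threshold_detected(self):
        got = candidate_pairs([atom(1, (0, 0, 0))],
                              [atom(2, (0, 0, 4.2), chain="H", role="heavy")])
        assert len(got) == 1 and got[0].distance == pytest.approx(4.2)

    def test_pair_beyond_threshold_ignored(self):
        got = candidate_pairs([atom(1, (0, 0, 0))],
                              [atom(2, (0, 0, 5.3), chain="H", role="heavy")])
        assert got == []

    def test_lattice_counts_match_brute_force_scan(self):
        epi = [atom(i, (4.0 * (i % 10), 4.0 * (i // 10), 0.0)) for i in range(100)]
        para = [
            atom(100 + i, (4.0 * (i % 10), 4.0 * (i // 10), 4.0),
                 chain="H", role="heavy")
            for i in range(100)
        ]
        got = candidate_pairs(epi, para)
        brute = sum(
            1
            for e in epi
            for p in para
            if np.linalg.norm(e.coords - p.coords) <= 5.0
        )
        assert len(got) == brute > 0

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_random_clouds_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        epi = [atom(i, xyz) for i, xyz in enumerate(rng.uniform(0, 12, (25, 3)))]
        para = [
            atom(100 + i, xyz, chain="H", role="heavy")
            for i, xyz in enumerate(rng.uniform(0, 12, (25, 3)))
        ]
        got = {(c.c_epitope.serial, c.c_paratope.serial)
               for c in candidate_pairs(epi, para)}
        brute = {
            (e.serial, p.serial)
            for e in epi for p in para
            if np.linalg.norm(e.coords - p.coords) <= 5.0
        }
        assert got == brute


class TestShieldingGeometry:
    def test_midpoint_polar_shields(self):
        c = pair((0, 0, 0), (0, 0, 4.0))
        res = shielding_test(c, [polar(3, (0, 0, 2.0))])
        assert not res.cleared and res.shielded_by is not None

    def test_perpendicular_polar_clears(self):
        c = pair((0, 0, 0), (0, 0, 4.0))
        res = shielding_test(c, [polar(3, (3.0, 0, 0.0))])
        assert res.cleared and res.shielded_by is None

    def test_polar_behind_epitope_carbon_clears(self):
        c = pair((0, 0, 0), (0, 0, 4.0))
        res = shielding_test(c, [polar(3, (0, 0, 6.5))])
        assert res.cleared and res.shielded_by is None

    def test_polar_behind_paratope_carbon_clears(self):
        c = pair((0, 0, 0), (0, 0, 4.0))
        res = shielding_test(c, [polar(3, (0, 0, -2.0))])
        assert res.cleared

    def test_polar_outside_search_radius_ignored(self):
        c = pair((0, 0, 0), (0, 0, 4.0))
        res = shielding_test(c, [polar(3, (0, 0, 9.5))])
        assert res.cleared

    def test_coincident_carbons_rejected_with_warning(self, caplog):
        c = pair((0, 0, 0), (0, 0, 0))
        res = shielding_test(c, [])
        assert not res.cleared

    def test_asymmetry_of_first_vector_anchor(self):
        """The first dot is anchored at the paratope carbon: a polar atom
        slightly beyond the epitope carbon shields nothing, while the
        mirrored geometry (beyond the paratope carbon) also clears —
        swapping roles flips which rule fires, not the outcome."""
        ce_side = shielding_test(pair((0, 0, 0), (0, 0, 4.0)),
                                 [polar(3, (0, 0, 4.8))])
        cp_side = shielding_test(pair((0, 0, 0), (0, 0, 4.0)),
                                 [polar(3, (0, 0, -0.8))])
        assert ce_side.cleared and cp_side.cleared


class TestClusters:
    def test_shared_node_merges_edges(self):
        a = atom(1, (0, 0, 0), chain="H", role="heavy")
        b = atom(2, (0, 0, 4))
        c = atom(3, (3, 0, 2), chain="H", role="heavy")
        contacts = [CarbonContact(a, b, 4.0, cleared=True),
                    CarbonContact(c, b, 3.6, cleared=True)]
        cl = build_clusters(contacts)
        assert len(cl.clusters) == 1 and cl.biggest == {a, b, c}

    def test_disjoint_edges_stay_separate(self):
        a, b = atom(1, (0, 0, 0), chain="H", role="heavy"), atom(2, (0, 0, 4))
        c, d = atom(3, (20, 0, 0), chain="H", role="heavy"), atom(4, (20, 0, 4))
        cl = build_clusters([CarbonContact(a, b, 4.0, cleared=True),
                             CarbonContact(c, d, 4.0, cleared=True)])
        assert len(cl.clusters) == 2

    def test_slab_cluster_matches_manifest(self, slab):
        cs, manifest, sets = slab
        clusters = find_hydrophobic_clusters(
            [a for a in cs.atoms_of(sets.epitope) if a.is_carbon],
            [a for a in cs.atoms_of(sets.paratope) if a.is_carbon],
            [a for a in cs.atoms if a.is_polar],
        )
        assert atom_keys(clusters.biggest) == atom_keyset(
            manifest["expected_cluster_atoms"]
        )

    def test_components_equal_union_find_oracle(self, slab):
        cs, _, sets = slab
        contacts = evaluate_contacts(
            [a for a in cs.atoms_of(sets.epitope) if a.is_carbon],
            [a for a in cs.atoms_of(sets.paratope) if a.is_carbon],
            [a for a in cs.atoms if a.is_polar],
        )
        got = {frozenset(atom_keys(c))
               for c in build_clusters(contacts).clusters}

        parent = {}

        def find(x):
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for c in contacts:
            if c.cleared:
                ra, rb = find(c.c_paratope), find(c.c_epitope)
                if ra != rb:
                    parent[ra] = rb
        groups = {}
        for x in parent:
            groups.setdefault(find(x), set()).add(x)
        brute = {frozenset(atom_keys(g)) for g in groups.values()}
        assert got == brute

    def test_rigid_motion_invariance(self, slab):
        cs, _, sets = slab
        epi = [a for a in cs.atoms_of(sets.epitope) if a.is_carbon]
        para = [a for a in cs.atoms_of(sets.paratope) if a.is_carbon]
        pol = [a for a in cs.atoms if a.is_polar]
        base = find_hydrophobic_clusters(epi, para, pol)

        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        shift = np.array([11.0, -3.0, 7.0])

        def moved(atoms):
            return [
                AtomRecord(a.serial, a.name, a.element, rot @ a.coords + shift,
                           a.residue, vdw_radius=a.vdw_radius)
                for a in atoms
            ]

        rotated = find_hydrophobic_clusters(moved(epi), moved(para), moved(pol))
        assert [sorted(a.serial for a in cl) for cl in rotated.clusters] == [
            sorted(a.serial for a in cl) for cl in base.clusters
        ]

    @pytest.mark.parametrize("cc_dist", [4.0, 4.5, 5.0])
    def test_membership_stable_across_cc_threshold(self, tmp_path, cc_dist):
        cs, manifest = load_fixture(
            make_zigzag_contact(8, separation=3.8, seed=0), tmp_path, "zig"
        )
        clusters = find_hydrophobic_clusters(
            [a for a in cs.ag_atoms if a.is_carbon],
            [a for a in cs.ab_atoms if a.is_carbon],
            [a for a in cs.atoms if a.is_polar],
            HydrophobicParams(cc_dist=cc_dist),
        )
        assert atom_keys(clusters.biggest) == atom_keyset(
            manifest["expected_cluster_atoms"]
        )

    def test_every_cluster_spans_both_molecules(self, slab):
        cs, _, sets = slab
        clusters = find_hydrophobic_clusters(
            [a for a in cs.atoms_of(sets.epitope) if a.is_carbon],
            [a for a in cs.atoms_of(sets.paratope) if a.is_carbon],
            [a for a in cs.atoms if a.is_polar],
        )
        for cl in clusters.clusters:
            roles = {a.residue.role for a in cl}
            assert "antigen" in roles and roles & {"heavy", "light"}


class TestClusterStats:
    def test_composition_counted_by_atoms_and_by_residues(self):
        tyr = [atom(i, (1.2 * i, 0, 0), name=n, aa3="TYR", resnum=50)
               for i, n in enumerate(("CB", "CG", "CD1", "CD2", "CE1"))]
        gly = [atom(10, (0, 3, 2), name="CA", aa3="GLY", resnum=60,
                    chain="H", role="heavy")]
        contacts = [CarbonContact(gly[0], t, 3.0, cleared=True) for t in tyr]
        stats = cluster_stats(build_clusters(contacts))
        assert stats.aa_by_atoms == {"TYR": 5, "GLY": 1}
        assert stats.aa_by_residues == {"TYR": 1, "GLY": 1}

    def test_cdr_pair_counted_once(self):
        h3 = atom(1, (0, 0, 4), name="CB", resnum=96, chain="H", role="heavy")
        l3 = atom(2, (3, 0, 4), name="CB", resnum=90, chain="L", role="light")
        epi = atom(3, (0, 0, 0))
        contacts = [CarbonContact(h3, epi, 4.0, cleared=True),
                    CarbonContact(l3, epi, 5.0, cleared=True)]
        stats = cluster_stats(build_clusters(contacts))
        assert stats.n_cdrs == 2 and stats.cdr_pairs == {("H3", "L3")}
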