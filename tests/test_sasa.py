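"""Solvent-accessibility engine against analytic and planted oracles."""

import math

import numpy as np
import pytest

from epiface.sasa import (
    compute_sasa,
    decompose_epitope,
    epitope_paratope,
    exposedness_profile,
    interface_area,
    sphere_points,
)
from epiface.structures import AtomRecord, ResidueKey
from epiface.synthetic import (
    make_pocket_antigen,
    make_seam_complex,
    make_slab_complex,
)

from conftest import load_fixture, residue_keys, residue_keyset


def carbon(serial, xyz, resnum=None, chain="A", role="antigen"):
    key = ResidueKey(chain, resnum if resnum is not None else serial, "", "ALA", role)
    return AtomRecord(serial, "CB", "C", np.array(xyz, float), key,
                      vdw_radius=1.70)


def two_sphere_exposed_area(r1, r2, d, probe):
    """Analytic accessible area of sphere 1 occluded by sphere 2."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * math.pi * R1**2
    x = (d * d + R1 * R1 - R2 * R2) / (2 * d)
    cap_height = R1 - x
    return 4 * math.pi * R1**2 - 2 * math.pi * R1 * cap_height


class TestComputeSasa:
    def test_isolated_sphere_area_exact(self):
        res = compute_sasa([carbon(1, (0, 0, 0))], 1.4, 960)
        assert res.per_atom_area[0] == pytest.approx(4 * math.pi * 3.1**2, rel=1e-9)

    def test_distant_atoms_do_not_occlude(self):
        res = compute_sasa([carbon(1, (0, 0, 0)), carbon(2, (50, 0, 0))], 1.4, 960)
        assert res.total_area == pytest.approx(2 * 4 * math.pi * 3.1**2, rel=1e-9)

    @pytest.mark.parametrize("d", [2.0, 3.0, 4.5])
    def test_two_sphere_cap_oracle_within_2_percent(self, d):
        res = compute_sasa([carbon(1, (0, 0, 0)), carbon(2, (d, 0, 0))], 1.4, 960)
        expected = two_sphere_exposed_area(1.7, 1.7, d, 1.4)
        assert res.per_atom_area[0] == pytest.approx(expected, rel=0.02)
        assert res.per_atom_area[1] == pytest.approx(expected, rel=0.02)

    def test_convergence_under_point_doubling(self, slab):
        cs, _, _ = slab
        atoms = cs.ag_atoms
        a1 = compute_sasa(atoms, 1.4, 960).total_area
        a2 = compute_sasa(atoms, 1.4, 1920).total_area
        assert abs(a2 - a1) / a2 < 0.01

    def test_independent_shrake_rupley_cross_check(self, slab):
        """biotite's Shrake-Rupley implementation agrees on a fixture."""
        import biotite.structure as struc

        cs, _, _ = slab
        atoms = cs.ag_atoms
        arr = struc.AtomArray(len(atoms))
        arr.coord = np.array([a.coords for a in atoms], dtype=np.float32)
        arr.chain_id[:] = "A"
        arr.res_id[:] = [a.residue.number for a in atoms]
        arr.atom_name[:] = [a.name for a in atoms]
        arr.res_name[:] = [a.residue.aa3 for a in atoms]
        arr.element[:] = [a.element for a in atoms]
        ref = struc.sasa(
            arr, probe_radius=1.4, point_number=960,
            vdw_radii=np.array([a.vdw_radius for a in atoms]),
        ).sum()
        ours = compute_sasa(atoms, 1.4, 960).total_area
        assert ours == pytest.approx(ref, rel=0.02)

    def test_deterministic_sampling(self):
        pts = sphere_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.array_equal(pts, sphere_points(960))


class TestInterfaceArea:
    def test_non_contacting_pair_zero(self):
        ab = [carbon(1, (0, 0, 100), role="heavy", chain="H")]
        ag = [carbon(2, (0, 0, 0))]
        assert interface_area(ab, ag) == pytest.approx(0.0, abs=1e-9)

    def test_per_atom_accounting_identity(self, slab):
        cs, _, sets = slab
        total = interface_area(cs.ab_atoms, cs.ag_atoms)
        per_atom = sum(sets.buried_area.values())
        assert total == pytest.approx(per_atom, rel=1e-6)

    def test_scaling_coordinates_radii_probe_scales_area_by_4(self):
        atoms = [carbon(1, (0, 0, 0)), carbon(2, (3.0, 0, 0))]
        a1 = compute_sasa(atoms, 1.4, 960).total_area
        scaled = [
            AtomRecord(a.serial, a.name, a.element, a.coords * 2, a.residue,
                       vdw_radius=a.vdw_radius * 2)
            for a in atoms
        ]
        a2 = compute_sasa(scaled, 2.8, 960).total_area
        assert a2 == pytest.approx(4 * a1, rel=1e-9)

    def test_calibration_factor_applied(self, slab):
        cs, _, _ = slab
        a = interface_area(cs.ab_atoms, cs.ag_atoms, calibration=1.0)
        b = interface_area(cs.ab_atoms, cs.ag_atoms, calibration=0.95)
        assert b == pytest.approx(0.95 * a, rel=1e-12)


class TestEpitopeParatope:
    def test_slab_epitope_matches_planted_truth_exactly(self, slab):
        _, manifest, sets = slab
        assert residue_keys(sets.epitope) == residue_keyset(
            manifest["expected_epitope"]
        )
        assert residue_keyset(manifest["expected_paratope"]) <= residue_keys(
            sets.paratope
        )

    def test_non_contacting_pair_empty_interface(self, tmp_path):
        cs, manifest = load_fixture(
            make_slab_complex(3, gap=40.0, seed=2), tmp_path, "wide"
        )
        sets = epitope_paratope(cs)
        assert sets.epitope == set() and sets.paratope == set()
        assert manifest["expected_epitope"] == []

    def test_epitope_and_paratope_on_different_molecules(self, slab):
        _, _, sets = slab
        assert not sets.epitope & sets.paratope
        assert all(r.role == "antigen" for r in sets.epitope)
        assert all(r.role in ("heavy", "light") for r in sets.paratope)

    def test_every_epitope_residue_has_buried_atom(self, slab):
        cs, _, sets = slab
        mono_exposed = sets.ag_sasa.exposed_atoms
        cplx_exposed = sets.complex_sasa.exposed_atoms
        for res in sets.epitope:
            atoms = [a for a in cs.ag_atoms if a.residue == res]
            assert any(
                a in mono_exposed and a not in cplx_exposed for a in atoms
            )

    def test_burial_equals_bruteforce_monomer_vs_complex(self, slab):
        cs, _, sets = slab
        mono = compute_sasa(cs.ab_atoms)
        cplx = compute_sasa(cs.ab_atoms + cs.ag_atoms)
        cplx_exposed = cplx.exposed_atoms
        brute = {
            a for a, m in zip(mono.atoms, mono.exposed_mask)
            if m and a not in cplx_exposed
        }
        assert brute == sets.interfacial_ab


@pytest.fixture(scope="session")
def slab_decomposition(slab):
    cs, manifest, sets = slab
    return manifest, sets, decompose_epitope(cs, sets)


class TestDecomposition:
    def test_single_cdr_contact_captures_whole_epitope(self, slab_decomposition):
        manifest, sets, dec = slab_decomposition
        assert dec.epitope_cdr["H3"] == sets.epitope
        for lab in ("H1", "H2", "L1", "L2", "L3"):
            assert dec.epitope_cdr[lab] == set()
        assert dec.epitope_shared == set()

    def test_extracdr_identity(self, slab_decomposition):
        _, sets, dec = slab_decomposition
        assert dec.epitope_extracdr == sets.epitope - dec.epitope_cdr_individuals

    def test_cdr_individuals_is_union(self, slab_decomposition):
        _, _, dec = slab_decomposition
        assert dec.epitope_cdr_individuals == set().union(
            *dec.epitope_cdr.values()
        )

    def test_shared_subset_of_individuals(self, slab_decomposition):
        _, _, dec = slab_decomposition
        assert dec.epitope_shared <= dec.epitope_cdr_individuals

    def test_interchain_subset_of_epitope(self, slab_decomposition):
        _, sets, dec = slab_decomposition
        assert dec.epitope_interchain <= sets.epitope

    @pytest.mark.parametrize("kind", ["interchain", "intercdr"])
    def test_seam_residue_lands_in_planted_subset(self, tmp_path, kind):
        cs, manifest = load_fixture(
            make_seam_complex(kind, seed=3), tmp_path, kind
        )
        sets = epitope_paratope(cs)
        dec = decompose_epitope(cs, sets)
        sr = manifest["notes"]["seam_residue"]
        key = (sr["chain"], sr["number"], sr["icode"])
        assert key in residue_keys(sets.epitope)
        target = (
            dec.epitope_interchain if kind == "interchain" else dec.epitope_intercdr
        )
        assert key in residue_keys(target)
        assert key in residue_keys(dec.epitope_extracdr)

    def test_framework_only_antibody_yields_pure_fw_epitope(self, tmp_path):
        cs, manifest = load_fixture(
            make_slab_complex(3, seed=5, cdr_mode="fw"), tmp_path, "fw"
        )
        sets = epitope_paratope(cs)
        dec = decompose_epitope(cs, sets)
        assert residue_keys(sets.epitope) == residue_keyset(
            manifest["expected_epitope"]
        )
        assert dec.epitope_cdr_individuals == set()
        assert dec.epitope_fw == sets.epitope
        assert dec.epitope_extracdr == sets.epitope


class TestExposedness:
    def test_probe_nesting_on_slab_antigen(self, slab):
        cs, _, sets = slab
        prof = exposedness_profile(cs.ag_atoms, sets.epitope, n_points=2000)
        e14, e9, e100 = (prof.exposed_at[p] for p in (1.4, 9.0, 100.0))
        assert e100 <= e9 <= e14

    def test_fractions_partition_epitope(self, slab):
        cs, _, sets = slab
        prof = exposedness_profile(cs.ag_atoms, sets.epitope, n_points=2000)
        assert sum(prof.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_convex_shell_fully_superficial(self, tmp_path):
        cs, _ = load_fixture(
            make_pocket_antigen(depth=0.0, seed=1), tmp_path, "convex"
        )
        epi = set(cs.residues("antigen"))
        prof = exposedness_profile(cs.ag_atoms, epi)
        assert prof.fractions["superficial"] == pytest.approx(1.0)

    def test_pocket_bottom_reachable_by_water_probe_only(self, tmp_path):
        cs, manifest = load_fixture(
            make_pocket_antigen(depth=8.0, mouth=8.0, seed=1), tmp_path, "pocket"
        )
        epi = set(cs.residues("antigen"))
        prof = exposedness_profile(cs.ag_atoms, epi)
        deep = residue_keys(prof.deep)
        assert residue_keyset(manifest["expected_deep"]) <= deep
        sup = residue_keys(prof.superficial)
        assert residue_keyset(manifest["expected_superficial"]) <= sup

    def test_pocket_bottom_against_dense_random_sampling_oracle(self, tmp_path):
        """Brute-force random-direction exposure check for the bottom atom."""
        cs, manifest = load_fixture(
            make_pocket_antigen(depth=8.0, mouth=8.0, seed=2), tmp_path, "pocket2"
        )
        bottom = residue_keyset(manifest["expected_deep"])
        atoms = cs.ag_atoms
        xyz = np.array([a.coords for a in atoms])
        target_idx = [
            i for i, a in enumerate(atoms)
            if (a.residue.chain_id, a.residue.number, a.residue.icode) in bottom
        ]
        rng = np.random.default_rng(0)
        for probe, expect in ((1.4, True), (9.0, False)):
            radii = np.array([a.vdw_radius for a in atoms]) + probe
            for i in target_idx:
                dirs = rng.normal(size=(4000, 3))
                dirs /= np.linalg.norm(dirs, axis=1)[:, None]
                pts = xyz[i] + radii[i] * dirs
                d2 = ((pts[:, None, :] - xyz[None, :, :]) ** 2).sum(-1)
                d2[:, i] = np.inf
                assert ((d2 >= radii**2).all(axis=1).any()) is np.bool_(expect)

    def test_empty_epitope_flagged_undefined(self, slab):
        cs, _, _ = slab
        prof = exposedness_profile(cs.ag_atoms, set(), n_points=960)
        assert not prof.defined and prof.fractions == {}
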