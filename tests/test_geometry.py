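import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from btbcul3.geometry import (
    ContactCriteria,
    buried_interface_area,
    cn_symmetry_score,
    detect_contacts,
    kabsch_superpose,
    partition_interfaces,
    sasa,
)
from btbcul3.structure_io import AssemblySpec, AtomRecord, Residue, StructureModel
from btbcul3.synthetic_data import SyntheticComplexSpec, make_cn_complex

from oracles import (
    apply_rigid_to_model,
    brute_force_contacts,
    contact_set,
    random_two_chain_model,
    rigid_transform,
    two_sphere_sasa,
)


def _atoms_model(atom_specs, chain="A", aa3="ALA"):
    atoms = [
        AtomRecord(i + 1, name, element, coords)
        for i, (name, element, coords) in enumerate(atom_specs)
    ]
    return StructureModel(
        "toy", {chain: [Residue(chain, 1, "", aa3, atoms)]}, source="synthetic"
    )


class TestSasa:
    def test_single_carbon_closed_form(self):
        model = _atoms_model([("CB", "C", [0.0, 0.0, 0.0])])
        _, total = sasa(model)
        assert total == pytest.approx(4 * math.pi * (1.70 + 1.4) ** 2, rel=5e-3)

    def test_disjoint_spheres_additive(self):
        model = _atoms_model(
            [("CB", "C", [0.0, 0.0, 0.0]), ("CG", "C", [100.0, 0.0, 0.0])]
        )
        _, total = sasa(model)
        assert total == pytest.approx(2 * 4 * math.pi * (3.10) ** 2, rel=5e-3)

    @pytest.mark.parametrize("d", [1.0, 2.0, 3.5, 5.0])
    def test_two_sphere_analytic_overlap(self, d):
        model = _atoms_model(
            [("CB", "C", [0.0, 0.0, 0.0]), ("OG", "O", [d, 0.0, 0.0])], aa3="SER"
        )
        _, total = sasa(model)
        assert total == pytest.approx(two_sphere_sasa(1.70, 1.52, d, 1.4), rel=1e-2)

    def test_unknown_element_raises_naming_atom(self):
        model = _atoms_model([("XX", "XX", [0.0, 0.0, 0.0])])
        with pytest.raises(KeyError, match="XX"):
            sasa(model)

    def test_biotite_cross_check(self, complex_fixture):
        """Independent SASA implementation agrees on the fixture within a
        few percent (different lattices and radii conventions)."""
        import biotite.structure as struc

        model, _ = complex_fixture
        sub = model.subset(["A"])
        atoms = struc.AtomArray(sub.n_atoms())
        for i, (res, atom) in enumerate(sub.iter_atoms()):
            atoms.coord[i] = atom.coords
            atoms.chain_id[i] = res.chain_id
            atoms.res_id[i] = res.seq_number
            atoms.res_name[i] = res.aa3
            atoms.atom_name[i] = atom.name
            atoms.element[i] = atom.element
        ref = struc.sasa(atoms, probe_radius=1.4, point_number=960, vdw_radii="Single").sum()
        _, ours = sasa(sub)
        assert ours == pytest.approx(ref, rel=0.05)


class TestBuriedArea:
    def test_separated_groups_bury_nothing(self):
        chains = {
            "A": [Residue("A", 1, "", "ALA", [AtomRecord(1, "CB", "C", [0, 0, 0])])],
            "B": [Residue("B", 1, "", "ALA", [AtomRecord(2, "CB", "C", [100, 0, 0])])],
        }
        model = StructureModel("m", chains, source="synthetic")
        assert buried_interface_area(model, ["A"], ["B"]) == 0.0

    def test_exact_symmetry(self, complex_fixture):
        model, _ = complex_fixture
        assert buried_interface_area(model, ["A"], ["X"]) == buried_interface_area(
            model, ["X"], ["A"]
        )

    def test_shared_chain_rejected(self, complex_fixture):
        model, _ = complex_fixture
        with pytest.raises(ValueError, match="share"):
            buried_interface_area(model, ["A"], ["A", "X"])

    def test_rigid_motion_invariance(self, complex_fixture, rng):
        model, _ = complex_fixture
        base = buried_interface_area(model, ["A"], ["X"])
        rot, trans = rigid_transform(rng)
        moved = apply_rigid_to_model(model, rot, trans)
        assert abs(buried_interface_area(moved, ["A"], ["X"]) - base) < 1e-6

    def test_matches_three_sasa_formula(self, complex_fixture):
        """The interface-restricted evaluation equals the explicit
        SASA(A)+SASA(B)-SASA(AB) difference up to lattice-frame quadrature."""
        model, _ = complex_fixture
        kw = dict(probe_radius=1.4, n_points=960)
        _, sa = sasa(model.subset(["A"]), **kw)
        _, sx = sasa(model.subset(["X"]), **kw)
        _, sax = sasa(model.subset(["A", "X"]), **kw)
        explicit = (sa + sx - sax) / 2
        fast = buried_interface_area(model, ["A"], ["X"])
        assert fast == pytest.approx(explicit, rel=0.03)

    def test_self_convergence_at_high_resolution(self, complex_fixture):
        model, _ = complex_fixture
        coarse = buried_interface_area(model, ["A"], ["X"], n_points=960)
        fine = buried_interface_area(model, ["A"], ["X"], n_points=4000)
        assert coarse == pytest.approx(fine, rel=0.03)


class TestContacts:
    def test_engineered_salt_bridge(self):
        chains = {
            "A": [Residue("A", 1, "", "ASP", [
                AtomRecord(1, "CA", "C", [0, 0, 0]),
                AtomRecord(2, "OD2", "O", [1.0, 0, 0]),
            ])],
            "B": [Residue("B", 1, "", "ARG", [
                AtomRecord(3, "CA", "C", [6.0, 0, 0]),
                AtomRecord(4, "NH1", "N", [3.8, 0, 0]),
            ])],
        }
        model = StructureModel("m", chains, source="synthetic")
        recs = detect_contacts(model, ["A"], ["B"])
        kinds = sorted(c.kind for c in recs)
        assert kinds == ["hbond", "salt_bridge"]  # 2.8 A N-O pair is both
        sb = next(c for c in recs if c.kind == "salt_bridge")
        assert (sb.atom_a, sb.atom_b) == ("OD2", "NH1")
        assert sb.distance == pytest.approx(2.8)
        assert not sb.backbone_involved

    def test_everything_beyond_cutoffs_is_empty(self):
        chains = {
            "A": [Residue("A", 1, "", "ASP", [AtomRecord(1, "OD2", "O", [0, 0, 0])])],
            "B": [Residue("B", 1, "", "ARG", [AtomRecord(2, "NH1", "N", [5.1, 0, 0])])],
        }
        model = StructureModel("m", chains, source="synthetic")
        assert detect_contacts(model, ["A"], ["B"]) == []

    @pytest.mark.parametrize("seed", range(25))
    def test_agrees_with_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        model = random_two_chain_model(rng)
        criteria = ContactCriteria()
        got = contact_set(detect_contacts(model, ["A"], ["B"], criteria))
        want = brute_force_contacts(model, ["A"], ["B"], criteria)
        assert got == want

    def test_backbone_flag(self):
        chains = {
            "A": [Residue("A", 1, "", "GLY", [AtomRecord(1, "N", "N", [0, 0, 0])])],
            "B": [Residue("B", 1, "", "GLY", [AtomRecord(2, "O", "O", [3.0, 0, 0])])],
        }
        model = StructureModel("m", chains, source="synthetic")
        (rec,) = detect_contacts(model, ["A"], ["B"])
        assert rec.kind == "hbond" and rec.backbone_involved

    def test_empty_group_rejected(self, complex_fixture):
        model, _ = complex_fixture
        with pytest.raises(ValueError):
            detect_contacts(model, [], ["X"])


class TestSuperposition:
    def test_identity(self, rng):
        pts = rng.normal(size=(20, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd < 1e-12
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_recovers_constructed_transform(self, rng):
        pts = rng.normal(size=(15, 3)) * 5
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([5.0, 0.0, 0.0])
        res = kabsch_superpose(pts, moved)
        assert res.rmsd < 1e-9
        assert np.allclose(res.rotation, rot, atol=1e-9)
        assert np.allclose(res.translation, [5.0, 0.0, 0.0], atol=1e-9)

    def test_fitted_never_worse_than_unfitted(self, rng):
        for _ in range(100):
            ref = rng.normal(size=(12, 3)) * 4
            mob = ref + rng.normal(scale=0.3, size=ref.shape)
            rot, trans = rigid_transform(rng)
            mob = mob @ rot.T + trans
            unfitted = np.sqrt(((mob - ref) ** 2).sum() / len(ref))
            assert kabsch_superpose(mob, ref).rmsd <= unfitted + 1e-12

    def test_agrees_with_scipy_wahba(self, rng):
        mob = rng.normal(size=(10, 3)) * 3
        ref = mob + rng.normal(scale=0.5, size=mob.shape)
        ours = kabsch_superpose(mob, ref)
        rot, rssd = Rotation.align_vectors(
            ref - ref.mean(axis=0), mob - mob.mean(axis=0)
        )
        assert ours.rmsd == pytest.approx(rssd / np.sqrt(len(mob)), abs=1e-9)

    def test_collinear_reference_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line + 0.1, line)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_proper_rotation_under_reflection_pressure(self, rng):
        mob = rng.normal(size=(8, 3))
        ref = mob.copy()
        ref[:, 2] *= -1  # mirrored target
        res = kabsch_superpose(mob, ref)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)


class TestCnSymmetry:
    @pytest.mark.parametrize("n", [2, 3, 5, 7])
    def test_ideal_assembly_scores_zero(self, n):
        model, _ = make_cn_complex(
            SyntheticComplexSpec(n_fold=n, subunit_size=14, partner=False, seed=n)
        )
        score, axis = cn_symmetry_score(model, n)
        assert score < 1e-6
        assert abs(axis[2]) == pytest.approx(1.0, abs=1e-6)

    def test_score_grows_with_displacement(self, pentamer):
        import copy

        model, _ = pentamer
        scores = []
        for amp in (0.5, 1.0, 2.0, 4.0):
            bent = copy.deepcopy(model)
            for res in bent.chains["C"]:
                for a in res.atoms:
                    a.coords = a.coords + np.array([amp, 0.0, 0.0])
            scores.append(cn_symmetry_score(bent, 5)[0])
        assert all(s > 0 for s in scores)
        assert scores == sorted(scores)

    def test_unequal_units_rejected(self, complex_fixture):
        model, _ = complex_fixture  # chain X breaks the equal-count premise
        with pytest.raises(ValueError, match="unequal|split"):
            cn_symmetry_score(model, 5, ["A", "B", "C", "D", "X"])


class TestInterfacePartition:
    def test_fixture_main_minor_match_manifest(self, complex_fixture):
        model, manifest = complex_fixture
        (summary,) = partition_interfaces(model, manifest.assembly)
        assert summary.main_kctd_chain == manifest.main_chain
        assert summary.minor_kctd_chain == manifest.minor_chain
        assert summary.area_main > summary.area_minor > 0

    def test_contacts_carry_interface_roles(self, complex_fixture):
        model, manifest = complex_fixture
        (summary,) = partition_interfaces(model, manifest.assembly)
        got = {(c.kind, c.res_a[:2], c.interface) for c in summary.contacts}
        want = {(c.kind, c.res_a[:2], c.interface) for c in manifest.contacts}
        assert got == want

    def test_one_to_one_assembly_has_no_minor(self):
        model, manifest = make_cn_complex(
            SyntheticComplexSpec(
                n_fold=1, partner=True, seed=3,
                engineered_contacts=(("hbond", "main", 3.0),),
            )
        )
        assembly = AssemblySpec(("A",), ("X",), (1, 1))
        (summary,) = partition_interfaces(model, assembly)
        assert summary.minor_kctd_chain is None
        assert summary.area_minor == 0.0

    def test_distant_partner_flags_no_interface(self, pentamer):
        import copy

        model, _ = pentamer
        far = copy.deepcopy(model)
        partner = copy.deepcopy(model.chains["A"])
        moved = []
        for res in partner:
            atoms = [
                AtomRecord(a.serial, a.name, a.element, a.coords + np.array([500.0, 0, 0]))
                for a in res.atoms
            ]
            moved.append(Residue("X", res.seq_number, "", res.aa3, atoms))
        far.chains["X"] = moved
        assembly = AssemblySpec(("A", "B", "C", "D", "E"), ("X",), (5, 1))
        (summary,) = partition_interfaces(far, assembly)
        assert summary.main_kctd_chain is None
        assert "no_interface" in summary.flags
        assert summary.area_main == 0.0

    def test_missing_chain_rejected(self, pentamer):
        model, _ = pentamer
        assembly = AssemblySpec(("A", "B", "C", "D", "E"), ("Z",), (5, 1))
        with pytest.raises(KeyError, match="Z"):
            partition_interfaces(model, assembly)
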