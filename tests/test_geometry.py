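import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bamdyn.errors import FrameError, PairingError, SelectionError
from bamdyn.geometry import (ComplexSelection, SelectionEntry,
                             barrel_in_plane_diameter, geometric_center,
                             kabsch_superpose, membrane_frame,
                             rmsd_between_models, select_atoms)
from bamdyn.structio import Atom, StructureModel
from bamdyn.synthetic_data import ToySpec, make_toy_complex

from _oracles import quaternion_rmsd


def _tiny_barrel(n=16, start=425) -> StructureModel:
    atoms = []
    serial = 1
    for i in range(n):
        theta = 2 * np.pi * i / n
        base = np.array([10 * np.cos(theta), 10 * np.sin(theta), i % 4])
        for name in ("N", "CA", "C", "O"):
            atoms.append(Atom(serial, name, "ALA", start + i, "A", name[0],
                              base + 0.1 * serial % 1))
            serial += 1
    return StructureModel(atoms, "tiny")


class TestSelectAtoms:
    def test_carbonyl_selection_on_tiny_barrel(self):
        model = _tiny_barrel()
        entry = SelectionEntry("A", ((425, 440),), "carbonyl_C")
        atoms = select_atoms(model, entry)
        assert len(atoms) == 16
        assert all(a.name == "C" for a in atoms)

    def test_missing_residues_are_skipped_without_error(self):
        model = _tiny_barrel()
        model.atoms = [a for a in model.atoms
                       if not (430 <= a.residue_number <= 432)]
        entry = SelectionEntry("A", ((425, 440),), "carbonyl_C")
        atoms = select_atoms(model, entry)
        assert len(atoms) == 13
        assert all(not (430 <= a.residue_number <= 432) for a in atoms)

    def test_ca_selection_matches_brute_force_filter(self, toy_model):
        entry = SelectionEntry("A", ((425, 810),), "CA")
        got = select_atoms(toy_model, entry)
        expected = [a for a in toy_model.atoms
                    if a.chain_id == "A" and 425 <= a.residue_number <= 810
                    and a.name == "CA"]
        assert [a.serial for a in got] == [a.serial for a in expected]

    def test_empty_selection_raises_with_description(self, toy_model):
        entry = SelectionEntry("Z", ((1, 5),), "CA", name="ghost")
        with pytest.raises(SelectionError, match="ghost"):
            select_atoms(toy_model, entry)


class TestGeometricCenter:
    def test_single_atom(self):
        a = Atom(1, "CA", "ALA", 1, "A", "C", np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(geometric_center([a]), [1, 2, 3])

    def test_two_atoms_midpoint(self):
        np.testing.assert_allclose(
            geometric_center(np.array([[0, 0, 0], [2, 0, 0]], float)), [1, 0, 0])

    def test_symmetric_ring_centers_at_origin(self):
        theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        ring = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(12)])
        np.testing.assert_allclose(geometric_center(ring), [0, 0, 0], atol=1e-9)

    def test_empty_set_rejected(self):
        with pytest.raises(SelectionError):
            geometric_center([])


class TestMembraneFrame:
    def test_toy_barrel_along_z_both_modes_agree(self, toy_model, selection):
        fz = membrane_frame(toy_model, selection, "z_axis")
        fp = membrane_frame(toy_model, selection, "barrel_principal")
        np.testing.assert_allclose(fz.normal, [0, 0, 1], atol=1e-6)
        np.testing.assert_allclose(fp.normal, [0, 0, 1], atol=1e-6)

    def test_principal_mode_is_equivariant_under_rigid_rotation(self, toy_model,
                                                                selection):
        rot = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], float)  # 90 deg about x
        rotated = toy_model.with_coords(toy_model.coords() @ rot.T)
        frame = membrane_frame(rotated, selection, "barrel_principal")
        np.testing.assert_allclose(frame.normal, rot @ [0, 0, 1], atol=1e-6)

    def test_z_axis_mode_ignores_structure_orientation(self, toy_model, selection):
        rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], float)
        rotated = toy_model.with_coords(toy_model.coords() @ rot.T)
        frame = membrane_frame(rotated, selection, "z_axis")
        np.testing.assert_allclose(frame.normal, [0, 0, 1])

    def test_triad_is_orthonormal_and_right_handed(self, toy_model, selection):
        f = membrane_frame(toy_model, selection, "barrel_principal")
        np.testing.assert_allclose(np.dot(f.normal, f.in_plane_x), 0, atol=1e-9)
        np.testing.assert_allclose(np.cross(f.in_plane_x, f.in_plane_y), f.normal,
                                   atol=1e-9)

    def test_collinear_barrel_raises_frame_error(self, selection):
        atoms = [Atom(i + 1, "C", "ALA", 425 + i, "A", "C",
                      np.array([0.0, 0.0, float(i)])) for i in range(20)]
        model = StructureModel(atoms, "line")
        with pytest.raises(FrameError):
            membrane_frame(model, selection, "barrel_principal")

    def test_toy_in_plane_diameter_matches_construction(self, toy_model, selection):
        d = barrel_in_plane_diameter(toy_model, selection)
        # CA ring of radius 20 Å -> diameter 40 Å (small intra-residue offsets)
        assert d == pytest.approx(40.0, abs=1.5)


class TestKabsch:
    def test_identical_sets_give_zero_rmsd_identity_rotation(self, rng):
        pts = rng.normal(size=(30, 3))
        tr = kabsch_superpose(pts, pts)
        assert tr.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-9)

    def test_pure_translation_fits_to_zero(self, rng):
        pts = rng.normal(size=(20, 3))
        tr = kabsch_superpose(pts, pts + [5.0, 0.0, 0.0])
        assert tr.rmsd == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_quaternion_oracle_to_1e9(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(scale=10, size=(40, 3))
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ])
        mob = ref @ rot.T + rng.normal(scale=0.2, size=ref.shape) + [3, -2, 7]
        tr = kabsch_superpose(ref, mob)
        assert tr.rmsd == pytest.approx(quaternion_rmsd(ref, mob), abs=1e-9)
        # sigma=0.2 noise in 3D: expected post-fit RMSD close to sqrt(3)*0.2
        assert tr.rmsd == pytest.approx(0.2 * np.sqrt(3), rel=0.35)

    def test_fitted_rmsd_never_exceeds_raw(self, rng):
        for _ in range(10):
            ref = rng.normal(size=(15, 3))
            mob = rng.normal(size=(15, 3))
            raw = float(np.sqrt(np.mean(np.sum((ref - mob) ** 2, axis=1))))
            assert kabsch_superpose(ref, mob).rmsd <= raw + 1e-12

    def test_count_mismatch_and_rank_errors(self, rng):
        with pytest.raises(PairingError):
            kabsch_superpose(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))
        with pytest.raises(PairingError):
            kabsch_superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))


class TestRMSDBetweenModels:
    def test_model_vs_itself_is_zero(self, toy_model, selection):
        res = rmsd_between_models(toy_model, toy_model,
                                  selection.barrel_as("CA"))
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_deleted_residue_drops_out_of_pairing(self, toy_model, selection):
        pruned = StructureModel(
            [a for a in toy_model.atoms if a.residue_number != 430],
            "pruned")
        res = rmsd_between_models(toy_model, pruned, selection.barrel_as("CA"))
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        full = len(select_atoms(toy_model, selection.barrel_as("CA")))
        assert res.n_paired == full - 1

    def test_rigid_motion_of_both_models_leaves_rmsd_invariant(self, toy_model,
                                                               selection, rng):
        jittered = toy_model.with_coords(
            toy_model.coords() + rng.normal(scale=0.5, size=(len(toy_model), 3)))
        base = rmsd_between_models(toy_model, jittered, selection.barrel_as("CA"))
        rot = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(rot) < 0:
            rot[:, 0] *= -1
        move = lambda m: m.with_coords(m.coords() @ rot.T + [10, -4, 2])
        res = rmsd_between_models(move(toy_model), move(jittered),
                                  selection.barrel_as("CA"))
        assert res.rmsd == pytest.approx(base.rmsd, abs=1e-9)

    def test_too_few_common_atoms_raises(self, toy_model):
        entry = SelectionEntry("A", ((425, 425),), "CA")
        with pytest.raises(PairingError):
            rmsd_between_models(toy_model, toy_model, entry)


@given(st.lists(st.tuples(st.floats(-100, 100), st.floats(-100, 100),
                          st.floats(-100, 100)), min_size=1, max_size=30))
def test_geometric_center_is_translation_equivariant(points):
    pts = np.array(points, dtype=float)
    shift = np.array([3.0, -7.0, 11.0])
    np.testing.assert_allclose(geometric_center(pts + shift),
                               geometric_center(pts) + shift, atol=1e-9)
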