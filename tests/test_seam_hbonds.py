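import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bamdyn.errors import ParameterError
from bamdyn.geometry import ComplexSelection, SelectionEntry
from bamdyn.seam_hbonds import (HBondCriteria, HBondSeries, classify_seam_state,
                                detect_backbone_hbonds, hbond_series,
                                min_seam_contact, moving_average)
from bamdyn.structio import Atom, StructureModel
from bamdyn.synthetic_data import make_seam_trajectory

from _oracles import brute_hbonds

SEAM1 = SelectionEntry("A", ((424, 435),), "backbone", "beta1")
SEAM16 = SelectionEntry("A", ((800, 810),), "backbone", "beta16")


def _strand_model(residues_atoms: dict) -> StructureModel:
    """{resnum: {atom_name: (x, y, z)}} -> StructureModel on chain A."""
    atoms = []
    serial = 1
    for resnum in sorted(residues_atoms):
        for name, pos in residues_atoms[resnum].items():
            atoms.append(Atom(serial, name, "ALA", resnum, "A", name[0],
                              np.array(pos, dtype=float)))
            serial += 1
    return StructureModel(atoms, "strands")


def _ideal_strands(n_bonds=4, spacing=3.5, no_dist=2.9):
    """Antiparallel-sheet-like register: n_bonds N···O contacts at 2.9 Å."""
    res = {}
    for k in range(n_bonds):
        x = spacing * k
        res[424 + k] = {"N": (x, 0.0, 0.0), "CA": (x + 0.8, -1.0, 0.0),
                        "C": (x + 1.6, -1.8, 0.0), "O": (x + 1.6, -3.0, 0.0)}
        res[800 + k] = {"O": (x, no_dist, 0.0), "C": (x, no_dist + 1.23, 0.0),
                        "CA": (x + 0.8, no_dist + 2.5, 0.0),
                        "N": (x + 0.4, no_dist + 4.0, 0.0)}
    return res


class TestDetect:
    def test_four_register_bonds_counted(self):
        model = _strand_model(_ideal_strands(4))
        bonds = detect_backbone_hbonds(model, SEAM1, SEAM16)
        assert len(bonds) == 4
        assert {(b.donor_residue, b.acceptor_residue) for b in bonds} == \
               {(424, 800), (425, 801), (426, 802), (427, 803)}

    def test_separated_strands_have_no_bonds(self):
        res = _ideal_strands(4)
        for resnum in list(res):
            if resnum >= 800:
                res[resnum] = {k: (p[0], p[1] + 20.0, p[2])
                               for k, p in res[resnum].items()}
        bonds = detect_backbone_hbonds(_strand_model(res), SEAM1, SEAM16)
        assert bonds == []

    def test_single_bond_between_432_and_806(self):
        """One N···O contact left at the seam — the tenuous closed state."""
        res = {432: {"N": (0.0, 0.0, 0.0), "CA": (0.8, -1.0, 0.0),
                     "C": (1.6, -1.8, 0.0), "O": (1.6, -3.0, 0.0)},
               433: {"N": (3.5, 0.0, 0.0), "CA": (4.3, -1.0, 0.0),
                     "C": (5.1, -1.8, 0.0), "O": (5.1, -3.0, 0.0)},
               806: {"O": (0.0, 2.9, 0.0), "C": (0.0, 4.13, 0.0),
                     "CA": (0.8, 5.5, 0.0), "N": (0.4, 7.0, 0.0)},
               807: {"O": (3.5, 9.0, 0.0), "C": (3.5, 10.23, 0.0),
                     "CA": (4.3, 11.5, 0.0), "N": (3.9, 13.0, 0.0)}}
        bonds = detect_backbone_hbonds(_strand_model(res), SEAM1, SEAM16)
        assert [(b.donor_residue, b.acceptor_residue) for b in bonds] == [(432, 806)]

    def test_angle_gate_rejects_bent_contacts(self):
        # O at 2.9 Å but C placed so the N···O=C angle is ~60 deg
        res = {424: {"N": (0.0, 0.0, 0.0), "CA": (0.8, -1.0, 0.0),
                     "C": (1.6, -1.8, 0.0), "O": (1.6, -3.0, 0.0)},
               800: {"O": (0.0, 2.9, 0.0), "C": (0.6, 1.9, 0.0),
                     "CA": (1.5, 4.0, 0.0), "N": (0.4, 6.0, 0.0)}}
        bonds = detect_backbone_hbonds(_strand_model(res), SEAM1, SEAM16)
        assert bonds == []

    def test_explicit_hydrogen_criterion(self):
        res = {424: {"N": (0.0, 0.0, 0.0), "H": (0.0, 1.0, 0.0),
                     "CA": (0.8, -1.0, 0.0), "C": (1.6, -1.8, 0.0),
                     "O": (1.6, -3.0, 0.0)},
               800: {"O": (0.0, 2.9, 0.0), "C": (0.0, 4.13, 0.0),
                     "CA": (0.8, 5.5, 0.0), "N": (0.4, 7.0, 0.0),
                     "H": (0.4, 8.0, 0.0)}}
        crit = HBondCriteria(use_explicit_H=True)
        bonds = detect_backbone_hbonds(_strand_model(res), SEAM1, SEAM16, crit)
        assert len(bonds) == 1  # N-H...O is linear
        bent = dict(res)
        bent[424] = dict(res[424], H=(1.0, 0.0, 0.0))  # H points sideways
        bonds = detect_backbone_hbonds(_strand_model(bent), SEAM1, SEAM16, crit)
        assert bonds == []

    def test_swapping_strands_transposes_pairs(self):
        model = _strand_model(_ideal_strands(3))
        fwd = detect_backbone_hbonds(model, SEAM1, SEAM16)
        rev = detect_backbone_hbonds(model, SEAM16, SEAM1)
        assert {(b.donor_residue, b.acceptor_residue) for b in fwd} == \
               {(b.donor_residue, b.acceptor_residue) for b in rev}

    def test_rigid_motion_leaves_count_invariant(self, rng):
        model = _strand_model(_ideal_strands(4))
        rot = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(rot) < 0:
            rot[:, 0] *= -1
        moved = model.with_coords(model.coords() @ rot.T + [7, -3, 11])
        assert len(detect_backbone_hbonds(moved, SEAM1, SEAM16)) == 4

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_scan_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        res = {}
        for base in (424, 800):
            for k in range(5):
                x = 3.5 * k + rng.normal(scale=1.5)
                y = (0.0 if base == 424 else rng.uniform(2.0, 7.0))
                origin = np.array([x, y + rng.normal(scale=1.0), rng.normal()])
                res[base + k] = {
                    "N": tuple(origin + rng.normal(scale=0.5, size=3)),
                    "CA": tuple(origin + [0.8, -1.0, 0.0]),
                    "C": tuple(origin + rng.normal(scale=0.5, size=3) + [1.5, 0, 0]),
                    "O": tuple(origin + rng.normal(scale=0.8, size=3)),
                }
        model = _strand_model(res)
        got = {(b.donor_residue, b.acceptor_residue)
               for b in detect_backbone_hbonds(model, SEAM1, SEAM16)}
        strand1 = {r: a for r, a in res.items() if r < 500}
        strand16 = {r: a for r, a in res.items() if r >= 800}
        assert got == brute_hbonds(strand1, strand16)


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(moving_average(np.full(7, 3.0), 5), 3.0)

    def test_window_one_is_identity(self):
        x = np.array([0.0, 2.0, 1.0, 4.0])
        np.testing.assert_allclose(moving_average(x, 1), x)

    def test_step_series_hand_computed(self):
        x = np.array([0, 0, 0, 4, 4, 4], dtype=float)
        expected = [0.0, 0.0, 4 / 3, 8 / 3, 4.0, 4.0]
        np.testing.assert_allclose(moving_average(x, 3), expected)

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            moving_average(np.zeros(5), 4)

    @given(st.lists(st.integers(0, 4), min_size=1, max_size=40),
           st.sampled_from([1, 3, 5, 7]))
    def test_smoothed_bounded_by_raw_extremes(self, counts, window):
        x = np.array(counts, dtype=float)
        sm = moving_average(x, window)
        assert np.all(sm >= x.min() - 1e-12)
        assert np.all(sm <= x.max() + 1e-12)


class TestSeries:
    def test_schedule_recovered_and_smoothing(self, selection):
        traj = make_seam_trajectory(5, [0, 1, 2, 3, 4])
        series = hbond_series(traj, selection, window=1)
        np.testing.assert_array_equal(series.counts, [0, 1, 2, 3, 4])
        np.testing.assert_allclose(series.smoothed, series.counts)

    def test_window_must_be_odd(self, selection):
        traj = make_seam_trajectory(3, [0, 0, 0])
        with pytest.raises(ParameterError):
            hbond_series(traj, selection, window=2)


class TestClassification:
    def _series(self, smoothed, contact):
        n = len(smoothed)
        return HBondSeries(times=np.arange(n, dtype=float),
                           counts=np.array(np.round(smoothed), dtype=int),
                           window=1, smoothed=np.array(smoothed, dtype=float),
                           bonds_per_frame=[[] for _ in range(n)],
                           min_contact=np.array(contact, dtype=float))

    def test_four_bonds_is_closed(self):
        s = self._series([4.0, 4.0], [2.9, 2.9])
        assert list(classify_seam_state(s)) == ["closed", "closed"]

    def test_no_bonds_and_no_contact_is_open(self):
        s = self._series([0.0, 0.0], [20.0, 20.0])
        assert list(classify_seam_state(s)) == ["open", "open"]

    def test_fractional_bonds_with_contact_is_tenuous(self):
        s = self._series([0.8], [3.2])
        assert list(classify_seam_state(s)) == ["tenuous"]

    def test_thresholds_must_be_ordered(self):
        s = self._series([0.0], [9.0])
        with pytest.raises(ParameterError):
            classify_seam_state(s, closed_min=1.0, open_max=2.0)

    def test_pipeline_all_four_then_all_zero(self, selection):
        closed = make_seam_trajectory(6, [4] * 6)
        series = hbond_series(closed, selection, window=3)
        assert set(classify_seam_state(series)) == {"closed"}
        open_ = make_seam_trajectory(6, [0] * 6)
        series = hbond_series(open_, selection, window=3)
        assert set(classify_seam_state(series)) == {"open"}


def test_min_seam_contact_reports_closest_no_pair(selection):
    traj = make_seam_trajectory(2, [1, 0])
    top = traj.topology
    d1 = min_seam_contact(top, selection.seam_strand_1,
                          selection.seam_strand_16, coords=traj.frames[0])
    d0 = min_seam_contact(top, selection.seam_strand_1,
                          selection.seam_strand_16, coords=traj.frames[1])
    assert d1 == pytest.approx(2.9, abs=1e-6)
    assert d0 > 3.5
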