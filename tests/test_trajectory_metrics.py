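"""Superposition, RMSD, R_g, SASA, contact maps, and the heme criterion."""

import numpy as np
import pytest

from unfoldscope import synthetic_data as sd
from unfoldscope.structure_io import Atom, Frame, Residue, Trajectory
from unfoldscope.trajectory_metrics import (
    ContactMap, contact_map, contact_similarity, detect_heme_loss,
    frame_metrics_table, heme_his_distance, radius_of_gyration, rmsd_matrix,
    rmsd_series, sasa, superpose,
)


def _random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=rng.integers(1 << 30)).as_matrix()


def _quaternion_rmsd(mobile, reference):
    """Independent oracle: Horn's quaternion method for optimal superposition."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    s = x.T @ y
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(key)[-1]
    e0 = np.sum(x ** 2) + np.sum(y ** 2)
    msd = max((e0 - 2.0 * lam) / len(x), 0.0)
    return np.sqrt(msd) / 10.0  # nm


class TestSuperpose:
    def test_rigid_transform_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 3)) * 5.0
        rot = _random_rotation(rng)
        y = x @ rot.T + np.array([3.0, -2.0, 7.0])
        _, _, rmsd = superpose(y, x)
        assert rmsd < 1e-6

    def test_mirror_image_not_matched(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 3)) * 5.0
        mirror = x * np.array([1.0, 1.0, -1.0])
        _, _, rmsd = superpose(mirror, x)
        assert rmsd > 0.01

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 3)) * 4.0
        y = rng.normal(size=(10, 3)) * 4.0
        _, _, rmsd = superpose(x, y)
        assert rmsd == pytest.approx(_quaternion_rmsd(x, y), abs=1e-9)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_collinear_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)


class TestRmsdSeries:
    def test_reference_frame_zero(self, unfolding):
        traj, _ = unfolding
        series = rmsd_series(traj, traj.frames[0])
        assert series[0] == pytest.approx(0.0, abs=1e-9)

    def test_tumbling_trajectory_flat(self, native_globin):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(5)
        frames = []
        for k in range(4):
            f = native_globin.copy()
            f.time = float(k)
            rot = Rotation.random(random_state=rng.integers(1 << 30)).as_matrix()
            shift = rng.normal(size=3) * 10.0
            for res in f.residues:
                for atom in res.atoms:
                    atom.coords = atom.coords @ rot.T + shift
            f.heme = None
            frames.append(f)
        series = rmsd_series(Trajectory(frames), native_globin)
        assert np.all(series < 1e-6)

    def test_unfolding_plateau_exceeds_start(self, unfolding):
        traj, _ = unfolding
        series = rmsd_series(traj, traj.frames[0])
        assert series[-20:].mean() > series[:20].mean()


class TestRmsdMatrix:
    def test_symmetry_zero_diagonal_and_oracle(self, unfolding):
        traj, _ = unfolding
        sub = Trajectory(traj.frames[:5])
        mat = rmsd_matrix(sub)
        assert np.allclose(mat, mat.T, atol=1e-9)
        assert np.allclose(np.diag(mat), 0.0)
        for i in range(5):
            for j in range(5):
                if i != j:
                    expected = superpose(sub[i].coords("CA"),
                                         sub[j].coords("CA"))[2]
                    assert mat[i, j] == pytest.approx(expected, abs=1e-12)

    def test_duplicated_frame(self, native_globin):
        f2 = native_globin.copy()
        f2.time = 1.0
        mat = rmsd_matrix(Trajectory([native_globin, f2]))
        assert mat[0, 1] == pytest.approx(0.0, abs=1e-9)


class TestRadiusOfGyration:
    def test_single_atom(self):
        frame = Frame(0.0, [Residue(1, "ALA", "A", [Atom("CA", "C", [1, 2, 3])])])
        assert radius_of_gyration(frame) == pytest.approx(0.0, abs=1e-12)

    def test_two_unit_masses(self):
        frame = Frame(0.0, [
            Residue(1, "ALA", "A", [Atom("CA", "C", [0, 0, 0], mass=1.0)]),
            Residue(2, "ALA", "A", [Atom("CA", "C", [2, 0, 0], mass=1.0)])])
        assert radius_of_gyration(frame) == pytest.approx(0.1)

    def test_native_globin_compact(self, native_globin):
        rg = radius_of_gyration(native_globin)
        assert 1.2 <= rg <= 1.8

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(Frame(0.0, []))


class TestSasa:
    def test_isolated_carbon_closed_form(self):
        frame = Frame(0.0, [Residue(1, "ALA", "A", [Atom("CA", "C", [0, 0, 0])])])
        total, per_res = sasa(frame)
        expected = 4.0 * np.pi * (1.70 + 1.4) ** 2 / 100.0
        assert total == pytest.approx(expected, rel=0.02)
        assert per_res[0] == pytest.approx(total)

    def test_fully_caged_atom_buried(self):
        from unfoldscope.trajectory_metrics import _sphere_lattice

        cage_dirs = _sphere_lattice(80)
        central = Residue(1, "ALA", "A", [Atom("C0", "C", [0.0, 0.0, 0.0])])
        cage = Residue(2, "ALA", "A",
                       [Atom(f"C{i}", "C", 2.0 * d)
                        for i, d in enumerate(cage_dirs, 1)])
        _, per_res = sasa(Frame(0.0, [central, cage]))
        assert per_res[0] == pytest.approx(0.0, abs=1e-9)

    def test_occlusion_monotone(self):
        lone = Frame(0.0, [Residue(1, "ALA", "A", [Atom("CA", "C", [0, 0, 0])])])
        pair = Frame(0.0, [Residue(1, "ALA", "A", [Atom("CA", "C", [0, 0, 0]),
                                                   Atom("CB", "C", [1.5, 0, 0])])])
        assert sasa(pair)[0] < 2 * sasa(lone)[0]

    def test_lattice_convergence(self, helix12):
        coarse = sasa(helix12, sphere_points=480)[0]
        fine = sasa(helix12, sphere_points=960)[0]
        assert abs(coarse - fine) / fine < 0.01


class TestContacts:
    def test_pair_within_cutoff(self):
        residues = [Residue(i, "ALA", "A", [Atom("CA", "C", c)]) for i, c in
                    [(1, [0, 0, 0]), (2, [4, 0, 0]), (3, [8, 0, 0]),
                     (4, [5, 3, 0])]]
        cm = contact_map(Frame(0.0, residues), cutoff=8.0)
        assert cm.contacts[0, 3]          # 1↔4: |i−j|=3, d≈5.8 Å
        assert not cm.contacts[0, 2]      # |i−j|=2 excluded by rule

    def test_rotation_invariance(self, native_globin):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("zyx", [10.0, 80.0, -30.0], degrees=True)
        moved = native_globin.copy()
        for res in moved.residues:
            for atom in res.atoms:
                atom.coords = rot.apply(atom.coords) + 4.0
        a = contact_map(native_globin)
        b = contact_map(moved)
        assert np.array_equal(a.contacts, b.contacts)

    def test_self_similarity_100(self, native_globin):
        cm = contact_map(native_globin)
        assert contact_similarity(cm, cm).similarity == 100.0

    def test_disjoint_maps_zero(self):
        n = 12
        m1 = np.zeros((n, n), dtype=bool)
        m2 = np.zeros((n, n), dtype=bool)
        m1[0, 5] = m1[5, 0] = True
        m2[2, 9] = m2[9, 2] = True
        comp = contact_similarity(ContactMap(m1, 8.0, "CA"),
                                  ContactMap(m2, 8.0, "CA"))
        assert comp.similarity == 0.0

    def test_shared_91_of_99(self):
        n = 40
        pairs = [(i, j) for i in range(n) for j in range(i + 3, n)]
        shared, only_a, only_b = pairs[:91], pairs[91:95], pairs[95:99]
        ma = np.zeros((n, n), dtype=bool)
        mb = np.zeros((n, n), dtype=bool)
        for i, j in shared + only_a:
            ma[i, j] = ma[j, i] = True
        for i, j in shared + only_b:
            mb[i, j] = mb[j, i] = True
        comp = contact_similarity(ContactMap(ma, 8.0, "CA"),
                                  ContactMap(mb, 8.0, "CA"))
        assert comp.similarity == pytest.approx(91.9, abs=0.05)
        assert len(comp.shared) == 91
        assert len(comp.unique_to_a) == 4 and len(comp.unique_to_b) == 4

    def test_symmetric_in_arguments(self, native_globin, unfolding):
        traj, _ = unfolding
        a = contact_map(native_globin)
        b = contact_map(traj.frames[100])
        assert contact_similarity(a, b).similarity == \
            contact_similarity(b, a).similarity


class TestHeme:
    def test_native_distance(self, native_globin):
        assert heme_his_distance(native_globin) == pytest.approx(0.64, abs=1e-6)

    def test_fe_at_com_gives_zero(self, native_globin):
        moved = native_globin.copy()
        res = moved.residue_by_index(93)
        coords = np.array([a.coords for a in res.atoms])
        masses = np.array([a.mass for a in res.atoms])
        com = np.average(coords, axis=0, weights=masses)
        for atom in moved.heme:
            atom.coords = atom.coords - moved.heme[0].coords + com
        assert heme_his_distance(moved) == pytest.approx(0.0, abs=1e-9)

    def test_missing_heme_rejected(self, helix12):
        with pytest.raises(ValueError, match="heme"):
            heme_his_distance(helix12)

    def test_constructed_crossing_detected(self, native_globin):
        frames = []
        for k in range(50):
            f = native_globin.copy()
            f.time = float(k * 100)
            d_nm = 0.64 if k < 37 else 1.30
            direction = np.array([1.0, 0.0, 0.0])
            res = f.residue_by_index(93)
            coords = np.array([a.coords for a in res.atoms])
            masses = np.array([a.mass for a in res.atoms])
            com = np.average(coords, axis=0, weights=masses)
            shift = com + 10.0 * d_nm * direction - f.heme[0].coords
            for atom in f.heme:
                atom.coords = atom.coords + shift
            frames.append(f)
        event = detect_heme_loss(Trajectory(frames))
        assert event.lost and event.first_time == pytest.approx(3700.0)

    def test_constant_native_distance_never_lost(self):
        traj, _ = sd.make_unfolding_trajectory(sd.UnfoldingConfig(
            seed=2, n_frames=10, t_loss_ns=None))
        event = detect_heme_loss(traj)
        assert not event.lost and event.first_time is None

    def test_scheduled_loss_recovered(self, unfolding):
        traj, truth = unfolding
        event = detect_heme_loss(traj)
        assert event.lost
        assert abs(event.first_time - 3700.0) <= traj.times[1] - traj.times[0]


class TestFrameMetricsTable:
    def test_columns_and_sanity(self, unfolding):
        traj, _ = unfolding
        sub = Trajectory(traj.frames[:6])
        df = frame_metrics_table(sub, traj.frames[0])
        for col in ["time_ps", "rmsd_ca", "rg", "sasa", "hbond_count",
                    "helix_count", "theta222", "fe_his93_dist"]:
            assert col in df.columns
        assert (df.rg > 0).all()
        assert (df.sasa > 0).all()
        assert df.fe_his93_dist.iloc[0] == pytest.approx(0.64, abs=1e-6)
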