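"""Kabsch–Sander H-bond energetics, code assignment, and helix bookkeeping."""

import numpy as np
import pytest

from unfoldscope import synthetic_data as sd
from unfoldscope.secondary_structure import (
    SSAssignment, assign_ss, count_mainchain_hbonds, detect_hbonds,
    fit_exponential_decay, hbond_energy, helix_segments, ss_timeseries,
)
from unfoldscope.structure_io import Atom, Frame, Residue


def _donor(n, h):
    return Residue(10, "ALA", "A", [Atom("N", "N", n), Atom("H", "H", h),
                                    Atom("CA", "C", np.add(n, [0, 1, 0]))])


def _acceptor(c, o):
    return Residue(1, "ALA", "A", [Atom("C", "C", c), Atom("O", "O", o),
                                   Atom("CA", "C", np.add(c, [0, 1, 0]))])


class TestHBondEnergy:
    def test_reference_distances(self):
        # geometry constructed to give r_ON=2.9, r_CH=4.0, r_OH=1.9, r_CN=3.5
        donor = _donor(n=[2.9, 0.0, 0.0], h=[1.9, 0.0, 0.0])
        acceptor = _acceptor(c=[4.275, 3.2185634597, 0.0], o=[0.0, 0.0, 0.0])
        e = hbond_energy(donor, acceptor)
        assert e == pytest.approx(-6.058, abs=2e-3)

    def test_equal_distances_cancel_exactly(self):
        donor = _donor(n=[-1.0, 0.0, 0.0], h=[1.0, 0.0, 0.0])
        acceptor = _acceptor(c=[0.0, -1.0, 0.0], o=[0.0, 1.0, 0.0])
        assert hbond_energy(donor, acceptor) == 0.0

    def test_clash_returns_sentinel(self):
        donor = _donor(n=[0.1, 0.0, 0.0], h=[0.2, 0.0, 0.0])
        acceptor = _acceptor(c=[3.0, 0.0, 0.0], o=[0.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="clash"):
            assert hbond_energy(donor, acceptor) == -9.9

    def test_missing_atoms_rejected(self):
        bare = Residue(5, "ALA", "A", [Atom("CA", "C", [0, 0, 0])])
        with pytest.raises(ValueError):
            hbond_energy(bare, _acceptor([3, 0, 0], [2, 0, 0]))

    def test_helix_i_i4_bonds_below_threshold(self, helix12):
        bonds = {(b.acceptor, b.donor): b.energy for b in detect_hbonds(helix12)}
        for i in range(1, 8):
            assert (i, i + 4) in bonds
            assert bonds[(i, i + 4)] < -0.5


class TestDetectHbonds:
    def test_helix_alpha_pattern(self, helix12):
        bonds = detect_hbonds(helix12)
        partners = {(b.acceptor, b.donor) for b in bonds}
        for i in range(1, 9):
            assert any(p == (i, i + 4) or p == (i - 4, i) for p in partners)

    def test_extended_strand_has_none(self, strand12):
        assert detect_hbonds(strand12) == []

    def test_two_residue_frame(self):
        frame = sd.build_backbone(2, "CC")
        assert detect_hbonds(frame) == []

    @pytest.mark.parametrize("fixture", ["helix12", "coil12", "hairpin",
                                         "native_globin"])
    def test_prefilter_is_lossfree(self, fixture, request):
        """The 9 Å CA prefilter must equal the brute-force all-pairs search."""
        frame = request.getfixturevalue(fixture)
        fast = detect_hbonds(frame, prefilter=True)
        slow = detect_hbonds(frame, prefilter=False)
        assert fast == slow

    def test_at_most_two_acceptors_per_donor(self, native_globin):
        donors = [b.donor for b in detect_hbonds(native_globin)]
        assert max(donors.count(d) for d in set(donors)) <= 2


class TestCountHbonds:
    def test_helix_count(self, helix12):
        assert count_mainchain_hbonds(helix12) >= 8

    def test_coil_count_low(self, coil12):
        assert count_mainchain_hbonds(coil12) <= 3

    def test_empty_frame(self):
        assert count_mainchain_hbonds(Frame(0.0, [])) == 0


class TestAssignSS:
    def test_ideal_helix(self, helix12):
        codes = assign_ss(helix12).codes
        assert codes.count("H") >= 8
        assert "E" not in codes

    def test_hairpin_sheet(self, hairpin):
        codes = assign_ss(hairpin).codes
        assert codes.count("E") >= 4

    def test_native_globin_helicity(self, native_globin):
        assign = assign_ss(native_globin)
        assert abs(assign.count() - 122) <= 5

    def test_rotation_invariance(self, native_globin):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [31.0, -57.0, 112.0], degrees=True)
        moved = native_globin.copy()
        for res in moved.residues:
            for atom in res.atoms:
                atom.coords = rot.apply(atom.coords) + np.array([5.0, -3.0, 11.0])
        assert assign_ss(moved).codes == assign_ss(native_globin).codes

    def test_incomplete_frame_rejected(self):
        residues = [Residue(i, "ALA", "A", [Atom("CA", "C", [4.0 * i, 0, 0])])
                    for i in range(1, 6)]
        with pytest.raises(ValueError, match="assignable"):
            assign_ss(Frame(0.0, residues))

    def test_helix_fraction_bounds(self, native_globin):
        assign = assign_ss(native_globin)
        f_h = assign.count() / len(assign)
        assert 0.0 <= f_h <= 1.0
        # the printed count→fraction conversion at N_r = 153
        assert round(105 / 153, 2) == 0.69
        assert round(120 / 153, 2) == 0.78


class TestHelixSegments:
    def test_hand_example(self):
        assign = SSAssignment("CCHHHHHHCCHHHHC")
        segs = helix_segments(assign, min_length=4)
        assert [(s.start, s.end, s.length) for s in segs] == [(3, 8, 6), (11, 14, 4)]

    def test_all_coil(self):
        assert helix_segments(SSAssignment("C" * 20)) == []

    def test_short_runs_discarded(self):
        assert helix_segments(SSAssignment("HHHCCCHHHH")) == \
            helix_segments(SSAssignment("CCCCCCHHHH"))

    def test_native_globin_eight_helices(self, native_globin):
        assert len(helix_segments(assign_ss(native_globin))) == 8

    def test_class_restriction(self):
        assign = SSAssignment("GGGGHHHH")
        assert len(helix_segments(assign, classes={"H"})) == 1
        assert len(helix_segments(assign, classes={"H", "G"})) == 1


class TestTimeseries:
    def test_constant_trajectory_columns_identical(self):
        traj, _ = sd.make_unfolding_trajectory(sd.UnfoldingConfig(
            seed=1, decay_rate_per_ns=0.0, noise_sigma_a=0.0, n_frames=4,
            t_loss_ns=None))
        ts = ss_timeseries(traj)
        raster = ts.raster
        assert raster.shape == (153, 4)
        assert all((raster[:, 0] == raster[:, k]).all() for k in range(4))

    def test_unfolding_decay_recovered(self, unfolding_ss):
        ts = unfolding_ss
        assert ts.raster.shape[0] == 153
        # helical content decays overall
        assert ts.helical_counts[-10:].mean() < ts.helical_counts[:10].mean()
        fit = fit_exponential_decay(ts.times, ts.helical_counts)
        assert fit.rate_per_ns == pytest.approx(0.2, rel=0.2)


class TestExponentialFit:
    def test_noiseless_recovery(self):
        t = np.linspace(0, 20000, 100)
        y = 20 + (120 - 20) * np.exp(-0.3 * t / 1000.0)
        fit = fit_exponential_decay(t, y)
        assert fit.n0 == pytest.approx(120, abs=1e-6)
        assert fit.rate_per_ns == pytest.approx(0.3, abs=1e-6)
        assert fit.offset == pytest.approx(20, abs=1e-6)

    def test_noisy_recovery_within_20pct(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0, 20000, 200)
        y = np.clip(20 + 100 * np.exp(-0.3 * t / 1000.0)
                    + rng.normal(0, 5, 200), 0, None)
        fit = fit_exponential_decay(t, y)
        assert fit.rate_per_ns == pytest.approx(0.3, rel=0.2)

    def test_constant_series_flagged(self):
        fit = fit_exponential_decay(np.arange(10) * 100.0, np.full(10, 42.0))
        assert fit.degenerate
        assert fit.rate_per_ns == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_decay(np.arange(3) * 100.0, np.arange(3) + 1.0)
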