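"""Structural observables against counting / geometric oracles."""

import numpy as np
import pytest

from conftest import build_ensemble, random_rotation
from tmdassoc import (AtomSelection, StructureEnsemble, com_distance, contacts,
                      d_imc, d_omc, hbond_occupancy, pc_overlap_convergence,
                      rmsd, rmsf, salt_bridge_occupancy, snorkeling_occupancy,
                      theta_angles)
from tmdassoc.exceptions import SelectionError, ValidationError


class TestComDistances:
    def test_toy_dimer_reproduces_requested_separation(self, toy_dimer):
        a = AtomSelection(chain="A", atom_names=("CA",))
        b = AtomSelection(chain="B", atom_names=("CA",))
        series = com_distance(toy_dimer, a, b)
        np.testing.assert_allclose(series.values, [9, 10, 12, 15, 20], atol=1e-6)

    def test_identical_selections_give_zero(self, toy_dimer):
        a = AtomSelection(chain="A", atom_names=("CA",))
        assert com_distance(toy_dimer, a, a).values.max() == 0.0

    def test_three_four_five_offset(self):
        # two single-atom "motifs" offset by (3, 4, 0) -> distance 5
        ens = build_ensemble([[[0, 0, 0], [3, 4, 0]]],
                             [("A", 972, "GLY", "CA", "C"), ("B", 700, "VAL", "CA", "C")])
        series = com_distance(ens, AtomSelection(chain="A"), AtomSelection(chain="B"))
        assert series.values[0] == pytest.approx(5.0)

    def test_d_omc_uses_motif_ca_groups(self, toy_dimer):
        series = d_omc(toy_dimer)
        assert series.values.shape == (5,)
        # pulling the helices apart must monotonically widen the outer clasp
        assert np.all(np.diff(series.values) > 0)


class TestInnerClasp:
    def _ens(self, d992, d993):
        rows = [("A", 992, "PHE", "RC", "C"), ("A", 993, "PHE", "RC", "C"),
                ("B", 715, "TRP", "RC", "C")]
        frames = [[[d992, 0, 0], [0, d993, 0], [0, 0, 0]]]
        return build_ensemble(frames, rows)

    def test_min_rule(self):
        assert d_imc(self._ens(3.0, 8.0)).values[0] == pytest.approx(3.0)
        assert d_imc(self._ens(8.0, 3.0)).values[0] == pytest.approx(3.0)

    def test_symmetric_placement(self):
        assert d_imc(self._ens(5.0, 5.0)).values[0] == pytest.approx(5.0)

    def test_missing_ring_raises(self, toy_dimer):
        with pytest.raises(SelectionError):
            d_imc(toy_dimer, trp_res=999)


class TestHbond:
    def _ens(self, geoms):
        """geoms: list of (d_DA, angle_deg); donor N, hydrogen on the D-H-A
        elbow, acceptor O."""
        rows = [("B", 716, "LYS", "NZ", "N"), ("B", 716, "LYS", "HZ", "H"),
                ("A", 992, "PHE", "O", "O")]
        frames = []
        for d, ang in geoms:
            h = np.array([1.0, 0.0, 0.0])
            # place acceptor so that angle D-H-A equals ang
            theta = np.deg2rad(180.0 - ang)
            a = h + (d - 1.0) * np.array([np.cos(theta), np.sin(theta), 0.0])
            frames.append([[0, 0, 0], h, a])
        return build_ensemble(frames, rows)

    donor = AtomSelection(chain="B", res_ids=(716,), atom_names=("NZ",))
    hydrogen = AtomSelection(chain="B", res_ids=(716,), atom_names=("HZ",))
    acceptor = AtomSelection(chain="A", res_ids=(992,), atom_names=("O",))

    def test_counting_oracle(self):
        ens = self._ens([(3.0, 175.0)] * 4 + [(5.0, 175.0)] * 6)
        occ = hbond_occupancy(ens, self.donor, self.acceptor, self.hydrogen)
        assert occ == pytest.approx(0.4)

    def test_angle_gate(self):
        ens = self._ens([(3.4, 90.0)] * 5)
        assert hbond_occupancy(ens, self.donor, self.acceptor, self.hydrogen) == 0.0

    def test_ideal_geometry(self):
        ens = self._ens([(2.9, 178.0)] * 5)
        assert hbond_occupancy(ens, self.donor, self.acceptor, self.hydrogen) == 1.0

    def test_distance_only_fallback_warns(self):
        ens = self._ens([(3.0, 90.0)] * 2)
        with pytest.warns(UserWarning, match="distance-only"):
            occ = hbond_occupancy(ens, self.donor, self.acceptor, hydrogen=None)
        assert occ == 1.0  # angle criterion dropped

    def test_donor_equals_acceptor_rejected(self):
        ens = self._ens([(3.0, 170.0)])
        with pytest.raises(ValidationError):
            hbond_occupancy(ens, self.donor, self.donor, self.hydrogen)


class TestSaltBridgeAndSnorkeling:
    def _bridge_ens(self, dists):
        rows = [("A", 995, "ARG", "NH1", "N"), ("A", 995, "ARG", "NH2", "N"),
                ("B", 723, "ASP", "OD1", "O"), ("B", 723, "ASP", "OD2", "O")]
        frames = [[[0, 0, 0], [0, 1.5, 0], [d, 0, 0], [d, 1.5, 0]] for d in dists]
        return build_ensemble(frames, rows)

    arg = AtomSelection(chain="A", atom_names=("NH1", "NH2"))
    asp = AtomSelection(chain="B", atom_names=("OD1", "OD2"))

    def test_alternating_distances(self):
        ens = self._bridge_ens([3.5, 4.5] * 5)
        assert salt_bridge_occupancy(ens, self.arg, self.asp) == pytest.approx(0.5)

    def test_boundary_is_inclusive(self):
        ens = self._bridge_ens([4.0] * 3)
        assert salt_bridge_occupancy(ens, self.arg, self.asp) == 1.0

    def test_far_apart_never_bridges(self):
        ens = self._bridge_ens([20.0] * 3)
        assert salt_bridge_occupancy(ens, self.arg, self.asp) == 0.0

    def _snork_ens(self, depths):
        rows = [("B", 716, "LYS", "NZ", "N")] + \
               [("L", i + 1, "LIP", "O", "O") for i in range(3)]
        frames = [[[0, 0, 0], [0, 0, -d], [5, 0, -d], [0, 5, -d]] for d in depths]
        return build_ensemble(frames, rows)

    def test_plane_three_angstrom_below(self):
        occ, series = snorkeling_occupancy(self._snork_ens([3.0] * 4))
        assert occ == 1.0
        np.testing.assert_allclose(series.values, 3.0)

    def test_plane_out_of_reach(self):
        occ, _ = snorkeling_occupancy(self._snork_ens([10.0] * 4))
        assert occ == 0.0

    def test_mixed_frames_counting_oracle(self):
        occ, _ = snorkeling_occupancy(self._snork_ens([3.0] * 7 + [8.0] * 3))
        assert occ == pytest.approx(0.7)


class TestContacts:
    def test_two_frame_counting_example(self):
        # frame 0: two inter-chain atom pairs within 7 Å; frame 1: one
        rows = [("A", 1, "ALA", "CA", "C"), ("A", 2, "ALA", "CA", "C"),
                ("A", 3, "ALA", "CA", "C"), ("B", 11, "ALA", "CA", "C"),
                ("B", 12, "ALA", "CA", "C"), ("B", 13, "ALA", "CA", "C")]
        f0 = [[0, 0, 0], [0, 0, 10], [0, 0, 20], [5, 0, 0], [5, 0, 10], [50, 0, 0]]
        f1 = [[0, 0, 0], [0, 0, 10], [0, 0, 20], [5, 0, 0], [30, 0, 10], [50, 0, 0]]
        ens = build_ensemble([f0, f1], rows)
        rep = contacts(ens, AtomSelection(chain="A"), AtomSelection(chain="B"),
                       granularity="atom")
        np.testing.assert_array_equal(rep.native, [2, 1])
        np.testing.assert_array_equal(rep.non_native, [0, 0])

    def test_reference_frame_has_no_nonnative(self, toy_dimer):
        rep = contacts(toy_dimer, AtomSelection(chain="A"), AtomSelection(chain="B"))
        assert rep.non_native[rep.reference_frame] == 0
        assert rep.native[rep.reference_frame] == max(rep.native)

    @pytest.mark.parametrize("granularity", ["atom", "residue"])
    def test_matches_bruteforce_oracle(self, granularity):
        rng = np.random.default_rng(5)
        n = 40
        rows = ([("A", i // 4 + 1, "ALA", f"X{i % 4}", "C") for i in range(n)]
                + [("B", i // 4 + 100, "ALA", f"Y{i % 4}", "C") for i in range(n)])
        frames = rng.uniform(0, 15, size=(4, 2 * n, 3))
        ens = build_ensemble(frames, rows)
        rep = contacts(ens, AtomSelection(chain="A"), AtomSelection(chain="B"),
                       granularity=granularity)
        res_ids = ens.atoms["res_id"].to_numpy()
        for f in range(4):
            pairs = set()
            for i in range(n):
                for j in range(n, 2 * n):
                    if np.linalg.norm(frames[f, i] - frames[f, j]) <= 7.0:
                        pairs.add((i, j) if granularity == "atom"
                                  else (res_ids[i], res_ids[j]))
            if f == 0:
                ref = pairs
            assert rep.native[f] == len(pairs & ref)
            assert rep.non_native[f] == len(pairs - ref)

    def test_overlapping_chain_selections_rejected(self, toy_dimer):
        sel = AtomSelection(chain="A")
        with pytest.raises(ValidationError):
            contacts(toy_dimer, sel, sel)


def _quaternion_rmsd(mobile, reference, weights):
    """Independent superposition oracle: Horn's quaternion method."""
    w = weights / weights.sum()
    m = mobile - (mobile * w[:, None]).sum(0)
    r = reference - (reference * w[:, None]).sum(0)
    cov = (m * w[:, None]).T @ r
    a = np.empty((4, 4))
    a[0, 0] = cov[0, 0] + cov[1, 1] + cov[2, 2]
    a[0, 1] = a[1, 0] = cov[1, 2] - cov[2, 1]
    a[0, 2] = a[2, 0] = cov[2, 0] - cov[0, 2]
    a[0, 3] = a[3, 0] = cov[0, 1] - cov[1, 0]
    a[1, 1] = cov[0, 0] - cov[1, 1] - cov[2, 2]
    a[1, 2] = a[2, 1] = cov[0, 1] + cov[1, 0]
    a[1, 3] = a[3, 1] = cov[0, 2] + cov[2, 0]
    a[2, 2] = -cov[0, 0] + cov[1, 1] - cov[2, 2]
    a[2, 3] = a[3, 2] = cov[1, 2] + cov[2, 1]
    a[3, 3] = -cov[0, 0] - cov[1, 1] + cov[2, 2]
    lam = np.linalg.eigvalsh(a)[-1]
    msd = (w * ((m ** 2).sum(1) + (r ** 2).sum(1))).sum() - 2.0 * lam
    return np.sqrt(max(msd, 0.0))


class TestRmsdRmsf:
    def test_reference_frame_rmsd_zero(self, toy_dimer):
        series = rmsd(toy_dimer, AtomSelection(chain="A", atom_names=("CA",)))
        assert series.values[0] == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(6, 3)) * 3
        rot = random_rotation(rng)
        rows = [("A", i + 1, "ALA", "CA", "C") for i in range(6)]
        ens = build_ensemble([base, base @ rot.T + [5, -3, 2]], rows)
        series = rmsd(ens, AtomSelection(chain="A"))
        assert series.values[1] == pytest.approx(0.0, abs=1e-8)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(3)
        rows = ([("A", i + 1, "ALA", "CA", "C") for i in range(3)]
                + [("A", 4, "ALA", "O", "O")])
        base = rng.normal(size=(4, 3)) * 4
        moved = base.copy()
        moved[3] += [1.2, -0.4, 2.0]
        moved = moved @ random_rotation(rng).T + [1, 2, 3]
        ens = build_ensemble([base, moved], rows)
        sel = AtomSelection(chain="A")
        series = rmsd(ens, sel)
        masses = ens.masses
        expected = _quaternion_rmsd(moved, base, masses)
        assert series.values[1] == pytest.approx(expected, abs=1e-8)

    def test_rmsf_static_is_zero(self, toy_dimer):
        ens = build_ensemble([toy_dimer.coords[0]] * 3, toy_dimer.atoms)
        out = rmsf(ens, AtomSelection(chain="A", atom_names=("CA",)))
        np.testing.assert_allclose(out["rmsf"], 0.0, atol=1e-10)

    def test_isotropic_jitter_gives_sqrt3_sigma(self):
        rng = np.random.default_rng(1)
        n_frames = 10_000
        base = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10], [20, 5, 5]],
                        dtype=float)
        rows = [("A", i + 1, "ALA", "CA", "C") for i in range(5)]
        frames = np.repeat(base[None], n_frames, axis=0)
        frames[:, 4, :] += rng.normal(0, 1.0, size=(n_frames, 3))
        ens = build_ensemble(frames, rows)
        out = rmsf(ens, AtomSelection(chain="A", atom_names=("CA",)),
                   fit_sel=AtomSelection(chain="A", res_ids=(1, 2, 3, 4)))
        assert out["rmsf"].iloc[4] == pytest.approx(np.sqrt(3.0), rel=0.05)

    def test_frame_permutation_leaves_rmsf_unchanged(self, toy_dimer):
        sel = AtomSelection(chain="A", atom_names=("CA",))
        a = rmsf(toy_dimer, sel)["rmsf"].to_numpy()
        permuted = StructureEnsemble(toy_dimer.coords[[2, 0, 4, 1, 3]], toy_dimer.atoms)
        b = rmsf(permuted, sel)["rmsf"].to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_single_frame_rmsf_undefined(self, toy_dimer):
        with pytest.raises(ValidationError):
            rmsf(toy_dimer.frame(0), AtomSelection(chain="A", atom_names=("CA",)))


class TestThetaAngles:
    def _ens(self, ref_a_pos):
        """Single-CA 'helices' plus one-residue reference triplets."""
        rows = [("A", 980, "ALA", "CA", "C"), ("B", 710, "ALA", "CA", "C"),
                ("A", 972, "ALA", "CA", "C"), ("B", 699, "ALA", "CA", "C")]
        # chains: A CAs = residues 980+972; B CAs = 710+699 -> use selections
        frames = [[[0, 0, 0], [10, 0, 0], list(ref_a_pos), [5, 5, 0]]]
        return build_ensemble(frames, rows)

    def _angles(self, ens):
        return theta_angles(
            ens,
            helix1_sel=AtomSelection(chain="A", res_ids=(980,)),
            helix2_sel=AtomSelection(chain="B", res_ids=(710,)),
            ref_a_sel=AtomSelection(chain="A", res_ids=(972,)),
            ref_b_sel=AtomSelection(chain="B", res_ids=(699,)))

    def test_collinear_gives_zero_or_pi(self):
        ta, _ = self._angles(self._ens([20, 0, 0]))
        assert ta.values[0] == pytest.approx(0.0, abs=1e-12)
        ta, _ = self._angles(self._ens([-20, 0, 0]))
        assert ta.values[0] == pytest.approx(np.pi, abs=1e-12)

    def test_right_angle(self):
        ta, _ = self._angles(self._ens([0, 7, 0]))
        assert ta.values[0] == pytest.approx(np.pi / 2, abs=1e-12)

    def test_rigid_rotation_invariance(self, toy_dimer):
        ta0, tb0 = theta_angles(toy_dimer)
        rng = np.random.default_rng(8)
        rot = random_rotation(rng)
        rotated = StructureEnsemble(toy_dimer.coords @ rot.T + [3, -1, 7],
                                    toy_dimer.atoms)
        ta1, tb1 = theta_angles(rotated)
        np.testing.assert_allclose(ta0.values, ta1.values, atol=1e-9)
        np.testing.assert_allclose(tb0.values, tb1.values, atol=1e-9)


class TestPCOverlap:
    def _jittered(self, center, n, seed):
        rng = np.random.default_rng(seed)
        base = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [10, 10, 0]], float)
        rows = [("A", i + 1, "ALA", "CA", "C") for i in range(4)]
        frames = np.repeat(base[None], n, axis=0)
        frames[:, 0, 0] += center + rng.normal(0, 0.1, n)
        return build_ensemble(frames, rows)

    def test_identical_trajectories_fully_overlap(self):
        ens = self._jittered(0.0, 60, seed=0)
        overlap = pc_overlap_convergence(ens, ens, n_components=2, n_timepoints=3)
        np.testing.assert_allclose(overlap[-1], 1.0, atol=1e-12)
        assert np.all((overlap >= 0) & (overlap <= 1))

    def test_separated_gaussians_do_not_overlap(self):
        a = self._jittered(0.0, 80, seed=1)
        b = self._jittered(1.0, 80, seed=2)  # 10 sigma apart along PC1
        overlap = pc_overlap_convergence(a, b, n_components=1, n_timepoints=2)
        assert overlap[-1, 0] < 0.01

    def test_too_few_frames_rejected(self):
        a = self._jittered(0.0, 2, seed=3)
        with pytest.raises(ValidationError):
            pc_overlap_convergence(a, a, n_components=3)


class TestRigidMotionInvariance:
    def test_distance_observables_invariant(self, toy_dimer):
        rng = np.random.default_rng(11)
        rot = random_rotation(rng)
        moved = StructureEnsemble(toy_dimer.coords @ rot.T + [1, 2, 3],
                                  toy_dimer.atoms)
        for func in (d_omc, d_imc):
            np.testing.assert_allclose(func(toy_dimer).values, func(moved).values,
                                       atol=1e-9)
        from tmdassoc import reference_distances
        a = reference_distances(toy_dimer)
        b = reference_distances(moved)
        for key in a:
            assert a[key] == pytest.approx(b[key], abs=1e-9)
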