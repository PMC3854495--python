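"""Superposition, RMSD series, helix angles, salt bridges, Ca2+ coordination."""

import numpy as np
import pytest

import lobescope as lb
from lobescope import DegenerateGeometryError
from lobescope.regions import RegionScheme
from lobescope.synth import _helix_points
from lobescope.topology import ConformerSet, make_atom

from conftest import random_rotation


class TestSuperpose:
    def test_identical_frames_zero_rmsd(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((30, 3)) * 10
        rmat, t, value = lb.superpose(x, x)
        assert value == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(rmat, np.eye(3), atol=1e-6)

    def test_recovers_constructed_rotation(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((50, 3)) * 10
        rot = random_rotation(rng)
        shift = np.array([5.0, -3.0, 12.0])
        moved = x @ rot.T + shift
        rmat, t, value = lb.superpose(x, moved)
        assert value == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(rmat, rot, atol=1e-6)
        assert np.linalg.det(rmat) == pytest.approx(1.0, abs=1e-9)

    def test_noise_rmsd_matches_sigma_sqrt3(self):
        rng = np.random.default_rng(3)
        sigma = 0.5
        x = rng.standard_normal((1000, 3)) * 15
        noisy = x + rng.normal(0, sigma, x.shape)
        _, _, value = lb.superpose(noisy, x)
        assert value == pytest.approx(sigma * np.sqrt(3), rel=0.1)

    def test_too_few_atoms(self):
        with pytest.raises(DegenerateGeometryError):
            lb.superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_selection_rejected(self):
        line = np.outer(np.arange(10.0), [1.0, 0, 0])
        with pytest.raises(DegenerateGeometryError):
            lb.superpose(line, line)

    def test_symmetric_and_rigid_motion_invariant(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((40, 3)) * 8
        b = a + rng.normal(0, 1.0, a.shape)
        _, _, ab = lb.superpose(a, b)
        _, _, ba = lb.superpose(b, a)
        assert ab == pytest.approx(ba, rel=1e-9)
        rot = random_rotation(rng)
        _, _, moved = lb.superpose(a @ rot.T + 3.0, b @ rot.T + 3.0)
        assert moved == pytest.approx(ab, rel=1e-6)


class TestRmsdSeries:
    def _two_domain(self, shift):
        n = 40
        atoms = [make_atom(i + 1, "CA", "ALA", i + 1, element="C") for i in range(n)]
        rng = np.random.default_rng(6)
        base = rng.standard_normal((n, 3)) * 6
        moved = base.copy()
        moved[20:] += shift
        return ConformerSet(atoms=atoms, frames=np.stack([base, moved])), n

    def test_reference_frame_scores_zero(self, dumbbell):
        idx = np.arange(dumbbell.n_atoms)
        values = lb.rmsd_series(dumbbell, 0, idx)
        assert values[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_body_motion_scores_zero(self, dumbbell):
        rng = np.random.default_rng(7)
        frames = [dumbbell.frames[0]]
        for _ in range(3):
            frames.append(dumbbell.frames[0] @ random_rotation(rng).T + rng.standard_normal(3) * 5)
        traj = dumbbell.with_frames(np.stack(frames))
        values = lb.rmsd_series(traj, 0, np.arange(traj.n_atoms))
        np.testing.assert_allclose(values, 0.0, atol=1e-8)

    def test_displaced_domain_closed_form(self):
        shift = np.array([5.0, 0.0, 0.0])
        cs, n = self._two_domain(shift)
        fixed = np.arange(20)
        moved = np.arange(20, n)
        # fit on the fixed domain: the displaced domain reads exactly |shift|
        values = lb.rmsd_series(cs, 0, fixed, moved)
        assert values[1] == pytest.approx(np.linalg.norm(shift), rel=1e-9)
        # fit = subunit, measure = all: dilution by sqrt(fraction displaced)
        values_all = lb.rmsd_series(cs, 0, fixed, np.arange(n))
        assert values_all[1] == pytest.approx(
            np.linalg.norm(shift) * np.sqrt(len(moved) / n), rel=1e-9
        )


class TestHelixAxis:
    def _helix_cs(self, n=13, axis=(0, 0, 1)):
        pts = _helix_points(n, (0, 0, 0), np.asarray(axis, dtype=float), 1.5, 100.0, 2.3)
        atoms = [make_atom(i + 1, "CA", "ALA", i + 1, element="C") for i in range(n)]
        return ConformerSet(atoms=atoms, frames=pts[None, :, :])

    def test_ideal_helix_axis_near_z(self):
        cs = self._helix_cs()
        axis = lb.helix_axis(cs, (1, 13))
        angle = np.degrees(np.arccos(np.clip(axis @ [0, 0, 1], -1, 1)))
        assert angle < 2.0

    def test_equivariance_under_rotation(self):
        cs = self._helix_cs()
        rng = np.random.default_rng(9)
        rot = random_rotation(rng)
        moved = cs.with_frames(cs.frames @ rot.T)
        a0 = lb.helix_axis(cs, (1, 13))
        a1 = lb.helix_axis(moved, (1, 13))
        np.testing.assert_allclose(a1, rot @ a0, atol=1e-9)

    def test_four_residue_helix_rejected(self):
        cs = self._helix_cs(n=4)
        with pytest.raises(DegenerateGeometryError):
            lb.helix_axis(cs, (1, 4))


class TestInterhelixAngle:
    def _pair_cs(self, angle_deg):
        return lb.make_helix_tilt_trajectory([angle_deg], helix_a=(1, 13), helix_b=(20, 32))

    def test_translated_copy_scores_zero(self):
        cs = self._pair_cs(0.0)
        assert lb.interhelix_angle(cs, (1, 13), (20, 32)) == pytest.approx(0.0, abs=1.0)

    def test_right_angle_recovered(self):
        cs = self._pair_cs(90.0)
        assert lb.interhelix_angle(cs, (1, 13), (20, 32)) == pytest.approx(90.0, abs=1.0)

    def test_antiparallel_copy_scores_180(self):
        cs = self._pair_cs(180.0)
        assert lb.interhelix_angle(cs, (1, 13), (20, 32)) == pytest.approx(180.0, abs=1.0)

    def test_reversed_helix_gives_supplement(self):
        cs = self._pair_cs(72.0)
        fwd = lb.interhelix_angle(cs, (1, 13), (20, 32))
        # reverse helix B by renumbering its residues backwards
        atoms = list(cs.atoms[:13]) + [
            make_atom(14 + k, "CA", "ALA", 32 - k, element="C") for k in range(13)
        ]
        rev = ConformerSet(atoms=atoms, frames=cs.frames.copy())
        back = lb.interhelix_angle(rev, (1, 13), (20, 32))
        assert fwd + back == pytest.approx(180.0, abs=1e-6)

    def test_scripted_step_tilt_crossing_recovered(self, scheme):
        """EF-hand-like rearrangement: helix II tilts from 80 to 56 degrees
        at frame 20; the measured series crosses 68 degrees within +-2."""
        cs = lb.make_helix_tilt_trajectory([80.0] * 20 + [56.0] * 20)
        series = lb.interhelix_angle_series(cs, scheme, "I", "II")
        crossing = int(np.argmax(series < 68.0))
        assert abs(crossing - 20) <= 2
        assert series[:18].mean() > 70 and series[-18:].mean() < 62


def glu_arg_system(distance, n_frames=5):
    """A GLU carboxylate and an ARG guanidinium group at a set separation."""
    atoms = [
        make_atom(1, "OE1", "GLU", 10, element="O"),
        make_atom(2, "OE2", "GLU", 10, element="O"),
        make_atom(3, "NH1", "ARG", 50, element="N"),
        make_atom(4, "NH2", "ARG", 50, element="N"),
        make_atom(5, "NE", "ARG", 50, element="N"),
    ]
    frame = np.array(
        [
            [0.0, 0.0, 0.0],
            [-1.0, 1.0, 0.0],
            [distance, 0.0, 0.0],
            [distance + 1.0, 1.0, 0.0],
            [distance + 1.0, -1.0, 0.0],
        ]
    )
    return ConformerSet(atoms=atoms, frames=np.tile(frame, (n_frames, 1, 1)))


class TestSaltBridges:
    def test_contact_pair_reported_with_full_occupancy(self):
        events = lb.salt_bridge_scan(glu_arg_system(3.0))
        assert len(events) == 1
        ev = events[0]
        assert (ev.acidic_residue, ev.basic_residue) == (10, 50)
        assert ev.occupancy == pytest.approx(1.0)
        assert ev.min_distance == pytest.approx(3.0)
        assert (ev.first_frame, ev.last_frame) == (0, 4)

    def test_distant_pair_not_reported(self):
        assert lb.salt_bridge_scan(glu_arg_system(8.0)) == []

    def test_event_list_matches_exhaustive_scan(self):
        rng = np.random.default_rng(31)
        cs = glu_arg_system(3.0, n_frames=40)
        frames = cs.frames.copy()
        # jitter the basic group away and back
        frames[:, 2:, 0] += rng.uniform(0, 4.0, size=(40, 1))
        cs = cs.with_frames(frames)
        events = lb.salt_bridge_scan(cs, cutoff=4.0, min_occupancy=0.0)
        mins = np.empty(40)
        for f in range(40):
            d = frames[f, :2][:, None, :] - frames[f, 2:][None, :, :]
            mins[f] = np.sqrt((d * d).sum(-1)).min()
        formed = mins <= 4.0
        if formed.any():
            assert len(events) == 1
            ev = events[0]
            assert ev.occupancy == pytest.approx(formed.mean())
            assert ev.first_frame == int(np.where(formed)[0][0])
            assert ev.last_frame == int(np.where(formed)[0][-1])
            assert ev.min_distance == pytest.approx(mins.min())
        else:
            assert events == []


def ef_site(broken=False):
    """One EF-loop-like site: two Asp side-chain oxygens around a Ca2+ ion."""
    atoms = [
        make_atom(1, "OD1", "ASP", 1, element="O"),
        make_atom(2, "OD1", "ASP", 2, element="O"),
        make_atom(3, "CA", "CA", 100, hetero=True),
    ]
    frame = np.array([[2.4, 0.0, 0.0], [-2.4, 0.0, 0.0], [0.0, 0.0, 0.0]])
    if broken:
        frame[1] = [-5.0, 0.0, 0.0]
    scheme = RegionScheme(regions={"site": (1, 2)}, ef_loops={"I": (1, 2)})
    return ConformerSet(atoms=atoms, frames=frame[None, :, :]), scheme


class TestCaCoordination:
    def test_intact_site(self):
        cs, scheme = ef_site()
        intact, distances = lb.ca_coordination_check(cs, scheme, cutoff=3.2)
        assert bool(intact["I"][0])
        assert distances[("I", 1)][0] == pytest.approx(2.4)

    def test_pulled_residue_flags_loop_broken(self):
        cs, scheme = ef_site(broken=True)
        intact, distances = lb.ca_coordination_check(cs, scheme, cutoff=3.2)
        assert not bool(intact["I"][0])
        assert distances[("I", 2)][0] == pytest.approx(5.0)

    def test_distances_match_brute_force(self):
        rng = np.random.default_rng(41)
        cs, scheme = ef_site()
        frames = np.repeat(cs.frames, 6, axis=0) + rng.normal(0, 0.3, (6, 3, 3))
        cs = cs.with_frames(frames)
        _, distances = lb.ca_coordination_check(cs, scheme, cutoff=3.2)
        for (loop, res), series in distances.items():
            idx = {1: 0, 2: 1}[res]
            brute = np.linalg.norm(frames[:, idx] - frames[:, 2], axis=1)
            np.testing.assert_allclose(series, brute, atol=1e-12)

    def test_missing_ions_rejected(self):
        cs, scheme = ef_site()
        no_ion = cs.subset([0, 1])
        with pytest.raises(lb.EmptySelectionError):
            lb.ca_coordination_check(no_ion, scheme, cutoff=3.2)
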