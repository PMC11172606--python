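"""Analysis quantities vs independent brute-force implementations, plus
the association-event state machine and collision-time arithmetic."""

import numpy as np
import pytest

from pacsab import (association_events, collision_time, contact_map,
                    distance_trace, make_synthetic_trace,
                    min_intermolecular_distance, radius_of_gyration,
                    rg_distribution, rg_series, rmsd, rmsd_2d, rmsd_series)
from pacsab.analysis import DistanceTrace, hbond_occupancy
from pacsab.io_formats import Trajectory


def toy_two_mol_traj(frames, box=87.0, res_per_chain=3):
    """Trajectory with 2 molecules x res_per_chain residues x 2 particles."""
    frames = np.asarray(frames, dtype=float)
    nf, n, _ = frames.shape
    per_mol = n // 2
    res_in = np.repeat(np.arange(per_mol // 2), 2)
    return Trajectory(
        coords=frames,
        times=np.arange(1, nf + 1) * 10.0,
        box=box,
        kinds=np.tile(np.array([2, 5], dtype=np.int8), n // 2),
        res_index=np.concatenate([res_in, res_in + per_mol // 2]).astype(np.int32),
        mol_index=np.repeat([0, 1], per_mol).astype(np.int32),
        masses=np.ones(n),
        metadata={},
    )


class TestMinDistance:
    def test_minimum_image_wrap(self):
        coords = np.array([[0.0, 0, 0], [86.0, 0, 0]])
        d = min_intermolecular_distance(coords, [0, 1], 87.0)
        assert d == pytest.approx(1.0)

    def test_superposed_molecules_give_zero(self):
        coords = np.array([[1.0, 2, 3], [1.0, 2, 3]])
        assert min_intermolecular_distance(coords, [0, 1], 50.0) == 0.0

    def test_matches_brute_force(self, rng):
        coords = rng.uniform(0, 87, size=(30, 3))
        mol = (np.arange(30) >= 15).astype(int)
        best = np.inf
        for i in range(15):
            for j in range(15, 30):
                d = coords[i] - coords[j]
                d -= 87.0 * np.floor(d / 87.0 + 0.5)
                best = min(best, np.sqrt((d ** 2).sum()))
        assert min_intermolecular_distance(coords, mol, 87.0) == pytest.approx(best)


class TestContactMap:
    def test_never_in_contact_gives_zero_map(self, rng):
        a = rng.uniform(0, 5, size=(5, 6, 3))
        b = a + np.array([40.0, 0, 0])
        t = toy_two_mol_traj(np.concatenate([a, b], axis=1), box=100.0)
        cm = contact_map(t, "inter", cutoff=6.5)
        assert cm.counts.sum() == 0

    def test_crafted_contacts_counted_per_frame(self):
        # residues 0 (mol 0) and 2 (mol 1) touch in exactly 7 of 10 frames
        nf = 10
        frames = np.zeros((nf, 12, 3))
        frames[:, :, 0] = np.arange(12) * 10.0  # all far apart
        frames[:, :, 1] = 0.0
        for f in range(7):
            frames[f, 10] = frames[f, 0] + np.array([0.0, 3.0, 0.0])  # res 2 of mol 1
        t = toy_two_mol_traj(frames, box=500.0)
        cm = contact_map(t, "inter", cutoff=6.5)
        assert cm.counts[0, 2] == 7
        assert cm.counts[2, 0] == 7  # symmetrised
        mask = np.ones_like(cm.counts, dtype=bool)
        mask[0, 2] = mask[2, 0] = False
        assert cm.counts[mask].sum() == 0

    def test_additive_over_frame_partitions(self, rng):
        frames = rng.uniform(0, 30, size=(8, 12, 3))
        t = toy_two_mol_traj(frames, box=30.0)
        full = contact_map(t, "inter", 6.5).counts
        part = (contact_map(t, "inter", 6.5, frame_range=(0, 3)).counts
                + contact_map(t, "inter", 6.5, frame_range=(3, 8)).counts)
        assert np.array_equal(full, part)
        sub = contact_map(t, "inter", 6.5, frame_range=(0, 3)).counts
        assert (full >= sub).all()  # subrange vs full-run relation

    def test_intra_excludes_near_diagonal(self, rng):
        frames = rng.uniform(0, 10, size=(4, 12, 3))
        t = toy_two_mol_traj(frames, box=100.0)
        cm = contact_map(t, "intra", cutoff=50.0)
        n = cm.counts.shape[0]
        for i in range(n):
            for j in range(n):
                if abs(i - j) < 3:
                    assert cm.counts[i, j] == 0

    def test_intra_matches_brute_force(self, rng):
        frames = rng.uniform(0, 15, size=(3, 12, 3))
        t = toy_two_mol_traj(frames, box=100.0)
        cm = contact_map(t, "intra", cutoff=6.0)
        nres = 3
        expected = np.zeros((nres, nres), dtype=int)
        for f in range(3):
            for mol in range(2):
                off = mol * 6
                for ri in range(nres):
                    for rj in range(ri + 3, nres):
                        pi = frames[f, off + 2 * ri: off + 2 * ri + 2]
                        pj = frames[f, off + 2 * rj: off + 2 * rj + 2]
                        d = np.linalg.norm(pi[:, None] - pj[None], axis=2).min()
                        if d < 6.0:
                            expected[ri, rj] += 1
                            expected[rj, ri] += 1
        assert np.array_equal(cm.counts, expected)


class TestRg:
    def test_point_mass_zero(self):
        assert radius_of_gyration(np.zeros((4, 3)), np.ones(4)) == 0.0

    def test_two_particles_closed_form(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(coords, np.ones(2)) == pytest.approx(1.0)

    def test_matches_definition(self, rng):
        coords = rng.normal(size=(20, 3)) * 5
        m = rng.uniform(1, 16, size=20)
        com = (m[:, None] * coords).sum(0) / m.sum()
        expected = np.sqrt((m * ((coords - com) ** 2).sum(1)).sum() / m.sum())
        assert radius_of_gyration(coords, m) == pytest.approx(expected, abs=1e-10)

    def test_distribution_integrates_to_one(self, rng):
        frames = rng.uniform(0, 30, size=(20, 12, 3))
        t = toy_two_mol_traj(frames, box=100.0)
        hist = rg_distribution(t)
        widths = np.diff(hist.edges)
        assert (hist.density * widths).sum() == pytest.approx(1.0)

    def test_series_shape(self, rng):
        frames = rng.uniform(0, 30, size=(5, 12, 3))
        t = toy_two_mol_traj(frames)
        assert rg_series(t).shape == (5, 2)


class TestRmsd:
    def test_self_rmsd_zero(self, rng):
        x = rng.normal(size=(10, 3))
        assert rmsd(x, x) == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_gives_zero(self, rng):
        from scipy.spatial.transform import Rotation

        x = rng.normal(size=(10, 3)) * 4
        y = Rotation.from_euler("zyx", [10, 60, -40], degrees=True).apply(x) + 7.0
        assert rmsd(y, x) == pytest.approx(0.0, abs=1e-8)

    def test_beats_rotation_grid_search(self, rng):
        from scipy.spatial.transform import Rotation

        x = rng.normal(size=(6, 3)) * 3
        y = rng.normal(size=(6, 3)) * 3
        k = rmsd(x, y)
        xc = x - x.mean(0)
        yc = y - y.mean(0)
        best = np.inf
        for a in np.linspace(0, 360, 13, endpoint=False):
            for b in np.linspace(0, 180, 7):
                for c in np.linspace(0, 360, 13, endpoint=False):
                    rot = Rotation.from_euler("zyz", [a, b, c], degrees=True)
                    best = min(best, np.sqrt(((xc - rot.apply(yc)) ** 2).sum() / 6))
        assert k <= best + 1e-9

    def test_small_selection_rejected(self):
        from pacsab.errors import ModelError

        with pytest.raises(ModelError):
            rmsd(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_series_starts_at_zero(self, rng):
        frames = rng.normal(size=(4, 12, 3)) * 5 + 20
        t = toy_two_mol_traj(frames)
        series = rmsd_series(t)
        np.testing.assert_allclose(series[0], 0.0, atol=1e-6)

    def test_2d_symmetric_zero_diagonal(self, rng):
        frames = rng.normal(size=(6, 12, 3)) * 5 + 20
        t = toy_two_mol_traj(frames)
        m = rmsd_2d(t, stride=2)
        assert m.shape == (3, 3)
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), 0.0, atol=1e-12)


class TestAssociationEvents:
    def test_always_unbound(self):
        tr = make_synthetic_trace([(100.0, 20.0)])
        ev = association_events(tr)
        assert ev.n_associations == 0
        assert ev.bound_fraction == 0.0
        assert ev.intervals == []

    def test_two_binding_cycles(self):
        tr = make_synthetic_trace([(100, 10.0), (100, 3.0), (100, 10.0),
                                   (100, 3.0), (100, 10.0)])
        ev = association_events(tr)
        assert ev.n_associations == 2
        assert ev.n_dissociations == 2
        assert len(ev.intervals) == 2

    def test_hysteresis_no_event_between_thresholds(self):
        tr = make_synthetic_trace([(100, 10.0), (100, 6.0), (100, 10.0)])
        ev = association_events(tr, d_on=5.0, d_off=8.0)
        assert ev.n_associations == 0

    def test_open_ended_interval_when_still_bound(self):
        tr = make_synthetic_trace([(100, 10.0), (100, 3.0)])
        ev = association_events(tr)
        assert ev.n_associations == 1
        assert ev.n_dissociations == 0
        assert ev.intervals[-1][1] is None
        assert 0.0 < ev.bound_fraction <= 0.5

    def test_invariant_to_threshold_free_oversampling(self):
        times = np.array([10.0, 20, 30, 40])
        values = np.array([10.0, 3.0, 3.0, 10.0])
        ev1 = association_events(DistanceTrace(times, values))
        dense_t = np.arange(1, 41) * 1.0
        dense_v = np.interp(dense_t, times, values)
        # keep only samples that do not graze the thresholds ambiguously:
        # interpolation crosses the same thresholds in the same order
        ev2 = association_events(DistanceTrace(dense_t, dense_v))
        assert ev1.n_associations == ev2.n_associations
        assert ev1.n_dissociations == ev2.n_dissociations


class TestCollisionTime:
    def test_200ns_at_half_mM(self):
        assert collision_time(1e10, 5e-4) == pytest.approx(200.0)

    def test_20ns_at_5mM(self):
        assert collision_time(1e10, 5e-3) == pytest.approx(20.0)

    def test_doubling_concentration_halves_tau(self):
        assert collision_time(1e10, 1e-3) == pytest.approx(
            collision_time(1e10, 5e-4) / 2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            collision_time(0.0, 1e-3)


class TestHbondOccupancy:
    def test_ideal_helix_fully_occupied(self):
        from pacsab import build_pacsab_model, make_polypeptide

        m = build_pacsab_model(make_polypeptide("A" * 10, "helix"))
        t = Trajectory(
            coords=m.coords[None, :, :].copy(),
            times=np.array([10.0]),
            box=200.0,
            kinds=m.kinds,
            res_index=m.res_index,
            mol_index=m.mol_index,
            masses=m.masses,
            metadata={},
        )
        occ = hbond_occupancy(t, sep=4)
        assert occ[0] > 0.9


class TestDistanceTraceOnTrajectory:
    def test_trace_matches_per_frame_min(self, rng):
        frames = rng.uniform(0, 50, size=(5, 12, 3))
        t = toy_two_mol_traj(frames, box=50.0)
        tr = distance_trace(t)
        for f in range(5):
            expected = min_intermolecular_distance(frames[f], t.mol_index, 50.0)
            assert tr.values[f] == pytest.approx(expected)
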