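"""Leaflet assignment, P-P thickness and the protein-adjacent deformation."""

import numpy as np
import pytest

from aqpflux.exceptions import (
    InsufficientDataError,
    SelectionError,
    StructureError,
)
from aqpflux.membrane_thickness import (
    ThicknessSchedule,
    adjacent_shell,
    assign_leaflets,
    delta_thickness,
    thickness,
)

from conftest import make_trajectory


def flat_bilayer(n_per_leaflet=16, z=15.0, noise=0.0, n_frames=1, seed=0):
    rng = np.random.default_rng(seed)
    side = int(np.sqrt(n_per_leaflet))
    g = (np.arange(side) + 0.5) * 10.0
    gx, gy = np.meshgrid(g, g)
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    coords = np.zeros((n_frames, 2 * len(xy), 3))
    coords[:, : len(xy), :2] = xy
    coords[:, len(xy):, :2] = xy
    coords[:, : len(xy), 2] = z
    coords[:, len(xy):, 2] = -z
    coords[:, :, 2] += rng.normal(0, noise, (n_frames, 2 * len(xy)))
    return make_trajectory(coords, box=(side * 10.0, side * 10.0, 100.0))


class TestLeaflets:
    def test_symmetric_bilayer_splits_evenly(self):
        traj = flat_bilayer()
        a = assign_leaflets(traj, 0, np.arange(32))
        assert a.upper.sum() == 16
        assert (~a.upper).sum() == 16

    def test_single_atom_rejected(self):
        traj = flat_bilayer()
        with pytest.raises(SelectionError):
            assign_leaflets(traj, 0, np.array([0]))

    def test_collapsed_bilayer_degenerate(self):
        # all P at one z: every atom sits on the midplane -> degenerate
        coords = np.zeros((1, 4, 3))
        coords[0, :, 2] = 5.0
        with pytest.raises(StructureError):
            assign_leaflets(make_trajectory(coords), 0, np.arange(4))
        # the midplane is the selection mean, so an offset bilayer still splits
        coords[0, :, 2] = [1.0, 1.0, 9.0, 9.0]
        a = assign_leaflets(make_trajectory(coords), 0, np.arange(4))
        assert a.upper.sum() == 2

    def test_matches_generator_labels(self, bilayer_system):
        sys = bilayer_system
        a = assign_leaflets(sys.trajectory, 0, sys.p_ids)
        np.testing.assert_array_equal(a.upper, sys.leaflet_labels > 0)


class TestThickness:
    def test_flat_noiseless_is_exact(self):
        traj = flat_bilayer(z=15.0)
        assert thickness(traj, 0, np.arange(32)) == pytest.approx(30.0, abs=1e-5)

    def test_noisy_thickness_within_clt_band(self):
        n, sigma = 144, 0.8
        traj = flat_bilayer(n_per_leaflet=n, z=15.0, noise=sigma, seed=4)
        d = thickness(traj, 0, np.arange(2 * n))
        se = sigma * np.sqrt(2.0 / n)
        assert abs(d - 30.0) < 3 * se

    def test_region_subset(self):
        traj = flat_bilayer()
        d = thickness(traj, 0, np.arange(32), region=np.array([0, 1, 16, 17]))
        assert d == pytest.approx(30.0, abs=1e-5)

    def test_region_missing_a_leaflet(self):
        traj = flat_bilayer()
        with pytest.raises(InsufficientDataError):
            thickness(traj, 0, np.arange(32), region=np.array([0, 1, 2]))


class TestAdjacentShell:
    def test_ring_geometry(self):
        # protein atoms on a 10-A-radius ring; P ring at lateral 12 A -> all
        # P are 2 A from the nearest protein atom direction-wise <= cutoff 5
        ang = np.linspace(0, 2 * np.pi, 90, endpoint=False)
        prot = 50.0 + 10.0 * np.column_stack([np.cos(ang), np.sin(ang)])
        p = 50.0 + 12.0 * np.column_stack([np.cos(ang), np.sin(ang)])
        coords = np.zeros((1, len(prot) + len(p), 3))
        coords[0, : len(p), :2] = p
        coords[0, len(p):, :2] = prot
        traj = make_trajectory(coords)
        shell = adjacent_shell(traj, 0, np.arange(len(p)),
                               np.arange(len(p), len(p) + len(prot)), cutoff=5.0)
        assert len(shell) == len(p)

    def test_zero_cutoff_empty_shell_warns(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 0, 0] = 30.0
        traj = make_trajectory(coords)
        with pytest.warns(UserWarning, match="empty"):
            shell = adjacent_shell(traj, 0, np.array([0]), np.array([1]), cutoff=0.0)
        assert shell.size == 0

    def test_empty_protein_selection(self):
        traj = flat_bilayer()
        with pytest.raises(SelectionError):
            adjacent_shell(traj, 0, np.arange(32), np.array([]), 5.0)

    def test_matches_brute_force_all_pairs(self, bilayer_system):
        sys = bilayer_system
        traj = sys.trajectory
        cutoff = 5.0
        subset = sys.p_ids[::7]  # keep the O(N*M) python oracle affordable
        shell = adjacent_shell(traj, 0, subset, sys.protein_ids, cutoff)
        lx, ly = traj.box[0, :2]
        expected = []
        for p in subset:
            best = np.inf
            px, py = traj.coords[0, p, :2]
            for q in sys.protein_ids:
                qx, qy = traj.coords[0, q, :2]
                dx = float(px) - float(qx)
                dx -= lx * round(dx / lx)
                dy = float(py) - float(qy)
                dy -= ly * round(dy / ly)
                best = min(best, np.hypot(dx, dy))
            if best <= cutoff:
                expected.append(p)
        assert list(shell) == expected


class TestDeltaThickness:
    def test_undeformed_bilayer_gives_zero_delta(self, bilayer_system):
        """An amplitude-0 system against its protein-free reference: delta is
        pure frame noise around zero."""
        from aqpflux.synthetic import BilayerConfig, gen_bilayer

        flat = gen_bilayer(BilayerConfig(amplitude=0.0, seed=11))
        rec = delta_thickness(
            flat.trajectory, flat.p_ids, flat.protein_ids,
            cutoff=5.0, reference=flat.reference,
        )
        assert abs(rec.delta_adj) < 3 * rec.delta_stderr + 0.05

    def test_planted_deformation_recovered(self, bilayer_system):
        sys = bilayer_system
        rec = delta_thickness(
            sys.trajectory, sys.p_ids, sys.protein_ids,
            cutoff=5.0, reference=sys.reference,
        )
        assert rec.delta_adj == pytest.approx(sys.delta_expected(5.0), abs=0.2)
        assert rec.delta_adj > 0  # compression -> positive sign convention

    def test_constant_reference_mode(self, bilayer_system):
        sys = bilayer_system
        d0 = sys.truth["config"].d0
        rec = delta_thickness(
            sys.trajectory, sys.p_ids, sys.protein_ids,
            cutoff=5.0, reference=float(d0),
        )
        assert rec.d_origin == d0
        assert rec.delta_adj == pytest.approx(sys.delta_expected(5.0), abs=0.2)

    def test_wider_shell_dilutes_local_deformation(self, bilayer_system):
        sys = bilayer_system
        near = delta_thickness(sys.trajectory, sys.p_ids, sys.protein_ids,
                               cutoff=5.0, reference=sys.reference)
        far = delta_thickness(sys.trajectory, sys.p_ids, sys.protein_ids,
                              cutoff=15.0, reference=sys.reference)
        assert abs(near.delta_adj) > abs(far.delta_adj)

    def test_rigid_z_translation_invariance(self, bilayer_system):
        sys = bilayer_system
        shifted = make_trajectory(
            sys.trajectory.coords + np.array([0, 0, 7.5], dtype=np.float32),
            box=sys.trajectory.box[0],
            dt=sys.trajectory.dt_frame,
        )
        a = delta_thickness(sys.trajectory, sys.p_ids, sys.protein_ids,
                            cutoff=5.0, reference=sys.reference)
        b = delta_thickness(shifted, sys.p_ids, sys.protein_ids,
                            cutoff=5.0, reference=sys.reference)
        assert b.delta_adj == pytest.approx(a.delta_adj, abs=1e-3)

    def test_trajectory_shorter_than_schedule(self, bilayer_system):
        sys = bilayer_system
        short = make_trajectory(
            sys.trajectory.coords[:10], box=sys.trajectory.box[0],
            dt=sys.trajectory.dt_frame,
        )
        with pytest.raises(InsufficientDataError):
            delta_thickness(short, sys.p_ids, sys.protein_ids,
                            cutoff=5.0, reference=sys.reference)

    def test_schedule_block_layout(self):
        time = np.arange(50) * 100.0  # 0..4900 ps
        blocks = ThicknessSchedule(n_points=5, spacing_ps=1000.0).blocks(time)
        assert [len(b) for b in blocks] == [10, 10, 10, 10, 10]
        assert blocks[0][0] == 0 and blocks[-1][-1] == 49
        # the blocks partition the schedule span: no frame in two blocks
        all_frames = np.concatenate(blocks)
        assert len(all_frames) == len(np.unique(all_frames))
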