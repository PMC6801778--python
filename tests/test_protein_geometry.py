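import numpy as np
import pytest

from memanchor import protein_geometry as geo
from memanchor import synthetic_data as synth
from memanchor import traj_core as core

from conftest import make_frame, point_topology


def _depth_frame(p_upper_z=2.0, p_lower_z=-2.0, gg_z=(1.5, 1.2, 1.0), n_p=8):
    """Frame with two phosphate rings around the origin plus anchor carbons."""
    n_gg = len(gg_z)
    top = point_topology(2 * n_p + n_gg)
    coords = []
    for z in (p_upper_z, p_lower_z):
        for k in range(n_p):
            ang = 2 * np.pi * k / n_p
            coords.append([5 + 0.6 * np.cos(ang), 5 + 0.6 * np.sin(ang), z])
    for z in gg_z:
        coords.append([5.0, 5.0, z])
    frame = make_frame(coords)
    p_set = core.AtomSet(np.arange(2 * n_p))
    gg_set = core.AtomSet(np.arange(2 * n_p, 2 * n_p + n_gg))
    return frame, gg_set, p_set


class TestInsertionDepth:
    def test_plane_minus_deepest_carbon(self):
        frame, gg, p = _depth_frame(p_upper_z=2.0, gg_z=(1.8, 1.4, 1.0))
        assert geo.anchor_insertion_depth(frame, gg, p) == pytest.approx(1.0)

    def test_anchor_above_plane_is_negative_not_clamped(self):
        frame, gg, p = _depth_frame(p_upper_z=2.0, gg_z=(2.6, 2.5))
        assert geo.anchor_insertion_depth(frame, gg, p) == pytest.approx(-0.5)

    def test_no_lateral_neighbors_falls_back_with_warning(self):
        frame, gg, p = _depth_frame()
        far = core.Frame(frame.coordinates.copy(), frame.box, 0.0)
        far.coordinates[gg.indices, 0] += 3.0  # move anchor away laterally
        with pytest.warns(UserWarning, match="whole-leaflet"):
            d = geo.anchor_insertion_depth(far, gg, p)
        assert d == pytest.approx(1.0)

    def test_planted_depths_measured_exactly(self, anchored_system):
        """Each frame's measured depth equals the generator's drawn depth."""
        aspec, traj = anchored_system
        p = core.select(traj.topology, "element P and name P")
        anchor = core.select(traj.topology, "resname GGA and element C")
        depths = np.array([geo.anchor_insertion_depth(f, anchor, p)
                           for f in traj.frames])
        rng = np.random.default_rng(aspec.seed)
        rng.choice(len(aspec.depth_weights), size=aspec.n_frames,
                   p=np.array(aspec.depth_weights))
        draws = np.array([rng.normal(aspec.depth_means[0], aspec.depth_sds[0])
                          for _ in range(aspec.n_frames)])
        assert np.allclose(depths, draws, atol=1e-12)

    def test_depth_invariant_under_rotation_about_z(self):
        frame, gg, p = _depth_frame()
        base = geo.anchor_insertion_depth(frame, gg, p)
        phi = 1.1
        R = np.array([[np.cos(phi), -np.sin(phi), 0],
                      [np.sin(phi), np.cos(phi), 0], [0, 0, 1]])
        center = np.array([5.0, 5.0, 0.0])
        rot = core.Frame((frame.coordinates - center) @ R.T + center, frame.box, 0.0)
        assert geo.anchor_insertion_depth(rot, gg, p) == pytest.approx(base, abs=1e-12)


class TestDepthDistribution:
    def test_single_gaussian_is_unimodal(self, rng):
        depths = rng.normal(1.71, 0.15, 2000)
        ds = geo.depth_distribution(depths)
        assert ds.modality == 1
        assert ds.mean == pytest.approx(depths.mean(), abs=1e-12)
        assert ds.mean == pytest.approx(1.71, abs=0.01)
        assert ds.counts.sum() == 2000

    def test_two_gaussians_recovered(self, rng):
        depths = np.concatenate([rng.normal(0.9, 0.1, 1000),
                                 rng.normal(1.6, 0.1, 1000)])
        ds = geo.depth_distribution(depths)
        assert ds.modality == 2
        assert ds.component_means[0] == pytest.approx(0.9, abs=0.05)
        assert ds.component_means[1] == pytest.approx(1.6, abs=0.05)

    def test_mean_equals_series_mean_exactly(self, rng):
        depths = rng.uniform(0.5, 2.0, 500)
        assert geo.depth_distribution(depths).mean == depths.mean()

    def test_too_few_frames_raise(self):
        with pytest.raises(ValueError):
            geo.depth_distribution(np.ones(50))


class TestResidueDistances:
    def _two_residue_traj(self):
        names = ["P"] * 8 + ["CA", "CA"]
        top = core.Topology(
            names=np.array(names, dtype=object),
            elements=np.array(["P"] * 8 + ["C", "C"], dtype=object),
            masses=np.array([30.97] * 8 + [12.0, 12.0]),
            resnames=np.array(["POPC"] * 8 + ["GLY", "GLY"], dtype=object),
            resids=np.array([1, 2, 3, 4, 5, 6, 7, 8, 10, 11]),
            segids=np.array(["MEMB"] * 8 + ["PROT"] * 2, dtype=object),
            molecule_ids=np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 8]),
            molecule_labels={i: "POPC" for i in range(8)} | {8: "protein"},
        )
        coords = np.zeros((10, 3))
        coords[:4, 2] = 2.0
        coords[4:8, 2] = -2.0
        coords[8] = [5, 5, 5.0]
        coords[9] = [5, 6, 5.0]
        return core.Trajectory(top, [make_frame(coords)]), top

    def test_com_z_minus_plane(self):
        traj, top = self._two_residue_traj()
        prot = core.select(top, "segid PROT")
        p = core.select(top, "element P")
        dmap = geo.residue_membrane_distances(traj, prot, p)
        assert dmap.distances.shape == (2, 1)
        assert np.allclose(dmap.distances, 3.0)

    def test_rigid_z_translation_shifts_all_distances(self):
        traj, top = self._two_residue_traj()
        prot = core.select(top, "segid PROT")
        p = core.select(top, "element P")
        base = geo.residue_membrane_distances(traj, prot, p).distances
        coords = traj.frames[0].coordinates.copy()
        coords[prot.indices, 2] += 1.0
        shifted_traj = core.Trajectory(top, [make_frame(coords)])
        shifted = geo.residue_membrane_distances(shifted_traj, prot, p).distances
        assert np.allclose(shifted - base, 1.0)

    def test_switch_regions_are_most_distal_in_planted_fixture(self, anchored_system):
        # the default pose lifts the switch blob above the rest of the domain,
        # so switch residues must carry the largest membrane distances
        _, traj = anchored_system
        top = traj.topology
        prot = core.select(top, "name CA and resid 15:185")
        p = core.select(top, "element P and name P")
        dmap = geo.residue_membrane_distances(traj, prot, p)
        mean_d = dmap.distances.mean(axis=1)
        switch = np.isin(dmap.resids, list(range(50, 61)) + list(range(75, 93)))
        assert dmap.resids[int(np.argmax(mean_d))] in dmap.resids[switch]
        assert mean_d[switch].mean() > mean_d[~switch].mean()


class TestRadiusOfGyration:
    def test_two_points_two_nm_apart(self):
        top = point_topology(2)
        frame = make_frame([[0, 0, 0], [0, 0, 2.0]])
        sel = core.AtomSet(np.arange(2))
        assert geo.radius_of_gyration(frame, top, sel) == pytest.approx(1.0)

    def test_invariant_under_rigid_transform(self, rng):
        top = point_topology(30)
        pts = rng.normal(size=(30, 3))
        sel = core.AtomSet(np.arange(30))
        base = geo.radius_of_gyration(make_frame(pts), top, sel)
        q = rng.normal(size=(3, 3))
        R = np.linalg.qr(q)[0]
        if np.linalg.det(R) < 0:
            R[:, 0] *= -1
        moved = pts @ R.T + rng.normal(size=3)
        assert geo.radius_of_gyration(make_frame(moved), top, sel) == \
            pytest.approx(base, abs=1e-9)

    def test_uniform_ball_approaches_analytic_moment(self, rng):
        # uniform solid sphere of radius R: r_gyr -> R * sqrt(3/5)
        R = 2.0
        pts = rng.normal(size=(1000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= R * rng.uniform(0, 1, size=(1000, 1)) ** (1 / 3)
        top = point_topology(1000)
        got = geo.radius_of_gyration(make_frame(pts + 5.0), top, core.AtomSet(np.arange(1000)))
        assert got == pytest.approx(R * np.sqrt(3 / 5), rel=0.03)


def _quaternion_rmsd(mobile, reference):
    """Independent quaternion-eigenvalue superposition RMSD oracle."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    R = x.T @ y
    F = np.array([
        [R[0, 0] + R[1, 1] + R[2, 2], R[1, 2] - R[2, 1], R[2, 0] - R[0, 2], R[0, 1] - R[1, 0]],
        [R[1, 2] - R[2, 1], R[0, 0] - R[1, 1] - R[2, 2], R[0, 1] + R[1, 0], R[0, 2] + R[2, 0]],
        [R[2, 0] - R[0, 2], R[0, 1] + R[1, 0], -R[0, 0] + R[1, 1] - R[2, 2], R[1, 2] + R[2, 1]],
        [R[0, 1] - R[1, 0], R[0, 2] + R[2, 0], R[1, 2] + R[2, 1], -R[0, 0] - R[1, 1] + R[2, 2]],
    ])
    lam = np.linalg.eigvalsh(F)[-1]
    sq = max(0.0, (np.sum(x**2) + np.sum(y**2) - 2 * lam) / len(x))
    return np.sqrt(sq)


class TestSuperpose:
    def test_identity_on_identical_sets(self, rng):
        pts = rng.normal(size=(10, 3))
        R, t, rmsd = geo.superpose(pts, pts)
        assert np.allclose(R, np.eye(3), atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_pure_rotation_recovered(self, rng):
        pts = rng.normal(size=(20, 3))
        phi = 0.7
        Rz = np.array([[np.cos(phi), -np.sin(phi), 0],
                       [np.sin(phi), np.cos(phi), 0], [0, 0, 1]])
        R, t, rmsd = geo.superpose(pts, pts @ Rz.T + np.array([1, 2, 3.0]))
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(R, Rz, atol=1e-10)

    def test_rmsd_matches_quaternion_oracle(self, rng):
        for _ in range(5):
            pts = rng.normal(size=(25, 3))
            phi = rng.uniform(0, np.pi)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            K = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            Rr = np.eye(3) + np.sin(phi) * K + (1 - np.cos(phi)) * K @ K
            noisy = pts @ Rr.T + rng.normal(scale=0.1, size=(25, 3))
            _, _, rmsd = geo.superpose(pts, noisy)
            assert rmsd == pytest.approx(_quaternion_rmsd(pts, noisy), abs=1e-8)

    def test_collinear_points_raise(self):
        pts = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2.0]])
        with pytest.raises(ValueError):
            geo.superpose(pts, pts + 1.0)


class TestRmsf:
    def _static_traj(self, rng, n_atoms=60, n_frames=50, sigma=0.0, tumble=False):
        top = point_topology(n_atoms, name="CA", element="C")
        base = rng.normal(size=(n_atoms, 3))
        frames = []
        for t in range(n_frames):
            pts = base.copy()
            if sigma > 0:
                pts = pts + rng.normal(scale=sigma, size=pts.shape)
            if tumble:
                phi = rng.uniform(0, 2 * np.pi)
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                K = np.array([[0, -axis[2], axis[1]],
                              [axis[2], 0, -axis[0]],
                              [-axis[1], axis[0], 0]])
                R = np.eye(3) + np.sin(phi) * K + (1 - np.cos(phi)) * K @ K
                pts = pts @ R.T + rng.normal(size=3)
            frames.append(make_frame(pts + 10.0, box=(40, 40, 40), time=float(t)))
        return core.Trajectory(top, frames), core.AtomSet(np.arange(n_atoms))

    def test_static_trajectory_has_zero_rmsf(self, rng):
        traj, sel = self._static_traj(rng)
        assert np.allclose(geo.rmsf(traj, sel, sel), 0.0, atol=1e-12)

    def test_rigid_tumbling_removed_by_superposition(self, rng):
        traj, sel = self._static_traj(rng, tumble=True)
        assert np.allclose(geo.rmsf(traj, sel, sel), 0.0, atol=1e-9)

    def test_isotropic_jitter_gives_sigma_root_three(self, rng):
        sigma = 0.05
        traj, sel = self._static_traj(rng, n_atoms=100, n_frames=200, sigma=sigma)
        r = geo.rmsf(traj, sel, sel)
        assert r.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_reference_frame_choice_changes_little(self, rng):
        traj, sel = self._static_traj(rng, n_atoms=80, n_frames=100, sigma=0.03)
        r0 = geo.rmsf(traj, sel, sel)
        reversed_traj = core.Trajectory(
            traj.topology,
            [core.Frame(f.coordinates, f.box, float(i))
             for i, f in enumerate(reversed(traj.frames))])
        r1 = geo.rmsf(reversed_traj, sel, sel)
        assert np.abs(r0.mean() - r1.mean()) / r0.mean() < 0.02


class TestOrientation:
    def _orient_frame(self, g_offset, s_offset):
        # atoms: 3 anchor carbons at A, 3 G-domain atoms, 3 switch atoms
        top = point_topology(9)
        A = np.array([5.0, 5.0, 3.0])
        spread = np.array([[0.1, 0, 0], [-0.1, 0, 0], [0, 0.1, 0]])
        coords = np.vstack([A + spread, A + g_offset + spread, A + s_offset + spread])
        frame = make_frame(coords)
        return (frame, top, core.AtomSet(np.arange(3, 6)),
                core.AtomSet(np.arange(6, 9)), core.AtomSet(np.arange(3)))

    def test_domain_along_normal_gives_zero_theta(self):
        frame, top, g, s, a = self._orient_frame(np.array([0, 0, 2.0]),
                                                 np.array([1.0, 0, 1.0]))
        theta, _ = geo.orientation_angles(frame, top, g, s, a)
        assert theta == pytest.approx(0.0, abs=1e-9)

    def test_domain_in_plane_gives_ninety_theta(self):
        frame, top, g, s, a = self._orient_frame(np.array([2.0, 0, 0]),
                                                 np.array([2.0, 0, 1.0]))
        theta, _ = geo.orientation_angles(frame, top, g, s, a)
        assert theta == pytest.approx(90.0, abs=1e-9)

    def test_coincident_points_error(self):
        frame, top, g, s, a = self._orient_frame(np.zeros(3), np.array([1.0, 0, 0]))
        with pytest.raises(ValueError):
            geo.orientation_angles(frame, top, g, s, a)

    def test_constructed_dihedral_of_80_degrees(self):
        p0 = np.array([0.0, 0, -1])
        p1 = np.zeros(3)
        p2 = np.array([0.0, 2, 0])
        ang = np.deg2rad(80.0)
        p3 = p2 + np.array([np.sin(ang) * 0, 0, 0])  # placeholder, built below
        # place p3 so that the half-plane angle from p0's side is exactly 80 deg
        ref = np.array([0.0, 0, -1])  # direction of p0 - p1 projected normal to axis
        axis = np.array([0.0, 1, 0])
        third = np.cross(axis, ref)
        p3 = p2 + np.cos(ang) * ref + np.sin(ang) * third
        assert geo.dihedral(p0, p1, p2, p3) == pytest.approx(80.0, abs=1e-9)

    def test_reflected_switch_flips_dihedral_sign(self):
        p0 = np.array([0.0, 0, -1])
        p1 = np.zeros(3)
        p2 = np.array([0.0, 2, 0])
        ref = np.array([0.0, 0, -1])
        axis = np.array([0.0, 1, 0])
        third = np.cross(axis, ref)
        ang = np.deg2rad(80.0)
        p3 = p2 + np.cos(ang) * ref + np.sin(ang) * third
        mirrored = p3 * np.array([-1.0, 1.0, 1.0])  # reflect through the axis plane
        assert geo.dihedral(p0, p1, p2, mirrored) == pytest.approx(280.0, abs=1e-9)

    @pytest.mark.parametrize("omega,label", [
        (80.0, "exo"), (190.0, "endo"), (300.0, "intermediate"), (40.0, "exo"),
    ])
    def test_omega_classification(self, omega, label):
        assert geo.classify_omega(omega) == label

    def test_planted_endo_pose_labels_every_frame_endo(self, anchored_system):
        _, traj = anchored_system
        top = traj.topology
        ori = geo.orientation_series(
            traj,
            core.select(top, "name CA and resid 15:185"),
            core.select(top, "name CA and resid 50:60 or name CA and resid 75:92"),
            core.select(top, "resname GGA and element C"))
        assert np.allclose(ori.theta, 90.0, atol=0.1)
        assert np.allclose(ori.omega, 190.0, atol=0.1)
        assert set(ori.labels) == {"endo"}
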