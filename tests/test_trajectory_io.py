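"""Trajectory data model, format round trips, unwrapping, rigid sites."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import sedyn as s
from sedyn.trajectory import quat_from_rotvec, quat_multiply, quat_rotate


def small_traj(n_frames=2, n_mol=2, box=10.0, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0, box, (n_frames, n_mol, 3))
    q = rng.standard_normal((n_frames, n_mol, 4))
    q /= np.linalg.norm(q, axis=-1, keepdims=True)
    return s.RigidMoleculeTrajectory(centers=centers, orientations=q,
                                     box_edge=box, frame_interval=0.5)


# ---------------------------------------------------------------------------
# quaternion helpers vs scipy (independent route)
# ---------------------------------------------------------------------------

@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_quat_rotate_matches_scipy(seed):
    rng = np.random.default_rng(seed)
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    v = rng.standard_normal(3)
    ours = quat_rotate(q, v)
    theirs = Rotation.from_quat(np.r_[q[1:], q[0]]).apply(v)
    assert np.allclose(ours, theirs, atol=1e-12)


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_quat_compose_matches_scipy(seed):
    rng = np.random.default_rng(seed)
    rv1, rv2 = rng.standard_normal(3), rng.standard_normal(3)
    q = quat_multiply(quat_from_rotvec(rv1), quat_from_rotvec(rv2))
    R = Rotation.from_rotvec(rv1) * Rotation.from_rotvec(rv2)
    qs = R.as_quat()
    qs = np.r_[qs[3], qs[:3]]
    assert np.allclose(q, qs, atol=1e-12) or np.allclose(q, -qs, atol=1e-12)


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

def test_xyz_roundtrip_lossless(tmp_path):
    traj = small_traj()
    p = tmp_path / "t.xyz"
    s.write_extended_xyz(traj, p)
    back = s.read_extended_xyz(p)
    assert np.array_equal(back.centers, traj.centers)
    assert np.array_equal(back.orientations, traj.orientations)
    assert back.box_edge == traj.box_edge
    assert back.frame_interval == traj.frame_interval


def test_xyz_second_write_byte_identical(tmp_path):
    traj = small_traj(n_frames=3, n_mol=4)
    p1, p2 = tmp_path / "a.xyz", tmp_path / "b.xyz"
    s.write_extended_xyz(traj, p1)
    s.write_extended_xyz(s.read_extended_xyz(p1), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_xyz_box_edge_parsed(tmp_path):
    traj = dataclasses.replace(small_traj(box=31.04), box_edge=31.04)
    p = tmp_path / "t.xyz"
    s.write_extended_xyz(traj, p)
    assert s.read_extended_xyz(p).box_edge == 31.04


def test_xyz_missing_orientation_columns_rejected(tmp_path):
    p = tmp_path / "bad.xyz"
    p.write_text("1\nbox_edge=10 time=0 columns=id:x:y:z\n1 1.0 2.0 3.0\n")
    with pytest.raises(s.TrajectoryFormatError, match="q"):
        s.read_extended_xyz(p)


def test_identity_quaternion_maps_dipole_to_itself():
    q = np.zeros((1, 1, 4))
    q[..., 0] = 1.0
    traj = s.RigidMoleculeTrajectory(
        centers=np.full((1, 1, 3), 5.0), orientations=q, box_edge=10.0,
        frame_interval=1.0, dipole_axis=np.array([0.0, 0.0, 1.0]))
    assert np.allclose(traj.dipole_vectors()[0, 0], [0, 0, 1])


# ---------------------------------------------------------------------------
# LAMMPS dump
# ---------------------------------------------------------------------------

def test_lammps_roundtrip(tmp_path):
    traj = small_traj(n_frames=2, n_mol=2)
    p = tmp_path / "t.dump"
    s.write_lammps_dump(traj, p, timestep=0.001)
    back = s.read_lammps_dump(p, timestep=0.001)
    assert np.array_equal(back.centers, traj.centers)
    assert np.array_equal(back.orientations, traj.orientations)
    assert back.frame_interval == traj.frame_interval


def test_lammps_missing_molecule_names_frame(tmp_path):
    traj = small_traj(n_frames=3, n_mol=2)
    p = tmp_path / "t.dump"
    s.write_lammps_dump(traj, p)
    lines = p.read_text().splitlines()
    # drop the last atom line of the second frame (frame index 1)
    del lines[2 * 11 - 1]
    p.write_text("\n".join(lines) + "\n")
    with pytest.raises(s.TrajectoryFormatError, match="frame"):
        s.read_lammps_dump(p)


def test_lammps_triclinic_rejected(tmp_path):
    p = tmp_path / "t.dump"
    p.write_text(
        "ITEM: TIMESTEP\n0\nITEM: NUMBER OF ATOMS\n1\n"
        "ITEM: BOX BOUNDS xy xz yz pp pp pp\n0 10 1\n0 10 0\n0 10 0\n"
        "ITEM: ATOMS id x y z qw qx qy qz\n1 1 1 1 1 0 0 0\n"
    )
    with pytest.raises(s.TrajectoryFormatError, match="orthorhombic|triclinic"):
        s.read_lammps_dump(p)


def test_saved_and_inmemory_paths_give_identical_estimates(tmp_path):
    spec = s.GeneratorSpec(n_molecules=5, n_frames=10, frame_interval=0.1,
                           D_r=0.05, seed=3)
    traj = s.gen_rotational_brownian(spec)
    p = tmp_path / "gen.xyz"
    s.write_extended_xyz(traj, p)
    reloaded = s.read_extended_xyz(p)
    a = s.legendre_autocorrelation(traj, 2)
    b = s.legendre_autocorrelation(reloaded, 2)
    assert np.array_equal(a.values, b.values)


# ---------------------------------------------------------------------------
# unwrap / wrap
# ---------------------------------------------------------------------------

def test_unwrap_boundary_crossing():
    L = 10.0
    centers = np.zeros((2, 1, 3))
    centers[0, 0, 0] = 0.9 * L
    centers[1, 0, 0] = 0.1 * L
    q = np.zeros((2, 1, 4))
    q[..., 0] = 1.0
    traj = s.RigidMoleculeTrajectory(centers=centers, orientations=q,
                                     box_edge=L, frame_interval=1.0)
    u = s.unwrap_periodic(traj)
    assert np.isclose(u.centers[1, 0, 0], 1.1 * L)


def test_unwrap_stationary_unchanged():
    traj = small_traj(n_frames=5, n_mol=3)
    static = dataclasses.replace(
        traj, centers=np.repeat(traj.centers[:1], 5, axis=0))
    u = s.unwrap_periodic(static)
    assert np.array_equal(u.centers, static.centers)


def test_unwrap_recovers_ground_truth_msd(brownian_traj, brownian_unwrapped):
    u = s.unwrap_periodic(brownian_traj)
    # unwrapped path equals ground truth up to the common starting point
    d_est = u.centers - u.centers[0]
    d_true = brownian_unwrapped.centers - brownian_unwrapped.centers[0]
    assert np.allclose(d_est, d_true, atol=1e-10)


def test_unwrap_then_rewrap_is_identity(brownian_traj):
    u = s.unwrap_periodic(brownian_traj)
    rewrapped = s.wrap_positions(u.centers, brownian_traj.box_edge)
    assert np.allclose(rewrapped, brownian_traj.centers, atol=1e-9)


def test_unwrap_half_box_jump_rejected():
    L = 10.0
    centers = np.zeros((2, 1, 3))
    centers[1, 0, 0] = L / 2.0
    q = np.zeros((2, 1, 4))
    q[..., 0] = 1.0
    traj = s.RigidMoleculeTrajectory(centers=centers, orientations=q,
                                     box_edge=L, frame_interval=1.0)
    with pytest.raises(ValueError, match="molecule 0"):
        s.unwrap_periodic(traj)


# ---------------------------------------------------------------------------
# rigid-body sites
# ---------------------------------------------------------------------------

def test_sites_identity_quaternion():
    q = np.zeros((1, 1, 4))
    q[..., 0] = 1.0
    traj = s.RigidMoleculeTrajectory(
        centers=np.full((1, 1, 3), 3.0), orientations=q,
        box_edge=20.0, frame_interval=1.0)
    sites = s.sites_from_rigid_body(traj)
    assert np.allclose(sites.O[0, 0], 3.0 + s.TIP4P2005_SITES["O"])
    assert np.allclose(sites.H1[0, 0], 3.0 + s.TIP4P2005_SITES["H1"])


def test_sites_half_turn_about_z():
    # 180 degrees about z maps a site at (1,0,0) to (-1,0,0)
    q = np.array([[[np.cos(np.pi / 2), 0.0, 0.0, np.sin(np.pi / 2)]]])
    traj = s.RigidMoleculeTrajectory(
        centers=np.full((1, 1, 3), 5.0), orientations=q,
        box_edge=20.0, frame_interval=1.0)
    sites = s.sites_from_rigid_body(traj, {"O": np.array([1.0, 0, 0]),
                                           "H1": np.zeros(3), "H2": np.zeros(3)})
    assert np.allclose(sites.O[0, 0] - 5.0, [-1, 0, 0], atol=1e-12)


def test_sites_rigidity_over_random_rotations(rng):
    n_frames, n_mol = 100, 5
    q = rng.standard_normal((n_frames, n_mol, 4))
    q /= np.linalg.norm(q, axis=-1, keepdims=True)
    centers = rng.uniform(0, 20, (n_frames, n_mol, 3))
    traj = s.RigidMoleculeTrajectory(centers=centers, orientations=q,
                                     box_edge=20.0, frame_interval=1.0)
    sites = s.sites_from_rigid_body(traj)
    d_oh = np.linalg.norm(sites.H1 - sites.O, axis=-1)
    assert np.allclose(d_oh, d_oh[0, 0], atol=1e-10)
    d_hh = np.linalg.norm(sites.H1 - sites.H2, axis=-1)
    assert np.allclose(d_hh, d_hh[0, 0], atol=1e-10)


# ---------------------------------------------------------------------------
# scalar series + validation
# ---------------------------------------------------------------------------

def test_scalar_series_roundtrip(tmp_path, rng):
    ser = s.ScalarSeries(values=rng.standard_normal(50), sample_interval=0.25,
                         label="sigma_xy")
    p = tmp_path / "s.txt"
    s.write_scalar_series(ser, p)
    back = s.read_scalar_series(p)
    assert np.array_equal(back.values, ser.values)
    assert back.sample_interval == 0.25
    assert back.label == "sigma_xy"


def test_trajectory_invariants_enforced():
    q = np.zeros((1, 1, 4))
    q[..., 0] = 1.1  # not unit norm
    with pytest.raises(ValueError, match="unit-norm"):
        s.RigidMoleculeTrajectory(centers=np.zeros((1, 1, 3)), orientations=q,
                                  box_edge=10.0, frame_interval=1.0)
    q[..., 0] = 1.0
    with pytest.raises(ValueError, match="frame_interval"):
        s.RigidMoleculeTrajectory(centers=np.zeros((1, 1, 3)), orientations=q,
                                  box_edge=10.0, frame_interval=0.0)
    with pytest.raises(ValueError, match=r"\[0, box_edge\)"):
        s.RigidMoleculeTrajectory(centers=np.full((1, 1, 3), 11.0),
                                  orientations=q, box_edge=10.0,
                                  frame_interval=1.0)
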