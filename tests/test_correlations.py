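"""Correlation estimators: trivial closed forms, naive O(n²) cross-checks,
and statistical agreement with generator oracles."""

import dataclasses

import numpy as np
import pytest
from scipy.special import eval_legendre

import sedyn as s


def identity_traj(centers, box=100.0, dt=1.0):
    """Unwrapped trajectory with identity orientations."""
    q = np.zeros(centers.shape[:2] + (4,))
    q[..., 0] = 1.0
    return s.RigidMoleculeTrajectory(centers=centers, orientations=q,
                                     box_edge=box, frame_interval=dt,
                                     wrapped=False)


def orient_traj(quats, box=100.0, dt=1.0):
    centers = np.full(quats.shape[:2] + (3,), box / 2.0)
    return s.RigidMoleculeTrajectory(centers=centers, orientations=quats,
                                     box_edge=box, frame_interval=dt)


# ---------------------------------------------------------------------------
# naive reference implementations (O(n^2), plain loops)
# ---------------------------------------------------------------------------

def naive_msd(centers, lag_frames, dt):
    out = []
    n = centers.shape[0]
    for lag in lag_frames:
        acc = []
        for t0 in range(n - lag):
            d = centers[t0 + lag] - centers[t0]
            acc.append((d**2).sum(axis=-1).mean())
        out.append(np.mean(acc) if acc else np.nan)
    return np.array(out)


def naive_legendre(e, order, lag_frames):
    out = []
    n = e.shape[0]
    for lag in lag_frames:
        acc = []
        for t0 in range(n - lag):
            dots = (e[t0 + lag] * e[t0]).sum(axis=-1)
            acc.append(eval_legendre(order, dots).mean())
        out.append(np.mean(acc))
    return np.array(out)


def naive_series_acf(x, max_lag):
    return np.array([(x[: len(x) - k] * x[k:]).mean() for k in range(max_lag + 1)])


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------

def test_msd_static_is_zero():
    traj = identity_traj(np.full((10, 3, 3), 5.0))
    res = s.msd(traj)
    assert np.allclose(res.values, 0.0)


def test_msd_ballistic_exact():
    v = np.array([0.3, -0.1, 0.2])
    t = np.arange(20)[:, None, None]
    centers = np.broadcast_to(v, (20, 2, 3)) * t
    traj = identity_traj(centers.copy())
    res = s.msd(traj,
                lag_grid=np.arange(10, dtype=float))
    expect = (v @ v) * res.lags**2
    assert np.allclose(res.values, expect, atol=1e-12)


def test_msd_matches_naive_reference(rng):
    centers = rng.standard_normal((100, 4, 3)).cumsum(axis=0)
    traj = identity_traj(centers.copy())
    lag_frames = np.array([0, 1, 3, 7, 20, 50, 99])
    res = s.msd(traj,
                lag_grid=lag_frames.astype(float), origin_stride=1)
    assert np.allclose(res.values, naive_msd(centers, lag_frames, 1.0), atol=1e-10)


def test_msd_rejects_wrapped_input(brownian_traj):
    with pytest.raises(ValueError, match="wrapped"):
        s.msd(brownian_traj)


# ---------------------------------------------------------------------------
# angular track
# ---------------------------------------------------------------------------

def test_angular_velocity_quarter_turn():
    # e rotates from +x to +y in 1 ps: omega = (0, 0, pi/2) rad/ps
    q = np.zeros((2, 1, 4))
    q[0, 0] = [1, 0, 0, 0]
    q[1, 0] = [np.cos(np.pi / 4), 0, 0, np.sin(np.pi / 4)]
    traj = orient_traj(q, dt=1.0)
    traj = dataclasses.replace(traj, dipole_axis=np.array([1.0, 0.0, 0.0]))
    track = s.angular_track(traj)
    assert np.allclose(track.omega[0, 0], [0, 0, np.pi / 2], atol=1e-12)


def test_angular_track_constant_orientation():
    q = np.zeros((5, 2, 4))
    q[..., 0] = 1.0
    track = s.angular_track(orient_traj(q))
    assert np.allclose(track.omega, 0.0)
    assert np.allclose(track.phi, 0.0)


def test_fixed_axis_rotation_accumulates_linearly():
    # rotation about z at rate w with dipole in the x-y plane: |phi(t)| = w t
    w, dt, n = 0.3, 0.5, 40
    angles = w * dt * np.arange(n)
    q = np.zeros((n, 1, 4))
    q[:, 0, 0] = np.cos(angles / 2)
    q[:, 0, 3] = np.sin(angles / 2)
    traj = dataclasses.replace(orient_traj(q, dt=dt),
                               dipole_axis=np.array([1.0, 0.0, 0.0]))
    track = s.angular_track(traj)
    norm_phi = np.linalg.norm(track.phi[:, 0], axis=-1)
    assert np.allclose(norm_phi, w * dt * np.arange(n), atol=1e-10)
    res = s.angular_msd(track, lag_grid=dt * np.arange(10))
    assert np.allclose(res.values, (w * res.lags) ** 2, atol=1e-10)


def test_angular_track_magnitude_identity(debye_traj):
    # |omega| * dt must equal arccos(e(t).e(t+dt)) by construction
    sub = dataclasses.replace(
        debye_traj, centers=debye_traj.centers[:50],
        orientations=debye_traj.orientations[:50])
    track = s.angular_track(sub)
    e = sub.dipole_vectors()
    dots = np.clip((e[:-1] * e[1:]).sum(-1), -1, 1)
    assert np.allclose(np.linalg.norm(track.omega, axis=-1) * track.stride,
                       np.arccos(dots), atol=1e-10)


def test_antiparallel_axes_rejected():
    q = np.zeros((2, 1, 4))
    q[0, 0] = [1, 0, 0, 0]
    q[1, 0] = [0, 1, 0, 0]  # pi rotation about x flips the z dipole
    with pytest.raises(ValueError, match="antiparallel"):
        s.angular_track(orient_traj(q))


# ---------------------------------------------------------------------------
# Legendre correlators
# ---------------------------------------------------------------------------

def test_legendre_constant_orientation_is_one():
    q = np.zeros((10, 3, 4))
    q[..., 0] = 1.0
    res = s.legendre_autocorrelation(orient_traj(q), 2)
    assert np.allclose(res.values, 1.0)


def test_legendre_matches_naive_reference(rng):
    q = rng.standard_normal((100, 5, 4))
    q /= np.linalg.norm(q, axis=-1, keepdims=True)
    traj = orient_traj(q)
    lag_frames = np.array([0, 1, 5, 17, 60, 99])
    for order in (1, 3):
        res = s.legendre_autocorrelation(traj, order, lag_frames.astype(float))
        naive = naive_legendre(traj.dipole_vectors(), order, lag_frames)
        assert np.allclose(res.values, naive, atol=1e-10)


def test_legendre_debye_matches_oracle(debye_traj):
    for order in (1, 2):
        res = s.legendre_autocorrelation(debye_traj, order, origin_stride=10)
        oracle = s.oracle_debye_correlator(order, 0.05, res.lags)
        mask = (res.lags > 0) & np.isfinite(res.stderr)
        dev = np.abs(res.values[mask] - oracle[mask])
        assert np.all(dev <= 3.0 * np.maximum(res.stderr[mask], 1e-3))


def test_correlators_invariant_under_time_shift(debye_traj):
    sub = dataclasses.replace(
        debye_traj, centers=debye_traj.centers[:200],
        orientations=debye_traj.orientations[:200])
    shifted = dataclasses.replace(
        debye_traj, centers=debye_traj.centers[100:300],
        orientations=debye_traj.orientations[100:300])
    grid = np.arange(0, 50, 5) * 0.1
    a = s.legendre_autocorrelation(sub, 1, grid)
    b = s.legendre_autocorrelation(shifted, 1, grid)
    # statistically identical: same process, overlapping data
    assert np.allclose(a.values, b.values, atol=6 * np.nanmax([a.stderr, b.stderr]))


# ---------------------------------------------------------------------------
# angular-velocity ACF
# ---------------------------------------------------------------------------

def test_angular_velocity_acf_constant_rate():
    w, dt, n = 0.2, 0.5, 30
    angles = w * dt * np.arange(n)
    q = np.zeros((n, 1, 4))
    q[:, 0, 0] = np.cos(angles / 2)
    q[:, 0, 3] = np.sin(angles / 2)
    traj = dataclasses.replace(orient_traj(q, dt=dt),
                               dipole_axis=np.array([1.0, 0.0, 0.0]))
    track = s.angular_track(traj)
    res = s.angular_velocity_acf(track, lag_grid=dt * np.arange(5))
    assert np.allclose(res.values, w**2 / 3.0, atol=1e-10)


def test_angular_velocity_white_noise_decorrelates(debye_traj):
    # Brownian rotation steps are independent: ACF ~ 0 beyond one stride
    track = s.angular_track(
        dataclasses.replace(debye_traj,
                            centers=debye_traj.centers[:1000],
                            orientations=debye_traj.orientations[:1000]))
    res = s.angular_velocity_acf(track, lag_grid=0.1 * np.arange(10))
    assert res.values[0] > 0.5  # ~ 2 D_r / dt = 1
    assert np.all(np.abs(res.values[2:]) < 0.02 * res.values[0])


# ---------------------------------------------------------------------------
# intermediate scattering function
# ---------------------------------------------------------------------------

def test_fs_static_is_one():
    traj = identity_traj(np.full((10, 4, 3), 5.0), box=10.0)
    res = s.intermediate_scattering(traj, 3.0)
    assert np.allclose(res.values, 1.0)
    assert res.values[0] == 1.0


def test_fs_brownian_matches_gaussian_oracle(brownian_unwrapped):
    k = 5 * 2 * np.pi / 31.04  # exactly commensurate
    res = s.intermediate_scattering(brownian_unwrapped, k, origin_stride=10,
                                    k_vectors=np.array([[k, 0.0, 0.0]]))
    oracle = np.exp(-(k**2) * 0.2 * res.lags)
    mask = (res.lags > 0) & np.isfinite(res.stderr)
    dev = np.abs(res.values[mask] - oracle[mask])
    assert np.all(dev <= 3.0 * np.maximum(res.stderr[mask], 2e-3))


def test_fs_incommensurate_k_rejected():
    traj = identity_traj(np.full((5, 2, 3), 5.0), box=10.0)
    with pytest.raises(ValueError, match="nearest"):
        s.commensurate_k_vectors(0.05, 10.0)


# ---------------------------------------------------------------------------
# series ACF
# ---------------------------------------------------------------------------

def test_series_acf_constant():
    ser = s.ScalarSeries(values=np.full(100, 3.0), sample_interval=1.0)
    res = s.series_acf(ser, max_lag=10)
    assert np.allclose(res.values, 9.0, atol=1e-10)


def test_series_acf_alternating():
    ser = s.ScalarSeries(values=(-1.0) ** np.arange(200), sample_interval=1.0)
    res = s.series_acf(ser, max_lag=10)
    assert np.allclose(res.values, (-1.0) ** np.arange(11), atol=1e-10)


def test_series_acf_matches_naive(rng):
    x = rng.standard_normal(300)
    ser = s.ScalarSeries(values=x, sample_interval=0.5)
    res = s.series_acf(ser, max_lag=40)
    assert np.allclose(res.values, naive_series_acf(x, 40), atol=1e-10)


def test_series_acf_ou_matches_oracle():
    spec = s.GeneratorSpec(stress_amplitude=1.5, stress_corr_time=5.0,
                           n_samples=200_000, sample_interval=0.5, seed=17)
    ser = s.gen_ou_stress(spec)
    res = s.series_acf(ser, max_lag=60)
    oracle = 1.5 * np.exp(-res.lags / 5.0)
    assert np.all(np.abs(res.values - oracle) <= 4.0 * np.maximum(res.stderr, 1e-4))


# ---------------------------------------------------------------------------
# multi-run averaging
# ---------------------------------------------------------------------------

def test_average_over_independent_runs():
    runs = []
    for seed in (1, 2, 3):
        spec = s.GeneratorSpec(n_molecules=100, n_frames=300, D_r=0.05,
                               frame_interval=0.1, seed=seed)
        traj = s.gen_rotational_brownian(spec)
        runs.append(s.legendre_autocorrelation(traj, 1, origin_stride=10))
    avg = s.average_correlation_results(runs)
    assert avg.params["n_runs"] == 3
    assert np.allclose(avg.values, np.mean([r.values for r in runs], axis=0))
    assert avg.values[0] == 1.0
    with pytest.raises(ValueError, match="two runs"):
        s.average_correlation_results(runs[:1])
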