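"""Shared fixtures: synthetic trajectories with known ground truth."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import sedyn as s


def unwrapped(traj):
    """Trajectory with the generator's unwrapped ground-truth centers."""
    return dataclasses.replace(
        traj, centers=traj.metadata["unwrapped_centers"], wrapped=False
    )


@pytest.fixture(scope="session")
def debye_traj():
    """Isotropic rotational Brownian motion: N=1000, 4000 frames at 0.1 ps,
    D_r = 0.05 rad²/ps (so τ_1 = 10 ps, τ_2 = 10/3 ps)."""
    spec = s.GeneratorSpec(n_molecules=1000, n_frames=4000, frame_interval=0.1,
                           D_r=0.05, seed=7)
    return s.gen_rotational_brownian(spec)


@pytest.fixture(scope="session")
def debye_fits(debye_traj):
    """KWW fits of C_1 and C_2 plus both D_r estimates on the Debye run."""
    c1 = s.legendre_autocorrelation(debye_traj, 1, origin_stride=10)
    c2 = s.legendre_autocorrelation(debye_traj, 2, origin_stride=10)
    fit1, fit2 = s.kww_fit(c1), s.kww_fit(c2)
    track = s.angular_track(debye_traj)
    amsd = s.angular_msd(track, origin_stride=10)
    D_msd, se_msd = s.fit_diffusion(amsd, divisor=4.0)
    acf_grid = np.arange(100) * debye_traj.frame_interval
    c_omega = s.angular_velocity_acf(track, acf_grid)
    D_gk, se_gk = s.rotational_diffusion_gk(c_omega)
    return {
        "c1": c1, "c2": c2, "fit1": fit1, "fit2": fit2,
        "D_r_msd": (D_msd, se_msd), "D_r_gk": (D_gk, se_gk),
    }


@pytest.fixture(scope="session")
def brownian_traj():
    """Free translational Brownian motion: N=1000, 2000 frames, D_t=0.2."""
    spec = s.GeneratorSpec(n_molecules=1000, n_frames=2000, frame_interval=0.1,
                           D_t=0.2, seed=11, box_edge=31.04)
    return s.gen_translational_brownian(spec)


@pytest.fixture(scope="session")
def brownian_unwrapped(brownian_traj):
    return unwrapped(brownian_traj)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
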