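"""Synthetic rigid-body trajectories and stress series with known truth.

Every generator here has at least one closed-form oracle against which the
estimator modules are validated:

* isotropic rotational Brownian motion with diffusivity D_r
  → C_ℓ(t) = exp(−ℓ(ℓ+1) D_r t), ⟨Δφ²⟩ = 4 D_r t, ∫C_Ω dt = D_r
* Ivanov-style rotational jumps (angle θ₀ about an axis uniform on the
  sphere, exponential waiting time τ_w)
  → 1/τ_ℓ = (1/τ_w)(1 − P_ℓ(cos θ₀))
* free translational Brownian motion with diffusivity D_t
  → ⟨|Δr|²⟩ = 6 D_t t,  F_s(k,t) = exp(−k² D_t t)
* a two-state (fast/slow) translational model for dynamic-heterogeneity
  tests
* a stationary Ornstein–Uhlenbeck stress series
  → ⟨σ(0)σ(t)⟩ = c·exp(−t/τ_c), Green–Kubo integral c·τ_c.

Rotational steps compose exact exponential-map (rotation-vector) increments
into the quaternion, so the Debye closed forms hold to O(Δt) without
coordinate singularities.  All generators are reproducible from an integer
seed and record their full parameter set in the trajectory metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.special import eval_legendre

from .trajectory import (
    RigidMoleculeTrajectory,
    ScalarSeries,
    SiteTrajectory,
    TIP4P2005_SITES,
    quat_from_rotvec,
    quat_multiply,
    random_unit_quaternions,
    sites_from_rigid_body,
    wrap_positions,
)

__all__ = [
    "GeneratorSpec",
    "gen_rotational_brownian",
    "gen_jump_rotation",
    "gen_translational_brownian",
    "gen_two_state_heterogeneous",
    "gen_combined_rigid_water",
    "gen_ou_stress",
    "oracle_debye_correlator",
    "oracle_jump_tau",
]


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic dynamics models.

    Only the fields used by a given model need to be set; units are the
    package's internal system (Å, ps, rad).
    """

    model: str = ""
    n_molecules: int = 1000
    n_frames: int = 2000
    frame_interval: float = 0.1  # ps
    box_edge: float = 31.04  # Å (1000 waters at 1 g/cm^3)
    seed: int = 0
    D_t: float = 0.2  # Å²/ps
    D_r: float = 0.05  # rad²/ps
    tau_wait: float = 5.0  # ps
    theta0: float = 1.2  # rad
    jump_length: float = 1.0  # Å
    D_fast: float = 0.5
    D_slow: float = 0.02
    switch_rate_fs: float = 0.0  # fast -> slow, 1/ps
    switch_rate_sf: float = 0.0  # slow -> fast, 1/ps
    stress_amplitude: float = 1.0  # c, internal stress units squared
    stress_corr_time: float = 10.0  # τ_c, ps
    n_samples: int = 100_000  # stress series length
    sample_interval: float = 1.0  # ps
    site_geometry: dict = field(default_factory=lambda: dict(TIP4P2005_SITES))

    def as_metadata(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if k != "site_geometry"}
        out["site_geometry"] = {k: list(map(float, v)) for k, v in self.site_geometry.items()}
        return out


def _check_positive(**kwargs) -> None:
    for name, v in kwargs.items():
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")


# ---------------------------------------------------------------------------
# Rotational models
# ---------------------------------------------------------------------------

def _advance_rotations(q0: np.ndarray, rotvecs_per_frame) -> np.ndarray:
    """Compose body-frame rotation-vector increments into quaternions.

    ``rotvecs_per_frame`` yields an (N, 3) rotation vector per step; the
    returned array has one more frame than there are steps.  Quaternions are
    renormalised each step (drift is far below 1e-12 per 1e4 steps, but the
    renormalisation keeps the invariant exact regardless of length).
    """
    frames = [q0]
    q = q0
    for rv in rotvecs_per_frame:
        dq = quat_from_rotvec(rv)
        q = quat_multiply(q, dq)  # body-frame increment
        norms = np.linalg.norm(q, axis=-1, keepdims=True)
        drifted = np.abs(norms[..., 0] - 1.0) > 1e-14
        if np.any(drifted):
            q = q.copy()
            q[drifted] /= norms[drifted]
        frames.append(q)
    return np.array(frames)


def gen_rotational_brownian(spec: GeneratorSpec) -> RigidMoleculeTrajectory:
    """Isotropic rotational Brownian motion; centers are static.

    Each step applies a body-frame rotation vector whose components are
    independent Gaussians of variance 2·D_r·frame_interval.  Requires
    D_r·frame_interval ≤ 0.05 rad² so the per-step rotation stays in the
    small-step regime where the Debye correlator is exact to O(Δt).
    """
    _check_positive(frame_interval=spec.frame_interval)
    if spec.D_r < 0:
        raise ValueError("D_r must be >= 0")
    if spec.D_r * spec.frame_interval > 0.05:
        raise ValueError(
            f"D_r*frame_interval = {spec.D_r * spec.frame_interval:.3g} rad² exceeds the "
            "small-step limit 0.05; use a finer frame_interval"
        )
    rng = np.random.default_rng(spec.seed)
    N = spec.n_molecules
    q0 = random_unit_quaternions(N, rng)
    sigma = np.sqrt(2.0 * spec.D_r * spec.frame_interval)
    steps = (rng.standard_normal((spec.n_frames - 1, N, 3)) * sigma
             if spec.n_frames > 1 else [])
    quats = _advance_rotations(q0, steps)
    centers = np.broadcast_to(
        rng.uniform(0, spec.box_edge, (1, N, 3)), (spec.n_frames, N, 3)
    ).copy()
    meta = {"generator": "rotational_brownian", "spec": spec.as_metadata()}
    return RigidMoleculeTrajectory(
        centers=centers, orientations=quats, box_edge=spec.box_edge,
        frame_interval=spec.frame_interval, metadata=meta,
    )


def gen_jump_rotation(spec: GeneratorSpec) -> RigidMoleculeTrajectory:
    """Ivanov jump rotation: fixed-angle jumps at exponential waiting times.

    Orientations are piecewise constant; at events (Poisson rate 1/τ_w per
    molecule) the molecular axis tilts by exactly θ₀ — the jump rotation
    axis is drawn uniformly on the circle perpendicular to the current
    molecular axis, so e(t⁺)·e(t⁻) = cos θ₀ at every event.  With uniform
    azimuth the spherical-harmonic addition theorem gives the exact
    relaxation times 1/τ_ℓ = (1 − P_ℓ(cos θ₀))/τ_w.
    """
    _check_positive(tau_wait=spec.tau_wait, frame_interval=spec.frame_interval)
    if not 0 < spec.theta0 <= np.pi:
        raise ValueError("theta0 must be in (0, pi]")
    if spec.tau_wait < 2 * spec.frame_interval:
        raise ValueError("tau_wait must be >= 2*frame_interval")
    rng = np.random.default_rng(spec.seed)
    N = spec.n_molecules
    dipole_axis = np.array([0.0, 0.0, 1.0])
    q = random_unit_quaternions(N, rng)
    p_per_frame = spec.frame_interval / spec.tau_wait
    counts = rng.poisson(p_per_frame, size=(spec.n_frames - 1, N))
    quats = np.empty((spec.n_frames, N, 4))
    quats[0] = q
    from .trajectory import quat_rotate

    for f in range(spec.n_frames - 1):
        max_ev = counts[f].max(initial=0)
        for ev in range(max_ev):
            active = np.nonzero(counts[f] > ev)[0]
            e = quat_rotate(q[active], dipole_axis)
            # random axis perpendicular to the current molecular axis
            raw = rng.standard_normal((active.size, 3))
            perp = raw - (np.einsum("ij,ij->i", raw, e))[:, None] * e
            perp /= np.linalg.norm(perp, axis=-1, keepdims=True)
            dq = quat_from_rotvec(spec.theta0 * perp)
            # world-frame rotation: pre-multiply
            q_new = quat_multiply(dq, q[active])
            q[active] = q_new / np.linalg.norm(q_new, axis=-1, keepdims=True)
        quats[f + 1] = q
    centers = np.broadcast_to(
        rng.uniform(0, spec.box_edge, (1, N, 3)), (spec.n_frames, N, 3)
    ).copy()
    meta = {
        "generator": "jump_rotation",
        "spec": spec.as_metadata(),
        "event_counts_total": int(counts.sum()),
    }
    return RigidMoleculeTrajectory(
        centers=centers, orientations=quats, box_edge=spec.box_edge,
        frame_interval=spec.frame_interval, metadata=meta,
    )


# ---------------------------------------------------------------------------
# Translational models
# ---------------------------------------------------------------------------

def _package_translation(spec: GeneratorSpec, unwrapped: np.ndarray,
                         rng: np.random.Generator, generator: str,
                         extra_meta: dict | None = None) -> RigidMoleculeTrajectory:
    N = spec.n_molecules
    quats = np.zeros((spec.n_frames, N, 4))
    quats[..., 0] = 1.0
    meta = {
        "generator": generator,
        "spec": spec.as_metadata(),
        "unwrapped_centers": unwrapped,
    }
    if extra_meta:
        meta.update(extra_meta)
    return RigidMoleculeTrajectory(
        centers=wrap_positions(unwrapped, spec.box_edge),
        orientations=quats, box_edge=spec.box_edge,
        frame_interval=spec.frame_interval, metadata=meta,
    )


def gen_translational_brownian(spec: GeneratorSpec) -> RigidMoleculeTrajectory:
    """Free Brownian centers: Gaussian increments of variance 2·D_t·Δt per
    component, wrapped into the box; the unwrapped ground truth is kept in
    ``metadata['unwrapped_centers']``.
    """
    _check_positive(frame_interval=spec.frame_interval, box_edge=spec.box_edge)
    if spec.D_t < 0:
        raise ValueError("D_t must be >= 0")
    if np.sqrt(2.0 * spec.D_t * spec.frame_interval) >= spec.box_edge / 10.0:
        raise ValueError("per-frame RMS step exceeds box_edge/10; refine frame_interval")
    rng = np.random.default_rng(spec.seed)
    N = spec.n_molecules
    x0 = rng.uniform(0, spec.box_edge, (1, N, 3))
    sigma = np.sqrt(2.0 * spec.D_t * spec.frame_interval)
    incr = rng.standard_normal((spec.n_frames - 1, N, 3)) * sigma
    unwrapped = np.concatenate([x0, x0 + np.cumsum(incr, axis=0)], axis=0)
    return _package_translation(spec, unwrapped, rng, "translational_brownian")


def gen_two_state_heterogeneous(spec: GeneratorSpec) -> RigidMoleculeTrajectory:
    """Two-state translational dynamics: each molecule carries a fast/slow
    Markov label switching in continuous time; increments use the current
    state's diffusivity, integrated exactly over within-frame occupancy.

    With both switch rates zero, molecules keep their initial label (half
    fast, half slow in expectation).
    """
    _check_positive(frame_interval=spec.frame_interval)
    if spec.switch_rate_fs < 0 or spec.switch_rate_sf < 0:
        raise ValueError("switch rates must be >= 0")
    if not spec.D_fast > spec.D_slow:
        raise ValueError("D_fast must exceed D_slow")
    rng = np.random.default_rng(spec.seed)
    N, dt = spec.n_molecules, spec.frame_interval
    kf, ks = spec.switch_rate_fs, spec.switch_rate_sf  # fast->slow, slow->fast
    if kf + ks > 0:
        p_fast = ks / (kf + ks)
    else:
        p_fast = 0.5
    state = rng.random(N) < p_fast  # True = fast
    states = np.empty((spec.n_frames, N), dtype=bool)
    states[0] = state
    x = rng.uniform(0, spec.box_edge, (N, 3))
    unwrapped = np.empty((spec.n_frames, N, 3))
    unwrapped[0] = x
    for f in range(1, spec.n_frames):
        # exact within-frame occupancy by event-driven switching
        t_fast = np.where(state, dt, 0.0).astype(float)
        if kf + ks > 0:
            t_left = np.full(N, dt)
            cur = state.copy()
            t_fast = np.zeros(N)
            alive = np.ones(N, dtype=bool)
            while alive.any():
                rates = np.where(cur, kf, ks)
                wait = np.full(N, np.inf)
                nz = alive & (rates > 0)
                wait[nz] = rng.exponential(1.0 / rates[nz])
                stay = wait >= t_left
                t_fast[alive & stay & cur] += t_left[alive & stay & cur]
                done = alive & stay
                t_fast[alive & ~stay & cur] += wait[alive & ~stay & cur]
                t_left[alive & ~stay] -= wait[alive & ~stay]
                cur[alive & ~stay] = ~cur[alive & ~stay]
                alive &= ~done
            state = cur
        var = 2.0 * (spec.D_fast * t_fast + spec.D_slow * (dt - t_fast))
        unwrapped[f] = unwrapped[f - 1] + rng.standard_normal((N, 3)) * np.sqrt(var)[:, None]
        states[f] = state
    return _package_translation(
        spec, unwrapped, rng, "two_state_heterogeneous", {"state_paths": states}
    )


# ---------------------------------------------------------------------------
# Combined rigid water and stress series
# ---------------------------------------------------------------------------

def gen_combined_rigid_water(spec: GeneratorSpec) -> tuple[RigidMoleculeTrajectory, SiteTrajectory]:
    """Translational Brownian centers + rotational Brownian orientations with
    a rigid three-site geometry mounted on each body frame."""
    trans = gen_translational_brownian(spec)
    rot = gen_rotational_brownian(spec)
    traj = RigidMoleculeTrajectory(
        centers=trans.centers,
        orientations=rot.orientations,
        box_edge=spec.box_edge,
        frame_interval=spec.frame_interval,
        metadata={
            "generator": "combined_rigid_water",
            "spec": spec.as_metadata(),
            "unwrapped_centers": trans.metadata["unwrapped_centers"],
        },
    )
    sites = sites_from_rigid_body(traj, spec.site_geometry)
    return traj, sites


def gen_ou_stress(spec: GeneratorSpec) -> ScalarSeries:
    """Stationary Ornstein–Uhlenbeck stress series by exact discretisation.

    ⟨σ(0)σ(t)⟩ = c·exp(−t/τ_c) holds at any sample interval; requires
    sample_interval ≤ τ_c/10 so Green–Kubo integrals resolve the decay.
    """
    _check_positive(stress_amplitude=spec.stress_amplitude,
                    stress_corr_time=spec.stress_corr_time,
                    sample_interval=spec.sample_interval)
    if spec.sample_interval > spec.stress_corr_time / 10.0:
        raise ValueError("sample_interval must be <= stress_corr_time/10")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    rho = np.exp(-spec.sample_interval / spec.stress_corr_time)
    sd = np.sqrt(spec.stress_amplitude)
    drive = np.empty(n)
    drive[0] = rng.standard_normal() * sd
    drive[1:] = rng.standard_normal(n - 1) * sd * np.sqrt(1.0 - rho * rho)
    x = lfilter([1.0], [1.0, -rho], drive)
    return ScalarSeries(
        values=x, sample_interval=spec.sample_interval, label="ou_stress",
        metadata={"generator": "ou_stress", "spec": spec.as_metadata()},
    )


# ---------------------------------------------------------------------------
# Closed-form oracles
# ---------------------------------------------------------------------------

def oracle_debye_correlator(order: int, D_r: float, t) -> np.ndarray:
    """Debye-model orientation correlator exp(−ℓ(ℓ+1)·D_r·t)."""
    if order < 1:
        raise ValueError("order must be >= 1")
    if D_r < 0:
        raise ValueError("D_r must be >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    return np.exp(-order * (order + 1) * D_r * t)


def oracle_jump_tau(order: int, tau_wait: float, theta0: float) -> float:
    """Ivanov jump-model relaxation time τ_w / (1 − P_ℓ(cos θ₀)).

    Undefined (no decay) when P_ℓ(cos θ₀) = 1, e.g. θ₀ = 0 for any ℓ or
    θ₀ = π for even ℓ.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    _check_positive(tau_wait=tau_wait)
    p = float(eval_legendre(order, np.cos(theta0)))
    if p >= 1.0 - 1e-12:
        raise ValueError(
            f"P_{order}(cos {theta0:g}) = {p:.6g}: correlator does not decay"
        )
    return tau_wait / (1.0 - p)
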