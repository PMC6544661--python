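"""Four-point susceptibilities and the joint translational–rotational
van Hove function.

χ₄-type susceptibilities measure dynamic heterogeneity as N times the
ensemble variance of a per-configuration correlator:

    χ_t(t) = N [⟨F̂_s(k,t)²⟩ − ⟨F̂_s(k,t)⟩²],   F̂_s = (1/N)Σ_j cos(k⃗·Δr⃗_j)
    χ_r(t) = N [⟨Ĉ_ℓ(t)²⟩ − ⟨Ĉ_ℓ(t)⟩²],        Ĉ_ℓ = (1/N)Σ_j P_ℓ(e_j(t)·e_j(0))

The variance is taken across configuration samples — time origins within a
single run (the default), or origins pooled across independent runs.  Both
susceptibilities peak at the time of maximal heterogeneity (τ_t, τ_r).

The joint van Hove function G_s(r, θ; t) is the probability density of a
molecule's displacement magnitude and reorientation angle after a lag t;
the surface 4πr²·G_s (probability per Å per rad) is what contour plots of
translation–rotation coupling show.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre

from .correlations import _lags_to_frames, _require_unwrapped, default_lag_grid
from .trajectory import RigidMoleculeTrajectory

__all__ = [
    "Chi4Result",
    "JointVanHove",
    "chi4_translational",
    "chi4_rotational",
    "peak_time",
    "joint_van_hove",
    "oracle_chi4_iid_translational",
    "oracle_debye_angle_density",
]


@dataclass
class Chi4Result:
    """A four-point susceptibility on a lag grid."""

    lags: np.ndarray
    chi: np.ndarray
    stderr: np.ndarray
    kind: str  # translational | rotational
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.chi = np.asarray(self.chi, dtype=float)
        self.stderr = np.asarray(self.stderr, dtype=float)


@dataclass
class JointVanHove:
    """Binned joint density of (|Δr⃗|, Δθ) at a set of lag times.

    ``surface[i]`` is the joint probability density P(r, θ; t_i) per
    (Å·rad) bin — the 4πr²·G_s-weighted surface of contour plots; its
    discrete integral Σ P·Δr·Δθ equals 1.  ``density[i]`` is the
    corresponding G_s(r, θ; t_i) = P/(4πr²) evaluated at bin centres.
    """

    times: np.ndarray
    r_edges: np.ndarray  # Å
    theta_edges: np.ndarray  # rad
    surface: np.ndarray  # (n_times, n_r, n_theta), per Å per rad
    density: np.ndarray  # G_s = surface / (4 pi r^2)
    counts: np.ndarray  # raw counts per bin
    normalization: str = "sum(surface * dr * dtheta) == 1 per time"

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def theta_centers(self) -> np.ndarray:
        return 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])

    def radial_marginal(self, i: int) -> np.ndarray:
        """P(r; t_i) per Å, marginalised over θ."""
        dth = np.diff(self.theta_edges)
        return (self.surface[i] * dth[None, :]).sum(axis=1)

    def angular_marginal(self, i: int) -> np.ndarray:
        """P(θ; t_i) per rad, marginalised over r."""
        dr = np.diff(self.r_edges)
        return (self.surface[i] * dr[:, None]).sum(axis=0)


# ---------------------------------------------------------------------------
# Four-point susceptibilities
# ---------------------------------------------------------------------------

def _chi4_from_samples(per_origin_fn, n_frames, lag_frames, frame_interval,
                       N, kind, params, origin_stride, n_blocks=10):
    vals, errs = [], []
    for lag in lag_frames:
        if lag == 0:
            vals.append(0.0)
            errs.append(0.0)
            continue
        origins = np.arange(0, n_frames - lag, origin_stride)
        if origins.size < 2:
            raise ValueError(
                f"need >= 2 configuration samples at lag {lag}; trajectory too short"
            )
        samples = per_origin_fn(origins, lag)  # per-config correlator values
        chi = N * samples.var(ddof=1)
        # block jackknife over contiguous origin blocks for the error
        nb = min(n_blocks, origins.size)
        if nb >= 2:
            blocks = np.array_split(samples, nb)
            bvals = []
            for b in range(nb):
                rest = np.concatenate([blocks[i] for i in range(nb) if i != b])
                if rest.size >= 2:
                    bvals.append(N * rest.var(ddof=1))
            bvals = np.array(bvals)
            # delete-one-block jackknife standard error
            se = (float((nb - 1) / np.sqrt(nb) * bvals.std(ddof=1))
                  if bvals.size >= 2 else np.nan)
        else:
            se = np.nan
        vals.append(float(chi))
        errs.append(se)
    return Chi4Result(
        lags=lag_frames * frame_interval,
        chi=np.array(vals), stderr=np.array(errs), kind=kind, params=dict(params),
    )


def chi4_translational(traj: RigidMoleculeTrajectory, k: float,
                       lag_grid: np.ndarray | None = None,
                       origin_stride: int = 1,
                       k_vector: np.ndarray | None = None) -> Chi4Result:
    """χ_t(t) = N·var(F̂_s(k,t)) across time-origin configuration samples.

    Uses a single fixed wave vector (by default the +x lattice vector
    nearest |k⃗| = k) so that closed-form iid variance identities apply;
    pass an explicit ``k_vector`` to override.
    """
    centers = _require_unwrapped(traj)
    if k_vector is None:
        dk = 2.0 * np.pi / traj.box_edge
        n = max(1, round(k / dk))
        k_vector = np.array([n * dk, 0.0, 0.0])
    k_vector = np.asarray(k_vector, dtype=float)
    if lag_grid is None:
        lag_grid = default_lag_grid(traj.n_frames, traj.frame_interval)
    lag_frames = _lags_to_frames(lag_grid, traj.frame_interval)

    def per_origin(origins, lag):
        d = centers[origins + lag] - centers[origins]
        return np.cos(d @ k_vector).mean(axis=1)

    return _chi4_from_samples(
        per_origin, traj.n_frames, lag_frames, traj.frame_interval,
        traj.n_molecules, "translational",
        {"k": float(np.linalg.norm(k_vector)), "k_vector": k_vector.tolist()},
        origin_stride,
    )


def chi4_rotational(traj: RigidMoleculeTrajectory, order: int,
                    lag_grid: np.ndarray | None = None,
                    origin_stride: int = 1) -> Chi4Result:
    """χ_r(t) = N·var(Ĉ_ℓ(t)) across time-origin configuration samples."""
    if not 1 <= order <= 6:
        raise ValueError("Legendre order must be in 1..6")
    e = traj.dipole_vectors()
    if lag_grid is None:
        lag_grid = default_lag_grid(traj.n_frames, traj.frame_interval)
    lag_frames = _lags_to_frames(lag_grid, traj.frame_interval)

    def per_origin(origins, lag):
        dots = np.einsum("ojk,ojk->oj", e[origins + lag], e[origins])
        return eval_legendre(order, np.clip(dots, -1.0, 1.0)).mean(axis=1)

    return _chi4_from_samples(
        per_origin, traj.n_frames, lag_frames, traj.frame_interval,
        traj.n_molecules, "rotational", {"order": order}, origin_stride,
    )


def peak_time(chi: Chi4Result) -> float:
    """Peak time of χ(t), refined by a three-point parabola in log-time.

    Raises when the maximum sits on the grid boundary (no interior peak).
    """
    pos = chi.lags > 0
    lags, vals = chi.lags[pos], chi.chi[pos]
    i = int(np.argmax(vals))
    if i == 0 or i == vals.size - 1:
        raise ValueError("no interior peak: chi is maximal at the lag-grid boundary")
    x = np.log(lags[i - 1 : i + 2])
    y = vals[i - 1 : i + 2]
    denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
    a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) / denom
    b = (x[2] ** 2 * (y[0] - y[1]) + x[1] ** 2 * (y[2] - y[0]) + x[0] ** 2 * (y[1] - y[2])) / denom
    if a >= 0:  # degenerate curvature; fall back to the grid argmax
        return float(lags[i])
    return float(np.exp(-b / (2.0 * a)))


# ---------------------------------------------------------------------------
# Joint van Hove
# ---------------------------------------------------------------------------

def joint_van_hove(traj: RigidMoleculeTrajectory, times,
                   r_edges: np.ndarray | None = None,
                   theta_edges: np.ndarray | None = None,
                   origin_stride: int = 1) -> JointVanHove:
    """Joint distribution of (|Δr⃗(t)|, Δθ(t)) pooled over molecules/origins.

    Δθ is the direct angle arccos(e(t₀)·e(t₀+t)) ∈ [0, π].  Defaults: 100
    radial bins over [0, 12 Å], 60 angular bins over [0, π].  Raises when
    observed displacements exceed the radial range.
    """
    centers = _require_unwrapped(traj)
    e = traj.dipole_vectors()
    if r_edges is None:
        r_edges = np.linspace(0.0, 12.0, 101)
    if theta_edges is None:
        theta_edges = np.linspace(0.0, np.pi, 61)
    r_edges = np.asarray(r_edges, dtype=float)
    theta_edges = np.asarray(theta_edges, dtype=float)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    lag_frames = _lags_to_frames(times, traj.frame_interval)
    n_r, n_th = r_edges.size - 1, theta_edges.size - 1
    counts = np.zeros((times.size, n_r, n_th))
    for i, lag in enumerate(lag_frames):
        origins = np.arange(0, traj.n_frames - lag, origin_stride)
        if origins.size == 0:
            raise ValueError(f"lag {times[i]} ps exceeds the trajectory length")
        dr = np.linalg.norm(centers[origins + lag] - centers[origins], axis=-1).ravel()
        if dr.max() > r_edges[-1]:
            raise ValueError(
                f"observed displacement {dr.max():.3g} Å exceeds radial range "
                f"{r_edges[-1]:.3g} Å; extend r_edges"
            )
        dots = np.einsum("ojk,ojk->oj", e[origins + lag], e[origins]).ravel()
        dth = np.arccos(np.clip(dots, -1.0, 1.0))
        H, _, _ = np.histogram2d(dr, dth, bins=[r_edges, theta_edges])
        counts[i] = H
    dr_w = np.diff(r_edges)[:, None]
    dth_w = np.diff(theta_edges)[None, :]
    total = counts.sum(axis=(1, 2), keepdims=True)
    surface = counts / total / (dr_w * dth_w)
    r_c = 0.5 * (r_edges[:-1] + r_edges[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        density = surface / (4.0 * np.pi * r_c[None, :, None] ** 2)
    return JointVanHove(
        times=times, r_edges=r_edges, theta_edges=theta_edges,
        surface=surface, density=density, counts=counts,
    )


# ---------------------------------------------------------------------------
# Closed-form oracles for iid dynamics
# ---------------------------------------------------------------------------

def oracle_chi4_iid_translational(k: float, D_t: float, t) -> np.ndarray:
    """χ_t for iid Gaussian molecules at a fixed k⃗:
    (1 + F_s(2k,t))/2 − F_s(k,t)², with F_s = exp(−k²D_t t)."""
    t = np.asarray(t, dtype=float)
    f_k = np.exp(-(k**2) * D_t * t)
    f_2k = np.exp(-(4.0 * k**2) * D_t * t)
    return (1.0 + f_2k) / 2.0 - f_k**2


def oracle_debye_angle_density(D_r: float, t: float, theta: np.ndarray,
                               ell_max: int = 60) -> np.ndarray:
    """Reorientation-angle density for isotropic rotational diffusion:

        p(θ; t) = Σ_ℓ (2ℓ+1)/2 · exp(−ℓ(ℓ+1)D_r t) · P_ℓ(cos θ) · sin θ

    truncated at ``ell_max`` (adequate once D_r·t ≳ 1/ell_max²)."""
    theta = np.asarray(theta, dtype=float)
    x = np.cos(theta)
    out = np.zeros_like(theta)
    for ell in range(ell_max + 1):
        out += (2 * ell + 1) / 2.0 * np.exp(-ell * (ell + 1) * D_r * t) * eval_legendre(ell, x)
    return out * np.sin(theta)
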