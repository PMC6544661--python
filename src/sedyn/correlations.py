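"""Time-correlation estimators with multiple-time-origin averaging.

All estimators share one result container, :class:`CorrelationResult`, and a
common convention: lags are physical times (ps) on an ascending grid, values
are averaged over molecules and over all valid time origins on that grid,
and standard errors come from contiguous origin blocks (origins within a
block are strongly correlated; block means are approximately independent).
When several independent runs are available,
:func:`average_correlation_results` averages the correlators first and
derives the error across runs, mirroring the usual multi-run MD workflow.

Quantities covered:

* translational mean-square displacement  ⟨|Δr(t)|²⟩
* angular displacement tracks φ(t) built from the molecular-axis angular
  velocity  ω(t) = e(t) × e(t+Δt)/Δt  with |ω| = arccos(e·e′)/Δt,
  and the angular MSD ⟨|Δφ(t)|²⟩
* orientation correlators  C_ℓ(t) = ⟨P_ℓ(e(t)·e(0))⟩
* the rigid-body angular-velocity autocorrelation  C_Ω(t) = ⟨Ω(t)·Ω(0)⟩/3
* the self intermediate scattering function  F_s(k,t) = ⟨cos(k·Δr(t))⟩
* stationary scalar-series autocovariance (for Green–Kubo integrals)
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre

from .trajectory import RigidMoleculeTrajectory, ScalarSeries, quat_multiply

__all__ = [
    "CorrelationResult",
    "AngularTrack",
    "default_lag_grid",
    "msd",
    "angular_track",
    "angular_msd",
    "legendre_autocorrelation",
    "angular_velocity_acf",
    "intermediate_scattering",
    "commensurate_k_vectors",
    "series_acf",
    "average_correlation_results",
]


@dataclass
class CorrelationResult:
    """A correlator on a lag-time grid with per-lag uncertainties."""

    lags: np.ndarray  # ps, ascending
    values: np.ndarray
    stderr: np.ndarray
    n_origins: np.ndarray
    kind: str  # MSD | angular_MSD | C_ell | C_Omega | F_s | stress_ACF | hbond_c
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.stderr = np.asarray(self.stderr, dtype=float)
        self.n_origins = np.asarray(self.n_origins)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")


@dataclass
class AngularTrack:
    """Angular velocities and accumulated angular displacements.

    ``omega`` is the molecular-axis angular velocity built from successive
    axis directions (no spin about the axis, two rotational degrees of
    freedom); ``phi`` is its running time integral with φ(0) = 0.  ``Omega``
    is the full rigid-body angular velocity in the world frame derived from
    successive quaternions (three degrees of freedom, includes spin).
    """

    stride: float  # Δt, ps
    omega: np.ndarray  # (n_frames-1, N, 3) rad/ps
    phi: np.ndarray  # (n_frames, N, 3) rad, phi[0] = 0
    Omega: np.ndarray  # (n_frames-1, N, 3) rad/ps


# ---------------------------------------------------------------------------
# Lag grids and origin-block errors
# ---------------------------------------------------------------------------

def default_lag_grid(n_frames: int, frame_interval: float, n_per_decade: int = 12,
                     include_zero: bool = True) -> np.ndarray:
    """Logarithmically spaced lag times (ps) realisable on the frame grid."""
    max_lag = n_frames - 1
    if max_lag < 1:
        raise ValueError("need at least two frames")
    n_points = max(2, int(np.log10(max_lag) * n_per_decade) + 1)
    lags = np.unique(np.round(np.logspace(0, np.log10(max_lag), n_points)).astype(int))
    if include_zero:
        lags = np.concatenate([[0], lags])
    return lags * frame_interval


def _lags_to_frames(lag_grid: np.ndarray, frame_interval: float) -> np.ndarray:
    frames = np.round(np.asarray(lag_grid, dtype=float) / frame_interval).astype(int)
    if not np.allclose(frames * frame_interval, lag_grid, rtol=1e-9, atol=1e-12):
        raise ValueError("lag grid must consist of integer multiples of the frame interval")
    return frames


def _block_stats(per_origin: np.ndarray, n_blocks: int = 10) -> tuple[float, float]:
    """Mean and block standard error of a per-origin sample sequence."""
    n = per_origin.shape[0]
    mean = float(per_origin.mean())
    nb = min(n_blocks, n)
    if nb < 2:
        return mean, np.nan
    blocks = np.array_split(per_origin, nb)
    bm = np.array([b.mean() for b in blocks])
    return mean, float(bm.std(ddof=1) / np.sqrt(nb))


def _origin_indices(n_frames: int, lag: int, stride: int) -> np.ndarray:
    return np.arange(0, n_frames - lag, stride)


def _multi_origin(values_fn, n_frames: int, lag_frames: np.ndarray,
                  frame_interval: float, kind: str, params: dict,
                  origin_stride: int = 1, zero_value: float | None = None,
                  ) -> CorrelationResult:
    """Average ``values_fn(origins, lag) -> per-origin values`` over origins."""
    vals, errs, nor = [], [], []
    for lag in lag_frames:
        if lag == 0 and zero_value is not None:
            vals.append(zero_value)
            errs.append(0.0)
            nor.append(n_frames)
            continue
        origins = _origin_indices(n_frames, lag, origin_stride)
        per_origin = values_fn(origins, lag)
        m, se = _block_stats(per_origin)
        vals.append(m)
        errs.append(se)
        nor.append(origins.size)
    return CorrelationResult(
        lags=lag_frames * frame_interval,
        values=np.array(vals), stderr=np.array(errs), n_origins=np.array(nor),
        kind=kind, params=dict(params),
    )


def average_correlation_results(results: list[CorrelationResult]) -> CorrelationResult:
    """Average correlators from independent runs; stderr across runs."""
    if len(results) < 2:
        raise ValueError("need at least two runs to average")
    lags = results[0].lags
    for r in results[1:]:
        if not np.array_equal(r.lags, lags) or r.kind != results[0].kind:
            raise ValueError("results must share lag grid and kind")
    stack = np.array([r.values for r in results])
    return CorrelationResult(
        lags=lags,
        values=stack.mean(axis=0),
        stderr=stack.std(axis=0, ddof=1) / np.sqrt(len(results)),
        n_origins=np.sum([r.n_origins for r in results], axis=0),
        kind=results[0].kind,
        params={**results[0].params, "n_runs": len(results)},
    )


# ---------------------------------------------------------------------------
# Translational MSD
# ---------------------------------------------------------------------------

def _require_unwrapped(traj: RigidMoleculeTrajectory) -> np.ndarray:
    centers = traj.centers
    if traj.wrapped:
        jumps = np.abs(np.diff(centers, axis=0)).max() if traj.n_frames > 1 else 0.0
        if jumps >= traj.box_edge / 2.0:
            raise ValueError(
                "trajectory appears wrapped (inter-frame jump >= box_edge/2); "
                "unwrap_periodic() it first"
            )
    return centers


def msd(traj: RigidMoleculeTrajectory, lag_grid: np.ndarray | None = None,
        origin_stride: int = 1) -> CorrelationResult:
    """Translational mean-square displacement ⟨|Δr(t)|²⟩ (Å²)."""
    centers = _require_unwrapped(traj)
    if lag_grid is None:
        lag_grid = default_lag_grid(traj.n_frames, traj.frame_interval)
    lag_frames = _lags_to_frames(lag_grid, traj.frame_interval)

    def per_origin(origins, lag):
        d = centers[origins + lag] - centers[origins]
        return np.einsum("ojk,ojk->oj", d, d).mean(axis=1)

    return _multi_origin(per_origin, traj.n_frames, lag_frames, traj.frame_interval,
                         "MSD", {}, origin_stride, zero_value=0.0)


# ---------------------------------------------------------------------------
# Angular tracks and rotational correlators
# ---------------------------------------------------------------------------

def angular_track(traj: RigidMoleculeTrajectory, stride: int = 1) -> AngularTrack:
    """Angular velocities/displacements at stride Δt = stride × frame_interval.

    Raises if any consecutive axis pair is (anti)parallel to within the
    arccos branch: an antiparallel pair means the stride is too coarse for
    the axis-based integration scheme.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    dt = stride * traj.frame_interval
    e = traj.dipole_vectors()[::stride]
    if e.shape[0] < 2:
        raise ValueError("need at least two strided frames")
    dots = np.einsum("fjk,fjk->fj", e[:-1], e[1:])
    if np.any(dots <= -1.0 + 1e-12):
        f, j = np.argwhere(dots <= -1.0 + 1e-12)[0]
        raise ValueError(
            f"axes of molecule {j} at strided frames {f},{f + 1} are antiparallel; "
            "use a smaller stride"
        )
    cross = np.cross(e[:-1], e[1:])
    cross_norm = np.linalg.norm(cross, axis=-1, keepdims=True)
    angle = np.arccos(np.clip(dots, -1.0, 1.0))[..., None]
    with np.errstate(invalid="ignore", divide="ignore"):
        axis = np.where(cross_norm > 1e-15, cross / np.where(cross_norm > 0, cross_norm, 1.0), 0.0)
    omega = axis * angle / dt
    phi = np.concatenate(
        [np.zeros((1,) + omega.shape[1:]), np.cumsum(omega * dt, axis=0)], axis=0
    )

    # full rigid-body angular velocity in the world frame from successive
    # quaternions: q(t+dt) = dq_world ⊗ q(t)
    q = traj.orientations[::stride]
    q_conj = q[:-1] * np.array([1.0, -1.0, -1.0, -1.0])
    dq = quat_multiply(q[1:], q_conj)
    # rotation vector of dq
    w = np.clip(np.abs(dq[..., 0]), 0.0, 1.0)
    sign = np.sign(dq[..., :1]) + (dq[..., :1] == 0)
    vec = dq[..., 1:] * sign
    vnorm = np.linalg.norm(vec, axis=-1, keepdims=True)
    ang = 2.0 * np.arctan2(vnorm[..., 0], w)
    with np.errstate(invalid="ignore", divide="ignore"):
        axis_q = np.where(vnorm > 1e-15, vec / np.where(vnorm > 0, vnorm, 1.0), 0.0)
    Omega = axis_q * ang[..., None] / dt
    return AngularTrack(stride=dt, omega=omega, phi=phi, Omega=Omega)


def angular_msd(track: AngularTrack, lag_grid: np.ndarray | None = None,
                origin_stride: int = 1) -> CorrelationResult:
    """Angular mean-square displacement ⟨|Δφ(t)|²⟩ (rad²)."""
    phi = track.phi
    n_frames = phi.shape[0]
    if lag_grid is None:
        lag_grid = default_lag_grid(n_frames, track.stride)
    lag_frames = _lags_to_frames(lag_grid, track.stride)

    def per_origin(origins, lag):
        d = phi[origins + lag] - phi[origins]
        return np.einsum("ojk,ojk->oj", d, d).mean(axis=1)

    return _multi_origin(per_origin, n_frames, lag_frames, track.stride,
                         "angular_MSD", {}, origin_stride, zero_value=0.0)


def legendre_autocorrelation(traj: RigidMoleculeTrajectory, order: int,
                             lag_grid: np.ndarray | None = None,
                             origin_stride: int = 1) -> CorrelationResult:
    """Orientation correlator C_ℓ(t) = ⟨P_ℓ(e(t₀+t)·e(t₀))⟩."""
    if not 1 <= order <= 6:
        raise ValueError("Legendre order must be in 1..6")
    e = traj.dipole_vectors()
    if lag_grid is None:
        lag_grid = default_lag_grid(traj.n_frames, traj.frame_interval)
    lag_frames = _lags_to_frames(lag_grid, traj.frame_interval)

    def per_origin(origins, lag):
        dots = np.einsum("ojk,ojk->oj", e[origins + lag], e[origins])
        return eval_legendre(order, np.clip(dots, -1.0, 1.0)).mean(axis=1)

    return _multi_origin(per_origin, traj.n_frames, lag_frames, traj.frame_interval,
                         "C_ell", {"order": order}, origin_stride, zero_value=1.0)


def angular_velocity_acf(track: AngularTrack, lag_grid: np.ndarray | None = None,
                         origin_stride: int = 1) -> CorrelationResult:
    """C_Ω(t) = ⟨Ω(t₀+t)·Ω(t₀)⟩ / 3 (rad² ps⁻², per component).

    The 1/3 normalisation makes ∫C_Ω dt the rotational diffusion constant
    for isotropic rotation (Green–Kubo route).
    """
    Om = track.Omega
    n = Om.shape[0]
    if lag_grid is None:
        lag_grid = default_lag_grid(n, track.stride)
    lag_frames = _lags_to_frames(lag_grid, track.stride)

    def per_origin(origins, lag):
        dots = np.einsum("ojk,ojk->oj", Om[origins + lag], Om[origins])
        return dots.mean(axis=1) / 3.0

    return _multi_origin(per_origin, n, lag_frames, track.stride,
                         "C_Omega", {}, origin_stride)


# ---------------------------------------------------------------------------
# Intermediate scattering function
# ---------------------------------------------------------------------------

def commensurate_k_vectors(k: float, box_edge: float, rel_tol: float = 0.02,
                           max_vectors: int = 50) -> np.ndarray:
    """Reciprocal-lattice vectors (2π/L)·n with |k⃗| within rel_tol of k.

    Raises with the nearest available magnitudes when none qualifies within
    5 % of the request.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    dk = 2.0 * np.pi / box_edge
    n_max = int(np.ceil(k * (1 + 0.06) / dk)) + 1
    rng = np.arange(-n_max, n_max + 1)
    grid = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid[np.any(grid != 0, axis=1)]
    mags = dk * np.linalg.norm(grid, axis=1)
    sel = np.abs(mags - k) <= rel_tol * k
    if not np.any(np.abs(mags - k) <= 0.05 * k):
        nearest = np.unique(np.round(mags, 6))
        nearest = nearest[np.argsort(np.abs(nearest - k))][:5]
        raise ValueError(
            f"no lattice vector within 5% of k={k}; nearest magnitudes: {list(nearest)}"
        )
    if not np.any(sel):
        sel = np.abs(mags - k) <= 0.05 * k
    vecs = dk * grid[sel].astype(float)
    if vecs.shape[0] > max_vectors:
        # deterministic thin-out: keep the magnitudes closest to k
        order = np.argsort(np.abs(np.linalg.norm(vecs, axis=1) - k), kind="stable")
        vecs = vecs[order[:max_vectors]]
    return vecs


def intermediate_scattering(traj: RigidMoleculeTrajectory, k: float,
                            lag_grid: np.ndarray | None = None,
                            origin_stride: int = 1,
                            k_vectors: np.ndarray | None = None) -> CorrelationResult:
    """Self intermediate scattering function F_s(k,t) = ⟨cos(k⃗·Δr(t))⟩.

    Averaged over molecules, origins and a set of lattice-commensurate
    wave vectors with |k⃗| ≈ k (pass ``k_vectors`` with a single row to pin
    one fixed k⃗, e.g. for variance identities).
    """
    centers = _require_unwrapped(traj)
    if k_vectors is None:
        k_vectors = commensurate_k_vectors(k, traj.box_edge)
    k_vectors = np.atleast_2d(np.asarray(k_vectors, dtype=float))
    if lag_grid is None:
        lag_grid = default_lag_grid(traj.n_frames, traj.frame_interval)
    lag_frames = _lags_to_frames(lag_grid, traj.frame_interval)

    def per_origin(origins, lag):
        d = centers[origins + lag] - centers[origins]  # (o, N, 3)
        phases = np.tensordot(d, k_vectors, axes=([2], [1]))  # (o, N, nk)
        return np.cos(phases).mean(axis=(1, 2))

    res = _multi_origin(per_origin, traj.n_frames, lag_frames, traj.frame_interval,
                        "F_s", {"k": k, "n_k_vectors": int(k_vectors.shape[0])},
                        origin_stride, zero_value=1.0)
    return res


# ---------------------------------------------------------------------------
# Scalar-series autocovariance
# ---------------------------------------------------------------------------

def series_acf(series: ScalarSeries, max_lag: int | None = None) -> CorrelationResult:
    """Stationary autocovariance ⟨σ(0)σ(t)⟩ (not mean-subtracted, not
    normalised), averaged over all time origins via FFT.
    """
    x = series.values
    n = x.size
    if max_lag is None:
        max_lag = n // 5
    if not max_lag < n / 5 + 1:
        raise ValueError("max_lag must be < series length / 5")
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    raw = np.fft.irfft(fx * np.conj(fx), nfft)[: max_lag + 1]
    counts = n - np.arange(max_lag + 1)
    acf = raw / counts
    # block error over 10 contiguous series segments
    nb = 10
    seg = np.array_split(x, nb)
    block_vals = np.full((nb, max_lag + 1), np.nan)
    for b, s in enumerate(seg):
        m = s.size
        if m <= max_lag:
            continue
        fb = np.fft.rfft(s, nfft)
        rb = np.fft.irfft(fb * np.conj(fb), nfft)[: max_lag + 1]
        block_vals[b] = rb / (m - np.arange(max_lag + 1))
    with np.errstate(invalid="ignore"):
        stderr = np.nanstd(block_vals, axis=0, ddof=1) / np.sqrt(
            np.sum(~np.isnan(block_vals[:, 0]))
        )
    return CorrelationResult(
        lags=np.arange(max_lag + 1) * series.sample_interval,
        values=acf, stderr=stderr, n_origins=counts,
        kind="stress_ACF", params={"label": series.label},
    )
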