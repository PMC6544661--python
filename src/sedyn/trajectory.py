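"""Trajectory data model and text-format I/O.

The pipeline's raw input is a rigid-molecule trajectory: per-frame molecular
centers (Å, wrapped into a cubic periodic box) plus per-molecule unit
quaternions giving each body's orientation.  The molecular axis used by the
orientation correlators (the dipole direction for water-like bodies) is a
fixed body-frame vector; laboratory-frame axes ``e_j(t)`` are always derived
from the quaternions, never stored.

Supported formats are the LAMMPS text dump dialect (``ITEM: TIMESTEP`` /
``BOX BOUNDS`` / ``ATOMS`` with quaternion columns) and an extended-XYZ
dialect whose comment line carries the box edge, frame time and column
layout.  Both round-trip losslessly at 17 significant digits.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RigidMoleculeTrajectory",
    "SiteTrajectory",
    "ScalarSeries",
    "TrajectoryFormatError",
    "TIP4P2005_SITES",
    "quat_multiply",
    "quat_rotate",
    "quat_from_rotvec",
    "random_unit_quaternions",
    "read_lammps_dump",
    "write_lammps_dump",
    "read_extended_xyz",
    "write_extended_xyz",
    "read_scalar_series",
    "write_scalar_series",
    "unwrap_periodic",
    "wrap_positions",
    "sites_from_rigid_body",
]


class TrajectoryFormatError(ValueError):
    """Raised for malformed trajectory files or inconsistent frames."""


# ---------------------------------------------------------------------------
# Quaternion helpers (scalar-first convention: q = (w, x, y, z))
# ---------------------------------------------------------------------------

def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product ``q1 ⊗ q2``, broadcasting over leading axes."""
    w1, x1, y1, z1 = np.moveaxis(q1, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(q2, -1, 0)
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vectors ``v`` by quaternions ``q`` (active rotation).

    ``q`` has shape (..., 4), ``v`` shape (..., 3) or (3,); broadcasting
    follows numpy rules on the leading axes.
    """
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    w = q[..., :1]
    u = q[..., 1:]
    # v' = v + 2 w (u × v) + 2 u × (u × v)
    uv = np.cross(u, np.broadcast_to(v, np.broadcast_shapes(u.shape, v.shape)))
    return v + 2.0 * (w * uv + np.cross(u, uv))


def quat_from_rotvec(rv: np.ndarray) -> np.ndarray:
    """Quaternion of the rotation with rotation vector ``rv`` (rad)."""
    rv = np.asarray(rv, dtype=float)
    angle = np.linalg.norm(rv, axis=-1, keepdims=True)
    half = 0.5 * angle
    # sinc-based small-angle-safe axis scaling
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(angle > 1e-12, np.sin(half) / np.where(angle > 0, angle, 1.0), 0.5)
    return np.concatenate([np.cos(half), scale * rv], axis=-1)


def random_unit_quaternions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotations as unit quaternions, shape (n, 4)."""
    q = rng.standard_normal((n, 4))
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RigidMoleculeTrajectory:
    """Per-frame centers and orientations of N rigid molecules.

    Parameters
    ----------
    centers : (n_frames, N, 3) float array, Å.  Wrapped into [0, box_edge)
        unless ``wrapped`` is False (e.g. after :func:`unwrap_periodic`).
    orientations : (n_frames, N, 4) unit quaternions, scalar first.
    box_edge : cubic periodic box edge, Å.
    frame_interval : time between consecutive frames, ps (> 0, uniform).
    dipole_axis : fixed body-frame unit vector from which the laboratory
        axis e_j(t) is derived.
    """

    centers: np.ndarray
    orientations: np.ndarray
    box_edge: float
    frame_interval: float
    dipole_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    wrapped: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        self.dipole_axis = np.asarray(self.dipole_axis, dtype=float)
        if self.centers.ndim != 3 or self.centers.shape[-1] != 3:
            raise ValueError("centers must have shape (n_frames, N, 3)")
        if self.orientations.shape != self.centers.shape[:2] + (4,):
            raise ValueError("orientations must have shape (n_frames, N, 4)")
        if self.n_molecules < 1:
            raise ValueError("need at least one molecule")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        if not self.box_edge > 0:
            raise ValueError("box_edge must be positive")
        norms = np.linalg.norm(self.orientations, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            worst = float(np.abs(norms - 1.0).max())
            raise ValueError(f"quaternions not unit-norm (worst deviation {worst:.2e})")
        # renormalise only clearly drifted entries so that already-normalised
        # values are a bit-exact fixpoint (lossless write/read/write cycles)
        drifted = np.abs(norms - 1.0) > 1e-13
        if np.any(drifted):
            self.orientations = self.orientations.copy()
            self.orientations[drifted] /= norms[drifted][..., None]
        if self.wrapped:
            if np.any(self.centers < 0) or np.any(self.centers >= self.box_edge):
                raise ValueError("wrapped centers must lie in [0, box_edge)")
        axis_norm = np.linalg.norm(self.dipole_axis)
        if not np.isclose(axis_norm, 1.0, atol=1e-9):
            raise ValueError("dipole_axis must be a unit vector")
        self.dipole_axis = self.dipole_axis / axis_norm

    @property
    def n_frames(self) -> int:
        return self.centers.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.centers.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def dipole_vectors(self) -> np.ndarray:
        """Laboratory-frame molecular axes e_j(t), shape (n_frames, N, 3)."""
        return quat_rotate(self.orientations, self.dipole_axis)


#: TIP4P/2005-style rigid three-site geometry, body frame, Å.  Oxygen at the
#: body origin, hydrogens in the x-z plane, dipole bisector along +z
#: (O-H = 0.9572 Å, H-O-H = 104.52°).
_R_OH = 0.9572
_HOH_DEG = 104.52
_half = np.deg2rad(_HOH_DEG) / 2.0
TIP4P2005_SITES = {
    "O": np.zeros(3),
    "H1": np.array([_R_OH * np.sin(_half), 0.0, _R_OH * np.cos(_half)]),
    "H2": np.array([-_R_OH * np.sin(_half), 0.0, _R_OH * np.cos(_half)]),
}


@dataclass
class SiteTrajectory:
    """Per-frame O, H1, H2 site positions derived from a rigid-body path."""

    O: np.ndarray  # (n_frames, N, 3), Å
    H1: np.ndarray
    H2: np.ndarray
    box_edge: float
    frame_interval: float

    @property
    def n_frames(self) -> int:
        return self.O.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.O.shape[1]


@dataclass
class ScalarSeries:
    """A uniformly sampled scalar time series (e.g. one shear-stress component)."""

    values: np.ndarray
    sample_interval: float  # ps
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 2:
            raise ValueError("series needs at least two samples")
        if not self.sample_interval > 0:
            raise ValueError("sample_interval must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.sample_interval


# ---------------------------------------------------------------------------
# Extended XYZ
# ---------------------------------------------------------------------------

_XYZ_COLUMNS = "id:x:y:z:qw:qx:qy:qz"


def write_extended_xyz(traj: RigidMoleculeTrajectory, path) -> None:
    """Write an extended-XYZ file; lossless at 17 significant digits."""
    ax = traj.dipole_axis
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            t = i * traj.frame_interval
            fh.write(f"{traj.n_molecules}\n")
            fh.write(
                f"box_edge={traj.box_edge:.17g} time={t:.17g} "
                f"dt={traj.frame_interval:.17g} "
                f"dipole_axis={ax[0]:.17g},{ax[1]:.17g},{ax[2]:.17g} "
                f"columns={_XYZ_COLUMNS}\n"
            )
            for j in range(traj.n_molecules):
                x, y, z = traj.centers[i, j]
                qw, qx, qy, qz = traj.orientations[i, j]
                fh.write(
                    f"{j + 1} {x:.17g} {y:.17g} {z:.17g} "
                    f"{qw:.17g} {qx:.17g} {qy:.17g} {qz:.17g}\n"
                )


def _parse_xyz_comment(line: str) -> dict:
    out = {}
    for tok in line.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v
    return out


def read_extended_xyz(path) -> RigidMoleculeTrajectory:
    """Read an extended-XYZ trajectory written by :func:`write_extended_xyz`."""
    centers, quats, times = [], [], []
    box_edge = None
    dipole_axis = np.array([0.0, 0.0, 1.0])
    dt_hint = None
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            meta = _parse_xyz_comment(fh.readline())
            if "box_edge" not in meta:
                raise TrajectoryFormatError("comment line lacks box_edge")
            cols = meta.get("columns", "")
            needed = {"qw", "qx", "qy", "qz"}
            have = set(cols.split(":"))
            if not needed <= have:
                raise TrajectoryFormatError(
                    f"missing orientation columns {sorted(needed - have)}; "
                    f"declared columns: {cols or '(none)'}"
                )
            box_edge = float(meta["box_edge"])
            times.append(float(meta.get("time", len(times))))
            if "dt" in meta:
                dt_hint = float(meta["dt"])
            if "dipole_axis" in meta:
                dipole_axis = np.array([float(v) for v in meta["dipole_axis"].split(",")])
            rows = np.array(
                [[float(v) for v in fh.readline().split()[1:]] for _ in range(n)]
            )
            centers.append(rows[:, :3])
            quats.append(rows[:, 3:7])
    if not centers:
        raise TrajectoryFormatError("empty file")
    counts = {c.shape[0] for c in centers}
    if len(counts) > 1:
        raise TrajectoryFormatError(f"inconsistent molecule counts across frames: {sorted(counts)}")
    if len(times) > 1:
        dts = np.diff(times)
        if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
            raise TrajectoryFormatError("non-uniform frame times are rejected")
        frame_interval = float(dts[0])
    else:
        frame_interval = dt_hint if dt_hint else 1.0
    return RigidMoleculeTrajectory(
        centers=np.array(centers),
        orientations=np.array(quats),
        box_edge=box_edge,
        frame_interval=frame_interval,
        dipole_axis=dipole_axis,
    )


# ---------------------------------------------------------------------------
# LAMMPS text dump
# ---------------------------------------------------------------------------

def write_lammps_dump(traj: RigidMoleculeTrajectory, path, timestep: float = 0.001) -> None:
    """Write the ITEM-based LAMMPS dump dialect.

    ``timestep`` is the MD timestep in ps used to convert frame times into
    integer step numbers (default 1 fs).
    """
    steps_per_frame = traj.frame_interval / timestep
    if abs(steps_per_frame - round(steps_per_frame)) > 1e-9:
        raise ValueError("frame_interval must be an integer multiple of timestep")
    steps_per_frame = round(steps_per_frame)
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{i * steps_per_frame}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{traj.n_molecules}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for _ in range(3):
                fh.write(f"0 {traj.box_edge:.17g}\n")
            fh.write("ITEM: ATOMS id x y z qw qx qy qz\n")
            for j in range(traj.n_molecules):
                x, y, z = traj.centers[i, j]
                qw, qx, qy, qz = traj.orientations[i, j]
                fh.write(
                    f"{j + 1} {x:.17g} {y:.17g} {z:.17g} "
                    f"{qw:.17g} {qx:.17g} {qy:.17g} {qz:.17g}\n"
                )


def read_lammps_dump(
    path,
    timestep: float = 0.001,
    dipole_axis: Sequence[float] = (0.0, 0.0, 1.0),
) -> RigidMoleculeTrajectory:
    """Read a LAMMPS text dump with per-molecule quaternion columns.

    ``timestep`` (ps per MD step, default 1 fs) converts TIMESTEP numbers to
    frame times.  Frames must be uniformly spaced with a constant molecule
    count; non-orthorhombic (triclinic-tilted) boxes and non-cubic boxes are
    rejected because the whole pipeline assumes a cubic periodic cell.
    """
    frames_c, frames_q, steps = [], [], []
    box_edge = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_idx = 0
    n_expected = None
    while i < len(lines):
        if not lines[i].startswith("ITEM: TIMESTEP"):
            if lines[i].strip() == "":
                i += 1
                continue
            raise TrajectoryFormatError(f"expected ITEM: TIMESTEP at line {i + 1}")
        steps.append(int(lines[i + 1]))
        if not lines[i + 2].startswith("ITEM: NUMBER OF ATOMS"):
            raise TrajectoryFormatError("expected ITEM: NUMBER OF ATOMS")
        n = int(lines[i + 3])
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise TrajectoryFormatError(
                f"frame {frame_idx} has {n} molecules, expected {n_expected}"
            )
        bounds_header = lines[i + 4]
        if not bounds_header.startswith("ITEM: BOX BOUNDS"):
            raise TrajectoryFormatError("expected ITEM: BOX BOUNDS")
        if any(t in bounds_header for t in ("xy", "xz", "yz")):
            raise TrajectoryFormatError("non-orthorhombic (triclinic) box is not supported")
        edges = []
        origin = []
        for d in range(3):
            lo, hi = (float(v) for v in lines[i + 5 + d].split()[:2])
            edges.append(hi - lo)
            origin.append(lo)
        if not np.allclose(edges, edges[0], rtol=1e-9):
            raise TrajectoryFormatError("non-cubic box is not supported")
        box_edge = edges[0]
        atoms_header = lines[i + 8]
        if not atoms_header.startswith("ITEM: ATOMS"):
            raise TrajectoryFormatError("expected ITEM: ATOMS")
        cols = atoms_header.split()[2:]
        needed = ["x", "y", "z", "qw", "qx", "qy", "qz"]
        missing = [c for c in needed if c not in cols]
        if missing:
            raise TrajectoryFormatError(f"dump lacks columns {missing}; has {cols}")
        idx = {c: cols.index(c) for c in needed + (["id"] if "id" in cols else [])}
        block = lines[i + 9 : i + 9 + n]
        if len(block) < n or any(b.startswith("ITEM:") for b in block):
            raise TrajectoryFormatError(
                f"frame {frame_idx} declares {n} molecules but fewer atom lines follow"
            )
        rows = np.array([[float(v) for v in b.split()] for b in block])
        order = np.argsort(rows[:, idx["id"]]) if "id" in idx else np.arange(n)
        rows = rows[order]
        xyz = rows[:, [idx["x"], idx["y"], idx["z"]]] - np.array(origin)
        frames_c.append(xyz)
        frames_q.append(rows[:, [idx["qw"], idx["qx"], idx["qy"], idx["qz"]]])
        i += 9 + n
        frame_idx += 1
    if not frames_c:
        raise TrajectoryFormatError("empty dump file")
    if len(steps) > 1:
        dsteps = np.diff(steps)
        if np.any(dsteps <= 0) or np.any(dsteps != dsteps[0]):
            raise TrajectoryFormatError("frames must be uniformly spaced in ascending time")
        frame_interval = dsteps[0] * timestep
    else:
        frame_interval = timestep
    return RigidMoleculeTrajectory(
        centers=np.array(frames_c),
        orientations=np.array(frames_q),
        box_edge=box_edge,
        frame_interval=frame_interval,
        dipole_axis=np.asarray(dipole_axis, dtype=float),
    )


# ---------------------------------------------------------------------------
# Scalar series I/O (plain two-column text: time value)
# ---------------------------------------------------------------------------

def write_scalar_series(series: ScalarSeries, path) -> None:
    with open(path, "w") as fh:
        if series.label:
            fh.write(f"# {series.label}\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.17g} {v:.17g}\n")


def read_scalar_series(path, label: str = "") -> ScalarSeries:
    times, values = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                if line.startswith("#") and not label:
                    label = line[1:].strip()
                continue
            t, v = line.split()[:2]
            times.append(float(t))
            values.append(float(v))
    times = np.asarray(times)
    if times.size < 2:
        raise TrajectoryFormatError("series needs at least two samples")
    dts = np.diff(times)
    if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
        raise TrajectoryFormatError("non-uniform sample times are rejected")
    return ScalarSeries(values=np.asarray(values), sample_interval=float(dts[0]), label=label)


# ---------------------------------------------------------------------------
# Periodic unwrapping and rigid-body sites
# ---------------------------------------------------------------------------

def wrap_positions(positions: np.ndarray, box_edge: float) -> np.ndarray:
    """Reduce positions into the primary cell [0, box_edge)."""
    return np.mod(positions, box_edge)


def unwrap_periodic(traj: RigidMoleculeTrajectory) -> RigidMoleculeTrajectory:
    """Remove periodic jumps from the center paths (minimum-image unwrap).

    Valid only when every single-frame displacement is below half the box
    edge; a larger jump means the frame spacing is too coarse to decide the
    image and raises ``ValueError`` naming molecule and frame.
    """
    L = traj.box_edge
    diffs = np.diff(traj.centers, axis=0)
    shifted = diffs - L * np.round(diffs / L)
    bad = np.abs(shifted) >= L / 2.0 - 1e-12
    # exactly L/2 jumps are ambiguous; np.round already maps |d|<L/2 correctly
    if np.any(np.abs(np.abs(shifted) - L / 2.0) < 1e-12):
        frame, mol, _ = np.argwhere(np.abs(np.abs(shifted) - L / 2.0) < 1e-12)[0]
        raise ValueError(
            f"molecule {mol} jumps by >= box_edge/2 between frames {frame} and "
            f"{frame + 1}; frame spacing too coarse for minimum-image unwrapping"
        )
    del bad
    unwrapped = np.concatenate(
        [traj.centers[:1], traj.centers[:1] + np.cumsum(shifted, axis=0)], axis=0
    )
    return dataclasses.replace(traj, centers=unwrapped, wrapped=False)


def sites_from_rigid_body(
    traj: RigidMoleculeTrajectory, geometry: dict | None = None
) -> SiteTrajectory:
    """Mount body-frame site coordinates on every molecule at every frame.

    ``geometry`` maps site names O/H1/H2 to body-frame positions (Å);
    defaults to the TIP4P/2005 three-site geometry.
    """
    geo = geometry if geometry is not None else TIP4P2005_SITES
    out = {}
    for name in ("O", "H1", "H2"):
        body = np.asarray(geo[name], dtype=float)
        out[name] = traj.centers + quat_rotate(traj.orientations, body)
    return SiteTrajectory(
        O=out["O"], H1=out["H1"], H2=out["H2"],
        box_edge=traj.box_edge, frame_interval=traj.frame_interval,
    )
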