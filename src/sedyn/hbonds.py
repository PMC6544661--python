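"""Geometric hydrogen-bond detection and lifetime kinetics.

A donor→acceptor pair (j→k) is bonded when the O_j–O_k minimum-image
distance is below ``r_oo_max`` and the H–O_j···O_k angle (at the donor
oxygen, for either of the two donor hydrogens) is below ``angle_max`` —
the standard geometric criterion (defaults 3.5 Å, 30°).  Both cutoffs are
explicit configuration, not constants.

The intermittent hydrogen-bond correlation

    c(t) = ⟨h(t₀) h(t₀+t)⟩ / ⟨h⟩

(h = 1 while a pair satisfies the criterion, regardless of intermediate
breaks) characterises irreversible bond breakage; its decay time is the
hydrogen-bond lifetime τ_HB.  A continuous-lifetime variant (a pair dies
at its first break) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlations import CorrelationResult
from .transport import kww_fit
from .trajectory import SiteTrajectory

__all__ = [
    "HBCriterion",
    "HBondSeries",
    "detect_hbonds",
    "hbond_indicator_series",
    "hbond_correlation",
    "tau_hb",
]


@dataclass
class HBCriterion:
    """Geometric hydrogen-bond criterion."""

    r_oo_max: float = 3.5  # Å
    angle_max: float = 30.0  # degrees, H-O(donor)...O(acceptor)

    def __post_init__(self) -> None:
        if not self.r_oo_max > 0:
            raise ValueError("r_oo_max must be positive")
        if not 0 < self.angle_max < 90:
            raise ValueError("angle_max must be in (0, 90) degrees")


@dataclass
class HBondSeries:
    """Bonded donor→acceptor pairs per frame, plus a dense indicator.

    ``pairs`` lists every ordered pair bonded in at least one frame;
    ``indicator[t, p]`` is True when ``pairs[p]`` is bonded at frame t.
    """

    pairs: np.ndarray  # (n_pairs, 2) int
    indicator: np.ndarray  # (n_frames, n_pairs) bool
    frame_interval: float
    criterion: HBCriterion = field(default_factory=HBCriterion)

    @property
    def n_frames(self) -> int:
        return self.indicator.shape[0]


def _min_image(d: np.ndarray, L: float) -> np.ndarray:
    return d - L * np.round(d / L)


def detect_hbonds(sites: SiteTrajectory, frame: int,
                  criterion: HBCriterion | None = None) -> set[tuple[int, int]]:
    """Bonded ordered (donor, acceptor) pairs at one frame."""
    crit = criterion or HBCriterion()
    L = sites.box_edge
    O = sites.O[frame]
    N = O.shape[0]
    d = _min_image(O[:, None, :] - O[None, :, :], L)  # O_j - O_k
    r = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(r, np.inf)
    close = r <= crit.r_oo_max
    bonded: set[tuple[int, int]] = set()
    cos_max = np.cos(np.deg2rad(crit.angle_max))
    for H in (sites.H1[frame], sites.H2[frame]):
        oh = _min_image(H - O, L)  # O_j -> H_j
        oh_unit = oh / np.linalg.norm(oh, axis=-1, keepdims=True)
        for j, k in zip(*np.nonzero(close)):
            oo = -d[j, k]  # O_j -> O_k, minimum image
            cosang = float(oh_unit[j] @ oo) / r[j, k]
            if cosang >= cos_max:
                bonded.add((int(j), int(k)))
    return bonded


def hbond_indicator_series(sites: SiteTrajectory,
                           criterion: HBCriterion | None = None,
                           frame_stride: int = 1) -> HBondSeries:
    """Scan the trajectory and build the dense bond-indicator matrix."""
    crit = criterion or HBCriterion()
    frames = range(0, sites.n_frames, frame_stride)
    per_frame = [detect_hbonds(sites, f, crit) for f in frames]
    all_pairs = sorted(set().union(*per_frame)) if per_frame else []
    if not all_pairs:
        raise ValueError("no hydrogen bonds detected in any frame")
    index = {p: i for i, p in enumerate(all_pairs)}
    ind = np.zeros((len(per_frame), len(all_pairs)), dtype=bool)
    for t, bonds in enumerate(per_frame):
        for p in bonds:
            ind[t, index[p]] = True
    return HBondSeries(
        pairs=np.array(all_pairs, dtype=int), indicator=ind,
        frame_interval=sites.frame_interval * frame_stride, criterion=crit,
    )


def hbond_correlation(series: HBondSeries, lag_grid: np.ndarray | None = None,
                      origin_stride: int = 1,
                      continuous: bool = False) -> CorrelationResult:
    """Hydrogen-bond correlation c(t) = ⟨h(t₀)h(t₀+t)⟩/⟨h⟩.

    The default is the intermittent correlation (bonds may break and
    reform); with ``continuous=True`` a pair's indicator is cut at its
    first break after each origin (continuous-lifetime convention).
    """
    h = series.indicator.astype(float)
    n_frames, _n_pairs = h.shape
    if h.sum() == 0:
        raise ValueError("no bonds present at any origin")
    from .correlations import default_lag_grid, _lags_to_frames

    if lag_grid is None:
        lag_grid = default_lag_grid(n_frames, series.frame_interval)
    lag_frames = _lags_to_frames(lag_grid, series.frame_interval)
    vals, errs, nor = [], [], []
    for lag in lag_frames:
        origins = np.arange(0, n_frames - lag, origin_stride)
        h0 = h[origins]
        norm = h0.sum(axis=1)
        if continuous and lag > 0:
            # a pair contributes only while unbroken since the origin
            surv = h0.astype(bool)
            for step in range(1, lag + 1):
                surv = surv & series.indicator[origins + step]
            prod = surv.sum(axis=1)
        else:
            ht = h[origins + lag]
            prod = (h0 * ht).sum(axis=1)
        if norm.sum() == 0:
            raise ValueError(f"no bonds at any origin for lag {lag}")
        # pooled ratio over pairs and origins: <h(0)h(t)> / <h>
        vals.append(float(prod.sum() / norm.sum()))
        # block error: pooled ratio within contiguous origin blocks
        nb = min(10, origins.size)
        if nb >= 2:
            bp = [b for b in zip(np.array_split(prod, nb), np.array_split(norm, nb))]
            ratios = np.array([p.sum() / w.sum() for p, w in bp if w.sum() > 0])
            errs.append(float(ratios.std(ddof=1) / np.sqrt(ratios.size))
                        if ratios.size >= 2 else np.nan)
        else:
            errs.append(np.nan)
        nor.append(int((norm > 0).sum()))
    return CorrelationResult(
        lags=lag_frames * series.frame_interval,
        values=np.array(vals), stderr=np.array(errs), n_origins=np.array(nor),
        kind="hbond_c",
        params={"continuous": continuous,
                "r_oo_max": series.criterion.r_oo_max,
                "angle_max": series.criterion.angle_max},
    )


def tau_hb(c_result: CorrelationResult, method: str = "fit") -> float:
    """Hydrogen-bond lifetime from c(t).

    ``method='fit'`` (default): KWW/exponential fit of the decaying part,
    τ_HB = fitted τ.  ``method='crossing'``: e⁻¹ crossing time.  Raises on
    a non-decaying correlation.
    """
    values = c_result.values
    if values.min() > np.exp(-1.0) and method == "crossing":
        raise ValueError("c(t) does not decay below 1/e")
    if np.all(np.diff(values) >= -1e-12) and values[-1] >= values[0] - 1e-12:
        raise ValueError("hydrogen-bond correlation does not decay")
    if method == "fit":
        # fit from the first nonzero lag; c(t) has no libration transient
        lags = c_result.lags
        t0 = lags[lags > 0][0]
        return kww_fit(c_result, fit_window=(t0, float(lags[-1]))).tau
    if method == "crossing":
        from .transport import tau_alpha

        return tau_alpha(c_result, method="crossing")
    raise ValueError(f"unknown method {method!r}")
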