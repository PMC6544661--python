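"""Transport coefficients and relaxation times from correlators.

This module turns :class:`~sedyn.correlations.CorrelationResult` objects
into the scalar quantities of the SE/SED analysis:

* D_t and D_r from long-time MSD slopes (divisors 6 and 4),
* D_r from the Green–Kubo integral ∫C_Ω dt,
* shear viscosity η = [V/(k_B T)]·∫⟨σ(0)σ(t)⟩dt,
* rotational relaxation times τ_ℓ by stretched-exponential (KWW) fits,
* the α-relaxation time from F_s(k,t),
* Debye-model diagnostics D_r·τ_ℓ·ℓ(ℓ+1) and the characteristic
  reorientation angle of each Legendre order (first zero of P_ℓ(cos θ)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq, curve_fit
from scipy.special import eval_legendre, gamma as gamma_fn

from .correlations import CorrelationResult
from .units import KB

__all__ = [
    "KWWFit",
    "TransportRecord",
    "PlateauError",
    "fit_diffusion",
    "rotational_diffusion_gk",
    "green_kubo_viscosity",
    "gk_integral",
    "kww_fit",
    "tau_alpha",
    "debye_product",
    "legendre_first_zero_angle",
]


class PlateauError(RuntimeError):
    """No plateau found in a running Green–Kubo integral.

    Carries the running-integral trace in ``lags`` / ``running_integral``.
    """

    def __init__(self, message: str, lags: np.ndarray, running_integral: np.ndarray):
        super().__init__(message)
        self.lags = lags
        self.running_integral = running_integral


@dataclass
class KWWFit:
    """Stretched-exponential fit A·exp(−(t/τ)^β) of a correlator."""

    A: float
    tau: float
    beta: float
    fit_window: tuple[float, float]
    residual_rms: float
    covariance: np.ndarray

    def __post_init__(self) -> None:
        if not 0 < self.beta <= 2:
            raise ValueError("beta must be in (0, 2]")
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if not 0 < self.A <= 1.05:
            raise ValueError("A must be in (0, 1.05]")

    @property
    def integrated_time(self) -> float:
        """∫A·exp(−(t/τ)^β)dt = A·(τ/β)·Γ(1/β)."""
        return self.A * self.tau / self.beta * gamma_fn(1.0 / self.beta)

    def __call__(self, t) -> np.ndarray:
        return self.A * np.exp(-((np.asarray(t, dtype=float) / self.tau) ** self.beta))


@dataclass
class TransportRecord:
    """One state point's transport/relaxation bundle feeding the SED ratios."""

    T: float  # K
    volume: float | None = None  # Å³
    eta: float | None = None  # internal viscosity units
    D_t: float | None = None  # Å²/ps
    D_r_msd: float | None = None  # rad²/ps
    D_r_gk: float | None = None
    tau_ell: dict[int, float] = field(default_factory=dict)
    tau_alpha: float | None = None
    tau_hb: float | None = None
    tau_t: float | None = None
    tau_r: float | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def D_r(self) -> float | None:
        """Preferred rotational diffusivity: angular-MSD route, else GK."""
        return self.D_r_msd if self.D_r_msd is not None else self.D_r_gk


# ---------------------------------------------------------------------------
# Diffusion from MSD slopes
# ---------------------------------------------------------------------------

def _auto_window(lags: np.ndarray, values: np.ndarray,
                 slope_band: tuple[float, float] = (0.95, 1.05),
                 min_points: int = 8) -> tuple[float, float]:
    """Longest contiguous lag range whose local log-log slope stays in band.

    Mirrors the "long-time diffusive limit": on log(MSD) vs log(t), the
    diffusive regime has slope 1.  Warns when the best window spans less
    than a decade.
    """
    pos = (lags > 0) & (values > 0)
    t, y = lags[pos], values[pos]
    if t.size < min_points:
        raise ValueError("not enough positive points for window auto-selection")
    logt, logy = np.log(t), np.log(y)
    # centred local slope, lightly smoothed over 3 points
    slope = np.gradient(logy, logt)
    slope = np.convolve(slope, np.ones(3) / 3.0, mode="same")
    ok = (slope >= slope_band[0]) & (slope <= slope_band[1])
    best = (0, 0)
    i = 0
    while i < ok.size:
        if ok[i]:
            j = i
            while j < ok.size and ok[j]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    if best[1] - best[0] < min_points:
        raise ValueError("no diffusive window found (log-log slope never near 1)")
    t_min, t_max = t[best[0]], t[best[1] - 1]
    if t_max / t_min < 10.0:
        warnings.warn("diffusive window spans less than one decade", stacklevel=3)
    return float(t_min), float(t_max)


def fit_diffusion(result: CorrelationResult, divisor: float = 6.0,
                  window: tuple[float, float] | None = None) -> tuple[float, float]:
    """Diffusion constant from an MSD: weighted LS slope over the window,
    divided by ``divisor`` (6 for 3-D translation, 4 for the two-axis
    angular MSD).  Returns ``(D, stderr)``.

    When ``window`` is None the diffusive regime is auto-selected as the
    longest contiguous range with local log-log slope in [0.95, 1.05].
    """
    lags, values = result.lags, result.values
    if window is None:
        window = _auto_window(lags, values)
    sel = (lags >= window[0]) & (lags <= window[1]) & (lags > 0)
    if sel.sum() < 8:
        raise ValueError(f"need >= 8 lag points inside window {window}, have {int(sel.sum())}")
    t, y = lags[sel], values[sel]
    # local slope sanity check over the chosen window
    slope_loc = np.gradient(np.log(np.maximum(y, 1e-300)), np.log(t))
    if np.any((slope_loc < 0.9) | (slope_loc > 1.1)):
        warnings.warn(
            "local log-log slope leaves [0.9, 1.1] inside the fit window", stacklevel=2
        )
    w = result.stderr[sel]
    w = np.where(np.isfinite(w) & (w > 0), w, np.nan)
    if np.all(np.isfinite(w)):
        sigma = w
    else:
        sigma = np.ones_like(y)
    # straight line y = a + b t by weighted least squares
    W = 1.0 / sigma**2
    Sw, Swt, Swt2 = W.sum(), (W * t).sum(), (W * t * t).sum()
    Swy, Swty = (W * y).sum(), (W * t * y).sum()
    det = Sw * Swt2 - Swt**2
    b = (Sw * Swty - Swt * Swy) / det
    var_b = Sw / det
    if not np.all(np.isfinite(result.stderr[sel])) or np.any(result.stderr[sel] <= 0):
        # unweighted fit: scale parameter variance by residual chi^2
        a = (Swt2 * Swy - Swt * Swty) / det
        resid = y - (a + b * t)
        dof = max(t.size - 2, 1)
        var_b *= (resid**2).sum() / dof
    return float(b / divisor), float(np.sqrt(var_b) / divisor)


# ---------------------------------------------------------------------------
# Green–Kubo integrals with plateau detection
# ---------------------------------------------------------------------------

def gk_integral(result: CorrelationResult, rtol: float = 0.01) -> tuple[float, float, dict]:
    """Integrate an ACF to its plateau.  Returns (integral, stderr, diagnostics).

    The running trapezoidal integral I(t) is scanned for the earliest lag
    t_c at which I stays flat over [t_c, min(10·t_c, t_end)] — "flat"
    meaning a drift below max(rtol·|I|, 3·σ_drift), where σ_drift is the
    statistical drift scale propagated from the ACF standard errors (a
    strict relative band alone would reject valid plateaus of noisy input).
    The reported value is the mean of I over the plateau window.
    """
    lags, acf = result.lags, result.values
    if lags[0] != 0:
        raise ValueError("ACF must start at lag 0")
    I = cumulative_trapezoid(acf, lags, initial=0.0)
    scale = np.max(np.abs(I))
    if scale < 1e-300 or abs(acf[0]) < 1e-300:
        return 0.0, 0.0, {"cutoff": float(lags[-1]), "plateau_window": (0.0, float(lags[-1]))}
    # decay sanity: ACF magnitude at the end should be small vs its start
    stderr = np.where(np.isfinite(result.stderr), result.stderr, 0.0)
    n = lags.size
    for i in range(1, n - 1):
        t_c = lags[i]
        # local integral correlation time for noise propagation
        tau_int = max(abs(I[i]) / abs(acf[0]), lags[1] - lags[0])
        t_hi = min(10.0 * t_c, lags[-1])
        if t_hi < 2.0 * t_c:
            break
        win = (lags >= t_c) & (lags <= t_hi)
        if win.sum() < 3:
            continue
        drift = I[win].max() - I[win].min()
        span = t_hi - t_c
        sigma_drift = float(np.mean(stderr[win])) * np.sqrt(2.0 * tau_int * span)
        tol = max(rtol * abs(I[i]), 3.0 * sigma_drift)
        if drift <= tol and tol > 0:
            value = float(I[win].mean())
            se = float(max(sigma_drift, drift / np.sqrt(12.0)))
            diag = {
                "cutoff": float(t_c),
                "plateau_window": (float(t_c), float(t_hi)),
                "drift": float(drift),
                "tolerance": float(tol),
            }
            return value, se, diag
    raise PlateauError(
        "no plateau found in the running Green-Kubo integral; extend the ACF "
        "or inspect the attached running-integral trace",
        lags, I,
    )


def rotational_diffusion_gk(c_omega: CorrelationResult) -> tuple[float, float]:
    """D_r = ∫C_Ω(t)dt (Green–Kubo route).  Returns (D_r, stderr).

    Requires the ACF to have decayed into its noise band by the end of the
    grid (otherwise the integral has not converged).
    """
    end_se = c_omega.stderr[-1] if np.isfinite(c_omega.stderr[-1]) else 0.0
    if abs(c_omega.values[-1]) > max(3.0 * end_se, 1e-12 * abs(c_omega.values[0])):
        raise ValueError("C_Omega has not decayed to within 3 SE of zero at the grid end")
    D, se, _ = gk_integral(c_omega)
    return D, se


def green_kubo_viscosity(stress_acfs: CorrelationResult | list[CorrelationResult],
                         volume: float, T: float) -> tuple[float, float, dict]:
    """Shear viscosity η = [V/(k_B T)]·∫⟨σ(0)σ(t)⟩dt.

    Accepts a single off-diagonal stress-component ACF or a list of
    component ACFs, which are averaged before integration (the standard
    multi-component Green–Kubo estimator).  Returns (η, stderr,
    diagnostics); internal viscosity units (amu Å⁻¹ ps⁻¹).
    """
    if not (volume > 0 and T > 0):
        raise ValueError("volume and T must be positive")
    if isinstance(stress_acfs, CorrelationResult):
        acf = stress_acfs
        nc = 1
    else:
        nc = len(stress_acfs)
        lags = stress_acfs[0].lags
        stack = np.array([a.values for a in stress_acfs])
        errs = np.array([a.stderr for a in stress_acfs])
        acf = CorrelationResult(
            lags=lags, values=stack.mean(axis=0),
            stderr=np.sqrt(np.nansum(errs**2, axis=0)) / nc,
            n_origins=stress_acfs[0].n_origins, kind="stress_ACF",
            params={"n_components": nc},
        )
    integral, se, diag = gk_integral(acf)
    pref = volume / (KB * T)
    diag["n_components"] = nc
    return pref * integral, pref * se, diag


# ---------------------------------------------------------------------------
# KWW fits and relaxation times
# ---------------------------------------------------------------------------

def _kww(t, A, tau, beta):
    return A * np.exp(-((t / tau) ** beta))


def kww_fit(result: CorrelationResult,
            fit_window: tuple[float, float] | None = None,
            t_min_factor: float = 10.0) -> KWWFit:
    """Fit A·exp(−(t/τ)^β) to a decaying correlator.

    The default window starts at ``t_min_factor`` × the first nonzero lag
    (excluding the libration-like early transient) and ends at the last lag.
    A is free in (0, 1.05] to absorb a fast initial drop.  Flags (warns) an
    extrapolation when the correlator never decays below 0.1 inside the
    window.  Several deterministic restarts are attempted before giving up.
    """
    lags, values = result.lags, result.values
    if fit_window is None:
        t0 = lags[lags > 0][0]
        fit_window = (t_min_factor * t0, float(lags[-1]))
    sel = (lags >= fit_window[0]) & (lags <= fit_window[1]) & (lags > 0)
    t, y = lags[sel], values[sel]
    if t.size < 4:
        raise ValueError("fewer than 4 points in the KWW fit window")
    if y.min() > 0.1:
        warnings.warn(
            "correlator does not decay below 0.1 in the fit window; "
            "tau is an extrapolation", stacklevel=2,
        )
    # crude tau guess: e^-1 crossing by interpolation
    below = np.nonzero(y < np.exp(-1.0) * max(y[0], 1e-12))[0]
    tau0 = t[below[0]] if below.size else t[-1]
    guesses = [(min(1.0, max(y[0], 0.1)), tau0, 1.0),
               (1.0, tau0, 0.7),
               (0.8, 2.0 * tau0, 1.0),
               (1.0, 0.5 * tau0, 1.3)]
    sigma = result.stderr[sel]
    use_sigma = np.all(np.isfinite(sigma)) and np.all(sigma > 0)
    last_err: Exception | None = None
    for g in guesses:
        try:
            popt, pcov = curve_fit(
                _kww, t, y, p0=g,
                sigma=sigma if use_sigma else None,
                bounds=([1e-12, 1e-12, 0.05], [1.05, np.inf, 2.0]),
                maxfev=20000,
            )
            resid = y - _kww(t, *popt)
            return KWWFit(
                A=float(popt[0]), tau=float(popt[1]), beta=float(popt[2]),
                fit_window=(float(fit_window[0]), float(fit_window[1])),
                residual_rms=float(np.sqrt((resid**2).mean())),
                covariance=pcov,
            )
        except (RuntimeError, ValueError) as err:  # non-convergence; try next start
            last_err = err
    raise RuntimeError(f"KWW fit failed after {len(guesses)} restarts: {last_err}")


def tau_alpha(f_s: CorrelationResult, method: str = "kww",
              fit_window: tuple[float, float] | None = None) -> float:
    """α-relaxation time from F_s(k,t).

    ``method='kww'`` (default): fitted KWW τ.  ``method='crossing'``: time
    of the e⁻¹ crossing by log-linear interpolation.  Requires F_s to decay
    below 1/e within the grid.
    """
    lags, values = f_s.lags, f_s.values
    target = np.exp(-1.0)
    below = np.nonzero(values < target)[0]
    if below.size == 0:
        raise ValueError("F_s does not decay below 1/e on the lag grid")
    if method == "kww":
        return kww_fit(f_s, fit_window=fit_window).tau
    if method == "crossing":
        i = below[0]
        if i == 0:
            return float(lags[0])
        t1, t2 = lags[i - 1], lags[i]
        v1, v2 = values[i - 1], values[i]
        # interpolate on log(value)
        lv1, lv2 = np.log(max(v1, 1e-300)), np.log(max(v2, 1e-300))
        frac = (np.log(target) - lv1) / (lv2 - lv1)
        return float(t1 + frac * (t2 - t1))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Debye diagnostics
# ---------------------------------------------------------------------------

def debye_product(D_r: float, tau_ell: float, order: int) -> float:
    """D_r·τ_ℓ·ℓ(ℓ+1); equals 1 exactly when the Debye model holds."""
    if not (D_r > 0 and tau_ell > 0):
        raise ValueError("inputs must be positive")
    return D_r * tau_ell * order * (order + 1)


def legendre_first_zero_angle(order: int) -> float:
    """Smallest θ ∈ (0, π) with P_ℓ(cos θ) = 0 (bracketed root, 1e−10).

    This is the characteristic reorientation angle probed by the ℓ-th
    orientation correlator (π/2 for ℓ = 1, ≈0.37 rad for ℓ = 6).
    """
    if order < 1:
        raise ValueError("order must be >= 1")

    def f(theta):
        return eval_legendre(order, np.cos(theta))

    # first zero of P_l(cos(theta)) corresponds to the largest root of P_l(x)
    thetas = np.linspace(1e-9, np.pi - 1e-9, 4096)
    vals = f(thetas)
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        raise RuntimeError("no sign change found")
    i = sign_change[0]
    return float(brentq(f, thetas[i], thetas[i + 1], xtol=1e-12, rtol=8.9e-16))
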