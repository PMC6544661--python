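"""Stokes–Einstein / Stokes–Einstein–Debye diagnostics.

The SE relation D_t = k_B T/(6πηR) and the Debye rotational analogue
D_r = k_B T/(8πηR³) combine into the SED relations

    τ_ℓ k_B T / η = 8πR³ / [ℓ(ℓ+1)]          (viscosity form)
    D_t τ_ℓ      = 4R² / [3ℓ(ℓ+1)]           (diffusion form)

Inverting them on measured transport coefficients gives the hydrodynamic
radii R_t and R_r; comparing the temperature dependence of the ratio
families (D_t η/(k_B T), τ_ℓ k_B T/η, D_t τ_ℓ, D_r/D_t, D_r τ_ℓ ℓ(ℓ+1),
D_t τ_HB) — each scaled by its value at a reference state point — is the
standard way to diagnose SE/SED violation and translational–rotational
decoupling.  Fractional relations y ∝ x^ζ are quantified by a log-log
least-squares exponent with a bootstrap confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transport import TransportRecord
from .units import AVOGADRO, KB, WATER_MOLAR_MASS

__all__ = [
    "SEDReport",
    "hydrodynamic_radius_translational",
    "hydrodynamic_radius_rotational",
    "sed_ratio_table",
    "power_law_exponent",
    "water_box_edge",
]


def hydrodynamic_radius_translational(D_t: float, eta: float, T: float) -> float:
    """R_t = k_B T / (6 π η D_t), Å (internal units throughout)."""
    if not (D_t > 0 and eta > 0 and T > 0):
        raise ValueError("D_t, eta, T must be positive")
    return KB * T / (6.0 * np.pi * eta * D_t)


def hydrodynamic_radius_rotational(D_r: float, eta: float, T: float) -> float:
    """R_r = [k_B T / (8 π η D_r)]^(1/3), Å."""
    if not (D_r > 0 and eta > 0 and T > 0):
        raise ValueError("D_r, eta, T must be positive")
    return (KB * T / (8.0 * np.pi * eta * D_r)) ** (1.0 / 3.0)


@dataclass
class SEDReport:
    """Per-state-point SED diagnostics with reference-scaled columns."""

    table: pd.DataFrame
    reference_T: float
    orders: tuple[int, ...] = (1, 2, 3, 6)
    scaled_suffix: str = "_scaled"

    def scaled(self, column: str) -> pd.Series:
        return self.table[column + self.scaled_suffix]


def _record_row(rec: TransportRecord, orders) -> dict:
    row: dict[str, float | None] = {
        "T": rec.T, "eta": rec.eta, "D_t": rec.D_t,
        "D_r": rec.D_r, "tau_alpha": rec.tau_alpha, "tau_hb": rec.tau_hb,
    }
    eta, T, D_t, D_r = rec.eta, rec.T, rec.D_t, rec.D_r
    row["R_t"] = (hydrodynamic_radius_translational(D_t, eta, T)
                  if D_t and eta else None)
    row["R_r"] = (hydrodynamic_radius_rotational(D_r, eta, T)
                  if D_r and eta else None)
    row["D_t_eta_over_kBT"] = D_t * eta / (KB * T) if D_t and eta else None
    row["D_r_eta_over_kBT"] = D_r * eta / (KB * T) if D_r and eta else None
    row["D_r_over_D_t"] = D_r / D_t if D_r and D_t else None
    row["D_t_over_D_r"] = D_t / D_r if D_r and D_t else None
    row["D_t_tau_hb"] = D_t * rec.tau_hb if D_t and rec.tau_hb else None
    row["D_t_tau_alpha"] = D_t * rec.tau_alpha if D_t and rec.tau_alpha else None
    for ell in orders:
        tau = rec.tau_ell.get(ell)
        row[f"tau_{ell}"] = tau
        row[f"tau_{ell}_kBT_over_eta"] = tau * KB * T / eta if tau and eta else None
        row[f"eta_over_tau_{ell}_T"] = eta / (tau * T) if tau and eta else None
        row[f"D_t_tau_{ell}"] = D_t * tau if tau and D_t else None
        row[f"debye_product_{ell}"] = (D_r * tau * ell * (ell + 1)
                                       if tau and D_r else None)
    return row


def sed_ratio_table(records: list[TransportRecord],
                    reference_T: float | None = None,
                    orders: tuple[int, ...] = (1, 2, 3, 6)) -> SEDReport:
    """Assemble all SE/SED ratio families and their reference-scaled columns.

    ``reference_T`` defaults to the highest temperature present; every
    ratio column gains a ``_scaled`` twin divided by its value at the
    reference row (exactly 1 there).  Missing inputs yield null cells,
    never silent drops.
    """
    if not records:
        raise ValueError("no records given")
    rows = [_record_row(r, orders) for r in records]
    df = pd.DataFrame(rows).astype(float)
    temps = df["T"].to_numpy()
    if reference_T is None:
        reference_T = float(np.max(temps))
    ref_idx = np.nonzero(np.isclose(temps, reference_T))[0]
    if ref_idx.size == 0:
        raise ValueError(f"reference temperature {reference_T} K not among records")
    ref = df.iloc[ref_idx[0]]
    ratio_cols = [c for c in df.columns if any(
        c.startswith(p) for p in (
            "R_", "D_t_", "D_r_", "eta_over_", "debye_product_",
        )
    ) or c.endswith("_kBT_over_eta")]
    for c in ratio_cols:
        df[c + "_scaled"] = df[c] / ref[c] if pd.notna(ref[c]) else np.nan
    return SEDReport(table=df, reference_T=reference_T, orders=tuple(orders))


def power_law_exponent(x, y, n_boot: int = 1000,
                       seed: int = 0) -> tuple[float, tuple[float, float]]:
    """Exponent ζ of y ∝ x^ζ by least squares on log-log axes.

    Returns (ζ, (lo, hi)) with a 95 % bootstrap confidence interval over
    points.  Requires ≥ 4 strictly positive points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("all points must be strictly positive")
    lx, ly = np.log(x), np.log(y)

    def slope(ix):
        a = np.polyfit(lx[ix], ly[ix], 1)
        return a[0]

    zeta = float(slope(np.arange(x.size)))
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        ix = rng.integers(0, x.size, x.size)
        if np.unique(lx[ix]).size < 2:
            continue
        boots.append(slope(ix))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return zeta, (float(lo), float(hi))


def water_box_edge(n_molecules: int, density: float = 1.0,
                   molar_mass: float = WATER_MOLAR_MASS) -> float:
    """Cubic box edge (Å) for N molecules at mass density ρ (g cm⁻³).

    L = (N·M/(ρ·N_A))^{1/3}, converted from cm to Å.  1000 water molecules
    at 1 g cm⁻³ give L = 31.04 Å.
    """
    if not (n_molecules > 0 and density > 0 and molar_mass > 0):
        raise ValueError("inputs must be positive")
    vol_cm3 = n_molecules * molar_mass / (density * AVOGADRO)
    return float(vol_cm3 ** (1.0 / 3.0) * 1e8)
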