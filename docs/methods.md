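# Methods

This note documents the estimators implemented in `sedyn`, the synthetic
dynamics they are validated against, and the numerical choices made where
the design was genuinely open.  Internal units throughout: Å, ps, K, amu
(`k_B = 0.8314462609…` amu Å² ps⁻² K⁻¹; one internal viscosity unit is
1.66054×10⁻² mPa·s).

## Data model

A trajectory is the pair (centers, orientations) of N rigid molecules on a
uniform time grid in a cubic periodic box, positions wrapped into
`[0, L)³`.  Orientations are unit quaternions (scalar-first); the
molecular axis `e_j(t)` used by all orientation correlators is a fixed
body-frame unit vector rotated into the laboratory frame on demand — it is
never stored, so there is a single source of truth for the full rigid-body
orientation (needed by the angular-velocity correlator) and the axis
(needed by `C_ℓ`).  Non-uniform frame times are rejected rather than
resampled: every correlator below assumes a uniform lag grid.  Quaternions
are validated to unit norm within 1e−9 on construction and renormalised
only when they have drifted beyond 1e−13, which keeps already-normalised
values bit-stable across file round trips.

Periodic unwrapping uses minimum-image increments and therefore requires
every single-frame displacement to be below L/2; the exactly-ambiguous
L/2 case raises an error naming molecule and frame, since it means the
frame spacing is too coarse to assign images.

## Correlation estimators

All correlators average over molecules and over multiple time origins on
a (by default logarithmically spaced) lag grid.  Standard errors come
from ten contiguous origin blocks: origins within a block are strongly
correlated, block means approximately independent.  When several
independent runs exist, `average_correlation_results` averages the
correlators first and takes the error across runs; averaging correlators
before fitting (rather than averaging fitted parameters) is the package
default for multi-run data.

* **MSD / angular MSD.**  `⟨|Δr(t)|²⟩` on unwrapped centers;
  `⟨|Δφ(t)|²⟩` on the accumulated angular displacement
  `φ(t) = Σ ω Δt`, where `ω = e×e′/Δt` with magnitude `arccos(e·e′)/Δt`
  from consecutive axis directions at stride Δt.  This construction has
  two rotational degrees of freedom (no spin about the axis), so the
  isotropic-diffusion law is `⟨Δφ²⟩ = 4 D_r t` and the diffusion fit uses
  divisor 4 (6 for translation).  An antiparallel axis pair at stride Δt
  is an error, not a silent fix — it signals an invalid stride for the
  integration scheme.
* **Angular-velocity ACF.**  `Ω(t)` is the *full* rigid-body angular
  velocity in the world frame, obtained from the rotation vector of
  `q(t+Δt) q(t)⁻¹`; it includes spin about the molecular axis, unlike ω.
  `C_Ω(t) = ⟨Ω(t)·Ω(0)⟩/3` (per-component normalisation), so that
  `∫C_Ω dt = D_r` for isotropic rotation.  Both estimators are exposed
  because the two conventions differ for non-axially-symmetric dynamics.
* **Orientation correlators.**  `C_ℓ(t) = ⟨P_ℓ(e(t₀+t)·e(t₀))⟩`,
  ℓ = 1…6, exactly 1 at zero lag.
* **Intermediate scattering function.**  `F_s(k,t) = ⟨cos(k⃗·Δr(t))⟩`
  averaged over all reciprocal-lattice vectors within 2 % of the requested
  magnitude (error listing the nearest magnitudes if none lies within
  5 %).  A single fixed k⃗ can be pinned — the four-point estimator does
  so by default because the iid variance identity
  `χ_t = (1+F_s(2k))/2 − F_s(k)²` holds per fixed wave vector, not for a
  direction average.
* **Scalar ACF.**  FFT-based stationary autocovariance `⟨σ(0)σ(t)⟩`
  (not mean-subtracted: the stress components of interest have zero mean,
  and a constant series should give its squared value, which the tests
  pin).

Time-origin striding is configurable (default every frame for cheap
quantities, every 10th in the pipeline); it affects only error bars, and
the direct O(n²) reference implementations in the test suite agree with
the production path to 1e−10.

## Transport coefficients and fits

* **Diffusion constants** are weighted least-squares slopes of the MSD
  over a window, divided by 6 (translation) or 4 (axis rotation).  When no
  window is given, the longest contiguous lag range with local log–log
  slope in [0.95, 1.05] is selected (with a warning if it spans less than
  a decade) — the practical reading of "long-time limit" on a finite
  trajectory.
* **Green–Kubo integrals** (rotational diffusion from `C_Ω`, viscosity
  `η = [V/(k_B T)]·∫⟨σ(0)σ(t)⟩dt`, with optional multi-component ACF
  averaging) use a running trapezoidal integral with plateau detection:
  the earliest lag `t_c` at which the integral stays within
  `max(1 %·|I|, 3 σ_drift)` over `[t_c, min(10 t_c, t_end)]`, where
  `σ_drift` propagates the ACF standard errors over the window using the
  local integral correlation time.  The noise-aware term matters: the
  running integral of a noisy ACF performs a random walk whose drift over
  a decade generically exceeds a strict 1 % band even when the integral
  has converged in the statistical sense, so a purely relative criterion
  would reject valid plateaus on stochastic input while passing noiseless
  input.  The reported value is the mean of the running integral over the
  plateau window; when no plateau exists the error carries the full
  running-integral trace for inspection.
* **KWW fits** `A·exp(−(t/τ)^β)` use bounded Levenberg–Marquardt with a
  small set of deterministic restarts.  `A` is free in (0, 1.05] to absorb
  a fast initial (libration-like) drop; the default window starts at
  10× the first lag to exclude such transients, and a fit whose data never
  decay below 0.1 is flagged as an extrapolation.  `τ_ℓ` is the fitted τ;
  the integrated relaxation time `A·(τ/β)·Γ(1/β)` is reported alongside
  for comparability with literature that uses the time integral.
* **α-relaxation time**: KWW-τ of `F_s(k,t)` by default, e⁻¹-crossing as
  a logged alternative; for stretched decay the two differ and both are
  available (the choice of estimator varies across the literature and is
  therefore explicit configuration here).
* **Debye diagnostics**: `D_r τ_ℓ ℓ(ℓ+1)` (exactly 1 under the Debye
  model) and the characteristic reorientation angle of order ℓ — the
  first zero of `P_ℓ(cos θ)`, found by bracketed root search to 1e−10:
  π/2 for ℓ=1, ≈0.9553 for ℓ=2, ≈0.37 rad for ℓ=6.

## Hydrogen bonds

Geometric criterion: donor→acceptor pair bonded when the O–O
minimum-image distance ≤ 3.5 Å and the H–O(donor)···O(acceptor) angle
≤ 30° for either donor hydrogen.  Both cutoffs are configuration fields
— the values are the standard geometric choice in the water literature,
but no claim is made that any particular published τ_HB used exactly
them.  The default correlation is the *intermittent* indicator
`c(t) = ⟨h(t₀)h(t₀+t)⟩/⟨h⟩` (a pooled ratio over pairs and origins, so
origins with few surviving bonds are weighted by their bond count rather
than equally), which probes irreversible bond breakage; a
continuous-lifetime variant (indicator cut at the first break) sits
behind a flag.  τ_HB is the KWW-fitted decay time by default, with the
e⁻¹ crossing as the robust alternative.  Reactive-flux (rate-constant)
analysis is out of scope.

## Dynamic heterogeneity

Four-point susceptibilities are `N × var` of the per-configuration
correlator (`F̂_s(k,t)` with a fixed k⃗, or `Ĉ_ℓ(t)`) across
configuration samples — time origins within one run, poolable across
runs.  Errors come from a delete-one-block jackknife over contiguous
origin blocks.  χ(0) is exactly 0 (the correlators are identically 1 at
zero lag), and for iid dynamics the long-time limits are 1/2
(translational, cosine variance) and 1/(2ℓ+1) (rotational, variance of
`P_ℓ` under a uniform cosine).  Peak times are refined with a three-point
parabola in log-time and it is an error if the maximum sits on the grid
boundary.

The joint van Hove function bins (|Δr⃗|, Δθ) pooled over molecules and
origins, where Δθ = arccos(e(t₀)·e(t₀+t)) ∈ [0, π] is the direct
reorientation angle (not the accumulated |φ⃗|, which differs once
libration accumulates; the accumulated-angle variant is available via the
angular track).  The stored `surface` is the joint probability density
per (Å·rad) — the `4πr²G_s` surface of contour plots, normalised so its
discrete integral is exactly 1 — and `density` is `G_s = surface/(4πr²)`
at bin centres.  Defaults: 100 radial bins over [0, 12 Å], 60 angular
bins over [0, π].

## SED assembly

`sed_ratio_table` computes, per state point, the hydrodynamic radii
`R_t = k_B T/(6πηD_t)` and `R_r = [k_B T/(8πηD_r)]^{1/3}` and every ratio
family (`D_t η/(k_B T)`, `τ_ℓ k_B T/η` and its display form `η/(τ_ℓ T)`,
`D_t τ_ℓ`, `D_r/D_t` and its inverse — emitted both ways to avoid the
axis-label ambiguity common in this literature — `D_r τ_ℓ ℓ(ℓ+1)`,
`D_t τ_HB`, `D_t τ_α`).  Ratio columns use the dimensionally explicit
`k_B T` form internally; the `T/η` display form is a presentation
convention.  Each ratio gains a `_scaled` twin divided by its value at a
reference state point (default: the highest temperature present, since a
fixed reference like 260 K is meaningless for synthetic families);
missing inputs yield explicit nulls, never silent drops.  Fractional
relations `y ∝ x^ζ` are fitted by least squares on log–log axes with a
bootstrap confidence interval; no automatic "violation onset" detection
is attempted — exponent fits use exactly the rows given.

The box-edge utility `L = (N·M/(ρ·N_A))^{1/3}` gives 31.04 Å for 1000
water molecules at 1 g cm⁻³ (M = 18.015 g/mol).

## Synthetic dynamics and what the tests establish

Each generator is seeded, emits its full parameter set in the trajectory
metadata, and has at least one closed-form oracle:

| model | oracle |
|---|---|
| rotational Brownian (body-frame rotation-vector steps, variance `2D_rΔt` per component, exact exponential map) | `C_ℓ = e^{−ℓ(ℓ+1)D_r t}`, `⟨Δφ²⟩ = 4D_r t`, `∫C_Ω dt = D_r` |
| Ivanov jump rotation | `1/τ_ℓ = (1 − P_ℓ(cos θ₀))/τ_w` |
| translational Brownian | `⟨Δr²⟩ = 6D_t t`, `F_s = e^{−k²D_t t}` |
| two-state fast/slow mixture | mixture moments; χ_t excess over the iid envelope |
| OU stress (exact discretisation) | `⟨σ(0)σ(t)⟩ = c·e^{−t/τ_c}`, `∫ = c·τ_c` |

Design choices worth recording:

* Rotational Brownian steps compose exact rotation-vector increments into
  the quaternion rather than updating Euler angles — no coordinate
  singularities, and the Debye closed form holds to O(Δt).  The generator
  enforces `D_r·Δt ≤ 0.05 rad²`.
* The jump model applies each jump about an axis drawn uniformly on the
  circle **perpendicular to the current molecular axis**, so the axis
  tilts by exactly θ₀ per event and, with uniform azimuth, the
  spherical-harmonic addition theorem makes `τ_ℓ = τ_w/(1−P_ℓ(cos θ₀))`
  exact at every order.  Axes uniform on the full sphere would *not*
  reproduce this closed form (the axis–jump angle is then not θ₀;
  numerically the θ₀ = π case decays `C_2`, which the perpendicular-axis
  convention correctly freezes at 1).
* The two-state model switches labels in continuous time and integrates
  the within-frame occupancy exactly, so increments are exact even when a
  switch falls inside a frame.
* The OU stress uses the exact AR(1) discretisation
  `x_{n+1} = ρ x_n + √(c(1−ρ²)) ξ`, `ρ = e^{−Δt/τ_c}`, making the ACF
  oracle exact at any sample interval.
* The rigid three-site geometry defaults to the TIP4P/2005 values
  (O–H = 0.9572 Å, H–O–H = 104.52°, dipole along the bisector) but is a
  configuration field, not a constant.

These synthetic systems are *non-interacting*: they validate estimator
correctness (normalisations, lag bookkeeping, fit bias, unit handling)
and the null behaviour of the SED diagnostics, but they do not emulate
caging, libration oscillations, structured `S(k)`, or the temperature
dependence of real supercooled water.  A green test suite therefore
establishes that the estimators measure what they claim on dynamics with
known answers — not that any particular physical system obeys or violates
the SE/SED relations.

## Problem sizes and reproducibility

The statistical benchmarks run at N = 1000 molecules with 2000–4000
frames at 0.1 ps (rotational relaxation resolved over ~2–3 decades of
lag), and 10⁶ samples for the OU viscosity check — sizes at which the
recovery tolerances (3–5 % on diffusivities, 10 % on τ ratios, 2 % on the
Green–Kubo integral) hold with wide margin across seeds.  All generators
draw from `numpy.random.default_rng` seeded explicitly; the pipeline
writes a JSON manifest with the seed and all resolved parameters, and its
outputs are bit-reproducible for a fixed seed and config.

## Known limitations

* Cubic periodic boxes only; triclinic cells are rejected at read time.
* No coherent scattering functions, no rank > 6 correlators, no
  wave-number-resolved four-point analysis or ξ₄ extraction, no
  Einstein–Helfand viscosity route, no finite-size corrections to `D_t`.
* H-bond analysis has no donor/acceptor asymmetry statistics and no
  reactive-flux rates.
* The jump-model relation `D_t ~ ℓ²_jump/τ_HB` is treated as an
  order-of-magnitude scaling, not a fit target.
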