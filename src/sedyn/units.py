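"""Internal unit system and physical constants.

Everything inside the package is expressed in a single internal system:

==============  =========================  =========================
quantity        internal unit              SI value of one unit
==============  =========================  =========================
length          angstrom (Å)               1e-10 m
time            picosecond (ps)            1e-12 s
mass            unified amu                1.66053906892e-27 kg
temperature     kelvin (K)                 1 K
energy          amu Å² ps⁻²                1.66053906892e-23 J
stress          amu Å⁻¹ ps⁻²               1.66053906892e7 Pa
viscosity       amu Å⁻¹ ps⁻¹               1.66053906892e-5 Pa s
==============  =========================  =========================

With these choices the Boltzmann constant is ``KB = 0.831446...`` internal
energy units per kelvin, and one internal viscosity unit is
``1.66053906892e-2`` mPa·s.  All unit conversions in the package go through
the constants below; nothing else hard-codes a conversion factor.
"""

from __future__ import annotations

# CODATA 2018 values.
AVOGADRO = 6.02214076e23  # mol^-1
KB_SI = 1.380649e-23  # J/K
AMU_KG = 1.66053906892e-27  # kg

#: Boltzmann constant in internal energy units (amu Å² ps⁻²) per kelvin.
KB = KB_SI / (AMU_KG * 1e-20 / 1e-24)  # = KB_SI / 1.66054e-23 J

#: One internal viscosity unit (amu Å⁻¹ ps⁻¹) in mPa·s.
VISCOSITY_TO_MPAS = AMU_KG / (1e-10 * 1e-12) * 1e3

#: Molar mass of water, g/mol.
WATER_MOLAR_MASS = 18.015
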