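"""Physical constants and unit conversions.

Everything is derived from CODATA values in :mod:`scipy.constants` at import
time rather than hard-coded, so the numbers stay consistent with the SI data
scipy ships.  Canonical internal units: length in Å, energy in cm⁻¹ (wavenumber),
transition dipoles in debye, rates in ps⁻¹, temperature in K.
"""

from __future__ import annotations

import math

from scipy import constants as _c

#: J per cm⁻¹ (h·c·100): converts a wavenumber to an energy.
JOULE_PER_WAVENUMBER: float = _c.h * _c.c * 100.0

#: cm⁻¹ per eV (≈ 8065.544).
WAVENUMBER_PER_EV: float = _c.e / JOULE_PER_WAVENUMBER

#: Boltzmann constant in cm⁻¹ per kelvin (≈ 0.6950348).
KB_WAVENUMBER_PER_K: float = _c.k / JOULE_PER_WAVENUMBER

#: C·m per debye (1 D = 1e-21/c C·m ≈ 3.33564e-30).
COULOMB_METER_PER_DEBYE: float = 1e-21 / _c.c

#: debye per e·Å (≈ 4.8032): converts Σ qᵢrᵢ in e·Å to debye.
DEBYE_PER_E_ANGSTROM: float = _c.e * 1e-10 / COULOMB_METER_PER_DEBYE

#: Coulomb energy of two unit charges (e) 1 Å apart, in cm⁻¹ (≈ 1.1614e5).
#: This is the conversion constant of the transition-charge (TrEsp) coupling
#: sum V = K·Σ qᵢqⱼ/rᵢⱼ with q in e and r in Å.
TRESP_COULOMB_WAVENUMBER_ANGSTROM: float = (
    _c.e**2 / (4.0 * math.pi * _c.epsilon_0 * 1e-10) / JOULE_PER_WAVENUMBER
)

#: Point-dipole coupling constant in cm⁻¹·Å³·D⁻² (≈ 5034.1):
#: V = C·κ·μ₁μ₂/R³ with μ in debye and R in Å, vacuum.
PDA_WAVENUMBER_ANGSTROM3_PER_DEBYE2: float = (
    COULOMB_METER_PER_DEBYE**2
    / (4.0 * math.pi * _c.epsilon_0 * 1e-30)
    / JOULE_PER_WAVENUMBER
)

#: Empirical Förster prefactor: k(ps⁻¹) = FORSTER_PREFACTOR · V(cm⁻¹)² · J(cm).
FORSTER_PREFACTOR: float = 1.18


def ev_to_wavenumber(energy_ev: float) -> float:
    """Convert an energy in eV to a wavenumber in cm⁻¹."""
    return energy_ev * WAVENUMBER_PER_EV


def wavenumber_to_ev(nu: float) -> float:
    """Convert a wavenumber in cm⁻¹ to an energy in eV."""
    return nu / WAVENUMBER_PER_EV


def nm_to_wavenumber(wavelength_nm: float) -> float:
    """Convert a vacuum wavelength in nm to a wavenumber in cm⁻¹."""
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
    return 1e7 / wavelength_nm


def wavenumber_to_nm(nu: float) -> float:
    """Convert a wavenumber in cm⁻¹ to a vacuum wavelength in nm."""
    if nu <= 0:
        raise ValueError(f"wavenumber must be positive, got {nu}")
    return 1e7 / nu
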