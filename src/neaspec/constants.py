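"""Physical constants and unit conversions (CODATA 2018).

Internal unit system used throughout the package:

========  ==========================
length    angstrom (Å)
mass      unified atomic mass (amu)
energy    electronvolt (eV)
time      femtosecond (fs)
wavenumber  cm⁻¹ (spectroscopic)
========  ==========================

A mass of ``m`` amu enters kinetic energy as ``0.5 * m * AMU_EVFS * v**2``
with ``v`` in Å/fs.  All conversions are centralized here; no other module
hard-codes a unit factor.
"""

import math

# --- CODATA 2018 exact/recommended values (SI) ---
E_CHARGE = 1.602176634e-19          # C (exact)
HBAR_SI = 1.054571817e-34           # J s
M_E_SI = 9.1093837015e-31           # kg
EPS0_SI = 8.8541878128e-12          # F m^-1
C_SI = 2.99792458e8                 # m s^-1 (exact)
KB_SI = 1.380649e-23                # J K^-1 (exact)
AMU_SI = 1.66053906660e-27          # kg

# --- internal-unit derived constants ---
#: hbar in eV fs
HBAR = HBAR_SI / E_CHARGE * 1e15
#: Boltzmann constant in eV/K
KB = KB_SI / E_CHARGE
#: speed of light in cm/fs (for wavenumber <-> angular frequency)
C_CM_FS = C_SI * 1e2 * 1e-15
#: 1 amu expressed in eV fs^2 / Å^2 (mass conversion for kinetic energy)
AMU_EVFS = AMU_SI * (1e-10 / 1e-15) ** 2 / E_CHARGE
#: hc in eV nm (photon energy E[eV] = HC_EVNM / lambda[nm])
HC_EVNM = (2 * math.pi * HBAR_SI * C_SI) / E_CHARGE * 1e9
#: hbar in amu Å^2 / fs (for mass-weighted normal coordinates)
HBAR_AMU = HBAR / AMU_EVFS
#: Bohr radius in Å (Molden [FR-COORD] sections are in Bohr)
BOHR_ANG = 0.529177210903

#: NEA cross-section prefactor K = pi e^2 hbar / (2 m_e c eps0), in eV cm^2.
#: sigma(E) = (K/E) * sum over states/geometries of dE * f * lineshape.
K_PREFACTOR = (
    math.pi * E_CHARGE**2 * HBAR_SI / (2.0 * M_E_SI * C_SI * EPS0_SI)
) / E_CHARGE * 1e4


def wavenumber_to_angular(nu_cm: float) -> float:
    """Convert a wavenumber in cm⁻¹ to angular frequency in fs⁻¹."""
    return 2.0 * math.pi * C_CM_FS * nu_cm


def angular_to_wavenumber(omega_fs: float) -> float:
    """Convert angular frequency in fs⁻¹ to a wavenumber in cm⁻¹."""
    return omega_fs / (2.0 * math.pi * C_CM_FS)


def ev_to_nm(energy_ev: float) -> float:
    """Photon energy (eV) to vacuum wavelength (nm)."""
    return HC_EVNM / energy_ev


def nm_to_ev(wavelength_nm: float) -> float:
    """Vacuum wavelength (nm) to photon energy (eV)."""
    return HC_EVNM / wavelength_nm


#: Standard atomic weights (amu), a pragmatic subset for light molecules.
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "He": 4.002602,
    "Li": 6.94, "Be": 9.0121831, "B": 10.81, "C": 12.011,
    "N": 14.007, "O": 15.999, "F": 18.998403163, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.305, "Al": 26.9815385, "Si": 28.085,
    "P": 30.973761998, "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.0983, "Ca": 40.078, "Br": 79.904, "I": 126.90447,
    # model-system pseudo-atoms: "X<mass>" handled in io_formats
}
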