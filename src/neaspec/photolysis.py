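"""Photolysis rate coefficients from cross-section, quantum yield and flux.

The first-order photolysis rate coefficient of a light-driven reaction is
the overlap integral

    j = ∫ σ(λ) φ(λ) F(λ) dλ        [s⁻¹]

with σ the photoabsorption cross-section (cm² molecule⁻¹), φ the
(wavelength-dependent) quantum yield and F the actinic flux
(photons cm⁻² s⁻¹ nm⁻¹).  Quadrature is trapezoidal on the union of the
three wavelength grids with linear interpolation — the convention of
piecewise-linear atmospheric tables.  Outside any table's support the
contribution is zero (no extrapolation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import ev_to_nm
from .io_formats import ValidationError
from .nea_spectrum import Spectrum


@dataclass
class FluxTable:
    """Actinic flux F(λ): photons cm⁻² s⁻¹ nm⁻¹ on an increasing nm grid."""

    wavelength_nm: np.ndarray
    flux: np.ndarray

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, float)
        self.flux = np.asarray(self.flux, float)
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValidationError("flux wavelengths must be strictly increasing")
        if np.any(self.flux < 0):
            raise ValidationError("flux must be non-negative")


@dataclass
class QuantumYieldTable:
    """Quantum yield φ(λ), dimensionless, on an increasing nm grid."""

    wavelength_nm: np.ndarray
    quantum_yield: np.ndarray

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, float)
        self.quantum_yield = np.asarray(self.quantum_yield, float)
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValidationError("yield wavelengths must be strictly increasing")
        if np.any(self.quantum_yield < 0):
            raise ValidationError("quantum yield must be non-negative")
        if np.any(self.quantum_yield > 1):
            warnings.warn("quantum yield exceeds 1 (multi-fragment convention?)")


def spectrum_on_wavelength(spectrum: Spectrum) -> tuple[np.ndarray, np.ndarray]:
    """σ re-indexed on an increasing wavelength grid (nm)."""
    wl = ev_to_nm(spectrum.energy_grid)[::-1]
    sig = spectrum.sigma[::-1]
    return wl, sig


def photolysis_rate(spectrum: Spectrum, phi: QuantumYieldTable,
                    flux: FluxTable,
                    lambda_range: tuple[float, float] | None = None) -> float:
    """j = ∫ σφF dλ on the union grid (s⁻¹)."""
    wl_s, sig = spectrum_on_wavelength(spectrum)
    lo = max(wl_s[0], phi.wavelength_nm[0], flux.wavelength_nm[0])
    hi = min(wl_s[-1], phi.wavelength_nm[-1], flux.wavelength_nm[-1])
    if lambda_range is not None:
        lo, hi = max(lo, lambda_range[0]), min(hi, lambda_range[1])
    if not hi > lo:
        raise ValidationError(
            f"no wavelength overlap between spectrum, yield and flux "
            f"(requested [{lo:.1f}, {hi:.1f}] nm)")
    union = np.unique(np.concatenate([
        wl_s[(wl_s >= lo) & (wl_s <= hi)],
        phi.wavelength_nm[(phi.wavelength_nm >= lo) & (phi.wavelength_nm <= hi)],
        flux.wavelength_nm[(flux.wavelength_nm >= lo) & (flux.wavelength_nm <= hi)],
        [lo, hi]]))
    s = np.interp(union, wl_s, sig)
    p = np.interp(union, phi.wavelength_nm, phi.quantum_yield)
    f = np.interp(union, flux.wavelength_nm, flux.flux)
    integrand = s * p * f
    if np.any(integrand < 0):
        warnings.warn("negative interpolated integrand clipped to zero")
        integrand = np.clip(integrand, 0.0, None)
    return float(np.trapezoid(integrand, union))
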