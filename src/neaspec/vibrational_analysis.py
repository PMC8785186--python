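"""Harmonic analysis: mass-weighted Hessians, Eckart projection, normal modes.

The harmonic model built here — wavenumbers and orthonormal mass-weighted
rectilinear mode vectors — is the input of Wigner sampling.  Rigid
translations and infinitesimal rotations are always projected out before
diagonalization; residual near-zero modes below a configurable wavenumber
floor are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import AMU_EVFS, angular_to_wavenumber
from .io_formats import Geometry, ValidationError


@dataclass
class HessianMatrix:
    """Cartesian Hessian (eV Å⁻²) evaluated at a geometry.

    Symmetrized on construction; ``mass_weighted`` marks matrices already
    transformed to M^(-1/2) H M^(-1/2) form (amu-weighted).
    """

    values: np.ndarray
    geometry: Geometry
    mass_weighted: bool = False
    projected: bool = False

    def __post_init__(self):
        h = np.asarray(self.values, float)
        n = 3 * self.geometry.n_atoms
        if h.shape != (n, n):
            raise ValidationError(f"Hessian shape {h.shape} does not match "
                                  f"3*n_atoms = {n}")
        asym = np.abs(h - h.T).max()
        scale = max(np.abs(h).max(), 1.0)
        if asym > 1e-8 * scale:
            warnings.warn(f"Hessian asymmetry {asym:.2e}; symmetrizing")
        self.values = 0.5 * (h + h.T)


@dataclass
class NormalModeSet:
    """Vibrational wavenumbers (cm⁻¹) and orthonormal mass-weighted modes.

    ``frequencies[i]`` < 0 encodes an imaginary frequency.  ``mode_vectors``
    rows are unit vectors in mass-weighted coordinates (amu^(1/2)·Å basis);
    the Cartesian displacement of mode i with normal coordinate Q_i is
    ``M^(-1/2) L_i Q_i``.
    """

    frequencies: np.ndarray        # cm^-1, sorted ascending
    mode_vectors: np.ndarray       # (n_modes, 3*n_atoms)
    geometry: Geometry
    reduced_masses: np.ndarray = field(default=None)   # amu, reporting only

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, float)
        self.mode_vectors = np.asarray(self.mode_vectors, float)
        if self.mode_vectors.shape[0] != self.frequencies.size:
            raise ValidationError("mode count does not match frequency count")
        gram = self.mode_vectors @ self.mode_vectors.T
        if not np.allclose(gram, np.eye(len(gram)), atol=1e-8):
            raise ValidationError("mode vectors are not orthonormal")
        if self.reduced_masses is None:
            # 1 / sum_i (L_{i,atom}^2 / m_atom), the Wilson convention
            m = np.repeat(self.geometry.masses, 3)
            with np.errstate(divide="ignore"):
                self.reduced_masses = 1.0 / ((self.mode_vectors**2) / m).sum(axis=1)

    @property
    def n_modes(self) -> int:
        return self.frequencies.size

    @property
    def has_imaginary(self) -> bool:
        return bool(np.any(self.frequencies < 0))


def _external_basis(geometry: Geometry) -> np.ndarray:
    """Orthonormal basis of mass-weighted rigid translations and rotations.

    Returns a (k, 3n) array with k = 5 for linear molecules, 6 otherwise
    (3 for a single atom).
    """
    m = geometry.masses
    x = geometry.coords - np.average(geometry.coords, weights=m, axis=0)
    sq = np.sqrt(m)
    n = geometry.n_atoms
    vecs = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = sq
        vecs.append(t.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        r = np.cross(x, e) * sq[:, None]
        vecs.append(r.ravel())
    basis = np.array(vecs)
    # orthonormalize and drop rank-deficient rotations (linear molecules)
    u, s, vt = np.linalg.svd(basis, full_matrices=False)
    rank = int((s > 1e-8 * s[0]).sum())
    return vt[:rank]


def mass_weight(hessian: HessianMatrix) -> HessianMatrix:
    """Transform a Cartesian Hessian to mass-weighted form (eV Å⁻² amu⁻¹)."""
    if hessian.mass_weighted:
        return hessian
    m = np.repeat(hessian.geometry.masses, 3)
    h = hessian.values / np.sqrt(np.outer(m, m))
    return HessianMatrix(h, hessian.geometry, mass_weighted=True)


def eckart_project(hessian: HessianMatrix) -> HessianMatrix:
    """Project rigid translations and rotations out of the Hessian.

    Accepts a Cartesian or mass-weighted Hessian; returns the projected
    mass-weighted Hessian.  After projection the external subspace maps to
    eigenvalues below 1e-8 of the largest eigenvalue.
    """
    if np.any(hessian.geometry.masses <= 0):
        raise ValidationError("zero or negative atomic mass")
    hmw = mass_weight(hessian)
    ext = _external_basis(hessian.geometry)
    p = np.eye(hmw.values.shape[0]) - ext.T @ ext
    h = p @ hmw.values @ p
    return HessianMatrix(0.5 * (h + h.T), hessian.geometry,
                         mass_weighted=True, projected=True)


def normal_mode_analysis(hessian: HessianMatrix,
                         floor_threshold_cm: float = 10.0) -> NormalModeSet:
    """Diagonalize a (projected, mass-weighted) Hessian into normal modes.

    Wavenumbers follow from eigenvalues λ (eV Å⁻² amu⁻¹) as
    ν̃ = sqrt(λ / amu_conv) / (2πc); negative λ are reported as negative ν̃.
    Modes with \\|ν̃\\| below ``floor_threshold_cm`` are dropped as residual
    translation/rotation.
    """
    h = hessian if hessian.projected else eckart_project(hessian)
    evals, evecs = np.linalg.eigh(h.values)
    omega2 = evals / AMU_EVFS            # fs^-2, signed
    nu = np.sign(omega2) * angular_to_wavenumber(np.sqrt(np.abs(omega2)))
    keep = np.abs(nu) >= floor_threshold_cm
    nu, vecs = nu[keep], evecs[:, keep].T
    order = np.argsort(nu)
    nu, vecs = nu[order], vecs[order]
    n_atoms = hessian.geometry.n_atoms
    expected = max(3 * n_atoms - 6, 1) if n_atoms > 1 else 0
    n_imag = int((nu < 0).sum())
    if n_imag:
        warnings.warn(f"{n_imag} imaginary frequencies present; "
                      "Wigner sampling will refuse these modes")
    return NormalModeSet(nu, vecs, hessian.geometry)


def modes_from_raw(geometry: Geometry, freqs_cm: np.ndarray,
                   raw_modes: np.ndarray,
                   floor_threshold_cm: float = 10.0) -> NormalModeSet:
    """Build a NormalModeSet from Cartesian displacement patterns.

    ``raw_modes`` (n_modes, 3n) are mass-weighted and normalized — the form
    frequency files store.  Modes below the wavenumber floor are dropped.
    """
    freqs = np.asarray(freqs_cm, float)
    raw = np.asarray(raw_modes, float)
    mw = raw * np.sqrt(np.repeat(geometry.masses, 3))
    norms = np.linalg.norm(mw, axis=1)
    if np.any(norms == 0):
        raise ValidationError("zero mode vector")
    mw = mw / norms[:, None]
    keep = np.abs(freqs) >= floor_threshold_cm
    order = np.argsort(freqs[keep])
    return NormalModeSet(freqs[keep][order], mw[keep][order], geometry)


def reconstruct_hessian(modes: NormalModeSet) -> np.ndarray:
    """Rebuild the projected mass-weighted Hessian as Σ λ_i L_i L_iᵀ."""
    from .constants import wavenumber_to_angular
    omega = wavenumber_to_angular(np.abs(modes.frequencies))
    lam = np.sign(modes.frequencies) * omega**2 * AMU_EVFS
    return (modes.mode_vectors.T * lam) @ modes.mode_vectors
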