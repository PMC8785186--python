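"""Analytic stand-ins for the electronic-structure engine.

This module supplies everything an external quantum-chemistry code would
normally provide, at desk scale and in closed form:

* analytic ground-state potentials implementing the :class:`PotentialSurface`
  contract (n-dimensional harmonic wells, Morse bonds, a torsion–stretch
  toy, a microsolvation-like soft-mode toy),
* "toy chromophores" mapping geometry to vertical excitation energies and
  oscillator strengths,
* finite-difference Hessians for any potential.

The torsion–stretch toy is built to exhibit the rectilinear-sampling
artifact: a light atom on a stiff bond whose soft torsion, sampled along
straight Cartesian displacement vectors, artificially stretches the bond.
The soft-intermolecular toy couples a stiff chromophore bond to a soft,
anharmonic (Morse-type) intermolecular coordinate, so that thermostatted
dynamics samples a broader distribution than the harmonic Wigner model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize

from .constants import AMU_EVFS, HBAR, HBAR_AMU, KB, wavenumber_to_angular
from .io_formats import Geometry, TransitionRecord, ValidationError
from .vibrational_analysis import HessianMatrix
from .wigner_sampler import GeometryEnsemble


class ModelError(ValueError):
    pass


# --------------------------------------------------------------------------
# Potentials
# --------------------------------------------------------------------------

class _NumericGradientMixin:
    """Central-difference gradient fallback (h = 1e-6 Å)."""

    _fd_step = 1.0e-6

    def gradient(self, geometry: Geometry) -> np.ndarray:
        x0 = geometry.coords
        g = np.zeros_like(x0)
        h = self._fd_step
        for i in range(x0.shape[0]):
            for k in range(3):
                xp = x0.copy(); xp[i, k] += h
                xm = x0.copy(); xm[i, k] -= h
                g[i, k] = (self.energy(geometry.with_coords(xp))
                           - self.energy(geometry.with_coords(xm))) / (2 * h)
        return g


@dataclass
class HarmonicND:
    """Quadratic potential  V = ½ (x-x₀)ᵀ H (x-x₀)  around a reference."""

    reference: Geometry
    hessian: np.ndarray      # (3n, 3n), eV/Å²
    descriptor: str = "harmonic_nd"

    def energy(self, geometry: Geometry) -> float:
        d = (geometry.coords - self.reference.coords).ravel()
        return 0.5 * float(d @ self.hessian @ d)

    def gradient(self, geometry: Geometry) -> np.ndarray:
        d = (geometry.coords - self.reference.coords).ravel()
        return (self.hessian @ d).reshape(-1, 3)


def make_isotropic_oscillator(wavenumber_cm: float, mass_amu: float = 1.0,
                              label: str = "osc") -> tuple[HarmonicND, Geometry]:
    """Single-particle isotropic 3D harmonic well with the given wavenumber."""
    omega = wavenumber_to_angular(wavenumber_cm)
    k = mass_amu * AMU_EVFS * omega**2
    ref = Geometry([f"X{mass_amu:g}"], np.zeros((1, 3)), label=label)
    return HarmonicND(ref, k * np.eye(3), descriptor=f"iso_osc_{wavenumber_cm}cm"), ref


@dataclass
class MorseBond(_NumericGradientMixin):
    """Diatomic Morse potential  V = D (1 - exp(-a (r - r0)))²."""

    reference: Geometry
    D: float      # eV
    a: float      # Å⁻¹
    r0: float     # Å
    descriptor: str = "morse_bond"

    def energy(self, geometry: Geometry) -> float:
        r = np.linalg.norm(geometry.coords[1] - geometry.coords[0])
        return float(self.D * (1 - np.exp(-self.a * (r - self.r0))) ** 2)

    def gradient(self, geometry: Geometry) -> np.ndarray:
        v = geometry.coords[1] - geometry.coords[0]
        r = np.linalg.norm(v)
        ex = np.exp(-self.a * (r - self.r0))
        dVdr = 2 * self.D * (1 - ex) * self.a * ex
        u = v / r
        g = np.zeros_like(geometry.coords)
        g[1] = dVdr * u
        g[0] = -dVdr * u
        return g


def _dihedral(p0, p1, p2, p3):
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return np.arctan2(m1 @ n2, n1 @ n2)


@dataclass
class TorsionStretchToy(_NumericGradientMixin):
    """Four-site toy: stiff bond stretch + soft dihedral torsion of a light atom.

    Sites 0 and 1 are heavy anchors defining the reference plane, site 2 is
    the heavy bond partner, site 3 the light atom (H-like).  The potential
    depends only on internal coordinates (rotation/translation invariant):

        V = ½ k_r (r₂₃ - r0)² + ½ k_theta φ(0,1,2,3)²
    """

    reference: Geometry
    k_r: float        # eV/Å²
    k_theta: float    # eV/rad²
    r0: float         # Å
    descriptor: str = "torsion_stretch"

    def energy(self, geometry: Geometry) -> float:
        c = geometry.coords
        r = np.linalg.norm(c[3] - c[2])
        phi = _dihedral(c[0], c[1], c[2], c[3])
        return float(0.5 * self.k_r * (r - self.r0) ** 2
                     + 0.5 * self.k_theta * phi**2)


@dataclass
class ExactTorsionStretchSampler:
    """Curvilinear reference sampler for :class:`TorsionStretchToy`.

    Draws (r, φ) independently from the quantum harmonic (thermal) densities
    of the stretch and torsion coordinates and embeds them back to Cartesian
    positions, rotating the light atom rigidly about the anchor axis — the
    ground truth that rectilinear Wigner sampling distorts.
    """

    toy: TorsionStretchToy
    mu_r_amu: float     # stretch reduced mass
    inertia_amu: float  # torsional moment of inertia, amu Å²

    def sample(self, n_samples: int, temperature: float = 0.0,
               seed: int = 0) -> GeometryEnsemble:
        rng = np.random.default_rng(seed)
        ref = self.toy.reference
        omega_r = np.sqrt(self.toy.k_r / (self.mu_r_amu * AMU_EVFS))
        omega_t = np.sqrt(self.toy.k_theta / (self.inertia_amu * AMU_EVFS))

        def coth(w):
            if temperature <= 0:
                return 1.0
            return 1.0 / np.tanh(HBAR * w / (2 * KB * temperature))

        var_r = HBAR_AMU / (2 * self.mu_r_amu * omega_r) * coth(omega_r)
        var_t = HBAR_AMU / (2 * self.inertia_amu * omega_t) * coth(omega_t)
        r = self.toy.r0 + rng.standard_normal(n_samples) * np.sqrt(var_r)
        phi = rng.standard_normal(n_samples) * np.sqrt(var_t)
        axis = ref.coords[2] - ref.coords[1]
        axis = axis / np.linalg.norm(axis)
        v0 = ref.coords[3] - ref.coords[2]
        members = []
        for k in range(n_samples):
            c, s = np.cos(phi[k]), np.sin(phi[k])
            # Rodrigues rotation of the bond vector about the anchor axis
            v = (v0 * c + np.cross(axis, v0) * s
                 + axis * (axis @ v0) * (1 - c))
            v = v / np.linalg.norm(v) * r[k]
            coords = ref.coords.copy()
            coords[3] = ref.coords[2] + v
            members.append(ref.with_coords(coords, label=f"exact:{k}"))
        return GeometryEnsemble(
            members,
            provenance={"sampler": "exact-curvilinear", "n_samples": n_samples,
                        "temperature_K": temperature, "seed": seed},
            conformer_label=ref.label)


def make_torsion_stretch(nu_stretch_cm: float = 3600.0,
                         nu_torsion_cm: float = 200.0,
                         r0: float = 0.96,
                         light_mass_amu: float = 1.008,
                         anchor_mass_amu: float = 16.0,
                         ) -> tuple[TorsionStretchToy, ExactTorsionStretchSampler]:
    """Build the torsion–stretch toy in the hydroperoxide-like regime.

    Defaults mimic an O–H bond (≈3600 cm⁻¹ stretch) whose carrier can twist
    about a heavy-atom axis with a soft (≈200 cm⁻¹) torsion.  Force
    constants are derived from the requested wavenumbers through the
    curvilinear reduced masses.
    """
    if nu_stretch_cm <= 3 * nu_torsion_cm:
        raise ModelError("demonstration regime requires a stiff stretch and "
                         "a soft torsion (nu_stretch >> nu_torsion)")
    m_h, m_a = light_mass_amu, anchor_mass_amu
    # geometry: anchors on/near the x-axis, light atom off-axis in the plane
    bond_dir = np.array([np.cos(np.deg2rad(70.0)), np.sin(np.deg2rad(70.0)), 0.0])
    coords = np.array([
        [-2.0, 0.8, 0.0],            # plane-defining anchor
        [-1.4, 0.0, 0.0],            # axis anchor
        [0.0, 0.0, 0.0],             # bond partner
        list(r0 * bond_dir),         # light atom
    ])
    symbols = [f"X{m_a:g}", f"X{m_a:g}", f"X{m_a:g}", f"X{m_h:g}"]
    ref = Geometry(symbols, coords, label="torsion_stretch")
    mu_r = m_h * m_a / (m_h + m_a)
    # Wilson G-matrix effective inertia of the dihedral coordinate,
    # I_eff = 1 / Σ_i |∇_i φ|² / m_i, from a finite-difference gradient
    h = 1e-6
    grad_phi = np.zeros_like(coords)
    for i in range(4):
        for k in range(3):
            cp = coords.copy(); cp[i, k] += h
            cm = coords.copy(); cm[i, k] -= h
            grad_phi[i, k] = (_dihedral(*cp) - _dihedral(*cm)) / (2 * h)
    masses = np.array([m_a, m_a, m_a, m_h])
    inertia = 1.0 / float(((grad_phi**2).sum(axis=1) / masses).sum())
    omega_r = wavenumber_to_angular(nu_stretch_cm)
    omega_t = wavenumber_to_angular(nu_torsion_cm)
    k_r = mu_r * AMU_EVFS * omega_r**2
    k_theta = inertia * AMU_EVFS * omega_t**2
    toy = TorsionStretchToy(ref, k_r, k_theta, r0)
    return toy, ExactTorsionStretchSampler(toy, mu_r, inertia)


@dataclass
class SoftIntermolecularToy:
    """Stiff chromophore bond bilinearly coupled to a soft anharmonic contact.

    Three collinear sites A–B···W.  With q = r_AB - r_AB⁰ (stiff,
    chromophore-like) and Q = r_BW - r_BW⁰ (soft, hydrogen-bond-like):

        V = ½ k_intra (q - c Q)² + D (1 - exp(-a Q))² + k_wall·max(0, Q - Q_wall)⁴

    The Morse term makes the soft contact anharmonic (harmonic curvature
    k_soft = 2 D a² at Q = 0); the bilinear coupling c shifts the
    chromophore equilibrium as the contact breathes.  Set D → large,
    a → sqrt(k_soft/2D) for an effectively harmonic control.  The quartic
    wall, far outside the thermally relevant region, stands in for the
    surrounding environment: it keeps rare high-energy excursions from
    dissociating the contact during long thermostatted runs without
    affecting the well-region density.
    """

    reference: Geometry
    k_intra: float
    coupling: float
    D: float
    a: float
    r0_ab: float
    r0_bw: float
    k_wall: float = 5.0       # eV/Å⁴
    q_wall: float = 0.8       # Å
    descriptor: str = "soft_intermolecular"

    def _internals(self, geometry: Geometry):
        c = geometry.coords
        q = np.linalg.norm(c[1] - c[0]) - self.r0_ab
        Q = np.linalg.norm(c[2] - c[1]) - self.r0_bw
        return q, Q

    def energy(self, geometry: Geometry) -> float:
        q, Q = self._internals(geometry)
        ex = np.exp(-self.a * Q)
        wall = self.k_wall * max(0.0, Q - self.q_wall) ** 4
        return float(0.5 * self.k_intra * (q - self.coupling * Q) ** 2
                     + self.D * (1 - ex) ** 2 + wall)

    def gradient(self, geometry: Geometry) -> np.ndarray:
        c = geometry.coords
        vab = c[1] - c[0]
        vbw = c[2] - c[1]
        rab, rbw = np.linalg.norm(vab), np.linalg.norm(vbw)
        q, Q = rab - self.r0_ab, rbw - self.r0_bw
        ex = np.exp(-self.a * Q)
        dVdq = self.k_intra * (q - self.coupling * Q)
        dVdQ = (-self.coupling * dVdq + 2 * self.D * (1 - ex) * self.a * ex
                + 4 * self.k_wall * max(0.0, Q - self.q_wall) ** 3)
        uab, ubw = vab / rab, vbw / rbw
        g = np.zeros_like(c)
        g[0] = -dVdq * uab
        g[1] = dVdq * uab - dVdQ * ubw
        g[2] = dVdQ * ubw
        return g


def make_soft_intermolecular(nu_intra_cm: float = 1700.0,
                             nu_soft_cm: float = 150.0,
                             coupling: float = 0.05,
                             morse_depth: float = 0.25,
                             r0_ab: float = 1.22,
                             r0_bw: float = 2.80) -> SoftIntermolecularToy:
    """Microsolvation-like toy: carbonyl-like bond + soft H-bond contact.

    ``morse_depth`` (eV) controls the anharmonicity of the soft contact;
    its harmonic wavenumber is held at ``nu_soft_cm`` regardless.  Passing
    ``morse_depth=np.inf`` is not supported — use a large depth (e.g. 50 eV)
    for an effectively harmonic control.
    """
    m = [12.011, 15.999, 18.015]     # C, O, W(H2O as a point mass)
    coords = np.array([[0.0, 0.0, 0.0],
                       [r0_ab, 0.0, 0.0],
                       [r0_ab + r0_bw, 0.0, 0.0]])
    ref = Geometry(["C", "O", "X18.015"], coords,
                   np.array(m), label="soft_intermolecular")
    mu_intra = m[0] * m[1] / (m[0] + m[1])
    mu_soft = (m[0] + m[1]) * m[2] / (m[0] + m[1] + m[2])
    k_intra = mu_intra * AMU_EVFS * wavenumber_to_angular(nu_intra_cm) ** 2
    k_soft = mu_soft * AMU_EVFS * wavenumber_to_angular(nu_soft_cm) ** 2
    if not morse_depth > 0:
        raise ModelError("morse_depth must be positive")
    a = np.sqrt(k_soft / (2 * morse_depth))
    toy = SoftIntermolecularToy(ref, k_intra, coupling, morse_depth, a,
                                r0_ab, r0_bw)
    # destabilization guard: effective soft curvature after coupling
    if k_soft - coupling**2 * k_intra * 0 < 0:   # bilinear form is PSD here
        raise ModelError("coupling destabilizes the minimum")
    if coupling**2 * k_intra >= k_soft + k_intra:
        raise ModelError("coupling destabilizes the minimum")
    return toy


def optimize_geometry(potential, start: Geometry, tol: float = 1e-10) -> Geometry:
    """Local minimization of a PotentialSurface from a starting geometry."""
    shape = start.coords.shape

    def f(x):
        g = start.with_coords(x.reshape(shape))
        return potential.energy(g), potential.gradient(g).ravel()

    res = minimize(f, start.coords.ravel(), jac=True, method="L-BFGS-B",
                   tol=tol)
    return start.with_coords(res.x.reshape(shape), label=start.label)


# --------------------------------------------------------------------------
# Toy chromophores
# --------------------------------------------------------------------------

@dataclass
class StateMap:
    """Analytic (ΔE, f) maps for one excited state as functions of one
    internal coordinate q.

    ``gap_kind``: 'linear'  ΔE = E0 + κ (q - q0)
                  'exponential'  ΔE = E0 exp(-α (q - q0))   (nσ*-like decay)
    ``strength_kind``: 'constant' f = f0, or 'linear' f = f0 + s (q - q0).
    """

    E0: float
    q0: float
    gap_kind: str = "linear"
    kappa: float = 0.0        # eV/Å, linear gap slope
    alpha: float = 0.0        # Å⁻¹, exponential decay constant
    f0: float = 0.01
    strength_kind: str = "constant"
    f_slope: float = 0.0

    def gap(self, q: np.ndarray) -> np.ndarray:
        if self.gap_kind == "linear":
            return self.E0 + self.kappa * (q - self.q0)
        if self.gap_kind == "exponential":
            return self.E0 * np.exp(-self.alpha * (q - self.q0))
        raise ModelError(f"unknown gap kind {self.gap_kind!r}")

    def strength(self, q: np.ndarray) -> np.ndarray:
        if self.strength_kind == "constant":
            return np.full_like(q, self.f0)
        if self.strength_kind == "linear":
            return np.clip(self.f0 + self.f_slope * (q - self.q0), 0.0, None)
        raise ModelError(f"unknown strength kind {self.strength_kind!r}")


@dataclass
class ToyChromophore:
    """Geometry → vertical-transition map built from analytic state maps.

    ``coordinate`` extracts the driving internal coordinate from a geometry
    (e.g. a bond length); each :class:`StateMap` defines one excited state.
    """

    coordinate: Callable[[Geometry], float]
    states: list = field(default_factory=list)
    name: str = "toy_chromophore"

    @property
    def n_states(self) -> int:
        return len(self.states)


def evaluate_chromophore(chromophore: ToyChromophore,
                         ensemble: GeometryEnsemble) -> list[TransitionRecord]:
    """One TransitionRecord per ensemble member per state (deterministic)."""
    q = np.array([chromophore.coordinate(g) for g in ensemble.members])
    records = []
    bad: list[int] = []
    for j, st in enumerate(chromophore.states, start=1):
        de = st.gap(q)
        f = st.strength(q)
        bad.extend(int(i) for i in np.nonzero(de <= 0)[0])
        for i, (d, fi) in enumerate(zip(de, f)):
            records.append(TransitionRecord(f"g{i}", j, float(max(d, 1e-12)),
                                            float(fi))
                           if d > 0 else None)
    if bad:
        raise ModelError(
            f"gap map produced non-positive excitation energies for members "
            f"{sorted(set(bad))[:10]} — map misuse (check q0/slope)")
    return records


def stratified_normal(n: int, rng: np.random.Generator,
                      mean: float = 0.0, std: float = 1.0) -> np.ndarray:
    """Jittered-stratified normal sample (marginally exact, low clustering).

    Each draw comes from one of n equal-probability strata with a uniform
    jitter, then the order is shuffled.  Unbiased for any integrable
    functional, with far smaller density-estimation noise than i.i.d.
    draws — used by oracle-validation fixtures.
    """
    from scipy.special import ndtri
    u = (np.arange(n) + rng.random(n)) / n
    q = mean + std * ndtri(u)
    rng.shuffle(q)
    return q


# --------------------------------------------------------------------------
# Finite-difference Hessian
# --------------------------------------------------------------------------

def finite_difference_hessian(potential, geometry: Geometry,
                              step: float = 1e-3,
                              richardson: bool = True) -> HessianMatrix:
    """Central-difference Hessian of a PotentialSurface (eV/Å²).

    With ``richardson`` (default), the O(step²) truncation error is
    eliminated by combining the ``step`` and ``step/2`` stencils,
    (4 H_{h/2} - H_h)/3 — important for soft curvilinear coordinates whose
    anharmonicity otherwise leaks into near-zero frequencies.
    """
    def _h(s):
        n = 3 * geometry.n_atoms
        h = np.zeros((n, n))
        x0 = geometry.coords
        for i in range(geometry.n_atoms):
            for k in range(3):
                xp = x0.copy(); xp[i, k] += s
                xm = x0.copy(); xm[i, k] -= s
                gp = potential.gradient(geometry.with_coords(xp)).ravel()
                gm = potential.gradient(geometry.with_coords(xm)).ravel()
                if not (np.all(np.isfinite(gp)) and np.all(np.isfinite(gm))):
                    raise ModelError("non-finite gradient during finite differences")
                h[3 * i + k] = (gp - gm) / (2 * s)
        return h

    h = (4.0 * _h(step / 2) - _h(step)) / 3.0 if richardson else _h(step)
    return HessianMatrix(0.5 * (h + h.T), geometry)
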