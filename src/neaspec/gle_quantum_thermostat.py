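"""Colored-noise generalized-Langevin (GLE) dynamics: the quantum thermostat.

A classical trajectory is thermostatted by a Markovian embedding of a
generalized Langevin equation: each Cartesian degree of freedom carries a
mass-weighted momentum u and Ns auxiliary momenta s, evolving between force
updates as

    d(u, s)/dt = -A (u, s) + B xi(t),     B B^T = A C + C A^T,

where A (fs⁻¹) is the drift matrix and C (eV) the stationary covariance of
(u, s) for a free particle.  With (A, C) fitted so that a harmonic
oscillator of frequency ω reaches position variance
(ħ/2mω)·coth(ħω/2k_BT), the dynamics samples an approximate quantum
nuclear distribution on arbitrary (anharmonic) potentials while remaining
exact for uncoupled harmonic oscillators.

The integrator is a symmetric splitting:
GLE half-step → velocity half-kick → position drift → force refresh →
velocity half-kick → GLE half-step.  The GLE substep uses the exact
Ornstein–Uhlenbeck update  (u,s) ← T (u,s) + S xi  with
T = exp(-A dt/2) and S S^T = C - T C T^T, so the thermostat itself
introduces no time-step error.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
from scipy.linalg import expm, solve_continuous_lyapunov

from .constants import AMU_EVFS, KB
from .io_formats import Geometry, GLEParameterFile, ValidationError
from .wigner_sampler import GeometryEnsemble


class ParameterError(ValueError):
    """Raised for unusable GLE parameter matrices."""


class PotentialSurface(Protocol):
    """Contract for ground-state potentials (analytic or external)."""

    def energy(self, geometry: Geometry) -> float: ...
    def gradient(self, geometry: Geometry) -> np.ndarray: ...


@dataclass
class QTSettings:
    """Molecular-dynamics settings for quantum-thermostat sampling."""

    dt: float = 0.5                   # fs
    n_steps: int = 10000
    equilibration_window: int = 1000  # steps
    temperature_tolerance: float = 0.05
    stride: int = 1                   # snapshot interval in steps
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if self.stride < 1:
            raise ValidationError("stride must be >= 1")
        if not 0 < self.temperature_tolerance < 1:
            raise ValidationError("temperature tolerance must be in (0, 1)")


@dataclass
class Trajectory:
    """QT trajectory: snapshot frames plus per-step diagnostic series."""

    frames: list                       # list[Geometry], every `stride` steps
    velocities: np.ndarray             # (n_frames, n_atoms, 3), Å/fs
    kinetic_temperature: np.ndarray    # (n_steps,), K
    potential_energy: np.ndarray       # (n_steps,), eV
    settings_hash: str = ""
    conformer_label: str = ""


def build_propagator(gle: GLEParameterFile, dt: float,
                     tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Precompute the exact half-step GLE propagator pair (T_half, S_half).

    T_half = exp(-(dt/2) A); S_half satisfies S S^T = C - T C T^T (symmetric
    square root).  Raises ParameterError when C - T C T^T has negative
    eigenvalues beyond tolerance (an unstable A/C pair).
    """
    A, C = gle.A_matrix, gle.C_matrix
    t_half = expm(-0.5 * dt * A)
    m = C - t_half @ C @ t_half.T
    m = 0.5 * (m + m.T)
    evals, evecs = np.linalg.eigh(m)
    scale = max(evals.max(), 1.0e-300)
    if evals.min() < -tol * scale:
        raise ParameterError(
            f"C - T C T^T indefinite (min eigenvalue {evals.min():.3e}); "
            "the A/C pair does not define a valid stationary process")
    s_half = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None))) @ evecs.T
    return t_half, s_half


def harmonic_stationary_variance(gle: GLEParameterFile, omega: float,
                                 mass_amu: float = 1.0):
    """Exact stationary (position, momentum) variance of a GLE-thermostatted
    harmonic oscillator, from the continuous Lyapunov equation.

    Returns ``(var_x, var_v)`` in Å² and (Å/fs)² for the given angular
    frequency (fs⁻¹) and mass (amu).  This is the design target of the
    thermostat fit and a strong oracle for the integrator.
    """
    A, C = gle.A_matrix, gle.C_matrix
    n = A.shape[0]
    F = np.zeros((n + 1, n + 1))
    F[0, 1] = 1.0
    F[1, 0] = -omega**2
    F[1:, 1:] = -A
    D = np.zeros((n + 1, n + 1))
    D[1:, 1:] = A @ C + C @ A.T
    S = solve_continuous_lyapunov(F, -D)
    m_int = mass_amu * AMU_EVFS
    return S[0, 0] / m_int, S[1, 1] / m_int


def run_qt(potential: PotentialSurface, start: Geometry,
           gle: GLEParameterFile, settings: QTSettings) -> Trajectory:
    """Propagate GLE-thermostatted dynamics from ``start``.

    The thermostat acts per Cartesian degree of freedom on mass-weighted
    momenta, so a single (A, C) pair serves all atoms.  Reproducible for a
    fixed seed.  Aborts on non-finite energies or single-step displacements
    beyond 0.5 Å (blow-up guard).
    """
    t_half, s_half = build_propagator(gle, settings.dt)
    rng = np.random.default_rng(settings.seed)
    n_atoms = start.n_atoms
    ndof = 3 * n_atoms
    m_int = np.repeat(start.masses, 3) * AMU_EVFS      # eV fs^2/Å^2
    sqrt_m = np.sqrt(m_int)

    x = start.coords.ravel().copy()
    # initial velocities from the classical Maxwell-Boltzmann distribution
    u = rng.standard_normal(ndof) * np.sqrt(KB * gle.target_temperature)
    aux = rng.standard_normal((ndof, gle.n_aux)) * 0.0
    state = np.concatenate([u[:, None], aux], axis=1)   # (ndof, 1+Ns)

    def gle_half(state):
        noise = rng.standard_normal(state.shape)
        return state @ t_half.T + noise @ s_half.T

    geom = start.with_coords(x.reshape(-1, 3))
    force = -potential.gradient(geom).ravel()
    n_steps, dt, stride = settings.n_steps, settings.dt, settings.stride
    kin_t = np.empty(n_steps)
    pot_e = np.empty(n_steps)
    frames, vels = [], []
    for step in range(n_steps):
        state = gle_half(state)
        state[:, 0] += force / sqrt_m * (0.5 * dt)
        dx = state[:, 0] / sqrt_m * dt
        if np.abs(dx).max() > 0.5:
            raise RuntimeError(
                f"blow-up guard: step {step} displacement {np.abs(dx).max():.2f} Å "
                "exceeds 0.5 Å; reduce dt or check the potential")
        x = x + dx
        geom = start.with_coords(x.reshape(-1, 3), label=f"qt:{step}")
        e = potential.energy(geom)
        g = potential.gradient(geom)
        if not np.isfinite(e) or not np.all(np.isfinite(g)):
            raise RuntimeError(f"non-finite energy/gradient at step {step}")
        force = -g.ravel()
        state[:, 0] += force / sqrt_m * (0.5 * dt)
        state = gle_half(state)
        kin_t[step] = np.sum(state[:, 0] ** 2) / (ndof * KB)
        pot_e[step] = e
        if (step + 1) % stride == 0:
            frames.append(geom)
            vels.append((state[:, 0] / sqrt_m).reshape(-1, 3).copy())
    desc = {"sampler": "qt", "dt": dt, "n_steps": n_steps,
            "stride": stride, "seed": settings.seed,
            "temperature_K": gle.target_temperature}
    digest = hashlib.sha256(json.dumps(desc, sort_keys=True).encode()).hexdigest()[:16]
    return Trajectory(frames, np.array(vels), kin_t, pot_e,
                      settings_hash=digest, conformer_label=start.label)


def detect_equilibration(trajectory: Trajectory, settings: QTSettings) -> int:
    """First step index from which the kinetic temperature is converged.

    Returns the smallest index i where the mean over
    ``[i, i + equilibration_window)`` is within ``temperature_tolerance``
    (relative) of the mean over the remaining trajectory ``[i, end)``.
    """
    t = np.asarray(trajectory.kinetic_temperature, float)
    if t.size == 0:
        raise ValidationError("empty temperature series")
    w = min(settings.equilibration_window, t.size)
    cs = np.concatenate([[0.0], np.cumsum(t)])
    n = t.size
    # require the remaining trajectory to extend beyond the window itself,
    # otherwise the comparison becomes trivially self-fulfilling at the tail
    for i in range(0, max(n - 2 * w + 1, 1)):
        win_mean = (cs[i + w] - cs[i]) / w
        rest_mean = (cs[n] - cs[i]) / (n - i)
        if abs(win_mean - rest_mean) <= settings.temperature_tolerance * rest_mean:
            return i
    raise RuntimeError(
        "kinetic temperature never converged within tolerance; "
        "run a longer trajectory or widen the equilibration window")


def extract_snapshots(trajectory: Trajectory, n_samples: int,
                      equilibrated_from: int = 0,
                      stride: int = 1) -> GeometryEnsemble:
    """Pick ``n_samples`` frames at uniform stride over the equilibrated tail.

    ``equilibrated_from`` is a step index; frames before it are discarded.
    ``stride`` is the trajectory's own snapshot interval in steps.
    """
    first_frame = int(np.ceil(equilibrated_from / stride))
    avail = len(trajectory.frames) - first_frame
    if avail < n_samples:
        need = (n_samples + first_frame) * stride
        raise ValidationError(
            f"only {max(avail, 0)} equilibrated frames available for "
            f"{n_samples} samples; run at least {need} steps")
    idx = first_frame + (np.arange(n_samples) * (avail // n_samples))
    members = [trajectory.frames[i] for i in idx]
    prov = {"sampler": "qt", "trajectory_hash": trajectory.settings_hash,
            "frame_indices": [int(i) for i in idx]}
    return GeometryEnsemble(members, provenance=prov,
                            conformer_label=trajectory.conformer_label)
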