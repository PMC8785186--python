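"""Harmonic Wigner sampling of the vibrational ground state.

For a harmonic mode of angular frequency ω at temperature T, the Wigner
density of the thermal state is Gaussian with

    Var(Q) = (ħ / 2ω) · coth(ħω / 2k_BT)        (amu Å², Q mass-weighted)
    Var(P) = (ħω / 2) · coth(ħω / 2k_BT)        (amu Å²/fs²)

At T = 0 the coth factor is 1 and the distribution is the ground-state
Wigner function.  Cartesian geometries are recovered through the
rectilinear back-transform  x = x_ref + M^(-1/2) Σ_i L_i Q_i — deliberately
without curvilinear corrections, so the well-known overstretching artifact
of softly-torsional light atoms is reproducible and can be mitigated by
excluding modes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .constants import HBAR, HBAR_AMU, KB, wavenumber_to_angular
from .io_formats import Geometry, ValidationError
from .vibrational_analysis import NormalModeSet


class SamplingError(ValueError):
    """Raised when sampling preconditions are violated."""


@dataclass
class WignerSettings:
    """Settings for Wigner ensemble generation."""

    n_samples: int = 500
    temperature: float = 0.0          # K
    excluded_mode_indices: frozenset = frozenset()
    seed: int = 0
    sample_momenta: bool = False

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.temperature < 0:
            raise ValidationError("temperature must be >= 0")
        self.excluded_mode_indices = frozenset(self.excluded_mode_indices)


@dataclass
class GeometryEnsemble:
    """A set of sampled nuclear configurations with provenance."""

    members: list                      # list[Geometry]
    normal_coordinates: np.ndarray = None    # (n_samples, n_modes), amu^1/2 Å
    momenta: np.ndarray = None               # (n_samples, n_modes) or None
    provenance: dict = field(default_factory=dict)
    conformer_label: str = ""

    def __post_init__(self):
        if not self.members:
            raise ValidationError("ensemble must contain at least one member")
        ref = self.members[0]
        for g in self.members[1:]:
            if g.symbols != ref.symbols or not np.allclose(g.masses, ref.masses):
                raise ValidationError("ensemble members must share atoms/masses")

    def __len__(self):
        return len(self.members)

    @property
    def coords(self) -> np.ndarray:
        """(n_samples, n_atoms, 3) coordinate stack."""
        return np.stack([g.coords for g in self.members])


def thermal_variances(modes: NormalModeSet, temperature: float,
                      indices=None) -> tuple[np.ndarray, np.ndarray]:
    """Per-mode Wigner variances (Var(Q), Var(P)) at the given temperature."""
    idx = np.arange(modes.n_modes) if indices is None else np.asarray(indices)
    nu = modes.frequencies[idx]
    if np.any(nu <= 0):
        raise SamplingError("thermal variances undefined for imaginary modes")
    omega = wavenumber_to_angular(nu)
    if temperature > 0:
        coth = 1.0 / np.tanh(HBAR * omega / (2.0 * KB * temperature))
    else:
        coth = np.ones_like(omega)
    var_q = HBAR_AMU / (2.0 * omega) * coth
    var_p = HBAR_AMU * omega / 2.0 * coth
    return var_q, var_p


def sample_wigner(modes: NormalModeSet, settings: WignerSettings) -> GeometryEnsemble:
    """Draw a geometry (and optionally momentum) ensemble from the Wigner
    distribution of the harmonic ground (or thermal) state.

    Excluded modes are frozen at Q = P = 0 exactly.
    """
    bad = [i for i in settings.excluded_mode_indices
           if i < 0 or i >= modes.n_modes]
    if bad:
        raise SamplingError(f"excluded mode indices out of range: {sorted(bad)}")
    active = [i for i in range(modes.n_modes)
              if i not in settings.excluded_mode_indices]
    imag = [i for i in active if modes.frequencies[i] <= 0]
    if imag:
        raise SamplingError(
            "Wigner sampling refused: imaginary/zero frequencies at mode "
            f"indices {imag} (wavenumbers "
            f"{[round(float(modes.frequencies[i]), 2) for i in imag]} cm^-1); "
            "exclude them or re-optimize the geometry")
    var_q, var_p = thermal_variances(modes, settings.temperature, active)
    rng = np.random.default_rng(settings.seed)
    n, n_modes = settings.n_samples, modes.n_modes
    q = np.zeros((n, n_modes))
    q[:, active] = rng.standard_normal((n, len(active))) * np.sqrt(var_q)
    p = None
    if settings.sample_momenta:
        p = np.zeros((n, n_modes))
        p[:, active] = rng.standard_normal((n, len(active))) * np.sqrt(var_p)

    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(modes.geometry.masses, 3))
    # Cartesian displacements: (n, 3N) = Q @ L, then un-mass-weight
    disp = (q @ modes.mode_vectors) * inv_sqrt_m
    ref = modes.geometry
    members = [ref.with_coords(ref.coords + d.reshape(-1, 3),
                               label=f"wigner:{k}")
               for k, d in enumerate(disp)]
    settings_desc = {
        "sampler": "wigner", "n_samples": n,
        "temperature_K": settings.temperature,
        "excluded_modes": sorted(settings.excluded_mode_indices),
        "seed": settings.seed, "sample_momenta": settings.sample_momenta,
    }
    digest = hashlib.sha256(
        json.dumps(settings_desc, sort_keys=True).encode()).hexdigest()[:16]
    return GeometryEnsemble(members, normal_coordinates=q, momenta=p,
                            provenance={**settings_desc, "settings_hash": digest},
                            conformer_label=ref.label)


def classical_limit_check(modes: NormalModeSet, temperature: float) -> np.ndarray:
    """Per-mode ratio of quantum to classical position variance.

    Returns (ħω/2k_BT)·coth(ħω/2k_BT) for each mode — always ≥ 1, tending
    to 1 in the classical limit ħω ≪ k_BT and to ħω/2k_BT for stiff modes.
    """
    if temperature <= 0:
        raise SamplingError("classical variance undefined at T = 0")
    nu = modes.frequencies
    if np.any(nu <= 0):
        raise SamplingError("ratio undefined for imaginary modes")
    omega = wavenumber_to_angular(nu)
    x = HBAR * omega / (2.0 * KB * temperature)
    return x / np.tanh(x)
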