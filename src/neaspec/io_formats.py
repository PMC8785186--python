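"""Readers and writers for on-disk artifacts.

Formats handled here:

* multi-frame XYZ geometry files (coordinates in Å),
* vibrational-frequency files (Molden ``[FREQ]`` dialect, with
  ``[FR-COORD]`` in Bohr, or a JSON fixture format),
* vertical-transition tables (CSV: ``geometry_id,state,delta_E_eV,osc_strength``),
* GLE thermostat matrices (whitespace-delimited square matrices),
* spectra (CSV: ``energy_eV,wavelength_nm,sigma_cm2``),
* actinic-flux / quantum-yield tables (CSV: ``wavelength_nm,value``).

Every writer records units in its header or comment line; every
reader/writer pair is a lossless round trip at the printed precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import ATOMIC_MASSES, BOHR_ANG, KB, ev_to_nm


class FormatError(ValueError):
    """Raised when an on-disk artifact cannot be parsed."""


class ValidationError(ValueError):
    """Raised when parsed content violates a domain invariant."""


def mass_for_symbol(symbol: str) -> float:
    """Standard atomic weight for a chemical symbol.

    Symbols of the form ``X`` or ``X<mass>`` (e.g. ``X16``) denote model-system
    pseudo-atoms; ``X`` alone defaults to 1 amu.
    """
    if symbol in ATOMIC_MASSES:
        return ATOMIC_MASSES[symbol]
    if symbol.startswith("X"):
        tail = symbol[1:]
        if not tail:
            return 1.0
        try:
            return float(tail)
        except ValueError:
            raise FormatError(f"unknown pseudo-atom symbol {symbol!r}") from None
    raise FormatError(f"unknown element symbol {symbol!r}")


@dataclass
class Geometry:
    """A molecular geometry: symbols, Cartesian coordinates (Å), masses (amu)."""

    symbols: list[str]
    coords: np.ndarray            # (n_atoms, 3), Å
    masses: np.ndarray = None     # (n_atoms,), amu
    label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 1:
            self.coords = self.coords.reshape(-1, 3)
        if self.coords.shape != (len(self.symbols), 3):
            raise ValidationError(
                f"coordinates shape {self.coords.shape} does not match "
                f"{len(self.symbols)} atoms"
            )
        if self.masses is None:
            self.masses = np.array([mass_for_symbol(s) for s in self.symbols])
        else:
            self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (len(self.symbols),):
            raise ValidationError("masses length does not match atom count")
        if np.any(self.masses <= 0):
            raise ValidationError("masses must be strictly positive")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Geometry":
        return Geometry(list(self.symbols), np.asarray(coords, float),
                        self.masses.copy(), self.label if label is None else label)


@dataclass(frozen=True)
class TransitionRecord:
    """One vertical transition: ΔE_0J (eV) and oscillator strength f_0J."""

    geometry_id: str
    state_index: int
    delta_E: float        # eV, > 0
    osc_strength: float   # dimensionless, >= 0

    def __post_init__(self):
        if self.state_index < 1:
            raise ValidationError(f"state index must be >= 1, got {self.state_index}")
        if not self.delta_E > 0:
            raise ValidationError(
                f"delta_E must be positive, got {self.delta_E} "
                f"(geometry {self.geometry_id}, state {self.state_index})")
        if self.osc_strength < 0:
            raise ValidationError(
                f"oscillator strength must be >= 0, got {self.osc_strength} "
                f"(geometry {self.geometry_id}, state {self.state_index})")


@dataclass
class GLEParameterFile:
    """GLE drift matrix A (fs⁻¹) and stationary covariance C (eV).

    ``A`` and ``C`` act on the (Ns+1)-vector of the physical mass-weighted
    momentum plus Ns auxiliary momenta.
    """

    A_matrix: np.ndarray
    C_matrix: np.ndarray
    target_temperature: float   # K
    classical_default: bool = False   # True when C was defaulted to kT * I

    def __post_init__(self):
        self.A_matrix = np.asarray(self.A_matrix, float)
        self.C_matrix = np.asarray(self.C_matrix, float)
        a, c = self.A_matrix, self.C_matrix
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError("A matrix must be square")
        if c.shape != a.shape:
            raise ValidationError(
                f"C matrix shape {c.shape} does not match A shape {a.shape}")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValidationError("C matrix must be symmetric")
        if np.linalg.eigvalsh(0.5 * (c + c.T)).min() <= 0:
            raise ValidationError("C matrix must be positive definite")

    @property
    def n_aux(self) -> int:
        """Number of auxiliary momenta Ns."""
        return self.A_matrix.shape[0] - 1


# --------------------------------------------------------------------------
# XYZ
# --------------------------------------------------------------------------

def read_xyz(path) -> list[Geometry]:
    """Read a (multi-frame) XYZ file; comment lines become geometry labels."""
    lines = Path(path).read_text().splitlines()
    geometries = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"{path}: line {i + 1}: expected atom count, "
                              f"got {lines[i]!r}") from None
        if i + 1 + n >= len(lines) + 1:
            raise FormatError(f"{path}: line {i + 1}: header announces {n} atoms "
                              f"but the file ends early")
        label = lines[i + 1].strip()
        symbols, coords = [], []
        for k in range(n):
            ln = i + 2 + k
            if ln >= len(lines):
                raise FormatError(f"{path}: line {ln + 1}: missing atom line "
                                  f"({n} announced)")
            parts = lines[ln].split()
            if len(parts) < 4:
                raise FormatError(f"{path}: line {ln + 1}: expected "
                                  f"'symbol x y z', got {lines[ln]!r}")
            symbols.append(parts[0])
            try:
                coords.append([float(p) for p in parts[1:4]])
            except ValueError:
                raise FormatError(f"{path}: line {ln + 1}: coordinate parse "
                                  f"failure in {lines[ln]!r}") from None
        for s in symbols:
            mass_for_symbol(s)   # validates the symbol
        geometries.append(Geometry(symbols, np.array(coords), label=label))
        i += 2 + n
    if not geometries:
        raise FormatError(f"{path}: no frames found")
    return geometries


def write_xyz(geometries: Iterable[Geometry], path) -> None:
    """Write geometries as multi-frame XYZ (Å, 10 decimal places)."""
    out = []
    for g in geometries:
        out.append(f"{g.n_atoms}")
        out.append(g.label or "")
        for s, (x, y, z) in zip(g.symbols, g.coords):
            out.append(f"{s:<4s} {x: .10f} {y: .10f} {z: .10f}")
    Path(path).write_text("\n".join(out) + "\n")


# --------------------------------------------------------------------------
# Frequency files
# --------------------------------------------------------------------------

def read_frequencies(path, dialect: str = "molden"):
    """Read frequencies and raw mode vectors.

    Returns ``(geometry, frequencies_cm, mode_vectors)`` where
    ``mode_vectors`` is an (n_modes, 3*n_atoms) array of raw (not yet
    mass-weighted or normalized) Cartesian displacement patterns.
    """
    if dialect == "molden":
        return _read_molden_frequencies(path)
    if dialect == "json-fixture":
        return _read_json_frequencies(path)
    raise ValueError(f"unknown frequency dialect {dialect!r}")


def _read_molden_frequencies(path):
    text = Path(path).read_text()
    sections: dict[str, list[str]] = {}
    current = None
    for line in text.splitlines():
        s = line.strip()
        if s.startswith("["):
            current = s.split("]")[0].strip("[").upper()
            sections[current] = []
        elif current is not None and s:
            sections[current].append(s)
    for req in ("FREQ", "FR-COORD", "FR-NORM-COORD"):
        if req not in sections:
            raise FormatError(f"{path}: missing [{req}] section")
    freqs = np.array([float(x) for x in sections["FREQ"]])
    symbols, coords = [], []
    for ln in sections["FR-COORD"]:
        parts = ln.split()
        if len(parts) != 4:
            raise FormatError(f"{path}: bad [FR-COORD] line {ln!r}")
        symbols.append(parts[0])
        coords.append([float(p) * BOHR_ANG for p in parts[1:4]])  # Bohr -> Å
    geometry = Geometry(symbols, np.array(coords), label=f"molden:{path}")
    n_cart = 3 * geometry.n_atoms
    modes: list[list[float]] = []
    vib = None
    for ln in sections["FR-NORM-COORD"]:
        if ln.lower().startswith("vibration"):
            if vib is not None:
                modes.append(vib)
            vib = []
        else:
            if vib is None:
                raise FormatError(f"{path}: mode data before 'vibration' header")
            vib.extend(float(p) for p in ln.split())
    if vib is not None:
        modes.append(vib)
    if len(modes) != len(freqs):
        raise FormatError(f"{path}: {len(freqs)} frequencies but "
                          f"{len(modes)} mode vectors")
    for k, m in enumerate(modes):
        if len(m) != n_cart:
            raise FormatError(f"{path}: mode {k + 1} has {len(m)} components, "
                              f"expected {n_cart}")
    return geometry, freqs, np.array(modes)


def _read_json_frequencies(path):
    data = json.loads(Path(path).read_text())
    geometry = Geometry(data["symbols"], np.array(data["coords_angstrom"]),
                        np.array(data["masses_amu"]) if "masses_amu" in data else None,
                        label=data.get("label", ""))
    freqs = np.array(data["frequencies_cm"], float)
    modes = np.array(data["mode_vectors"], float)
    if modes.ndim != 2 or modes.shape[0] != len(freqs):
        raise FormatError(f"{path}: mode vector count does not match frequencies")
    if modes.shape[1] != 3 * geometry.n_atoms:
        raise FormatError(f"{path}: mode length {modes.shape[1]} != "
                          f"3*n_atoms = {3 * geometry.n_atoms}")
    return geometry, freqs, modes


def write_molden_frequencies(geometry: Geometry, freqs_cm: np.ndarray,
                             modes: np.ndarray, path,
                             mass_weighted: bool = True) -> None:
    """Write a Molden-dialect frequency file ([FR-COORD] in Bohr).

    [FR-NORM-COORD] holds Cartesian displacement patterns (the Molden
    convention).  With ``mass_weighted`` (default), ``modes`` are taken as
    orthonormal mass-weighted vectors L_i and converted to Cartesian
    displacements L_i / sqrt(m) before writing.
    """
    modes = np.asarray(modes, float)
    if mass_weighted:
        modes = modes / np.sqrt(np.repeat(geometry.masses, 3))
    lines = ["[Molden Format]", "[FREQ]"]
    lines += [f"{f: .6f}" for f in np.asarray(freqs_cm)]
    lines.append("[FR-COORD]")
    for s, xyz in zip(geometry.symbols, geometry.coords):
        b = xyz / BOHR_ANG
        lines.append(f"{s:<4s} {b[0]: .10f} {b[1]: .10f} {b[2]: .10f}")
    lines.append("[FR-NORM-COORD]")
    for k, mode in enumerate(np.asarray(modes)):
        lines.append(f"vibration {k + 1}")
        for a in range(0, len(mode), 3):
            lines.append(f" {mode[a]: .10f} {mode[a+1]: .10f} {mode[a+2]: .10f}")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Transition tables
# --------------------------------------------------------------------------

_TT_COLUMNS = ["geometry_id", "state", "delta_E_eV", "osc_strength"]


def read_transition_table(path) -> list[TransitionRecord]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in _TT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bad = df[(df["delta_E_eV"] <= 0) | (df["osc_strength"] < 0)]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad.index[:10])
        raise ValidationError(
            f"{path}: invalid transitions (delta_E <= 0 or f < 0) at rows {rows}")
    records = [
        TransitionRecord(str(r.geometry_id), int(r.state), float(r.delta_E_eV),
                         float(r.osc_strength))
        for r in df.itertuples()
    ]
    seen = set()
    for r in records:
        key = (r.geometry_id, r.state_index)
        if key in seen:
            raise ValidationError(f"{path}: duplicate (geometry, state) pair {key}")
        seen.add(key)
    return records


def write_transition_table(records: Sequence[TransitionRecord], path) -> None:
    df = pd.DataFrame(
        {"geometry_id": [r.geometry_id for r in records],
         "state": [r.state_index for r in records],
         "delta_E_eV": [r.delta_E for r in records],
         "osc_strength": [r.osc_strength for r in records]})
    with open(path, "w") as fh:
        fh.write("# vertical transitions: energies in eV, "
                 "oscillator strengths dimensionless\n")
        df.to_csv(fh, index=False, float_format="%.17g")


# --------------------------------------------------------------------------
# GLE matrices
# --------------------------------------------------------------------------

def _read_matrix(path) -> np.ndarray:
    rows = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        rows.append([float(x) for x in s.split()])
    m = np.array(rows, float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError(f"{path}: matrix is not square (shape {m.shape})")
    return m


def read_gle_parameters(path_A, path_C=None, temperature: float = 296.0,
                        A_unit: str = "fs^-1", C_unit: str = "eV") -> GLEParameterFile:
    """Read GLE (A, C) matrices from plain-text files.

    ``A_unit`` may be ``fs^-1`` or ``ps^-1``; ``C_unit`` may be ``eV`` or
    ``K`` (each element multiplied by k_B).  When ``path_C`` is omitted, C
    defaults to k_B*T times the identity — the classical white-noise limit —
    and the returned object is flagged ``classical_default``.
    """
    A = _read_matrix(path_A)
    if A_unit == "ps^-1":
        A = A / 1000.0
    elif A_unit != "fs^-1":
        raise ValueError(f"unsupported A unit {A_unit!r}")
    if path_C is None:
        C = KB * temperature * np.eye(A.shape[0])
        return GLEParameterFile(A, C, temperature, classical_default=True)
    C = _read_matrix(path_C)
    if C_unit == "K":
        C = C * KB
    elif C_unit != "eV":
        raise ValueError(f"unsupported C unit {C_unit!r}")
    if C.shape != A.shape:
        raise ValidationError(
            f"A is {A.shape[0]}x{A.shape[0]} but C is {C.shape[0]}x{C.shape[0]}")
    return GLEParameterFile(A, C, temperature)


def write_gle_matrix(matrix: np.ndarray, path, comment: str = "") -> None:
    lines = [f"# {c}" for c in comment.splitlines()] if comment else []
    for row in np.asarray(matrix):
        lines.append(" ".join(f"{x: .16e}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Spectra and flux/yield tables
# --------------------------------------------------------------------------

def write_spectrum(spectrum, path) -> None:
    """Write a spectrum as CSV (energy_eV, wavelength_nm, sigma_cm2)."""
    grid = np.asarray(spectrum.energy_grid)
    if grid.size == 0:
        raise ValidationError("cannot write an empty spectrum")
    if np.any(np.diff(grid) <= 0):
        raise ValidationError("spectrum grid must be strictly increasing")
    with open(path, "w") as fh:
        fh.write("# photoabsorption cross-section: energy in eV, vacuum "
                 "wavelength in nm, sigma in cm^2 molecule^-1\n")
        fh.write("energy_eV,wavelength_nm,sigma_cm2\n")
        for e, s in zip(grid, spectrum.sigma):
            fh.write(f"{e:.8g},{ev_to_nm(e):.8g},{s:.8g}\n")


def read_spectrum(path):
    from .nea_spectrum import Spectrum
    df = pd.read_csv(path, comment="#")
    return Spectrum(df["energy_eV"].to_numpy(), df["sigma_cm2"].to_numpy())


def read_wavelength_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a CSV table (wavelength_nm, value): actinic flux or quantum yield."""
    df = pd.read_csv(path, comment="#")
    cols = list(df.columns)
    if "wavelength_nm" not in cols or len(cols) < 2:
        raise FormatError(f"{path}: expected columns 'wavelength_nm,<value>'")
    value_col = [c for c in cols if c != "wavelength_nm"][0]
    wl = df["wavelength_nm"].to_numpy(float)
    if np.any(np.diff(wl) <= 0):
        raise ValidationError(f"{path}: wavelengths must be strictly increasing")
    return wl, df[value_col].to_numpy(float)


def write_wavelength_table(wavelength_nm, values, path, value_name="value",
                           comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write(f"wavelength_nm,{value_name}\n")
        for w, v in zip(wavelength_nm, values):
            fh.write(f"{w:.8g},{v:.8g}\n")
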