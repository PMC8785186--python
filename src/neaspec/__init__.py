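"""neaspec: nuclear-ensemble photoabsorption cross-sections for small molecules.

Pipeline: harmonic analysis → quantum sampling (Wigner or GLE quantum
thermostat) → per-geometry vertical transitions (file contract or analytic
toy chromophores) → absolute cross-section assembly → photolysis rates.
"""

from .constants import K_PREFACTOR, HBAR, KB
from .io_formats import (
    FormatError, Geometry, GLEParameterFile, TransitionRecord, ValidationError,
    read_frequencies, read_gle_parameters, read_transition_table, read_xyz,
    write_spectrum, write_transition_table, write_xyz,
)
from .vibrational_analysis import (
    HessianMatrix, NormalModeSet, eckart_project, normal_mode_analysis,
)
from .wigner_sampler import (
    GeometryEnsemble, SamplingError, WignerSettings, classical_limit_check,
    sample_wigner,
)
from .gle_quantum_thermostat import (
    QTSettings, Trajectory, build_propagator, detect_equilibration,
    extract_snapshots, harmonic_stationary_variance, run_qt,
)
from .model_systems import (
    ToyChromophore, StateMap, evaluate_chromophore, finite_difference_hessian,
    make_soft_intermolecular, make_torsion_stretch, optimize_geometry,
)
from .nea_spectrum import (
    ConformerWeights, LineShapeSpec, Spectrum, assemble_sigma,
    boltzmann_weights, combine_conformers, composite_spectrum,
    integrated_strength, reflection_reference,
)
from .photolysis import FluxTable, QuantumYieldTable, photolysis_rate
from .ensemble_analysis import (
    InternalCoordinateSpec, compare_samplers, coordinate_series, histogram,
)

__version__ = "0.1.0"


def bundled_qt_parameters(temperature: float = 296.0) -> GLEParameterFile:
    """The fitted quantum-thermostat (A, C) matrix pair bundled with the
    package (Ns = 6, fitted at 296 K for 160–3700 cm⁻¹)."""
    from importlib.resources import files
    data = files("neaspec") / "data"
    return read_gle_parameters(str(data / "gle_qt_296K_A.txt"),
                               str(data / "gle_qt_296K_C.txt"),
                               temperature)
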