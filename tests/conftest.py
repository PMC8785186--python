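import numpy as np
import pytest

import neaspec as ns
from neaspec.io_formats import Geometry
from neaspec.model_systems import (
    finite_difference_hessian, make_soft_intermolecular, make_torsion_stretch,
)
from neaspec.vibrational_analysis import eckart_project, normal_mode_analysis


@pytest.fixture(scope="session")
def torsion_toy():
    """Torsion-stretch toy (3600 / 200 cm^-1) plus its exact sampler."""
    return make_torsion_stretch()


@pytest.fixture(scope="session")
def torsion_modes(torsion_toy):
    toy, _ = torsion_toy
    hess = finite_difference_hessian(toy, toy.reference)
    return normal_mode_analysis(eckart_project(hess))


@pytest.fixture(scope="session")
def soft_toy():
    return make_soft_intermolecular()


@pytest.fixture(scope="session")
def qt_parameters():
    return ns.bundled_qt_parameters()


@pytest.fixture
def water_like():
    """Bent 3-atom geometry (no potential attached)."""
    return Geometry(
        ["O", "H", "H"],
        np.array([[0.0, 0.0, 0.0],
                  [0.9572, 0.0, 0.0],
                  [-0.2400, 0.9266, 0.0]]),
        label="water-like")


def synthetic_mode_set(frequencies_cm, seed=0):
    """NormalModeSet with prescribed wavenumbers on a 3-atom scaffold.

    Mode vectors are an arbitrary orthonormal triple orthogonal to nothing
    in particular — sufficient for sampling-statistics tests that live
    entirely in normal-coordinate space.
    """
    from neaspec.vibrational_analysis import NormalModeSet
    rng = np.random.default_rng(seed)
    geom = Geometry(["O", "H", "H"],
                    rng.normal(0, 1, (3, 3)), label="synthetic")
    q, _ = np.linalg.qr(rng.normal(0, 1, (9, len(frequencies_cm))))
    return NormalModeSet(np.asarray(frequencies_cm, float), q.T, geom)
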