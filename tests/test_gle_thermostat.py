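import numpy as np
import pytest

import neaspec as ns
from neaspec.constants import AMU_EVFS, KB, wavenumber_to_angular
from neaspec.gle_quantum_thermostat import (
    ParameterError, QTSettings, Trajectory, build_propagator,
    detect_equilibration, extract_snapshots, harmonic_stationary_variance,
    run_qt,
)
from neaspec.io_formats import GLEParameterFile, ValidationError
from neaspec.model_systems import make_isotropic_oscillator

TEMP = 296.0


def white_noise_gle(gamma=0.01, temp=TEMP):
    return GLEParameterFile(np.array([[gamma]]), np.array([[KB * temp]]), temp)


class TestPropagator:
    def test_free_dynamics_limit(self):
        """A = 0 gives the identity propagator and no noise."""
        gle = GLEParameterFile(np.zeros((1, 1)), np.array([[KB * TEMP]]), TEMP)
        t_half, s_half = build_propagator(gle, 0.5)
        np.testing.assert_allclose(t_half, [[1.0]])
        np.testing.assert_allclose(s_half, [[0.0]], atol=1e-12)

    def test_white_noise_closed_form(self):
        gamma, dt = 0.02, 0.5
        t_half, s_half = build_propagator(white_noise_gle(gamma), dt)
        np.testing.assert_allclose(t_half, [[np.exp(-gamma * dt / 2)]])
        np.testing.assert_allclose(
            s_half[0, 0] ** 2, KB * TEMP * (1 - np.exp(-gamma * dt)),
            rtol=1e-12)

    def test_bundled_matrices_factorization(self, qt_parameters):
        t_half, s_half = build_propagator(qt_parameters, 0.5)
        c = qt_parameters.C_matrix
        target = c - t_half @ c @ t_half.T
        np.testing.assert_allclose(s_half @ s_half.T, target, atol=1e-10)

    def test_unstable_pair_rejected(self):
        # negative "damping" grows the covariance: C - T C T^T indefinite
        gle = GLEParameterFile(np.array([[-0.05]]), np.array([[KB * TEMP]]),
                               TEMP)
        with pytest.raises(ParameterError):
            build_propagator(gle, 0.5)

    def test_ou_stationary_covariance_is_C(self, qt_parameters):
        """Iterating the exact OU update on a free particle reproduces C."""
        t_half, s_half = build_propagator(qt_parameters, 0.5)
        rng = np.random.default_rng(0)
        n_chains, n_steps = 400, 3000
        state = rng.standard_normal((n_chains, 7)) @ np.linalg.cholesky(
            qt_parameters.C_matrix).T
        for _ in range(n_steps):
            state = state @ t_half.T + rng.standard_normal(state.shape) @ s_half.T
        cov = np.cov(state.T)
        scale = np.abs(qt_parameters.C_matrix).max()
        assert np.abs(cov - qt_parameters.C_matrix).max() < 0.15 * scale


class TestLyapunovOracle:
    def test_white_noise_is_classical(self):
        """With C = kT the stationary position variance is kT/(m w^2)."""
        omega = wavenumber_to_angular(500.0)
        var_x, var_v = harmonic_stationary_variance(white_noise_gle(), omega,
                                                    mass_amu=2.0)
        m_int = 2.0 * AMU_EVFS
        np.testing.assert_allclose(var_x, KB * TEMP / (m_int * omega**2),
                                   rtol=1e-8)
        np.testing.assert_allclose(var_v, KB * TEMP / m_int, rtol=1e-8)

    def test_bundled_matrices_match_quantum_variance(self, qt_parameters):
        """The fitted thermostat holds each frequency near the quantum
        width (design accuracy ~4% over the fitted band)."""
        from neaspec.constants import HBAR
        for nu in (300.0, 1000.0, 3600.0):
            omega = wavenumber_to_angular(nu)
            var_x, _ = harmonic_stationary_variance(qt_parameters, omega, 1.0)
            m_int = AMU_EVFS
            target = ns.HBAR / (2 * m_int * omega) \
                / np.tanh(ns.HBAR * omega / (2 * KB * TEMP))
            assert abs(var_x / target - 1) < 0.05


class TestIntegrator:
    def test_energy_conservation_without_thermostat(self):
        """A = 0 reduces the scheme to velocity Verlet: energy conserved."""
        pot, ref = make_isotropic_oscillator(1000.0, 2.0)
        gle = GLEParameterFile(np.zeros((1, 1)), np.array([[KB * TEMP]]), TEMP)
        traj = run_qt(pot, ref, gle, QTSettings(dt=0.5, n_steps=10000, seed=1))
        kin = traj.kinetic_temperature * (3 * KB / 2)   # eV per atom, 3 dof
        total = traj.potential_energy + kin
        # bounded shadow-energy oscillation ~ (w dt)^2, but no secular drift
        assert total.std() / total.mean() < 2e-3
        drift = abs(total[-100:].mean() - total[:100].mean()) / total.mean()
        assert drift < 1e-6

    def test_classical_equipartition(self):
        pot, ref = make_isotropic_oscillator(300.0, 1.0)
        traj = run_qt(pot, ref, white_noise_gle(gamma=0.05),
                      QTSettings(dt=0.5, n_steps=60000, seed=2, stride=10))
        xs = np.array([f.coords.ravel() for f in traj.frames])
        omega = wavenumber_to_angular(300.0)
        target = KB * TEMP / (AMU_EVFS * omega**2)
        assert abs(xs.var(axis=0).mean() / target - 1) < 0.05

    def test_integrator_matches_lyapunov_prediction(self, qt_parameters):
        """Simulated position variance agrees with the exact stationary
        solution of the same (A, C) pair — integrator correctness."""
        nu = 1000.0
        pot, ref = make_isotropic_oscillator(nu, 1.0)
        traj = run_qt(pot, ref, qt_parameters,
                      QTSettings(dt=0.5, n_steps=80000, seed=3, stride=10))
        xs = np.array([f.coords.ravel() for f in traj.frames])
        omega = wavenumber_to_angular(nu)
        var_pred, _ = harmonic_stationary_variance(qt_parameters, omega, 1.0)
        assert abs(xs.var(axis=0).mean() / var_pred - 1) < 0.08

    def test_determinism(self, qt_parameters):
        pot, ref = make_isotropic_oscillator(500.0, 1.0)
        s = QTSettings(dt=0.5, n_steps=200, seed=11, stride=5)
        t1 = run_qt(pot, ref, qt_parameters, s)
        t2 = run_qt(pot, ref, qt_parameters, s)
        np.testing.assert_array_equal(t1.kinetic_temperature,
                                      t2.kinetic_temperature)
        for f1, f2 in zip(t1.frames, t2.frames):
            np.testing.assert_array_equal(f1.coords, f2.coords)

    def test_blow_up_guard(self, qt_parameters):
        pot, ref = make_isotropic_oscillator(3600.0, 1.0)
        with pytest.raises(RuntimeError, match="blow-up"):
            run_qt(pot, ref, qt_parameters,
                   QTSettings(dt=40.0, n_steps=100, seed=0))


class TestEquilibration:
    def _traj(self, temps):
        return Trajectory([], np.empty((0, 1, 3)), np.asarray(temps, float),
                          np.zeros(len(temps)))

    def test_constant_series(self):
        s = QTSettings(equilibration_window=10, temperature_tolerance=0.05)
        assert detect_equilibration(self._traj(np.full(100, 296.0)), s) == 0

    def test_step_function(self):
        temps = np.concatenate([np.full(1000, 600.0), np.full(4000, 296.0)])
        s = QTSettings(equilibration_window=200, temperature_tolerance=0.02)
        idx = detect_equilibration(self._traj(temps), s)
        assert 900 <= idx <= 1200

    def test_never_converges(self):
        temps = np.linspace(1000.0, 100.0, 500)   # monotone drift
        s = QTSettings(equilibration_window=50, temperature_tolerance=0.001)
        with pytest.raises(RuntimeError, match="longer"):
            detect_equilibration(self._traj(temps), s)


class TestSnapshots:
    def _traj_with_frames(self, n_frames, stride=1):
        from neaspec.io_formats import Geometry
        frames = [Geometry(["H"], np.array([[float(i), 0, 0]]))
                  for i in range(n_frames)]
        return Trajectory(frames, np.zeros((n_frames, 1, 3)),
                          np.zeros(n_frames * stride), np.zeros(n_frames * stride))

    def test_uniform_stride(self):
        ens = extract_snapshots(self._traj_with_frames(1000), 500, 0)
        assert len(ens) == 500
        xs = [g.coords[0, 0] for g in ens.members]
        assert np.all(np.diff(xs) == 2.0)    # every 2nd frame

    def test_insufficient_frames(self):
        with pytest.raises(ValidationError, match="run at least"):
            extract_snapshots(self._traj_with_frames(100), 500, 0)

    def test_conformer_labels_preserved(self, qt_parameters):
        pot, ref = make_isotropic_oscillator(500.0, 1.0, label="confA")
        traj = run_qt(pot, ref.with_coords(ref.coords, label="confA"),
                      qt_parameters, QTSettings(n_steps=200, seed=1, stride=2))
        ens = extract_snapshots(traj, 50, 0, 2)
        assert ens.conformer_label == "confA"
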