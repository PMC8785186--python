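import numpy as np
import pytest

from neaspec.constants import KB, K_PREFACTOR
from neaspec.io_formats import TransitionRecord, ValidationError
from neaspec.nea_spectrum import (
    LineShapeSpec, Spectrum, assemble_sigma, boltzmann_weights,
    combine_conformers, composite_spectrum, default_grid, integrated_strength,
    reflection_reference,
)


def single_line(delta_e=4.0, f=0.01):
    return [TransitionRecord("g0", 1, delta_e, f)]


WIDE = np.arange(1.0, 7.0, 0.005)


class TestPrefactor:
    def test_k_value(self):
        """K = pi e^2 hbar / (2 m_e c eps0) in eV cm^2 from CODATA."""
        assert K_PREFACTOR == pytest.approx(1.0975e-16, rel=2e-4)


class TestAssembly:
    def test_sum_rule_single_line(self):
        ls = LineShapeSpec("lorentzian", 0.05)
        sp = assemble_sigma(single_line(), ls, WIDE)
        f = integrated_strength(sp, ls)
        assert abs(f / 0.01 - 1) < 0.02

    def test_zero_strength_zero_sigma(self):
        sp = assemble_sigma(single_line(f=0.0), LineShapeSpec(), WIDE)
        assert np.all(sp.sigma == 0.0)

    def test_duplication_invariance(self):
        """Duplicating every geometry (N_p doubles) leaves sigma unchanged."""
        rng = np.random.default_rng(0)
        recs = [TransitionRecord(f"g{i}", 1, float(rng.uniform(3.5, 4.5)),
                                 0.01) for i in range(100)]
        dup = recs + [TransitionRecord(f"h{i}", 1, r.delta_E, r.osc_strength)
                      for i, r in enumerate(recs)]
        ls = LineShapeSpec("lorentzian", 0.05)
        grid = np.arange(3.0, 5.0, 0.005)
        np.testing.assert_allclose(assemble_sigma(recs, ls, grid).sigma,
                                   assemble_sigma(dup, ls, grid).sigma,
                                   rtol=1e-12)

    def test_linearity_in_oscillator_strength(self):
        ls = LineShapeSpec()
        a = assemble_sigma(single_line(f=0.01), ls, WIDE).sigma
        b = assemble_sigma(single_line(f=0.03), ls, WIDE).sigma
        np.testing.assert_allclose(b, 3 * a, rtol=1e-12)

    def test_grid_refinement_stability(self):
        ls = LineShapeSpec("lorentzian", 0.05)
        coarse = assemble_sigma(single_line(), ls, np.arange(1.0, 7.0, 0.005))
        fine = assemble_sigma(single_line(), ls, np.arange(1.0, 7.0, 0.0025))
        assert abs(fine.integral() / coarse.integral() - 1) < 1e-3

    def test_empty_records_rejected(self):
        with pytest.raises(ValidationError):
            assemble_sigma([], LineShapeSpec(), WIDE)

    def test_clipped_lines_warn(self):
        with pytest.warns(UserWarning, match="outside"):
            assemble_sigma(single_line(delta_e=10.0), LineShapeSpec(),
                           np.arange(3.0, 5.0, 0.01))

    def test_default_grid_covers_lines(self):
        recs = single_line()
        grid = default_grid(recs, LineShapeSpec("lorentzian", 0.05))
        assert grid[0] <= 4.0 - 5 * 0.05 + 1e-9
        assert grid[-1] >= 4.0 + 5 * 0.05 - 1e-9
        assert grid[1] - grid[0] == pytest.approx(0.005)

    def test_lineshapes_normalized(self):
        x = np.linspace(-60, 60, 2000001)
        for kind in ("lorentzian", "gaussian"):
            w = LineShapeSpec(kind, 0.05).evaluate(x)
            assert np.trapezoid(w, x) == pytest.approx(1.0, rel=1e-3)


class TestConformerWeighting:
    def test_equal_energies(self):
        w = boltzmann_weights([0.0, 0.0], 296.0)
        np.testing.assert_allclose(w.weights, [0.5, 0.5])

    def test_ln2_splitting(self):
        de = KB * 296.0 * np.log(2.0)
        w = boltzmann_weights([0.0, de], 296.0)
        np.testing.assert_allclose(w.weights, [2 / 3, 1 / 3], rtol=1e-12)

    def test_eight_conformers(self):
        rng = np.random.default_rng(4)
        energies = rng.uniform(0, 0.1, 8)
        w = boltzmann_weights(energies, 296.0)
        assert w.weights.sum() == pytest.approx(1.0, abs=1e-12)
        # weight order is the reverse of energy order
        assert np.all(np.argsort(w.weights) == np.argsort(-energies))

    def test_nonpositive_temperature(self):
        with pytest.raises(ValidationError):
            boltzmann_weights([0.0, 0.1], 0.0)

    def test_combine_weight_one(self):
        ls = LineShapeSpec()
        s1 = assemble_sigma(single_line(4.0), ls, WIDE)
        s2 = assemble_sigma(single_line(5.0), ls, WIDE)
        w = boltzmann_weights([0.0, 10.0], 296.0, labels=["a", "b"])
        combined = combine_conformers([s1, s2], w)
        np.testing.assert_allclose(combined.sigma, s1.sigma, atol=1e-30)

    def test_combine_linearity_of_integral(self):
        ls = LineShapeSpec()
        s1 = assemble_sigma(single_line(4.0, 0.01), ls, WIDE)
        s2 = assemble_sigma(single_line(4.5, 0.02), ls, WIDE)
        w = boltzmann_weights([0.0, 0.01], 296.0, labels=["a", "b"])
        total = combine_conformers([s1, s2], w)
        expected = (w.weights[0] * s1.integral() + w.weights[1] * s2.integral())
        assert total.integral() == pytest.approx(expected, rel=1e-10)

    def test_grid_mismatch_rejected(self):
        ls = LineShapeSpec()
        s1 = assemble_sigma(single_line(4.0), ls, WIDE)
        s2 = assemble_sigma(single_line(4.0), ls, np.arange(1.0, 7.0, 0.004))
        w = boltzmann_weights([0.0, 0.0], 296.0, labels=["a", "b"])
        with pytest.raises(ValidationError, match="grid"):
            combine_conformers([s1, s2], w)


class TestComposite:
    def test_zero_fragment_identity(self):
        ls = LineShapeSpec()
        s = assemble_sigma(single_line(), ls, WIDE)
        zero = Spectrum(WIDE, np.zeros_like(WIDE))
        np.testing.assert_array_equal(composite_spectrum([s, zero]).sigma,
                                      s.sigma)

    def test_integral_additivity(self):
        ls = LineShapeSpec()
        s1 = assemble_sigma(single_line(4.0, 0.01), ls, WIDE)
        s2 = assemble_sigma(single_line(5.0, 0.02), ls, WIDE)
        comp = composite_spectrum([s1, s2])
        assert comp.integral() == pytest.approx(
            s1.integral() + s2.integral(), rel=1e-12)
        assert comp.metadata["composite"]

    def test_parent_with_interaction_exceeds_composite(self):
        """A parent whose two chromophores interact (each state's strength
        enhanced by the coupling term) absorbs at least as much as the sum
        of its isolated fragments — the multichromophore enhancement."""
        ls = LineShapeSpec("lorentzian", 0.05)
        frag_a = assemble_sigma(single_line(4.0, 0.010), ls, WIDE)
        frag_b = assemble_sigma(single_line(5.0, 0.020), ls, WIDE)
        comp = composite_spectrum([frag_a, frag_b])
        enhancement = 0.004      # H-bond-like intramolecular interaction
        parent_records = [TransitionRecord("g0", 1, 4.0, 0.010 + enhancement),
                          TransitionRecord("g0", 2, 5.0, 0.020 + enhancement)]
        parent = assemble_sigma(parent_records, ls, WIDE)
        assert np.all(parent.sigma >= comp.sigma - 1e-30)
        assert parent.integral() > comp.integral()


class TestReflectionPrinciple:
    def test_collapses_to_lineshape_as_kappa_vanishes(self):
        ls = LineShapeSpec("lorentzian", 0.05)
        grid = np.linspace(3.0, 5.0, 2001)
        ref = reflection_reference(4.0, kappa=1e-4, sigma_x=0.05,
                                   f0=0.01, lineshape=ls, grid=grid)
        direct = assemble_sigma(single_line(4.0, 0.01), ls, grid)
        dev = np.abs(ref.sigma - direct.sigma).max() / direct.sigma.max()
        assert dev < 0.01

    def test_doubling_kappa_doubles_band_std(self):
        grid = np.linspace(2.0, 6.0, 4001)
        s1 = reflection_reference(4.0, 1.0, 0.05, grid=grid)
        s2 = reflection_reference(4.0, 2.0, 0.05, grid=grid)

        def fitted_std(sp):
            w = sp.sigma / sp.sigma.sum()
            mu = (w * sp.energy_grid).sum()
            return np.sqrt((w * (sp.energy_grid - mu) ** 2).sum())

        assert fitted_std(s2) / fitted_std(s1) == pytest.approx(2.0, rel=1e-3)

    def test_nea_matches_reflection_band(self):
        """Monte-Carlo NEA with a linear gap map reproduces the closed-form
        Gaussian band to a few percent of the peak."""
        from neaspec.model_systems import stratified_normal
        rng = np.random.default_rng(6)
        E0, kappa, sx = 4.0, 2.0, 0.05
        q = stratified_normal(5000, rng, 0.0, sx)
        recs = [TransitionRecord(f"g{i}", 1, E0 + kappa * qi, 0.01)
                for i, qi in enumerate(q)]
        ls = LineShapeSpec("lorentzian", 0.01)
        grid = np.linspace(E0 - 0.8, E0 + 0.8, 2001)
        nea = assemble_sigma(recs, ls, grid)
        ref = reflection_reference(E0, kappa, sx, 0.01, ls, grid)
        assert np.abs(nea.sigma - ref.sigma).max() / ref.sigma.max() < 0.03
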