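"""Fit the bundled quantum-thermostat GLE matrices.

Maintenance script: regenerates ``src/neaspec/data/gle_qt_296K_{A,C}.txt``.

The drift matrix A couples the physical mass-weighted momentum to Ns = 6
auxiliary momenta organized as three damped-oscillator channels
(antisymmetric momentum coupling + rotation-damping 2x2 blocks), plus a
weak white-noise term.  The noise matrix B is diagonal; C solves
A C + C A^T = B B^T, so the fluctuation-dissipation pair is positive by
construction.  Parameters are optimized so that the exact stationary
position and momentum variances of a GLE-thermostatted harmonic oscillator
(from the continuous Lyapunov equation) match the quantum values
(ħω/2)·coth(ħω/2k_BT) at T = 296 K over 160–3700 cm⁻¹, under a penalty
keeping the slowest relaxation rate of the thermostatted oscillator above
~3e-3 fs⁻¹ (so 1e5-fs trajectories carry useful statistics).  The fit is
staged: an accurate weak-coupling solution is first obtained, then the
mixing-rate floor is ramped up (homotopy) to avoid the poor local optima
that a direct strongly-coupled fit falls into.

Run:  python scripts/fit_qt_matrices.py  (takes ~15 min on one CPU)
"""

import sys
from pathlib import Path

import numpy as np
from scipy.linalg import eigvals, solve_continuous_lyapunov
from scipy.optimize import least_squares

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from neaspec.constants import HBAR, KB, wavenumber_to_angular  # noqa: E402
from neaspec.io_formats import write_gle_matrix  # noqa: E402

T_TARGET = 296.0
KT = KB * T_TARGET
N_CHANNELS = 3


def theta(omega):
    """Quantum effective temperature (ħω/2)coth(ħω/2kT), eV."""
    x = HBAR * omega / (2 * KT)
    return np.where(x < 1e-8, KT, HBAR * omega / 2 / np.tanh(np.maximum(x, 1e-12)))


def build(params):
    """Assemble (A, D=BBᵀ) from the log/linear parameter vector."""
    a_pp, b0 = np.exp(params[0]), np.exp(params[1])
    n = 1 + 2 * N_CHANNELS
    A = np.zeros((n, n))
    bdiag = np.zeros(n)
    A[0, 0] = a_pp
    bdiag[0] = b0
    for j in range(N_CHANNELS):
        g, h, alpha, wtilde, b = np.exp(params[2 + 5 * j:7 + 5 * j])
        i = 1 + 2 * j
        A[0, i] = -g          # antisymmetric coupling: positive friction,
        A[i, 0] = h           # stable drift for any g, h > 0
        A[i, i] = A[i + 1, i + 1] = alpha
        A[i, i + 1] = wtilde
        A[i + 1, i] = -wtilde
        bdiag[i] = bdiag[i + 1] = b
    return A, np.diag(bdiag**2)


def predict(A, D, omega):
    """Exact stationary Var(q), Var(p) and slowest relaxation rate."""
    n = A.shape[0]
    F = np.zeros((n + 1, n + 1))
    F[0, 1] = 1.0
    F[1, 0] = -omega**2
    F[1:, 1:] = -A
    Dfull = np.zeros((n + 1, n + 1))
    Dfull[1:, 1:] = D
    S = solve_continuous_lyapunov(F, -Dfull)
    return S[0, 0], S[1, 1], float(np.max(eigvals(F).real))


NU_GRID = np.concatenate([np.geomspace(15, 140, 5),
                          np.geomspace(160, 3700, 28), [3900, 4200]])
W_GRID = wavenumber_to_angular(NU_GRID)
TARGETS = theta(W_GRID)
WEIGHTS = np.where((NU_GRID >= 160) & (NU_GRID <= 3700), 5.0, 0.2)


def make_residual(rate_floor, penalty_weight):
    def residual(p):
        if not np.all(np.isfinite(p)) or np.abs(p).max() > 40:
            return np.full(2 * len(W_GRID) + 1, 1e3)
        A, D = build(p)
        out, pen = [], 0.0
        for w, t, wt in zip(W_GRID, TARGETS, WEIGHTS):
            floor = min(rate_floor, w / 3)   # a slow oscillator cannot relax
            try:                             # faster than ~its own frequency
                vq, vp, rmax = predict(A, D, w)
            except Exception:
                return np.full(2 * len(W_GRID) + 1, 1e3)
            if not np.isfinite(vq) or vq <= 0 or vp <= 0 or rmax >= -1e-7:
                out += [10.0, 10.0]
                pen += 10.0
                continue
            out.append(wt * np.log(w * w * vq / t))
            out.append(0.4 * wt * np.log(vp / t))    # momenta weighted lighter
            pen += max(0.0, rmax + floor) * penalty_weight
        return np.array(out + [pen])
    return residual


def initial_guess():
    p0 = [np.log(0.003), 0.5 * np.log(2 * 0.003 * KT)]
    for nu_c in (150.0, 800.0, 3000.0):
        w0 = wavenumber_to_angular(nu_c)
        alpha = 0.25 * w0
        g = np.sqrt(0.015 * 2 * alpha)
        p0 += [np.log(g), np.log(g), np.log(alpha), np.log(w0),
               0.5 * np.log(2 * alpha * float(theta(np.array(w0))))]
    return np.array(p0)


def main():
    p = initial_guess()
    for rate_floor, pw in [(5e-4, 500), (1e-3, 800), (2e-3, 1200),
                           (3e-3, 1500), (3.2e-3, 4000)]:
        sol = least_squares(make_residual(rate_floor, pw), p, method="trf",
                            max_nfev=8000, xtol=1e-14, ftol=1e-14)
        p = sol.x
        print(f"stage rate_floor={rate_floor:g}: cost={sol.cost:.4f}")
    A, D = build(p)
    C = solve_continuous_lyapunov(A, D)
    for nu in (160, 300, 600, 1000, 2000, 3000, 3600):
        w = wavenumber_to_angular(nu)
        vq, vp, rmax = predict(A, D, w)
        print(f"  {nu:5d} cm^-1: Var(q) ratio {w * w * vq / float(theta(np.array(w))):.4f}"
              f"  slowest rate {-rmax:.1e} fs^-1")
    data = Path(__file__).resolve().parents[1] / "src" / "neaspec" / "data"
    write_gle_matrix(A, data / "gle_qt_296K_A.txt",
                     "GLE drift matrix A for quantum-thermostat sampling at 296 K, units fs^-1.\n"
                     "Dimension 7x7: physical mass-weighted momentum + Ns=6 auxiliary momenta\n"
                     "(three damped-oscillator channels). Fitted so that a GLE-thermostatted\n"
                     "harmonic oscillator reaches position variance (hbar/2 m w) coth(hbar w / 2 kB T)\n"
                     "within ~4% over 160-3700 cm^-1, with stationary-state relaxation rates\n"
                     ">= 3e-3 fs^-1 across that band. Fit: scripts/fit_qt_matrices.py.")
    write_gle_matrix(C, data / "gle_qt_296K_C.txt",
                     "GLE stationary covariance matrix C for quantum-thermostat sampling at 296 K,\n"
                     "units eV. Same dimension/ordering as the A matrix. C solves A C + C A^T = B B^T\n"
                     "for the fitted diagonal noise matrix B; it is the free-particle stationary\n"
                     "covariance of (p, s). Fit: scripts/fit_qt_matrices.py.")
    print("wrote", data / "gle_qt_296K_A.txt")


if __name__ == "__main__":
    main()
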