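# GLE drift matrix A for quantum-thermostat sampling at 296 K, units fs^-1.
# Dimension 7x7: physical mass-weighted momentum + Ns=6 auxiliary momenta
# (three damped-oscillator channels). Fitted so that a GLE-thermostatted
# harmonic oscillator reaches position variance (hbar/2 m w) coth(hbar w / 2 kB T)
# within ~4% over 160-3700 cm^-1, with stationary-state relaxation rates
# >= 3e-3 fs^-1 across that band. Fit: scripts/fit_qt_matrices.py.
 3.4199543608847893e-03 -1.3222777379886783e-02  0.0000000000000000e+00 -1.2963245250853152e-02  0.0000000000000000e+00 -6.8832693612694229e-02  0.0000000000000000e+00
 4.1184491088998597e-02  4.4872455057179204e-02  3.7917461529616177e-02  0.0000000000000000e+00  0.0000000000000000e+00  0.0000000000000000e+00  0.0000000000000000e+00
 0.0000000000000000e+00 -3.7917461529616177e-02  4.4872455057179204e-02  0.0000000000000000e+00  0.0000000000000000e+00  0.0000000000000000e+00  0.0000000000000000e+00
 5.5927649772753815e-02  0.0000000000000000e+00  0.0000000000000000e+00  9.7803657053702156e-02  9.8004244586529371e-02  0.0000000000000000e+00  0.0000000000000000e+00
 0.0000000000000000e+00  0.0000000000000000e+00  0.0000000000000000e+00 -9.8004244586529371e-02  9.7803657053702156e-02  0.0000000000000000e+00  0.0000000000000000e+00
 4.7571119398444404e-02  0.0000000000000000e+00  0.0000000000000000e+00  0.0000000000000000e+00  0.0000000000000000e+00  2.3463667921710932e-01  7.4115684439804319e-01
 0.0000000000000000e+00  0.0000000000000000e+00  0.0000000000000000e+00  0.0000000000000000e+00  0.0000000000000000e+00 -7.4115684439804319e-01  2.3463667921710932e-01
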