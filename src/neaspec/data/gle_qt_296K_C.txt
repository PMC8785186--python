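# GLE stationary covariance matrix C for quantum-thermostat sampling at 296 K,
# units eV. Same dimension/ordering as the A matrix. C solves A C + C A^T = B B^T
# for the fitted diagonal noise matrix B; it is the free-particle stationary
# covariance of (p, s). Fit: scripts/fit_qt_matrices.py.
 3.0728914792799988e-02 -1.4239168634767638e-02 -8.6914169836675333e-03 -8.3192392232019838e-03 -7.0262598789382520e-03  5.8202214967619393e-03  1.8006353446222537e-02
-1.4239168634767638e-02  8.8122450677764474e-03  5.5484215281859997e-03  4.3720995550814634e-03  4.2602685021170842e-03  1.0918580891306538e-03  1.6877594840013631e-04
-8.6914169836675333e-03  5.5484215281859988e-03  5.1202519764232107e-03  2.5758134539909895e-03  2.9015313962812523e-03  1.9507034546952320e-04  5.4015149668149075e-04
-8.3192392232019838e-03  4.3720995550814634e-03  2.5758134539909895e-03  3.6306928147529761e-03  2.1917166516440567e-03  1.2060024021367146e-03 -4.8334509258091092e-04
-7.0262598789382512e-03  4.2602685021170842e-03  2.9015313962812528e-03  2.1917166516440554e-03  3.2658759035896112e-03  2.8116019361677271e-04  4.8433933440368191e-04
 5.8202214967619341e-03  1.0918580891306543e-03  1.9507034546952456e-04  1.2060024021367151e-03  2.8116019361677254e-04  2.3481301341623850e-01 -3.3604786355571946e-04
 1.8006353446222541e-02  1.6877594840013682e-04  5.4015149668149097e-04 -4.8334509258091108e-04  4.8433933440368180e-04 -3.3604786355570998e-04  2.3387004960840496e-01
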