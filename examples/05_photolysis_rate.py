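"""Photolysis rate coefficient from a cross-section, yield and flux.

Assembles a small absorption band, overlaps it with a synthetic actinic
flux and a unit quantum yield, and integrates j = int sigma*phi*F dlambda.
"""

import numpy as np

from neaspec import LineShapeSpec, TransitionRecord, assemble_sigma, photolysis_rate
from neaspec.constants import ev_to_nm
from neaspec.photolysis import FluxTable, QuantumYieldTable

# a band centered at 3.8 eV (~326 nm), inside the actinic window
rng = np.random.default_rng(0)
records = [TransitionRecord(f"g{i}", 1, float(rng.normal(3.8, 0.15)), 0.005)
           for i in range(500)]
spectrum = assemble_sigma(records, LineShapeSpec("lorentzian", 0.05))
peak_nm = ev_to_nm(spectrum.energy_grid[np.argmax(spectrum.sigma)])
print(f"band peak at {peak_nm:.0f} nm, "
      f"sigma_max = {spectrum.sigma.max():.3e} cm^2/molecule")

# Gaussian-envelope actinic flux (photons cm^-2 s^-1 nm^-1), phi = 1
wl = np.linspace(290.0, 420.0, 131)
flux = FluxTable(wl, 5e14 * np.exp(-((wl - 340.0) / 60.0) ** 2))
phi = QuantumYieldTable(wl, np.ones_like(wl))

j = photolysis_rate(spectrum, phi, flux)
print(f"photolysis rate j = {j:.3e} s^-1  "
      f"(photolytic lifetime 1/j ~ {1.0 / j:.0f} s)")
# j is the first-order rate at which molecules are destroyed by light:
# the overlap of what the molecule absorbs with what the sun provides.
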