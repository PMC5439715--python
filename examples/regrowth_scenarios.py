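"""Regrowth scenarios: is post-irradiation growth suppressed locally or by the host?

Runs the cellular automaton from an irradiated implant under three
assumptions — cell kill only, local division inhibition within R cell
diameters of NPMA (senescent-like) survivors, and a global host-mediated
elevation of the death probability — and compares the regrowth rates
fitted above the tumor detection size.

Takes a couple of minutes: each run grows a ~45,000-cell tumor.
"""

from regrowth.presets import run_invivo_scenario
from regrowth.automaton import dormancy_fraction

print("scenario        dose   rate/day   R^2")
for label, scenario, dose, radius in (
    ("kill only      ", "none", 8.0, 0),
    ("local R=1      ", "local", 8.0, 1),
    ("local R=2      ", "local", 8.0, 2),
    ("global pa=5.5% ", "global", 8.0, 0),
    ("kill only      ", "none", 12.0, 0),
    ("global pa=6%   ", "global", 12.0, 0),
):
    res = run_invivo_scenario(scenario, dose, seed=0, inhibition_radius=radius)
    fit = res.growth_fit
    print(f"{label} {dose:4.0f}   {fit.rate:8.4f}  {fit.r_squared:.3f}")

res = run_invivo_scenario("global", 12.0, seed=0, stop_size=20000)
frac = dormancy_fraction(res.final_state, 4)
print(
    f"\npost-12 Gy global inhibition: {100 * frac:.1f}% of cells undivided >= 4 days"
    " at detection size"
)
print(
    "-> local inhibition barely moves the rate; only the global death-rate"
    " elevation suppresses regrowth, and it leaves ~half the population dormant"
)
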