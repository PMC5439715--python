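"""Clonogenic survival: anchor the LQ curve, then recover it from a noisy assay.

Interpolates the linear-quadratic survival curve S(D) = exp(-aD - bD^2)
through the two printed anchor survivals (2.55% at 8 Gy, 0.009% at
16 Gy), simulates a six-dose clonogenic assay from it, and refits by
weighted least squares on -ln S.
"""

from regrowth.presets import anchored_lq
from regrowth.survival import ClonogenicRecord, fit_lq, lq_surviving_fraction
from regrowth.synthetic import CloneAssayTruth, gen_clonogenic

lq = anchored_lq()
print(f"anchored curve: alpha = {lq.alpha:.4f} /Gy, beta = {lq.beta:.5f} /Gy^2")
for d in (2, 4, 8, 12, 16):
    print(f"  S({d:2d} Gy) = {100 * lq_surviving_fraction(lq, d):8.4f} %")

truth = CloneAssayTruth(
    alpha=lq.alpha, beta=lq.beta, plating_efficiency=0.6,
    doses=[0, 2, 4, 8, 12, 16], cells_plated=500, replicates=4, seed=1,
)
table = gen_clonogenic(truth)
print("\nsimulated assay (4 dishes x 500 cells, plating efficiency 0.6):")
print(table.groupby("dose_gy")["colonies"].sum().rename("total colonies").to_string())

records = [
    ClonogenicRecord(r.dose_gy, r.cells_plated, r.colonies) for r in table.itertuples()
]
fit = fit_lq(records, method="least_squares")
print(
    f"\nrefit from counts: alpha = {fit.alpha:.4f}, beta = {fit.beta:.5f}"
    f"  ->  S(8 Gy) = {100 * lq_surviving_fraction(fit, 8.0):.3f} %"
)
print("(the refit wobbles around 2.55% with the Poisson noise of ~30 colonies at 8 Gy)")
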