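"""Differential-expression screen on the 39-array, 12-group design.

Generates a synthetic study (3 doses x 4 days, with planted
inflammatory-style up-regulation at days 4-6 and additive batch
effects), runs quantile normalization -> log2 -> batch centering ->
per-gene 12-group ANOVA -> Holm -> +-1.5 fold-change filter, and lists
what the screen recovers.
"""

from regrowth.expression import anova_screen, preprocess
from regrowth.synthetic import ExpressionTruth, gen_expression_study

planted = {
    f"gene_{i:05d}": {(8.0, 4): 1.2, (16.0, 4): 1.5, (8.0, 6): 1.2, (16.0, 6): 1.5}
    for i in range(8)
}
truth = ExpressionTruth(
    n_genes=2000,
    de_genes=planted,
    noise_sd=0.2,
    batch_shift={1: 0.3, 2: -0.2, 3: 0.1, 4: 0.0},
    seed=4,
)
study = gen_expression_study(truth)
result = anova_screen(preprocess(study), q=0.10, fc_threshold=1.5)

sig = result[result.significant].sort_values("p_holm")
print(f"significant genes (Holm FWER < 10%, |fold| > 1.5): {len(sig)} of {len(result)}")
print(sig[["F", "p_holm", "max_log2fc"]].head(10).to_string(float_format=lambda v: f"{v:.3g}"))
hits = sum(g in sig.index for g in planted)
print(f"\nplanted inflammatory-style genes recovered: {hits}/{len(planted)}")
print("(batch shifts were removed by per-batch mean-centering before the ANOVA)")
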