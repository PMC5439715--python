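# Methods

## Linear-quadratic clonogenic survival

Reproductive survival after a single acute dose D (Gy) is modeled as
`S(D) = exp(−αD − βD²)`. Two fitting modes are exposed:

* **interpolate** — solves the 2×2 linear system in (α, β) on −ln S through
  exactly two nonzero-dose survival points. Anchoring through
  (8 Gy, 2.55%) and (16 Gy, 0.009%) gives α = 0.33504 /Gy,
  β = 0.015450 /Gy², the curve used throughout the package's presets.
* **least_squares** — weighted non-negative least squares of −ln S on
  (D, D²), with per-dose weights equal to total colony counts. The weights
  are Poisson-motivated: the variance of −ln Ŝ at a dose is approximately
  the reciprocal of its colony count. Doses where no colony grew carry zero
  weight and are dropped rather than erroring. Survival is normalized by
  the 0 Gy plating efficiency, so S(0) ≡ 1 — standard clonogenic practice.

A caution the test suite documents deliberately: with a realistic assay
(doses 0–16 Gy, 4 dishes × 500 cells, plating efficiency 0.6) the design's
Fisher information bounds the precision of the refitted S(8 Gy) at a
relative sd of ≈ 14% (only ~31 colonies are expected at 8 Gy), so
individual refits scatter well beyond ±15%; only the mean over many assays
is a sharp estimate.

## Growth-rate and doubling kinetics

Exponential rates are ordinary least squares of ln(value) on time,
restricted to values at or above a threshold (`min_value`) so lag phases
below a detection size do not bias the rate; duplicate time points are
averaged in log space; R² is the ordinary coefficient of determination of
the log-linear fit. Cumulative population doublings over serial passages
accumulate log2(harvested/plated), with per-interval rates using the
inter-passage day spans.

## Cellular-automaton regrowth model

Cells occupy a 2-D square lattice (Moore 8-neighborhood; Chebyshev
distance for the inhibition radius) in three states: proliferative,
quiescent (viable but with no free neighbor site — reversible the moment
space opens), and NPMA (non-proliferative, metabolically active:
radiation-inactivated, senescent-like cells that hold their site, never
divide or migrate, and are cleared at `npma_clearance` per day).

One step is one day; cells act in freshly shuffled order (random
sequential update, avoiding directional lattice artifacts and daughter
conflicts). Death and division are **exclusive competing daily fates**:
a viable cell dies with probability `p_a`, divides with probability `p_d`
(requiring maturity ≥ m, a free Moore neighbor, no local inhibition, and
spare capacity; the daughter takes a uniformly chosen free neighbor and
both dormancy counters reset), and otherwise makes `μ` migration attempts
into free neighbor sites (expected attempts/day: integer part plus a
Bernoulli remainder). The exclusive draw makes the low-density expected
per-day growth factor exactly `1 + p_d − p_a`, which is the closed-form
oracle the simulator is verified against, and gives the space-free lineage
process the offspring distribution {0 w.p. p_a, 2 w.p. p_d, 1 otherwise},
whose Galton–Watson extinction probability (q = p_a/p_d when
supercritical) is the second oracle. It requires `p_a + p_d ≤ 1`
(validated; all regimes used satisfy it comfortably).

Irradiation converts each viable cell independently: it remains clonogenic
with probability S(D); otherwise it becomes NPMA with probability `p_s`
or is removed. Local inhibition suppresses **division only** within
Chebyshev radius R of any NPMA cell (the minimal reading of growth
inhibition; migration and survival are untouched). Global host inhibition
replaces `p_a` by `global_pa` for every viable cell from irradiation
onward. Two documented presets exist for `global_pa` — the main values
(5.5% at 8 Gy, 6% at 12 Gy) used by all analyses, and an alternative
(4%/7%) pairing kept for sensitivity work.

### Calibration defaults and desk-scale geometry

`p_d = 0.28`, `p_a = 0.01`, `μ = 5`, `m = 1` give an unirradiated
low-density doubling time of ~2.6 days, near the U87-MG in vitro curve;
they are calibration knobs, not biological claims. Parameters the source
setting leaves open were fixed once: `p_s = 0.5` (the NPMA fraction of
inactivated cells is estimated but not printed in the source data);
`npma_clearance = 0.05`/day in vivo (~20-day NPMA lifespan — giant
senescent cells persist through the two-week in vitro assay window, where
clearance stays 0, but are cleared in a host).

The in vivo surrogate geometry preserves the experiment's *scale ratio*
rather than its absolute size: rates are fitted above a detection size an
order of magnitude larger than the implanted bolus (implant 2,000 cells,
detection 20,000, stop 45,000, lattice 320²), because in the experiment
the 200 mm³ detection volume is ~100× the inoculum. This matters: if
rates are fitted while the tumor is still inside or near its NPMA-laden
implant core, local inhibition artifactually moves the measured rate by
tens of percent (in either direction, depending on the window, through
delayed-morphology effects). Above ~10× the implant size the fitted
windows are cleanly log-linear (R² ≈ 0.997) and the local-inhibition
scenarios sit within ~2% of the kill-only rate. A 100× ratio is not
feasible in pure-Python runtime; 10× is the desk-scale compromise.

On this 2-D lattice, bulk growth at these sizes is surface-limited, so the
fitted "exponential" rates (~0.02–0.024/day) are an order of magnitude
below the low-density mean-field rate; they are comparable *across*
scenarios, which is what the discrimination analysis uses. Dormancy
(days since last division, reset in both mother and daughter, accumulated
by quiescent, migrating and NPMA cells alike) is reported as the fraction
of living cells at or above a threshold; at detection size after the
post-12 Gy global scenario ~48% of cells have not divided for ≥ 4 days.

## Expression screen

Raw intensities → quantile normalization (per-rank across-sample means,
midrank ties) → log2 → optional probe-to-gene collapse (probe with maximal
mean intensity) → per-gene, per-batch mean-centering to the gene's grand
mean → per-gene one-way ANOVA across the 12 (dose, day) groups → Holm
step-down adjustment (FWER ≤ q, default 10%) → significance requires
additionally a maximal |linear fold change| > 1.5 against the day-matched
0 Gy control group. The fold-change cutoff is interpreted on the linear
scale (|log2 FC| ≥ log2 1.5). Short-term (days 1/4/6) and long-term
(day 35) samples can be normalized separately, mirroring arrays hybridized
in separate campaigns; batch centering applies to the short-term block,
where replicate/chip batching lives.

Holm is a family-wise error procedure; Benjamini–Hochberg can be swapped
in by adjusting the returned raw p-values externally. Batch adjustment is
deliberately location-only (not an empirical-Bayes ComBat): within-batch
contrasts are preserved exactly, scale effects are not corrected, and
published gene counts from the original genome-scale data are not claimed
to be reproduced.

Two desk-scale artifacts of the simulation setup are documented because
the test suite works at ~100–300 genes rather than ~31,000: (i) separate
quantile normalization of a 27-sample and a 12-sample block uses two rank
references that differ by sampling noise, which at small gene counts
plants spurious day-35 shifts (measured null FWER 0.61 at 100 genes) but
vanishes at genome scale; (ii) mean-centering batches of 9 samples
induces a negative within-batch correlation that the ANOVA's degrees of
freedom ignore at 3 replicates (measured null FWER 0.17). The FWER
control check therefore runs the screen with joint normalization and no
batch centering — matching its generated world, which plants neither
batch effects nor a campaign split — and confirms Holm's guarantee
(empirical FWER ≈ 0.10). A green FWER test establishes Holm's control
given valid per-gene nulls; it does not establish that location
adjustments are harmless at desk scale (they are not), nor that ComBat
would behave identically.

2^−ΔΔCt quantification: per well ΔCt = Ct_target − Ct_housekeeping;
ΔΔCt = mean ΔCt(condition) − mean ΔCt(control); fold change = 2^−ΔΔCt.
Invariant to any constant shift applied to all Ct values.

## Dye-dilution deconvolution

Log intensities are modeled as a (G+1)-component Gaussian mixture with
means constrained to `μ₀ − k·ln 2` (each division halves the dye) and a
shared width σ. EM runs with uniform initial weights until the per-cell
log-likelihood gain falls below 1e-8 (500-iteration cap → convergence
error carrying the count). With a day-0 stained reference, μ₀ is fixed;
without one it is estimated by multi-start from the histogram mode and
its +k·ln2 shifts, with likelihood ties broken toward the smallest μ₀
(labeling the brightest populated peak as generation 0) — absolute
generation labels are only weakly identifiable without a reference. An
optional unconstrained background (autofluorescence) component is off by
default. The FL2-low statistic is the summed weight of generations ≥ 2.

## Synthetic data

Generators state the study designs they emulate: binomial colony counts
under pe·S(D); piecewise-exponential in vitro growth (dose-dependent lag,
then the control rate — the recovery structure of long-term cultures);
exponential in vivo volumes with log-normal noise and Bernoulli
engraftment per animal (emulating take rates reported as counts);
the 39-array design (3 doses × days 1/4/6 × 3 replicates + 3 doses ×
day 35 × 4 replicates, 12 (dose, day) groups, batches following replicate
for short-term arrays and a separate day-35 batch) with additive log2
group effects, batch shifts and Gaussian noise, exponentiated to raw
intensities; paired target/housekeeping Ct wells; and log-normal dye
mixtures with sd = sqrt(ln(1+cv²)). Every generator takes an explicit
seed, draws from a private RNG stream, and is bit-reproducible. What the
generators do *not* emulate: probe-level bead summarization, real
series-matrix idiosyncrasies, heavy-tailed array noise, cytometry
autofluorescence/compensation, or measurement error in colony counting —
green tests establish correctness of the estimators on the stated
generative world, not robustness to those realities.

## Pipeline

`run_pipeline` validates the full config (schema version, stage names,
scenario requirements) before any stage executes, derives one seed per
stage from the global seed via SHA-256 of `"{seed}:{stage}"` (stable under
re-running stages in isolation), and writes a manifest with the config
echo, per-stage seeds, sha256 content hashes of every output, library
versions and wall time. Fixed config + seed reproduce byte-identical
outputs.

## Known limitations

* 2-D lattice only; no vasculature, oxygen gradients, or explicit immune
  agents — the host effect is exactly the aggregate death-rate elevation.
* Surface-limited growth at desk scale means absolute simulated rates are
  not comparable to in vivo rates; only cross-scenario contrasts are.
* The NPMA fraction (`p_s`) and clearance are plausible defaults, not
  measured values; dormancy percentages shift with them.
* The batch adjustment is location-only; the screen's gene counts on real
  genome-scale data would differ from an empirical-Bayes pipeline.
* Division-profile fits assume a shared peak width and exact intensity
  halving; dye transfer, staining heterogeneity and autofluorescence are
  not modeled.
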