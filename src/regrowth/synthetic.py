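"""Synthetic data generators with known ground truth.

Each generator emulates one of the study designs the analysis modules
consume — binomial clonogenic assays under linear-quadratic survival,
lag-then-recovery in vitro growth curves, dose-suppressed in vivo tumor
volumes with stochastic graft failure, a 39-sample / 12-group expression
design with planted differentially expressed genes and additive batch
effects, paired-well qPCR Ct tables, and log-normal dye-dilution intensity
mixtures — so every downstream fit can be validated against a known truth
without external data.

All generators draw from a private ``numpy.random.Generator`` seeded
explicitly per call; none touches global RNG state, and a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CloneAssayTruth",
    "ExpressionTruth",
    "DyeTruth",
    "ExpressionStudy",
    "default_expression_design",
    "gen_clonogenic",
    "gen_growth_trajectories",
    "gen_expression_study",
    "gen_qpcr",
    "gen_dye_intensities",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class CloneAssayTruth:
    """Ground truth for a clonogenic assay: LQ parameters and design.

    alpha (1/Gy) and beta (1/Gy^2) define S(D) = exp(-alpha*D - beta*D^2);
    ``plating_efficiency`` is the colony-forming fraction of unirradiated
    cells, so the expected per-dish colony probability is
    plating_efficiency * S(D).
    """

    alpha: float
    beta: float
    plating_efficiency: float
    doses: Sequence[float]
    cells_plated: int
    replicates: int
    seed: int = 0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if not 0 < self.plating_efficiency <= 1:
            raise ValueError("plating_efficiency must lie in (0, 1]")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")
        if self.cells_plated < 1 or self.replicates < 1:
            raise ValueError("cells_plated and replicates must be >= 1")


def gen_clonogenic(truth: CloneAssayTruth) -> pd.DataFrame:
    """Simulate a clonogenic assay; one row per (dose, replicate) dish.

    Colony counts are Binomial(cells_plated, pe * S(D)), the success
    probability capped at 1.
    """
    rng = np.random.default_rng(truth.seed)
    rows = []
    for dose in truth.doses:
        p = truth.plating_efficiency * np.exp(
            -truth.alpha * dose - truth.beta * dose * dose
        )
        p = min(p, 1.0)
        colonies = rng.binomial(truth.cells_plated, p, size=truth.replicates)
        for rep, c in enumerate(colonies):
            rows.append(
                {
                    "dose_gy": dose,
                    "replicate": rep,
                    "cells_plated": truth.cells_plated,
                    "colonies": int(c),
                }
            )
    return pd.DataFrame(rows)


def gen_growth_trajectories(
    kind: str,
    dose_specs: Mapping[float, Mapping[str, float]],
    times: Sequence[float],
    n_subjects: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate growth trajectories per dose and subject.

    kind="invitro"
        Piecewise-exponential cell counts: a suppressed rate for a
        dose-dependent lag, then the recovered (control) rate. Per-dose keys: ``rate`` (1/day, post-recovery), ``lag`` (days),
        ``lag_rate`` (1/day during lag, default 0), ``v0`` (initial count).
    kind="invivo"
        Exponential tumor volumes (mm^3) with multiplicative log-normal
        noise; each subject takes (engrafts) with probability
        ``take_probability``; non-takers are flagged extinct and hold a
        residual volume with no growth. Per-dose keys: ``rate``, ``v0``,
        ``take_probability``.

    Returns a tidy table (time_days, value, dose_gy, subject, kind,
    extinct).
    """
    if kind not in ("invitro", "invivo"):
        raise ValueError(f"kind must be 'invitro' or 'invivo', got {kind!r}")
    t = np.asarray(list(times), dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for dose, spec in dose_specs.items():
        rate = float(spec["rate"])
        if not np.isfinite(rate):
            raise ValueError("rates must be finite")
        v0 = float(spec.get("v0", 1e4 if kind == "invitro" else 50.0))
        for subj in range(n_subjects):
            extinct = False
            if kind == "invitro":
                lag = float(spec.get("lag", 0.0))
                lag_rate = float(spec.get("lag_rate", 0.0))
                # growth integrates lag_rate up to `lag`, then `rate`
                log_v = np.where(
                    t <= lag,
                    np.log(v0) + lag_rate * t,
                    np.log(v0) + lag_rate * lag + rate * (t - lag),
                )
            else:
                p_take = float(spec.get("take_probability", 1.0))
                extinct = bool(rng.random() >= p_take)
                log_v = np.log(v0) + (0.0 if extinct else rate) * t
            if noise_sd > 0:
                log_v = log_v + rng.normal(0.0, noise_sd, size=t.size)
            for ti, lv in zip(t, log_v):
                rows.append(
                    {
                        "time_days": ti,
                        "value": float(np.exp(lv)),
                        "dose_gy": dose,
                        "subject": subj,
                        "kind": kind,
                        "extinct": extinct,
                    }
                )
    return pd.DataFrame(rows)


def default_expression_design() -> pd.DataFrame:
    """The 39-sample design: 3 doses x days {1,4,6} x 3 replicates, plus
    3 doses x day 35 x 4 replicates; short-term batches follow the
    replicate (chip run), day-35 samples form their own batch."""
    rows = []
    for day in (1, 4, 6):
        for dose in (0, 8, 16):
            for rep in range(1, 4):
                rows.append((dose, day, rep, rep))
    for dose in (0, 8, 16):
        for rep in range(1, 5):
            rows.append((dose, 35, rep, 4))
    df = pd.DataFrame(rows, columns=["dose_gy", "day", "replicate", "batch"])
    df.insert(
        0,
        "sample_id",
        [
            f"d{dose}gy_day{day}_r{rep}"
            for dose, day, rep in zip(df["dose_gy"], df["day"], df["replicate"])
        ],
    )
    return df


@dataclass(frozen=True)
class ExpressionTruth:
    """Ground truth for a synthetic expression study.

    ``de_genes`` maps gene id -> {(dose, day): log2 effect}; groups not
    listed get no effect. ``batch_shift`` maps batch -> additive log2
    shift. Noise is i.i.d. Gaussian on the log2 scale; the emitted matrix
    is linear-scale intensities (2**log2), mirroring raw microarray export.
    """

    n_genes: int = 1000
    design: pd.DataFrame | None = None
    de_genes: Mapping[str, Mapping[tuple[float, float], float]] = field(
        default_factory=dict
    )
    noise_sd: float = 0.2
    batch_shift: Mapping[int, float] = field(default_factory=dict)
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class ExpressionStudy:
    """An expression matrix (genes/probes x samples) plus sample metadata.

    ``matrix`` holds positive linear-scale intensities or log2 values
    (tracked by ``log_scale``); ``samples`` carries dose_gy, day,
    replicate, batch per sample_id; ``truth_de`` (optional) carries the
    planted per-group log2 effects for generator output.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    log_scale: bool = False
    truth_de: Mapping[str, Mapping[tuple[float, float], float]] | None = None

    def __post_init__(self):
        missing = set(self.matrix.columns) - set(self.samples["sample_id"])
        if missing:
            raise ValueError(f"samples metadata missing for {sorted(missing)[:5]} ...")

    def groups(self) -> pd.Series:
        """(dose, day) group label per sample, aligned to matrix columns."""
        meta = self.samples.set_index("sample_id").loc[list(self.matrix.columns)]
        return pd.Series(
            list(zip(meta["dose_gy"], meta["day"])), index=self.matrix.columns
        )


def gen_expression_study(truth: ExpressionTruth) -> ExpressionStudy:
    """Simulate the expression study on the 12-group design.

    Per gene g and sample s: log2 x_gs = baseline_g + effect_g(group_s)
    + batch_shift(batch_s) + N(0, noise_sd); the matrix is returned on the
    linear intensity scale with the planted truth attached.
    """
    design = truth.design if truth.design is not None else default_expression_design()
    genes = [f"gene_{i:05d}" for i in range(truth.n_genes)]
    unknown = set(truth.de_genes) - set(genes)
    if unknown:
        raise ValueError(f"de_genes reference unknown gene ids: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(truth.seed)
    baseline = rng.normal(truth.baseline_mean, truth.baseline_sd, size=truth.n_genes)
    log2x = np.tile(baseline[:, None], (1, len(design)))
    gene_index = {g: i for i, g in enumerate(genes)}
    group_keys = list(zip(design["dose_gy"], design["day"]))
    for g, effects in truth.de_genes.items():
        gi = gene_index[g]
        for j, key in enumerate(group_keys):
            eff = effects.get(key, 0.0)
            if eff:
                log2x[gi, j] += eff
    for j, b in enumerate(design["batch"]):
        log2x[:, j] += truth.batch_shift.get(int(b), 0.0)
    if truth.noise_sd > 0:
        log2x += rng.normal(0.0, truth.noise_sd, size=log2x.shape)
    matrix = pd.DataFrame(
        np.exp2(log2x), index=genes, columns=list(design["sample_id"])
    )
    return ExpressionStudy(
        matrix=matrix,
        samples=design.copy(),
        log_scale=False,
        truth_de=dict(truth.de_genes),
    )


def gen_qpcr(
    condition_dct: Mapping[str, float],
    sd: float = 0.0,
    n: int = 3,
    housekeeping_ct: float = 12.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate paired target/housekeeping Ct wells per condition.

    ``condition_dct`` maps condition label -> true mean dCt
    (Ct_target - Ct_housekeeping); each of ``n`` wells draws independent
    Gaussian noise (sd) on both probes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for cond, dct in condition_dct.items():
        hk = housekeeping_ct + rng.normal(0.0, sd, size=n)
        target = hk + dct + rng.normal(0.0, sd, size=n)
        for tc, hc in zip(target, hk):
            rows.append(
                {
                    "condition": cond,
                    "target_ct": float(tc),
                    "housekeeping_ct": float(hc),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DyeTruth:
    """Ground truth for a dye-dilution intensity sample.

    Cells of generation k (k divisions since staining) carry log intensity
    Normal(mu0 - k*ln2, sd) where sd = sqrt(ln(1 + cv^2)) — the dye halves
    with each division. ``generation_fractions`` maps k -> fraction and
    must sum to 1.
    """

    generation_fractions: Mapping[int, float]
    mu0: float = 6.0
    cv: float = 0.15
    n_cells: int = 10000
    seed: int = 0

    def __post_init__(self):
        fr = dict(self.generation_fractions)
        if not fr or any(k < 0 or k > 10 for k in fr):
            raise ValueError("generations must lie in 0..10")
        if any(v < 0 for v in fr.values()) or abs(sum(fr.values()) - 1.0) > 1e-12:
            raise ValueError("generation_fractions must be a simplex (sum to 1)")
        if self.mu0 <= 0:
            raise ValueError("mu0 must be positive")
        if self.cv <= 0:
            raise ValueError("cv must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def gen_dye_intensities(truth: DyeTruth) -> np.ndarray:
    """Simulate per-cell dye fluorescence intensities (linear scale)."""
    rng = np.random.default_rng(truth.seed)
    gens = np.array(sorted(truth.generation_fractions), dtype=int)
    probs = np.array([truth.generation_fractions[int(k)] for k in gens], dtype=float)
    k = rng.choice(gens, size=truth.n_cells, p=probs / probs.sum())
    sd = float(np.sqrt(np.log1p(truth.cv**2)))
    log_i = rng.normal(truth.mu0 - k * LN2, sd)
    return np.exp(log_i)
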