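"""Differential-expression screen and relative qPCR quantification.

The screen mirrors a standard bulk-microarray workflow: quantile
normalization of raw intensities, log2 transform, collapse of probes to
unique genes, a simple per-gene batch location adjustment, a per-gene
one-way ANOVA across the (dose, day) groups of the 12-group design,
Holm step-down multiple-testing adjustment at a family-wise error bound
(default 10%), and a +-1.5 linear fold-change filter against the
day-matched 0 Gy controls. Relative qPCR quantification uses the
2^-ddCt method against a multiplexed housekeeping probe.

Batch adjustment here is deliberately a location-only (mean-centering)
correction, not an empirical-Bayes ComBat; within-batch contrasts are
preserved exactly, but scale effects are not touched.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import ExpressionStudy

__all__ = [
    "quantile_normalize",
    "log2_transform",
    "collapse_probes",
    "batch_mean_center",
    "holm_adjust",
    "anova_screen",
    "ddct_fold_change",
    "preprocess",
]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns (samples) of a positive intensity matrix.

    After normalization every sample carries the identical value
    distribution: the across-sample mean of each sorted rank. Ties within
    a sample receive the mean of the reference values their tied ranks
    span (midrank convention).
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    x = matrix.to_numpy(dtype=float)
    if np.any(x <= 0):
        raise ValueError("intensities must be positive")
    n = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(n, dtype=float)
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2 of positive intensities."""
    if (matrix.to_numpy() <= 0).any():
        raise ValueError("intensities must be positive")
    return np.log2(matrix)


def collapse_probes(matrix: pd.DataFrame, probe_map: Mapping[str, str]) -> pd.DataFrame:
    """Collapse probes to unique genes, keeping the probe with the highest
    mean intensity per gene; probes absent from the map are dropped."""
    if not probe_map:
        raise ValueError("empty probe map")
    keep = [p for p in matrix.index if p in probe_map]
    sub = matrix.loc[keep]
    genes = pd.Series([probe_map[p] for p in keep], index=sub.index, name="gene")
    means = sub.mean(axis=1)
    best = means.groupby(genes).idxmax()
    collapsed = sub.loc[best.to_numpy()]
    collapsed.index = best.index
    return collapsed.sort_index()


def batch_mean_center(matrix: pd.DataFrame, batches: Sequence) -> pd.DataFrame:
    """Per gene, shift each batch's mean to the gene's grand mean.

    Expects log-scale values. Batches with a single sample are passed
    through unchanged with a warning (no location estimate to remove).
    """
    batches = np.asarray(list(batches))
    if batches.size != matrix.shape[1]:
        raise ValueError("one batch label per sample is required")
    out = matrix.to_numpy(dtype=float).copy()
    grand = out.mean(axis=1, keepdims=True)
    for b in np.unique(batches):
        cols = batches == b
        if cols.sum() < 2:
            warnings.warn(
                f"batch {b!r} has a single sample; passed through uncorrected"
            )
            continue
        out[:, cols] += grand - out[:, cols].mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="holm")[1]


def _anova_f(x: np.ndarray, group_codes: np.ndarray, n_groups: int):
    """Vectorized one-way ANOVA over rows of ``x``; returns (F, p).

    Zero within-group variance across all groups (a degenerate,
    all-identical gene) yields p = 1.
    """
    n = x.shape[1]
    counts = np.bincount(group_codes, minlength=n_groups).astype(float)
    sums = np.zeros((x.shape[0], n_groups))
    sq = np.zeros_like(sums)
    np.add.at(sums.T, group_codes, x.T)
    np.add.at(sq.T, group_codes, (x * x).T)
    grand_mean = x.mean(axis=1, keepdims=True)
    group_means = sums / counts
    ss_between = ((group_means - grand_mean) ** 2 * counts).sum(axis=1)
    ss_within = (sq - sums**2 / counts).sum(axis=1)
    df_b = n_groups - 1
    df_w = n - n_groups
    if df_w <= 0:
        raise ValueError("need replicates within groups (df_within <= 0)")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    p = stats.f.sf(f, df_b, df_w)
    degenerate = ss_within <= 0
    if degenerate.any():
        # all-identical genes are non-informative; truly varying genes with
        # zero within-group noise are maximally significant
        flat = degenerate & (ss_between <= 1e-12)
        p[degenerate] = 0.0
        f[degenerate] = np.inf
        p[flat] = 1.0
        f[flat] = 0.0
    return f, p


def anova_screen(
    study: ExpressionStudy,
    q: float = 0.10,
    fc_threshold: float = 1.5,
    control_dose: float = 0.0,
) -> pd.DataFrame:
    """Per-gene 12-group ANOVA + Holm + fold-change screen.

    Expects a log2-scale study. Groups are the (dose, day) pairs. The
    fold change per irradiated group is taken against the day-matched
    ``control_dose`` group; a gene is significant when its Holm-adjusted
    p-value is below ``q`` and its maximal absolute linear fold change
    exceeds ``fc_threshold``.

    Returns a DataFrame indexed by gene with columns F, p, p_holm,
    max_log2fc, significant.
    """
    if not study.log_scale:
        raise ValueError("anova_screen expects log2-scale data; run preprocess first")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    x = study.matrix.to_numpy(dtype=float)
    groups = study.groups()
    keys = sorted(set(groups))
    if len(keys) < 2:
        raise ValueError("need >=2 (dose, day) groups")
    code_of = {k: i for i, k in enumerate(keys)}
    codes = np.array([code_of[g] for g in groups], dtype=int)
    if np.min(np.bincount(codes, minlength=len(keys))) < 2:
        raise ValueError("every (dose, day) group needs >=2 replicates")
    f, p = _anova_f(x, codes, len(keys))
    p_holm = holm_adjust(p)

    # max |log2 FC| of irradiated groups vs the day-matched control group
    counts = np.bincount(codes, minlength=len(keys)).astype(float)
    sums = np.zeros((x.shape[0], len(keys)))
    np.add.at(sums.T, codes, x.T)
    group_means = sums / counts
    days = sorted({day for _, day in keys})
    max_abs_fc = np.zeros(x.shape[0])
    signed_fc = np.zeros(x.shape[0])
    for day in days:
        ctrl_key = (control_dose, day)
        if ctrl_key not in code_of:
            continue
        ctrl = group_means[:, code_of[ctrl_key]]
        for key in keys:
            if key[1] != day or key[0] == control_dose:
                continue
            fc = group_means[:, code_of[key]] - ctrl
            upd = np.abs(fc) > max_abs_fc
            max_abs_fc[upd] = np.abs(fc[upd])
            signed_fc[upd] = fc[upd]
    significant = (p_holm < q) & (max_abs_fc > np.log2(fc_threshold))
    return pd.DataFrame(
        {
            "F": f,
            "p": p,
            "p_holm": p_holm,
            "max_log2fc": signed_fc,
            "significant": significant,
        },
        index=study.matrix.index,
    )


def preprocess(
    study: ExpressionStudy,
    probe_map: Mapping[str, str] | None = None,
    normalize_separately: bool = True,
    long_term_days: Sequence[float] = (35,),
    batch_correct: bool = True,
) -> ExpressionStudy:
    """Raw intensities -> screen-ready log2 study.

    Quantile normalization and log2 transform run separately for the
    short-term (days 1/4/6) and long-term (day 35) samples when
    ``normalize_separately`` (the arrays were hybridized in separate
    campaigns); probes collapse to genes by maximal mean intensity; batch
    mean-centering is applied to the short-term samples only, which is
    where the replicate/chip batching lives.
    """
    meta = study.samples.set_index("sample_id").loc[list(study.matrix.columns)]
    is_long = meta["day"].isin(long_term_days).to_numpy()
    mat = study.matrix
    if normalize_separately and is_long.any() and (~is_long).any():
        short = quantile_normalize(mat.loc[:, ~is_long])
        long = quantile_normalize(mat.loc[:, is_long])
        mat = pd.concat([short, long], axis=1)[mat.columns]
    else:
        mat = quantile_normalize(mat)
    mat = log2_transform(mat)
    if probe_map is not None:
        mat = collapse_probes(mat, probe_map)
    if batch_correct:
        short_cols = mat.columns[~is_long]
        if len(short_cols) >= 2:
            corrected = batch_mean_center(
                mat.loc[:, short_cols], meta.loc[short_cols, "batch"]
            )
            mat = pd.concat([corrected, mat.loc[:, mat.columns[is_long]]], axis=1)[
                mat.columns
            ]
    return ExpressionStudy(
        matrix=mat, samples=study.samples, log_scale=True, truth_de=study.truth_de
    )


def ddct_fold_change(
    records: pd.DataFrame, control_condition: str
) -> pd.Series:
    """2^-ddCt relative expression per condition.

    ``records`` needs columns condition, target_ct, housekeeping_ct. Per
    well dCt = Ct_target - Ct_housekeeping; ddCt = mean dCt(condition) -
    mean dCt(control); the returned fold change is 2^-ddCt (control == 1).
    """
    required = {"condition", "target_ct", "housekeeping_ct"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    if not np.isfinite(records[["target_ct", "housekeeping_ct"]].to_numpy()).all():
        raise ValueError("Ct values must be finite")
    dct = records["target_ct"] - records["housekeeping_ct"]
    mean_dct = dct.groupby(records["condition"]).mean()
    if control_condition not in mean_dct.index:
        raise ValueError(f"control condition {control_condition!r} has no records")
    ddct = mean_dct - mean_dct[control_condition]
    return np.exp2(-ddct).rename("fold_change")
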