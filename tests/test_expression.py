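"""Differential-expression screen components and qPCR quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from regrowth.expression import (
    anova_screen,
    batch_mean_center,
    collapse_probes,
    ddct_fold_change,
    holm_adjust,
    preprocess,
    quantile_normalize,
)
from regrowth.synthetic import ExpressionStudy, ExpressionTruth, gen_expression_study


def _brute_force_quantile(x: np.ndarray) -> np.ndarray:
    """Independent rank-average oracle (loops, midranks by explicit search)."""
    n, m = x.shape
    ref = np.mean(np.stack([np.sort(x[:, j]) for j in range(m)], axis=1), axis=1)
    out = np.zeros_like(x, dtype=float)
    for j in range(m):
        col = x[:, j]
        for i in range(n):
            smaller = np.sum(col < col[i])
            ties = np.sum(col == col[i])
            ranks = range(smaller, smaller + ties)
            out[i, j] = np.mean([ref[r] for r in ranks])
    return out


class TestQuantileNormalize:
    def test_identical_samples_unchanged(self):
        m = pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [1.0, 5.0, 2.0]})
        assert np.allclose(quantile_normalize(m), m)

    def test_permuted_samples_share_distribution(self, rng):
        col = rng.lognormal(size=50)
        m = pd.DataFrame({"a": col, "b": rng.permutation(col), "c": rng.permutation(col)})
        q = quantile_normalize(m)
        for c in q.columns[1:]:
            assert np.allclose(np.sort(q[c]), np.sort(q["a"]))

    def test_matches_brute_force_oracle(self, rng):
        x = rng.lognormal(size=(7, 3))
        x[2, 1] = x[5, 1]  # force a tie
        q = quantile_normalize(pd.DataFrame(x))
        assert np.allclose(q.to_numpy(), _brute_force_quantile(x))

    def test_idempotent(self, rng):
        m = pd.DataFrame(rng.lognormal(size=(30, 4)))
        q1 = quantile_normalize(m)
        q2 = quantile_normalize(q1)
        assert np.allclose(q1, q2)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"a": [1.0, -1.0], "b": [2.0, 3.0]}))


class TestCollapseProbes:
    def test_one_probe_per_gene_is_identity(self, rng):
        m = pd.DataFrame(rng.lognormal(size=(3, 2)), index=["p1", "p2", "p3"])
        out = collapse_probes(m, {"p1": "g1", "p2": "g2", "p3": "g3"})
        assert sorted(out.index) == ["g1", "g2", "g3"]
        assert np.allclose(out.loc["g2"], m.loc["p2"])

    def test_brightest_probe_selected(self):
        m = pd.DataFrame(
            {"s1": [1.0, 10.0], "s2": [2.0, 20.0]}, index=["dim", "bright"]
        )
        out = collapse_probes(m, {"dim": "g", "bright": "g"})
        assert np.allclose(out.loc["g"], m.loc["bright"])

    def test_five_probe_two_gene_enumeration(self, rng):
        x = rng.lognormal(size=(5, 3))
        probes = [f"p{i}" for i in range(5)]
        pmap = {"p0": "gA", "p1": "gA", "p2": "gB", "p3": "gB", "p4": "gB"}
        m = pd.DataFrame(x, index=probes)
        out = collapse_probes(m, pmap)
        for gene, members in (("gA", [0, 1]), ("gB", [2, 3, 4])):
            best = max(members, key=lambda i: x[i].mean())
            assert np.allclose(out.loc[gene], x[best])

    def test_unmapped_probes_dropped_and_empty_map_rejected(self, rng):
        m = pd.DataFrame(rng.lognormal(size=(2, 2)), index=["p1", "p2"])
        out = collapse_probes(m, {"p1": "g1"})
        assert list(out.index) == ["g1"]
        with pytest.raises(ValueError):
            collapse_probes(m, {})


class TestBatchMeanCenter:
    def test_single_batch_unchanged(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 4)))
        out = batch_mean_center(m, [1, 1, 1, 1])
        assert np.allclose(out, m)

    def test_planted_shift_removed_exactly(self, rng):
        base = rng.normal(8, 1, size=(20, 6))
        shifted = base.copy()
        shifted[:, 3:] += 0.7  # additive batch-2 shift
        out = batch_mean_center(pd.DataFrame(shifted), [1, 1, 1, 2, 2, 2])
        expect = batch_mean_center(pd.DataFrame(base), [1, 1, 1, 2, 2, 2])
        # identical up to the per-gene grand-mean offset the shift induces
        delta = (out - expect).to_numpy()
        assert np.allclose(delta, delta.mean(), atol=1e-12)
        # and the planted between-batch contrast is gone
        grand = out.mean(axis=1)
        assert np.allclose(out.iloc[:, :3].mean(axis=1), grand, atol=1e-12)
        assert np.allclose(out.iloc[:, 3:].mean(axis=1), grand, atol=1e-12)

    def test_batch_means_equal_grand_mean(self, rng):
        m = pd.DataFrame(rng.normal(size=(15, 9)))
        batches = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
        out = batch_mean_center(m, batches).to_numpy()
        grand = out.mean(axis=1)
        for b in (1, 2, 3):
            assert np.allclose(out[:, batches == b].mean(axis=1), grand)

    def test_singleton_batch_warns_and_passes_through(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 3)))
        with pytest.warns(UserWarning, match="single sample"):
            out = batch_mean_center(m, [1, 1, 2])
        assert np.allclose(out.iloc[:, 2], m.iloc[:, 2])


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_step_down(self):
        assert np.allclose(holm_adjust([0.01, 0.02, 0.03]), [0.03, 0.04, 0.04])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_adjusted_dominates_raw_and_bonferroni_bounds(self, ps):
        adj = holm_adjust(ps)
        p = np.asarray(ps)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= np.minimum(p * len(ps), 1.0) + 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


def _log2_study(matrix: pd.DataFrame, samples: pd.DataFrame) -> ExpressionStudy:
    return ExpressionStudy(matrix=matrix, samples=samples, log_scale=True)


class TestAnovaScreen:
    def _small_study(self, rng, n_genes=50, effect=None):
        truth = ExpressionTruth(
            n_genes=n_genes,
            de_genes=effect or {},
            noise_sd=0.15,
            seed=int(rng.integers(2**31)),
        )
        return gen_expression_study(truth)

    def test_f_statistic_matches_scipy_per_gene(self, rng):
        study = preprocess(self._small_study(rng, n_genes=20), batch_correct=False)
        res = anova_screen(study)
        groups = study.groups()
        keys = sorted(set(groups))
        for gene in study.matrix.index[:5]:
            samples = [
                study.matrix.loc[gene, groups[groups == k].index].to_numpy()
                for k in keys
            ]
            f_ref, p_ref = sps.f_oneway(*samples)
            assert res.loc[gene, "F"] == pytest.approx(f_ref, rel=1e-8)
            assert res.loc[gene, "p"] == pytest.approx(p_ref, rel=1e-6)

    def test_planted_effect_detected(self, rng):
        effect = {"gene_00003": {(8.0, 4): 1.5, (16.0, 4): 1.5}}
        study = preprocess(self._small_study(rng, effect=effect))
        res = anova_screen(study)
        assert bool(res.loc["gene_00003", "significant"])
        assert res.loc["gene_00003", "max_log2fc"] == pytest.approx(1.5, abs=0.4)

    def test_pure_null_mostly_clean(self, rng):
        study = preprocess(self._small_study(rng))
        res = anova_screen(study)
        assert res["significant"].sum() == 0

    def test_invariant_to_column_order(self, rng):
        study = self._small_study(rng, n_genes=15)
        proc = preprocess(study, batch_correct=False)
        res1 = anova_screen(proc)
        cols = list(proc.matrix.columns)
        shuffled = list(rng.permutation(cols))
        res2 = anova_screen(
            _log2_study(proc.matrix[shuffled], proc.samples)
        )
        assert np.allclose(res1["F"], res2["F"])

    def test_invariant_to_gene_level_constant_shift(self, rng):
        study = self._small_study(rng, n_genes=10)
        proc = preprocess(study, batch_correct=False)
        shifted = proc.matrix.copy()
        shifted.iloc[0] += 5.0
        res1 = anova_screen(proc)
        res2 = anova_screen(_log2_study(shifted, proc.samples))
        assert res1.loc[shifted.index[0], "F"] == pytest.approx(
            res2.loc[shifted.index[0], "F"], rel=1e-9
        )

    def test_all_identical_gene_gets_p_one(self):
        samples = gen_expression_study(ExpressionTruth(n_genes=2, seed=0)).samples
        mat = pd.DataFrame(
            np.vstack([np.full(39, 7.0), np.random.default_rng(0).normal(7, 1, 39)]),
            index=["flat", "noisy"],
            columns=samples["sample_id"],
        )
        res = anova_screen(_log2_study(mat, samples))
        assert res.loc["flat", "p"] == 1.0

    def test_raw_scale_rejected(self, rng):
        study = self._small_study(rng)
        with pytest.raises(ValueError, match="log2"):
            anova_screen(study)


class TestDdct:
    def test_control_is_unity_and_known_fold_changes(self):
        records = pd.DataFrame(
            {
                "condition": ["c", "c", "x", "x", "y", "y"],
                "target_ct": [15.0, 15.0, 14.0, 14.0, 18.321928, 18.321928],
                "housekeeping_ct": [10.0] * 6,
            }
        )
        fc = ddct_fold_change(records, "c")
        assert fc["c"] == pytest.approx(1.0)
        assert fc["x"] == pytest.approx(2.0)
        assert fc["y"] == pytest.approx(0.1, abs=1e-6)

    @given(shift=st.floats(-5.0, 5.0))
    def test_invariant_to_global_ct_shift(self, shift):
        records = pd.DataFrame(
            {
                "condition": ["c", "x", "x"],
                "target_ct": [15.0, 13.5, 14.1],
                "housekeeping_ct": [10.0, 10.2, 9.9],
            }
        )
        base = ddct_fold_change(records, "c")
        moved = records.copy()
        moved["target_ct"] += shift
        moved["housekeeping_ct"] += shift
        assert ddct_fold_change(moved, "c")["x"] == pytest.approx(base["x"], rel=1e-9)

    def test_missing_control_rejected(self):
        records = pd.DataFrame(
            {"condition": ["x"], "target_ct": [14.0], "housekeeping_ct": [10.0]}
        )
        with pytest.raises(ValueError, match="control"):
            ddct_fold_change(records, "c")
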