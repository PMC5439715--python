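"""Cellular-automaton bookkeeping, oracles, and scenario machinery."""

import numpy as np
import pytest

from regrowth.automaton import (
    NPMA,
    VIABLE,
    CAParameters,
    apply_irradiation,
    dormancy_fraction,
    extinction_probability,
    gw_extinction_probability,
    init_state,
    local_inhibition_mask,
    mean_field_growth_factor,
    run_scenario,
    step,
)


def _quiet_params(**kw):
    base = dict(p_d=0.0, p_a=0.0, p_s=0.5, mu=0.0, m=1, lattice_size=32, seed=0)
    base.update(kw)
    return CAParameters(**base)


class TestInitState:
    def test_single_cell_at_center(self):
        p = _quiet_params()
        st = init_state(p, 1)
        assert st.grid[16, 16] == VIABLE
        assert st.counts()["n_total"] == 1

    def test_full_lattice_has_no_births(self):
        p = _quiet_params(p_d=1.0, lattice_size=8)
        st = init_state(p, 64)
        step(st, p)
        assert st.counts()["n_viable"] == 64  # nowhere to place daughters

    def test_capacity_respected(self):
        p = _quiet_params(capacity=10)
        with pytest.raises(ValueError):
            init_state(p, 11)

    def test_deterministic_for_fixed_seed(self):
        p = _quiet_params(p_d=0.3, p_a=0.05, mu=2.0, seed=42)
        runs = []
        for _ in range(2):
            st = init_state(p, 50)
            for _ in range(10):
                step(st, p)
            runs.append((st.grid.copy(), st.dormancy.copy()))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])


class TestIrradiation:
    def test_full_survival_is_noop(self):
        p = _quiet_params()
        st = init_state(p, 100)
        before = st.grid.copy()
        apply_irradiation(st, 1.0, 0.5)
        assert np.array_equal(st.grid, before)

    def test_surviving_count_binomial_at_8gy_survival(self):
        p = _quiet_params(lattice_size=128)
        st = init_state(p, 10000)
        apply_irradiation(st, 0.0255, 1.0)
        c = st.counts()
        expected, sd = 255.0, np.sqrt(10000 * 0.0255 * (1 - 0.0255))
        assert abs(c["n_viable"] - expected) < 3 * sd
        # with p_s = 1 every inactivated cell persists as NPMA
        assert c["n_viable"] + c["n_npma"] == 10000

    def test_npma_conversion_two_stage_binomial(self):
        p = _quiet_params(lattice_size=128)
        st = init_state(p, 10000)
        apply_irradiation(st, 0.5, 0.5)
        n_npma = st.counts()["n_npma"]
        sd = np.sqrt(10000 * 0.25 * 0.75)
        assert abs(n_npma - 2500) < 3 * sd

    def test_invalid_survival_rejected(self):
        st = init_state(_quiet_params(), 10)
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                apply_irradiation(st, bad, 0.5)


class TestStep:
    def test_inert_parameters_change_only_counters(self):
        p = _quiet_params()
        st = init_state(p, 20)
        before = st.grid.copy()
        step(st, p)
        assert np.array_equal(st.grid, before)
        assert dormancy_fraction(st, 1) == 1.0  # nobody divided

    def test_certain_death_clears_viable_cells(self):
        p = _quiet_params(p_a=1.0, p_d=0.0)
        st = init_state(p, 30)
        step(st, p)
        assert st.counts()["n_viable"] == 0

    def test_bookkeeping_grid_matches_counts(self):
        p = _quiet_params(p_d=0.3, p_a=0.05, mu=2.0, npma_clearance=0.1)
        st = init_state(p, 200, placement="scatter")
        apply_irradiation(st, 0.6, 0.5)
        for _ in range(15):
            step(st, p)
            c = st.counts()
            assert c["n_viable"] == np.count_nonzero(st.grid == VIABLE)
            assert c["n_npma"] == np.count_nonzero(st.grid == NPMA)
            assert c["n_prolif"] + c["n_quiescent"] == c["n_viable"]
            assert c["n_total"] <= p.effective_capacity

    def test_capacity_cap_enforced(self):
        p = _quiet_params(p_d=0.5, capacity=40)
        st = init_state(p, 30)
        for _ in range(20):
            step(st, p)
            assert st.counts()["n_total"] <= 40

    def test_npma_never_divides(self):
        p = _quiet_params(p_d=1.0, m=0)
        st = init_state(p, 1)
        st.grid[16, 16] = NPMA
        for _ in range(5):
            step(st, p)
        assert st.counts()["n_total"] == 1


class TestLocalInhibition:
    def test_no_npma_empty_mask(self):
        st = init_state(_quiet_params(), 10)
        assert not local_inhibition_mask(st, 1).any()

    def test_single_npma_radius1_masks_nine_sites(self):
        p = _quiet_params()
        st = init_state(p, 0)
        st.grid[10, 10] = NPMA
        mask = local_inhibition_mask(st, 1)
        assert mask.sum() == 9
        assert mask[9:12, 9:12].all()

    def test_mask_monotone_in_radius(self):
        p = _quiet_params(lattice_size=64, seed=5)
        st = init_state(p, 300, placement="scatter")
        apply_irradiation(st, 0.5, 0.8)
        m1 = local_inhibition_mask(st, 1)
        m2 = local_inhibition_mask(st, 2)
        assert (m1 <= m2).all()

    def test_inhibited_cell_does_not_divide(self):
        p = _quiet_params(p_d=1.0, m=0, inhibition_radius=1)
        st = init_state(p, 1)
        st.grid[15, 15] = NPMA  # adjacent to the center cell at (16, 16)
        step(st, p)
        assert st.counts()["n_viable"] == 1


class TestMeanFieldOracle:
    def test_closed_form(self):
        assert mean_field_growth_factor(CAParameters(p_d=0.0, p_a=0.0)) == 1.0
        assert mean_field_growth_factor(CAParameters(p_d=0.3, p_a=0.05)) == pytest.approx(1.25)
        assert mean_field_growth_factor(CAParameters(p_d=0.2, p_a=0.2)) == pytest.approx(1.0)

    def test_low_density_growth_matches_closed_form(self):
        pd_, pa_ = 0.3, 0.05
        factors = []
        for seed in range(10):
            p = CAParameters(p_d=pd_, p_a=pa_, m=0, mu=0.0, lattice_size=200, seed=seed)
            st = init_state(p, 300, placement="scatter")
            counts = [300]
            for _ in range(5):
                step(st, p)
                counts.append(st.counts()["n_viable"])
            c = np.asarray(counts, float)
            factors.extend(c[1:] / c[:-1])
        se = np.std(factors) / np.sqrt(len(factors))
        assert abs(np.mean(factors) - (1 + pd_ - pa_)) < 3 * se


class TestExtinction:
    def test_certain_extinction(self):
        # one expected survivor then certain death, division off
        p = _quiet_params(p_a=1.0, p_d=0.0, lattice_size=64)
        phat, se = extinction_probability(
            p, (0.01, 0.0), n_reps=5, t_max=5, n0=100
        )
        assert phat == 1.0

    def test_no_death_never_extinct(self):
        p = _quiet_params(p_d=0.3, p_a=0.0, lattice_size=64)
        phat, _ = extinction_probability(p, (0.5, 0.0), n_reps=5, t_max=10, n0=50)
        assert phat == 0.0

    def test_branching_process_fixed_point(self):
        # space-non-limiting regime: scattered single cells, high migration
        pd_, pa_ = 0.3, 0.1
        q = gw_extinction_probability(pd_, pa_)
        assert q == pytest.approx(pa_ / pd_, abs=1e-9)
        ext = 0
        n_reps = 200
        for seed in range(n_reps):
            p = CAParameters(p_d=pd_, p_a=pa_, m=0, mu=5.0, lattice_size=64, seed=seed)
            st = init_state(p, 1, placement="scatter")
            n = 1
            for _ in range(150):
                step(st, p)
                n = st.counts()["n_viable"]
                if n == 0 or n > 150:
                    break
            ext += n == 0
        se = np.sqrt(q * (1 - q) / n_reps)
        assert abs(ext / n_reps - q) < 3 * se

    def test_subcritical_is_certain(self):
        assert gw_extinction_probability(0.1, 0.2) == 1.0


class TestScenarios:
    def test_global_requires_global_pa(self):
        p = _quiet_params(p_d=0.3)
        with pytest.raises(ValueError, match="global_pa"):
            run_scenario(p, 10, (0.5, 0.5), scenario="global", t_max=2)

    def test_local_requires_radius(self):
        p = _quiet_params(p_d=0.3)
        with pytest.raises(ValueError, match="inhibition_radius"):
            run_scenario(p, 10, (0.5, 0.5), scenario="local", t_max=2)

    def test_unirradiated_scenario_matches_baseline_growth(self):
        p = CAParameters(p_d=0.28, p_a=0.01, mu=5.0, m=1, lattice_size=128, seed=2)
        res = run_scenario(
            p, 200, (1.0, 0.5), scenario="none", t_max=60,
            detection_size=400, stop_size=1600,
        )
        assert not res.extinct
        assert res.growth_fit is not None
        # surface-limited lattice growth sits below the mean-field rate
        assert 0.0 < res.growth_fit.rate < np.log(mean_field_growth_factor(p))

    def test_elevated_death_slows_growth_on_matched_seeds(self):
        rates = {}
        for pa_override, key in ((None, "baseline"), (0.06, "global")):
            rs = []
            for seed in range(3):
                p = CAParameters(
                    p_d=0.28, p_a=0.01, mu=5.0, global_pa=pa_override,
                    npma_clearance=0.05, lattice_size=128, seed=seed,
                )
                res = run_scenario(
                    p, 2000, (0.1, 0.5),
                    scenario="global" if pa_override else "none",
                    t_max=80, detection_size=500, stop_size=2000,
                )
                assert res.growth_fit is not None
                rs.append(res.growth_fit.rate)
            rates[key] = np.mean(rs)
        assert rates["global"] < rates["baseline"]


class TestDormancy:
    def test_fresh_state_has_no_dormant_fraction(self):
        st = init_state(_quiet_params(), 50)
        assert dormancy_fraction(st, 1) == 0.0

    def test_handcrafted_registry(self):
        p = _quiet_params()
        st = init_state(p, 0)
        for (i, j), d in {(1, 1): 5, (2, 2): 5, (3, 3): 1, (4, 4): 0}.items():
            st.grid[i, j] = VIABLE
            st.dormancy[i, j] = d
        assert dormancy_fraction(st, 4) == pytest.approx(0.5)

    def test_empty_state_and_validation(self):
        st = init_state(_quiet_params(), 0)
        assert dormancy_fraction(st, 4) == 0.0
        with pytest.raises(ValueError):
            dormancy_fraction(st, -1)
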