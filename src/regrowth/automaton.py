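"""Stochastic lattice cellular automaton of post-irradiation tumor regrowth.

Cells live on a 2-D square lattice with a Moore (8-site) neighborhood and
occupy one of three states:

* proliferative — clonogenically viable with at least one free neighbor
  site, hence able to divide;
* quiescent — viable but transiently arrested because no neighbor site is
  free (reversible the moment space opens up);
* NPMA — non-proliferative but metabolically active: stably arrested
  radiation-inactivated cells (the senescent-like, secretory survivors)
  that occupy space, never divide or migrate, and are cleared at a
  configurable per-day rate.

Each simulated day every cell, in freshly shuffled order, performs exactly
one of {clear/die, divide, migrate, persist}. Death and division are
exclusive competing fates drawn once per day: a viable cell dies with
probability ``p_a`` (or the elevated ``global_pa`` under the host-mediated
inhibition scenario), divides with probability ``p_d`` into a uniformly
chosen free neighbor site provided it is mature (``m`` days old) and not
suppressed by local inhibition, and otherwise makes ``mu`` migration
attempts into free neighbor sites. The exclusive draw makes the
low-density expected per-day growth factor exactly ``1 + p_d - p_a``
(offspring 0 with p_a, 2 with p_d, 1 otherwise), which is the closed-form
oracle the simulator is verified against; it requires ``p_a + p_d <= 1``. Local inhibition suppresses division
(only) within Chebyshev radius ``R`` of any NPMA cell. Counters track
maturity since birth and dormancy (days since last division).

Three irradiation-response scenarios are exposed through
:func:`run_scenario`: ``none`` (cell kill only), ``local`` (NPMA-secreted
factors inhibit division within R cell diameters) and ``global`` (a
systemic, host-mediated elevation of the death probability for every
tumor cell), which is the machinery used to discriminate local from
host-mediated growth inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .survival import GrowthFit, InsufficientDataError, fit_exponential_growth

__all__ = [
    "EMPTY",
    "VIABLE",
    "NPMA",
    "CAParameters",
    "SimState",
    "SimResult",
    "init_state",
    "apply_irradiation",
    "local_inhibition_mask",
    "step",
    "run_scenario",
    "dormancy_fraction",
    "extinction_probability",
    "mean_field_growth_factor",
    "gw_extinction_probability",
]

EMPTY, VIABLE, NPMA = 0, 1, 2
_BORDER = 3  # sentinel ring kept outside the public lattice view


@dataclass(frozen=True)
class CAParameters:
    """Cellular-automaton parameters; probabilities are per day.

    Defaults are calibrated so the unirradiated low-density doubling time
    (~ln2/(p_d - p_a) ≈ 2.6 days) sits near the U87-MG in vitro growth
    curve; they are calibration knobs, not biological claims.
    """

    p_d: float = 0.28  # division probability per day
    p_a: float = 0.01  # baseline death probability per day
    p_s: float = 0.5  # P(inactivated cell becomes NPMA rather than dying)
    mu: float = 5.0  # expected migration attempts per day
    m: int = 1  # maturation days before division competence
    inhibition_radius: int = 0  # Chebyshev radius R of local inhibition (0 = off)
    global_pa: Optional[float] = None  # replacement p_a for the global scenario
    lattice_size: int = 256
    capacity: Optional[int] = None  # optional total-count cap (<= lattice_size**2)
    npma_clearance: float = 0.0  # per-day NPMA removal probability
    seed: int = 0

    def __post_init__(self):
        for name in ("p_d", "p_a", "p_s", "npma_clearance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.global_pa is not None and not 0.0 <= self.global_pa <= 1.0:
            raise ValueError("global_pa must lie in [0, 1]")
        if self.p_a + self.p_d > 1.0:
            raise ValueError("p_a + p_d must not exceed 1 (exclusive daily fates)")
        if self.global_pa is not None and self.global_pa + self.p_d > 1.0:
            raise ValueError("global_pa + p_d must not exceed 1")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.m < 0 or self.inhibition_radius < 0:
            raise ValueError("m and inhibition_radius must be non-negative integers")
        if self.lattice_size < 8:
            raise ValueError("lattice_size must be >= 8")
        if self.capacity is not None and self.capacity > self.lattice_size**2:
            raise ValueError("capacity cannot exceed lattice_size**2")

    @property
    def effective_capacity(self) -> int:
        return self.capacity if self.capacity is not None else self.lattice_size**2


class SimState:
    """Lattice state: occupancy grid plus per-site maturity/dormancy counters.

    ``grid`` (int8: EMPTY/VIABLE/NPMA), ``maturity`` (days since birth,
    capped at m) and ``dormancy`` (days since last division) are L x L
    views onto internally padded arrays — the one-cell sentinel border
    lets the update loop use flat neighbor offsets without bounds checks.
    """

    def __init__(
        self,
        grid: np.ndarray,
        maturity: np.ndarray,
        dormancy: np.ndarray,
        t: float = 0.0,
        rng: Optional[np.random.Generator] = None,
    ):
        L = grid.shape[0]
        self._grid = np.full((L + 2, L + 2), _BORDER, dtype=np.int8)
        self._grid[1:-1, 1:-1] = grid
        self._maturity = np.zeros((L + 2, L + 2), dtype=np.int32)
        self._maturity[1:-1, 1:-1] = maturity
        self._dormancy = np.zeros((L + 2, L + 2), dtype=np.int32)
        self._dormancy[1:-1, 1:-1] = dormancy
        self.t = t
        self.rng = rng if rng is not None else np.random.default_rng()

    @property
    def grid(self) -> np.ndarray:
        return self._grid[1:-1, 1:-1]

    @property
    def maturity(self) -> np.ndarray:
        return self._maturity[1:-1, 1:-1]

    @property
    def dormancy(self) -> np.ndarray:
        return self._dormancy[1:-1, 1:-1]

    def counts(self) -> dict:
        """Per-state tallies; proliferative = viable with a free neighbor."""
        viable = self.grid == VIABLE
        npma = self.grid == NPMA
        free_adjacent = ndimage.maximum_filter(
            (self.grid == EMPTY).astype(np.uint8), size=3, mode="constant", cval=0
        ).astype(bool)
        n_prolif = int(np.count_nonzero(viable & free_adjacent))
        n_viable = int(np.count_nonzero(viable))
        return {
            "n_prolif": n_prolif,
            "n_quiescent": n_viable - n_prolif,
            "n_npma": int(np.count_nonzero(npma)),
            "n_viable": n_viable,
            "n_total": n_viable + int(np.count_nonzero(npma)),
        }

    def dormancy_histogram(self) -> pd.Series:
        occ = self.grid != EMPTY
        return pd.Series(self.dormancy[occ]).value_counts().sort_index()


@dataclass
class SimResult:
    """Trajectory and summary of one scenario run."""

    trajectory: pd.DataFrame  # columns t, n_prolif, n_quiescent, n_npma, n_viable, n_total
    extinct: bool
    growth_fit: Optional[GrowthFit]
    final_state: SimState
    scenario: str
    params: CAParameters


def init_state(params: CAParameters, n0: int, placement: str = "disc") -> SimState:
    """Create a state with ``n0`` viable cells, mature and never-divided.

    placement="disc" packs them into a compact disc at the lattice center
    (an implanted bolus); placement="scatter" spreads them uniformly over
    free sites (a low-density culture, useful for mean-field checks).
    """
    if n0 > params.effective_capacity:
        raise ValueError(f"n0={n0} exceeds capacity {params.effective_capacity}")
    L = params.lattice_size
    if n0 > L * L:
        raise ValueError("n0 exceeds lattice size")
    rng = np.random.default_rng(params.seed)
    grid = np.zeros((L, L), dtype=np.int8)
    if placement == "disc":
        c = L // 2
        ii, jj = np.indices((L, L))
        r2 = (ii - c) ** 2 + (jj - c) ** 2
        order = np.argsort(r2, axis=None, kind="stable")[:n0]
        grid.flat[order] = VIABLE
    elif placement == "scatter":
        sites = rng.choice(L * L, size=n0, replace=False)
        grid.flat[sites] = VIABLE
    else:
        raise ValueError(f"unknown placement {placement!r}")
    maturity = np.zeros((L, L), dtype=np.int32)
    maturity[grid == VIABLE] = params.m
    dormancy = np.zeros((L, L), dtype=np.int32)
    return SimState(grid=grid, maturity=maturity, dormancy=dormancy, t=0.0, rng=rng)


def apply_irradiation(
    state: SimState, surviving_fraction: float, p_s: float
) -> SimState:
    """Irradiate in place: each viable cell keeps clonogenic viability with
    probability ``surviving_fraction``; inactivated cells convert to NPMA
    with probability ``p_s`` and are removed otherwise."""
    if not 0.0 < surviving_fraction <= 1.0:
        raise ValueError("surviving_fraction must lie in (0, 1]")
    if not 0.0 <= p_s <= 1.0:
        raise ValueError("p_s must lie in [0, 1]")
    if surviving_fraction == 1.0:
        return state
    viable = state.grid == VIABLE
    n = int(viable.sum())
    u = state.rng.random(n)
    keeps = u < surviving_fraction
    fate_npma = state.rng.random(n) < p_s
    idx = np.argwhere(viable)
    killed = idx[~keeps & ~fate_npma]
    converted = idx[~keeps & fate_npma]
    state.grid[killed[:, 0], killed[:, 1]] = EMPTY
    state.grid[converted[:, 0], converted[:, 1]] = NPMA
    state.dormancy[converted[:, 0], converted[:, 1]] = 0
    return state


def local_inhibition_mask(state: SimState, radius: int) -> np.ndarray:
    """Boolean lattice mask of positions within Chebyshev distance
    ``radius`` of any NPMA cell; division is suppressed there for the step.
    ``radius`` 0 (or no NPMA cells) gives an all-False mask."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    npma = state.grid == NPMA
    if radius == 0 or not npma.any():
        return np.zeros_like(npma, dtype=bool)
    return ndimage.maximum_filter(
        npma.astype(np.uint8), size=2 * radius + 1, mode="constant", cval=0
    ).astype(bool)


def step(state: SimState, params: CAParameters, p_a: Optional[float] = None) -> SimState:
    """Advance the automaton one day (in place; returns the state).

    Cells act in a freshly shuffled order (random sequential update). Each
    acts exactly once even if a later-listed site is re-occupied by a mover
    or daughter. ``p_a`` overrides the death probability (used by the
    global-inhibition scenario).

    The loop runs over flat indices of the padded lattice through
    memoryviews (a measured ~3x over 2-D ndarray indexing); neighbor
    choices consume a pre-drawn uniform pool so the RNG call count stays
    off the per-cell hot path.
    """
    rng = state.rng
    W = state._grid.shape[0]
    pa = params.p_a if p_a is None else p_a
    pa_pd = pa + params.p_d
    mu, m_req = params.mu, params.m
    clr = params.npma_clearance
    capacity = params.effective_capacity
    offs = (-W - 1, -W, -W + 1, -1, 1, W - 1, W, W + 1)

    gflat = state._grid.ravel()
    occ = np.flatnonzero((gflat == VIABLE) | (gflat == NPMA))
    n = occ.size
    if n == 0:
        state.t += 1.0
        return state
    occ = occ[rng.permutation(n)].tolist()
    u_fate = rng.random(n).tolist()
    u_mig_frac = rng.random(n).tolist()
    pool = rng.random(2 * n + 64).tolist()
    pool_i = 0
    pool_len = len(pool)

    inh = None
    if params.inhibition_radius > 0:
        mask = local_inhibition_mask(state, params.inhibition_radius)
        if mask.any():
            padded = np.zeros((W, W), dtype=np.uint8)
            padded[1:-1, 1:-1] = mask
            inh = memoryview(padded.ravel())

    g = memoryview(gflat)
    mat = memoryview(state._maturity.ravel())
    dor = memoryview(state._dormancy.ravel())
    acted = bytearray(W * W)
    n_total = n
    mu_int = int(mu)
    mu_frac = mu - mu_int

    for idx in range(n):
        p = occ[idx]
        s = g[p]
        if s == EMPTY or acted[p]:
            continue
        u = u_fate[idx]
        if s == NPMA:
            if clr > 0.0 and u < clr:
                g[p] = EMPTY
                n_total -= 1
            else:
                dor[p] += 1
            continue
        # viable cell: one exclusive fate draw — death, division, or neither
        if u < pa:
            g[p] = EMPTY
            n_total -= 1
            continue
        free = [q for q in (p + o for o in offs) if g[q] == EMPTY]
        moved_or_divided = False
        if free:
            if (
                u < pa_pd
                and mat[p] >= m_req
                and n_total < capacity
                and (inh is None or not inh[p])
            ):
                if pool_i >= pool_len:
                    pool.extend(rng.random(n + 64).tolist())
                    pool_len = len(pool)
                q = free[int(pool[pool_i] * len(free))]
                pool_i += 1
                g[q] = VIABLE
                mat[q] = 0
                dor[q] = 0
                acted[q] = 1
                dor[p] = 0
                if mat[p] < m_req:
                    mat[p] += 1
                n_total += 1
                moved_or_divided = True
            elif mu_int or mu_frac:
                # migration: mu expected attempts per day
                attempts = mu_int + (1 if u_mig_frac[idx] < mu_frac else 0)
                c = p
                for _ in range(attempts):
                    free_here = [q for q in (c + o for o in offs) if g[q] == EMPTY]
                    if not free_here:
                        break
                    if pool_i >= pool_len:
                        pool.extend(rng.random(n + 64).tolist())
                        pool_len = len(pool)
                    q = free_here[int(pool[pool_i] * len(free_here))]
                    pool_i += 1
                    g[q] = VIABLE
                    mat[q] = mat[c]
                    dor[q] = dor[c]
                    g[c] = EMPTY
                    mat[c] = 0
                    dor[c] = 0
                    acted[q] = 1
                    c = q
                if c != p:
                    dor[c] += 1
                    if mat[c] < m_req:
                        mat[c] += 1
                    moved_or_divided = True  # counters handled at new site
        # quiescent (no free site) or non-dividing cell staying in place
        if not moved_or_divided:
            dor[p] += 1
            if mat[p] < m_req:
                mat[p] += 1
    state.t += 1.0
    return state


def dormancy_fraction(state: SimState, k: int) -> float:
    """Fraction of living cells (viable + NPMA) not having divided for at
    least ``k`` days. Returns 0 for an empty lattice."""
    if k < 0:
        raise ValueError("k must be >= 0")
    occ = state.grid != EMPTY
    n = int(occ.sum())
    if n == 0:
        return 0.0
    return float(np.count_nonzero(state.dormancy[occ] >= k)) / n


def mean_field_growth_factor(params: CAParameters) -> float:
    """Low-density, maturity-saturated per-step growth factor 1 + p_d - p_a."""
    return 1.0 + params.p_d - params.p_a


def run_scenario(
    params: CAParameters,
    n0: int,
    dose_spec: tuple[float, float],
    scenario: str = "none",
    t_max: int = 120,
    detection_size: int = 2000,
    stop_size: Optional[int] = None,
    placement: str = "disc",
) -> SimResult:
    """Initialize, irradiate, and iterate the automaton under a scenario.

    ``dose_spec`` is (surviving_fraction, p_s). Scenarios:

    * ``none``   — irradiation cell kill only;
    * ``local``  — NPMA cells suppress division within ``inhibition_radius``
      (requires R >= 1);
    * ``global`` — host-mediated systemic inhibition: the death probability
      is replaced by ``params.global_pa`` from the irradiation time onward
      (requires ``global_pa``).

    Runs to ``t_max`` days, extinction, or total viable count reaching
    ``stop_size`` (default 4x ``detection_size``). The growth rate is
    fitted by log-linear regression to viable counts at or above
    ``detection_size``.
    """
    if scenario not in ("none", "local", "global"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "global" and params.global_pa is None:
        raise ValueError("scenario='global' requires params.global_pa")
    if scenario == "local" and params.inhibition_radius < 1:
        raise ValueError("scenario='local' requires inhibition_radius >= 1")
    if scenario != "local" and params.inhibition_radius != 0:
        params = replace(params, inhibition_radius=0)
    if stop_size is None:
        stop_size = 4 * detection_size

    surviving_fraction, p_s = dose_spec
    state = init_state(params, n0, placement=placement)
    apply_irradiation(state, surviving_fraction, p_s)
    pa_override = params.global_pa if scenario == "global" else None

    rows = [dict(t=state.t, **state.counts())]
    while state.t < t_max:
        step(state, params, p_a=pa_override)
        c = state.counts()
        rows.append(dict(t=state.t, **c))
        if c["n_viable"] == 0 or c["n_viable"] >= stop_size:
            break
    traj = pd.DataFrame(rows)
    extinct = bool(traj["n_viable"].iloc[-1] == 0)
    fit = None
    if not extinct:
        try:
            above = traj[traj["n_viable"] >= detection_size]
            fit = fit_exponential_growth(
                above["t"], above["n_viable"], min_value=detection_size
            )
        except InsufficientDataError:
            fit = None
    return SimResult(
        trajectory=traj,
        extinct=extinct,
        growth_fit=fit,
        final_state=state,
        scenario=scenario,
        params=params,
    )


def extinction_probability(
    params: CAParameters,
    dose_spec: tuple[float, float],
    scenario: str = "none",
    n_reps: int = 20,
    t_max: int = 60,
    n0: int = 1000,
    placement: str = "disc",
) -> tuple[float, float]:
    """Monte-Carlo extinction probability with binomial standard error.

    Runs ``n_reps`` replicate simulations (seeds derived from
    ``params.seed``) and reports the fraction ending with zero viable
    cells, +- sqrt(p(1-p)/n).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    seeds = np.random.SeedSequence(params.seed).generate_state(n_reps) % (2**31)
    extinct = 0
    for s in seeds:
        p = replace(params, seed=int(s))
        res = run_scenario(
            p,
            n0,
            dose_spec,
            scenario=scenario,
            t_max=t_max,
            detection_size=10**9,  # no early stop on size
            stop_size=10**9,
            placement=placement,
        )
        extinct += int(res.extinct)
    phat = extinct / n_reps
    se = float(np.sqrt(phat * (1 - phat) / n_reps))
    return phat, se


def gw_extinction_probability(p_d: float, p_a: float, tol: float = 1e-12) -> float:
    """Galton-Watson extinction probability for the space-free automaton.

    Per day a lineage cell leaves 0 offspring with probability p_a, 2 with
    probability p_d, else 1 (the automaton's exclusive daily fate draw).
    The extinction probability starting from one cell is the smallest
    fixed point of the offspring pgf
    f(q) = p_a + (1 - p_a - p_d) q + p_d q^2, found numerically. Serves as
    the independent oracle for sparse-lattice extinction runs.
    """
    if p_a + p_d > 1.0:
        raise ValueError("p_a + p_d must not exceed 1")
    mean_offspring = 1.0 + p_d - p_a
    if mean_offspring <= 1.0 or p_d == 0.0:
        return 1.0
    a = p_d
    b = -(p_a + p_d)
    c = p_a
    # f(q) - q = a q^2 + b q + c = 0; roots are 1 and c/a — take the smaller
    def g(q):
        return a * q * q + b * q + c

    root = float(optimize.brentq(g, 0.0, 1.0 - 1e-9, xtol=tol))
    return root
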