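"""Daily update semantics, crossing times and the deterministic-limit oracle."""

import json
import math

import numpy as np
import pytest

from intrares import (
    CellState,
    DrugClass,
    Gene,
    ModelParams,
    PopulationState,
    SENSITIZING_GENES,
    expected_growth_time,
    simulate_until,
    step,
)

MUTATION_FREE = ModelParams(
    s=0.05,
    mu_sens={g: 0.0 for g in SENSITIZING_GENES},
    mu_res={d: 0.0 for d in DrugClass},
)


def test_every_divided_cell_leaves_two_daughters(rng):
    """One step maps each cell to 0 or 2 daughters, so totals are even."""
    pop = PopulationState(counts={CellState(): 10_000})
    for day in range(1, 21):
        pop = step(pop, ModelParams.default(), rng)
        assert pop.total % 2 == 0
        assert pop.day == day


def test_mutation_free_population_never_diversifies(rng):
    pop = PopulationState(counts={CellState(): 5_000})
    for _ in range(50):
        pop = step(pop, MUTATION_FREE, rng)
        assert set(pop.counts) <= {CellState()}


def test_critical_process_preserves_mean_total(rng):
    """At s=0 the expected one-step multiplication factor is exactly 1."""
    p = ModelParams(
        s=0.0,
        mu_sens={g: 0.0 for g in SENSITIZING_GENES},
        mu_res={d: 0.0 for d in DrugClass},
    )
    n0 = 1_000_000
    factors = []
    for _ in range(100):
        nxt = step(PopulationState(counts={CellState(): n0}), p, rng)
        factors.append(nxt.total / n0)
    mean = np.mean(factors)
    se = np.std(factors, ddof=1) / math.sqrt(len(factors))
    assert abs(mean - 1.0) < 4 * se + 1e-9


def test_mutant_daughters_are_allocated_proportionally(rng):
    """Asynchronous daughters land on targets in proportion to their rates."""
    p = ModelParams(
        s=0.05,
        mu_sens={g: (0.3 if g is Gene.KRAS else (0.1 if g is Gene.EGFR else 0.0))
                 for g in SENSITIZING_GENES},
        mu_res={d: 0.0 for d in DrugClass},
    )
    pop = PopulationState(counts={CellState(): 2_000_000})
    nxt = step(pop, p, rng)
    kras = nxt.counts.get(CellState(gene=Gene.KRAS), 0)
    egfr = nxt.counts.get(CellState(gene=Gene.EGFR), 0)
    assert kras + egfr > 10_000
    ratio = kras / (kras + egfr)
    se = math.sqrt(0.75 * 0.25 / (kras + egfr))
    assert abs(ratio - 0.75) < 5 * se


class TestSimulateUntil:
    def test_stop_at_initial_burden_takes_zero_steps(self, params):
        initial = PopulationState(counts={CellState(): 100})
        traj = simulate_until(initial, params, stop_burden=100, thresholds=[50, 100],
                              seed=0)
        assert traj.final.day == 0
        assert traj.crossing_days == {50: 0, 100: 0}

    def test_crossing_days_monotone_in_threshold(self, params):
        thresholds = [10, 100, 1_000, 10_000]
        traj = simulate_until(None, params, stop_burden=10_000,
                              thresholds=thresholds, seed=3)
        days = [traj.crossing_days[t] for t in thresholds]
        assert days == sorted(days)
        assert traj.final.total >= 10_000

    def test_restarts_are_counted_and_conditioned_on_survival(self):
        """Starting from one cell, most attempts die; the survivor is kept."""
        restarts = [
            simulate_until(None, MUTATION_FREE, stop_burden=1_000, seed=s).restarts
            for s in range(8)
        ]
        assert all(r >= 0 for r in restarts)
        assert sum(restarts) > 0  # extinction of a single founder is common

    def test_extinction_without_restart_is_reported_not_raised(self):
        p = ModelParams(
            s=0.0,
            mu_sens={g: 0.0 for g in SENSITIZING_GENES},
            mu_res={d: 0.0 for d in DrugClass},
        )
        extinct_seen = False
        for seed in range(10):
            traj = simulate_until(None, p, stop_burden=10**6, seed=seed,
                                  restart_on_extinction=False)
            if traj.extinct:
                extinct_seen = True
                assert traj.final.total == 0
                assert traj.restarts == 0
        assert extinct_seen

    def test_rejects_bad_stop_burden(self, params):
        with pytest.raises(ValueError):
            simulate_until(None, params, stop_burden=0, seed=0)
        big = PopulationState(counts={CellState(): 10})
        with pytest.raises(ValueError):
            simulate_until(big, params, stop_burden=5, seed=0)

    def test_trajectory_csv_and_sidecar(self, tmp_path, params):
        traj = simulate_until(None, params, stop_burden=5_000, thresholds=[1_000],
                              seed=7)
        out = tmp_path / "traj.csv"
        traj.to_csv(out)
        frame = traj.to_frame()
        assert {"day", "total_cells", "resistant_cells", "kras"} <= set(frame.columns)
        sidecar = json.loads((tmp_path / "traj.json").read_text())
        assert sidecar["crossing_days"]["1000"] == traj.crossing_days[1_000]
        assert sidecar["restarts"] == traj.restarts


class TestGrowthTimeOracle:
    @pytest.mark.parametrize(
        "s, n0, n1, days",
        [
            (0.05, 1e9, 1e11, 94.39),
            (0.005, 1e9, 1e11, 923.4),
        ],
    )
    def test_closed_form(self, s, n0, n1, days):
        assert expected_growth_time(s, n0, n1) == pytest.approx(days, rel=1e-3)

    def test_equal_endpoints_take_zero_days(self):
        assert expected_growth_time(0.05, 1e9, 1e9) == 0.0

    def test_critical_growth_is_undefined(self):
        with pytest.raises(ValueError):
            expected_growth_time(0.0, 1e9, 1e11)

    def test_large_population_crossings_match_oracle(self):
        """Medians of the stochastic crossing gap agree with the closed form
        once the population is large enough to grow deterministically."""
        gaps = []
        for r in range(30):
            traj = simulate_until(
                None, MUTATION_FREE, stop_burden=10**8,
                thresholds=[10**6, 10**8], seed=100 + r, record_every=10**9,
            )
            gaps.append(traj.crossing_days[10**8] - traj.crossing_days[10**6])
        oracle = expected_growth_time(0.05, 1e6, 1e8)
        assert np.median(gaps) == pytest.approx(oracle, rel=0.05)
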