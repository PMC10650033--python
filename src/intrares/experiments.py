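"""The three headline simulation experiments.

* :func:`resistance_scan` — how many drug-resistant cells a tumor carries
  at diagnosis, over a grid of diagnosis burden M (in cm³) and generic
  per-division resistance probability u_resistance;
* :func:`stage_timing` — how long an early tumor (1 cm³, 10⁹ cells) takes
  to become an advanced one (100 cm³, 10¹¹ cells), as a function of the
  selection advantage s;
* the cohort-signature experiment lives in :mod:`intrares.cohort`.

Replicate r of any scenario uses an RNG derived from (seed, scenario
index, r), so grids can be extended without reshuffling earlier cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import expected_growth_time, simulate_until
from .model import DrugClass, ModelParams

CELLS_PER_CM3 = 1e9


def generic_resistance_params(
    u_resistance: float, base: ModelParams | None = None
) -> ModelParams:
    """Model parameters with one generic resistance class at rate ``u_resistance``.

    The whole resistance probability is routed through the platinum class —
    the one class reachable from every cell state — so every cell gains one
    mechanism per division with probability exactly ``u_resistance``,
    regardless of its sensitization status.  Sensitization rates keep their
    defaults (or those of ``base``).
    """
    base = base or ModelParams.default()
    mu_res = {d: 0.0 for d in DrugClass}
    mu_res[DrugClass.PT] = u_resistance
    return ModelParams(
        s=base.s,
        mu_sens=dict(base.mu_sens),
        mu_res=mu_res,
        signature_threshold=base.signature_threshold,
        cells_per_cm3=base.cells_per_cm3,
        days_per_month=base.days_per_month,
    )


@dataclass
class ResistanceScanResult:
    """Median resistant-cell burden per (M, u_resistance) grid cell."""

    table: pd.DataFrame
    replicates: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def resistance_scan(
    m_grid_cm3: Sequence[float],
    u_grid: Sequence[float],
    s: float = 0.05,
    reps: int = 20,
    seed: int = 0,
    base: ModelParams | None = None,
) -> ResistanceScanResult:
    """Scan the resistant-cell burden at diagnosis over (M, u_resistance).

    For each grid cell, ``reps`` tumors are grown from a single cell until
    the total reaches M·10⁹ cells; the cells carrying at least one
    resistance mechanism are counted on the stopping day.  Reported per
    cell: median resistant-cell count, median resistant fraction, and
    log10(count + 1) of the median (the log-scaled heatmap value).
    """
    if not m_grid_cm3 or not u_grid:
        raise ValueError("grids must be non-empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = []
    scenario = 0
    for m_cm3 in m_grid_cm3:
        stop = int(round(m_cm3 * CELLS_PER_CM3))
        for u in u_grid:
            params = replace(generic_resistance_params(u, base), s=s)
            counts = np.empty(reps, dtype=float)
            fracs = np.empty(reps, dtype=float)
            for r in range(reps):
                rng = np.random.default_rng([seed, scenario, r])
                traj = simulate_until(
                    None, params, stop_burden=stop, rng=rng, record_every=10**9
                )
                total = traj.final.total
                resistant = traj.final.count_where(lambda st: st.is_resistant)
                counts[r] = resistant
                fracs[r] = resistant / total
            med = float(np.median(counts))
            rows.append(
                {
                    "M_cm3": m_cm3,
                    "u_resistance": u,
                    "median_resistant_cells": med,
                    "median_resistant_cm3": med / CELLS_PER_CM3,
                    "median_fraction": float(np.median(fracs)),
                    "log10p1": math.log10(med + 1.0),
                }
            )
            scenario += 1
    return ResistanceScanResult(table=pd.DataFrame(rows), replicates=reps)


@dataclass
class StageTimingResult:
    """Median (with quartiles) days between the 1 cm³ and 100 cm³ crossings."""

    table: pd.DataFrame
    replicates: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def stage_timing(
    s_grid: Sequence[float],
    reps: int = 100,
    seed: int = 0,
    *,
    early_cells: int = 10**9,
    late_cells: int = 10**11,
    base: ModelParams | None = None,
) -> StageTimingResult:
    """Elapsed time between an early and an advanced tumor, per selection
    advantage.

    Each replicate grows a tumor from a single cell and records the first
    days on which the total reaches ``early_cells`` (1 cm³) and
    ``late_cells`` (100 cm³); the elapsed difference is aggregated as
    median and quartiles, reported in days and months.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    base = base or ModelParams.default()
    rows = []
    for scenario, s in enumerate(s_grid):
        if not 0.0 < s < 1.0:
            raise ValueError(f"selection advantage must be in (0, 1), got {s}")
        params = replace(base, s=s)
        elapsed = np.empty(reps, dtype=float)
        for r in range(reps):
            rng = np.random.default_rng([seed, scenario, r])
            traj = simulate_until(
                None,
                params,
                stop_burden=late_cells,
                thresholds=[early_cells, late_cells],
                rng=rng,
                record_every=10**9,
            )
            elapsed[r] = (
                traj.crossing_days[late_cells] - traj.crossing_days[early_cells]
            )
        q1, med, q3 = np.percentile(elapsed, [25, 50, 75])
        rows.append(
            {
                "s": s,
                "median_days": float(med),
                "q1_days": float(q1),
                "q3_days": float(q3),
                "median_months": float(med) / params.days_per_month,
                "oracle_days": expected_growth_time(s, early_cells, late_cells),
            }
        )
    return StageTimingResult(table=pd.DataFrame(rows), replicates=reps)
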