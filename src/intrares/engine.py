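"""Discrete-time synchronous simulator of the branching process.

Once per day every cell, independently, either dies or divides; divisions
are synchronous (two identical daughters) or asynchronous (one parental
daughter, one daughter carrying a single new mutation).  Because cells of
the same subclone are exchangeable, the whole population is advanced per
subclone with multinomial draws rather than per cell, which keeps a
simulation to 10^11 cells cheap: the per-subclone multinomial
(death / synchronous / asynchronous) is sampled by sequential binomial
decomposition, mathematically identical to a direct multinomial draw and
exact for counts far beyond what a tumor reaches.

Populations are sparse maps from :class:`~intrares.model.CellState` to cell
count; only occupied subclones cost anything.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    CellState,
    Gene,
    ModelParams,
    SENSITIZING_GENES,
    division_probability,
    enumerate_transitions,
    total_transition_rate,
)


@dataclass
class PopulationState:
    """Sparse population: cell count per subclone, plus the current day."""

    counts: dict[CellState, int]
    day: int = 0

    @classmethod
    def single_cell(cls, state: CellState | None = None) -> "PopulationState":
        """The canonical initial condition: one founding cell.

        By default the founder carries no sensitizing mutation and no
        resistance mechanisms — it is sensitive to platinum chemotherapy
        and not (yet) targetable by any inhibitor.
        """
        return cls(counts={state or CellState(): 1}, day=0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def count_where(self, predicate) -> int:
        return sum(n for s, n in self.counts.items() if predicate(s))


class TransitionCache:
    """Per-parameter memo of each subclone's transition set.

    Stores, per :class:`CellState`: the total transition rate ``u``, the
    list of target states, and the normalized allocation probabilities.
    Only a handful of subclones are ever occupied in one run, so the cache
    stays tiny.
    """

    def __init__(self, params: ModelParams):
        self.params = params
        self._memo: dict[CellState, tuple[float, list[CellState], np.ndarray]] = {}

    def get(self, state: CellState) -> tuple[float, list[CellState], np.ndarray]:
        hit = self._memo.get(state)
        if hit is None:
            trans = enumerate_transitions(state, self.params)
            u = total_transition_rate(state, self.params)
            targets = [t.target for t in trans]
            probs = np.array([t.prob for t in trans], dtype=float)
            if u > 0:
                probs = probs / probs.sum()
            hit = (u, targets, probs)
            self._memo[state] = hit
        return hit


def step(
    pop: PopulationState,
    params: ModelParams,
    rng: np.random.Generator,
    cache: TransitionCache | None = None,
) -> PopulationState:
    """Advance the population by one day.

    For each occupied subclone with ``n`` cells, the split into deaths,
    synchronous divisions and asynchronous divisions is multinomial with
    probabilities ``(d, b(1-u), bu)``; the subclone's next-day count is
    ``2·n_sync + n_async`` (each asynchronous division keeps one parental
    daughter) and the ``n_async`` mutant daughters are allocated over the
    subclone's available transitions proportionally to their rates.  All
    subclones are updated simultaneously from the pre-step state.
    """
    if cache is None or cache.params is not params:
        cache = TransitionCache(params)
    b = division_probability(params.s)
    d = 1.0 - b

    states = list(pop.counts.keys())
    n = np.fromiter(pop.counts.values(), dtype=np.int64, count=len(states))
    cached = [cache.get(s) for s in states]
    u = np.array([c[0] for c in cached])

    n_death = rng.binomial(n, d)
    n_div = n - n_death
    # Given division, the asynchronous branch has conditional probability u.
    n_async = rng.binomial(n_div, u)
    n_sync = n_div - n_async

    new_counts: dict[CellState, int] = {}
    keep = 2 * n_sync + n_async
    for i, state in enumerate(states):
        if keep[i]:
            new_counts[state] = new_counts.get(state, 0) + int(keep[i])
        if n_async[i]:
            _, targets, probs = cached[i]
            alloc = rng.multinomial(int(n_async[i]), probs)
            for tgt, k in zip(targets, alloc):
                if k:
                    new_counts[tgt] = new_counts.get(tgt, 0) + int(k)
    return PopulationState(counts=new_counts, day=pop.day + 1)


@dataclass
class Trajectory:
    """Recorded time course of one simulation.

    ``crossing_days`` holds, per burden threshold, the first day on which
    the total reached the threshold (evaluated after the daily update; the
    initial condition counts as day 0).  When the population goes extinct
    and restarting is enabled, the recording starts over from a fresh
    founder cell and ``restarts`` counts the discarded attempts, i.e. the
    trajectory is conditioned on tumor survival.
    """

    days: list[int] = field(default_factory=list)
    totals: list[int] = field(default_factory=list)
    resistant: list[int] = field(default_factory=list)
    gene_counts: dict[Gene, list[int]] = field(
        default_factory=lambda: {g: [] for g in SENSITIZING_GENES}
    )
    crossing_days: dict[int, int] = field(default_factory=dict)
    restarts: int = 0
    extinct: bool = False
    final: PopulationState | None = None
    states_seen: set[CellState] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "day": self.days,
            "total_cells": self.totals,
            "resistant_cells": self.resistant,
        }
        for g in SENSITIZING_GENES:
            data[g.value] = self.gene_counts[g]
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        """Write the time course as CSV with a JSON sidecar for crossing
        times and the restart count."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "crossing_days": {str(k): v for k, v in self.crossing_days.items()},
            "restarts": self.restarts,
            "extinct": self.extinct,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def _snapshot(traj: Trajectory, pop: PopulationState, total: int) -> None:
    per_gene = {g: 0 for g in SENSITIZING_GENES}
    resistant = 0
    for state, n in pop.counts.items():
        if state.gene is not Gene.NONE:
            per_gene[state.gene] += n
        if state.is_resistant:
            resistant += n
    traj.days.append(pop.day)
    traj.totals.append(total)
    traj.resistant.append(resistant)
    for g in SENSITIZING_GENES:
        traj.gene_counts[g].append(per_gene[g])


def simulate_until(
    initial: PopulationState | None,
    params: ModelParams,
    stop_burden: int,
    thresholds: Sequence[int] = (),
    rng: np.random.Generator | None = None,
    *,
    restart_on_extinction: bool = True,
    record_every: int = 1,
    seed: int | None = None,
) -> Trajectory:
    """Grow the population until its total reaches ``stop_burden``.

    Starting from ``initial`` (default: a single founder cell), iterate
    daily steps until the total cell count first reaches ``stop_burden``,
    recording every ``record_every``-th day plus every threshold crossing.
    If the population dies out and ``restart_on_extinction`` is set
    (default), the run restarts from a fresh copy of the initial condition
    with the day reset to 0 — the returned trajectory is conditioned on
    non-extinction, with the number of discarded attempts in ``restarts``.
    With restarting disabled an extinct run is returned as-is with
    ``extinct=True``.
    """
    if stop_burden <= 0:
        raise ValueError(f"stop_burden must be positive, got {stop_burden}")
    if initial is None:
        initial = PopulationState.single_cell()
    if initial.total == 0:
        raise ValueError("initial population is empty")
    if stop_burden < initial.total:
        raise ValueError("stop_burden is below the initial population size")
    if rng is None:
        rng = np.random.default_rng(seed)

    cache = TransitionCache(params)
    traj = Trajectory()
    pending = sorted(set(int(t) for t in thresholds))

    def begin_attempt() -> tuple[PopulationState, list[int], int]:
        pop = PopulationState(counts=dict(initial.counts), day=initial.day)
        total = pop.total
        traj.days.clear()
        traj.totals.clear()
        traj.resistant.clear()
        for g in SENSITIZING_GENES:
            traj.gene_counts[g].clear()
        traj.crossing_days.clear()
        todo = list(pending)
        _snapshot(traj, pop, total)
        traj.states_seen.update(pop.counts)
        while todo and total >= todo[0]:
            traj.crossing_days[todo.pop(0)] = pop.day
        return pop, todo, total

    pop, todo, total = begin_attempt()
    while total < stop_burden:
        pop = step(pop, params, rng, cache)
        total = sum(pop.counts.values())
        if total == 0:
            if restart_on_extinction:
                traj.restarts += 1
                pop, todo, total = begin_attempt()
                continue
            traj.extinct = True
            _snapshot(traj, pop, total)
            break
        traj.states_seen.update(pop.counts)
        while todo and total >= todo[0]:
            traj.crossing_days[todo.pop(0)] = pop.day
        if pop.day % record_every == 0 or total >= stop_burden:
            _snapshot(traj, pop, total)
    traj.final = pop
    return traj


def expected_growth_time(s: float, n0: float, n1: float) -> float:
    """Deterministic-limit days for the population to grow from ``n0`` to
    ``n1``: ``ln(n1/n0) / ln(1+s)``.

    With daily multiplication ``1+s``, a large population's growth is
    essentially deterministic; this closed form is the oracle against which
    stochastic crossing times are checked.
    """
    if not 0.0 < s < 1.0:
        raise ValueError(f"s must be in (0, 1) for deterministic growth, got {s}")
    if not 0 < n0 <= n1:
        raise ValueError("need 0 < n0 <= n1")
    return math.log(n1 / n0) / math.log(1.0 + s)
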