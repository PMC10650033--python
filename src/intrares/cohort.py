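"""Virtual-cohort simulation and mutational-signature extraction.

Each virtual patient is grown from a single founder cell until the tumor
reaches that patient's diagnosis burden.  At diagnosis the fraction of
cells sensitized to each of the nine driver genes is computed; a gene
counts as *mutated in the patient* when its sensitized-cell fraction is at
or above the signature threshold (default 5%), giving a per-patient binary
signature over the nine genes.  Cohort-level outputs are the per-gene
percentage of patients mutated and the distribution of how many genes are
mutated per patient; model-versus-data frequency comparison uses a
two-sided two-proportion z-test per gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from .engine import PopulationState, Trajectory, simulate_until
from .model import CellState, Gene, ModelParams, SENSITIZING_GENES
from .patients import PatientProfile, StageDistribution, generate_patient


@dataclass
class PatientResult:
    """Diagnosis-day summary of one simulated patient."""

    profile: PatientProfile
    fractions: dict[Gene, float]
    signature: tuple[int, ...]
    resistant_cells: int
    resistant_fraction: float
    days_to_diagnosis: int
    restarts: int

    @property
    def signature_string(self) -> str:
        return "".join(str(b) for b in self.signature)


def extract_signature(
    fractions: Mapping[Gene, float], threshold: float
) -> tuple[int, ...]:
    """Binary signature over the nine genes, in canonical gene order.

    Bit g is 1 iff the sensitized-cell fraction of gene g is greater than
    or equal to ``threshold`` (the boundary is inclusive).
    """
    bits = []
    for g in SENSITIZING_GENES:
        f = fractions.get(g, 0.0)
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fraction for {g.name} outside [0, 1]: {f}")
        bits.append(1 if f >= threshold else 0)
    return tuple(bits)


def simulate_patient(
    profile: PatientProfile,
    params: ModelParams,
    rng: np.random.Generator,
    *,
    collect_states: set[CellState] | None = None,
) -> PatientResult:
    """Grow one tumor from a single cell to the patient's diagnosis burden
    and summarize its composition on the stopping day.

    Fractions are taken over the live cells present at the stopping day.
    ``collect_states`` (optional) accumulates every subclone occupied at
    any point of the run, for state-space audits.
    """
    traj: Trajectory = simulate_until(
        None,
        params,
        stop_burden=profile.m_diagnosis,
        rng=rng,
        record_every=10**9,
    )
    pop = traj.final
    total = pop.total
    per_gene = {g: 0 for g in SENSITIZING_GENES}
    resistant = 0
    for state, n in pop.counts.items():
        if state.gene is not Gene.NONE:
            per_gene[state.gene] += n
        if state.is_resistant:
            resistant += n
    fractions = {g: per_gene[g] / total for g in SENSITIZING_GENES}
    if collect_states is not None:
        collect_states.update(traj.states_seen)
    return PatientResult(
        profile=profile,
        fractions=fractions,
        signature=extract_signature(fractions, params.signature_threshold),
        resistant_cells=resistant,
        resistant_fraction=resistant / total,
        days_to_diagnosis=pop.day,
        restarts=traj.restarts,
    )


@dataclass
class CohortTable:
    """Results of a simulated cohort, with per-gene summary accessors."""

    results: list[PatientResult]

    def __len__(self) -> int:
        return len(self.results)

    def frequencies(self) -> pd.Series:
        """Per-gene percentage of patients with the gene mutated."""
        if not self.results:
            raise ValueError("empty cohort")
        sig = np.array([r.signature for r in self.results])
        return pd.Series(
            100.0 * sig.mean(axis=0), index=[g.value for g in SENSITIZING_GENES]
        )

    def mutated_gene_counts(self) -> pd.Series:
        """Distribution of the number of mutated genes per patient."""
        if not self.results:
            raise ValueError("empty cohort")
        counts = pd.Series([sum(r.signature) for r in self.results])
        return counts.value_counts().sort_index()

    def signature_matrix(self) -> pd.DataFrame:
        """Binary patients × genes matrix (the cohort heatmap data)."""
        return pd.DataFrame(
            [r.signature for r in self.results],
            columns=[g.value for g in SENSITIZING_GENES],
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {
                "t_stage": r.profile.t_stage,
                "diameter_cm": r.profile.diameter_cm,
                "m_diagnosis": r.profile.m_diagnosis,
                "days_to_diagnosis": r.days_to_diagnosis,
                "restarts": r.restarts,
                "resistant_cells": r.resistant_cells,
                "resistant_fraction": r.resistant_fraction,
            }
            for g in SENSITIZING_GENES:
                row[f"frac_{g.value}"] = r.fractions[g]
            for g, bit in zip(SENSITIZING_GENES, r.signature):
                row[f"bit_{g.value}"] = bit
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def cohort_frequencies(cohort: CohortTable) -> pd.Series:
    """Per-gene percentage of patients mutated (convenience wrapper)."""
    return cohort.frequencies()


def simulate_cohort(
    n_patients: int,
    params: ModelParams | None = None,
    dist: StageDistribution | None = None,
    rng: np.random.Generator | None = None,
    *,
    seed: int | None = None,
    collect_states: set[CellState] | None = None,
) -> CohortTable:
    """Simulate ``n_patients`` virtual patients to diagnosis."""
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    params = params or ModelParams.default()
    dist = dist or StageDistribution()
    if rng is None:
        rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_patients):
        profile = generate_patient(dist, params, rng)
        results.append(
            simulate_patient(profile, params, rng, collect_states=collect_states)
        )
    return CohortTable(results)


def compare_frequencies(
    model_pct: Mapping[str, float] | pd.Series,
    data_pct: Mapping[str, float] | pd.Series,
    n_model: int,
    n_data: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided two-proportion z-test per gene, model cohort versus data.

    Percentages are converted back to patient counts at the given cohort
    sizes.  Degenerate genes — both proportions 0 or both 1, where the
    pooled variance vanishes — are assigned p = 1 (no evidence of a
    difference).  ``passed`` is True when p ≥ alpha.
    """
    if n_model <= 0 or n_data <= 0:
        raise ValueError("cohort sizes must be positive")
    model_pct = pd.Series(dict(model_pct))
    data_pct = pd.Series(dict(data_pct))
    rows = []
    for gene in model_pct.index:
        pm, pd_ = float(model_pct[gene]), float(data_pct.get(gene, 0.0))
        k_model = round(pm / 100.0 * n_model)
        k_data = round(pd_ / 100.0 * n_data)
        if (k_model == 0 and k_data == 0) or (k_model == n_model and k_data == n_data):
            p_value = 1.0
        else:
            _, p_value = proportions_ztest(
                [k_model, k_data], [n_model, n_data], alternative="two-sided"
            )
        rows.append(
            {
                "gene": gene,
                "model_pct": pm,
                "data_pct": pd_,
                "p_value": float(p_value),
                "passed": bool(p_value >= alpha),
            }
        )
    return pd.DataFrame(rows)
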